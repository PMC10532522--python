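"""Synthetic CT-like thorax/heart phantoms with pixel-perfect masks.

The generator stands in for a clinical chest-CT cohort: each subject is an
axial-slice-like picture of a mid-gray thorax ellipse containing a bright
heart ellipse.  The cardiothoracic ratio (CTR) — heart width over thorax
width — controls the diagnosis: subjects with CTR >= 0.5 are "enlarged"
(cardiomegaly) and carry a bright central core labelled class 2, while
healthy subjects (CTR < 0.5) contain no class-2 pixels at all.  Ground
truth is exact by construction, so every downstream stage (feature
extraction, the voting ensemble, the metrics) can be tested without any
external download.

Intensity levels before noise: background 0.10, thorax 0.45, heart tissue
0.80, enlarged core 0.95.  The distinct core level is what makes class 2
separable from class 1 by local pixel evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import SIDE, Image224, LabelMask

# phantom geometry (pixels) and intensity levels
THORAX_CENTER = (112.0, 112.0)  # (row, col)
THORAX_SEMI = (68.0, 90.0)      # (semi-height, semi-width)
HEART_CENTER_ROW = 118.0
HEART_ASPECT = 0.75             # heart semi-height / semi-width
CORE_SCALE = 0.70               # enlarged core as a fraction of the heart
LEVEL_BG, LEVEL_THORAX, LEVEL_HEART, LEVEL_CORE = 0.10, 0.45, 0.80, 0.95
ENLARGED_CTR = 0.5              # diagnostic threshold on the ratio


@dataclass(frozen=True)
class PhantomSpec:
    """One subject: deterministic given (seed, ctr, noise_sd)."""

    seed: int
    ctr: float
    noise_sd: float = 0.0
    n_classes: int = 3

    def __post_init__(self) -> None:
        if not 0.05 < self.ctr < 0.95:
            raise ValueError(f"ctr must lie in (0.05, 0.95), got {self.ctr}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PhantomDatasetSpec:
    """A cohort; defaults mirror a 20-subject cohort with 11 enlarged."""

    n_subjects: int = 20
    n_enlarged: int = 11
    master_seed: int = 0
    ctr_healthy_range: tuple[float, float] = (0.35, 0.45)
    ctr_enlarged_range: tuple[float, float] = (0.55, 0.70)
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if not 0 <= self.n_enlarged <= self.n_subjects:
            raise ValueError("n_enlarged must be within [0, n_subjects]")
        if self.ctr_healthy_range[1] > ENLARGED_CTR:
            raise ValueError("ctr_healthy_range must stay below 0.5")
        if self.ctr_enlarged_range[0] < ENLARGED_CTR:
            raise ValueError("ctr_enlarged_range must start at/above 0.5")


@dataclass
class PhantomSubject:
    subject_id: str
    image: Image224
    mask3: LabelMask
    mask2: LabelMask
    enlarged: bool
    ctr: float = field(default=float("nan"))
    seed: int = field(default=-1)


def _ellipse(rows, cols, center, semi) -> np.ndarray:
    cr, cc = center
    sr, sc = semi
    return ((rows - cr) / sr) ** 2 + ((cols - cc) / sc) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[Image224, LabelMask]:
    """Render one phantom and its exact three-class mask."""
    rows, cols = np.mgrid[0:SIDE, 0:SIDE].astype(np.float64)

    thorax = _ellipse(rows, cols, THORAX_CENTER, THORAX_SEMI)
    heart_sw = spec.ctr * THORAX_SEMI[1]
    heart_sh = HEART_ASPECT * heart_sw
    heart_center = (HEART_CENTER_ROW, THORAX_CENTER[1])
    heart = _ellipse(rows, cols, heart_center, (heart_sh, heart_sw))

    enlarged = spec.ctr >= ENLARGED_CTR
    gray = np.full((SIDE, SIDE), LEVEL_BG)
    gray[thorax] = LEVEL_THORAX
    gray[heart] = LEVEL_HEART

    mask = np.zeros((SIDE, SIDE), dtype=np.int64)
    mask[heart] = 1
    if enlarged:
        core = _ellipse(
            rows, cols, heart_center,
            (CORE_SCALE * heart_sh, CORE_SCALE * heart_sw),
        )
        gray[core] = LEVEL_CORE
        mask[core] = 2

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        gray = gray + rng.normal(0.0, spec.noise_sd, gray.shape)
    gray = np.clip(gray, 0.0, 1.0)
    pixels = np.repeat(gray[:, :, None], 3, axis=2)
    return (
        Image224(pixels, source_id=f"phantom_{spec.seed}"),
        LabelMask(mask, n_classes=3),
    )


def generate_dataset(spec: PhantomDatasetSpec) -> list[PhantomSubject]:
    """Generate a cohort with exactly ``n_enlarged`` enlarged subjects.

    Per-subject seeds and CTR draws derive deterministically from
    ``master_seed``; the two-class mask is the indicator of class 2.
    """
    rng = np.random.default_rng(spec.master_seed)
    flags = np.zeros(spec.n_subjects, dtype=bool)
    flags[rng.permutation(spec.n_subjects)[: spec.n_enlarged]] = True

    subjects = []
    for i in range(spec.n_subjects):
        lo, hi = (
            spec.ctr_enlarged_range if flags[i] else spec.ctr_healthy_range
        )
        ctr = float(rng.uniform(lo, hi))
        seed = int(rng.integers(0, 2**31 - 1))
        image, mask3 = generate_phantom(
            PhantomSpec(seed=seed, ctr=ctr, noise_sd=spec.noise_sd)
        )
        sid = f"subject_{i:02d}"
        image.source_id = sid
        mask2 = LabelMask((mask3.classes == 2).astype(np.int64), n_classes=2)
        subjects.append(
            PhantomSubject(sid, image, mask3, mask2, bool(flags[i]), ctr, seed)
        )
    return subjects


def augment_flips(
    image: Image224, mask: LabelMask
) -> list[tuple[Image224, LabelMask]]:
    """Return [original, horizontal flip, vertical flip], masks in lockstep."""
    if mask.shape != image.pixels.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image "
            f"{image.pixels.shape[:2]}"
        )
    out = [(image, mask)]
    for axis, tag in ((1, "hflip"), (0, "vflip")):
        flipped = Image224(
            np.flip(image.pixels, axis=axis).copy(),
            source_id=f"{image.source_id}_{tag}" if image.source_id else tag,
        )
        fmask = LabelMask(
            np.flip(mask.classes, axis=axis).copy(), n_classes=mask.n_classes
        )
        out.append((flipped, fmask))
    return out
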