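"""The three-member voting ensemble that classifies pixel feature rows.

Members
-------
* Gaussian Naive Bayes — per class and feature, the mean and *population*
  standard deviation (divisor n) are estimated from the training table;
  posteriors are prior x product of Gaussian densities, evaluated in log
  space.  Standard deviations are clamped to ``sd_floor`` so constant
  features stay well-defined.
* Random forest — bagged decision trees with ``floor(log2 M) + 1``
  candidate features per split (M = number of inputs); the forest's class
  probabilities are the average of the per-tree responses.
* Regularized boosted trees — additive trees fit by the second-order
  expansion of a logistic loss with an L2 leaf-weight penalty ``lambda``
  and a per-leaf pruning penalty ``gamma``; a leaf collecting gradient sum
  G and hessian sum H gets weight -G/(H + lambda).

The combiner supports three voting rules: ``hard`` (mode of member
predictions), ``weighted`` (argmax of weighted indicator sums) and ``soft``
(argmax of the weighted average of member class probabilities, the
default).  All ties break to the lowest class index in the fixed class
order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import joblib
import numpy as np
import xgboost as xgb
from scipy.special import logsumexp
from sklearn.ensemble import RandomForestClassifier

MEMBER_NAMES = ("naive_bayes", "random_forest", "boosted_trees")
_ARCHIVE_VERSION = 1


# ---------------------------------------------------------------- Naive Bayes

def nb_pdf(x, mean, sd):
    """Gaussian probability density (1/(sqrt(2 pi) sd)) exp(-(x-m)^2/(2 sd^2))."""
    sd = np.asarray(sd, dtype=np.float64)
    if np.any(sd <= 0):
        raise ValueError("sd must be positive")
    x = np.asarray(x, dtype=np.float64)
    mean = np.asarray(mean, dtype=np.float64)
    z = (x - mean) / sd
    return np.exp(-0.5 * z * z) / (math.sqrt(2.0 * math.pi) * sd)


@dataclass
class GaussianNBModel:
    class_order: np.ndarray        # (K,) original labels, ascending
    class_priors: np.ndarray       # (K,)
    class_means: np.ndarray        # (K, C)
    class_sds: np.ndarray          # (K, C), every entry >= sd_floor
    sd_floor: float = 1e-6

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]


def fit_gaussian_nb(
    rows: np.ndarray, labels: np.ndarray, sd_floor: float = 1e-6
) -> GaussianNBModel:
    """Estimate per-class feature means/sds (population divisor) and priors."""
    rows = np.asarray(rows, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("Gaussian NB needs at least 2 classes in training")
    priors, means, sds = [], [], []
    for c in classes:
        sub = rows[labels == c]
        if len(sub) < 2:
            raise ValueError(f"class {c} needs at least 2 training rows")
        priors.append(len(sub) / len(rows))
        means.append(sub.mean(axis=0))
        sds.append(np.maximum(sub.std(axis=0, ddof=0), sd_floor))
    return GaussianNBModel(
        classes, np.array(priors), np.array(means), np.array(sds), sd_floor
    )


def nb_posterior(model: GaussianNBModel, rows: np.ndarray) -> np.ndarray:
    """Normalized per-class posteriors, computed in log space.

    Accepts a single feature row or an (n, C) matrix; returns (K,) or (n, K)
    in ``model.class_order``.
    """
    x = np.atleast_2d(np.asarray(rows, dtype=np.float64))
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"row length {x.shape[1]} != model features {model.n_features}"
        )
    # log prior + sum_f log N(x_f | mean, sd), per class
    z = (x[:, None, :] - model.class_means[None]) / model.class_sds[None]
    log_lik = (
        -0.5 * np.sum(z * z, axis=2)
        - np.sum(np.log(model.class_sds), axis=1)[None]
        - 0.5 * model.n_features * math.log(2.0 * math.pi)
    )
    log_post = np.log(model.class_priors)[None] + log_lik
    post = np.exp(log_post - logsumexp(log_post, axis=1, keepdims=True))
    return post[0] if np.ndim(rows) == 1 else post


# --------------------------------------------------------------- Random forest

def features_per_split(n_features: int) -> int:
    """floor(log2 M) + 1 candidate features per split."""
    return int(math.floor(math.log2(n_features))) + 1


@dataclass
class ForestModel:
    clf: RandomForestClassifier
    class_order: np.ndarray
    n_trees: int
    seed: int

    @property
    def features_per_split(self) -> int:
        return self.clf.max_features


def fit_forest(
    rows: np.ndarray, labels: np.ndarray, n_trees: int = 25, seed: int = 0
) -> ForestModel:
    """Bootstrap-bagged trees; deterministic under ``seed``."""
    rows = np.asarray(rows, dtype=np.float64)
    labels = np.asarray(labels)
    if len(rows) == 0:
        raise ValueError("cannot fit a forest on an empty frame")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    class_order = np.unique(labels)
    y = np.searchsorted(class_order, labels)
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=features_per_split(rows.shape[1]),
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(rows, y)
    return ForestModel(clf, class_order, n_trees, seed)


def forest_predict(model: ForestModel, rows: np.ndarray) -> np.ndarray:
    """Average of the per-tree class-probability responses, (n, K)."""
    return model.clf.predict_proba(np.atleast_2d(np.asarray(rows, float)))


# --------------------------------------------------------------- Boosted trees

@dataclass
class BoostedModel:
    booster: xgb.Booster
    class_order: np.ndarray
    n_rounds: int
    learning_rate: float
    lambda_reg: float
    gamma_penalty: float
    base_score: float
    seed: int

    @property
    def is_multiclass(self) -> bool:
        return len(self.class_order) > 2

    def predict_proba(
        self, rows: np.ndarray, n_rounds: int | None = None
    ) -> np.ndarray:
        d = xgb.DMatrix(np.atleast_2d(np.asarray(rows, np.float64)))
        rng = (0, n_rounds if n_rounds is not None else self.n_rounds)
        raw = self.booster.predict(d, iteration_range=rng)
        if raw.ndim == 1:  # binary: probability of class_order[1]
            return np.column_stack([1.0 - raw, raw])
        return raw

    def predict_margin(self, rows: np.ndarray) -> np.ndarray:
        d = xgb.DMatrix(np.atleast_2d(np.asarray(rows, np.float64)))
        return self.booster.predict(d, output_margin=True)

    def staged_logloss(self, rows: np.ndarray, labels: np.ndarray) -> np.ndarray:
        """Mean logistic loss after each boosting round (training curve)."""
        y = np.searchsorted(self.class_order, np.asarray(labels))
        losses = []
        for r in range(1, self.n_rounds + 1):
            p = np.clip(self.predict_proba(rows, n_rounds=r), 1e-12, 1.0)
            losses.append(-np.mean(np.log(p[np.arange(len(y)), y])))
        return np.array(losses)


def fit_boosted(
    rows: np.ndarray,
    labels: np.ndarray,
    n_rounds: int = 30,
    learning_rate: float = 0.3,
    lambda_reg: float = 1.0,
    gamma_penalty: float = 0.0,
    seed: int = 0,
    base_score: float = 0.5,
    max_depth: int = 6,
    n_classes: int | None = None,
) -> BoostedModel:
    """Gradient-boosted trees on the second-order logistic objective.

    Two classes use a single logistic model; more use the softmax
    multi-class objective with the same regularized tree machinery.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    if lambda_reg < 0 or gamma_penalty < 0:
        raise ValueError("lambda and gamma penalties must be >= 0")
    rows = np.asarray(rows, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if n_classes is not None and n_classes > classes.size:
        classes = np.arange(n_classes)
    elif classes.size == 1:
        # degenerate single-class frame on the binary {0,1} domain
        if classes[0] not in (0, 1):
            raise ValueError("single-class boosting requires labels in {0,1}")
        classes = np.array([0, 1])
    y = np.searchsorted(classes, labels)
    params = {
        "eta": learning_rate,
        "reg_lambda": lambda_reg,
        "gamma": gamma_penalty,
        "max_depth": max_depth,
        "base_score": base_score,
        "tree_method": "hist",
        "nthread": 1,
        "seed": seed,
    }
    if classes.size > 2:
        params.update(objective="multi:softprob", num_class=int(classes.size))
    else:
        params.update(objective="binary:logistic")
    booster = xgb.train(
        params, xgb.DMatrix(rows, label=y), num_boost_round=n_rounds
    )
    return BoostedModel(
        booster, classes, n_rounds, learning_rate, lambda_reg,
        gamma_penalty, base_score, seed,
    )


# -------------------------------------------------------------------- Voting

@dataclass
class VotingConfig:
    mode: str = "soft"             # hard | weighted | soft
    weights: np.ndarray = field(default_factory=lambda: np.ones(3))
    members: tuple[str, ...] = MEMBER_NAMES

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.mode not in ("hard", "weighted", "soft"):
            raise ValueError(f"unknown voting mode {self.mode!r}")
        if len(self.weights) != len(self.members):
            raise ValueError("one weight per member required")
        if np.any(self.weights < 0) or not np.any(self.weights > 0):
            raise ValueError("weights must be >= 0 and not all zero")


def _member_matrix(member_labels) -> tuple[np.ndarray, bool]:
    """Normalize to shape (n_members, n_items); flag single-item input."""
    labels = np.asarray(member_labels)
    if labels.ndim == 1:
        return labels[:, None], True
    return labels, False


def _count_votes(
    labels: np.ndarray, class_order: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Weighted indicator sums over members, shape (n_items, K)."""
    counts = np.zeros((labels.shape[1], len(class_order)))
    for j, w in enumerate(weights):
        counts += w * (labels[j][:, None] == class_order[None, :])
    return counts


def vote_hard(member_labels, class_order) -> np.ndarray:
    """Mode of member predictions; ties to the lowest class index."""
    class_order = np.asarray(class_order)
    labels, single = _member_matrix(member_labels)
    counts = _count_votes(labels, class_order, np.ones(labels.shape[0]))
    out = class_order[counts.argmax(axis=1)]
    return out[0] if single else out


def vote_weighted(member_labels, weights, class_order) -> np.ndarray:
    """argmax_i sum_j w_j * [C_j(x) = i]; ties to the lowest class index."""
    labels, single = _member_matrix(member_labels)
    weights = np.asarray(weights, dtype=np.float64)
    if labels.shape[0] != len(weights):
        raise ValueError("one weight per member required")
    class_order = np.asarray(class_order)
    counts = _count_votes(labels, class_order, weights)
    out = class_order[counts.argmax(axis=1)]
    return out[0] if single else out


def vote_soft(member_probs, weights, class_order=None):
    """Weighted average of member class probabilities, then argmax.

    ``member_probs`` is (m, K) for one item or (m, n, K) for a batch; each
    member row must be a valid distribution (sum 1 within 1e-6).
    Returns ``(classes, combined_probs)``.
    """
    probs = np.asarray(member_probs, dtype=np.float64)
    single = probs.ndim == 2
    if single:
        probs = probs[:, None, :]
    weights = np.asarray(weights, dtype=np.float64)
    if probs.shape[0] != len(weights):
        raise ValueError("one weight per member required")
    if np.any(probs < -1e-12) or np.any(
        np.abs(probs.sum(axis=2) - 1.0) > 1e-6
    ):
        raise ValueError("member probabilities must each sum to 1")
    combined = np.tensordot(weights, probs, axes=(0, 0)) / weights.sum()
    idx = combined.argmax(axis=1)
    if class_order is None:
        class_order = np.arange(probs.shape[2])
    classes = np.asarray(class_order)[idx]
    if single:
        return classes[0], combined[0]
    return classes, combined


# ------------------------------------------------------------------- Ensemble

@dataclass
class EnsembleConfig:
    voting_mode: str = "soft"
    weights: tuple[float, ...] = (1.0, 1.0, 1.0)
    sd_floor: float = 1e-6
    n_trees: int = 25
    forest_seed: int = 0
    n_rounds: int = 30
    learning_rate: float = 0.3
    lambda_reg: float = 1.0
    gamma_penalty: float = 0.0
    boost_seed: int = 0
    max_depth: int = 6


@dataclass
class TrainedEnsemble:
    nb: GaussianNBModel
    forest: ForestModel
    boosted: BoostedModel
    voting: VotingConfig
    class_order: np.ndarray
    bank_fingerprint: str | None = None


def fit_ensemble(
    rows: np.ndarray, labels: np.ndarray, config: EnsembleConfig | None = None
) -> TrainedEnsemble:
    """Fit all three members on the same labeled pixel-feature table."""
    config = config or EnsembleConfig()
    rows = np.asarray(rows, dtype=np.float64)
    labels = np.asarray(labels)
    class_order = np.unique(labels)
    if class_order.size < 2:
        raise ValueError("ensemble training needs at least 2 classes")
    nb = fit_gaussian_nb(rows, labels, sd_floor=config.sd_floor)
    forest = fit_forest(
        rows, labels, n_trees=config.n_trees, seed=config.forest_seed
    )
    boosted = fit_boosted(
        rows,
        labels,
        n_rounds=config.n_rounds,
        learning_rate=config.learning_rate,
        lambda_reg=config.lambda_reg,
        gamma_penalty=config.gamma_penalty,
        seed=config.boost_seed,
        max_depth=config.max_depth,
    )
    voting = VotingConfig(mode=config.voting_mode, weights=config.weights)
    return TrainedEnsemble(nb, forest, boosted, voting, class_order)


def member_probabilities(
    model: TrainedEnsemble, rows: np.ndarray
) -> np.ndarray:
    """Stack of member class-probability matrices, shape (3, n, K)."""
    rows = np.atleast_2d(np.asarray(rows, dtype=np.float64))
    if rows.shape[1] != model.nb.n_features:
        raise ValueError(
            f"feature count {rows.shape[1]} != training "
            f"{model.nb.n_features}"
        )
    return np.stack([
        nb_posterior(model.nb, rows),
        forest_predict(model.forest, rows),
        model.boosted.predict_proba(rows),
    ])


def ensemble_predict(
    model: TrainedEnsemble, rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row voted class and combined class probabilities."""
    probs = member_probabilities(model, rows)
    co = model.class_order
    w = model.voting.weights
    if model.voting.mode == "soft":
        classes, combined = vote_soft(probs, w, class_order=co)
    else:
        member_labels = co[probs.argmax(axis=2)]
        if model.voting.mode == "hard":
            classes = vote_hard(member_labels, co)
        else:
            classes = vote_weighted(member_labels, w, co)
        combined = np.tensordot(w, probs, axes=(0, 0)) / w.sum()
    return classes, combined


def save_ensemble(model: TrainedEnsemble, path) -> None:
    """Persist a trained ensemble as a single versioned archive."""
    joblib.dump({"format_version": _ARCHIVE_VERSION, "ensemble": model}, path)


def load_ensemble(path) -> TrainedEnsemble:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != _ARCHIVE_VERSION:
        raise ValueError(
            f"unsupported ensemble archive version {version!r}"
        )
    return payload["ensemble"]
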