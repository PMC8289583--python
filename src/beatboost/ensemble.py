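"""AdaBoost with random-forest base learners for imbalanced heartbeats.

The boosting recursion, per round m over N training samples with
weights w summing to 1:

    e_m     = sum_j w_j * [G_m(x_j) != y_j]           (weighted error)
    alpha_m = 1/2 * ln((1 - e_m) / e_m)               (learner weight)
    w'_i    = w_i / z_m * exp(-alpha_m * s_i),  s_i = +1 if correct,
                                                       -1 if wrong
    z_m such that sum_i w'_i = 1.

A round whose base learner errs on more than half the weight is
discarded: the weights are reset to uniform, a fresh bootstrap is
drawn, and the round is retried (bounded retries).  The final
classifier is the alpha-weighted vote over base learners — for the
binary +/-1 case this reduces exactly to the sign of the weighted sum,
and for K classes it is the SAMME-style argmax of per-class alpha
totals (ties broken by canonical class order N, S, V, F, Q).

Class imbalance is handled at the bootstrap level: every class whose
size falls below the balanced share (N / n_classes) is included in
full each round, and the remainder of the bootstrap is drawn from the
larger classes in proportion to the current sample weights.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from beatboost.evaluate import AAMI_CLASSES

__all__ = [
    "AdaBoostConfig",
    "AdaBoostModel",
    "TrainingError",
    "alpha",
    "fit",
    "load_model",
    "predict",
    "resample_round",
    "save_model",
    "update_weights",
    "weighted_error",
]

ARCHIVE_VERSION = 1


class TrainingError(RuntimeError):
    pass


def weighted_error(predictions, labels, weights) -> float:
    """e_m: total weight on misclassified samples (weights must sum to 1)."""
    predictions = np.asarray(predictions, dtype=object)
    labels = np.asarray(labels, dtype=object)
    weights = np.asarray(weights, dtype=float)
    if not (len(predictions) == len(labels) == len(weights)):
        raise ValueError("predictions, labels and weights must align")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {weights.sum()}, expected 1")
    return float(weights[predictions != labels].sum())


def alpha(e_m: float, clamp: float = 1e-10) -> float:
    """Learner weight 1/2*ln((1-e)/e), with e clamped away from {0, 1}."""
    e = min(max(e_m, clamp), 1.0 - clamp)
    return 0.5 * math.log((1.0 - e) / e)


def update_weights(weights, correct: np.ndarray, alpha_m: float) -> np.ndarray:
    """Reweight: exp(-alpha) on correct, exp(+alpha) on wrong, normalize."""
    w = np.asarray(weights, dtype=float)
    sign = np.where(np.asarray(correct, dtype=bool), -1.0, 1.0)
    w_new = w * np.exp(alpha_m * sign)
    z = w_new.sum()
    if z <= 0 or not np.isfinite(z):
        raise TrainingError("degenerate weights: normalizer z_m is zero")
    return w_new / z


def resample_round(
    labels,
    rng: np.random.Generator,
    balanced: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Reset weights to uniform and draw a fresh bootstrap.

    Returns ``(uniform_weights, bootstrap_indices)``; used after a
    round whose weighted error exceeded 0.5.
    """
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    w = np.full(n, 1.0 / n)
    idx = _draw_bootstrap(labels, w, rng, balanced)
    return w, idx


def _draw_bootstrap(
    labels: np.ndarray,
    weights: np.ndarray,
    rng: np.random.Generator,
    balanced: bool,
) -> np.ndarray:
    n = len(labels)
    if not balanced:
        return rng.choice(n, size=n, replace=True, p=weights)
    classes, counts = np.unique(labels, return_counts=True)
    threshold = n / len(classes)
    minority = {c for c, k in zip(classes, counts) if k < threshold}
    keep = np.nonzero(np.isin(labels, list(minority)))[0] if minority else np.array([], dtype=int)
    pool = np.nonzero(~np.isin(labels, list(minority)))[0]
    n_rest = n - len(keep)
    if len(pool) == 0:
        return rng.choice(n, size=n, replace=True, p=weights)
    p = weights[pool]
    total = p.sum()
    p = np.full(len(pool), 1.0 / len(pool)) if total <= 0 else p / total
    drawn = rng.choice(pool, size=n_rest, replace=True, p=p)
    return np.sort(np.concatenate([keep, drawn]))


def _class_order(y: np.ndarray) -> list:
    present = set(y)
    if present <= set(AAMI_CLASSES):
        return [c for c in AAMI_CLASSES if c in present]
    # stable first-appearance order for non-AAMI label sets
    return list(dict.fromkeys(y))


@dataclass(frozen=True)
class AdaBoostConfig:
    rounds: int = 10
    n_estimators: int = 70
    seed: int = 0
    clamp: float = 1e-10
    max_resample_retries: int = 5
    balanced_bootstrap: bool = True
    #: fit base learners on a weighted bootstrap (True) or directly on
    #: the full set with sample weights (False; used for oracle checks)
    bootstrap: bool = True
    base_learner: str | Callable[[int], object] = "forest"
    one_vs_rest: bool = False
    rf_params: dict = field(default_factory=dict)

    def make_learner(self, random_state: int):
        if callable(self.base_learner):
            return self.base_learner(random_state)
        if self.base_learner == "forest":
            return RandomForestClassifier(
                n_estimators=self.n_estimators,
                random_state=random_state,
                n_jobs=1,
                **self.rf_params,
            )
        if self.base_learner == "stump":
            return DecisionTreeClassifier(max_depth=1, random_state=random_state)
        raise ValueError(f"unknown base learner {self.base_learner!r}")


@dataclass
class AdaBoostModel:
    base_learners: list
    alphas: list[float]
    classes: list
    config: AdaBoostConfig
    errors: list[float] = field(default_factory=list)
    weight_history: list[np.ndarray] | None = None
    submodels: list | None = None  # one-vs-rest mode

    def __post_init__(self) -> None:
        if self.submodels is None and len(self.base_learners) != len(self.alphas):
            raise ValueError("one alpha per base learner required")


def fit(
    X,
    y,
    config: AdaBoostConfig = AdaBoostConfig(),
    keep_history: bool = False,
) -> AdaBoostModel:
    """Train the boosted ensemble; deterministic under ``config.seed``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if config.rounds < 1:
        raise ValueError("rounds must be >= 1")
    classes = _class_order(y)
    if len(classes) < 2:
        raise TrainingError("training set must contain at least two classes")

    if config.one_vs_rest:
        subs = []
        for k, c in enumerate(classes):
            y_bin = np.where(y == c, "pos", "neg").astype(object)
            sub_cfg = AdaBoostConfig(
                **{
                    **config.__dict__,
                    "one_vs_rest": False,
                    "seed": config.seed + 7919 * (k + 1),
                }
            )
            subs.append(fit(X, y_bin, sub_cfg))
        return AdaBoostModel(
            base_learners=[], alphas=[], classes=classes, config=config,
            submodels=subs,
        )

    rng = np.random.default_rng(config.seed)
    n = len(y)
    w = np.full(n, 1.0 / n)
    learners: list = []
    alphas: list[float] = []
    errors: list[float] = []
    history: list[np.ndarray] = [w.copy()] if keep_history else []

    m = 0
    retries = 0
    while m < config.rounds:
        learner = config.make_learner(int(rng.integers(2**31 - 1)))
        if config.bootstrap:
            idx = _draw_bootstrap(y, w, rng, config.balanced_bootstrap)
            learner.fit(X[idx], y[idx])
        else:
            learner.fit(X, y, sample_weight=w * n)
        pred = learner.predict(X).astype(object)
        e_m = weighted_error(pred, y, w)
        if e_m > 0.5:
            retries += 1
            if retries > config.max_resample_retries:
                raise TrainingError(
                    f"round {m + 1}: base learner error {e_m:.3f} > 0.5 after "
                    f"{config.max_resample_retries} resampling retries"
                )
            w, _ = resample_round(y, rng, config.balanced_bootstrap)
            continue
        retries = 0
        a = alpha(e_m, config.clamp)
        w = update_weights(w, pred == y, a)
        learners.append(learner)
        alphas.append(a)
        errors.append(e_m)
        if keep_history:
            history.append(w.copy())
        m += 1

    return AdaBoostModel(
        base_learners=learners,
        alphas=alphas,
        classes=classes,
        config=config,
        errors=errors,
        weight_history=history if keep_history else None,
    )


def _vote_scores(model: AdaBoostModel, X: np.ndarray) -> np.ndarray:
    scores = np.zeros((len(X), len(model.classes)))
    for learner, a in zip(model.base_learners, model.alphas):
        pred = np.asarray(learner.predict(X), dtype=object)
        for j, c in enumerate(model.classes):
            scores[pred == c, j] += a
    return scores


def predict(model: AdaBoostModel, rows) -> np.ndarray:
    """Alpha-weighted vote; ties resolved toward the earlier class."""
    X = np.asarray(rows, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if model.submodels is not None:
        margins = np.column_stack(
            [
                _vote_scores(sub, X)[:, sub.classes.index("pos")]
                - _vote_scores(sub, X)[:, sub.classes.index("neg")]
                for sub in model.submodels
            ]
        )
        return np.array(model.classes, dtype=object)[np.argmax(margins, axis=1)]
    first = model.base_learners[0]
    expected = getattr(first, "n_features_in_", X.shape[1])
    if X.shape[1] != expected:
        raise ValueError(
            f"feature count {X.shape[1]} does not match training ({expected})"
        )
    scores = _vote_scores(model, X)
    # argmax returns the first maximum, i.e. the earlier class on ties
    return np.array(model.classes, dtype=object)[np.argmax(scores, axis=1)]


def save_model(model: AdaBoostModel, path) -> None:
    """Persist as a versioned pickle archive (config + forests)."""
    payload = {
        "format_version": ARCHIVE_VERSION,
        "config": model.config,
        "classes": model.classes,
        "alphas": model.alphas,
        "errors": model.errors,
        "base_learners": model.base_learners,
        "submodels": model.submodels,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> AdaBoostModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != ARCHIVE_VERSION:
        raise ValueError(f"unsupported model archive version in {path}")
    return AdaBoostModel(
        base_learners=payload["base_learners"],
        alphas=payload["alphas"],
        classes=payload["classes"],
        config=payload["config"],
        errors=payload["errors"],
        submodels=payload["submodels"],
    )
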