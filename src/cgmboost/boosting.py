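"""From-scratch binary AdaBoost variants over decision stumps and blocks.

Four ensemble trainers share one model container:

* :func:`train_discrete` — classical AdaBoost: each round fits the
  weighted-error-minimizing decision stump h_t ∈ {−1, +1}, weighs it by
  α_t = ½·ln((1−ε_t)/ε_t) and reweights the samples multiplicatively.
* :func:`train_real` — Real AdaBoost (Schapire–Singer): per feature the
  value range is split into disjoint blocks; each block emits the
  half-log-odds of the weighted class masses, and the feature minimizing
  the normalizer z = 2·Σ_j √(p₊ʲ p₋ʲ) is kept.
* :func:`train_gentle` — Gentle AdaBoost: a regression stump fit by
  weighted least squares of y on x (each side outputs the weighted mean
  label), chosen to minimize weighted squared error.
* :func:`train_modest` — Modest AdaBoost: block responses
  f_j = P₊ʲ(1−P̄₊ʲ) − P₋ʲ(1−P̄₋ʲ), where P uses the sample weights D and
  P̄ uses the inverted distribution D̄ ∝ 1−D, damping contributions from
  regions the ensemble already handles; responses are bounded in [−1, 1].

Labels are +1/−1; the final classifier is sign(Σ_t α_t h_t(x)) with
sign(0) → +1 (a documented, deterministic tie rule).  Training is fully
deterministic: stump ties break on (lowest feature index, lowest
threshold, positive polarity first).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError

logger = logging.getLogger(__name__)

VARIANTS = ("discrete", "real", "gentle", "modest")

#: Floor applied to a zero training error before taking the log for α.
EPS_FLOOR = 1e-10

#: Best-gain threshold below which Modest AdaBoost stops adding learners.
MODEST_GAIN_TOL = 1e-12


# ---------------------------------------------------------------------------
# weak learners
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Stump:
    """Binary decision stump: ``polarity`` where x > threshold, else −polarity."""

    feature_index: int
    threshold: float
    polarity: int

    def response(self, X: np.ndarray) -> np.ndarray:
        above = X[:, self.feature_index] > self.threshold
        return np.where(above, float(self.polarity), float(-self.polarity))


@dataclass(frozen=True)
class RegressionStump:
    """Real-valued stump used by Gentle AdaBoost (per-side weighted means)."""

    feature_index: int
    threshold: float
    left_value: float
    right_value: float

    def response(self, X: np.ndarray) -> np.ndarray:
        above = X[:, self.feature_index] > self.threshold
        return np.where(above, self.right_value, self.left_value)


@dataclass(frozen=True)
class BlockLearner:
    """Piecewise-constant learner over disjoint blocks of one feature.

    ``bin_edges`` are the interior cut points; a value lands in block
    ``searchsorted(bin_edges, x, side="right")``, so blocks are disjoint
    and exhaustive over the real line.
    """

    feature_index: int
    bin_edges: tuple[float, ...]
    bin_outputs: tuple[float, ...]

    def response(self, X: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(np.asarray(self.bin_edges), X[:, self.feature_index],
                              side="right")
        return np.asarray(self.bin_outputs, dtype=float)[idx]


@dataclass
class BoostModel:
    """An ordered ensemble of weak learners with combination weights.

    ``alphas`` hold the discrete-AdaBoost round weights α_t; for the
    real-valued variants every α_t is 1 and the learner responses carry the
    scale.  Diagnostic per-round quantities (ε_t for discrete, z_t for
    Real) are kept for analysis and for the classical error bounds.
    """

    variant: str
    learners: list
    alphas: np.ndarray
    n_features: int
    feature_names: tuple[str, ...] | None = None
    epsilons: tuple[float, ...] = ()
    z_values: tuple[float, ...] = ()
    stopped_early: bool = False
    weight_history: list = field(default_factory=list, repr=False)

    @property
    def n_rounds(self) -> int:
        return len(self.learners)

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise DataError(
                f"model expects {self.n_features} features, got {X.shape[1]}"
            )
        return X

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Signed ensemble score Σ_t α_t h_t(x)."""
        X = self._check_X(X)
        score = np.zeros(X.shape[0])
        for alpha, learner in zip(self.alphas, self.learners):
            score += alpha * learner.response(X)
        return score

    def staged_scores(self, X: np.ndarray) -> np.ndarray:
        """Cumulative scores after each round, shape ``(n_rounds, n)``."""
        X = self._check_X(X)
        stages = np.empty((self.n_rounds, X.shape[0]))
        score = np.zeros(X.shape[0])
        for t, (alpha, learner) in enumerate(zip(self.alphas, self.learners)):
            score = score + alpha * learner.response(X)
            stages[t] = score
        return stages


def predict(model: BoostModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (labels, scores); score 0 maps to the +1 label."""
    scores = model.decision_function(X)
    return np.where(scores >= 0, 1, -1), scores


def staged_errors(model: BoostModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Misclassification rate using only the first t learners, t = 1..T."""
    y = np.asarray(y)
    stages = model.staged_scores(X)
    labels = np.where(stages >= 0, 1, -1)
    return np.mean(labels != y[None, :], axis=1)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _validate_training_set(X, y, T: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise DataError(f"X shape {X.shape} incompatible with y shape {y.shape}")
    if X.shape[0] < 2:
        raise DataError("need at least two training samples")
    if not np.all(np.isfinite(X)):
        raise DataError("training features contain non-finite values")
    if not np.all(np.isin(y, (-1, 1))):
        raise DataError("labels must be +1 or -1")
    if np.unique(y).size < 2:
        raise DataError("training set must contain both classes")
    if T < 1:
        raise DataError("number of boosting rounds T must be >= 1")
    return X, y.astype(int)


def _best_stump(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> Stump:
    """Exhaustive weighted-error-minimizing stump over all features.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values; ties break on (lowest feature index, lowest threshold,
    positive polarity).
    """
    best_err = np.inf
    best: Stump | None = None
    total = w.sum()
    for f in range(X.shape[1]):
        order = np.argsort(X[:, f], kind="stable")
        xs, ys, ws = X[order, f], y[order], w[order]
        cut = np.flatnonzero(xs[:-1] < xs[1:])
        if cut.size == 0:
            continue
        cum_pos = np.cumsum(ws * (ys == 1))
        cum_neg = np.cumsum(ws * (ys == -1))
        thresholds = 0.5 * (xs[cut] + xs[cut + 1])
        # polarity +1 predicts +1 above the threshold, -1 at or below it
        err_plus = cum_pos[cut] + (cum_neg[-1] - cum_neg[cut])
        for polarity, errs in ((1, err_plus), (-1, total - err_plus)):
            k = int(np.argmin(errs))  # first minimum → lowest threshold
            if errs[k] < best_err:
                best_err = float(errs[k])
                best = Stump(f, float(thresholds[k]), polarity)
    if best is None:
        raise DataError("all features are constant; no stump can split the data")
    return best


def _equal_frequency_edges(x: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.quantile(x, np.linspace(0.0, 1.0, n_bins + 1)[1:-1])
    return np.unique(qs)


def _precompute_bins(X: np.ndarray, n_bins: int) -> tuple[list[np.ndarray], list[np.ndarray]]:
    if n_bins < 2:
        raise DataError("n_bins must be >= 2")
    edges = [_equal_frequency_edges(X[:, f], n_bins) for f in range(X.shape[1])]
    assignments = [
        np.searchsorted(edges[f], X[:, f], side="right") for f in range(X.shape[1])
    ]
    return edges, assignments


def _class_masses(bins_f: np.ndarray, n_blocks: int, w: np.ndarray,
                  y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p_pos = np.bincount(bins_f, weights=w * (y == 1), minlength=n_blocks)
    p_neg = np.bincount(bins_f, weights=w * (y == -1), minlength=n_blocks)
    return p_pos, p_neg


# ---------------------------------------------------------------------------
# trainers
# ---------------------------------------------------------------------------


def train_discrete(
    X,
    y,
    T: int = 100,
    *,
    feature_names: Sequence[str] | None = None,
    record_weights: bool = False,
) -> BoostModel:
    """Classical (discrete) AdaBoost over decision stumps.

    A perfect round (ε_t = 0) gets its α through the floored error
    ``max(ε, 1e-10)`` and training halts early, since the remaining weight
    update would be degenerate.
    """
    X, y = _validate_training_set(X, y, T)
    m = X.shape[0]
    w = np.full(m, 1.0 / m)
    model = BoostModel("discrete", [], np.array([]), X.shape[1],
                       feature_names=tuple(feature_names) if feature_names else None)
    epsilons: list[float] = []
    alphas: list[float] = []
    for t in range(T):
        stump = _best_stump(X, y, w)
        h = stump.response(X)
        eps = float(w[h != y].sum())
        # the polarity flip in the stump search makes ε > 1/2 unreachable
        assert eps <= 0.5 + 1e-12, f"round {t}: ε = {eps} > 1/2"
        epsilons.append(eps)
        eps_eff = max(eps, EPS_FLOOR)
        alpha = 0.5 * np.log((1.0 - eps_eff) / eps_eff)
        model.learners.append(stump)
        alphas.append(alpha)
        w = w * np.exp(-alpha * y * h)
        w /= w.sum()
        if record_weights:
            model.weight_history.append(w.copy())
        if eps == 0.0:
            logger.info("discrete AdaBoost: perfect stump at round %d, stopping", t + 1)
            model.stopped_early = True
            break
    model.alphas = np.array(alphas)
    model.epsilons = tuple(epsilons)
    return model


def train_real(
    X,
    y,
    T: int = 100,
    n_bins: int = 8,
    *,
    feature_names: Sequence[str] | None = None,
    record_weights: bool = False,
) -> BoostModel:
    """Real AdaBoost with per-feature equal-frequency block partitions.

    Block outputs are ½·log(p₊ʲ/p₋ʲ) with Schapire–Singer smoothing
    p ← (p + ε_s)/(1 + 2ε_s), ε_s = 1/(4m); an empty block therefore
    outputs exactly 0.  Each round keeps the feature minimizing
    z = 2·Σ_j √(p₊ʲ p₋ʲ).
    """
    X, y = _validate_training_set(X, y, T)
    m = X.shape[0]
    edges, assignments = _precompute_bins(X, n_bins)
    eps_s = 1.0 / (4.0 * m)
    w = np.full(m, 1.0 / m)
    model = BoostModel("real", [], np.array([]), X.shape[1],
                       feature_names=tuple(feature_names) if feature_names else None)
    zs: list[float] = []
    for _ in range(T):
        best_z, best_f = np.inf, -1
        for f in range(X.shape[1]):
            p_pos, p_neg = _class_masses(assignments[f], len(edges[f]) + 1, w, y)
            z = 2.0 * float(np.sum(np.sqrt(p_pos * p_neg)))
            if z < best_z:
                best_z, best_f = z, f
        p_pos, p_neg = _class_masses(assignments[best_f], len(edges[best_f]) + 1, w, y)
        outputs = 0.5 * np.log((p_pos + eps_s) / (p_neg + eps_s))
        learner = BlockLearner(best_f, tuple(edges[best_f]), tuple(outputs))
        model.learners.append(learner)
        zs.append(best_z)
        h = outputs[assignments[best_f]]
        w = w * np.exp(-y * h)
        w /= w.sum()
        if record_weights:
            model.weight_history.append(w.copy())
    model.alphas = np.ones(len(model.learners))
    model.z_values = tuple(zs)
    return model


def fit_regression_stump(X, y, w) -> RegressionStump:
    """Weighted-least-squares regression stump (the Gentle base learner).

    Each candidate split's side outputs are the weighted mean of y on that
    side; the split maximizing the weighted sum-of-squares reduction is
    kept.  A side carrying zero total weight outputs 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    best_gain = -np.inf
    best: RegressionStump | None = None
    s_tot = float(np.sum(w * y))
    w_tot = float(np.sum(w))
    for f in range(X.shape[1]):
        order = np.argsort(X[:, f], kind="stable")
        xs, ys, ws = X[order, f], y[order], w[order]
        cut = np.flatnonzero(xs[:-1] < xs[1:])
        if cut.size == 0:
            continue
        w_left = np.cumsum(ws)[cut]
        s_left = np.cumsum(ws * ys)[cut]
        w_right = w_tot - w_left
        s_right = s_tot - s_left
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = np.where(w_left > 0, s_left**2 / w_left, 0.0) + np.where(
                w_right > 0, s_right**2 / w_right, 0.0
            )
        k = int(np.argmax(gain))
        if gain[k] > best_gain:
            best_gain = float(gain[k])
            left = float(s_left[k] / w_left[k]) if w_left[k] > 0 else 0.0
            right = float(s_right[k] / w_right[k]) if w_right[k] > 0 else 0.0
            threshold = 0.5 * (xs[cut[k]] + xs[cut[k] + 1])
            best = RegressionStump(f, float(threshold), left, right)
    if best is None:
        raise DataError("all features are constant; no stump can split the data")
    return best


def train_gentle(
    X,
    y,
    T: int = 100,
    *,
    feature_names: Sequence[str] | None = None,
    record_weights: bool = False,
) -> BoostModel:
    """Gentle AdaBoost: weighted least-squares regression stumps."""
    X, y = _validate_training_set(X, y, T)
    m = X.shape[0]
    w = np.full(m, 1.0 / m)
    model = BoostModel("gentle", [], np.array([]), X.shape[1],
                       feature_names=tuple(feature_names) if feature_names else None)
    for _ in range(T):
        stump = fit_regression_stump(X, y.astype(float), w)
        model.learners.append(stump)
        h = stump.response(X)
        w = w * np.exp(-y * h)
        w /= w.sum()
        if record_weights:
            model.weight_history.append(w.copy())
    model.alphas = np.ones(len(model.learners))
    return model


def modest_block_outputs(
    bins_f: np.ndarray, n_blocks: int, w: np.ndarray, w_inv: np.ndarray,
    y: np.ndarray
) -> np.ndarray:
    """Modest-AdaBoost block responses f_j = P₊(1−P̄₊) − P₋(1−P̄₋).

    ``w`` is the boosting distribution D and ``w_inv`` the normalized
    inverted distribution D̄ ∝ 1−D; each response lies in [−1, 1].
    """
    p_pos, p_neg = _class_masses(bins_f, n_blocks, w, y)
    pbar_pos, pbar_neg = _class_masses(bins_f, n_blocks, w_inv, y)
    return p_pos * (1.0 - pbar_pos) - p_neg * (1.0 - pbar_neg)


def train_modest(
    X,
    y,
    T: int = 100,
    n_bins: int = 8,
    *,
    feature_names: Sequence[str] | None = None,
    record_weights: bool = False,
) -> BoostModel:
    """Modest AdaBoost over per-feature block partitions.

    Each round picks the feature maximizing the weighted margin gain
    Σ_i D(i)·y_i·f(x_i) and reweights as in Real AdaBoost; training stops
    early when the best achievable gain vanishes (the response would be
    identically ~0, the variant's natural stopping point).
    """
    X, y = _validate_training_set(X, y, T)
    m = X.shape[0]
    edges, assignments = _precompute_bins(X, n_bins)
    w = np.full(m, 1.0 / m)
    model = BoostModel("modest", [], np.array([]), X.shape[1],
                       feature_names=tuple(feature_names) if feature_names else None)
    for t in range(T):
        w_inv = 1.0 - w
        w_inv /= w_inv.sum()
        best_gain, best_f, best_out = -np.inf, -1, None
        for f in range(X.shape[1]):
            n_blocks = len(edges[f]) + 1
            out = modest_block_outputs(assignments[f], n_blocks, w, w_inv, y)
            p_pos, p_neg = _class_masses(assignments[f], n_blocks, w, y)
            gain = float(np.sum(out * (p_pos - p_neg)))
            if gain > best_gain:
                best_gain, best_f, best_out = gain, f, out
        if best_gain <= MODEST_GAIN_TOL:
            logger.info("modest AdaBoost: margin gain vanished at round %d, stopping",
                        t + 1)
            model.stopped_early = True
            break
        learner = BlockLearner(best_f, tuple(edges[best_f]), tuple(best_out))
        model.learners.append(learner)
        h = best_out[assignments[best_f]]
        w = w * np.exp(-y * h)
        w /= w.sum()
        if record_weights:
            model.weight_history.append(w.copy())
    if not model.learners:
        raise DataError("modest AdaBoost: no learner with positive margin gain")
    model.alphas = np.ones(len(model.learners))
    return model


_TRAINERS = {
    "discrete": train_discrete,
    "real": train_real,
    "gentle": train_gentle,
    "modest": train_modest,
}


def train(variant: str, X, y, T: int = 100, n_bins: int = 8, **kwargs) -> BoostModel:
    """Dispatch to a variant trainer by name (see :data:`VARIANTS`)."""
    if variant not in _TRAINERS:
        raise DataError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    if variant in ("real", "modest"):
        return _TRAINERS[variant](X, y, T, n_bins=n_bins, **kwargs)
    return _TRAINERS[variant](X, y, T, **kwargs)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def _learner_to_dict(learner) -> dict:
    if isinstance(learner, Stump):
        return {"kind": "stump", "feature_index": learner.feature_index,
                "threshold": learner.threshold, "polarity": learner.polarity}
    if isinstance(learner, RegressionStump):
        return {"kind": "regression_stump", "feature_index": learner.feature_index,
                "threshold": learner.threshold, "left_value": learner.left_value,
                "right_value": learner.right_value}
    if isinstance(learner, BlockLearner):
        return {"kind": "block", "feature_index": learner.feature_index,
                "bin_edges": list(learner.bin_edges),
                "bin_outputs": list(learner.bin_outputs)}
    raise TypeError(f"unserializable learner {type(learner).__name__}")


def _learner_from_dict(d: dict):
    kind = d.get("kind")
    if kind == "stump":
        return Stump(d["feature_index"], d["threshold"], d["polarity"])
    if kind == "regression_stump":
        return RegressionStump(d["feature_index"], d["threshold"],
                               d["left_value"], d["right_value"])
    if kind == "block":
        return BlockLearner(d["feature_index"], tuple(d["bin_edges"]),
                            tuple(d["bin_outputs"]))
    raise DataError(f"unknown learner kind {kind!r} in model file")


def model_to_json(model: BoostModel) -> str:
    payload = {
        "format_version": _FORMAT_VERSION,
        "variant": model.variant,
        "n_features": model.n_features,
        "feature_names": list(model.feature_names) if model.feature_names else None,
        "alphas": model.alphas.tolist(),
        "learners": [_learner_to_dict(l) for l in model.learners],
        "epsilons": list(model.epsilons),
        "z_values": list(model.z_values),
        "stopped_early": model.stopped_early,
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def model_from_json(text: str) -> BoostModel:
    payload = json.loads(text)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise DataError(
            f"unsupported model format version {payload.get('format_version')!r}"
        )
    return BoostModel(
        variant=payload["variant"],
        learners=[_learner_from_dict(d) for d in payload["learners"]],
        alphas=np.asarray(payload["alphas"], dtype=float),
        n_features=payload["n_features"],
        feature_names=tuple(payload["feature_names"]) if payload["feature_names"] else None,
        epsilons=tuple(payload["epsilons"]),
        z_values=tuple(payload["z_values"]),
        stopped_early=payload["stopped_early"],
    )
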