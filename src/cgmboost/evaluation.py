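"""Evaluation protocols: confusion-matrix metrics, hold-out split,
stratified k-fold cross-validation, and the upper-threshold sweep.

The positive class is type 1 diabetes (+1).  Accuracy is
ACC = (TP+TN)/(P+N); the Matthews correlation coefficient is

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with the standard convention MCC = 0 when the denominator vanishes.
The hold-out protocol mirrors the study design of training on 2/7 of the
cohort (300 of 1050) and testing on the rest; the threshold sweep
re-extracts the 17 features at each upper threshold μ and evaluates every
boosting variant on the same split, yielding a (variant × μ) error grid
and per-cell error-vs-iteration curves.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .boosting import BoostModel, predict, staged_errors, train
from .errors import DataError
from .features import (FEATURE_NAMES, MealSchedule, ThresholdConfig,
                       extract_features)
from .trace import GlucoseTrace

DEFAULT_MU_LIST = (7.0, 8.0, 9.0, 10.0, 11.0)
DEFAULT_TRAIN_FRACTION = 300 / 1050


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FN/FP/TN counts of a binary evaluation (positive class = +1)."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise DataError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Tally a confusion matrix from ±1 label vectors of equal length."""
    yt = np.asarray(true_labels)
    yp = np.asarray(predicted_labels)
    if yt.shape != yp.shape:
        raise DataError(f"label vectors differ in length: {yt.shape} vs {yp.shape}")
    if not (np.all(np.isin(yt, (-1, 1))) and np.all(np.isin(yp, (-1, 1)))):
        raise DataError("labels must be +1 or -1")
    return ConfusionMatrix(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == -1))),
        fp=int(np.sum((yt == -1) & (yp == 1))),
        tn=int(np.sum((yt == -1) & (yp == -1))),
    )


def acc(cm: ConfusionMatrix) -> float:
    """Accuracy (TP+TN)/(P+N)."""
    if cm.total == 0:
        raise DataError("cannot compute accuracy of an empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 when the denominator is 0."""
    if cm.total == 0:
        raise DataError("cannot compute MCC of an empty confusion matrix")
    denom = math.sqrt(
        float(cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom == 0.0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / denom


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------


@dataclass
class HoldoutResult:
    """Metrics of one train/test split for one variant."""

    variant: str
    error_rate: float
    acc: float
    mcc: float
    staged_error_curve: np.ndarray
    model: BoostModel
    confusion: ConfusionMatrix
    train_indices: np.ndarray = field(repr=False, default=None)
    test_indices: np.ndarray = field(repr=False, default=None)


def holdout_protocol(
    X,
    y,
    variant: str,
    T: int = 100,
    *,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
    n_bins: int = 8,
) -> HoldoutResult:
    """Seeded shuffle, train on the first ``round(train_fraction·n)``
    samples, evaluate on the rest (default ratio 300:750 ≡ 2/7 train)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    n_train = int(round(train_fraction * n))
    if not 2 <= n_train <= n - 1:
        raise DataError(f"degenerate split: n={n}, n_train={n_train}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    if np.unique(y[train_idx]).size < 2:
        raise DataError("training part lacks one class; change the seed")
    model = train(variant, X[train_idx], y[train_idx], T, n_bins=n_bins)
    labels, _ = predict(model, X[test_idx])
    cm = confusion(y[test_idx], labels)
    a = acc(cm)
    return HoldoutResult(
        variant=variant,
        error_rate=1.0 - a,
        acc=a,
        mcc=mcc(cm),
        staged_error_curve=staged_errors(model, X[test_idx], y[test_idx]),
        model=model,
        confusion=cm,
        train_indices=train_idx,
        test_indices=test_idx,
    )


@dataclass
class CVResult:
    """Stratified k-fold cross-validation output for one variant."""

    variant: str
    fold_errors: list[float]
    fold_curves: list[np.ndarray]
    mean_error: float
    mean_curve: np.ndarray
    folds: list[np.ndarray] = field(repr=False, default=None)


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (1, -1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _pad_curve(curve: np.ndarray, length: int) -> np.ndarray:
    # an early-stopped ensemble's error is constant after its last round
    if curve.size >= length:
        return curve[:length]
    return np.concatenate([curve, np.full(length - curve.size, curve[-1])])


def kfold_cv(
    X,
    y,
    variant: str,
    T: int = 100,
    k: int = 5,
    *,
    seed: int = 0,
    n_bins: int = 8,
) -> CVResult:
    """Seeded, stratified k-fold cross-validation.

    Each fold is held out once; per-fold staged test-error curves are
    returned along with their arithmetic mean (shorter curves of
    early-stopped ensembles are extended with their final value).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if k < 2 or n < k:
        raise DataError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, k, rng)
    fold_errors: list[float] = []
    fold_curves: list[np.ndarray] = []
    for held_out in folds:
        train_idx = np.setdiff1d(np.arange(n), held_out)
        if np.unique(y[train_idx]).size < 2:
            raise DataError(
                "a training fold lacks one class; use a different seed or k"
            )
        model = train(variant, X[train_idx], y[train_idx], T, n_bins=n_bins)
        curve = staged_errors(model, X[held_out], y[held_out])
        fold_curves.append(curve)
        fold_errors.append(float(curve[-1]))
    length = max(c.size for c in fold_curves)
    mean_curve = np.mean([_pad_curve(c, length) for c in fold_curves], axis=0)
    return CVResult(
        variant=variant,
        fold_errors=fold_errors,
        fold_curves=fold_curves,
        mean_error=float(np.mean(fold_errors)),
        mean_curve=mean_curve,
        folds=folds,
    )


# ---------------------------------------------------------------------------
# threshold sweep
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    """(variant × μ) grid of hold-out results from the threshold sweep."""

    variants: tuple[str, ...]
    mu_list: tuple[float, ...]
    cells: dict[tuple[str, float], HoldoutResult]

    def _table(self, attr: str) -> pd.DataFrame:
        data = {
            mu: [getattr(self.cells[(v, mu)], attr) for v in self.variants]
            for mu in self.mu_list
        }
        frame = pd.DataFrame(data, index=list(self.variants))
        frame.columns = [f"{mu:g} mmol/L" for mu in self.mu_list]
        frame.index.name = "variant"
        return frame

    def error_table(self) -> pd.DataFrame:
        """Error-rate grid, variants as rows and μ values as columns."""
        return self._table("error_rate")

    def acc_table(self) -> pd.DataFrame:
        return self._table("acc")

    def mcc_table(self) -> pd.DataFrame:
        return self._table("mcc")

    def curves(self) -> dict[str, list[float]]:
        return {
            f"{v}@{mu:g}": self.cells[(v, mu)].staged_error_curve.tolist()
            for v in self.variants
            for mu in self.mu_list
        }


def extract_feature_matrix(
    traces: Sequence[GlucoseTrace],
    thresholds: ThresholdConfig,
    meals: MealSchedule | None = None,
    **feature_kwargs,
) -> np.ndarray:
    """Stack :func:`extract_features` over traces into an ``(n, 17)`` matrix."""
    return np.stack(
        [
            extract_features(tr, thresholds, meals, **feature_kwargs).to_array()
            for tr in traces
        ]
    )


def threshold_sweep(
    traces: Sequence[GlucoseTrace],
    labels,
    variants: Sequence[str] = ("discrete", "real", "gentle", "modest"),
    mu_list: Sequence[float] = DEFAULT_MU_LIST,
    T: int = 100,
    *,
    lower: float = 3.9,
    meals: MealSchedule | None = None,
    seed: int = 0,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    n_bins: int = 8,
) -> SweepResult:
    """Re-extract features at each μ and run the hold-out protocol per
    variant, assembling the (variant × μ) comparison grid.

    The same seeded split is reused across all cells so grid differences
    reflect the threshold and the variant, not the partition.
    """
    labels = np.asarray(labels)
    if len(traces) != labels.size:
        raise DataError("traces and labels differ in length")
    mu_list = tuple(float(mu) for mu in mu_list)
    if any(b <= a for a, b in zip(mu_list, mu_list[1:])):
        raise DataError("mu_list must be strictly ascending")
    cells: dict[tuple[str, float], HoldoutResult] = {}
    for mu in mu_list:
        X = extract_feature_matrix(traces, ThresholdConfig(upper=mu, lower=lower), meals)
        for variant in variants:
            cells[(variant, mu)] = holdout_protocol(
                X, labels, variant, T,
                train_fraction=train_fraction, seed=seed, n_bins=n_bins,
            )
    return SweepResult(tuple(variants), mu_list, cells)


def plot_error_curves(sweep: SweepResult, path) -> None:
    """Write an error-vs-iteration figure, one panel per upper threshold."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(sweep.mu_list)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, mu in zip(axes, sweep.mu_list):
        for variant in sweep.variants:
            curve = sweep.cells[(variant, mu)].staged_error_curve
            ax.plot(np.arange(1, curve.size + 1), curve, label=variant)
        ax.set_title(f"μ = {mu:g} mmol/L")
        ax.set_xlabel("iterations")
    axes[0].set_ylabel("test error rate")
    axes[-1].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
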