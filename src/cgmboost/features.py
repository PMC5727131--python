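"""Glycemic-variability features from CGM day curves.

Seventeen features summarise one patient's glucose record at a given upper
glucose threshold ``upper`` (the target-range ceiling, swept over 7–11
mmol/L in the classification experiments) and a fixed lower threshold
(default 3.9 mmol/L, the standard hypoglycemia cut-off):

* seven averages — whole-day mean plus pre-/post-meal means for breakfast,
  lunch and dinner;
* SDBG — the population standard deviation of the day curve;
* LAGE — the largest amplitude of glucose excursions, ``max − min``;
* MODD — mean of daily differences between time-matched samples of two
  consecutive days (inter-day variability);
* AUC — excess area outside the ``[lower, upper]`` band, in mmol/L·h;
* MAGE — mean amplitude of glycemic excursions exceeding one SD;
* TH / TL — counts of excursion peaks above ``upper`` / troughs below
  ``lower``;
* HL / LL / WL — percentage of the day spent above / below / within the
  band (they sum to 100 by construction).

All per-day operations require a complete 288-sample day; a patient-level
:func:`extract_features` averages per-day values across days and computes
MODD over consecutive day pairs, so it needs at least two days.
"""
from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import ConfigurationError, DataError
from .trace import MINUTES_PER_DAY, SAMPLE_MINUTES, SAMPLES_PER_DAY, GlucoseTrace

HOURS_PER_SAMPLE = SAMPLE_MINUTES / 60.0  # 1/12 h

#: Canonical feature order used everywhere (tables, models, serialization).
FEATURE_NAMES: tuple[str, ...] = (
    "mean_day",
    "mean_pre_breakfast",
    "mean_pre_lunch",
    "mean_pre_dinner",
    "mean_post_breakfast",
    "mean_post_lunch",
    "mean_post_dinner",
    "sdbg",
    "lage",
    "modd",
    "auc",
    "mage",
    "th",
    "tl",
    "hl",
    "ll",
    "wl",
)

N_FEATURES = len(FEATURE_NAMES)


def parse_time_of_day(text: str) -> int:
    """Parse ``"HH:MM"`` into minutes since midnight."""
    try:
        hh, mm = text.strip().split(":")
        minutes = int(hh) * 60 + int(mm)
    except (ValueError, AttributeError) as exc:
        raise ConfigurationError(f"cannot parse time of day {text!r}") from exc
    if not 0 <= minutes < MINUTES_PER_DAY:
        raise ConfigurationError(f"time of day {text!r} outside 00:00–23:59")
    return minutes


@dataclass(frozen=True)
class ThresholdConfig:
    """Glucose target band: ``upper`` is the swept threshold μ (mmol/L)."""

    upper: float
    lower: float = 3.9

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper):
            raise ConfigurationError(
                f"thresholds must satisfy 0 < lower < upper, got "
                f"lower={self.lower}, upper={self.upper}"
            )


@dataclass(frozen=True)
class MealSchedule:
    """Clock-time meal windows (minutes since midnight).

    The pre-meal window is ``[meal - pre_window, meal)`` and the post-meal
    window ``(meal, meal + post_window]``; membership is decided by each
    5-minute slot's midpoint.  Defaults: breakfast 07:30, lunch 12:00,
    dinner 18:00, 30 min pre-window, 120 min post-window.
    """

    breakfast: int = 7 * 60 + 30
    lunch: int = 12 * 60
    dinner: int = 18 * 60
    pre_window: int = 30
    post_window: int = 120

    def __post_init__(self) -> None:
        if self.pre_window <= 0 or self.post_window <= 0:
            raise ConfigurationError("meal windows must have positive length")
        spans = sorted(
            (m - self.pre_window, m + self.post_window, name)
            for name, m in self.meal_times().items()
        )
        for lo, hi, name in spans:
            if lo < 0 or hi > MINUTES_PER_DAY:
                raise ConfigurationError(f"{name} window [{lo}, {hi}] leaves the day")
        for (_, hi_prev, prev), (lo_next, _, nxt) in zip(spans, spans[1:]):
            if lo_next < hi_prev:
                raise ConfigurationError(f"meal windows overlap: {prev} and {nxt}")

    def meal_times(self) -> dict[str, int]:
        return {"breakfast": self.breakfast, "lunch": self.lunch, "dinner": self.dinner}


@dataclass(frozen=True)
class FeatureVector:
    """The 17 features for one patient at one threshold configuration.

    Units: the seven means, SDBG, LAGE, MODD and MAGE are mmol/L; AUC is
    mmol/L·h; TH and TL are mean daily counts; HL, LL, WL are percent of
    the day and always sum to 100.
    """

    mean_day: float
    mean_pre_breakfast: float
    mean_pre_lunch: float
    mean_pre_dinner: float
    mean_post_breakfast: float
    mean_post_lunch: float
    mean_post_dinner: float
    sdbg: float
    lage: float
    modd: float
    auc: float
    mage: float
    th: float
    tl: float
    hl: float
    ll: float
    wl: float

    def __post_init__(self) -> None:
        arr = self.to_array()
        if not np.all(np.isfinite(arr)):
            raise DataError("feature vector contains non-finite values")
        for name in ("sdbg", "lage", "modd", "auc", "mage", "th", "tl"):
            if getattr(self, name) < 0:
                raise DataError(f"feature {name} must be non-negative")
        if abs(self.hl + self.ll + self.wl - 100.0) > 1e-9:
            raise DataError("hl + ll + wl must equal 100")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "FeatureVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_FEATURES,):
            raise DataError(f"expected {N_FEATURES} features, got shape {arr.shape}")
        return cls(**dict(zip(FEATURE_NAMES, arr.tolist())))


@dataclass(frozen=True)
class LabeledSample:
    """A patient's feature vector with its diabetes-type label (+1 = type 1)."""

    patient_id: str
    features: FeatureVector
    label: int

    def __post_init__(self) -> None:
        if self.label not in (+1, -1):
            raise DataError(f"label must be +1 or -1, got {self.label}")


# ---------------------------------------------------------------------------
# per-day operations
# ---------------------------------------------------------------------------


def _check_day(day) -> np.ndarray:
    day = np.asarray(day, dtype=float)
    if day.shape != (SAMPLES_PER_DAY,):
        raise DataError(
            f"a complete day has exactly {SAMPLES_PER_DAY} samples, "
            f"got shape {day.shape}"
        )
    if not np.all(np.isfinite(day)):
        raise DataError("day contains non-finite glucose values")
    return day


def daily_mean(day) -> float:
    """Whole-day mean glucose, ``(1/n) Σ x_i`` with n = 288."""
    day = _check_day(day)
    return float(day.sum() / SAMPLES_PER_DAY)


def _slot_midpoints() -> np.ndarray:
    return np.arange(SAMPLES_PER_DAY) * SAMPLE_MINUTES + SAMPLE_MINUTES / 2.0


def window_means(day, meals: MealSchedule | None = None) -> dict[str, float]:
    """Pre-/post-meal means for breakfast, lunch and dinner.

    Returns a dict keyed ``mean_pre_<meal>`` / ``mean_post_<meal>``.  A slot
    belongs to the pre-meal window when its midpoint lies in
    ``[meal - pre_window, meal)`` and to the post-meal window when it lies
    in ``(meal, meal + post_window]``.
    """
    day = _check_day(day)
    meals = meals or MealSchedule()
    mid = _slot_midpoints()
    out: dict[str, float] = {}
    for name, t in meals.meal_times().items():
        pre = (mid >= t - meals.pre_window) & (mid < t)
        post = (mid > t) & (mid <= t + meals.post_window)
        for kind, mask in (("pre", pre), ("post", post)):
            if not mask.any():
                raise ConfigurationError(
                    f"{kind}-{name} window contains no samples"
                )
            out[f"mean_{kind}_{name}"] = float(day[mask].mean())
    return out


def sdbg(day) -> float:
    """Population standard deviation of the day curve (1/n form)."""
    day = _check_day(day)
    xbar = day.sum() / SAMPLES_PER_DAY
    return float(np.sqrt(np.sum((day - xbar) ** 2) / SAMPLES_PER_DAY))


def lage(day) -> float:
    """Largest amplitude of glucose excursions: daily max minus min."""
    day = _check_day(day)
    return float(day.max() - day.min())


def modd(day1, day2, denominator: int = 287) -> float:
    """Mean of daily differences between two consecutive days.

    The 288 time-matched absolute differences are summed and divided by
    ``denominator`` (default 287, exactly as the defining formula prints;
    pass 288 for the self-consistent mean).
    """
    day1, day2 = _check_day(day1), _check_day(day2)
    if denominator not in (287, 288):
        raise ConfigurationError("modd denominator must be 287 or 288")
    return float(np.abs(day1 - day2).sum() / denominator)


def auc_excess(day, thresholds: ThresholdConfig) -> float:
    """Excess area outside the glucose target band, in mmol/L·h.

    Trapezoidal integration of ``max(x - upper, 0)`` plus
    ``max(lower - x, 0)`` on the 5-minute grid.  The day is treated as a
    closed 24 h interval: the final sample is held to midnight, so a curve
    at a constant excess of c integrates to exactly 24·c.
    """
    day = _check_day(day)
    total = 0.0
    for excess in (np.maximum(day - thresholds.upper, 0.0),
                   np.maximum(thresholds.lower - day, 0.0)):
        closed = np.append(excess, excess[-1])
        total += float(np.trapezoid(closed, dx=HOURS_PER_SAMPLE))
    return total


def _collapse_plateaus(day: np.ndarray) -> np.ndarray:
    # runs of equal consecutive values collapse to one (midpoint) sample so
    # that strict sign-change extrema are well defined
    change = np.flatnonzero(np.diff(day) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [day.size - 1]))
    return day[(starts + ends) // 2]


def _interior_extrema(values: np.ndarray) -> np.ndarray:
    """Indices of strict local extrema of a plateau-free series."""
    if values.size < 3:
        return np.array([], dtype=int)
    d = np.diff(values)
    return np.flatnonzero(d[:-1] * d[1:] < 0) + 1


def mage(day) -> float:
    """Mean amplitude of glycemic excursions.

    Four steps: (1) collect all local extrema of the (plateau-collapsed)
    curve; (2) find the first extreme point whose absolute difference to
    BOTH adjacent extrema exceeds the day's SDBG — if none exists MAGE is
    0; (3) collect the amplitudes of all consecutive extremum pairs that
    exceed the SD, each counted once; (4) return their mean.
    """
    day = _check_day(day)
    sd = sdbg(day)
    values = _collapse_plateaus(day)
    ext = values[_interior_extrema(values)]
    if ext.size < 3:
        return 0.0
    amps = np.abs(np.diff(ext))
    valid_anchor = (amps[:-1] > sd) & (amps[1:] > sd)
    if not valid_anchor.any():
        return 0.0
    return float(amps[amps > sd].mean())


def excursion_counts(
    day, thresholds: ThresholdConfig, mode: str = "peaks"
) -> tuple[int, int]:
    """TH and TL: excursion events beyond the target band in one day.

    ``mode="peaks"`` (default) counts local maxima above ``upper`` and
    local minima below ``lower``; ``mode="crossings"`` counts maximal runs
    of samples beyond each threshold instead.
    """
    day = _check_day(day)
    if mode == "peaks":
        values = _collapse_plateaus(day)
        idx = _interior_extrema(values)
        if idx.size == 0:
            return 0, 0
        is_max = values[idx] > values[idx - 1]
        th = int(np.sum(is_max & (values[idx] > thresholds.upper)))
        tl = int(np.sum(~is_max & (values[idx] < thresholds.lower)))
        return th, tl
    if mode == "crossings":
        th = _count_runs(day > thresholds.upper)
        tl = _count_runs(day < thresholds.lower)
        return th, tl
    raise ConfigurationError(f"unknown TH/TL mode {mode!r}")


def _count_runs(mask: np.ndarray) -> int:
    padded = np.concatenate(([False], mask))
    return int(np.sum(~padded[:-1] & padded[1:]))


def time_percentages(
    day, thresholds: ThresholdConfig
) -> tuple[float, float, float]:
    """(HL, LL, WL): percent of the day above / below / within the band."""
    day = _check_day(day)
    hl = 100.0 * np.sum(day > thresholds.upper) / SAMPLES_PER_DAY
    ll = 100.0 * np.sum(day < thresholds.lower) / SAMPLES_PER_DAY
    return float(hl), float(ll), float(100.0 - hl - ll)


# ---------------------------------------------------------------------------
# patient-level extraction
# ---------------------------------------------------------------------------


def extract_features(
    trace: GlucoseTrace,
    thresholds: ThresholdConfig,
    meals: MealSchedule | None = None,
    *,
    modd_denominator: int = 287,
    th_tl_mode: str = "peaks",
) -> FeatureVector:
    """Compute the 17-feature vector for one patient.

    Per-day features are averaged across the record's days; MODD is
    computed on each consecutive day pair and averaged, so the trace must
    contain at least two complete days.
    """
    meals = meals or MealSchedule()
    days = trace.days()
    if days.shape[0] < 2:
        raise DataError(
            f"trace {trace.patient_id!r} has {days.shape[0]} day(s); "
            "MODD requires at least two consecutive days"
        )
    per_day: dict[str, list[float]] = {name: [] for name in FEATURE_NAMES if name != "modd"}
    for day in days:
        per_day["mean_day"].append(daily_mean(day))
        for key, val in window_means(day, meals).items():
            per_day[key].append(val)
        per_day["sdbg"].append(sdbg(day))
        per_day["lage"].append(lage(day))
        per_day["auc"].append(auc_excess(day, thresholds))
        per_day["mage"].append(mage(day))
        th, tl = excursion_counts(day, thresholds, mode=th_tl_mode)
        per_day["th"].append(th)
        per_day["tl"].append(tl)
        hl, ll, wl = time_percentages(day, thresholds)
        per_day["hl"].append(hl)
        per_day["ll"].append(ll)
        per_day["wl"].append(wl)
    values = {name: float(np.mean(vals)) for name, vals in per_day.items()}
    values["modd"] = float(
        np.mean(
            [
                modd(days[i], days[i + 1], denominator=modd_denominator)
                for i in range(days.shape[0] - 1)
            ]
        )
    )
    return FeatureVector(**{name: values[name] for name in FEATURE_NAMES})
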