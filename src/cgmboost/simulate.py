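"""Synthetic CGM cohorts with type-1 / type-2 glycemic phenotypes.

Each simulated day is a sum of interpretable components on the 5-minute
grid:

* a per-patient baseline (class mean plus Gaussian patient-level jitter);
* three meal-locked excursions — Gaussian bumps peaking ~75 min after
  each meal, with class-scaled amplitude and per-patient/per-meal jitter;
* a slow sinusoidal circadian drift with a random per-patient phase;
* optional hypoglycemic dips (Poisson-placed negative bumps, more
  frequent in the type-1 phenotype);
* white measurement noise;

clipped to the CGM sensor dynamic range [2, 25] mmol/L.  The default
phenotype contrast follows textbook CGM physiology: type 1 shows larger
excursions and more hypoglycemic events, type 2 a higher, blunted
baseline.  Every patient draws from an independent substream of the
master seed, so cohorts are reproducible and order-independent.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .features import MealSchedule
from .trace import MINUTES_PER_DAY, SAMPLE_MINUTES, SAMPLES_PER_DAY, GlucoseTrace

T1D, T2D = +1, -1
_CLASS_STREAM = {T1D: 1, T2D: 2}


@dataclass(frozen=True)
class ClassProfile:
    """Generative parameters of one diabetes-type phenotype (mmol/L, events/day).

    Besides the three meal-locked excursions, a phenotype may carry
    additional Poisson-placed excursions at random times of day
    (``excursion_rate`` events/day of amplitude ``excursion_amplitude``),
    modelling snacks, stress responses and other non-meal glycemic events.
    """

    baseline_mean: float
    meal_amplitude: float
    hypo_rate: float
    baseline_sd: float = 0.3
    amplitude_jitter: float = 0.25
    drift_amplitude: float = 0.4
    hypo_depth: tuple[float, float] = (1.5, 3.0)
    excursion_rate: float = 0.0
    excursion_amplitude: float = 0.0
    excursion_width_sd: float = 30.0

    def __post_init__(self) -> None:
        if min(self.baseline_mean, self.meal_amplitude, self.hypo_rate,
               self.baseline_sd, self.amplitude_jitter, self.drift_amplitude,
               self.excursion_rate, self.excursion_amplitude) < 0:
            raise ConfigurationError("class-profile parameters must be non-negative")
        if self.baseline_mean <= 0:
            raise ConfigurationError("baseline_mean must be positive")
        if self.excursion_width_sd <= 0:
            raise ConfigurationError("excursion_width_sd must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic type-1/type-2 CGM cohort generator."""

    n_per_class: int = 525
    n_days: int = 2
    t1d: ClassProfile = field(
        default_factory=lambda: ClassProfile(
            baseline_mean=7.0, meal_amplitude=4.5, hypo_rate=0.5
        )
    )
    t2d: ClassProfile = field(
        default_factory=lambda: ClassProfile(
            baseline_mean=8.5, meal_amplitude=2.0, hypo_rate=0.05
        )
    )
    noise_sd: float = 0.3
    meal_peak_delay: float = 75.0  # minutes after the meal
    meal_response_sd: float = 40.0  # bump width (minutes)
    hypo_width_sd: float = 15.0
    # class-independent random excursions shared by both phenotypes
    snack_rate: float = 0.0
    snack_amplitude_range: tuple[float, float] = (1.0, 3.3)
    snack_width_sd: float = 20.0
    meals: MealSchedule = field(default_factory=MealSchedule)
    clip: tuple[float, float] = (2.0, 25.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.n_days < 2:
            raise ConfigurationError(
                "need n_per_class >= 1 and n_days >= 2 (MODD needs a day pair)"
            )
        if self.noise_sd < 0 or self.meal_response_sd <= 0 or self.hypo_width_sd <= 0 \
                or self.snack_width_sd <= 0 or self.snack_rate < 0:
            raise ConfigurationError("noise/width parameters must be positive")
        if not 0 < self.clip[0] < self.clip[1]:
            raise ConfigurationError("clip range must satisfy 0 < low < high")

    def profile(self, label: int) -> ClassProfile:
        if label == T1D:
            return self.t1d
        if label == T2D:
            return self.t2d
        raise ConfigurationError(f"label must be +1 or -1, got {label}")


def _gaussian_bump(t: np.ndarray, center: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sd) ** 2)


def _daily_count(rate: float, rng: np.random.Generator) -> int:
    # low-dispersion event count: fixed integer part plus a Bernoulli
    # remainder, so day-to-day occupancy is stable at the configured rate
    base = int(rate)
    return base + int(rng.random() < rate - base)


def simulate_trace(
    label: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    patient_id: str = "sim",
) -> GlucoseTrace:
    """Draw one patient's multi-day trace from the given random stream.

    All stochastic draws happen in a fixed order, so a trace is
    bit-reproducible from its stream state.
    """
    prof = config.profile(label)
    t = np.arange(SAMPLES_PER_DAY) * SAMPLE_MINUTES  # minutes since midnight
    baseline = prof.baseline_mean + rng.normal(0.0, prof.baseline_sd) \
        if prof.baseline_sd > 0 else prof.baseline_mean
    amp_scale = rng.uniform(1.0 - prof.amplitude_jitter, 1.0 + prof.amplitude_jitter)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    drift = prof.drift_amplitude * np.sin(2.0 * np.pi * t / MINUTES_PER_DAY + phase)
    days = []
    for _ in range(config.n_days):
        curve = baseline + drift.copy()
        for meal_time in config.meals.meal_times().values():
            amp = prof.meal_amplitude * amp_scale * rng.uniform(0.85, 1.15)
            center = meal_time + config.meal_peak_delay
            curve = curve + amp * _gaussian_bump(t, center, config.meal_response_sd)
        n_excursions = _daily_count(prof.excursion_rate, rng)
        for _ in range(n_excursions):
            center = rng.uniform(0.0, MINUTES_PER_DAY)
            amp = prof.excursion_amplitude * amp_scale * rng.uniform(0.75, 1.25)
            curve = curve + amp * _gaussian_bump(t, center, prof.excursion_width_sd)
        n_snacks = _daily_count(config.snack_rate, rng)
        for _ in range(n_snacks):
            center = rng.uniform(0.0, MINUTES_PER_DAY)
            amp = rng.uniform(*config.snack_amplitude_range)
            curve = curve + amp * _gaussian_bump(t, center, config.snack_width_sd)
        n_hypos = rng.poisson(prof.hypo_rate)
        for _ in range(n_hypos):
            center = rng.uniform(0.0, MINUTES_PER_DAY)
            depth = rng.uniform(*prof.hypo_depth)
            curve = curve - depth * _gaussian_bump(t, center, config.hypo_width_sd)
        if config.noise_sd > 0:
            curve = curve + rng.normal(0.0, config.noise_sd, SAMPLES_PER_DAY)
        days.append(np.clip(curve, config.clip[0], config.clip[1]))
    return GlucoseTrace(patient_id, np.concatenate(days))


def _patient_rng(config: SimulationConfig, label: int, index: int) -> np.random.Generator:
    # independent per-patient substream, order-independent by construction
    return np.random.default_rng([abs(int(config.seed)), _CLASS_STREAM[label], index])


def simulate_cohort(config: SimulationConfig) -> list[tuple[GlucoseTrace, int]]:
    """Generate ``n_per_class`` patients per class, labels +1 (T1D) / −1 (T2D)."""
    cohort: list[tuple[GlucoseTrace, int]] = []
    for label, prefix in ((T1D, "T1D"), (T2D, "T2D")):
        for i in range(config.n_per_class):
            rng = _patient_rng(config, label, i)
            trace = simulate_trace(label, config, rng, patient_id=f"{prefix}_{i:04d}")
            cohort.append((trace, label))
    return cohort


def cohort_arrays(cohort: list[tuple[GlucoseTrace, int]]) -> tuple[list[GlucoseTrace], np.ndarray]:
    """Split a cohort into a trace list and a ±1 label vector."""
    traces = [tr for tr, _ in cohort]
    labels = np.array([lab for _, lab in cohort], dtype=int)
    return traces, labels


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def default_cohort_config(seed: int = 0, n_per_class: int = 525) -> SimulationConfig:
    """The standard study-scale cohort: 525+525 patients, 2 days each."""
    return SimulationConfig(n_per_class=n_per_class, seed=seed)


def null_cohort_config(seed: int = 0, n_per_class: int = 525) -> SimulationConfig:
    """Zero class contrast: both classes draw from the midpoint phenotype.

    Held-out error of any classifier on this cohort has no signal to
    exploit and concentrates around 1/2.
    """
    mid = ClassProfile(baseline_mean=7.75, meal_amplitude=3.25, hypo_rate=0.275)
    return SimulationConfig(n_per_class=n_per_class, t1d=mid, t2d=mid, seed=seed)


def structured_cohort_config(seed: int = 0, n_per_class: int = 150) -> SimulationConfig:
    """A cohort whose class signal is concentrated below ~9.5 mmol/L.

    The class contrast is a frequency-versus-amplitude tradeoff in
    non-meal-locked excursions: the type-1 phenotype has frequent moderate
    excursions (5/day of ≈1.9 mmol/L), the type-2 phenotype rare taller
    ones (2/day of ≈2.85 mmol/L).  Rates, amplitudes and baselines are
    chosen so the whole-day mean and variance of the two phenotypes match
    (rate × amplitude² equal; the residual mean gap absorbed into the
    baseline), meal-locked bumps are off, and a class-independent "snack"
    process with a wide amplitude range overlapping both phenotypes blurs
    the amplitude-sensitive threshold-free features (MAGE, LAGE).  What
    remains separable is the occupancy above 7–8 mmol/L (time, peak counts
    and excess area), while both phenotypes stay essentially below
    10 mmol/L, so features extracted at upper thresholds of 10–11 mmol/L
    carry no class information.
    """
    t1d = ClassProfile(
        baseline_mean=5.90, meal_amplitude=0.0, hypo_rate=0.0,
        baseline_sd=0.30, amplitude_jitter=0.1, drift_amplitude=0.25,
        excursion_rate=6.0, excursion_amplitude=1.7, excursion_width_sd=38.0,
    )
    t2d = ClassProfile(
        baseline_mean=6.28, meal_amplitude=0.0, hypo_rate=0.0,
        baseline_sd=0.30, amplitude_jitter=0.1, drift_amplitude=0.60,
        excursion_rate=1.5, excursion_amplitude=3.0, excursion_width_sd=38.0,
    )
    return SimulationConfig(
        n_per_class=n_per_class, t1d=t1d, t2d=t2d, seed=seed,
        noise_sd=0.30, snack_rate=1.0, snack_amplitude_range=(1.0, 3.0),
        snack_width_sd=20.0,
    )


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """A copy of ``config`` with a different master seed."""
    return replace(config, seed=seed)
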