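"""Plain-text (CSV) input/output for CGM traces and labeled feature tables.

Trace files carry one sample per row with columns
``patient_id,day,slot,glucose_mmol_per_L`` (slot 0–287 within the day);
a ``timestamp`` column may replace ``day``/``slot``, in which case the
5-minute grid position is derived from it.  Feature tables carry one row
per patient: ``patient_id``, the 17 feature columns in canonical order,
and a ``label`` column holding ``T1D`` (+1) or ``T2D`` (−1).
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParseError, TraceValidationError
from .features import FEATURE_NAMES, FeatureVector, LabeledSample
from .trace import MINUTES_PER_DAY, SAMPLE_MINUTES, SAMPLES_PER_DAY, GlucoseTrace

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ("patient_id", "day", "slot", "glucose_mmol_per_L")
LABEL_TO_INT = {"T1D": +1, "T2D": -1}
INT_TO_LABEL = {v: k for k, v in LABEL_TO_INT.items()}

#: Longest run of missing samples the optional interpolation will bridge.
MAX_INTERP_RUN = 3


def _apply_schema(frame: pd.DataFrame, schema: Mapping[str, str] | None) -> pd.DataFrame:
    if schema:
        frame = frame.rename(columns={v: k for k, v in schema.items()})
    return frame


def _grid_from_timestamps(sub: pd.DataFrame, patient: str) -> pd.DataFrame:
    ts = pd.to_datetime(sub["timestamp"], errors="raise")
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ParseError(f"patient {patient!r}: timestamps are not strictly increasing")
    minutes = (ts - ts.dt.normalize().iloc[0]).dt.total_seconds() / 60.0
    if np.any(np.mod(minutes, SAMPLE_MINUTES) != 0):
        raise ParseError(f"patient {patient!r}: timestamps off the 5-minute grid")
    sub = sub.copy()
    sub["day"] = (minutes // MINUTES_PER_DAY).astype(int)
    sub["slot"] = ((minutes % MINUTES_PER_DAY) // SAMPLE_MINUTES).astype(int)
    return sub


def read_traces(
    path,
    schema: Mapping[str, str] | None = None,
    *,
    max_missing_per_day: int = 0,
    interpolate: bool = False,
) -> list[GlucoseTrace]:
    """Read CGM traces from a CSV file, one validated trace per patient.

    Values are partitioned into complete 288-sample days; a trailing
    partial day is dropped with a logged warning.  A non-trailing day with
    more than ``max_missing_per_day`` missing samples makes the whole trace
    invalid.  With ``interpolate=True``, missing runs of at most
    :data:`MAX_INTERP_RUN` samples (15 min) are filled linearly first.

    Parameters
    ----------
    schema
        Optional mapping from canonical column names (``patient_id``,
        ``day``, ``slot``, ``glucose_mmol_per_L``, ``timestamp``) to the
        file's actual column names.
    """
    frame = _apply_schema(pd.read_csv(path), schema)
    if "patient_id" not in frame.columns or "glucose_mmol_per_L" not in frame.columns:
        raise ParseError(
            f"{path}: need columns 'patient_id' and 'glucose_mmol_per_L' "
            f"(found {list(frame.columns)})"
        )
    bad = frame.index[~np.isfinite(frame["glucose_mmol_per_L"]) | (frame["glucose_mmol_per_L"] <= 0)]
    if len(bad):
        raise ParseError(
            f"{path}: non-positive or non-finite glucose value at data row "
            f"{int(bad[0]) + 2} (patient {frame.loc[bad[0], 'patient_id']!r})"
        )
    traces: list[GlucoseTrace] = []
    for patient, sub in frame.groupby("patient_id", sort=True):
        if "day" not in sub.columns or "slot" not in sub.columns:
            if "timestamp" not in sub.columns:
                raise ParseError(
                    f"{path}: need 'day'/'slot' columns or a 'timestamp' column"
                )
            sub = _grid_from_timestamps(sub, str(patient))
        traces.append(
            _assemble_trace(
                str(patient),
                sub,
                max_missing_per_day=max_missing_per_day,
                interpolate=interpolate,
            )
        )
    return traces


def _assemble_trace(
    patient: str,
    sub: pd.DataFrame,
    *,
    max_missing_per_day: int,
    interpolate: bool,
) -> GlucoseTrace:
    sub = sub.sort_values(["day", "slot"])
    if sub.duplicated(subset=["day", "slot"]).any():
        raise ParseError(f"patient {patient!r}: duplicate (day, slot) sample")
    if (sub["slot"] < 0).any() or (sub["slot"] >= SAMPLES_PER_DAY).any():
        raise ParseError(f"patient {patient!r}: slot outside 0..{SAMPLES_PER_DAY - 1}")
    day_ids = sorted(sub["day"].unique())
    days: list[np.ndarray] = []
    for pos, day_id in enumerate(day_ids):
        rows = sub[sub["day"] == day_id]
        values = np.full(SAMPLES_PER_DAY, np.nan)
        values[rows["slot"].to_numpy()] = rows["glucose_mmol_per_L"].to_numpy()
        missing = np.isnan(values)
        if interpolate and missing.any():
            values = _interpolate_short_runs(values)
            missing = np.isnan(values)
        n_missing = int(missing.sum())
        if n_missing == 0:
            days.append(values)
            continue
        if pos == len(day_ids) - 1:
            logger.warning(
                "patient %r: dropping trailing partial day %s (%d samples)",
                patient, day_id, SAMPLES_PER_DAY - n_missing,
            )
            continue
        if n_missing > max_missing_per_day:
            raise TraceValidationError(
                f"patient {patient!r}: day {day_id} has {n_missing} missing "
                f"samples (> {max_missing_per_day} allowed)"
            )
        days.append(_interpolate_short_runs(values, limit=SAMPLES_PER_DAY))
    if not days:
        raise TraceValidationError(f"patient {patient!r}: no complete day")
    return GlucoseTrace(patient, np.concatenate(days))


def _interpolate_short_runs(values: np.ndarray, limit: int = MAX_INTERP_RUN) -> np.ndarray:
    series = pd.Series(values)
    filled = series.interpolate(limit=limit, limit_area="inside")
    # keep longer runs missing: pandas fills the first `limit` samples of a
    # long run too, so blank any run that was longer than the limit
    missing = series.isna().to_numpy()
    run_start = None
    out = filled.to_numpy().copy()
    for i, m in enumerate(np.append(missing, False)):
        if m and run_start is None:
            run_start = i
        elif not m and run_start is not None:
            if i - run_start > limit:
                out[run_start:i] = np.nan
            run_start = None
    return out


def write_traces(traces: Iterable[GlucoseTrace], path) -> None:
    """Write traces in the canonical 4-column CSV format."""
    records = []
    for trace in traces:
        days = trace.days()
        for day_idx in range(days.shape[0]):
            records.append(
                pd.DataFrame(
                    {
                        "patient_id": trace.patient_id,
                        "day": day_idx,
                        "slot": np.arange(SAMPLES_PER_DAY),
                        "glucose_mmol_per_L": days[day_idx],
                    }
                )
            )
    frame = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(columns=list(TRACE_COLUMNS))
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def write_feature_table(samples: Sequence[LabeledSample], path) -> None:
    """Write one row per patient: id, 17 features, T1D/T2D label."""
    rows = []
    for s in samples:
        row: dict[str, object] = {"patient_id": s.patient_id}
        row.update(dict(zip(FEATURE_NAMES, s.features.to_array())))
        row["label"] = INT_TO_LABEL[s.label]
        rows.append(row)
    columns = ["patient_id", *FEATURE_NAMES, "label"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> list[LabeledSample]:
    """Read a labeled feature table written by :func:`write_feature_table`."""
    frame = pd.read_csv(path)
    expected = ["patient_id", *FEATURE_NAMES, "label"]
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing feature-table columns {missing}")
    samples = []
    for _, row in frame.iterrows():
        label = row["label"]
        if label not in LABEL_TO_INT:
            raise ParseError(f"{path}: unknown label {label!r} (expected T1D/T2D)")
        vec = FeatureVector.from_array(row[list(FEATURE_NAMES)].to_numpy(dtype=float))
        samples.append(LabeledSample(str(row["patient_id"]), vec, LABEL_TO_INT[label]))
    return samples


def write_labels(pairs: Iterable[tuple[str, int]], path) -> None:
    """Write a two-column ``patient_id,label`` CSV (labels as T1D/T2D)."""
    frame = pd.DataFrame(
        [(pid, INT_TO_LABEL[label]) for pid, label in pairs],
        columns=["patient_id", "label"],
    )
    frame.to_csv(path, index=False)


def read_labels(path) -> dict[str, int]:
    """Read a ``patient_id,label`` CSV into an id → ±1 mapping."""
    frame = pd.read_csv(path)
    if "patient_id" not in frame.columns or "label" not in frame.columns:
        raise ParseError(f"{path}: need columns 'patient_id' and 'label'")
    out: dict[str, int] = {}
    for _, row in frame.iterrows():
        if row["label"] not in LABEL_TO_INT:
            raise ParseError(f"{path}: unknown label {row['label']!r}")
        out[str(row["patient_id"])] = LABEL_TO_INT[row["label"]]
    return out


def samples_to_arrays(samples: Sequence[LabeledSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack labeled samples into an ``(m, 17)`` matrix and a label vector."""
    if not samples:
        raise DataError("no samples")
    X = np.stack([s.features.to_array() for s in samples])
    y = np.array([s.label for s in samples], dtype=int)
    return X, y
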