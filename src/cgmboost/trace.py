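"""The ``GlucoseTrace`` container: one patient's CGM record on a regular grid.

A CGM sensor samples interstitial glucose every 5 minutes, i.e. 288 samples
per day.  All downstream feature definitions assume a complete, equally
spaced grid, so the container enforces it at construction time.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TraceValidationError

SAMPLES_PER_DAY = 288
SAMPLE_MINUTES = 5
MINUTES_PER_DAY = SAMPLES_PER_DAY * SAMPLE_MINUTES  # 1440


@dataclass(frozen=True)
class GlucoseTrace:
    """A patient's glucose concentrations (mmol/L) on the 5-minute grid.

    Parameters
    ----------
    patient_id
        Opaque identifier; never influences any computed feature.
    values
        Concatenated whole days, ``n_days * 288`` samples, all finite and
        strictly positive.
    """

    patient_id: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise TraceValidationError(
                f"trace {self.patient_id!r}: values must be one-dimensional"
            )
        if v.size == 0 or v.size % SAMPLES_PER_DAY != 0:
            raise TraceValidationError(
                f"trace {self.patient_id!r}: length {v.size} is not a "
                f"positive multiple of {SAMPLES_PER_DAY}"
            )
        if not np.all(np.isfinite(v)):
            raise TraceValidationError(
                f"trace {self.patient_id!r}: non-finite glucose value"
            )
        if np.any(v <= 0):
            raise TraceValidationError(
                f"trace {self.patient_id!r}: non-positive glucose value"
            )
        v = v.copy()
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    @property
    def n_days(self) -> int:
        return self.values.size // SAMPLES_PER_DAY

    def days(self) -> np.ndarray:
        """Return the record as an ``(n_days, 288)`` array (a view)."""
        return self.values.reshape(self.n_days, SAMPLES_PER_DAY)
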