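"""Core data containers: concentration time series and per-subject datasets.

All times are seconds internally; concentrations are mM (gadoxetate).
Minute-based files are converted at the I/O boundary (see :mod:`gadopk.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

#: Recognized tissue labels for measured/simulated curves.
TISSUES = ("liver", "spleen", "blood_aorta", "blood_portal")


class ValidationError(ValueError):
    """Raised when input data violate a structural invariant."""


@dataclass
class TimeSeries:
    """One tissue's gadoxetate concentration curve.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing, all >= 0.
    values
        Concentrations in mM.
    sigmas
        Per-point measurement SD in mM (all positive), or ``None`` for
        noise-free simulated curves.
    tissue
        One of :data:`TISSUES`.
    """

    times: np.ndarray
    values: np.ndarray
    sigmas: np.ndarray | None = None
    tissue: str = "liver"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.sigmas is not None:
            self.sigmas = np.asarray(self.sigmas, dtype=float)
        if self.tissue not in TISSUES:
            raise ValidationError(f"unknown tissue {self.tissue!r}; expected one of {TISSUES}")
        if self.times.ndim != 1 or self.values.shape != self.times.shape:
            raise ValidationError("times and values must be 1-D arrays of equal length")
        if self.times.size and self.times[0] < 0:
            raise ValidationError("times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if self.sigmas is not None:
            if self.sigmas.shape != self.times.shape:
                raise ValidationError("sigmas must match times in length")
            if np.any(self.sigmas <= 0):
                raise ValidationError("sigmas must all be positive")

    def __len__(self) -> int:
        return self.times.size

    @property
    def peak(self) -> float:
        return float(np.max(self.values))

    def interp(self, t: np.ndarray) -> np.ndarray:
        """Piecewise-linear interpolation of the curve at times ``t`` (s).

        Raises on extrapolation: the curve must cover the requested range.
        """
        t = np.asarray(t, dtype=float)
        if t.size and (t.min() < self.times[0] - 1e-9 or t.max() > self.times[-1] + 1e-9):
            raise ValidationError(
                f"requested times [{t.min():g}, {t.max():g}] s outside input support "
                f"[{self.times[0]:g}, {self.times[-1]:g}] s"
            )
        return np.interp(t, self.times, self.values)

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class SubjectDataset:
    """All measured curves plus dose metadata for one rat or human.

    ``dose_mg_per_kg`` is the hepatotoxic-drug dose (not the contrast agent);
    ``gadoxetate_dose_mmol_per_kg`` is the injected tracer amount used by the
    whole-body model.
    """

    subject_id: str
    species: str  # "rat" | "human"
    curves: Mapping[str, TimeSeries] = field(default_factory=dict)
    dose_mg_per_kg: float = 0.0
    gadoxetate_dose_mmol_per_kg: float = 0.025
    injection_duration_s: float = 10.0

    def __post_init__(self) -> None:
        if self.species not in ("rat", "human"):
            raise ValidationError(f"species must be 'rat' or 'human', got {self.species!r}")
        if self.dose_mg_per_kg < 0:
            raise ValidationError("dose must be non-negative")
        for tissue, ts in self.curves.items():
            if ts.tissue != tissue:
                raise ValidationError(f"curve stored under {tissue!r} is labelled {ts.tissue!r}")

    def __getitem__(self, tissue: str) -> TimeSeries:
        return self.curves[tissue]

    def __contains__(self, tissue: str) -> bool:
        return tissue in self.curves

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(self.curves)
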