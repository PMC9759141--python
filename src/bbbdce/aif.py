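"""Population arterial input function (AIF).

Plasma concentration Cp(t) is modelled as a dose-scaled bi-exponential decay
after bolus arrival,

    Cp(t) = D * (a1 * exp(-m1 (t - t0)) + a2 * exp(-m2 (t - t0))),  t >= t0,

with Cp = 0 before arrival. Amplitudes a1, a2 carry units of kg/L so that a
dose D in mmol/kg yields Cp in mmol/L; decay rates m1 > m2 are in min^-1.
Both the simulator and the Patlak fitter consume the same curve, sampled on
the acquisition's volume time grid.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .acquisition import AcquisitionParams

__all__ = ["AifParams", "AifCurve", "make_aif", "protocol_aif"]


@dataclass(frozen=True)
class AifParams:
    """Bi-exponential population AIF parameters.

    Defaults are the classic adult population values: amplitudes
    a1 = 3.99, a2 = 4.78 kg/L and decay rates m1 = 0.144, m2 = 0.0111 min^-1.
    ``t0_min`` is the bolus arrival time in minutes.
    """

    a1: float = 3.99
    a2: float = 4.78
    m1: float = 0.144
    m2: float = 0.0111
    t0_min: float = 0.0

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("AIF amplitudes must be non-negative")
        if not self.m1 > self.m2 > 0:
            raise ValueError(
                f"decay rates must satisfy m1 > m2 > 0, got m1={self.m1}, m2={self.m2}"
            )
        if self.t0_min < 0:
            raise ValueError("bolus arrival t0_min must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AifParams":
        return cls(**d)


@dataclass(frozen=True)
class AifCurve:
    """Plasma concentration Cp(t) (mmol/L) sampled on a minutes grid."""

    times_min: np.ndarray
    cp: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        c = np.asarray(self.cp, dtype=float)
        if t.ndim != 1 or c.shape != t.shape:
            raise ValueError("times_min and cp must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("AIF time grid must be strictly increasing")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "cp", c)

    def __len__(self) -> int:
        return self.times_min.size

    def same_grid(self, times_min: np.ndarray) -> bool:
        other = np.asarray(times_min, dtype=float)
        return other.shape == self.times_min.shape and np.allclose(
            other, self.times_min, rtol=0.0, atol=1e-12
        )


def make_aif(params: AifParams, dose: float, times_min: np.ndarray) -> AifCurve:
    """Evaluate the dose-scaled population AIF on a time grid.

    Parameters
    ----------
    params :
        Bi-exponential shape parameters including bolus arrival ``t0_min``.
    dose :
        Amplitude scale; with amplitudes in kg/L, pass the dose in mmol/kg
        to obtain Cp in mmol/L (1.0 gives the unit-dose curve).
    times_min :
        Strictly increasing minutes grid starting at 0.
    """
    t = np.asarray(times_min, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("times_min must be a non-empty 1-D array")
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError("time grid must be strictly increasing")
    if t[0] != 0.0:
        raise ValueError(f"time grid must start at 0, got t[0]={t[0]}")
    if dose < 0:
        raise ValueError("dose must be non-negative")
    dt = t - params.t0_min
    dt_pos = np.maximum(dt, 0.0)
    cp = dose * (
        params.a1 * np.exp(-params.m1 * dt_pos) + params.a2 * np.exp(-params.m2 * dt_pos)
    )
    cp[dt < 0] = 0.0
    return AifCurve(times_min=t, cp=cp)


def protocol_aif(
    acq: AcquisitionParams,
    params: AifParams | None = None,
    dose: float | None = None,
) -> AifCurve:
    """AIF on the acquisition grid with bolus arrival at the protocol time.

    Arrival is pinned to the start of volume ``n_baseline`` (the protocol
    starts the injection once the baseline block is complete) unless the
    supplied ``params`` already carry a positive ``t0_min``.
    """
    params = params or AifParams()
    if params.t0_min == 0.0:
        params = AifParams(
            a1=params.a1, a2=params.a2, m1=params.m1, m2=params.m2,
            t0_min=acq.bolus_arrival_min,
        )
    if dose is None:
        dose = acq.dose_mmol_per_kg
    return make_aif(params, dose, acq.times_min)
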