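"""Acquisition parameters for the dynamic contrast-enhanced (DCE) protocol.

The protocol modelled throughout this package is a T1-weighted 3D spoiled
gradient-echo (VIBE) acquisition repeated over the contrast injection:
a block of pre-contrast baseline volumes followed by the dynamic series,
with a weight-based gadoterate dose. All unit conversions (TR in ms, kinetic
time grid in minutes, relaxation rates in s^-1) are centralised here.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

__all__ = ["AcquisitionParams"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Sequence timing and contrast parameters of the dynamic acquisition.

    Parameters
    ----------
    tr_ms :
        Repetition time in milliseconds.
    te_ms :
        Echo time in milliseconds. Recorded for provenance only; the signal
        model deliberately omits T2*/TE decay.
    flip_deg :
        Nominal excitation flip angle in degrees.
    n_volumes :
        Number of dynamic volumes.
    dt_s :
        Acquisition time of one volume in seconds; volume ``k`` is assigned
        the time stamp ``k * dt_s``.
    n_baseline :
        Number of pre-contrast volumes. Contrast arrival is pinned to the
        start of volume index ``n_baseline``.
    dose_mmol_per_kg :
        Contrast dose in mmol per kg body weight; scales the population
        arterial input function.
    relaxivity_r1 :
        Longitudinal relaxivity of the contrast agent in L mmol^-1 s^-1
        (default 3.6, gadoterate at 3 T).
    """

    tr_ms: float = 2.56
    te_ms: float = 0.86
    flip_deg: float = 15.0
    n_volumes: int = 432
    dt_s: float = 2.4
    n_baseline: int = 10
    dose_mmol_per_kg: float = 0.05
    relaxivity_r1: float = 3.6

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ValueError(f"tr_ms must be positive, got {self.tr_ms}")
        if not 0.0 < self.flip_deg < 90.0:
            raise ValueError(f"flip_deg must lie in (0, 90), got {self.flip_deg}")
        if self.dt_s <= 0:
            raise ValueError(f"dt_s must be positive, got {self.dt_s}")
        if self.n_volumes < 2:
            raise ValueError(f"n_volumes must be >= 2, got {self.n_volumes}")
        if not 1 <= self.n_baseline < self.n_volumes:
            raise ValueError(
                f"n_baseline must satisfy 1 <= n_baseline < n_volumes, "
                f"got {self.n_baseline} with {self.n_volumes} volumes"
            )
        if self.dose_mmol_per_kg < 0:
            raise ValueError("dose_mmol_per_kg must be non-negative")
        if self.relaxivity_r1 <= 0:
            raise ValueError("relaxivity_r1 must be positive")

    @property
    def flip_rad(self) -> float:
        return math.radians(self.flip_deg)

    @property
    def times_min(self) -> np.ndarray:
        """Kinetic time grid in minutes; volume k at t = k*dt_s."""
        return np.arange(self.n_volumes, dtype=float) * (self.dt_s / 60.0)

    @property
    def bolus_arrival_min(self) -> float:
        """Contrast arrival time: start of the first post-baseline volume."""
        return self.n_baseline * self.dt_s / 60.0

    @property
    def total_time_min(self) -> float:
        return (self.n_volumes - 1) * self.dt_s / 60.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        return cls(**d)
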