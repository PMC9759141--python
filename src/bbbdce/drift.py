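"""Scanner signal-drift estimation and removal from in-FOV phantom tubes.

Gain drift over a ~17-minute dynamic acquisition biases the fitted leakage
rate, because the slow tissue enhancement it mimics (or cancels) is exactly
the signal the Patlak slope measures. Gel tubes placed in the field of view
have constant true signal, so their measured time course isolates the
scanner gain. The estimator fits a low-order polynomial (default linear) to
the mean tube signal over time and normalizes it to mean 1 over the
pre-contrast baseline window; correction divides every frame by the fitted
multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DriftCurve", "estimate_drift", "correct_drift"]


@dataclass(frozen=True)
class DriftCurve:
    """Multiplicative gain per frame, mean 1 over the reference window."""

    multipliers: np.ndarray  # (T,)
    reference_frames: int  # baseline window = frames [0, reference_frames)
    slope_per_min: float  # fitted linear coefficient (diagnostic)

    def __post_init__(self) -> None:
        m = np.asarray(self.multipliers, dtype=float)
        if m.ndim != 1:
            raise ValueError("multipliers must be 1-D")
        if np.any(m <= 0):
            raise ValueError("drift multipliers must be positive")
        object.__setattr__(self, "multipliers", m)


def estimate_drift(
    dce_4d: np.ndarray,
    phantom_labels: np.ndarray,
    n_baseline: int,
    times_min: np.ndarray | None = None,
    order: int = 1,
) -> DriftCurve:
    """Fit the scanner gain curve from the phantom-tube time course.

    Parameters
    ----------
    dce_4d :
        Dynamic signal (x, y, z, t).
    phantom_labels :
        Integer label volume; every voxel with label > 0 is a tube voxel.
    n_baseline :
        Pre-contrast window length; the fitted curve is normalized to mean 1
        over these frames.
    times_min :
        Frame times in minutes (defaults to the frame index).
    order :
        Polynomial order of the gain model (default 1, linear in time).
    """
    dce_4d = np.asarray(dce_4d, dtype=float)
    if dce_4d.ndim != 4:
        raise ValueError("dce_4d must be 4-D (x, y, z, t)")
    labels = np.asarray(phantom_labels)
    if labels.shape != dce_4d.shape[:3]:
        raise ValueError("phantom label volume does not match the image grid")
    tube = labels > 0
    if not tube.any():
        raise ValueError("phantom label volume contains no tube voxels")
    n_t = dce_4d.shape[-1]
    if not 1 <= n_baseline <= n_t:
        raise ValueError(f"n_baseline must lie in [1, {n_t}]")
    if times_min is None:
        times_min = np.arange(n_t, dtype=float)
    times_min = np.asarray(times_min, dtype=float)
    if times_min.shape != (n_t,):
        raise ValueError("times_min length does not match the frame count")
    if order < 0:
        raise ValueError("polynomial order must be >= 0")

    tube_mean = dce_4d[tube].mean(axis=0)  # (T,)
    coeffs = np.polynomial.polynomial.polyfit(times_min, tube_mean, deg=order)
    fitted = np.polynomial.polynomial.polyval(times_min, coeffs)
    if np.any(fitted <= 0):
        raise ValueError("fitted drift curve is non-positive; check phantom data")
    ref = fitted[:n_baseline].mean()
    slope = float(coeffs[1]) / ref if order >= 1 else 0.0
    return DriftCurve(
        multipliers=fitted / ref, reference_frames=n_baseline, slope_per_min=slope
    )


def correct_drift(dce_4d: np.ndarray, drift: DriftCurve) -> np.ndarray:
    """Divide each frame by its gain multiplier.

    Idempotent up to numerical tolerance: re-estimating on corrected data
    yields multipliers of 1. Commutes with global intensity scaling.
    """
    dce_4d = np.asarray(dce_4d, dtype=float)
    if dce_4d.ndim != 4:
        raise ValueError("dce_4d must be 4-D (x, y, z, t)")
    if drift.multipliers.size != dce_4d.shape[-1]:
        raise ValueError(
            f"drift curve has {drift.multipliers.size} frames, data has "
            f"{dce_4d.shape[-1]}"
        )
    return dce_4d / drift.multipliers
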