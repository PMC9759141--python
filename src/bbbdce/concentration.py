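"""Signal-to-concentration conversion for the dynamic series.

The dynamic signal is converted voxel-wise to contrast-agent concentration
by inverting the SPGR steady-state equation with the pre-contrast T1 map and
the B1 (flip-angle scale) map:

    alpha_eff = b1 * alpha
    E1_0  = exp(-TR / T1_0)
    A     = (1 - E1_0) / (1 - E1_0 * cos(alpha_eff))
    y(t)  = (S(t) / S0) * A
    E1(t) = (1 - y) / (1 - y * cos(alpha_eff))
    R1(t) = -ln(E1(t)) / TR          (in s^-1)
    C(t)  = (R1(t) - R1_0) / r1      (mmol/L)

Voxel-frames whose implied E1 falls outside (0, 1) are flagged invalid and
excluded from fitting rather than clamped. Gaussian spatial smoothing (the
pipeline default is a 4-mm-FWHM isotropic kernel, applied to the T1 map and
every dynamic frame before conversion) lives here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .acquisition import AcquisitionParams

__all__ = [
    "ConcentrationSeries",
    "smooth_gaussian",
    "baseline_signal",
    "signal_to_concentration",
    "FWHM_TO_SIGMA",
]

logger = logging.getLogger(__name__)

#: FWHM = sigma * 2*sqrt(2*ln 2); this is the divisor taking FWHM -> sigma.
FWHM_TO_SIGMA: float = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass
class ConcentrationSeries:
    """Voxel-wise concentration (mmol/L) with per-voxel-frame validity."""

    values: np.ndarray  # (X, Y, Z, T)
    valid: np.ndarray  # bool, same shape
    times_min: np.ndarray  # (T,)
    n_baseline: int

    def __post_init__(self) -> None:
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must share a shape")
        if self.values.shape[-1] != self.times_min.size:
            raise ValueError("time axis length does not match times_min")
        if not np.isfinite(self.values[self.valid]).all():
            raise ValueError("non-finite concentration flagged valid")


def smooth_gaussian(data: np.ndarray, fwhm_mm, voxel_size_mm) -> np.ndarray:
    """Spatial Gaussian smoothing of a 3-D volume or 4-D dynamic series.

    ``fwhm_mm`` is the kernel full-width-at-half-maximum (scalar isotropic or
    per-axis); sigma per axis is ``fwhm / (2.3548 * voxel_size)`` voxels.
    For 4-D input each time frame is smoothed independently (sigma 0 on the
    time axis). ``fwhm_mm = 0`` returns an unmodified copy. Edges use
    nearest-neighbour extension, so constant images stay constant.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim not in (3, 4):
        raise ValueError("expected a 3-D volume or 4-D dynamic series")
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,)).copy()
    vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,)).copy()
    if np.any(fwhm < 0):
        raise ValueError("fwhm_mm must be non-negative")
    if np.any(vox <= 0):
        raise ValueError("voxel_size_mm must be positive on every axis")
    if np.all(fwhm == 0):
        return data.copy()
    sigma_vox = fwhm / (FWHM_TO_SIGMA * vox)
    if data.ndim == 4:
        sigma = tuple(sigma_vox) + (0.0,)
    else:
        sigma = tuple(sigma_vox)
    return ndimage.gaussian_filter(data, sigma=sigma, mode="nearest")


def baseline_signal(dce_4d: np.ndarray, n_baseline: int) -> np.ndarray:
    """Voxel-wise mean of the first ``n_baseline`` pre-contrast frames."""
    dce_4d = np.asarray(dce_4d, dtype=float)
    if dce_4d.ndim != 4:
        raise ValueError("dce_4d must be 4-D (x, y, z, t)")
    if not 1 <= n_baseline <= dce_4d.shape[-1]:
        raise ValueError(
            f"n_baseline must lie in [1, {dce_4d.shape[-1]}], got {n_baseline}"
        )
    return dce_4d[..., :n_baseline].mean(axis=-1)


def signal_to_concentration(
    dce_4d: np.ndarray,
    s0_map: np.ndarray,
    t10_map_ms: np.ndarray,
    b1_map: np.ndarray,
    acq: AcquisitionParams,
    mask: np.ndarray | None = None,
) -> ConcentrationSeries:
    """Invert the SPGR equation frame-by-frame to concentration.

    Parameters
    ----------
    dce_4d :
        Dynamic signal (x, y, z, t), already drift-corrected / smoothed as
        desired.
    s0_map :
        Pre-contrast baseline signal (e.g. :func:`baseline_signal` output).
    t10_map_ms :
        Pre-contrast T1 in ms; voxels with T1 <= 0 are excluded.
    b1_map :
        Multiplicative flip-angle scale; 1 everywhere reproduces the
        uncorrected conversion.
    mask :
        Optional voxel mask restricting the conversion (e.g. brain only).

    Voxels with S0 <= 0 or T1_0 <= 0 are masked out entirely (count logged);
    individual frames whose implied E1 leaves (0, 1) are flagged invalid.
    """
    dce_4d = np.asarray(dce_4d, dtype=float)
    if dce_4d.ndim != 4:
        raise ValueError("dce_4d must be 4-D (x, y, z, t)")
    spatial = dce_4d.shape[:3]
    n_t = dce_4d.shape[-1]
    if n_t != acq.n_volumes:
        raise ValueError(
            f"dynamic series has {n_t} frames but acquisition declares "
            f"{acq.n_volumes}"
        )
    for name, arr in (("s0_map", s0_map), ("t10_map_ms", t10_map_ms), ("b1_map", b1_map)):
        if np.asarray(arr).shape != spatial:
            raise ValueError(f"{name} shape {np.asarray(arr).shape} != grid {spatial}")
    s0 = np.asarray(s0_map, dtype=float)
    t10 = np.asarray(t10_map_ms, dtype=float)
    b1 = np.asarray(b1_map, dtype=float)

    voxel_ok = (s0 > 0) & (t10 > 0) & (b1 > 0)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != spatial:
            raise ValueError("mask shape does not match grid")
        n_bad = int((mask & ~voxel_ok).sum())
        voxel_ok &= mask
    else:
        n_bad = int((~voxel_ok).sum())
    if n_bad:
        logger.info("signal_to_concentration: %d voxels masked (S0/T1/B1 invalid)", n_bad)

    values = np.zeros(spatial + (n_t,), dtype=float)
    valid = np.zeros(spatial + (n_t,), dtype=bool)
    if voxel_ok.any():
        cos_a = np.cos(np.deg2rad(acq.flip_deg) * b1[voxel_ok])[:, None]
        e10 = np.exp(-acq.tr_ms / t10[voxel_ok])[:, None]
        amp = (1.0 - e10) / (1.0 - e10 * cos_a)
        y = dce_4d[voxel_ok] / s0[voxel_ok][:, None] * amp
        denom = 1.0 - y * cos_a
        with np.errstate(divide="ignore", invalid="ignore"):
            e1t = np.where(denom != 0, (1.0 - y) / denom, np.nan)
            frame_ok = np.isfinite(e1t) & (e1t > 0) & (e1t < 1)
            r1t = np.where(frame_ok, -np.log(np.where(frame_ok, e1t, 0.5)), np.nan)
        r1t *= 1000.0 / acq.tr_ms  # ms^-1 -> s^-1
        r10 = (1000.0 / t10[voxel_ok])[:, None]
        conc = (r1t - r10) / acq.relaxivity_r1
        conc[~frame_ok] = 0.0
        values[voxel_ok] = conc
        valid[voxel_ok] = frame_ok
        n_invalid_frames = int((~frame_ok).sum())
        if n_invalid_frames:
            logger.info(
                "signal_to_concentration: %d voxel-frames flagged invalid "
                "(E1 outside (0, 1))",
                n_invalid_frames,
            )
    return ConcentrationSeries(
        values=values, valid=valid, times_min=acq.times_min, n_baseline=acq.n_baseline
    )
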