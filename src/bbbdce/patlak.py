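"""Voxel-wise Patlak fitting of concentration data to K-trans and Vp maps.

The Patlak model for slow, effectively unidirectional leakage reads

    Ct(t) = Ktrans * int_0^t Cp dtau + vp * Cp(t),

linear in the two parameters. Each voxel is fitted by ordinary least squares
of Ct on the two regressors [Cp(t), int Cp] with no intercept, over the
post-bolus frames: the coefficient on the running integral is K-trans
(min^-1), the coefficient on Cp is the plasma fraction vp. This direct
bilinear form avoids dividing by small late-time Cp values, but equals the
classic Patlak-plot regression (Ct/Cp vs intCp/Cp) on noise-free data.
Negative estimates are kept as-is — they carry distributional information
for the ROI histograms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .acquisition import AcquisitionParams
from .aif import AifCurve
from .concentration import ConcentrationSeries

__all__ = ["PkMaps", "cumulative_integral", "patlak_fit_voxel", "fit_maps"]

logger = logging.getLogger(__name__)

#: Minimum valid frames in the fit window for a voxel to be fitted.
MIN_VALID_FRAMES: int = 5

#: Relative condition-number cutoff flagging a rank-deficient Patlak design.
_RANK_RCOND: float = 1e-10


@dataclass
class PkMaps:
    """Voxel-wise pharmacokinetic maps from the Patlak fit.

    ``ktrans`` in min^-1, ``vp`` unitless, ``fit_quality`` the uncentered
    R^2 of the no-intercept regression, all NaN outside ``fit_mask``.
    """

    ktrans: np.ndarray
    vp: np.ndarray
    fit_quality: np.ndarray
    fit_mask: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not (
            self.ktrans.shape == self.vp.shape == self.fit_quality.shape == self.fit_mask.shape
        ):
            raise ValueError("all maps must share one grid")
        fq = self.fit_quality[self.fit_mask]
        if fq.size and (np.nanmin(fq) < -1e-9 or np.nanmax(fq) > 1 + 1e-9):
            raise ValueError("fit_quality must lie in [0, 1] where defined")


def cumulative_integral(cp: AifCurve) -> np.ndarray:
    """Running trapezoid integral of Cp (mmol.min/L); first element 0."""
    if len(cp) < 2:
        raise ValueError("AIF needs at least two samples to integrate")
    return cumulative_trapezoid(cp.cp, cp.times_min, initial=0.0)


def _r2_no_intercept(ct: np.ndarray, resid_ss: np.ndarray) -> np.ndarray:
    """Uncentered R^2; total SS about zero since the model has no intercept."""
    total_ss = np.sum(ct * ct, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(total_ss > 0, 1.0 - resid_ss / total_ss, 1.0)
    return np.clip(r2, 0.0, 1.0)


def patlak_fit_voxel(
    ct: np.ndarray,
    cp: AifCurve,
    fit_window: np.ndarray | None = None,
    valid: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Fit one voxel's concentration series; returns (ktrans, vp, r2).

    ``fit_window`` holds the frame indices entering the regression (default:
    all frames); ``valid`` is an optional per-frame validity flag further
    restricting it. Raises if fewer than 5 usable frames remain or the
    two-column design is rank deficient.
    """
    ct = np.asarray(ct, dtype=float)
    if ct.shape != (len(cp),):
        raise ValueError("ct length does not match the AIF grid")
    idx = np.arange(len(cp)) if fit_window is None else np.asarray(fit_window, dtype=int)
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        if valid.shape != (len(cp),):
            raise ValueError("valid flags length does not match the AIF grid")
        idx = idx[valid[idx]]
    if idx.size < MIN_VALID_FRAMES:
        raise ValueError(
            f"need at least {MIN_VALID_FRAMES} valid frames in the fit window, "
            f"got {idx.size}"
        )
    design = np.column_stack([cp.cp[idx], cumulative_integral(cp)[idx]])
    if np.linalg.matrix_rank(design, tol=_RANK_RCOND * np.abs(design).max()) < 2:
        raise ValueError(
            "rank-deficient Patlak design (Cp proportional to its integral "
            "over the fit window); voxel excluded"
        )
    coef, _, _, _ = np.linalg.lstsq(design, ct[idx], rcond=None)
    resid = ct[idx] - design @ coef
    r2 = float(_r2_no_intercept(ct[idx], np.sum(resid * resid)))
    return float(coef[1]), float(coef[0]), r2


def fit_maps(
    conc: ConcentrationSeries,
    cp: AifCurve,
    brain_mask: np.ndarray,
    acq: AcquisitionParams,
    fit_start_offset: int = 0,
) -> PkMaps:
    """Patlak-fit every masked voxel over the post-bolus frames.

    The fit window is frame index >= ``n_baseline + fit_start_offset`` (the
    offset skips early bolus-passage non-equilibrium; default 0). Voxels with
    fewer than 5 valid frames in the window, or a rank-deficient design, are
    excluded from the maps and counted in ``n_excluded``.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    spatial = conc.values.shape[:3]
    if brain_mask.shape != spatial:
        raise ValueError("brain_mask shape does not match the concentration grid")
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    if not cp.same_grid(conc.times_min):
        raise ValueError("AIF grid does not match the concentration time grid")
    start = acq.n_baseline + int(fit_start_offset)
    if start >= acq.n_volumes - MIN_VALID_FRAMES:
        raise ValueError("fit window too short after the start offset")
    window = np.arange(start, acq.n_volumes)

    cumcp = cumulative_integral(cp)
    design_full = np.column_stack([cp.cp[window], cumcp[window]])
    if np.linalg.matrix_rank(
        design_full, tol=_RANK_RCOND * np.abs(design_full).max()
    ) < 2:
        raise ValueError("rank-deficient Patlak design over the fit window")

    nan = np.full(spatial, np.nan)
    ktrans, vp, r2 = nan.copy(), nan.copy(), nan.copy()
    fit_mask = np.zeros(spatial, dtype=bool)

    ct_vox = conc.values[brain_mask][:, window]  # (N, F)
    ok_vox = conc.valid[brain_mask][:, window]
    vox_index = np.flatnonzero(brain_mask.ravel())
    n_excluded = 0

    all_valid = ok_vox.all(axis=1)
    if all_valid.any():
        y = ct_vox[all_valid].T  # (F, Nv)
        coef, _, _, _ = np.linalg.lstsq(design_full, y, rcond=None)
        resid = y - design_full @ coef
        r2_batch = _r2_no_intercept(y.T, np.sum(resid * resid, axis=0))
        flat = vox_index[all_valid]
        ktrans.ravel()[flat] = coef[1]
        vp.ravel()[flat] = coef[0]
        r2.ravel()[flat] = r2_batch
        fit_mask.ravel()[flat] = True

    # Voxels with some invalid frames: fit individually on their valid subset.
    partial = np.flatnonzero(~all_valid)
    for j in partial:
        ok = ok_vox[j]
        if ok.sum() < MIN_VALID_FRAMES:
            n_excluded += 1
            continue
        design = design_full[ok]
        if np.linalg.matrix_rank(design, tol=_RANK_RCOND * np.abs(design).max()) < 2:
            n_excluded += 1
            continue
        coef, _, _, _ = np.linalg.lstsq(design, ct_vox[j, ok], rcond=None)
        resid = ct_vox[j, ok] - design @ coef
        flat = vox_index[j]
        ktrans.ravel()[flat] = coef[1]
        vp.ravel()[flat] = coef[0]
        r2.ravel()[flat] = _r2_no_intercept(ct_vox[j, ok], float(np.sum(resid * resid)))
        fit_mask.ravel()[flat] = True

    if n_excluded:
        logger.info("fit_maps: %d voxels excluded (<%d valid frames or rank "
                    "deficiency)", n_excluded, MIN_VALID_FRAMES)
    return PkMaps(ktrans=ktrans, vp=vp, fit_quality=r2, fit_mask=fit_mask,
                  n_excluded=n_excluded)
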