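"""Synthetic multi-subject DCE-MRI datasets with known ground-truth kinetics.

The generator emulates the acquisition the downstream pipeline targets: a
T1-weighted spoiled gradient-echo dynamic series (432 volumes x 2.4 s by
default, 10 pre-contrast baselines), a pre-contrast T1 map, a smooth
multiplicative B1 (flip-angle scale) map, ten anatomical ROI labels, and
in-FOV drift phantom tubes whose true signal is constant apart from scanner
gain drift and noise. Tissue enhancement follows the forward Patlak model

    Ct(t) = Ktrans * int_0^t Cp dtau + vp * Cp(t)

with the cumulative integral evaluated by the trapezoid rule on the sampled
grid, so the downstream fit (which shares that quadrature) is exact on
noiseless data. Concentration is mapped to signal through the SPGR
steady-state equation via the linear relaxivity model
R1(t) = R1_0 + r1 * Ct(t).

A sampling-level cohort simulator (:func:`sample_cohort_metrics`) draws
per-subject, per-ROI voxel K-trans values from the same generative
distributions without rendering images; it exists so that cohort-scale
statistical studies (null calibration, direction-of-effect) run in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .acquisition import AcquisitionParams
from .aif import AifCurve, AifParams, protocol_aif
from .roi_histogram import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_HIST_RANGE,
    ROI_NAMES,
    RoiSample,
    histogram_metrics,
)

__all__ = [
    "PhantomSpec",
    "GroupEffectSpec",
    "SubjectDataset",
    "spgr_signal",
    "simulate_tissue_curve",
    "generate_subject",
    "generate_cohort",
    "iter_cohort",
    "sample_cohort_metrics",
    "default_phantom",
    "uniform_phantom",
    "KTRANS_BASE_BY_ROI",
    "KTRANS_SHIFT_BY_ROI",
]

#: Group-A (reference genotype) mean K-trans per ROI in min^-1, set to the
#: observed modal positions of the ten regions (~0.5-1.9 x 1e-3 min^-1).
KTRANS_BASE_BY_ROI: dict[int, float] = {
    1: 1.21e-3,
    2: 1.16e-3,
    3: 1.00e-3,
    4: 0.77e-3,
    5: 0.78e-3,
    6: 0.52e-3,
    7: 1.90e-3,
    8: 1.44e-3,
    9: 1.16e-3,
    10: 1.18e-3,
}

#: Additive group-B shift per ROI (min^-1): subtle, mostly positive in the
#: hippocampal/subcortical regions, near zero or negative in cortical ones.
KTRANS_SHIFT_BY_ROI: dict[int, float] = {
    1: 0.14e-3,
    2: 0.13e-3,
    3: 0.02e-3,
    4: 0.01e-3,
    5: -0.10e-3,
    6: 0.04e-3,
    7: -0.05e-3,
    8: 0.28e-3,
    9: 0.13e-3,
    10: 0.11e-3,
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Digital-phantom geometry, tissue properties and corruption levels.

    ``roi_layout`` and ``phantom_layout`` map label id -> boolean voxel mask;
    they must be disjoint. ``brain_mask`` is the full parenchyma (ROIs
    included). Drift is a fractional gain change per minute applied to every
    voxel; noise is additive Gaussian on the magnitude signal by default
    (``noise_model="rician"`` switches to magnitude-of-complex noise).
    """

    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    roi_layout: dict[int, np.ndarray]
    phantom_layout: dict[int, np.ndarray]
    brain_mask: np.ndarray
    t1_by_tissue: dict[str, float] = field(
        default_factory=lambda: {"brain": 1200.0, "phantom": 400.0}
    )
    m0_by_tissue: dict[str, float] = field(
        default_factory=lambda: {"brain": 1000.0, "phantom": 1400.0}
    )
    b1_field_range: tuple[float, float] = (0.92, 1.08)
    noise_sigma: float = 0.3
    drift_slope: float = 0.0
    ktrans_background: float = 1.0e-3
    ktrans_voxel_cv: float = 0.5
    noise_model: str = "gaussian"

    def __post_init__(self) -> None:
        shape = tuple(self.grid_shape)
        occupancy = np.zeros(shape, dtype=int)
        for layout in (self.roi_layout, self.phantom_layout):
            for label, mask in layout.items():
                mask = np.asarray(mask, dtype=bool)
                if mask.shape != shape:
                    raise ValueError(
                        f"label {label} mask shape {mask.shape} != grid {shape}"
                    )
                occupancy += mask
        if (occupancy > 1).any():
            raise ValueError("ROI and phantom label masks must be disjoint")
        brain = np.asarray(self.brain_mask, dtype=bool)
        if brain.shape != shape:
            raise ValueError("brain_mask shape does not match grid")
        for rid, mask in self.roi_layout.items():
            if not brain[np.asarray(mask, dtype=bool)].all():
                raise ValueError(f"ROI {rid} extends outside the brain mask")
        for pid, mask in self.phantom_layout.items():
            if brain[np.asarray(mask, dtype=bool)].any():
                raise ValueError(f"phantom tube {pid} overlaps the brain mask")
        lo, hi = self.b1_field_range
        if not (0.0 < lo <= hi < 2.0):
            raise ValueError("b1_field_range must lie within (0, 2)")
        for name, t1 in self.t1_by_tissue.items():
            if t1 <= 0:
                raise ValueError(f"T1 of tissue '{name}' must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.ktrans_voxel_cv < 0:
            raise ValueError("ktrans_voxel_cv must be non-negative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")

    def roi_label_volume(self) -> np.ndarray:
        vol = np.zeros(self.grid_shape, dtype=np.int16)
        for label, mask in self.roi_layout.items():
            vol[np.asarray(mask, dtype=bool)] = label
        return vol

    def phantom_label_volume(self) -> np.ndarray:
        vol = np.zeros(self.grid_shape, dtype=np.int16)
        for label, mask in self.phantom_layout.items():
            vol[np.asarray(mask, dtype=bool)] = label
        return vol


@dataclass
class GroupEffectSpec:
    """Two-group cohort structure with a subtle regional K-trans shift.

    Group A is the reference genotype (n=19 by default), group B the risk
    genotype (n=17). Per-subject ROI mean K-trans is drawn normally around
    the group mean with coefficient of variation ``ktrans_cv`` (clipped at a
    small positive floor). ``ktrans_shift_by_roi`` is added for group B.
    """

    n_group_a: int = 19
    n_group_b: int = 17
    ktrans_base_by_roi: dict[int, float] = field(
        default_factory=lambda: dict(KTRANS_BASE_BY_ROI)
    )
    ktrans_shift_by_roi: dict[int, float] = field(
        default_factory=lambda: dict(KTRANS_SHIFT_BY_ROI)
    )
    ktrans_cv: float = 0.4
    vp_base: float = 0.02
    rng_seed: int = 0

    group_a_label: str = "APOE3"
    group_b_label: str = "APOE4"

    def __post_init__(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("each group needs at least 2 subjects")
        if any(v < 0 for v in self.ktrans_base_by_roi.values()):
            raise ValueError("base K-trans values must be non-negative")
        if any(
            self.ktrans_base_by_roi[r] + self.ktrans_shift_by_roi.get(r, 0.0) < 0
            for r in self.ktrans_base_by_roi
        ):
            raise ValueError("shifted group-B K-trans means must be non-negative")
        if not 0.0 <= self.vp_base < 1.0:
            raise ValueError("vp_base must lie in [0, 1)")
        if self.ktrans_cv < 0:
            raise ValueError("ktrans_cv must be non-negative")

    @property
    def n_subjects(self) -> int:
        return self.n_group_a + self.n_group_b

    def group_label(self, index: int) -> str:
        return self.group_a_label if index < self.n_group_a else self.group_b_label


@dataclass
class SubjectDataset:
    """One aligned synthetic subject: dynamic signal, maps, labels, truth."""

    subject_id: str
    signal: np.ndarray  # (X, Y, Z, T)
    t1_map_ms: np.ndarray  # (X, Y, Z), 0 outside tissue
    b1_map: np.ndarray  # (X, Y, Z)
    roi_labels: np.ndarray  # int, 0 = none
    phantom_labels: np.ndarray  # int, 0 = none
    brain_mask: np.ndarray  # bool
    truth_ktrans: np.ndarray  # min^-1
    truth_vp: np.ndarray  # fraction
    acq: AcquisitionParams
    aif_params: AifParams
    voxel_size_mm: tuple[float, float, float]
    seed: int
    group: str | None = None

    @property
    def times_min(self) -> np.ndarray:
        return self.acq.times_min


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------


def spgr_signal(m0, t1_ms, flip_deg: float, b1=1.0, tr_ms: float = 2.56):
    """Spoiled gradient-echo steady-state signal.

    S = m0 * sin(b1*alpha) * (1 - E1) / (1 - E1*cos(b1*alpha)),
    E1 = exp(-TR/T1). TE/T2* decay is deliberately omitted. Scalar or
    broadcastable array arguments are accepted.
    """
    m0 = np.asarray(m0, dtype=float)
    t1_ms = np.asarray(t1_ms, dtype=float)
    b1 = np.asarray(b1, dtype=float)
    if np.any(t1_ms <= 0):
        raise ValueError("t1_ms must be positive")
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    alpha = np.deg2rad(flip_deg) * b1
    if np.any(alpha <= 0) or np.any(alpha >= np.pi):
        raise ValueError("effective flip angle b1*alpha must lie in (0, 180) degrees")
    e1 = np.exp(-tr_ms / t1_ms)
    out = m0 * np.sin(alpha) * (1.0 - e1) / (1.0 - e1 * np.cos(alpha))
    return out if out.ndim else float(out)


def simulate_tissue_curve(ktrans, vp, aif: AifCurve, times_min=None):
    """Forward Patlak tissue concentration on the AIF's time grid.

    Ct(t) = ktrans * int_0^t Cp dtau + vp * Cp(t), with the running integral
    computed by the trapezoid rule on the sampled grid (the same quadrature
    the fitter uses). ``ktrans``/``vp`` may be scalars or arrays of matching
    shape; the output gains a trailing time axis.
    """
    if times_min is not None and not aif.same_grid(times_min):
        raise ValueError("times_min does not match the AIF time grid")
    ktrans = np.asarray(ktrans, dtype=float)
    vp = np.asarray(vp, dtype=float)
    if np.any(ktrans < 0):
        raise ValueError("ktrans must be non-negative in simulation")
    if np.any(vp < 0) or np.any(vp >= 1):
        raise ValueError("vp must lie in [0, 1)")
    cumcp = cumulative_trapezoid(aif.cp, aif.times_min, initial=0.0)
    ct = np.multiply.outer(ktrans, cumcp) + np.multiply.outer(vp, aif.cp)
    return ct


# ---------------------------------------------------------------------------
# Phantom builders
# ---------------------------------------------------------------------------


def _box(shape, xs: slice, ys: slice, zs: slice) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[xs, ys, zs] = True
    return m


def default_phantom(
    noise_sigma: float = 0.3,
    drift_slope: float = 0.0,
    ktrans_voxel_cv: float = 0.5,
    noise_model: str = "gaussian",
) -> PhantomSpec:
    """Default 32x32x12 digital phantom at 2.5 x 2.5 x 5 mm voxels.

    The parenchyma is a central box; the ten ROIs are disjoint 5x4x3-voxel
    blocks (60 voxels each) arranged in two columns of five, and three
    phantom tubes sit outside the head along the first axis.
    """
    shape = (32, 32, 12)
    brain = _box(shape, slice(4, 28), slice(4, 28), slice(2, 10))
    roi_layout: dict[int, np.ndarray] = {}
    for row in range(5):
        y0 = 5 + 4 * row
        for col, x0 in enumerate((6, 21)):
            rid = 2 * row + col + 1
            roi_layout[rid] = _box(
                shape, slice(x0, x0 + 5), slice(y0, y0 + 4), slice(4, 7)
            )
    phantom_layout = {
        tid + 1: _box(shape, slice(0, 3), slice(y0, y0 + 3), slice(3, 8))
        for tid, y0 in enumerate((2, 14, 26))
    }
    return PhantomSpec(
        grid_shape=shape,
        voxel_size_mm=(2.5, 2.5, 5.0),
        roi_layout=roi_layout,
        phantom_layout=phantom_layout,
        brain_mask=brain,
        noise_sigma=noise_sigma,
        drift_slope=drift_slope,
        ktrans_voxel_cv=ktrans_voxel_cv,
        noise_model=noise_model,
    )


def uniform_phantom(
    grid_shape: tuple[int, int, int] = (20, 20, 8),
    roi_margin: int = 2,
    noise_sigma: float = 0.0,
    drift_slope: float = 0.0,
) -> PhantomSpec:
    """Single-ROI phantom with spatially uniform kinetics.

    The whole interior (grid minus ``roi_margin``) is one ROI (label 1) with
    zero within-ROI K-trans spread — the geometry used for parameter-recovery
    studies where a large ROI of identical truth is required. One phantom
    tube occupies a strip outside the parenchyma.
    """
    shape = tuple(grid_shape)
    m = roi_margin
    brain = _box(shape, slice(m + 2, shape[0] - m), slice(m, shape[1] - m), slice(m, shape[2] - m))
    roi = brain.copy()
    tube = _box(shape, slice(0, 2), slice(2, 5), slice(1, shape[2] - 1))
    return PhantomSpec(
        grid_shape=shape,
        voxel_size_mm=(2.5, 2.5, 5.0),
        roi_layout={1: roi},
        phantom_layout={1: tube},
        brain_mask=brain,
        noise_sigma=noise_sigma,
        drift_slope=drift_slope,
        ktrans_voxel_cv=0.0,
    )


# ---------------------------------------------------------------------------
# Subject and cohort generation
# ---------------------------------------------------------------------------


def _b1_field(phantom: PhantomSpec) -> np.ndarray:
    """Smooth, deterministic multiplicative flip-angle scale field."""
    nx, ny, nz = phantom.grid_shape
    x = np.linspace(0.0, 1.0, nx)[:, None, None]
    y = np.linspace(0.0, 1.0, ny)[None, :, None]
    z = np.linspace(0.0, 1.0, nz)[None, None, :]
    ramp = (x + y + z) / 3.0  # linear in space, spans [0, 1]
    lo, hi = phantom.b1_field_range
    return lo + (hi - lo) * ramp


def generate_subject(
    phantom: PhantomSpec,
    acq: AcquisitionParams,
    aif_params: AifParams,
    truth_ktrans_by_roi: dict[int, float],
    truth_vp: float,
    seed: int,
    subject_id: str = "sub-000",
) -> SubjectDataset:
    """Render one synthetic subject from ground-truth kinetics.

    Pipeline: draw the voxel-wise truth K-trans map (per-ROI mean with
    within-ROI CV ``phantom.ktrans_voxel_cv``), forward-simulate tissue
    concentration, map through the SPGR signal equation with the subject's
    B1 field, impose multiplicative linear gain drift, and add noise. The
    phantom tubes carry no contrast: their true signal is constant up to
    drift and noise. Identical inputs and seed give bit-identical output.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError("seed must be an integer")
    rng = np.random.default_rng(int(seed))
    shape = phantom.grid_shape
    times = acq.times_min

    roi_labels = phantom.roi_label_volume()
    phantom_labels = phantom.phantom_label_volume()
    brain = np.asarray(phantom.brain_mask, dtype=bool)
    tubes = phantom_labels > 0

    t1_map = np.zeros(shape, dtype=float)
    m0_map = np.zeros(shape, dtype=float)
    t1_map[brain] = phantom.t1_by_tissue["brain"]
    m0_map[brain] = phantom.m0_by_tissue["brain"]
    t1_map[tubes] = phantom.t1_by_tissue["phantom"]
    m0_map[tubes] = phantom.m0_by_tissue["phantom"]
    b1_map = _b1_field(phantom)

    # Voxel-wise truth K-trans: background level everywhere in brain, per-ROI
    # means inside the labelled regions, both with within-ROI spread.
    truth_ktrans = np.zeros(shape, dtype=float)
    cv = phantom.ktrans_voxel_cv

    def _draw(mask: np.ndarray, mean: float) -> None:
        n = int(mask.sum())
        if n == 0:
            return
        if cv > 0 and mean > 0:
            vals = rng.normal(mean, cv * mean, size=n)
            np.clip(vals, 0.0, None, out=vals)
        else:
            vals = np.full(n, mean)
        truth_ktrans[mask] = vals

    _draw(brain & (roi_labels == 0), phantom.ktrans_background)
    for rid in sorted(phantom.roi_layout):
        if rid not in truth_ktrans_by_roi:
            raise KeyError(f"truth_ktrans_by_roi missing ROI {rid}")
        _draw(roi_labels == rid, float(truth_ktrans_by_roi[rid]))

    if not 0.0 <= truth_vp < 1.0:
        raise ValueError("truth_vp must lie in [0, 1)")
    truth_vp_map = np.zeros(shape, dtype=float)
    truth_vp_map[brain] = truth_vp

    aif = protocol_aif(acq, aif_params)

    # Tissue signal: SPGR of the contrast-shortened T1, brain voxels only.
    signal = np.zeros(shape + (acq.n_volumes,), dtype=float)
    kt_b = truth_ktrans[brain]
    vp_b = truth_vp_map[brain]
    ct = simulate_tissue_curve(kt_b, vp_b, aif)  # (Nb, T)
    r10 = 1000.0 / t1_map[brain]  # s^-1
    r1t = r10[:, None] + acq.relaxivity_r1 * ct
    t1t_ms = 1000.0 / r1t
    signal[brain] = spgr_signal(
        m0_map[brain][:, None], t1t_ms, acq.flip_deg, b1_map[brain][:, None], acq.tr_ms
    )
    # Phantom tubes: constant true signal (no contrast uptake).
    s_tube = spgr_signal(
        m0_map[tubes], t1_map[tubes], acq.flip_deg, b1_map[tubes], acq.tr_ms
    )
    signal[tubes] = np.repeat(s_tube[:, None], acq.n_volumes, axis=1)

    if phantom.drift_slope != 0.0:
        gain = 1.0 + phantom.drift_slope * times
        if np.any(gain <= 0):
            raise ValueError("drift_slope drives the gain non-positive")
        signal *= gain

    if phantom.noise_sigma > 0:
        if phantom.noise_model == "rician":
            n_re = rng.normal(0.0, phantom.noise_sigma, signal.shape)
            n_im = rng.normal(0.0, phantom.noise_sigma, signal.shape)
            signal = np.sqrt((signal + n_re) ** 2 + n_im**2)
        else:
            signal = signal + rng.normal(0.0, phantom.noise_sigma, signal.shape)

    return SubjectDataset(
        subject_id=subject_id,
        signal=signal,
        t1_map_ms=t1_map,
        b1_map=b1_map,
        roi_labels=roi_labels,
        phantom_labels=phantom_labels,
        brain_mask=brain,
        truth_ktrans=truth_ktrans,
        truth_vp=truth_vp_map,
        acq=acq,
        aif_params=aif_params,
        voxel_size_mm=tuple(phantom.voxel_size_mm),
        seed=int(seed),
        group=None,
    )


def _subject_roi_means(
    effect: GroupEffectSpec, rng: np.random.Generator, is_group_b: bool
) -> dict[int, float]:
    """Per-subject ROI mean K-trans around the group mean at the stated CV."""
    means: dict[int, float] = {}
    for rid, base in sorted(effect.ktrans_base_by_roi.items()):
        mu = base + (effect.ktrans_shift_by_roi.get(rid, 0.0) if is_group_b else 0.0)
        if effect.ktrans_cv > 0 and mu > 0:
            val = rng.normal(mu, effect.ktrans_cv * mu)
            val = max(val, 1e-6)
        else:
            val = mu
        means[rid] = float(val)
    return means


def iter_cohort(
    effect: GroupEffectSpec,
    phantom: PhantomSpec | None = None,
    acq: AcquisitionParams | None = None,
    aif_params: AifParams | None = None,
):
    """Lazily generate the cohort's subjects (memory-friendly form).

    Yields ``(SubjectDataset, group_label)`` with per-subject seeds drawn
    from ``effect.rng_seed``, so cohorts are reproducible end to end.
    """
    phantom = phantom or default_phantom()
    acq = acq or AcquisitionParams()
    aif_params = aif_params or AifParams()
    missing = set(phantom.roi_layout) - set(effect.ktrans_base_by_roi)
    if missing:
        raise ValueError(f"effect spec lacks base K-trans for ROIs {sorted(missing)}")
    rng = np.random.default_rng(effect.rng_seed)
    for i in range(effect.n_subjects):
        group = effect.group_label(i)
        is_b = group == effect.group_b_label
        subject_seed = int(rng.integers(0, 2**31 - 1))
        roi_means = _subject_roi_means(effect, rng, is_b)
        ds = generate_subject(
            phantom,
            acq,
            aif_params,
            roi_means,
            effect.vp_base,
            seed=subject_seed,
            subject_id=f"sub-{i:03d}",
        )
        ds.group = group
        yield ds, group


def generate_cohort(
    effect: GroupEffectSpec,
    phantom: PhantomSpec | None = None,
    acq: AcquisitionParams | None = None,
    aif_params: AifParams | None = None,
) -> list[tuple[SubjectDataset, str]]:
    """Generate the full cohort as a list of (subject, group-label) pairs."""
    return list(iter_cohort(effect, phantom, acq, aif_params))


# ---------------------------------------------------------------------------
# Sampling-level cohort simulator (no image rendering)
# ---------------------------------------------------------------------------


def sample_cohort_metrics(
    effect: GroupEffectSpec,
    seed: int | None = None,
    n_voxels_mean: int = 150,
    n_voxels_jitter: float = 0.3,
    ktrans_voxel_cv: float = 0.5,
    fit_noise_sd: float = 0.4e-3,
    bin_width: float = DEFAULT_BIN_WIDTH,
    hist_range: tuple[float, float] = DEFAULT_HIST_RANGE,
) -> pd.DataFrame:
    """Per-subject ROI histogram metrics drawn at the sampling level.

    Voxel K-trans estimates for subject i, ROI r are drawn as

        N(mu_ir, sqrt((cv_vox * mu_ir)^2 + fit_noise_sd^2)),

    where mu_ir is the subject's ROI mean (group mean + shift, between-subject
    CV ``effect.ktrans_cv``) — the same distributions the image generator
    uses, with ``fit_noise_sd`` standing in for the per-voxel noise floor of
    the Patlak estimates. ROI voxel counts vary uniformly within
    ``n_voxels_mean * (1 +/- n_voxels_jitter)``, supplying a realistic ANCOVA
    covariate. Returns the same long-format table the imaging pipeline emits:
    one row per subject per ROI with columns subject_id, group, roi_id,
    roi_name, voxel_count, peak_height, peak_position, roi_mean_ktrans
    (metrics on the 1e-3 min^-1 scale).
    """
    rng = np.random.default_rng(effect.rng_seed if seed is None else seed)
    lo = max(2, int(round(n_voxels_mean * (1.0 - n_voxels_jitter))))
    hi = max(lo + 1, int(round(n_voxels_mean * (1.0 + n_voxels_jitter))) + 1)
    rows = []
    for i in range(effect.n_subjects):
        group = effect.group_label(i)
        is_b = group == effect.group_b_label
        roi_means = _subject_roi_means(effect, rng, is_b)
        for rid, mu in sorted(roi_means.items()):
            n_vox = int(rng.integers(lo, hi))
            sd = math.hypot(ktrans_voxel_cv * mu, fit_noise_sd)
            values = rng.normal(mu, sd, size=n_vox) if sd > 0 else np.full(n_vox, mu)
            sample = RoiSample(
                roi_id=rid,
                roi_name=ROI_NAMES.get(rid, f"roi_{rid}"),
                values=values * 1e3,
            )
            hm = histogram_metrics(sample, bin_width=bin_width, hist_range=hist_range)
            rows.append(
                {
                    "subject_id": f"sub-{i:03d}",
                    "group": group,
                    "roi_id": rid,
                    "roi_name": sample.roi_name,
                    "voxel_count": n_vox,
                    "peak_height": hm.peak_height,
                    "peak_position": hm.peak_position,
                    "roi_mean_ktrans": sample.mean,
                }
            )
    return pd.DataFrame(rows)
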