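import numpy as np
import pytest

from bbbdce import (
    cumulative_integral,
    fit_maps,
    patlak_fit_voxel,
    simulate_tissue_curve,
)
from bbbdce.aif import AifCurve
from bbbdce.concentration import ConcentrationSeries


class TestCumulativeIntegral:
    def test_hand_trapezoid(self):
        aif = AifCurve(times_min=np.array([0.0, 1.0, 2.0]), cp=np.array([0.0, 1.0, 2.0]))
        np.testing.assert_allclose(cumulative_integral(aif), [0.0, 0.5, 2.0])

    def test_zero_cp(self):
        aif = AifCurve(times_min=np.arange(5.0), cp=np.zeros(5))
        np.testing.assert_array_equal(cumulative_integral(aif), 0.0)

    def test_constant_cp_exact(self):
        t = np.array([0.0, 0.3, 1.1, 2.0, 4.0])
        aif = AifCurve(times_min=t, cp=np.full(5, 3.0))
        np.testing.assert_allclose(cumulative_integral(aif), 3.0 * t, rtol=1e-15)

    def test_single_sample_rejected(self):
        aif = AifCurve(times_min=np.array([0.0]), cp=np.array([1.0]))
        with pytest.raises(ValueError, match="two samples"):
            cumulative_integral(aif)


class TestVoxelFit:
    def test_pure_vp_limit(self, aif_short):
        ct = 0.02 * aif_short.cp
        k, v, r2 = patlak_fit_voxel(ct, aif_short)
        assert k == pytest.approx(0.0, abs=1e-15)
        assert v == pytest.approx(0.02, rel=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_recovers_generating_parameters(self, aif_short):
        ct = simulate_tissue_curve(1.5e-3, 0.02, aif_short)
        k, v, r2 = patlak_fit_voxel(ct, aif_short)
        assert k == pytest.approx(1.5e-3, rel=1e-9)
        assert v == pytest.approx(0.02, rel=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_zero_concentration(self, aif_short):
        k, v, r2 = patlak_fit_voxel(np.zeros(len(aif_short)), aif_short)
        assert k == 0.0 and v == 0.0

    def test_scale_equivariance(self, aif_short):
        """Scaling Cp and Ct together leaves K-trans and Vp unchanged."""
        ct = simulate_tissue_curve(2e-3, 0.03, aif_short)
        scaled = AifCurve(times_min=aif_short.times_min, cp=7.0 * aif_short.cp)
        k, v, _ = patlak_fit_voxel(7.0 * ct, scaled)
        assert k == pytest.approx(2e-3, rel=1e-9)
        assert v == pytest.approx(0.03, rel=1e-9)

    def test_matches_classic_patlak_plot(self, aif_short, acq_short):
        """Direct bilinear fit equals the ratio-form regression, Cp > 0."""
        ct = simulate_tissue_curve(1.2e-3, 0.025, aif_short)
        window = np.arange(acq_short.n_baseline, acq_short.n_volumes)
        k, v, _ = patlak_fit_voxel(ct, aif_short, fit_window=window)
        # oracle: OLS of Ct/Cp on intCp/Cp with intercept (classic plot)
        cp = aif_short.cp[window]
        x = cumulative_integral(aif_short)[window] / cp
        y = ct[window] / cp
        slope, intercept = np.polyfit(x, y, 1)
        assert k == pytest.approx(slope, rel=1e-9)
        assert v == pytest.approx(intercept, rel=1e-9)

    def test_too_few_frames_rejected(self, aif_short):
        ct = np.zeros(len(aif_short))
        with pytest.raises(ValueError, match="at least 5 valid frames"):
            patlak_fit_voxel(ct, aif_short, fit_window=np.arange(4))

    def test_rank_deficient_design_rejected(self):
        # Cp == 0 over the window: both regressors vanish
        aif = AifCurve(times_min=np.arange(10.0), cp=np.zeros(10))
        with pytest.raises(ValueError, match="rank-deficient"):
            patlak_fit_voxel(np.zeros(10), aif)

    def test_negative_estimates_returned_unclamped(self, aif_short):
        cum = cumulative_integral(aif_short)
        ct = -1e-3 * cum + 0.01 * aif_short.cp
        k, v, _ = patlak_fit_voxel(ct, aif_short)
        assert k == pytest.approx(-1e-3, rel=1e-9)


class TestFitMaps:
    def _conc_from_truth(self, subject):
        """Noise-free concentration series straight from the truth maps."""
        from bbbdce.aif import protocol_aif

        aif = protocol_aif(subject.acq, subject.aif_params)
        shape = subject.truth_ktrans.shape
        values = np.zeros(shape + (subject.acq.n_volumes,))
        values[subject.brain_mask] = simulate_tissue_curve(
            subject.truth_ktrans[subject.brain_mask],
            subject.truth_vp[subject.brain_mask],
            aif,
        )
        return (
            ConcentrationSeries(
                values=values,
                valid=np.ones_like(values, dtype=bool),
                times_min=subject.acq.times_min,
                n_baseline=subject.acq.n_baseline,
            ),
            aif,
        )

    def test_noiseless_maps_match_truth(self, multi_roi_subject):
        conc, aif = self._conc_from_truth(multi_roi_subject)
        maps = fit_maps(conc, aif, multi_roi_subject.brain_mask, multi_roi_subject.acq)
        brain = multi_roi_subject.brain_mask
        truth = multi_roi_subject.truth_ktrans[brain]
        # rtol 1e-9 with a tiny absolute floor for truth values clipped to ~0
        np.testing.assert_allclose(maps.ktrans[brain], truth, rtol=1e-9, atol=1e-12)
        assert maps.fit_mask[brain].all()

    def test_single_voxel_mask(self, multi_roi_subject):
        conc, aif = self._conc_from_truth(multi_roi_subject)
        mask = np.zeros_like(multi_roi_subject.brain_mask)
        idx = tuple(np.argwhere(multi_roi_subject.brain_mask)[0])
        mask[idx] = True
        maps = fit_maps(conc, aif, mask, multi_roi_subject.acq)
        assert maps.fit_mask.sum() == 1
        assert maps.ktrans[idx] == pytest.approx(
            multi_roi_subject.truth_ktrans[idx], rel=1e-9
        )

    def test_voxels_with_few_valid_frames_excluded(self, multi_roi_subject):
        conc, aif = self._conc_from_truth(multi_roi_subject)
        idx = tuple(np.argwhere(multi_roi_subject.brain_mask)[0])
        nb = multi_roi_subject.acq.n_baseline
        conc.valid[idx][nb + 4:] = False  # only 4 valid post-bolus frames
        maps = fit_maps(conc, aif, multi_roi_subject.brain_mask, multi_roi_subject.acq)
        assert not maps.fit_mask[idx]
        assert np.isnan(maps.ktrans[idx])
        assert maps.n_excluded == 1

    def test_empty_mask_rejected(self, multi_roi_subject):
        conc, aif = self._conc_from_truth(multi_roi_subject)
        with pytest.raises(ValueError, match="empty"):
            fit_maps(
                conc, aif, np.zeros_like(multi_roi_subject.brain_mask),
                multi_roi_subject.acq,
            )

    def test_unbiased_over_noisy_voxels(self, aif_short, acq_short):
        """Mean K-trans over 1000 noisy voxels within 2 MC SEs of truth."""
        rng = np.random.default_rng(12)
        n_vox, truth_k, truth_v = 1000, 1.5e-3, 0.02
        ct = simulate_tissue_curve(truth_k, truth_v, aif_short)
        window = np.arange(acq_short.n_baseline, acq_short.n_volumes)
        noisy = ct[None, :] + rng.normal(0.0, 2e-4, (n_vox, ct.size))
        design = np.column_stack(
            [aif_short.cp[window], cumulative_integral(aif_short)[window]]
        )
        coef, *_ = np.linalg.lstsq(design, noisy[:, window].T, rcond=None)
        k_hat = coef[1]
        se = k_hat.std(ddof=1) / np.sqrt(n_vox)
        assert abs(k_hat.mean() - truth_k) < 2 * se
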