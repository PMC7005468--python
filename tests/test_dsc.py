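"""Tests of DSC perfusion quantification: dR2* conversion, gamma-variate
fitting, leakage correction, QC masking and NAWM normalisation."""

import warnings

import numpy as np
import pytest
from scipy.integrate import quad

from pedmri.dsc import (
    DSCSeries,
    GammaVariateFit,
    PerfusionMaps,
    apply_qc_mask,
    compute_ucbv,
    fit_gamma_variate,
    gamma_variate,
    gamma_variate_integral,
    leakage_correct,
    normalise_to_nawm,
    signal_to_delta_r2star,
)

T = np.arange(60) * 1.5
TE = 0.03


def _series(signal_1d):
    return DSCSeries(
        signal=np.asarray(signal_1d).reshape(1, 1, 1, -1),
        t=T, TE_s=TE, baseline_window=(0, 5),
    )


class TestSignalToDeltaR2star:
    def test_constant_signal_gives_zero(self):
        conc = signal_to_delta_r2star(_series(np.full(60, 80.0)))
        assert np.allclose(conc, 0.0)

    def test_inverts_forward_model_exactly(self):
        c_true = gamma_variate(T, 1.0, 3.0, 1.5, 10.0)
        s = 100.0 * np.exp(-TE * c_true)
        conc = signal_to_delta_r2star(_series(s))[0, 0, 0]
        assert np.allclose(conc, c_true, atol=1e-12)

    def test_non_positive_signal_flagged_nan(self):
        s = np.full(60, 100.0)
        s[30] = -1.0
        conc = signal_to_delta_r2star(_series(s))[0, 0, 0]
        assert np.isnan(conc).all()


class TestFitGammaVariate:
    def test_noiseless_recovery(self):
        c = gamma_variate(T, 1.0, 3.0, 1.5, 10.0)
        fit = fit_gamma_variate(c, T)
        assert fit.converged
        assert fit.A == pytest.approx(1.0, rel=1e-3)
        assert fit.alpha == pytest.approx(3.0, rel=1e-3)
        assert fit.beta == pytest.approx(1.5, rel=1e-3)
        assert fit.t0 == pytest.approx(10.0, rel=1e-3)
        assert fit.rmse < 1e-8

    def test_all_zero_curve(self):
        fit = fit_gamma_variate(np.zeros(60), T)
        assert fit.A == 0.0 and not fit.converged
        assert compute_ucbv(GammaVariateFit(A=0.0, alpha=3, beta=1.5, t0=10,
                                            rmse=0.0, converged=True)) == 0.0

    def test_noise_increases_rmse(self):
        c = gamma_variate(T, 1.0, 3.0, 1.5, 10.0)
        rng = np.random.default_rng(0)
        noisy = fit_gamma_variate(c + rng.normal(0, 0.2, c.size), T)
        clean = fit_gamma_variate(c, T)
        assert clean.rmse < noisy.rmse

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma_variate(np.zeros(5), np.arange(5.0))


class TestComputeUCBV:
    def test_closed_form_example(self):
        # A=1, alpha=3, beta=1.5: A * beta^4 * Gamma(4) = 1.5^4 * 6 = 30.375
        assert gamma_variate_integral(1.0, 3.0, 1.5) == pytest.approx(30.375)

    def test_closed_form_matches_quadrature(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            A = rng.uniform(0.1, 5.0)
            alpha = rng.uniform(0.5, 8.0)
            beta = rng.uniform(0.2, 4.0)
            analytic = gamma_variate_integral(A, alpha, beta)
            numeric, _ = quad(
                lambda x: A * x**alpha * np.exp(-x / beta), 0, np.inf
            )
            assert analytic == pytest.approx(numeric, rel=1e-6)

    def test_linearity_in_amplitude(self):
        f1 = GammaVariateFit(A=1.0, alpha=3, beta=1.5, t0=10, rmse=0, converged=True)
        f2 = GammaVariateFit(A=2.0, alpha=3, beta=1.5, t0=10, rmse=0, converged=True)
        assert compute_ucbv(f2) == pytest.approx(2 * compute_ucbv(f1))

    def test_increasing_amplitude_increases_ucbv(self):
        # noiseless monotonicity through the full fit path
        vals = []
        for A in (0.5, 1.0, 2.0):
            c = gamma_variate(T, A, 3.0, 1.5, 10.0)
            vals.append(compute_ucbv(fit_gamma_variate(c, T)))
        assert vals[0] < vals[1] < vals[2]

    def test_non_converged_is_masked(self):
        assert np.isnan(compute_ucbv(GammaVariateFit(converged=False)))


def _leakage_volume(k2_values, n_ref=20, amp_ref=3.0):
    """Reference voxels (pure gamma curves) plus one test voxel per k2."""
    shape_curve = gamma_variate(T, 1.0, 3.0, 1.5, 10.0)
    rng = np.random.default_rng(2)
    amps = amp_ref * rng.uniform(0.8, 1.2, n_ref)
    c_ref_mean = amps.mean() * shape_curve
    ref_int = np.concatenate(
        [[0.0], np.cumsum(0.5 * (c_ref_mean[1:] + c_ref_mean[:-1]) * np.diff(T))]
    )
    curves = [a * shape_curve for a in amps]
    test_amp = 4.0
    for k2 in k2_values:
        curves.append(test_amp * shape_curve - k2 * ref_int)
    conc = np.array(curves).reshape(len(curves), 1, 1, -1)
    ref_mask = np.zeros(conc.shape[:-1], dtype=bool)
    ref_mask[:n_ref] = True
    return conc, ref_mask, test_amp


class TestLeakageCorrect:
    def test_k2_recovery_and_no_leak_limit(self):
        k2_true = [0.0, 0.01, 0.05]
        conc, ref_mask, test_amp = _leakage_volume(k2_true)
        ucbv_raw = np.trapezoid(conc, T, axis=-1)
        k2, ccbv = leakage_correct(conc, T, ref_mask, ucbv_raw=ucbv_raw)
        for true, got in zip(k2_true, k2[-3:, 0, 0]):
            if true == 0.0:
                assert abs(got) < 1e-10
            else:
                assert got == pytest.approx(true, rel=0.01)
        # zero-leak voxel keeps CCBV == UCBV to float tolerance
        assert ccbv[-3, 0, 0] == pytest.approx(ucbv_raw[-3, 0, 0], abs=1e-9)
        # leaky voxels: corrected CBV closer to amplitude-implied truth
        window_truth = np.trapezoid(
            test_amp * gamma_variate(T, 1.0, 3.0, 1.5, 10.0), T
        )
        assert abs(ccbv[-1, 0, 0] - window_truth) < abs(
            ucbv_raw[-1, 0, 0] - window_truth
        )

    def test_identical_curves_give_constant_k2(self):
        shape_curve = gamma_variate(T, 1.0, 3.0, 1.5, 10.0)
        conc = np.tile(shape_curve, (10, 1, 1, 1)).reshape(10, 1, 1, -1)
        ref = np.ones((10, 1, 1), dtype=bool)
        k2, _ = leakage_correct(conc, T, ref)
        assert np.allclose(k2, k2.flat[0], atol=1e-12)

    def test_flat_reference_skips_correction(self):
        conc = np.ones((4, 1, 1, 60))
        ref = np.ones((4, 1, 1), dtype=bool)
        ucbv = np.full((4, 1, 1), 2.0)
        with pytest.warns(UserWarning, match="degenerate"):
            k2, ccbv = leakage_correct(conc, T, ref, ucbv_raw=ucbv)
        assert np.allclose(k2, 0.0)
        assert np.allclose(ccbv, ucbv)

    def test_empty_reference_rejected(self):
        conc = np.ones((4, 1, 1, 60))
        with pytest.raises(ValueError):
            leakage_correct(conc, T, np.zeros((4, 1, 1), dtype=bool))


def _toy_maps(values, rmse=None):
    v = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    rmse = (np.zeros_like(v) if rmse is None
            else np.asarray(rmse, dtype=float).reshape(-1, 1, 1))
    return PerfusionMaps(
        ucbv=v, k2=np.zeros_like(v), ccbv=v.copy(),
        qc_mask=np.ones_like(v, dtype=bool), rmse=rmse,
    )


class TestQCMask:
    def test_cbv_ceiling_masks_high_voxels(self):
        maps = apply_qc_mask(_toy_maps([1.0, 2.9, 3.5]), rmse_threshold=np.inf)
        assert maps.qc_mask.ravel().tolist() == [True, True, False]

    def test_infinite_thresholds_keep_everything(self):
        maps = apply_qc_mask(
            _toy_maps([1.0, 2.9, 3.5]), rmse_threshold=np.inf, cbv_ceiling=np.inf
        )
        assert maps.qc_mask.all()

    def test_matches_brute_force_predicate(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 2.5, 200)
        rmse = rng.uniform(0, 1, 200)
        maps = apply_qc_mask(_toy_maps(vals, rmse), rmse_threshold=0.6)
        expected = np.array(
            [(r <= 0.6) and (abs(v) <= 3.0) for v, r in zip(vals, rmse)]
        )
        assert np.array_equal(maps.qc_mask.ravel(), expected)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        maps = _toy_maps(rng.normal(0, 2.5, 100), rng.uniform(0, 1, 100))
        once = apply_qc_mask(maps, rmse_threshold=0.5)
        twice = apply_qc_mask(once, rmse_threshold=0.5)
        assert np.array_equal(once.qc_mask, twice.qc_mask)

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            apply_qc_mask(_toy_maps([5.0, 6.0]), rmse_threshold=np.inf)


class TestNormaliseToNAWM:
    def test_simple_ratio(self):
        vol = np.array([[[3.0, 2.0]]])
        nawm = np.array([[[False, True]]])
        out, ref = normalise_to_nawm(vol, nawm)
        assert ref == 2.0
        assert out[0, 0, 0] == pytest.approx(1.5)

    def test_constant_map_becomes_one(self):
        vol = np.full((3, 3, 3), 4.2)
        nawm = np.zeros_like(vol, dtype=bool)
        nawm[1, 1, 1] = True
        out, _ = normalise_to_nawm(vol, nawm)
        assert np.allclose(out, 1.0)

    def test_nawm_mean_is_one_by_construction(self):
        rng = np.random.default_rng(5)
        vol = rng.uniform(0.5, 3.0, (4, 4, 4))
        nawm = rng.uniform(size=vol.shape) > 0.7
        out, _ = normalise_to_nawm(vol, nawm)
        assert out[nawm].mean() == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        vol = rng.uniform(0.5, 3.0, (4, 4, 4))
        nawm = rng.uniform(size=vol.shape) > 0.7
        a, _ = normalise_to_nawm(vol, nawm)
        b, _ = normalise_to_nawm(7.3 * vol, nawm)
        assert np.allclose(a, b)

    def test_zero_reference_rejected(self):
        vol = np.zeros((2, 2, 2))
        nawm = np.ones_like(vol, dtype=bool)
        with pytest.raises(ValueError):
            normalise_to_nawm(vol, nawm)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            normalise_to_nawm(np.ones((2, 2, 2)), np.zeros((2, 2, 2), dtype=bool))


class TestEndToEnd:
    def test_dr2star_matches_generator_concentration(self, noiseless_subject):
        s = noiseless_subject
        conc = signal_to_delta_r2star(s.dsc_series, s.brain_mask)
        amp = s.ground_truth["amplitude"]
        k2 = s.ground_truth["k2"]
        # non-leaky brain voxel: dR2* equals amplitude * bolus shape exactly
        bg = s.brain_mask & ~s.roi_mask & (k2 == 0)
        idx = tuple(np.argwhere(bg)[0])
        expected = amp[idx] * gamma_variate(s.dsc_series.t, 1.0, 3.0, 1.5, 10.0)
        assert np.allclose(conc[idx], expected, atol=1e-9)

    def test_quantified_k2_recovers_ground_truth(self, noiseless_subject, quantified):
        s = noiseless_subject
        got = np.nanmean(quantified["K2"][s.roi_mask])
        true = s.ground_truth["k2"][s.roi_mask].mean()
        assert got == pytest.approx(true, rel=0.05)

    def test_nawm_mean_unity_after_normalisation(self, noiseless_subject, quantified):
        s = noiseless_subject
        vals = quantified["CCBV"][s.nawm_mask]
        assert np.nanmean(vals) == pytest.approx(1.0, abs=1e-6)
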