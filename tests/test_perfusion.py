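"""Perfusion-map operations against brute-force and analytic oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import toeplitz

from perfcell.perfusion import (
    AIFSelection,
    DynamicSeries,
    compute_basemaps,
    detect_bolus_and_baseline,
    mask_maps,
    median_filter_maps,
    nanmedian_filter,
    select_aif,
    signal_to_concentration,
    ssvd_deconvolve,
)
from perfcell.phantom import (
    AcquisitionParams,
    gamma_variate_aif,
    generate_phantom,
    simulate_dynamic_series,
)

TR, TE = 1.5, 0.015


def make_series(curves, tr=TR, te=TE, mask=None):
    """Wrap a (n_voxels, n_frames) array of signal curves as a 1D-grid series."""
    sig = np.asarray(curves, float)[:, None, None, :]
    if mask is None:
        mask = np.ones(sig.shape[:3], bool)
    return DynamicSeries(signal=sig, tr=tr, te=te, brain_mask=mask)


class TestBolusDetection:
    def test_flat_series_has_no_bolus(self):
        series = make_series(np.full((3, 40), 100.0))
        with pytest.raises(ValueError, match="no bolus"):
            detect_bolus_and_baseline(series)

    def test_noiseless_arrival_frame(self, noiseless_bundle):
        # gamma-variate delay t0 = 15 s on a 1.5 s grid -> arrival frame 10
        bolus, s0 = detect_bolus_and_baseline(noiseless_bundle["series"])
        assert bolus == 10
        ph = noiseless_bundle["phantom"]
        np.testing.assert_allclose(
            s0[ph.brain_mask & ~ph.artery_mask], noiseless_bundle["acq"].s0
        )

    def test_noisy_arrival_within_one_frame(self):
        ph = generate_phantom((24, 24, 10), seed=31)
        acq = AcquisitionParams(n_frames=80)  # SNR 20
        series = simulate_dynamic_series(ph, gamma_variate_aif(acq), acq, seed=8)
        bolus, _ = detect_bolus_and_baseline(series)
        assert abs(bolus - acq.n_baseline) <= 1


class TestConcentration:
    def test_constant_signal_is_zero_concentration(self):
        series = make_series(np.full((2, 20), 500.0))
        conc = signal_to_concentration(series, np.full((2, 1, 1), 500.0), 5)
        np.testing.assert_array_equal(conc.conc, 0.0)

    def test_exact_inverse_of_the_exponential_model(self):
        c = np.linspace(0.0, 3.0, 20)
        sig = 100.0 * np.exp(-TE * c)
        series = make_series(sig[None, :])
        conc = signal_to_concentration(series, np.full((1, 1, 1), 100.0), 0)
        np.testing.assert_allclose(conc.conc[0, 0, 0], c, atol=1e-12)

    def test_nonpositive_baseline_becomes_nan(self):
        series = make_series(np.full((1, 20), 10.0))
        conc = signal_to_concentration(series, np.zeros((1, 1, 1)), 4)
        assert np.isnan(conc.conc).all()


class TestBasemaps:
    def test_flat_voxel_yields_zero_maps(self):
        series = make_series(np.full((1, 30), 200.0))
        conc = signal_to_concentration(series, np.full((1, 1, 1), 200.0), 6)
        maps = compute_basemaps(series, conc)
        at = (0, 0, 0)
        assert maps.dsovers[at] == 0
        assert maps.ms[at] == 0
        assert maps.cbv_auc[at] == 0
        assert maps.ttp[at] == 0  # earliest-frame tie rule

    def test_single_frame_dip(self):
        # S0=100, dip to 60 at frame 7 after the bolus frame, tr=1.5
        sig = np.full(30, 100.0)
        bolus = 5
        sig[bolus + 7] = 60.0
        series = make_series(sig[None, :])
        conc = signal_to_concentration(series, np.full((1, 1, 1), 100.0), bolus)
        maps = compute_basemaps(series, conc)
        assert maps.dsovers[0, 0, 0] == pytest.approx(0.4)
        assert maps.ttp[0, 0, 0] == pytest.approx(10.5)

    def test_gamma_variate_voxel_matches_analytic_and_scan_oracles(self):
        # C(t) = A (t-t0)^a exp(-(t-t0)/b) appended to a flat baseline
        tr = TR
        n, bolus = 220, 10
        t = np.arange(n) * tr
        a_, b_, amp = 3.0, 1.5, 1.0
        tshift = np.clip(t - bolus * tr, 0, None)
        c = amp * tshift**a_ * np.exp(-tshift / b_)
        c[: bolus + 1] = 0.0
        sig = 100.0 * np.exp(-TE * c)
        series = make_series(sig[None, :])
        conc = signal_to_concentration(series, np.full((1, 1, 1), 100.0), bolus)
        maps = compute_basemaps(series, conc)

        analytic_auc = amp * b_ ** (a_ + 1) * math.gamma(a_ + 1)
        assert maps.cbv_auc[0, 0, 0] == pytest.approx(analytic_auc, rel=0.01)

        # brute-force frame-by-frame oracles
        post = c[bolus:]
        assert maps.ttp[0, 0, 0] == pytest.approx(tr * int(np.argmax(post)))
        sig_post = sig[bolus:]
        assert maps.dsovers[0, 0, 0] == pytest.approx((100 - sig_post.min()) / 100)
        slopes = [(sig[i - 1] - sig[i]) / tr for i in range(1, n)]
        assert maps.ms[0, 0, 0] == pytest.approx(max(slopes))


class TestSelectAIF:
    def _conc(self, curves, bolus=0):
        series = make_series(np.asarray(curves) + 100.0)
        return signal_to_concentration(
            series, np.full(series.signal.shape[:3], 100.0), bolus
        ), series

    def test_manual_single_voxel_verbatim(self):
        curves = np.zeros((3, 20))
        curves[1, 5:10] = -50.0  # signal dip -> positive concentration
        conc, _ = self._conc(curves)
        sel = select_aif(conc, [(1, 0, 0)])
        np.testing.assert_array_equal(sel.curve, conc.conc[1, 0, 0])

    def test_auto_prefers_tall_early_peak(self):
        rng = np.random.default_rng(0)
        n_vox, n_t = 40, 30
        curves = np.zeros((n_vox, n_t))
        for i in range(1, n_vox):
            peak_at = rng.integers(8, 25)
            curves[i, peak_at] = -rng.uniform(10, 40)
        curves[0, 4] = -80.0  # strictly tallest and earliest
        conc, series = self._conc(curves)
        sel = select_aif(conc, "auto", brain_mask=series.brain_mask, n_candidates=1)
        assert sel.voxel_list[0] == (0, 0, 0)

        # exhaustive scoring oracle over every voxel
        scores = []
        for i in range(n_vox):
            cv = conc.conc[i, 0, 0]
            peak = cv.max()
            ttp = TR * int(np.argmax(cv))
            scores.append(peak / (ttp + TR))
        assert int(np.argmax(scores)) == 0

    def test_zero_concentration_volume_errors(self):
        conc, series = self._conc(np.zeros((4, 20)))
        with pytest.raises(ValueError, match="no AIF candidate"):
            select_aif(conc, "auto", brain_mask=series.brain_mask)


class TestSSVD:
    def test_impulse_aif_recovers_residue_exactly(self):
        n, tr = 40, TR
        aif = np.zeros(n)
        aif[0] = 1.0  # discrete impulse, area tr
        flow = 0.02
        resid = np.exp(-np.arange(n) * tr / 4.0)
        c = flow * tr * resid  # A = tr * I
        conc_arr = c[None, None, None, :]
        from perfcell.perfusion import ConcentrationSeries

        conc = ConcentrationSeries(
            conc=conc_arr, tr=tr, s0_map=np.ones((1, 1, 1)), bolus_frame=0
        )
        maps = ssvd_deconvolve(conc, AIFSelection.from_curve(aif), trunc_frac=0.0)
        assert maps.cbf_ssvd[0, 0, 0] == pytest.approx(flow, abs=1e-8)
        assert maps.tmax_ssvd[0, 0, 0] == 0.0

    def test_matches_dense_least_squares_on_toy_problem(self):
        n, tr = 16, 1.0
        t = np.arange(n) * tr
        aif = t * np.exp(-t / 2.0)
        resid = np.exp(-t / 3.0)
        A = tr * toeplitz(aif, np.zeros(n))
        c = A @ (0.05 * resid)
        from perfcell.perfusion import ConcentrationSeries

        conc = ConcentrationSeries(
            conc=c[None, None, None, :], tr=tr, s0_map=np.ones((1, 1, 1)), bolus_frame=0
        )
        maps = ssvd_deconvolve(conc, AIFSelection.from_curve(aif), trunc_frac=0.0)
        r_lstsq, *_ = np.linalg.lstsq(A, c, rcond=None)
        assert maps.cbf_ssvd[0, 0, 0] == pytest.approx(r_lstsq.max(), abs=1e-8)
        # reconstruction consistency
        np.testing.assert_allclose(A @ r_lstsq, c, atol=1e-6)

    def test_zero_voxel_conventions(self):
        n = 20
        aif = np.exp(-np.arange(n) / 3.0)
        from perfcell.perfusion import ConcentrationSeries

        conc = ConcentrationSeries(
            conc=np.zeros((1, 1, 1, n)), tr=TR, s0_map=np.ones((1, 1, 1)), bolus_frame=0
        )
        maps = ssvd_deconvolve(conc, AIFSelection.from_curve(aif), trunc_frac=0.2)
        assert maps.cbf_ssvd[0, 0, 0] == 0.0
        assert maps.cbv_ssvd[0, 0, 0] == 0.0
        assert maps.tmax_ssvd[0, 0, 0] == 0.0
        assert np.isnan(maps.mtt_ssvd[0, 0, 0])

    def test_degenerate_aif_rejected(self):
        from perfcell.perfusion import ConcentrationSeries

        conc = ConcentrationSeries(
            conc=np.zeros((1, 1, 1, 10)), tr=TR, s0_map=np.ones((1, 1, 1)), bolus_frame=0
        )
        # one nonzero sample off the origin: A is nilpotent, not invertible
        aif = np.zeros(10)
        aif[3] = 1.0
        with pytest.raises(ValueError, match="degenerate AIF"):
            ssvd_deconvolve(conc, AIFSelection.from_curve(aif))

    def test_central_volume_closure_is_exact(self, noiseless_bundle):
        acq = noiseless_bundle["acq"]
        series = noiseless_bundle["series"]
        bolus, s0 = detect_bolus_and_baseline(series)
        conc = signal_to_concentration(series, s0, bolus)
        aifsel = AIFSelection.from_curve(
            noiseless_bundle["aif"].concentration * acq.k_t2star
        )
        maps = ssvd_deconvolve(conc, aifsel, trunc_frac=0.1)
        ok = np.isfinite(maps.mtt_ssvd)
        np.testing.assert_allclose(
            maps.mtt_ssvd[ok] * maps.cbf_ssvd[ok], maps.cbv_ssvd[ok], rtol=1e-12
        )

    def test_reconstruction_consistency_at_zero_truncation(self, noiseless_bundle):
        acq = noiseless_bundle["acq"]
        series = noiseless_bundle["series"]
        bolus, s0 = detect_bolus_and_baseline(series)
        conc = signal_to_concentration(series, s0, bolus)
        a = noiseless_bundle["aif"].concentration * acq.k_t2star
        A = acq.tr * toeplitz(a, np.zeros_like(a))
        ph = noiseless_bundle["phantom"]
        vox = tuple(np.argwhere(ph.brain_mask & ~ph.artery_mask)[40])
        maps = ssvd_deconvolve(conc, AIFSelection.from_curve(a), trunc_frac=0.0)
        # recompute the voxel residue and check A r ~ c
        U, s, Vt = np.linalg.svd(A)
        keep = s >= 1e-10 * s[0]
        r = (Vt.T * np.where(keep, 1 / s, 0.0)) @ U.T @ conc.conc[vox]
        np.testing.assert_allclose(A @ r, conc.conc[vox], atol=1e-6)
        assert maps.cbf_ssvd[vox] == pytest.approx(r.max(), rel=1e-8)


class TestMedianFilter:
    def test_radius_zero_is_identity(self, noiseless_bundle):
        series = noiseless_bundle["series"]
        bolus, s0 = detect_bolus_and_baseline(series)
        conc = signal_to_concentration(series, s0, bolus)
        maps = compute_basemaps(series, conc)
        out = median_filter_maps(maps, radius=0)
        np.testing.assert_array_equal(out.ttp, maps.ttp)

    def test_single_outlier_removed(self):
        vol = np.full((7, 7, 7), 3.0)
        vol[3, 3, 3] = 100.0
        out = nanmedian_filter(vol, 1)
        assert out[3, 3, 3] == 3.0

    def test_matches_brute_force_sort_oracle(self):
        rng = np.random.default_rng(4)
        vol = rng.normal(size=(6, 5, 4))
        vol[1, 1, 1] = np.nan
        out = nanmedian_filter(vol, 1)
        for i in range(6):
            for j in range(5):
                for k in range(4):
                    vals = []
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            for dk in (-1, 0, 1):
                                a, b, c = i + di, j + dj, k + dk
                                if 0 <= a < 6 and 0 <= b < 5 and 0 <= c < 4:
                                    if not np.isnan(vol[a, b, c]):
                                        vals.append(vol[a, b, c])
                    assert out[i, j, k] == pytest.approx(float(np.median(vals)))


class TestScalingInvariance:
    @settings(max_examples=10, deadline=None)
    @given(scale=st.floats(min_value=0.1, max_value=50.0))
    def test_global_signal_scaling(self, scale, noiseless_bundle):
        """The log-ratio concentration is invariant to a global signal scale,
        so every concentration-derived map is unchanged; MS, computed on raw
        signal differences, scales linearly."""
        series = noiseless_bundle["series"]
        scaled = DynamicSeries(
            signal=series.signal * scale,
            tr=series.tr,
            te=series.te,
            brain_mask=series.brain_mask,
        )
        b1, s01 = detect_bolus_and_baseline(series)
        b2, s02 = detect_bolus_and_baseline(scaled)
        assert b1 == b2
        c1 = signal_to_concentration(series, s01, b1)
        c2 = signal_to_concentration(scaled, s02, b2)
        m1 = compute_basemaps(series, c1)
        m2 = compute_basemaps(scaled, c2)
        np.testing.assert_allclose(m2.ttp, m1.ttp, atol=1e-12)
        np.testing.assert_allclose(m2.dsovers, m1.dsovers, atol=1e-12)
        np.testing.assert_allclose(m2.cbv_auc, m1.cbv_auc, rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(m2.ms, scale * m1.ms, rtol=1e-9, atol=1e-9)


def test_mask_maps_sets_outside_to_nan(noiseless_bundle):
    series = noiseless_bundle["series"]
    ph = noiseless_bundle["phantom"]
    bolus, s0 = detect_bolus_and_baseline(series)
    conc = signal_to_concentration(series, s0, bolus)
    maps = mask_maps(compute_basemaps(series, conc), ph.brain_mask)
    assert np.isnan(maps.cbv_auc[~ph.brain_mask]).all()
    assert np.isfinite(maps.cbv_auc[ph.brain_mask]).all()
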