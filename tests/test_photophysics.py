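"""Anisotropy arithmetic, decay fitting and FRET-efficiency chains."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdquant.errors import (
    InvalidArgumentError,
    LowCountError,
    UndefinedRatioError,
)
from pdquant.image_quant import ROI, ROISet
from pdquant.photophysics import (
    CalibrationConstants,
    DecayHistogram,
    IRFModel,
    LifetimeFit,
    PolarizedPair,
    amplitude_weighted_lifetime,
    anisotropy_by_roi,
    compute_anisotropy,
    decay_model_probabilities,
    delta_fret,
    fit_decay,
    fret_efficiency,
    merge_frames,
)
from pdquant.synthetic_data import (
    DecaySimSpec,
    expected_decay_counts,
    simulate_decay,
    simulate_polarized_pair,
)

CALIB_63X = CalibrationConstants(G=0.481, L1=0.013, L2=0.037)


class TestMergeFrames:
    def test_single_frame_identity(self):
        out = merge_frames([PolarizedPair(3.0, 5.0)])
        assert (out.I_par, out.I_perp, out.n_frames_merged) == (3.0, 5.0, 1)

    def test_twenty_frames_sum(self):
        out = merge_frames([PolarizedPair(1.0, 2.0)] * 20)
        assert (out.I_par, out.I_perp, out.n_frames_merged) == (20.0, 40.0, 20)

    def test_shape_mismatch_rejected(self):
        frames = [PolarizedPair(np.ones((4, 4)), np.ones((4, 4))),
                  PolarizedPair(np.ones((5, 5)), np.ones((5, 5)))]
        with pytest.raises(InvalidArgumentError):
            merge_frames(frames)


class TestComputeAnisotropy:
    def test_null_case_with_calibrated_g(self):
        r = compute_anisotropy(PolarizedPair(481.0, 1000.0), CALIB_63X)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_reduces_to_classic_formula(self):
        calib = CalibrationConstants(G=1.0, L1=0.0, L2=0.0)
        r = compute_anisotropy(PolarizedPair(3.0, 1.0), calib)
        assert r == pytest.approx(0.4)

    def test_direct_arithmetic_oracle(self):
        # independent high-precision evaluation of the standard grouping
        I_par, I_perp = 200.0, 100.0
        G, L1, L2 = 0.481, 0.013, 0.037
        expected = (I_par - G * I_perp) / (
            (1 - 3 * L2) * I_par + (2 - 3 * L1) * G * I_perp
        )
        r = compute_anisotropy(PolarizedPair(I_par, I_perp), CALIB_63X)
        assert r == pytest.approx(expected, rel=1e-12)

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedRatioError):
            compute_anisotropy(PolarizedPair(0.0, 0.0), CALIB_63X)

    @settings(derandomize=True, max_examples=50)
    @given(
        scale=st.floats(1e-3, 1e6),
        par=st.floats(1.0, 1e4),
        perp=st.floats(1.0, 1e4),
    )
    def test_scale_invariance(self, scale, par, perp):
        """r depends only on the intensity ratio, not the overall gain."""
        r1 = compute_anisotropy(PolarizedPair(par, perp), CALIB_63X)
        r2 = compute_anisotropy(PolarizedPair(par * scale, perp * scale), CALIB_63X)
        assert r2 == pytest.approx(r1, rel=1e-9, abs=1e-12)

    def test_variant_flag(self):
        # literal variant drops G on the denominator perpendicular term
        r_std = compute_anisotropy(PolarizedPair(200.0, 100.0), CALIB_63X, "standard")
        r_lit = compute_anisotropy(PolarizedPair(200.0, 100.0), CALIB_63X, "literal")
        assert r_lit != pytest.approx(r_std)
        with pytest.raises(InvalidArgumentError):
            compute_anisotropy(PolarizedPair(1.0, 1.0), CALIB_63X, "bogus")


class TestAnisotropyByRoi:
    def _rois(self):
        a = np.argwhere(np.ones((4, 4), dtype=bool))
        b = np.argwhere(np.ones((4, 4), dtype=bool)) + 8
        return ROISet([ROI("r1", "PD", a), ROI("r2", "PM", b)])

    def test_uniform_images_give_same_r(self):
        par = np.full((16, 16), 6.0)
        perp = np.full((16, 16), 4.0)
        out = anisotropy_by_roi(PolarizedPair(par, perp), self._rois(), CALIB_63X)
        assert out["r1"] == pytest.approx(out["r2"])

    def test_painted_roi_round_trip(self):
        pair = simulate_polarized_pair(0.25, 1000.0, CALIB_63X)
        par = np.zeros((16, 16))
        perp = np.zeros((16, 16))
        par[0:4, 0:4] = pair.I_par / 16.0
        perp[0:4, 0:4] = pair.I_perp / 16.0
        rois = ROISet([ROI("r1", "PD", np.argwhere(np.ones((4, 4), dtype=bool)))])
        out = anisotropy_by_roi(PolarizedPair(par, perp), rois, CALIB_63X)
        assert out["r1"] == pytest.approx(0.25, abs=1e-9)

    def test_cytosol_vs_pm_ordering_monte_carlo(self):
        """Two ROIs at r_true 0.30 (cytosol-like) and 0.22 (PM-like) with
        1e5 Poisson photons each keep their ordering essentially always."""
        rng_ok = 0
        reps = 100
        for s in range(reps):
            cyt = simulate_polarized_pair(0.30, 1e5, CALIB_63X, "poisson", seed=2 * s)
            pm = simulate_polarized_pair(0.22, 1e5, CALIB_63X, "poisson", seed=2 * s + 1)
            r_cyt = compute_anisotropy(cyt, CALIB_63X)
            r_pm = compute_anisotropy(pm, CALIB_63X)
            rng_ok += r_cyt > r_pm
        assert rng_ok >= 99

    def test_empty_roi_skipped_with_warning(self):
        par = np.ones((8, 8))
        rois = ROISet([ROI("empty", "PD", np.empty((0, 2), dtype=int))])
        with pytest.warns(UserWarning, match="empty"):
            out = anisotropy_by_roi(PolarizedPair(par, par), rois, CALIB_63X)
        assert out == {}


DELTA_IRF = IRFModel(kind="gaussian", center=0.0, sigma=0.0)
NARROW_IRF = IRFModel(kind="gaussian", center=2.0, sigma=0.1)


def _noiseless_histogram(tau, n_photons=10**6, n_bins=256, period=25.0):
    spec = DecaySimSpec(
        lifetimes=(tau,), amplitude_fractions=(1.0,), irf_sigma=0.0,
        irf_center=0.0, n_photons=n_photons, n_bins=n_bins,
        background_fraction=0.0,
    )
    centers, expected = expected_decay_counts(spec)
    return DecayHistogram(centers, np.round(expected).astype(int), period)


class TestFitDecay:
    def test_mono_exponential_self_consistency(self):
        """Exact model data, delta IRF: the fitted lifetime is recovered to
        sub-picosecond accuracy."""
        hist = _noiseless_histogram(2.5)
        fit = fit_decay(hist, DELTA_IRF, n_components=1)
        assert fit.lifetimes[0] == pytest.approx(2.5, abs=1e-3)

    def test_biexponential_recovery_vs_grid_oracle(self):
        spec = DecaySimSpec(
            lifetimes=(0.8, 3.0), amplitude_fractions=(0.4, 0.6),
            n_photons=10**6, irf_sigma=0.1, irf_center=2.0,
            background_fraction=0.0,
        )
        hist = simulate_decay(spec, seed=7)
        fit = fit_decay(hist, NARROW_IRF, n_components=2)
        assert fit.lifetimes[0] == pytest.approx(0.8, rel=0.05)
        assert fit.lifetimes[1] == pytest.approx(3.0, rel=0.05)
        assert fit.amplitudes[0] == pytest.approx(0.4, abs=0.05)

        # coarse grid-search MLE oracle over (tau1, tau2, alpha)
        counts = hist.counts.astype(float)
        total = counts.sum()
        best = (None, -np.inf)
        for t1 in np.arange(0.6, 1.05, 0.05):
            for t2 in np.arange(2.6, 3.45, 0.05):
                p1 = decay_model_probabilities(hist.bin_centers, t1, NARROW_IRF, 25.0)
                p2 = decay_model_probabilities(hist.bin_centers, t2, NARROW_IRF, 25.0)
                for a in np.arange(0.25, 0.56, 0.025):
                    mu = total * (a * p1 + (1 - a) * p2)
                    ll = float(np.sum(counts * np.log(np.clip(mu, 1e-12, None))) - mu.sum())
                    if ll > best[1]:
                        best = ((t1, t2, a), ll)
        (t1, t2, a), _ = best
        assert fit.lifetimes[0] == pytest.approx(t1, abs=0.06)
        assert fit.lifetimes[1] == pytest.approx(t2, abs=0.06)
        assert fit.amplitudes[0] == pytest.approx(a, abs=0.05)

    def test_all_zero_histogram_is_low_count_error(self):
        centers = (np.arange(64) + 0.5) * 25.0 / 64
        hist = DecayHistogram(centers, np.zeros(64, dtype=int), 25.0)
        with pytest.raises(LowCountError):
            fit_decay(hist, DELTA_IRF, 1)

    def test_invalid_component_count(self):
        hist = _noiseless_histogram(2.0)
        with pytest.raises(InvalidArgumentError):
            fit_decay(hist, DELTA_IRF, 3)

    def test_nested_deviance(self):
        """Adding a component can only improve the Poisson deviance."""
        spec = DecaySimSpec(lifetimes=(0.8, 3.0), amplitude_fractions=(0.4, 0.6),
                            n_photons=10**5)
        hist = simulate_decay(spec, seed=11)
        d1 = fit_decay(hist, NARROW_IRF, 1).fit_deviance
        d2 = fit_decay(hist, NARROW_IRF, 2).fit_deviance
        assert d2 <= d1 + 1e-6

    def test_tau_av_recovery_rate(self):
        """|tau_av_hat - tau_av_true| <= 0.05 ns in >= 90% of 50 seeded
        1e5-photon biexponential decays."""
        tau_true = 0.4 * 0.8 + 0.6 * 3.0
        spec = DecaySimSpec(lifetimes=(0.8, 3.0), amplitude_fractions=(0.4, 0.6),
                            n_photons=10**5, background_fraction=0.01)
        ok = 0
        for s in range(50):
            fit = fit_decay(simulate_decay(spec, seed=s), NARROW_IRF, 2)
            ok += abs(fit.tau_av - tau_true) <= 0.05
        assert ok >= 45

    def test_quenched_component_lowers_tau_av(self):
        """Mixing in a shorter-lifetime (FRET-quenched) component strictly
        decreases the amplitude-weighted lifetime — the readout direction
        used to detect donor quenching."""
        base = LifetimeFit(np.array([1.0]), np.array([2.9]), 0.0, 2.9, 0.0, 1)
        for alpha in (0.1, 0.3, 0.5):
            mixed = LifetimeFit(
                np.array([alpha, 1 - alpha]), np.array([0.8, 2.9]),
                0.0, 0.0, 0.0, 2,
            )
            assert amplitude_weighted_lifetime(mixed) < amplitude_weighted_lifetime(base)

    def test_measured_irf_mode(self):
        """Fitting with the IRF supplied as a measured histogram recovers
        the same lifetime as the analytic Gaussian it sampled."""
        spec = DecaySimSpec(lifetimes=(2.5,), amplitude_fractions=(1.0,),
                            n_photons=10**6, irf_sigma=0.1, irf_center=2.0)
        hist = simulate_decay(spec, seed=3)
        centers = hist.bin_centers
        irf_hist = np.exp(-0.5 * ((centers - 2.0) / 0.1) ** 2)
        measured = IRFModel(kind="measured", measured=irf_hist)
        fit = fit_decay(hist, measured, 1)
        assert fit.lifetimes[0] == pytest.approx(2.5, rel=0.02)


class TestLifetimeAverages:
    def test_single_component_identity(self):
        fit = LifetimeFit(np.array([1.0]), np.array([2.0]), 0.0, 2.0, 0.0, 1)
        assert amplitude_weighted_lifetime(fit) == pytest.approx(2.0)

    def test_symmetric_mixture(self):
        fit = LifetimeFit(np.array([0.5, 0.5]), np.array([1.0, 3.0]), 0.0, 0.0, 0.0, 2)
        assert amplitude_weighted_lifetime(fit) == pytest.approx(2.0)

    def test_weighted_mean_arithmetic(self):
        fit = LifetimeFit(np.array([0.4, 0.6]), np.array([0.8, 3.0]), 0.0, 0.0, 0.0, 2)
        assert amplitude_weighted_lifetime(fit) == pytest.approx(2.12)

    def test_tau_av_between_extremes(self):
        fit = LifetimeFit(np.array([0.3, 0.7]), np.array([0.5, 4.0]), 0.0, 0.0, 0.0, 2)
        t = amplitude_weighted_lifetime(fit)
        assert 0.5 <= t <= 4.0


class TestFretEfficiency:
    def test_no_transfer(self):
        assert fret_efficiency(2.9, 2.9) == pytest.approx(0.0)

    def test_complete_quenching(self):
        assert fret_efficiency(0.0, 2.9) == pytest.approx(1.0)

    def test_chitin_scale_magnitude(self):
        # a 0.1 ns lifetime drop on a 2.9 ns donor is ~3.4% efficiency
        assert fret_efficiency(2.8, 2.9) == pytest.approx(0.0345, abs=5e-4)

    def test_invalid_donor_lifetime(self):
        with pytest.raises(InvalidArgumentError):
            fret_efficiency(2.0, 0.0)

    def test_negative_efficiency_warns(self):
        with pytest.warns(UserWarning, match="negative"):
            assert fret_efficiency(3.0, 2.9) < 0


class TestDeltaFret:
    def test_identical_conditions_give_zero(self):
        d, ci = delta_fret(2.9, [2.6, 2.7], [2.6, 2.7], seed=0)
        assert d == pytest.approx(0.0)
        assert ci[0] <= 0.0 <= ci[1]

    def test_direct_arithmetic(self):
        d, _ = delta_fret(2.9, [2.61], [2.70], seed=0)
        assert d == pytest.approx(100 * (2.70 - 2.61) / 2.9, rel=1e-9)

    def test_empty_condition_rejected(self):
        with pytest.raises(InvalidArgumentError):
            delta_fret(2.9, [], [2.7])
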