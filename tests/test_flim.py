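import numpy as np
import pytest

from fretion import (
    DecayHistogram,
    DecaySpec,
    IrfModel,
    decay_model,
    estimate_irf,
    fit_decay,
    flim_map,
    fret_efficiency,
    simulate_decay,
)


class TestSimulateDecay:
    def test_single_exponential_bin_ratio(self):
        # near-delta IRF, no noise: counts(t+dt)/counts(t) = exp(-dt/tau)
        spec = DecaySpec(
            lifetimes_ns=(2.5,),
            amplitudes=(1.0,),
            irf_center_ns=0.5,
            irf_width_ns=0.02,
            noise="none",
        )
        hist = simulate_decay(spec)
        tail = hist.times_ns > 2.0  # well past the IRF
        c = hist.counts[tail]
        ratios = c[1:] / c[:-1]
        np.testing.assert_allclose(
            ratios, np.exp(-spec.bin_width_ns / 2.5), rtol=1e-6
        )

    def test_two_component_intensity_weighted_lifetime_closed_form(self):
        spec = DecaySpec(lifetimes_ns=(1.0, 3.0), amplitudes=(1.0, 1.0))
        # (A1 t1^2 + A2 t2^2) / (A1 t1 + A2 t2) = 10/4
        assert spec.intensity_weighted_lifetime() == pytest.approx(2.5)

    def test_poisson_total_counts_within_three_sigma(self):
        spec = DecaySpec(
            lifetimes_ns=(2.5,), amplitudes=(1.0,), total_counts=100_000, seed=12
        )
        hist = simulate_decay(spec)
        assert abs(hist.total_counts - 1e5) < 3 * np.sqrt(1e5)

    def test_noise_free_total_is_exact(self):
        spec = DecaySpec(
            lifetimes_ns=(2.5,), amplitudes=(1.0,), total_counts=50_000, noise="none"
        )
        assert simulate_decay(spec).total_counts == pytest.approx(50_000)

    def test_window_must_span_lifetimes(self):
        with pytest.raises(ValueError, match="window"):
            DecaySpec(lifetimes_ns=(20.0,), amplitudes=(1.0,), n_bins=64,
                      bin_width_ns=0.1)

    def test_log_slope_equals_negative_inverse_lifetime(self):
        spec = DecaySpec(
            lifetimes_ns=(2.0,),
            amplitudes=(1.0,),
            irf_center_ns=0.5,
            irf_width_ns=0.02,
            total_counts=1_000_000,
            seed=3,
        )
        hist = simulate_decay(spec)
        sel = (hist.times_ns > 2.0) & (hist.counts > 50)
        slope = np.polyfit(hist.times_ns[sel], np.log(hist.counts[sel]), 1)[0]
        assert slope == pytest.approx(-1 / 2.0, rel=0.02)


class TestEstimateIrf:
    def test_recovers_planted_gaussian_irf(self):
        spec = DecaySpec(
            lifetimes_ns=(2.5,),
            amplitudes=(1.0,),
            irf_center_ns=2.0,
            irf_width_ns=0.2,
            total_counts=1_000_000,
            seed=1,
        )
        irf = estimate_irf(simulate_decay(spec))
        assert irf.center_ns == pytest.approx(2.0, abs=0.05)
        assert irf.width_ns == pytest.approx(0.2, rel=0.2)

    def test_delta_like_irf_flagged(self):
        spec = DecaySpec(
            lifetimes_ns=(2.5,),
            amplitudes=(1.0,),
            irf_center_ns=0.3,
            irf_width_ns=0.005,
            noise="none",
        )
        irf = estimate_irf(simulate_decay(spec))
        assert irf.delta_like

    def test_monotone_decreasing_histogram_rejected(self):
        t = np.arange(64) * 0.1
        hist = DecayHistogram(times_ns=t, counts=1000 * np.exp(-t / 2), bin_width_ns=0.1)
        with pytest.raises(ValueError, match="rising"):
            estimate_irf(hist)


class TestFitDecay:
    def test_one_component_recovery_within_three_percent(self):
        spec = DecaySpec(
            lifetimes_ns=(2.5,), amplitudes=(1.0,), total_counts=100_000, seed=3
        )
        hist = simulate_decay(spec)
        fit = fit_decay(hist, estimate_irf(hist), n_components=1)
        assert fit.tau_av_int_ns == pytest.approx(2.5, rel=0.03)

    def test_two_component_intensity_weighted_recovery(self):
        spec = DecaySpec(
            lifetimes_ns=(1.0, 3.0),
            amplitudes=(1.0, 1.0),
            total_counts=1_000_000,
            seed=5,
        )
        hist = simulate_decay(spec)
        fit = fit_decay(hist, estimate_irf(hist), n_components=2)
        assert fit.tau_av_int_ns == pytest.approx(2.5, rel=0.03)

    def test_two_component_fit_with_true_irf_recovers_components(self):
        spec = DecaySpec(
            lifetimes_ns=(1.0, 3.0),
            amplitudes=(1.0, 1.0),
            total_counts=1_000_000,
            seed=5,
        )
        fit = fit_decay(simulate_decay(spec), IrfModel(2.0, 0.2), n_components=2)
        assert fit.tau_ns[0] == pytest.approx(1.0, rel=0.05)
        assert fit.tau_ns[1] == pytest.approx(3.0, rel=0.05)
        assert fit.reduced_chi2 < 2.0

    def test_overfitting_single_component_data_is_flagged_degenerate(self):
        spec = DecaySpec(
            lifetimes_ns=(2.5,), amplitudes=(1.0,), total_counts=100_000, seed=8
        )
        hist = simulate_decay(spec)
        fit = fit_decay(hist, estimate_irf(hist), n_components=2)
        assert fit.degenerate
        assert fit.tau_av_int_ns == pytest.approx(2.5, rel=0.03)

    def test_count_scaling_invariance(self):
        base = dict(lifetimes_ns=(2.5,), amplitudes=(1.0,), seed=4)
        t1 = fit_decay(
            (h := simulate_decay(DecaySpec(total_counts=100_000, **base))),
            estimate_irf(h), n_components=1,
        ).tau_av_int_ns
        t2 = fit_decay(
            (h2 := simulate_decay(DecaySpec(total_counts=200_000, **base))),
            estimate_irf(h2), n_components=1,
        ).tau_av_int_ns
        assert t1 == pytest.approx(t2, rel=0.02)

    def test_low_count_histogram_rejected(self):
        spec = DecaySpec(
            lifetimes_ns=(2.5,), amplitudes=(1.0,), total_counts=500, seed=0
        )
        with pytest.raises(ValueError, match="counts"):
            fit_decay(simulate_decay(spec), IrfModel(2.0, 0.2))

    def test_simulate_and_fit_bias_is_small(self):
        # no systematic bias: median error < 1%, IQR < 3% over seeds
        errs = []
        for seed in range(12):
            spec = DecaySpec(
                lifetimes_ns=(2.7,), amplitudes=(1.0,), total_counts=100_000,
                seed=seed,
            )
            hist = simulate_decay(spec)
            fit = fit_decay(hist, estimate_irf(hist), n_components=1)
            errs.append(fit.tau_av_int_ns / 2.7 - 1)
        errs = np.asarray(errs)
        assert abs(np.median(errs)) < 0.01
        assert np.subtract(*np.percentile(errs, [75, 25])) < 0.03


class TestEfficiency:
    def test_equal_lifetimes_give_zero(self):
        assert fret_efficiency(3.0, 3.0).E == 0.0

    def test_substitution(self):
        res = fret_efficiency(2.7, 3.0)
        assert res.E == pytest.approx(0.10)
        assert not res.anomalous

    def test_longer_sample_lifetime_is_anomalous_negative(self):
        res = fret_efficiency(3.3, 3.0)
        assert res.E < 0
        assert res.anomalous

    def test_strictly_decreasing_in_sample_lifetime(self):
        es = [fret_efficiency(t, 3.0).E for t in (1.0, 2.0, 2.5, 3.0)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_nonpositive_donor_rejected(self):
        with pytest.raises(ValueError):
            fret_efficiency(2.5, 0.0)


class TestFlimMap:
    @staticmethod
    def _pixel_grid(tau_map, counts_per_px=4000, seed=0):
        rng = np.random.default_rng(seed)
        t = (np.arange(128) + 0.5) * 0.097
        grid = np.zeros(tau_map.shape + (t.size,))
        for i in range(tau_map.shape[0]):
            for j in range(tau_map.shape[1]):
                model = decay_model(t, [tau_map[i, j]], [1.0], 1.0, 0.15)
                model *= counts_per_px / model.sum()
                grid[i, j] = rng.poisson(model)
        return grid, t

    def test_uniform_lifetime_field_maps_constant(self):
        tau_map = np.full((4, 4), 2.5)
        grid, t = self._pixel_grid(tau_map)
        out = flim_map(grid, t, IrfModel(1.0, 0.15), binning=2, threshold=100,
                       n_components=1)
        assert out.shape == (2, 2)
        np.testing.assert_allclose(out, 2.5, rtol=0.05)

    def test_two_region_field_resolves_both_lifetimes(self):
        tau_map = np.full((4, 8), 2.0)
        tau_map[:, 4:] = 3.0
        grid, t = self._pixel_grid(tau_map, seed=1)
        out = flim_map(grid, t, IrfModel(1.0, 0.15), binning=2, threshold=100,
                       n_components=1)
        assert np.nanmean(out[:, :2]) == pytest.approx(2.0, rel=0.05)
        assert np.nanmean(out[:, 2:]) == pytest.approx(3.0, rel=0.05)

    def test_threshold_above_counts_errors(self):
        tau_map = np.full((2, 2), 2.5)
        grid, t = self._pixel_grid(tau_map, counts_per_px=300)
        with pytest.raises(ValueError, match="threshold"):
            flim_map(grid, t, IrfModel(1.0, 0.15), binning=2, threshold=1e9)

    def test_round_trip_efficiency_recovery(self):
        # generator -> fit -> Eq.-of-lifetimes: E back within 0.02 absolute
        tau_donor = 3.0
        recovered = []
        for i, e_true in enumerate((0.0, 0.05, 0.1, 0.15, 0.2)):
            spec = DecaySpec(
                lifetimes_ns=(tau_donor * (1 - e_true),),
                amplitudes=(1.0,),
                total_counts=100_000,
                seed=20 + i,
            )
            hist = simulate_decay(spec)
            fit = fit_decay(hist, estimate_irf(hist), n_components=2)
            recovered.append(fret_efficiency(fit.tau_av_int_ns, tau_donor).E)
        for e_true, e_fit in zip((0.0, 0.05, 0.1, 0.15, 0.2), recovered):
            assert e_fit == pytest.approx(e_true, abs=0.02)
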