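"""Generators: determinism, spectral contracts, ground-truth bookkeeping."""

import numpy as np
import pytest

import respiro as r
from respiro.synthetic import DEFAULT_GROUP_SPECS

from conftest import brute_cross_sampen, brute_sampen, logistic_lyapunov_oracle


class TestColoredNoise:
    def test_standardized_output(self):
        s = r.gen_colored_noise(4096, 1.0, seed=3)
        assert abs(s.values.mean()) < 1e-12
        assert np.isclose(s.values.std(ddof=1), 1.0)

    def test_deterministic_given_seed(self):
        a = r.gen_colored_noise(512, 1.5, seed=9)
        b = r.gen_colored_noise(512, 1.5, seed=9)
        np.testing.assert_array_equal(a.values, b.values)
        c = r.gen_colored_noise(512, 1.5, seed=10)
        assert not np.array_equal(a.values, c.values)

    @pytest.mark.parametrize("beta", [0.0, 1.0, 2.0])
    def test_periodogram_slope_matches_beta(self, beta):
        """Log-log periodogram slope ~ -beta within +/-0.15 at n=2^14."""
        slopes = []
        for seed in range(4):
            x = r.gen_colored_noise(2**14, beta, seed=seed).values
            spec = np.abs(np.fft.rfft(x)[1:]) ** 2
            freqs = np.fft.rfftfreq(x.size)[1:]
            # average log-power in log-spaced frequency bands before fitting
            edges = np.geomspace(freqs[0], freqs[-1], 24)
            idx = np.digitize(freqs, edges)
            lf, lp = [], []
            for b in np.unique(idx):
                band = idx == b
                if band.sum() >= 1:
                    lf.append(np.log10(freqs[band]).mean())
                    lp.append(np.log10(spec[band].mean()))
            slopes.append(np.polyfit(lf, lp, 1)[0])
        assert abs(np.mean(slopes) - (-beta)) < 0.15

    @pytest.mark.parametrize("beta", [0.0, 0.5, 1.0, 1.5, 2.0])
    def test_dfa_recovers_alpha(self, beta):
        """Fitted DFA exponent ~ (beta+1)/2, mean over 10 seeds."""
        alphas = [r.dfa(r.gen_colored_noise(2**14, beta, seed=s)).alpha
                  for s in range(10)]
        assert abs(np.mean(alphas) - (beta + 1) / 2) < 0.1

    def test_rejects_bad_args(self):
        with pytest.raises(ValueError):
            r.gen_colored_noise(32, 1.0, seed=0)
        with pytest.raises(ValueError):
            r.gen_colored_noise(128, float("nan"), seed=0)
        with pytest.raises(ValueError):
            r.gen_colored_noise(128, 5.0, seed=0)


class TestLogisticSeries:
    def test_direct_iteration(self):
        s = r.gen_logistic_series(3, r=4.0, x0=0.2, burn_in=0)
        np.testing.assert_allclose(s.values, [0.2, 0.64, 0.9216])

    def test_chaotic_orbit_matches_analytic_exponent(self):
        """Orbit average of ln|r(1-2x)| at r=4 is ln 2."""
        lam = logistic_lyapunov_oracle(4.0, 0.2)
        assert abs(lam - np.log(2)) < 0.02

    def test_converges_to_fixed_point(self):
        s = r.gen_logistic_series(10, r=2.5, x0=0.31, burn_in=500)
        np.testing.assert_allclose(s.values, 1 - 1 / 2.5, atol=1e-9)

    def test_rejects_x0_outside_unit_interval(self):
        with pytest.raises(ValueError):
            r.gen_logistic_series(10, r=4.0, x0=1.2)


class TestPeriodicSeries:
    def test_noiseless_is_deterministic_and_regular(self):
        a = r.gen_periodic_series(1000, 10.0, noise_sd=0.0, seed=1)
        b = r.gen_periodic_series(1000, 10.0, noise_sd=0.0, seed=99)
        np.testing.assert_array_equal(a.values, b.values)
        rng = np.random.default_rng(0)
        noise = rng.standard_normal(1000)
        se_sine = brute_sampen(a.values[:300], 2, 0.2)
        se_noise = brute_sampen(noise[:300], 2, 0.2)
        assert se_sine < se_noise

    def test_large_noise_approaches_iid_entropy(self):
        noisy = r.gen_periodic_series(400, 10.0, noise_sd=10.0, seed=2)
        rng = np.random.default_rng(3)
        se_noisy = brute_sampen(noisy.values, 2, 0.2)
        se_iid = brute_sampen(rng.standard_normal(400), 2, 0.2)
        assert abs(se_noisy - se_iid) < 0.35

    def test_rejects_short_period(self):
        with pytest.raises(ValueError):
            r.gen_periodic_series(100, 1.0)


class TestCoupledPair:
    def test_full_coupling_gives_identical_series(self):
        a, b = r.gen_coupled_pair(500, coupling=1.0, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_anticoupling_gives_negated_series(self):
        a, b = r.gen_coupled_pair(500, coupling=-1.0, seed=5)
        np.testing.assert_array_equal(a.values, -b.values)

    def test_cross_entropy_decreases_with_coupling(self):
        """Asynchrony falls as driver correlation rises: strict at full
        coupling, and as a seed-averaged trend at 0.9 (the per-seed margin
        there is comparable to sampling noise).  The estimator itself is
        validated against the brute-force oracle in the complexity tests."""
        a1, b1 = r.gen_coupled_pair(300, coupling=1.0, seed=7)
        a0, b0 = r.gen_coupled_pair(300, coupling=0.0, seed=7)
        assert brute_cross_sampen(a1.values, b1.values, 2, 0.2) < \
            brute_cross_sampen(a0.values, b0.values, 2, 0.2)
        margins = []
        for seed in range(20):
            u0, v0 = r.gen_coupled_pair(1000, coupling=0.0, seed=seed)
            u9, v9 = r.gen_coupled_pair(1000, coupling=0.9, seed=seed)
            margins.append(r.cross_sample_entropy(u0, v0)
                           - r.cross_sample_entropy(u9, v9))
        assert np.mean(margins) > 0

    def test_rejects_invalid_coupling(self):
        with pytest.raises(ValueError):
            r.gen_coupled_pair(100, coupling=1.5)


class TestBreathWaveform:
    def test_ground_truth_recovers_spec(self):
        spec = r.BreathSpec(seed=11)
        _, table = r.gen_breath_waveform(spec, fs=50.0)
        ibi = np.diff(table.peak_times)
        assert abs(ibi.mean() - spec.mean_ibi) / spec.mean_ibi < 0.05
        cv = ibi.std(ddof=1) / ibi.mean()
        assert abs(cv - spec.cv_ibi) / spec.cv_ibi < 0.05
        lv = table.peak_volumes
        assert abs(lv.mean() - spec.mean_lv) / spec.mean_lv < 0.05

    def test_zero_cv_gives_metronomic_breathing(self):
        spec = r.BreathSpec(cv_ibi=0.0, cv_lv=0.0, duration=600.0, seed=1)
        _, table = r.gen_breath_waveform(spec, fs=50.0)
        np.testing.assert_allclose(np.diff(table.peak_times), spec.mean_ibi,
                                   atol=1e-9)
        np.testing.assert_allclose(table.peak_volumes, spec.mean_lv)

    def test_breath_count_matches_duration(self):
        spec = r.BreathSpec(duration=600.0, seed=3)
        _, table = r.gen_breath_waveform(spec, fs=50.0)
        assert abs(len(table) - 600.0 / spec.mean_ibi) <= 2 + 0.1 * 600 / spec.mean_ibi

    def test_table_matches_interval_draws_exactly(self):
        """Peak-to-peak differences equal the interval draws the renderer used."""
        spec = r.BreathSpec(duration=300.0, seed=8)
        ibi, lv = r.gen_breath_series(spec)
        _, table = r.gen_breath_waveform(spec, fs=50.0)
        n = len(table)
        np.testing.assert_allclose(np.diff(table.peak_times),
                                   ibi.values[:n - 1], rtol=0, atol=1e-12)
        np.testing.assert_allclose(table.peak_volumes, lv.values[:n])

    def test_band_mix_reconstructs_volume(self):
        spec = r.BreathSpec(duration=120.0, seed=4)
        wf, _ = r.gen_breath_waveform(spec, fs=50.0)
        np.testing.assert_allclose(0.6 * wf.ribcage + 0.4 * wf.abdomen,
                                   wf.volume_ref, atol=1e-9)


class TestCohort:
    def test_feature_table_mode_shapes_and_determinism(self):
        table = {"f1": (0.0, 1.0), "f2": (5.0, 2.0)}
        spec = r.CohortSpec(groups=[("A", 5, table), ("B", 5, table)], seed=2)
        c1 = r.gen_cohort(spec)
        c2 = r.gen_cohort(spec)
        assert c1.features.shape == (10, 2)
        assert list(c1.labels.unique()) == ["A", "B"]
        assert c1.features.equals(c2.features)

    def test_identical_specs_give_chance_auc(self):
        table = {"f1": (0.0, 1.0)}
        spec = r.CohortSpec(groups=[("A", 30, table), ("B", 30, table)], seed=6)
        c = r.gen_cohort(spec)
        roc = r.roc_curve(c.features["f1"], c.labels, positive="A",
                          direction="none")
        assert abs(roc.auc - 0.5) < 0.2

    def test_default_group_specs_cover_study_design(self):
        assert set(DEFAULT_GROUP_SPECS) == {"Healthy", "CAA", "UAA", "UNAA"}
        spec = r.default_cohort_spec(n_per_group=2, duration=900.0, seed=0)
        assert len(spec.groups) == 4

    def test_rejects_duplicate_labels(self):
        table = {"f1": (0.0, 1.0)}
        with pytest.raises(ValueError):
            r.CohortSpec(groups=[("A", 3, table), ("A", 3, table)])
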