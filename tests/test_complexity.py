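"""Complexity indices against independent brute-force oracles and
closed-form calibration values."""

import numpy as np
import pytest
from scipy.stats import norm

import respiro as r
from respiro.complexity import EntropyParams, _auto_box_sizes
from respiro.types import Series

from conftest import (brute_cross_sampen, brute_dfa_fluctuation, brute_sampen,
                      logistic_lyapunov_oracle)


class TestDFA:
    def test_fluctuations_match_bruteforce_boxes(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(64)
        res = r.dfa(Series(x), box_sizes=[4, 8, 12, 16])
        for n, f in zip(res.box_sizes, res.fluctuations):
            assert f == pytest.approx(brute_dfa_fluctuation(x, n), rel=1e-10)

    @pytest.mark.parametrize("beta,alpha", [(0.0, 0.5), (1.0, 1.0), (2.0, 1.5)])
    def test_calibration_on_colored_noise(self, beta, alpha):
        est = r.dfa(r.gen_colored_noise(2**14, beta, seed=2)).alpha
        assert abs(est - alpha) < 0.1

    def test_loglog_linearity_on_fractal_series(self):
        res = r.dfa(r.gen_colored_noise(1024, 1.0, seed=4))
        assert res.r_squared >= 0.98

    def test_alpha_monotone_in_beta(self):
        grid = [0.0, 0.5, 1.0, 1.5, 2.0]
        means = [np.mean([r.dfa(r.gen_colored_noise(4096, b, seed=s)).alpha
                          for s in range(5)]) for b in grid]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_shuffling_destroys_correlation(self):
        alphas = []
        for s in range(10):
            x = r.gen_colored_noise(4096, 2.0, seed=s).values.copy()
            np.random.default_rng(s).shuffle(x)
            alphas.append(r.dfa(Series(x)).alpha)
        assert abs(np.mean(alphas) - 0.5) < 0.1

    def test_auto_boxes_span_4_to_quarter_n(self):
        sizes = _auto_box_sizes(1024)
        assert sizes[0] == 4 and sizes[-1] == 256
        assert np.all(np.diff(sizes) > 0)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            r.dfa(Series(np.ones(128)))


class TestSampleEntropy:
    @pytest.mark.parametrize("n,seed", [(120, 0), (300, 1), (500, 2)])
    def test_matches_bruteforce_exactly(self, n, seed):
        x = np.random.default_rng(seed).standard_normal(n)
        est = r.sample_entropy(Series(x))
        assert est == pytest.approx(brute_sampen(x, 2, 0.2), abs=1e-12)

    def test_iid_gaussian_closed_form(self):
        """SampEn(m=2, r=0.2) of iid noise ~ -ln(2 Phi(0.2/sqrt 2) - 1)."""
        x = np.random.default_rng(3).standard_normal(10_000)
        expected = -np.log(2 * norm.cdf(0.2 / np.sqrt(2)) - 1)
        assert r.sample_entropy(Series(x)) == pytest.approx(expected, rel=0.05)

    def test_affine_invariance(self):
        x = np.random.default_rng(4).standard_normal(400)
        a = r.sample_entropy(Series(x))
        b = r.sample_entropy(Series(3.7 * x - 11.0))
        assert a == pytest.approx(b, rel=1e-9)

    def test_strictly_periodic_series_is_fully_regular(self):
        """Every m-match extends to an (m+1)-match, so A = B and SampEn = 0."""
        x = np.tile([0.0, 1.0], 30)
        assert r.sample_entropy(Series(x)) == pytest.approx(0.0, abs=1e-12)

    def test_regular_beats_noise(self):
        sine = r.gen_periodic_series(500, 20.0).values
        noise = np.random.default_rng(5).standard_normal(500)
        assert r.sample_entropy(Series(sine)) < r.sample_entropy(Series(noise))

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            r.sample_entropy(Series(np.full(100, 2.0)))


class TestCrossSampleEntropy:
    def test_self_comparison_matches_oracle(self):
        x = np.random.default_rng(6).standard_normal(300)
        est = r.cross_sample_entropy(Series(x), Series(x))
        assert est == pytest.approx(brute_cross_sampen(x, x, 2, 0.2), abs=1e-12)

    def test_matches_oracle_on_distinct_series(self):
        rng = np.random.default_rng(7)
        xa, xb = rng.standard_normal(300), rng.standard_normal(300)
        est = r.cross_sample_entropy(Series(xa), Series(xb))
        assert est == pytest.approx(brute_cross_sampen(xa, xb, 2, 0.2),
                                    abs=1e-12)

    def test_coupling_lowers_cross_entropy(self):
        a1, b1 = r.gen_coupled_pair(500, coupling=1.0, seed=8)
        a0, b0 = r.gen_coupled_pair(500, coupling=0.0, seed=8)
        assert r.cross_sample_entropy(a1, b1) < r.cross_sample_entropy(a0, b0)

    def test_independent_pair_near_iid_closed_form(self):
        rng = np.random.default_rng(9)
        a = Series(rng.standard_normal(8000))
        b = Series(rng.standard_normal(8000))
        expected = -np.log(2 * norm.cdf(0.2 / np.sqrt(2)) - 1)
        assert r.cross_sample_entropy(a, b) == pytest.approx(expected, rel=0.08)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            r.cross_sample_entropy(Series(np.arange(50.0)),
                                   Series(np.arange(40.0)))

    def test_symmetrized_mean_between_directions(self):
        rng = np.random.default_rng(10)
        a, b = Series(rng.standard_normal(200)), Series(rng.standard_normal(200))
        fwd = r.cross_sample_entropy(a, b)
        rev = r.cross_sample_entropy(b, a)
        sym = r.cross_sample_entropy(a, b, symmetric=True)
        assert sym == pytest.approx((fwd + rev) / 2)


class TestEmbeddingSelection:
    def test_incommensurate_sine_delay_near_quarter_period(self):
        tau, mi = r.average_mutual_information(r.gen_periodic_series(2000, 20.7))
        # oracle: exhaustive scan — the first local minimum of the MI curve
        k = next(i for i in range(1, len(mi) - 1)
                 if mi[i] < mi[i - 1] and mi[i] <= mi[i + 1])
        assert tau == k + 1
        assert 4 <= tau <= 6

    def test_iid_noise_delay_is_one(self):
        s = Series(np.random.default_rng(11).standard_normal(3000))
        tau, _ = r.average_mutual_information(s)
        assert tau == 1

    def test_chaotic_map_delay_is_short(self):
        tau, _ = r.average_mutual_information(r.gen_logistic_series(5000))
        assert tau <= 2

    def test_max_lag_one_rejected(self):
        with pytest.raises(ValueError):
            r.average_mutual_information(Series(np.arange(100.0)), max_lag=1)

    def test_fnn_logistic_low_dimension(self):
        m, _, capped = r.false_nearest_neighbors(r.gen_logistic_series(5000), tau=1)
        assert m <= 3 and not capped

    def test_fnn_sine_embeds_in_low_dimension(self):
        m, _, capped = r.false_nearest_neighbors(
            r.gen_periodic_series(2000, 20.7), tau=5)
        assert 2 <= m <= 3 and not capped

    def test_fnn_noise_hits_cap_with_flag(self):
        s = Series(np.random.default_rng(12).standard_normal(2000))
        m, _, capped = r.false_nearest_neighbors(s, tau=1, max_dim=4)
        assert m == 4 and capped


class TestLargestLyapunov:
    def test_logistic_map_matches_analytic_exponent(self):
        s = r.gen_logistic_series(5000, r=4.0, x0=0.2)
        res = r.largest_lyapunov(s)
        oracle = logistic_lyapunov_oracle(4.0, 0.2)
        assert res.lle > 0
        assert abs(res.lle - oracle) / oracle < 0.15

    def test_sine_is_nonchaotic(self):
        res = r.largest_lyapunov(r.gen_periodic_series(2000, 20.7))
        assert res.lle <= 0.05

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            r.largest_lyapunov(Series(np.random.default_rng(0).standard_normal(50)),
                               embedding=r.EmbeddingParams(m=2, tau=1))


class TestComplexityProfile:
    def test_healthy_subject_profile_is_finite(self):
        ibi, lv = r.gen_breath_series(r.BreathSpec(seed=17))
        prof = r.complexity_profile(ibi, lv)
        row = prof.as_row()
        assert all(np.isfinite(v) for v in row.values())
        assert prof.params["entropy_m"] == 2

    def test_dfa_separates_spectral_exponents(self):
        """beta=1 vs beta=0 subjects differ in DFA_IBI by ~ 0.5."""
        diffs = []
        for seed in range(3):
            p1 = r.complexity_profile(*r.gen_breath_series(
                r.BreathSpec(beta_ibi=1.0, seed=seed)))
            p0 = r.complexity_profile(*r.gen_breath_series(
                r.BreathSpec(beta_ibi=0.0, seed=seed)))
            diffs.append(p1.dfa_ibi - p0.dfa_ibi)
        assert abs(np.mean(diffs) - 0.5) < 0.15

    def test_coupled_drivers_lower_cross_entropy(self):
        p_hi = r.complexity_profile(*r.gen_breath_series(
            r.BreathSpec(coupling=1.0, seed=23)))
        p_lo = r.complexity_profile(*r.gen_breath_series(
            r.BreathSpec(coupling=0.0, seed=23)))
        assert p_hi.cross_sampen_ibi_lv < p_lo.cross_sampen_ibi_lv

    def test_stage_errors_are_labelled(self):
        ibi = Series(np.full(200, 3.5), unit="seconds")
        lv = Series(np.random.default_rng(1).uniform(0.5, 0.8, 200),
                    unit="liters")
        with pytest.raises(ValueError):
            r.complexity_profile(ibi, lv)
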