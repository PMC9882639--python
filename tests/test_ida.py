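"""Bayesian random-effects correlate models, ROPE tests, heterogeneity."""

import numpy as np
import pytest

from sensefactor.ida import (
    IdaModelSpec,
    IdaRefusal,
    categorize_log_bf,
    effect_size_summary,
    evidence_tally,
    fit_ida_model,
    hdi,
    heterogeneity_summary,
    rope_bayes_factor,
)


def simulate_multistudy(seed, r_true, tau1, n_studies=10, per_study=200):
    rng = np.random.default_rng(seed)
    study = np.repeat(np.arange(n_studies), per_study)
    r_s = np.clip(r_true + rng.normal(0, tau1, n_studies), -0.99, 0.99)
    x = rng.standard_normal(study.size)
    y = r_s[study] * x + np.sqrt(1 - r_s[study] ** 2) * \
        rng.standard_normal(study.size)
    return y, x, study.astype(str)


@pytest.fixture(scope="module")
def fitted_r03():
    y, x, s = simulate_multistudy(5, 0.3, 0.05)
    return fit_ida_model(y, x, s, IdaModelSpec(seed=11))


class TestFitting:
    def test_true_effect_inside_hdi(self, fitted_r03):
        summ = effect_size_summary(fitted_r03)
        assert summ.hdi_low <= 0.3 <= summ.hdi_high + 0.02
        assert abs(summ.median - 0.3) < 0.07

    def test_null_by_permutation(self):
        y, x, s = simulate_multistudy(8, 0.0, 0.0)
        rng = np.random.default_rng(1)
        x = rng.permutation(x)
        post = fit_ida_model(y, x, s, IdaModelSpec(seed=2, draws=1000))
        summ = effect_size_summary(post)
        assert abs(summ.median) < 0.05
        assert summ.p_rope > 0.9

    def test_refusal_below_minimum_cases(self):
        y, x, s = simulate_multistudy(3, 0.2, 0.0, n_studies=2, per_study=40)
        res = fit_ida_model(y[:80], x[:80], s[:80], IdaModelSpec(seed=0))
        assert isinstance(res, IdaRefusal)
        assert "100" in res.reason

    def test_missing_pairs_counted_for_refusal(self):
        y, x, s = simulate_multistudy(3, 0.2, 0.0, n_studies=2, per_study=100)
        x = x.copy()
        x[:150] = np.nan  # only 50 complete pairs remain
        res = fit_ida_model(y, x, s, IdaModelSpec(seed=0))
        assert isinstance(res, IdaRefusal)
        assert res.n_cases == 50

    def test_seeded_determinism(self):
        y, x, s = simulate_multistudy(4, 0.2, 0.02, n_studies=5,
                                      per_study=100)
        spec = IdaModelSpec(seed=9, chains=2, draws=200, warmup=200)
        a = fit_ida_model(y, x, s, spec)
        b = fit_ida_model(y, x, s, spec)
        np.testing.assert_array_equal(a.beta1, b.beta1)


class TestHdi:
    def test_matches_bruteforce_shortest_window(self):
        rng = np.random.default_rng(12)
        draws = rng.gamma(2.0, 1.0, 2500)  # skewed, HDI != equal-tailed
        lo, hi = hdi(draws, 0.9)
        xs = np.sort(draws)
        k = int(np.ceil(0.9 * xs.size))
        best = min(((xs[i + k - 1] - xs[i], i) for i in range(xs.size - k + 1)))
        assert lo == pytest.approx(xs[best[1]])
        assert hi == pytest.approx(xs[best[1] + k - 1])

    def test_symmetric_draws_close_to_equal_tailed(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal(200000)
        lo, hi = hdi(draws, 0.95)
        qlo, qhi = np.quantile(draws, [0.025, 0.975])
        assert abs(lo - qlo) < 0.03
        assert abs(hi - qhi) < 0.03


class TestRope:
    def test_all_draws_inside_rope(self):
        draws = np.random.default_rng(1).uniform(-0.05, 0.05, 4000)
        p_rope, log_bf, cat = rope_bayes_factor(draws, (-0.1, 0.1))
        assert p_rope == 1.0
        assert cat == "strong null"

    def test_posterior_equal_to_prior_is_inconclusive(self):
        draws = np.random.default_rng(2).standard_normal(100000)
        _, log_bf, cat = rope_bayes_factor(draws, (-0.1, 0.1), prior_sd=1.0)
        assert abs(log_bf) < 0.1
        assert cat == "inconclusive"

    def test_point_mass_outside_rope(self):
        draws = np.full(4000, 0.5)
        p_rope, log_bf, cat = rope_bayes_factor(draws, (-0.1, 0.1))
        assert p_rope == 0.0
        assert cat == "strong effect"

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            rope_bayes_factor(np.zeros(100), (-0.1, 0.1))

    @pytest.mark.parametrize("log_bf,expected", [
        (2.4, "strong effect"),
        (np.log(10) + 1e-9, "strong effect"),
        (1.2, "moderate effect"),
        (np.log(3) + 1e-9, "moderate effect"),
        (1.0, "inconclusive"),
        (-1.0, "inconclusive"),
        (-1.2, "moderate null"),
        (-2.4, "strong null"),
    ])
    def test_category_boundaries(self, log_bf, expected):
        assert categorize_log_bf(log_bf) == expected

    def test_evidence_accumulates_with_n(self):
        meds = []
        for n in (200, 1000, 5000):
            y, x, s = simulate_multistudy(21, 0.4, 0.02, n_studies=5,
                                          per_study=n // 5)
            post = fit_ida_model(y, x, s, IdaModelSpec(
                seed=3, chains=2, draws=1000, warmup=300, rhat_max=1.05))
            _, log_bf, _ = rope_bayes_factor(post.beta1, (-0.1, 0.1))
            meds.append(log_bf)
        assert meds == sorted(meds) or meds[-1] == meds[-2]  # saturates at clip
        assert meds[-1] > np.log(10)


class TestHeterogeneity:
    def test_homogeneous_versus_heterogeneous(self):
        """Between-study heterogeneity is ordered correctly: data generated
        with tau1 = 0 yield smaller I^2 and a narrower prediction-to-HDI
        ratio than data with tau1 = 0.2, and the prediction interval always
        contains the HDI's center (it adds new-study variance)."""
        spec = IdaModelSpec(seed=5, draws=1500, warmup=500, rhat_max=1.02)
        results = {}
        for tau1 in (0.0, 0.2):
            y, x, s = simulate_multistudy(33, 0.2, tau1, n_studies=12)
            post = fit_ida_model(y, x, s, IdaModelSpec(
                **{**spec.__dict__, "seed": 5 + int(tau1 * 10)}))
            summ = effect_size_summary(post)
            pi = summ.prediction_interval
            assert pi[0] <= summ.median <= pi[1]
            assert pi[1] - pi[0] >= (summ.hdi_high - summ.hdi_low) - 1e-9
            results[tau1] = summ
        assert results[0.0].i2 < results[0.2].i2
        ratio = {t: (s.prediction_interval[1] - s.prediction_interval[0])
                 / (s.hdi_high - s.hdi_low) for t, s in results.items()}
        assert ratio[0.0] < ratio[0.2]

    def test_tau_rank_recovery(self):
        taus = []
        for i, tau1 in enumerate((0.0, 0.15)):
            y, x, s = simulate_multistudy(40 + i, 0.2, tau1, n_studies=12,
                                          per_study=300)
            post = fit_ida_model(y, x, s, IdaModelSpec(
                seed=6, chains=2, draws=400, warmup=300, rhat_max=1.05))
            taus.append(float(np.median(post.tau1)))
        assert taus[0] < taus[1]


class TestTally:
    def test_single_summary_sums_to_one(self, fitted_r03):
        summ = effect_size_summary(fitted_r03)
        tally = evidence_tally([summ])
        assert sum(tally["counts"].values()) == 1
        assert tally["total"] == 1

    def test_empty_battery(self):
        tally = evidence_tally([])
        assert tally["total"] == 0
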