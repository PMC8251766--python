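import numpy as np
import pytest
from scipy import stats

from vpdmeta.database import StudyDatabase
from vpdmeta.effects import EffectEstimate
from vpdmeta.imputation import impute_database
from vpdmeta.pooling import (PooledEffectModel, bca_interval,
                             bootstrap_L_star, percentile_interval,
                             summarize_trait, weighted_mean_L)

from conftest import make_record


def est(sid, L, v=None, unit=False, **kw):
    return EffectEstimate(sid, L, None if unit else v,
                          "unit_weight" if unit else "reported", **kw)


class TestWeightedMean:
    def test_equal_variances_give_midpoint(self):
        assert weighted_mean_L([est("a", 0.1, 0.02), est("b", 0.3, 0.02)]) \
            == pytest.approx(0.2)

    def test_inverse_variance_arithmetic(self):
        # w = 100, 33.333 -> (0*100 + 0.3*33.333)/133.333 = 0.075
        assert weighted_mean_L([est("a", 0.0, 0.01), est("b", 0.3, 0.03)]) \
            == pytest.approx(0.075)

    def test_single_study_returns_its_own_L(self):
        assert weighted_mean_L([est("a", -0.42, 0.05)]) == pytest.approx(-0.42)

    def test_unit_weight_is_plain_mean(self):
        assert weighted_mean_L([est("a", 0.1, unit=True),
                                est("b", 0.5, unit=True)]) == pytest.approx(0.3)

    def test_errors(self):
        with pytest.raises(ValueError):
            weighted_mean_L([])
        with pytest.raises(ValueError, match="mixed"):
            weighted_mean_L([est("a", 0.1, 0.01), est("b", 0.2, unit=True)])

    def test_matches_independent_recomputation(self, rng):
        """Oracle: from-scratch loop arithmetic on <=5 studies to 1e-12."""
        for _ in range(20):
            k = int(rng.integers(1, 6))
            Ls = rng.normal(0, 0.5, k)
            vs = rng.uniform(0.001, 0.1, k)
            num = den = 0.0
            for L, v in zip(Ls, vs):
                num += L / v
                den += 1.0 / v
            ests = [est(f"s{i}", float(Ls[i]), float(vs[i]))
                    for i in range(k)]
            assert weighted_mean_L(ests) == pytest.approx(num / den,
                                                          abs=1e-12)


class TestBootstrap:
    def test_degenerate_all_equal(self):
        ests = [est(f"s{i}", 0.25, 0.01) for i in range(5)]
        reps = bootstrap_L_star(ests, B=200, seed=3)
        assert np.all(reps == pytest.approx(0.25))

    def test_same_seed_reproduces(self):
        ests = [est(f"s{i}", float(L), 0.01 + i * 0.001)
                for i, L in enumerate([0.1, -0.2, 0.4, 0.0])]
        a = bootstrap_L_star(ests, B=500, seed=11)
        b = bootstrap_L_star(ests, B=500, seed=11)
        assert np.array_equal(a, b)
        c = bootstrap_L_star(ests, B=500, seed=12)
        assert not np.array_equal(a, c)

    def test_replicate_mean_consistent_with_observed(self, rng):
        k, B = 20, 4999
        ests = [est(f"s{i:02d}", float(rng.normal(-0.2, 0.15)),
                    float(rng.uniform(0.005, 0.05))) for i in range(k)]
        obs = weighted_mean_L(ests)
        reps = bootstrap_L_star(ests, B=B, seed=5)
        mc_se = reps.std(ddof=1) / np.sqrt(B)
        # bootstrap distribution centers near the observed statistic
        assert abs(reps.mean() - obs) < 3 * mc_se + 0.5 * reps.std(ddof=1)


class TestBcaInterval:
    def test_degenerate_replicates_zero_width(self):
        ci = bca_interval(np.full(100, 0.2), 0.2, [0.2] * 10)
        assert (ci.low, ci.high) == (0.2, 0.2)
        assert ci.method == "degenerate"

    def test_symmetric_replicates_reduce_to_percentile(self, rng):
        # symmetric replicate cloud + symmetric jackknife => z0 ~ 0, a = 0
        z = rng.normal(0, 1, 20001)
        reps = np.concatenate([z, -z])  # exactly symmetric about 0
        jack = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])  # zero skewness
        bca = bca_interval(reps, 0.0, jack)
        perc = percentile_interval(reps)
        step = np.diff(np.sort(reps)).max()
        assert bca.low == pytest.approx(perc.low, abs=step)
        assert bca.high == pytest.approx(perc.high, abs=step)

    def test_observed_outside_replicates_falls_back(self):
        reps = np.linspace(1.0, 2.0, 99)
        ci = bca_interval(reps, observed=0.0, jackknife_values=[0.0, 0.1])
        assert ci.method == "percentile_fallback"
        assert ci.low == pytest.approx(np.quantile(reps, 0.025))

    def test_matches_scipy_bca_on_plain_mean(self, rng):
        """Same replicates, same jackknife: endpoints must agree with the
        independently implemented BCa in scipy.stats.bootstrap."""
        x = rng.normal(0.3, 1.0, 25)
        B = 1999
        seed = 77
        idx = np.random.default_rng(seed).integers(0, x.size, size=(B, x.size))
        reps = x[idx].mean(axis=1)
        jack = (x.sum() - x) / (x.size - 1)
        mine = bca_interval(reps, x.mean(), jack)
        ref = stats.bootstrap((x,), np.mean, n_resamples=B, method="BCa",
                              confidence_level=0.95,
                              random_state=np.random.default_rng(seed))
        assert mine.low == pytest.approx(ref.confidence_interval.low,
                                         rel=1e-12)
        assert mine.high == pytest.approx(ref.confidence_interval.high,
                                          rel=1e-12)


class TestSummarizeTrait:
    @pytest.fixture
    def db3(self):
        recs = [make_record(f"s{i}", mean_high=mh, measurement_condition="NA")
                for i, mh in enumerate([70.0, 85.0, 95.0, 105.0])]
        db = StudyDatabase(recs)
        return impute_database(db)

    def test_row_order_invariance(self, db3):
        db, rep = db3
        res = summarize_trait(db, "stomatal_conductance", report=rep,
                              B=499, seed=9)
        shuffled = StudyDatabase(list(reversed(db.records)), validate=False)
        res2 = summarize_trait(shuffled, "stomatal_conductance", report=rep,
                               B=499, seed=9)
        assert res.L_star == res2.L_star
        assert res.ci_low == res2.ci_low and res.ci_high == res2.ci_high

    def test_interval_brackets_estimate_after_back_transform(self, db3):
        db, rep = db3
        res = summarize_trait(db, "stomatal_conductance", report=rep,
                              B=1999, seed=9)
        assert res.ci_low <= res.effect_size <= res.ci_high
        assert res.effect_size == pytest.approx(np.expm1(res.L_star))
        # monotone back-transform of the L-scale endpoints
        assert res.ci_low == pytest.approx(np.expm1(res.ci_low_L))
        assert res.ci_high == pytest.approx(np.expm1(res.ci_high_L))

    def test_small_trait_has_no_ci(self):
        recs = [make_record("a", measurement_condition="NA"),
                make_record("b", mean_high=90.0, measurement_condition="NA")]
        db, rep = impute_database(StudyDatabase(recs))
        res = summarize_trait(db, "stomatal_conductance", report=rep, B=999)
        assert res.n_studies == 2
        assert res.ci_low is None and res.ci_high is None
        assert res.L_star != 0.0

    def test_zero_studies_errors(self, db3):
        db, rep = db3
        with pytest.raises(ValueError, match="no studies"):
            summarize_trait(db, "stomatal_conductance", "SC", report=rep)

    def test_unit_weight_trait_pools_with_weight_one(self):
        recs = [make_record(f"u{i}", trait="length_of_mesophyll_cell",
                            sd_control=None, sd_high=None,
                            mean_high=mh, measurement_condition="NA")
                for i, mh in enumerate([80.0, 90.0, 120.0])]
        db, rep = impute_database(StudyDatabase(recs))
        res = summarize_trait(db, "length_of_mesophyll_cell", report=rep,
                              B=499, seed=2)
        assert res.weighting == "unit_weight"
        expected = np.mean([np.log(mh / 100.0) for mh in (80.0, 90.0, 120.0)])
        assert res.L_star == pytest.approx(expected)


def test_model_results_summary_mentions_counts():
    ests = [est(f"s{i}", 0.1 * i, 0.01, species=f"sp{i}") for i in range(4)]
    res = PooledEffectModel(ests, trait="leaf_area").fit(B=199, seed=1)
    s = res.summary()
    assert "n=4" in s and "N=4" in s and "leaf_area" in s
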