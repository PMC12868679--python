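import numpy as np
import pandas as pd
import pytest

from metatme.core import ValidationError
from metatme.survival import (
    SurvivalFit,
    kfold_cox_auc,
    km_logrank,
    mwu_enrichment,
    prognosis_score,
    univariate_cox,
)


def _exp_cohort(rng, n, beta, x=None, censor=0.02):
    x = rng.standard_normal(n) if x is None else x
    t = rng.exponential(1 / (0.1 * np.exp(beta * x)))
    if censor > 0:
        c = rng.exponential(1 / censor, size=n)
        return x, np.minimum(t, c), t <= c
    return x, t, np.ones(n, dtype=bool)


class TestMwu:
    def test_exact_small_sample_p(self):
        m = pd.DataFrame({"f": [1, 2, 3, 4, 5, 6]})
        res = mwu_enrichment(m, [True, True, True, False, False, False])
        # exact two-sided p for complete separation of 3 vs 3
        assert res["p"].iloc[0] == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        m = pd.DataFrame({"f": [1, 2, 3, 1, 2, 3]})
        res = mwu_enrichment(m, [True] * 3 + [False] * 3)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_constant_feature_convention(self):
        m = pd.DataFrame({"f": [2.0] * 6})
        res = mwu_enrichment(m, [True] * 3 + [False] * 3)
        assert res["p"].iloc[0] == 1.0

    def test_bh_adjustment_properties(self, rng):
        m = pd.DataFrame(rng.standard_normal((40, 20)),
                         columns=[f"f{i}" for i in range(20)])
        res = mwu_enrichment(m, [True] * 20 + [False] * 20)
        assert (res["q"] >= res["p"] - 1e-12).all()
        # BH preserves the p-value ordering
        srt = res.sort_values("p")
        assert (np.diff(srt["q"]) >= -1e-12).all()

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            mwu_enrichment(pd.DataFrame({"f": [1.0, 2.0]}), [True, True])


class TestUnivariateCox:
    def test_recovers_hr_two(self, rng):
        x = (rng.uniform(size=500) < 0.5).astype(float)
        x, times, events = _exp_cohort(rng, 500, np.log(2), x=x)
        res = univariate_cox(pd.DataFrame({"x": x}), times, events)
        assert abs(res["loghr"].iloc[0] - np.log(2)) < 0.2

    def test_all_zero_feature_flagged(self, rng):
        _, times, events = _exp_cohort(rng, 100, 0.0)
        res = univariate_cox(pd.DataFrame({"x": np.zeros(100)}), times, events)
        assert not res["converged"].iloc[0]

    def test_too_few_events_rejected(self, rng):
        with pytest.raises(ValidationError):
            univariate_cox(
                pd.DataFrame({"x": rng.standard_normal(20)}),
                np.ones(20), np.zeros(20, dtype=bool),
            )


class TestKmLogrank:
    def test_identical_strata_chi2_zero(self):
        values = np.array([1, 1, 2, 2, 1, 1, 2, 2], dtype=float)
        times = np.array([5, 6, 5, 6, 7, 8, 7, 8], dtype=float)
        events = np.ones(8, dtype=bool)
        res = km_logrank(values, times, events)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_strata_swap_symmetric(self, rng):
        values = rng.standard_normal(60)
        _, times, events = _exp_cohort(rng, 60, 0.0)
        a = km_logrank(values, times, events)
        b = km_logrank(-values, times, events)
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-6)

    def test_planted_hazard_detected(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = (r.uniform(size=200) < 0.5).astype(float)
            x, times, events = _exp_cohort(r, 200, np.log(3), x=x)
            hits += km_logrank(x, times, events).p < 0.01
        assert hits >= 9

    def test_degenerate_stratum_rejected(self):
        with pytest.raises(ValidationError):
            km_logrank(np.ones(10), np.arange(1, 11, dtype=float),
                       np.ones(10, dtype=bool))


class TestKfoldCoxAuc:
    def test_perfect_binary_score_auc_one(self, rng):
        # no censoring before the horizon; a score that perfectly separates
        # early from late events discriminates perfectly
        n = 200
        x = np.concatenate([np.ones(n // 2), np.zeros(n // 2)])
        times = np.concatenate([
            rng.uniform(1, 10, n // 2),    # high risk: early events
            rng.uniform(50, 60, n // 2),   # low risk: far beyond horizon
        ])
        events = np.ones(n, dtype=bool)
        fit = kfold_cox_auc(pd.DataFrame({"x": x}), times, events, k=5, seed=0)
        # past the last high-risk event every case ranks above every control
        late = fit.auc_times > 10.0
        vals = fit.auc_mean[late]
        vals = vals[~np.isnan(vals)]
        assert len(vals)
        assert vals.min() >= 0.999

    def test_fit_shapes_and_bounds(self, rng):
        x, times, events = _exp_cohort(rng, 150, 1.0)
        fit = kfold_cox_auc(pd.DataFrame({"x": x}), times, events, k=4, seed=1)
        assert fit.auc_folds.shape == (4, len(fit.auc_times))
        vals = fit.auc_folds[~np.isnan(fit.auc_folds)]
        assert ((vals >= 0) & (vals <= 1)).all()
        assert len(fit.loghr) == 1

    def test_signature_partition(self):
        fit = SurvivalFit(
            loghr=pd.DataFrame(), auc_times=np.array([]),
            auc_folds=np.empty((0, 0)), auc_mean=np.array([]),
            auc_lo=np.array([]), auc_hi=np.array([]),
            weights=pd.Series({"a": 0.5, "b": -0.2, "c": 1.0}),
        )
        assert set(fit.resistance_features) == {"a", "c"}
        assert set(fit.response_features) == {"b"}
        assert set(fit.resistance_features) | set(fit.response_features) == {
            "a", "b", "c"
        }


class TestPrognosisScore:
    def _fit(self, weights):
        return SurvivalFit(
            loghr=pd.DataFrame(), auc_times=np.array([]),
            auc_folds=np.empty((0, 0)), auc_mean=np.array([]),
            auc_lo=np.array([]), auc_hi=np.array([]),
            weights=pd.Series(weights),
        )

    def test_weighted_sum(self):
        fit = self._fit({"a": 0.5, "b": 0.5})
        m = pd.DataFrame({"a": [1.0], "b": [-1.0]})
        assert prognosis_score(fit, m).iloc[0] == pytest.approx(0.0)

    def test_sign_flip_negates_scores(self, rng):
        w = {"a": 0.7, "b": -0.3}
        m = pd.DataFrame(rng.standard_normal((10, 2)), columns=["a", "b"])
        s1 = prognosis_score(self._fit(w), m)
        s2 = prognosis_score(self._fit({k: -v for k, v in w.items()}), m)
        np.testing.assert_allclose(s1, -s2)

    def test_subsets_partition_score(self, rng):
        w = {"a": 0.7, "b": -0.3, "c": 1.2}
        m = pd.DataFrame(rng.standard_normal((10, 3)), columns=["a", "b", "c"])
        full = prognosis_score(self._fit(w), m)
        res = prognosis_score(self._fit(w), m, subset="resistance")
        resp = prognosis_score(self._fit(w), m, subset="response")
        np.testing.assert_allclose(full, res + resp)

    def test_high_score_worse_survival(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(100 + seed)
            x, times, events = _exp_cohort(r, 150, 1.5)
            fit = self._fit({"x": 1.0})
            scores = prognosis_score(fit, pd.DataFrame({"x": x}))
            hits += km_logrank(scores.to_numpy(), times, events).p < 0.05
        assert hits >= 9

    def test_unknown_subset_rejected(self):
        with pytest.raises(ValidationError):
            prognosis_score(self._fit({"a": 1.0}), pd.DataFrame({"a": [1.0]}),
                            subset="bogus")
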