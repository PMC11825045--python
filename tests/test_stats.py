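"""Group comparisons, odds ratios, the safe-upper-limit procedure, and
survival stratification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ventmp import stats as vs


class TestCompareGroups:
    def test_identical_samples_non_significant(self):
        x = [1.0, 2, 3, 4, 5, 6]
        res = vs.compare_groups(x, x, "nonsymmetric")
        assert res.p_value > 0.99

    def test_exact_rank_p_for_separated_triples(self):
        # [1,2,3] vs [4,5,6]: the two-sided exact p is 2/20
        res = vs.compare_groups([1, 2, 3], [4, 5, 6], "nonsymmetric")
        assert res.p_value == pytest.approx(0.1)

    def test_balanced_contingency_table(self):
        dead = ["a"] * 50 + ["b"] * 50
        alive = ["a"] * 50 + ["b"] * 50
        res = vs.compare_groups(dead, alive, "categorical")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_symmetric_uses_t(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(2, 1, 50)
        res = vs.compare_groups(a, b, "symmetric")
        assert res.p_value < 1e-6

    def test_small_arm_rejected(self):
        with pytest.raises(ValueError):
            vs.compare_groups([1], [2, 3], "nonsymmetric")


class TestUnadjustedOR:
    def test_null_exposure(self, rng):
        x = rng.normal(size=5000)
        y = rng.integers(0, 2, size=5000)
        res = vs.unadjusted_or(x, y)
        assert res.ci_low < 1.0 < res.ci_high

    def test_recovers_known_or(self, rng):
        # logistic truth: OR 1.02 per unit over a wide exposure range
        beta = np.log(1.02)
        x = rng.uniform(0, 200, size=20000)
        p = 1 / (1 + np.exp(-(-2.5 + beta * x)))
        y = (rng.random(20000) < p).astype(int)
        res = vs.unadjusted_or(x, y)
        assert res.ci_low <= 1.02 <= res.ci_high

    def test_separation_flagged(self):
        x = np.r_[np.zeros(20), np.ones(20) + 5]
        y = np.r_[np.zeros(20), np.ones(20)]
        res = vs.unadjusted_or(x, y)
        assert res.separation and res.or_per_unit is None


def brute_force_one_sided_p(x, y):
    """Enumeration oracle via rank sums: P(rank-sum of arm x >= observed)
    under exchangeability, with midranks for ties."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n = len(x)
    obs = ranks[:n].sum()
    sums = [sum(ranks[list(idx)]) for idx in
            itertools.combinations(range(len(pooled)), n)]
    return np.mean([s >= obs - 1e-12 for s in sums])


class TestSafeUpperLimit:
    def test_exchangeable_arms_no_limit(self):
        x = [1.0, 2, 3, 4, 5]
        res = vs.safe_upper_limit(x, x)
        assert res.limit is None
        assert res.p_value > 0.4

    def test_fully_separated_quadruples(self):
        # exact one-sided p = 1/70; limit = 95th pct of {1,2,3,4} = 3.85
        res = vs.safe_upper_limit([1, 2, 3, 4], [5, 6, 7, 8], alpha=0.05)
        assert res.p_value == pytest.approx(1 / 70)
        assert res.limit == pytest.approx(3.85)

    def test_limit_equals_survivor_95th_percentile(self, rng):
        surv = rng.normal(0, 1, 500)
        nonsurv = rng.normal(1, 1, 500)
        res = vs.safe_upper_limit(surv, nonsurv, alpha=0.05)
        assert res.limit == pytest.approx(np.percentile(surv, 95))

    def test_limit_within_survivor_range(self, rng):
        surv = rng.exponential(1, 200)
        nonsurv = surv + 1
        res = vs.safe_upper_limit(surv, nonsurv)
        assert surv.min() <= res.limit <= surv.max()

    @pytest.mark.parametrize("n,m", [(3, 3), (5, 4), (8, 8), (2, 8)])
    def test_exact_p_matches_enumeration(self, rng, n, m):
        x = rng.normal(1, 1, n)
        y = rng.normal(0, 1, m)
        p_pkg = vs.mw_one_sided_greater(x, y)
        assert p_pkg == pytest.approx(brute_force_one_sided_p(x, y))

    def test_exact_p_matches_enumeration_with_ties(self):
        x = [1.0, 2.0, 2.0, 5.0]
        y = [2.0, 3.0, 3.0, 1.0]
        assert vs.mw_one_sided_greater(x, y) == pytest.approx(
            brute_force_one_sided_p(x, y))

    def test_monotone_transform_invariance(self, rng):
        # n=301 puts the 95th percentile exactly on an order statistic, so
        # the interpolated percentile commutes with the monotone transform
        surv = rng.lognormal(0, 0.5, 301)
        nonsurv = rng.lognormal(0.5, 0.5, 301)
        res_raw = vs.safe_upper_limit(surv, nonsurv)
        res_log = vs.safe_upper_limit(np.log(surv), np.log(nonsurv))
        assert res_raw.p_value == pytest.approx(res_log.p_value)
        assert np.log(res_raw.limit) == pytest.approx(res_log.limit)

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            vs.safe_upper_limit([1, 2], [3, 4], alpha=0.7)

    def test_null_rejection_rate_near_alpha(self, rng):
        # type-I control: both arms iid, present-limit rate ~ alpha
        hits = 0
        reps = 400
        for _ in range(reps):
            pooled = rng.normal(size=120)
            res = vs.safe_upper_limit(pooled[:60], pooled[60:], alpha=0.05)
            hits += res.limit is not None
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(hits / reps - 0.05) <= 3 * se


class TestLimitsByStratum:
    @staticmethod
    def _tables(rng, n=400, shift=0.0):
        feats = pd.DataFrame({
            "admission_id": [f"A{i}" for i in range(n)],
            "window_h": 48,
            "twa_mp": rng.normal(20, 5, n),
            "twa_mp_ibw": rng.normal(0.3, 0.07, n),
        })
        adm = pd.DataFrame({
            "admission_id": feats["admission_id"],
            "icu_mortality": rng.integers(0, 2, n),
            "hypoxemia_group": rng.choice(["mild", "moderate"], n),
        })
        dead = adm["icu_mortality"] == 1
        feats.loc[dead.to_numpy(), "twa_mp_ibw"] += shift
        return feats, adm

    def test_bookkeeping_single_stratum(self, rng):
        feats, adm = self._tables(rng, n=60)
        adm["hypoxemia_group"] = "mild"
        res = vs.limits_by_stratum(feats, adm, variables=("twa_mp_ibw",),
                                   windows_h=(48,))
        assert [r.stratum for r in res] == ["all", "mild"]

    def test_injected_effect_recovered_per_stratum(self, rng):
        feats, adm = self._tables(rng, n=600, shift=0.08)
        res = vs.limits_by_stratum(feats, adm, variables=("twa_mp_ibw",),
                                   windows_h=(48,))
        merged = feats.merge(adm, on="admission_id")
        for r in res:
            assert r.limit is not None
            sub = merged if r.stratum == "all" else \
                merged[merged["hypoxemia_group"] == r.stratum]
            surv = sub.loc[sub["icu_mortality"] == 0, "twa_mp_ibw"]
            assert r.limit == pytest.approx(np.percentile(surv, 95))

    def test_thin_stratum_skipped_with_warning(self, rng):
        feats, adm = self._tables(rng, n=40)
        adm.loc[adm.index[:3], "hypoxemia_group"] = "severe"
        adm.loc[adm.index[:3], "icu_mortality"] = [1, 0, 0]  # 1 nonsurvivor
        with pytest.warns(UserWarning, match="severe"):
            vs.limits_by_stratum(feats, adm, variables=("twa_mp_ibw",),
                                 windows_h=(48,))


class TestToAbsoluteMP:
    @pytest.mark.parametrize("per_kg,expected", [
        (0.22, 15.53), (0.27, 19.05), (0.34, 23.99), (0.0, 0.0),
    ])
    def test_printed_conversions_at_median_ibw(self, per_kg, expected):
        assert vs.to_absolute_mp(per_kg, 70.57) == expected

    def test_multiplicative(self):
        assert vs.to_absolute_mp(0.5, 60) == pytest.approx(30.0)


class TestSurvival:
    @staticmethod
    def _cohort(rng, hr=1.0, n=600):
        mp = rng.normal(0.3, 0.08, n)
        limit = float(np.percentile(mp, 60))
        above = (mp > limit).astype(int)
        lam = 0.02 * hr ** above
        t = rng.exponential(1 / lam)
        event = (t < 90).astype(int)
        t = np.minimum(t, 90)
        feats = pd.DataFrame({
            "admission_id": range(n), "window_h": 48, "twa_mp_ibw": mp})
        adm = pd.DataFrame({
            "admission_id": range(n), "followup_days": t, "event": event,
            "hypoxemia_group": "mild"})
        res = vs.SafeLimitResult("all", "twa_mp_ibw", 48, 0.05, 0.01,
                                 limit, n, n)
        return feats, adm, [res]

    def test_identical_groups_hr_near_one(self, rng):
        feats, adm, limits = self._cohort(rng, hr=1.0)
        rep = vs.survival_by_limit(feats, adm, limits)[0]
        assert rep.ci_low < 1.0 < rep.ci_high

    def test_recovers_known_hazard_ratio(self, rng):
        feats, adm, limits = self._cohort(rng, hr=0.5, n=1000)
        rep = vs.survival_by_limit(feats, adm, limits)[0]
        assert rep.ci_low <= 0.5 <= rep.ci_high
        assert rep.hazard_ratio < 1.0

    def test_km_curves_monotone(self, rng):
        feats, adm, limits = self._cohort(rng)
        rep = vs.survival_by_limit(feats, adm, limits)[0]
        for _, g in rep.km.groupby("group"):
            surv = g.sort_values("time")["survival"].to_numpy()
            assert np.all(np.diff(surv) <= 1e-12)
            assert ((surv >= 0) & (surv <= 1)).all()

    def test_absent_limit_omitted_with_note(self, rng):
        feats, adm, _ = self._cohort(rng)
        res = vs.SafeLimitResult("severe", "twa_mp_ibw", 48, 0.05, 0.4,
                                 None, 10, 10)
        rep = vs.survival_by_limit(feats, adm, [res])[0]
        assert rep.hazard_ratio is None and "no limit" in rep.note

    def test_degenerate_single_group_flagged(self, rng):
        feats, adm, limits = self._cohort(rng, n=50)
        limits[0].limit = float(feats["twa_mp_ibw"].max() + 1)  # nobody above
        rep = vs.survival_by_limit(feats, adm, limits)[0]
        assert rep.degenerate
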