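"""Signature fitting, scoring, KM, weighted log-rank, C-index, combined Cox."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from _oracles import (
    harrell_cindex_bruteforce,
    km_survival_bruteforce,
    standard_logrank_bruteforce,
)
from radsurv.survival import (
    CombinedCoxModel,
    CoxSignature,
    SignatureModel,
    SurvivalData,
    fit_lasso_cox,
    harrell_cindex,
    hazard_ratio,
    km_estimate,
    optimal_cutpoint,
    radiomics_score,
    stratify_by_score,
    weighted_logrank,
)

# reference six-deep-feature signature, used as a worked-example fixture
SIX_FEATURE_SIGNATURE = CoxSignature(
    [
        ("FLAIR_ST_F7_870", 0.06867720),
        ("FLAIR_SN_F7_2297", -0.05909112),
        ("T1C_SNE_F6_806", 0.05420293),
        ("T2_SNE_F7_772", -0.03454031),
        ("T1C_SNE_F7_1508", -0.02240571),
        ("FLAIR_SNE_F6_2981", -0.00958802),
    ]
)


def _exp_cohort(rng, n, lp=None, scale=500.0, censor_frac=0.0):
    lp = np.zeros(n) if lp is None else lp
    t = rng.exponential(scale * np.exp(-lp))
    ev = rng.uniform(size=n) > censor_frac
    t_obs = np.where(ev, t, rng.uniform(0, t))
    return SurvivalData(np.maximum(t_obs, 1e-3), ev.astype(int))


class TestRadiomicsScore:
    def test_zero_vector(self):
        values = {n: 0.0 for n in SIX_FEATURE_SIGNATURE.names}
        assert radiomics_score(values, SIX_FEATURE_SIGNATURE) == 0.0

    def test_unit_responses(self):
        for name, coef in SIX_FEATURE_SIGNATURE.features:
            values = {n: float(n == name) for n in SIX_FEATURE_SIGNATURE.names}
            assert radiomics_score(values, SIX_FEATURE_SIGNATURE) == pytest.approx(coef, abs=1e-12)

    def test_all_ones_sums_coefficients(self):
        values = {n: 1.0 for n in SIX_FEATURE_SIGNATURE.names}
        assert radiomics_score(values, SIX_FEATURE_SIGNATURE) == pytest.approx(-0.00274503, abs=1e-8)

    def test_missing_feature_named(self):
        with pytest.raises(KeyError, match="missing signature feature"):
            radiomics_score({"FLAIR_ST_F7_870": 1.0}, SIX_FEATURE_SIGNATURE)

    def test_linearity(self, rng):
        x = pd.Series(rng.normal(size=6), index=SIX_FEATURE_SIGNATURE.names)
        y = pd.Series(rng.normal(size=6), index=SIX_FEATURE_SIGNATURE.names)
        sx = radiomics_score(x, SIX_FEATURE_SIGNATURE)
        sy = radiomics_score(y, SIX_FEATURE_SIGNATURE)
        assert radiomics_score(3.0 * x, SIX_FEATURE_SIGNATURE) == pytest.approx(3.0 * sx)
        assert radiomics_score(x + y, SIX_FEATURE_SIGNATURE) == pytest.approx(sx + sy)

    def test_dataframe_scoring(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 6)), columns=SIX_FEATURE_SIGNATURE.names)
        scores = radiomics_score(df, SIX_FEATURE_SIGNATURE)
        assert len(scores) == 5
        assert scores.iloc[0] == pytest.approx(radiomics_score(df.iloc[0], SIX_FEATURE_SIGNATURE))


class TestLassoCox:
    @pytest.fixture(scope="class")
    def planted_fit(self):
        rng = np.random.default_rng(17)
        n = 400
        names = ["planted_0", "planted_1", "planted_2"] + [f"noise_{i}" for i in range(300)]
        X = rng.standard_normal((n, len(names)))
        surv = _exp_cohort(rng, n, lp=X[:, :3].sum(axis=1), censor_frac=0.2)
        table = pd.DataFrame(X, columns=names)
        sig, info = fit_lasso_cox(table, surv, seed=0)
        return table, surv, sig, info

    def test_full_shrinkage_limit(self, planted_fit):
        _, _, _, info = planted_fit
        # the regularization path starts at a penalty with no active features
        assert info["n_active"][0] == 0

    def test_active_set_monotone_near_path_start(self, planted_fit):
        _, _, _, info = planted_fit
        n_active = np.asarray(info["n_active"], dtype=int)
        assert n_active[0] <= n_active[1] <= n_active[5]

    def test_planted_support_recovered(self, planted_fit):
        _, _, sig, _ = planted_fit
        assert {"planted_0", "planted_1", "planted_2"} <= set(sig.names)

    def test_duplicate_collapses_after_pruning(self, planted_fit):
        table, surv, _, _ = planted_fit
        from radsurv.selection import SelectionConfig, cindex_filter, correlation_prune

        dup = table.copy()
        dup["planted_dup"] = dup["planted_0"]
        kept, cvals = cindex_filter(dup, surv.time, surv.event, SelectionConfig())
        pruned = correlation_prune(dup[kept], cvals)
        assert not {"planted_0", "planted_dup"} <= set(pruned)
        sig, _ = fit_lasso_cox(dup[pruned], surv, seed=0)
        assert len({"planted_0", "planted_dup"} & set(sig.names)) <= 1

    def test_insufficient_events_rejected(self, rng):
        table = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("abc"))
        surv = SurvivalData(rng.exponential(10, 12) + 0.1, np.zeros(12, int))
        with pytest.raises(ValueError, match="events"):
            fit_lasso_cox(table, surv)


class TestKaplanMeier:
    def test_three_event_curve(self):
        km = km_estimate(SurvivalData([1.0, 2.0, 3.0], [1, 1, 1]))
        assert np.allclose(km.survival_at([1.0, 2.0, 3.0]), [2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat(self):
        km = km_estimate(SurvivalData([1.0, 2.0, 3.0], [0, 0, 0]))
        assert km.survival_at(3.0) == pytest.approx(1.0)

    def test_matches_bruteforce_with_censoring(self, rng):
        surv = _exp_cohort(rng, 50, censor_frac=0.3)
        km = km_estimate(surv)
        t_o, s_o = km_survival_bruteforce(surv.time, surv.event)
        assert np.allclose(km.survival_at(t_o), s_o)

    def test_exponential_median(self, rng):
        surv = _exp_cohort(rng, 1000, scale=300.0)
        km = km_estimate(surv)
        assert abs(km.median - np.log(2) * 300.0) / (np.log(2) * 300.0) < 0.10

    def test_monotone_in_unit_interval(self, rng):
        surv = _exp_cohort(rng, 80, censor_frac=0.2)
        km = km_estimate(surv)
        assert (np.diff(km.survival) <= 1e-12).all()
        assert ((km.survival >= 0) & (km.survival <= 1)).all()


class TestWeightedLogrank:
    def test_identical_groups_null(self):
        t = np.tile([5.0, 10.0, 15.0, 20.0], 2)
        e = np.ones(8, int)
        g = np.repeat([0, 1], 4)
        res = weighted_logrank(SurvivalData(t, e), g, rho=1.0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_rho_zero_matches_handcoded_oracle(self, rng):
        t = rng.exponential(10, size=10) + 0.1
        e = rng.integers(0, 2, size=10)
        e[:3] = 1
        g = np.array([0, 1] * 5)
        ours = weighted_logrank(SurvivalData(t, e), g, rho=0.0)
        assert ours.statistic == pytest.approx(standard_logrank_bruteforce(t, e, g), abs=1e-10)

    def test_rho_zero_matches_lifelines(self, rng):
        t = rng.exponential(10, size=30) + 0.1
        e = np.ones(30, int)
        g = rng.integers(0, 2, size=30)
        g[:2] = [0, 1]
        ours = weighted_logrank(SurvivalData(t, e), g, rho=0.0)
        ref = logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two"):
            weighted_logrank(SurvivalData([1.0, 2.0], [1, 1]), np.array([0, 0]))


class TestHarrellCIndex:
    def test_perfect_ordering(self):
        c, _ = harrell_cindex([3.0, 2.0, 1.0], SurvivalData([1.0, 2.0, 3.0], [1, 1, 1]))
        assert c == pytest.approx(1.0)

    def test_null_scores(self, rng):
        surv = _exp_cohort(rng, 500)
        c, _ = harrell_cindex(rng.normal(size=500), surv)
        assert abs(c - 0.5) < 0.05

    def test_six_patient_bruteforce(self, rng):
        t = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        e = np.array([1, 0, 1, 1, 0, 1])
        x = rng.normal(size=6)
        c, (lo, hi) = harrell_cindex(x, SurvivalData(t, e))
        assert c == pytest.approx(harrell_cindex_bruteforce(x, t, e))
        assert 0.0 <= lo <= c <= hi <= 1.0


class TestHazardRatio:
    def test_identical_groups_unity(self):
        t = np.tile([2.0, 4.0, 6.0, 8.0, 10.0], 2)
        e = np.ones(10, int)
        g = np.repeat([0, 1], 5)
        hr, _, _ = hazard_ratio(g, SurvivalData(t, e))
        assert hr == pytest.approx(1.0, abs=0.05)

    def test_rate_ratio_three_recovered(self, rng):
        n = 500
        t0 = rng.exponential(300.0, n)
        t1 = rng.exponential(100.0, n)
        surv = SurvivalData(np.concatenate([t0, t1]) + 1e-3, np.ones(2 * n, int))
        g = np.repeat([0, 1], n)
        hr, (lo, hi), p = hazard_ratio(g, surv)
        assert 2.4 < hr < 3.7
        assert p < 0.001

    def test_label_swap_inverts(self, rng):
        surv = _exp_cohort(rng, 60)
        g = rng.integers(0, 2, size=60)
        g[:2] = [0, 1]
        hr1, _, _ = hazard_ratio(g, surv)
        hr2, _, _ = hazard_ratio(1 - g, surv)
        assert hr1 == pytest.approx(1.0 / hr2, rel=1e-6)


class TestOptimalCutpoint:
    def test_separated_clusters(self, rng):
        n = 40
        scores = np.concatenate([rng.normal(0.0, 0.01, n), rng.normal(1.0, 0.01, n)])
        t = np.concatenate([rng.exponential(500, n), rng.exponential(30, n)]) + 1e-3
        cut = optimal_cutpoint(scores, SurvivalData(t, np.ones(2 * n, int)))
        assert 0.4 < cut < 0.6

    def test_null_finite(self, rng):
        surv = _exp_cohort(rng, 50)
        cut = optimal_cutpoint(rng.normal(size=50), surv)
        assert np.isfinite(cut)

    def test_half_constraint_forces_median(self, rng):
        scores = np.arange(10, dtype=float)
        surv = _exp_cohort(rng, 10)
        cut = optimal_cutpoint(scores, surv, min_group_frac=0.5)
        assert cut == pytest.approx(4.5)

    def test_constant_scores_rejected(self, rng):
        with pytest.raises(ValueError, match="distinct"):
            optimal_cutpoint(np.ones(10), _exp_cohort(rng, 10))


class TestStratify:
    def test_groups_and_km_shapes(self, rng):
        surv = _exp_cohort(rng, 60)
        scores = rng.normal(size=60)
        res = stratify_by_score(scores, surv, cutoff=float(np.median(scores)))
        assert res.n_high + res.n_low == 60
        assert res.km_high.survival[0] <= 1.0
        assert (np.diff(res.km_low.survival) <= 1e-12).all()


class TestCombinedCox:
    def test_single_covariate_consistency(self, rng):
        n = 100
        score = rng.normal(size=n)
        surv = _exp_cohort(rng, n, lp=score)
        cov = pd.DataFrame({"rad_score": score, "age": np.full(n, 55.0), "kps": np.full(n, 80.0)})
        with pytest.warns(UserWarning, match="constant"):
            res = CombinedCoxModel(cov, surv).fit()
        assert res.covariate_names == ["rad_score"]
        c_combined, _ = res.concordance()
        c_score, _ = harrell_cindex(score, surv)
        assert c_combined == pytest.approx(c_score, abs=1e-12)

    def test_combined_not_worse_than_parts(self, rng):
        n = 250
        score = rng.normal(size=n)
        age = rng.normal(size=n)
        surv = _exp_cohort(rng, n, lp=0.8 * score + 0.8 * age)
        cov = pd.DataFrame({"rad_score": score, "age": age})
        res = CombinedCoxModel(cov, surv).fit()
        c_comb, _ = res.concordance()
        c_each = max(
            harrell_cindex(score, surv)[0],
            harrell_cindex(age, surv)[0],
        )
        assert c_comb >= c_each - 0.02

    def test_null_covariate_wald_calibration(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            n = 120
            score = rng.normal(size=n)
            null_cov = rng.normal(size=n)
            surv = _exp_cohort(rng, n, lp=score)
            cov = pd.DataFrame({"rad_score": score, "null": null_cov})
            res = CombinedCoxModel(cov, surv).fit()
            if res.p_values_["null"] > 0.05:
                hits += 1
        assert hits >= 17  # ~19/20 expected at the 5% level

    def test_summary_columns(self, rng):
        n = 80
        score = rng.normal(size=n)
        surv = _exp_cohort(rng, n, lp=score)
        res = CombinedCoxModel(pd.DataFrame({"rad_score": score}), surv).fit()
        s = res.summary()
        assert {"coef", "p"} <= set(s.columns)


class TestSignatureModelSurface:
    def test_fit_score_stratify(self, rng):
        n = 120
        names = [f"f{i}" for i in range(10)]
        X = rng.standard_normal((n, 10))
        surv = _exp_cohort(rng, n, lp=1.2 * X[:, 0])
        model = SignatureModel(pd.DataFrame(X, columns=names), surv)
        res = model.fit(n_folds=5, seed=0, allow_empty=False)
        assert len(res.signature) >= 1
        scores = res.score()
        assert len(scores) == n
        strat = res.stratify()
        assert strat.n_high > 0 and strat.n_low > 0
        assert "Radiomics signature" in res.summary()
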