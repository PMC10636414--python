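"""Subgroup analysis and Knapp-Hartung meta-regression."""

import dataclasses

import numpy as np
import pytest

from mpvmeta import StudyTable, meta_regress, pool_random_dl, subgroup_analysis
from mpvmeta.moderators import _fit_kh

from conftest import make_effects

# Independent oracle: rma(yi, vi, mods=~age, method="REML", test="knha") in
# r-metafor 4.8-0 on the default Hedges effects of the packaged table.
METAFOR_AGE = {"slope": -0.128366, "se": 0.044157, "p": 0.008430,
               "ci": (-0.2202, -0.0365), "tau2": 1.229692}


class TestMetaRegress:
    def test_age_slope_matches_metafor_oracle(self, table24):
        res = meta_regress(table24, "age")
        assert res.k_used == 23  # Mukta has no age data
        assert res.slope() == pytest.approx(METAFOR_AGE["slope"], abs=1e-5)
        assert res.se_kh["age"] == pytest.approx(METAFOR_AGE["se"], abs=1e-5)
        assert res.p["age"] == pytest.approx(METAFOR_AGE["p"], abs=1e-4)
        assert res.ci_low["age"] == pytest.approx(METAFOR_AGE["ci"][0], abs=1e-4)
        assert res.ci_high["age"] == pytest.approx(METAFOR_AGE["ci"][1], abs=1e-4)
        assert res.tau2_resid == pytest.approx(METAFOR_AGE["tau2"], abs=1e-4)

    def test_centering_leaves_slope_inference_unchanged(self, table24):
        res = meta_regress(table24, "age")
        shifted = StudyTable(
            tuple(
                dataclasses.replace(
                    r,
                    age_case=None if r.age_case is None else r.age_case - 35.0,
                )
                for r in table24
            )
        )
        res2 = meta_regress(shifted, "age")
        for attr in ("coefficients", "se_kh", "t", "p"):
            assert getattr(res2, attr)["age"] == pytest.approx(
                getattr(res, attr)["age"], rel=1e-8)
        assert res2.coefficients["intercept"] != pytest.approx(
            res.coefficients["intercept"], abs=1e-3)

    def test_mm_and_reml_agree_on_sign_and_rough_size(self, table24):
        reml = meta_regress(table24, "age", tau2_method="reml")
        mm = meta_regress(table24, "age", tau2_method="mm")
        assert np.sign(reml.slope()) == np.sign(mm.slope())
        assert mm.slope() == pytest.approx(reml.slope(), abs=0.01)

    def test_intercept_only_mm_fit_reproduces_dl_pooling(self, effects24):
        theta = np.array([e.theta for e in effects24])
        v = np.array([e.variance for e in effects24])
        X = np.ones((len(theta), 1))
        fit = _fit_kh(theta, v, X, ["intercept"], tau2_method="mm")
        pooled = pool_random_dl(effects24)
        assert fit.coefficients["intercept"] == pytest.approx(pooled.theta_hat, rel=1e-10)
        assert fit.tau2_resid == pytest.approx(pooled.tau2, rel=1e-10)

    def test_kh_truncation_branches(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0, 1, 12)
        # nearly exact linear signal: residual scatter far below sampling noise -> s2 < 1
        theta = 0.2 + 0.5 * x + rng.normal(0, 0.002, 12)
        v = np.full(12, 0.04)
        X = np.column_stack([np.ones(12), x])
        untrunc = _fit_kh(theta, v, X, ["intercept", "x"], tau2_method="mm", kh="untruncated")
        trunc = _fit_kh(theta, v, X, ["intercept", "x"], tau2_method="mm", kh="truncated")
        assert untrunc.s2 < 1
        assert trunc.se_kh["x"] > untrunc.se_kh["x"]
        # under the method-of-moments tau2 the scale is 1 by construction
        # whenever tau2 is not truncated at zero
        theta2 = 0.2 + 0.5 * x + rng.normal(0, 0.6, 12)
        m2 = _fit_kh(theta2, v, X, ["intercept", "x"], tau2_method="mm", kh="untruncated")
        assert m2.s2 == pytest.approx(1.0)

    def test_kh_coincides_across_variants_when_s2_above_one(self, table24):
        # REML leaves s2 slightly above 1 on the packaged table, so truncation
        # is a no-op there
        u = meta_regress(table24, "age", kh="untruncated")
        t = meta_regress(table24, "age", kh="truncated")
        assert u.s2 > 1
        assert t.se_kh["age"] == pytest.approx(u.se_kh["age"])

    def test_constant_moderator_is_rank_deficient(self, table24):
        same_age = StudyTable(
            tuple(dataclasses.replace(r, age_case=40.0) for r in table24))
        with pytest.raises(ValueError, match="rank-deficient"):
            meta_regress(same_age, "age")

    def test_all_missing_moderator_rejected(self, table24):
        with pytest.raises(ValueError, match="male_ratio"):
            meta_regress(table24, "male_ratio")

    def test_too_few_studies_rejected(self, table24):
        tiny = StudyTable(table24.records[:2])
        with pytest.raises(ValueError, match=">= 3"):
            meta_regress(tiny, "age")


class TestSubgroupAnalysis:
    def test_diagnosis_strata_sizes_and_bipolar_homogeneity(self, table24):
        res = subgroup_analysis(table24, "diagnosis")
        ks = {g: s.k for g, s in res.per_group.items()}
        assert ks == {"depression": 6, "anxiety": 8, "bipolar": 4, "schizophrenia": 6}
        bd = res.per_group["bipolar"]
        assert bd.I2 == 0.0 and bd.tau2 == 0.0
        assert bd.theta_hat == pytest.approx(0.35, abs=0.02)
        assert sum(s.k for s in res.per_group.values()) == 24
        assert res.df1 == 3 and res.df2 == 20

    def test_turkey_versus_other_split(self, table24):
        res = subgroup_analysis(table24, "region_turkey")
        assert res.per_group["Turkey"].k == 16
        assert res.per_group["other"].k == 8

    def test_two_level_f_equals_squared_t_of_indicator(self, table24):
        res = subgroup_analysis(table24, "region_turkey")
        (name,) = res.regression.moderators
        assert res.between_F == pytest.approx(res.regression.t[name] ** 2, rel=1e-9)
        assert res.between_p == pytest.approx(res.regression.p[name], rel=1e-9)

    def test_identical_groups_give_zero_between_f(self):
        from mpvmeta import StudyRecord

        def rec(sid, region):
            return StudyRecord(sid, "anxiety", region, "case-control", "DSM-5",
                               50, 9.5, 1.0, 50, 9.0, 1.0)

        table = StudyTable(tuple(
            rec(f"s{i}{g}", g) for g in ("Turkey", "Egypt") for i in range(3)))
        res = subgroup_analysis(table, "region")
        assert res.between_F == pytest.approx(0.0, abs=1e-12)
        assert res.Q_between == pytest.approx(0.0, abs=1e-9)

    def test_singleton_level_is_rejected_with_its_name(self, table24):
        with pytest.raises(ValueError, match="prospective-cohort"):
            subgroup_analysis(table24, "design")

    def test_unpopulated_grouping_rejected(self, table24):
        with pytest.raises(ValueError, match="apd_recent"):
            subgroup_analysis(table24, "apd_recent")
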