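"""Adaptive ANCOVA: screening, zone classification, fitting, diagnostics."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from ahglm import (
    classify_zone,
    fit_region,
    generate_cohort,
    generate_volumes,
    run_diagnostics,
    screen_covariate,
    screen_interaction,
    whole_brain_spec,
)
from ahglm.model import ZONE_TABLE, ZoneClassification, _screen_decision
from ahglm.simulate import RegionSpec
from ahglm.volumetrics import ROIVolumeTable, SubjectRecord


def _table_from_arrays(gmv, med, age, tiv, region="r"):
    subs = [
        SubjectRecord(f"s{i}", int(m), float(a), "F", float(t))
        for i, (m, a, t) in enumerate(zip(med, age, tiv))
    ]
    return ROIVolumeTable(subjects=subs, regions=[region],
                          volumes=np.asarray(gmv, float)[:, None])


class TestScreenCovariate:
    def test_identical_vectors_pass(self):
        x = np.linspace(1.0, 10.0, 10)
        res = screen_covariate(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.passes

    def test_agrees_with_pearsonr(self, rng):
        for _ in range(50):
            gmv = rng.standard_normal(46)
            cov = rng.standard_normal(46) + 0.3 * gmv
            res = screen_covariate(gmv, cov)
            r, p = stats.pearsonr(gmv, cov)
            assert res.r == pytest.approx(r)
            assert res.p == pytest.approx(p)
            assert res.passes == ((p < 0.05) and (abs(r) > 0.4))

    def test_thresholds_are_strict(self):
        assert not _screen_decision(r=0.4, p=0.001)
        assert not _screen_decision(r=0.9, p=0.05)
        assert _screen_decision(r=0.41, p=0.049)
        assert _screen_decision(r=-0.41, p=0.049)  # |r|, age slopes are negative

    def test_zero_variance_fails_with_flag(self):
        res = screen_covariate(np.ones(10), np.arange(10.0))
        assert not res.passes
        assert "zero-variance" in res.flags

    def test_null_passing_fraction_matches_closed_form(self):
        """Under independence at n=46 the screen is dominated by |r| > 0.4;
        the pass rate must match P(|r| > 0.4) from the exact null law of r^2
        (Beta(1/2, (n-2)/2))."""
        n, reps = 46, 4000
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(reps):
            res = screen_covariate(rng.standard_normal(n), rng.standard_normal(n))
            hits += res.passes
        expected = stats.beta.sf(0.4**2, 0.5, (n - 2) / 2)
        se = np.sqrt(expected * (1 - expected) / reps)
        assert hits / reps == pytest.approx(expected, abs=4 * se)


class TestScreenInteraction:
    def test_null_inclusion_rate_is_nominal(self):
        """With no true interaction the include flag should fire ~5%."""
        rng = np.random.default_rng(7)
        reps, hits = 800, 0
        med = np.repeat([0.0, 1.0], 23)
        for _ in range(reps):
            cov = rng.standard_normal(46)
            gmv = 2.0 * cov + rng.standard_normal(46)
            hits += screen_interaction(gmv, cov, med)[1]
        se = np.sqrt(0.05 * 0.95 / reps)
        assert hits / reps == pytest.approx(0.05, abs=4 * se)

    def test_strong_interaction_detected(self, rng):
        med = np.repeat([0.0, 1.0], 23)
        cov = rng.standard_normal(46)
        # meditator slope differs by 5 residual SDs
        gmv = cov + 5.0 * med * cov + 0.2 * rng.standard_normal(46)
        p, include = screen_interaction(gmv, cov, med)
        assert include and p < 1e-6

    def test_singular_design_excluded_with_warning(self):
        med = np.repeat([0.0, 1.0], 5)
        cov = np.zeros(10)
        with pytest.warns(UserWarning, match="singular"):
            p, include = screen_interaction(np.arange(10.0), cov, med)
        assert not include


def _sr(passes, name="Age"):
    return screen_covariate(
        np.arange(10.0), np.arange(10.0) if passes else np.r_[np.ones(9), 0.0], name
    )


class TestClassifyZone:
    @pytest.mark.parametrize("flags,code", list(ZONE_TABLE.items()))
    def test_decision_table(self, flags, code):
        inc_age, inc_tiv, ix_age, ix_tiv = flags
        zc = classify_zone(
            _sr(inc_age, "Age"),
            _sr(inc_tiv, "TIV"),
            (0.01 if ix_age else 0.5, ix_age) if inc_age else None,
            (0.01 if ix_tiv else 0.5, ix_tiv) if inc_tiv else None,
        )
        assert zc.zone_code == code
        assert (zc.include_age, zc.include_tiv,
                zc.include_med_x_age, zc.include_med_x_tiv) == flags

    def test_interaction_without_covariate_is_error(self):
        with pytest.raises(ValueError, match="failed screening"):
            classify_zone(_sr(False, "Age"), _sr(True, "TIV"), (0.01, True), None)

    def test_zone_code_is_pure_function_of_flags(self):
        assert len(set(ZONE_TABLE.values())) == 9  # all nine cells distinct


def _zone(code, **inc):
    flags = dict(include_age=False, include_tiv=False,
                 include_med_x_age=False, include_med_x_tiv=False)
    flags.update(inc)
    return ZoneClassification(zone_code=code, **flags)


class TestFitRegion:
    def test_zone1_equals_pooled_t_squared(self, rng):
        med = np.repeat([0, 1], 23)
        gmv = 600 + 40 * med + 70 * rng.standard_normal(46)
        table = _table_from_arrays(gmv, med, 40 + np.zeros(46) + rng.random(46),
                                   1500 + rng.standard_normal(46))
        fit = fit_region(table, "r", zone=_zone("1"))
        t, _ = stats.ttest_ind(gmv[med == 1], gmv[med == 0], equal_var=True)
        assert fit.F_med == pytest.approx(t**2, abs=1e-9)
        assert fit.df_error == 44

    def test_df_error_by_zone(self, hemi_table):
        z3a = _zone("3A", include_age=True, include_tiv=True)
        fit = fit_region(hemi_table, "whole_brain", zone=z3a)
        assert fit.df_error == 42  # n=46, 4 parameters
        fit1 = fit_region(hemi_table, "whole_brain", zone=_zone("1"))
        assert fit1.df_error == 44

    def test_coefficients_match_normal_equations(self, rng):
        """OLS solution must equal the brute-force (X'X)^-1 X'y oracle."""
        med = np.repeat([0, 1], 8)
        age = rng.uniform(21, 63, 16)
        tiv = rng.normal(1500, 120, 16)
        gmv = 600 + 30 * med - 2 * (age - age.mean()) + 0.3 * (
            tiv - tiv.mean()) + 20 * rng.standard_normal(16)
        table = _table_from_arrays(gmv, med, age, tiv)
        zone = _zone("3D", include_age=True, include_tiv=True,
                     include_med_x_age=True, include_med_x_tiv=True)
        fit = fit_region(table, "r", zone=zone)
        med_c = med - 0.5
        X = np.column_stack([
            np.ones(16), med_c, age - age.mean(), tiv - tiv.mean(),
            med_c * (age - age.mean()), med_c * (tiv - tiv.mean()),
        ])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ gmv)
        np.testing.assert_allclose(fit.beta, beta_oracle, atol=1e-8)

    def test_partial_f_matches_statsmodels_t_squared(self, hemi_table):
        """Independent cross-check: the 1-df partial F equals the squared
        statsmodels t of the group column in the same design."""
        fit = fit_region(hemi_table, "whole_brain")
        res = sm.OLS(hemi_table.region_values("whole_brain"), fit.design).fit()
        t_med = res.tvalues[fit.terms.index("med")]
        assert fit.F_med == pytest.approx(t_med**2, rel=1e-9)
        assert fit.p_nominal == pytest.approx(res.pvalues[fit.terms.index("med")],
                                              rel=1e-9)

    def test_eta2_identity_on_every_fit(self, lobar_table):
        for region in lobar_table.regions:
            fit = fit_region(lobar_table, region)
            assert fit.eta2_partial == pytest.approx(
                fit.F_med / (fit.F_med + fit.df_error), abs=1e-12
            )
            assert 0 <= fit.eta2_partial < 1
            assert fit.df1 == 1

    def test_nesting_never_increases_ss_error(self, hemi_table):
        zones = [
            _zone("1"),
            _zone("2A", include_tiv=True),
            _zone("3A", include_age=True, include_tiv=True),
            _zone("3D", include_age=True, include_tiv=True,
                  include_med_x_age=True, include_med_x_tiv=True),
        ]
        fits = [fit_region(hemi_table, "whole_brain", zone=z) for z in zones]
        for smaller, larger in zip(fits, fits[1:]):
            assert larger.ss_error <= smaller.ss_error + 1e-9
        assert [f.df_error for f in fits] == [44, 43, 42, 40]

    def test_group_summaries_are_raw(self, hemi_table):
        fit = fit_region(hemi_table, "whole_brain")
        med = hemi_table.covariates["med"].to_numpy()
        gmv = hemi_table.region_values("whole_brain")
        assert fit.group_mean_ctrl == pytest.approx(gmv[med == 0].mean())
        assert fit.group_sd_med == pytest.approx(gmv[med == 1].std(ddof=1))
        expected_rel = (fit.group_mean_med - fit.group_mean_ctrl) * 100 / fit.group_mean_ctrl
        assert fit.relative_diff_pct == pytest.approx(expected_rel)

    def test_too_few_subjects_per_group(self):
        med = np.array([0, 0, 1, 1, 1])
        table = _table_from_arrays(np.arange(5.0) + 1, med,
                                   np.arange(5.0) + 30, np.full(5, 1500.0))
        with pytest.raises(ValueError, match="3 subjects per group"):
            fit_region(table, "r")

    def test_parameter_recovery_bias(self):
        """The fitted group coefficient should be unbiased for the generated
        effect (~42 mL at the 6.9% default) to within 5%."""
        effects = []
        spec = whole_brain_spec()
        true_effect = spec.baseline_ml * spec.effect_pct / 100.0
        for s in range(120):
            cohort = generate_cohort(seed=s)
            tbl = generate_volumes(cohort, [spec], seed=30_000 + s)
            fit = fit_region(tbl, "whole_brain")
            effects.append(fit.beta[fit.terms.index("med")])
        bias = np.mean(effects) - true_effect
        assert abs(bias) < 0.05 * true_effect


class TestDiagnostics:
    def test_outlier_detected(self, rng):
        med = np.repeat([0, 1], 23)
        gmv = 600 + 70 * rng.standard_normal(46)
        gmv[0] += 700  # ~10 SD displacement
        table = _table_from_arrays(gmv, med, rng.uniform(21, 63, 46),
                                   rng.normal(1500, 100, 46))
        fit = fit_region(table, "r", zone=_zone("1"))
        rep = run_diagnostics(fit, table)
        assert rep.n_outliers >= 1
        assert "outliers" in rep.flags

    def test_equal_variances_rarely_flagged(self):
        """Groups generated with equal variance should pass Levene ~95%."""
        hits, reps = 0, 300
        for s in range(reps):
            r = np.random.default_rng(s)
            med = np.repeat([0, 1], 23)
            gmv = 600 + 40 * med + 70 * r.standard_normal(46)
            table = _table_from_arrays(gmv, med, r.uniform(21, 63, 46),
                                       r.normal(1500, 100, 46))
            fit = fit_region(table, "r", zone=_zone("1"))
            rep = run_diagnostics(fit, table)
            hits += rep.levene_p > 0.05
        assert hits / reps > 0.90

    def test_shapiro_p_uniform_under_gaussian_noise(self):
        """On Gaussian data the Shapiro p over repeated draws is ~uniform."""
        ps = []
        for s in range(200):
            r = np.random.default_rng(1000 + s)
            med = np.repeat([0, 1], 23)
            gmv = 600 + 70 * r.standard_normal(46)
            table = _table_from_arrays(gmv, med, r.uniform(21, 63, 46),
                                       r.normal(1500, 100, 46))
            fit = fit_region(table, "r", zone=_zone("1"))
            ps.append(run_diagnostics(fit, table).shapiro_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_slope_homogeneity_reported_for_included_covariates(self, hemi_table):
        fit = fit_region(hemi_table, "whole_brain")
        rep = run_diagnostics(fit, hemi_table)
        included = {"Age"} if fit.zone.include_age else set()
        included |= {"TIV"} if fit.zone.include_tiv else set()
        assert set(rep.slope_homogeneity_p) == included
        for p in rep.slope_homogeneity_p.values():
            assert 0 <= p <= 1

    def test_diagnostics_never_change_fit(self, hemi_table):
        fit = fit_region(hemi_table, "whole_brain")
        before = (fit.F_med, fit.p_nominal, tuple(fit.beta))
        run_diagnostics(fit, hemi_table)
        assert (fit.F_med, fit.p_nominal, tuple(fit.beta)) == before
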