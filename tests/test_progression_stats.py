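import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lordquant.errors import UnderdeterminedError, ValidationError
from lordquant.progression_stats import (
    bonferroni_adjust,
    circle_sqrt_dynamic_range,
    filter_endstage_bcva,
    fit_hinge,
    fit_lmm,
    normalized_rate,
    rm_correlation,
)
from lordquant.synthetic_cohort import HingeParams, hinge_mean

from conftest import hinge_frame


class TestLMM:
    def test_degenerate_equals_ols(self):
        # no random-effect variance: fixed slope must match plain OLS
        rng = np.random.default_rng(0)
        ages = np.tile(np.arange(55.0, 65.0), 4)
        vals = 2.0 + 0.5 * ages + rng.normal(0, 0.3, ages.size)
        df = pd.DataFrame(
            dict(
                patient_id=np.repeat(["A", "B"], 20),
                eye=np.tile(np.repeat(["OD", "OS"], 10), 2),
                age_years=ages,
                value=vals,
            )
        )
        fit = fit_lmm(df)
        ols = np.polyfit(ages, vals, 1)[0]
        assert fit.slope == pytest.approx(ols, abs=1e-6)

    def test_recovers_planted_slope_within_ci(self):
        rng = np.random.default_rng(7)
        params = HingeParams(40.0, 0.53, 0.53, 0.0, 0.5, 0.3, 0.3)  # pure line
        df = hinge_frame(params, rng, n_patients=20, age_lo=55, age_hi=70)
        fit = fit_lmm(df)
        assert fit.slope == pytest.approx(0.53, abs=3 * fit.slope_se)
        assert fit.lrt_p < 1e-6
        assert fit.var_patient > 0

    def test_slope_invariant_to_patient_relabelling(self):
        rng = np.random.default_rng(8)
        df = hinge_frame(HingeParams(50, 0, 1.0, 0, 0.4, 0.2, 0.2), rng, n_patients=8)
        relabelled = df.copy()
        relabelled["patient_id"] = relabelled["patient_id"].map(
            lambda s: f"Z{int(s[1:]) * 13 % 97}"
        )
        assert fit_lmm(relabelled).slope == pytest.approx(fit_lmm(df).slope, abs=1e-8)

    def test_duplicating_rows_uses_model_not_naive_df(self):
        """Duplicating every row must not let the CI machinery behave like
        pooled OLS: the slope stays within its standard error and the SE
        reflects the clustering, staying well above the naive row-count SE."""
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        df = hinge_frame(HingeParams(50, 0, 1.0, 0, 0.4, 0.2, 0.2), rng, n_patients=8)
        doubled = pd.concat([df, df], ignore_index=True)
        base, dup = fit_lmm(df), fit_lmm(doubled)
        assert abs(dup.slope - base.slope) < base.slope_se
        naive = sm.OLS(doubled.value, sm.add_constant(doubled.age_years)).fit()
        assert dup.slope_se > 1.5 * naive.bse["age_years"]

    def test_underdetermined_ages_rejected(self):
        df = pd.DataFrame(
            dict(
                patient_id=["A"] * 4,
                eye=["OD", "OD", "OS", "OS"],
                age_years=[60.0, 61.0, 60.0, 61.0],
                value=[1.0, 2.0, 1.1, 2.1],
            )
        )
        with pytest.raises(UnderdeterminedError):
            fit_lmm(df)

    def test_matches_lme4_reference(self, tmp_path):
        """Cross-check the mixed-model slope against R lme4 on one dataset."""
        rng = np.random.default_rng(10)
        df = hinge_frame(HingeParams(45, 0.3, 0.3, 5.0, 0.6, 0.3, 0.4), rng, n_patients=10)
        df["eye_uid"] = df.patient_id + ":" + df.eye
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                m <- lmer(value ~ age_years + (1|patient_id) + (1|patient_id:eye), d, REML=TRUE)
                cat(sprintf("%.10f", fixef(m)[["age_years"]]))
                """
            )
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        r_slope = float(out.stdout.strip().split()[-1])
        py_slope = fit_lmm(df).slope
        assert py_slope == pytest.approx(r_slope, abs=5e-4)


class TestHinge:
    @pytest.mark.parametrize(
        "psi,post", [(53.9, 0.53), (56.3, 0.24), (50.8, -257.0), (70.3, 0.05)]
    )
    def test_noiseless_breakpoint_recovered_to_grid_step(self, psi, post):
        ages = np.arange(psi - 14, psi + 6, 1.0)
        vals = hinge_mean(HingeParams(psi, 0.0, post, 10.0), ages)
        df = pd.DataFrame(dict(patient_id="P", eye="OD", age_years=ages, value=vals))
        fit = fit_hinge(df, n_boot=0)
        assert fit.psi == pytest.approx(psi, abs=0.1)
        assert fit.pre_slope == pytest.approx(0.0, abs=1e-6)
        assert fit.post_slope == pytest.approx(post, rel=1e-6)

    def test_hinge_rss_never_exceeds_line_rss(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            df = hinge_frame(
                HingeParams(55, 0, rng.uniform(-1, 1), 0, 0.3, 0.2, 0.5), rng, n_patients=6
            )
            fit = fit_hinge(df, n_boot=0)
            assert fit.rss <= fit.rss_line + 1e-8

    def test_pure_line_flagged_collapsed_slopes(self):
        ages = np.arange(40.0, 70.0)
        df = pd.DataFrame(
            dict(patient_id="P", eye="OD", age_years=ages, value=1.0 + 0.2 * ages)
        )
        fit = fit_hinge(df, n_boot=0)
        assert fit.pre_slope == pytest.approx(fit.post_slope, abs=1e-6)

    def test_bootstrap_ci_contains_point_estimate(self):
        rng = np.random.default_rng(12)
        df = hinge_frame(HingeParams(53.9, 0, 0.53, 0, 0.5, 0.3, 0.3), rng)
        fit = fit_hinge(df, n_boot=200, seed=3)
        assert fit.psi_ci[0] <= fit.psi <= fit.psi_ci[1] or fit.boundary

    def test_too_few_distinct_ages_rejected(self):
        df = pd.DataFrame(
            dict(patient_id="P", eye="OD", age_years=[1.0, 2.0, 3.0], value=[1, 2, 3])
        )
        with pytest.raises(UnderdeterminedError):
            fit_hinge(df, n_boot=0)


class TestRmcorr:
    def test_identical_series_give_unit_correlation(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=30)
        df = pd.DataFrame(dict(patient_id=np.repeat(range(5), 6), x=x, y=x))
        assert rm_correlation(df).r == pytest.approx(1.0, abs=1e-9)

    def test_per_subject_offsets_absorbed(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=30)
        subj = np.repeat(range(5), 6)
        offsets = np.array([10, -3, 7, 0, 22])[subj]
        df = pd.DataFrame(dict(patient_id=subj, x=x + offsets, y=x - 2 * offsets))
        assert rm_correlation(df).r == pytest.approx(1.0, abs=1e-9)

    def test_matches_subject_centred_pearson(self):
        # independent closed-form route: Pearson r of subject-centred series
        rng = np.random.default_rng(15)
        subj = np.repeat(range(8), 6)
        df = pd.DataFrame(
            dict(patient_id=subj, x=rng.normal(size=48), y=rng.normal(size=48))
        )
        xc = df.x - df.groupby("patient_id").x.transform("mean")
        yc = df.y - df.groupby("patient_id").y.transform("mean")
        oracle = float(np.corrcoef(xc, yc)[0, 1])
        assert rm_correlation(df).r == pytest.approx(oracle, abs=1e-10)

    def test_single_visit_subjects_dropped_with_warning(self):
        df = pd.DataFrame(
            dict(
                patient_id=[0, 0, 0, 1, 2, 2, 2, 3, 3, 3],
                x=[1.0, 2, 3, 9, 1, 2, 3, 2, 4, 6],
                y=[1.0, 2, 3, 9, 3, 2, 1, 1, 5, 6],
            )
        )
        with pytest.warns(UserWarning, match="single visit"):
            res = rm_correlation(df)
        assert res.n_subjects == 3


class TestRatesAndFilters:
    def test_circle_dynamic_ranges(self):
        assert circle_sqrt_dynamic_range(14.0) == pytest.approx(np.sqrt(np.pi * 49))
        assert circle_sqrt_dynamic_range(6.0) == pytest.approx(np.sqrt(np.pi * 9))

    def test_normalized_rate_arithmetic(self):
        assert normalized_rate(0.53, np.sqrt(np.pi * 49)) == pytest.approx(4.27, abs=0.01)
        assert normalized_rate(0.24, np.sqrt(np.pi * 9)) == pytest.approx(4.51, abs=0.01)
        assert normalized_rate(0.0, 5.0) == 0.0

    def test_nonpositive_range_rejected(self):
        with pytest.raises(ValidationError):
            normalized_rate(1.0, 0.0)

    def test_endstage_rows_removed(self):
        df = pd.DataFrame(dict(value=[0.3, 1.4, 2.6], end_stage=[False, False, True]))
        out = filter_endstage_bcva(df)
        assert out["value"].tolist() == [0.3, 1.4]

    def test_no_endstage_rows_is_identity(self):
        df = pd.DataFrame(dict(value=[0.3, 1.4], end_stage=[False, False]))
        pd.testing.assert_frame_equal(filter_endstage_bcva(df), df)

    def test_all_endstage_warns_and_empties(self):
        df = pd.DataFrame(dict(value=[2.6, 2.9], end_stage=[True, True]))
        with pytest.warns(UserWarning):
            assert filter_endstage_bcva(df).empty

    @pytest.mark.parametrize(
        "p,m,expected", [(0.01, 4, 0.04), (0.5, 4, 1.0), (0.2, 1, 0.2)]
    )
    def test_bonferroni(self, p, m, expected):
        assert bonferroni_adjust(p, m)[0] == pytest.approx(expected)

    def test_bonferroni_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_adjust([1.2], 2)

    @given(
        p=st.floats(min_value=0.0, max_value=1.0),
        m=st.integers(min_value=1, max_value=50),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_bonferroni_properties(self, p, m):
        adj = float(bonferroni_adjust(p, m)[0])
        assert 0.0 <= adj <= 1.0
        assert adj >= min(p, 1.0) - 1e-15  # never anti-conservative
        if m == 1:
            assert adj == pytest.approx(p)
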