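import subprocess

import numpy as np
import pandas as pd
import pytest

from napscape import simulate, stats
from napscape.errors import ParameterError, ValidationError


class TestWinsorize:
    def test_high_outlier_pulled_to_max_plus_unit(self):
        vals = np.array(list(range(1, 21)) + [500], dtype=float)
        adj, log = stats.winsorize(vals, sd_limit=4.0, unit=1.0)
        assert adj[-1] == 21.0
        assert log == [{"index": 20, "original": 500.0, "replaced": 21.0}]
        assert np.array_equal(adj[:-1], vals[:-1])

    def test_no_outliers_identity(self, rng):
        vals = rng.normal(10, 2, 50)
        adj, log = stats.winsorize(vals)
        assert np.array_equal(adj, vals)
        assert log == []

    def test_zero_variance_identity(self):
        adj, log = stats.winsorize(np.zeros(4))
        assert np.array_equal(adj, np.zeros(4)) and log == []

    def test_low_outlier_sign_respected(self):
        vals = np.array(list(range(100, 121)) + [-500], dtype=float)
        adj, _ = stats.winsorize(vals, unit=1.0)
        assert adj[-1] == 99.0  # min of non-outliers minus one unit

    def test_declared_unit_granularity(self):
        vals = np.array(list(range(1, 21)) + [500], dtype=float)
        adj, _ = stats.winsorize(vals, unit=0.1)
        assert adj[-1] == pytest.approx(20.1)

    def test_too_few_values(self):
        with pytest.raises(ParameterError):
            stats.winsorize([1.0, 2.0])


@pytest.fixture(scope="module")
def cohort():
    return simulate.simulate_cohort(simulate.CohortSpec(n_subjects=30, seed=11)).feature_rows


class TestFitLmm:
    def test_matches_lmertest_reference(self, cohort, tmp_path):
        """Estimates, SEs, Satterthwaite df and p-values must agree with R's
        lmerTest (ML fit) on the same data."""
        csv = tmp_path / "d.csv"
        cohort.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            """
suppressMessages(library(lmerTest))
d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
m <- lmer(sw_density ~ condition + reactivity + sex + age
          + condition:reactivity + (1|subject), data=d, REML=FALSE)
co <- summary(m)$coefficients
write.csv(data.frame(term=rownames(co), est=co[,1], se=co[,2], df=co[,3],
                     t=co[,4], p=co[,5]), commandArgs(trailingOnly=TRUE)[2],
          row.names=FALSE)
"""
        )
        out = tmp_path / "ref.csv"
        subprocess.run(
            ["Rscript", "--vanilla", str(rscript), str(csv), str(out)],
            check=True, capture_output=True,
        )
        ref = pd.read_csv(out)
        fit = stats.fit_lmm(cohort, "sw_density", "interaction")
        ours = fit.terms.set_index("term")
        mapping = {
            "(Intercept)": "Intercept",
            "condition": "condition",
            "reactivity": "reactivity",
            "sex": "sex",
            "age": "age",
            "condition:reactivity": "condition:reactivity",
        }
        for rterm, term in mapping.items():
            row = ref[ref.term == rterm].iloc[0]
            assert ours.loc[term, "beta"] == pytest.approx(row.est, rel=1e-4, abs=1e-8)
            assert ours.loc[term, "se"] == pytest.approx(row.se, rel=1e-3)
            assert ours.loc[term, "df"] == pytest.approx(row.df, rel=0.05)
            assert ours.loc[term, "p"] == pytest.approx(row.p, abs=5e-3)

    def test_zero_intercept_variance_collapses_to_ols(self, rng):
        import statsmodels.api as sm

        n = 60
        df = pd.DataFrame(
            {
                "subject": [f"S{i}" for i in range(n)],  # one nap per subject
                "condition": rng.integers(0, 2, n),
                "reactivity": rng.uniform(1.1, 2.8, n),
                "sex": rng.integers(0, 2, n),
                "age": rng.normal(300, 30, n),
            }
        )
        df["y"] = 1.0 + 0.5 * df.condition + rng.normal(0, 1.0, n)
        fit = stats.fit_lmm(df, "y", "base")
        X = np.column_stack(
            [np.ones(n), df.condition, df.reactivity, df.sex, df.age]
        )
        ols = sm.OLS(df.y.to_numpy(), X).fit()
        assert np.allclose(fit.terms.beta.to_numpy(), ols.params, atol=1e-5)

    def test_row_permutation_invariance(self, cohort, rng):
        fit1 = stats.fit_lmm(cohort, "swa", "interaction")
        shuffled = cohort.sample(frac=1.0, random_state=7).reset_index(drop=True)
        fit2 = stats.fit_lmm(shuffled, "swa", "interaction")
        assert np.allclose(
            fit1.terms.beta.to_numpy(), fit2.terms.beta.to_numpy(), rtol=1e-6
        )

    def test_sensitivity_variant_adds_only_autism_likelihood(self, cohort):
        base = stats.fit_lmm(cohort, "sw_density", "base")
        sens = stats.fit_lmm(cohort, "sw_density", "sensitivity_base")
        assert set(sens.terms.term) - set(base.terms.term) == {"autism_likelihood"}

    def test_standardized_and_raw_betas_agree_in_sign(self, cohort):
        # in the base model z-scoring is a pure positive rescaling of each
        # column, so every coefficient keeps its sign; in interaction models
        # the standardized condition effect is evaluated at mean reactivity
        # and may legitimately differ
        fit = stats.fit_lmm(cohort, "spindle_density", "base")
        nonzero = fit.terms[fit.terms.beta.abs() > 1e-8]
        nonzero = nonzero[nonzero.term != "Intercept"]
        assert np.all(np.sign(nonzero.beta) == np.sign(nonzero.beta_std))
        inter = stats.fit_lmm(cohort, "spindle_density", "interaction")
        row = inter.term("condition:reactivity")
        assert np.sign(row["beta"]) == np.sign(row["beta_std"])

    def test_report_combines_base_and_interaction_models(self, cohort):
        rep = stats.lmm_report(cohort, "sigma")
        base = stats.fit_lmm(cohort, "sigma", "base")
        inter = stats.fit_lmm(cohort, "sigma", "interaction")
        cond_row = rep[rep.term == "condition"].iloc[0]
        assert cond_row.beta == base.term("condition")["beta"]
        int_row = rep[rep.term == "condition:reactivity"].iloc[0]
        assert int_row.beta == inter.term("condition:reactivity")["beta"]

    def test_stim_window_models(self, rng):
        subjects = simulate.simulate_cohort(
            simulate.CohortSpec(n_subjects=29, seed=4)
        ).subjects
        rows = simulate.simulate_likelihood_rows(
            rng, subjects, beta_window=0.38, beta_inter=0.0
        )
        fit = stats.fit_lmm(rows, "likelihood", "base", stim_col="stim_window")
        assert fit.term("stim_window")["beta"] == pytest.approx(0.38, abs=0.15)


class TestStageProportionModel:
    def test_zero_rem_naps_handled_and_null_effects_near_zero(self, rng):
        df = simulate.simulate_stage_proportions(
            rng, n_subjects=40,
            stage_logits={"N1": -1.1, "N2": -1.1, "N3": -1.1, "REM": -1.1},
        )
        assert (df.prop == 0).any()  # the zero case exists by design
        fit = stats.fit_stage_proportion_model(df)
        terms = fit.terms.set_index("term")
        for t in ("stageN2", "stageN3", "stageREM"):
            assert abs(terms.loc[t, "beta"]) < 0.4

    def test_planted_n3_shift_recovered(self, rng):
        df = simulate.simulate_stage_proportions(
            rng, n_subjects=40,
            stage_logits={"N1": -1.5, "N2": -1.5, "N3": -0.6, "REM": -1.5},
        )
        df["reactivity"] -= df["reactivity"].mean()
        fit = stats.fit_stage_proportion_model(df)
        beta = fit.terms.set_index("term").loc["stageN3", "beta"]
        assert beta == pytest.approx(0.9, rel=0.25)

    def test_proportions_outside_unit_interval_rejected(self):
        df = pd.DataFrame(
            {"subject": ["a"], "condition": [0], "reactivity": [1.5],
             "stage": ["N1"], "prop": [1.2]}
        )
        with pytest.raises(ValidationError):
            stats.fit_stage_proportion_model(df)
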