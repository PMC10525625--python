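"""Covariate screening and stepwise model building."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from posapk import estimation as est
from posapk.cohort import (CohortSpec, SamplingDesign, generate_covariates,
                           generate_tdm_dataset)
from posapk.covariates import (ScreeningTable, screen_covariates,
                               screen_covariates_conditional, stepwise_build)
from posapk.pk import DosingRegimen
from posapk.population import PopulationParameters


def _fake_ebes(rng, n=64):
    etas = rng.standard_normal((n, 3)) * [0.5, 0.45, 0.36]
    return pd.DataFrame(etas, columns=["eta_ka", "eta_v", "eta_cl"],
                        index=pd.RangeIndex(1, n + 1, name="ID"))


class TestScreening:
    def test_perfect_correlation_flagged(self):
        rng = np.random.default_rng(0)
        ebes = _fake_ebes(rng)
        cov = pd.DataFrame({"proxy": ebes["eta_cl"]}, index=ebes.index)
        table = screen_covariates(ebes, cov)
        assert table.pvalues.loc["proxy", "cl"] < 1e-10
        assert table.flags.loc["proxy", "cl"]

    def test_null_pvalues_uniform(self):
        """An independent covariate yields U(0,1) p-values over repeated
        screens (Kolmogorov-Smirnov at alpha = 0.01)."""
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(1000):
            ebes = _fake_ebes(rng, n=32)
            cov = pd.DataFrame({"noise": rng.standard_normal(32)},
                               index=ebes.index)
            pvals.append(screen_covariates(ebes, cov).pvalues.loc["noise",
                                                                  "cl"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_categorical_uses_group_test(self):
        rng = np.random.default_rng(2)
        ebes = _fake_ebes(rng, n=60)
        grp = np.repeat(["a", "b", "c"], 20)
        shifted = ebes.copy()
        shifted["eta_v"] += np.repeat([0.0, 1.0, 2.0], 20)
        cov = pd.DataFrame({"group": grp}, index=ebes.index)
        table = screen_covariates(shifted, cov)
        assert table.pvalues.loc["group", "v"] < 1e-6
        assert table.pvalues.loc["group", "cl"] > 0.001

    def test_constant_covariate_warns_and_reports_missing(self):
        rng = np.random.default_rng(3)
        ebes = _fake_ebes(rng)
        cov = pd.DataFrame({"flat": np.ones(len(ebes))}, index=ebes.index)
        with pytest.warns(UserWarning, match="constant"):
            table = screen_covariates(ebes, cov)
        assert table.pvalues.loc["flat"].isna().all()

    def test_text_rendering_marks_significance(self):
        rng = np.random.default_rng(4)
        ebes = _fake_ebes(rng)
        cov = pd.DataFrame({"proxy": ebes["eta_cl"],
                            "noise": rng.standard_normal(len(ebes))},
                           index=ebes.index)
        txt = screen_covariates(ebes, cov).to_text()
        assert "proxy" in txt and "*" in txt

    def test_conditional_screen_median_p(self):
        rng = np.random.default_rng(5)
        n = 50
        true_eta = rng.standard_normal((n, 3)) * 0.4
        # conditional samples scattered around the true etas
        cond = true_eta[:, None, :] + 0.05 * rng.standard_normal((n, 40, 3))
        ids = pd.RangeIndex(1, n + 1, name="ID")
        cov = pd.DataFrame({"proxy": true_eta[:, 2]}, index=ids)
        table = screen_covariates_conditional(cond, ids, cov, rng=rng)
        assert table.pvalues.loc["proxy", "cl"] < 1e-6


class TestStepwise:
    def test_age_effect_enters_and_noise_does_not(self, pop_final):
        """On data generated with the age effect, forward selection keeps
        age on clearance and rejects a pure-noise covariate."""
        rng = np.random.default_rng(6)
        cohort = generate_covariates(CohortSpec(n_subjects=100), rng)
        cohort["noise"] = rng.standard_normal(len(cohort))
        design = SamplingDesign(samples_range=(4, 4), samples_mean=4.0,
                                end_day=30)
        ds = generate_tdm_dataset(cohort, design, pop_final,
                                  DosingRegimen(300.0), rng)
        screening = ScreeningTable(pvalues=pd.DataFrame(
            {"ka": [np.nan, np.nan], "v": [np.nan, np.nan],
             "cl": [0.001, 0.04]}, index=["age", "noise"]))
        settings = est.EstimationSettings(n_explore=120, n_smooth=60, seed=7,
                                          ofv_method="none",
                                          compute_rse=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final, trace = stepwise_build(ds, None, pop_final, screening,
                                          settings=settings)
        steps = trace.steps
        age_row = steps[(steps["covariate"] == "age")
                        & (steps["phase"] == "forward")].iloc[0]
        assert age_row["accepted"] and age_row["delta_ofv"] > 3.84
        noise_rows = steps[(steps["covariate"] == "noise")
                           & (steps["phase"] == "forward")]
        assert not noise_rows["accepted"].any()
        assert "age" in final.covariate_model.get("cl", [])
        assert "noise" not in final.covariate_model.get("cl", [])
        # acceptance recorded iff the OFV drop exceeds the criterion
        fwd = steps[steps["phase"] == "forward"]
        assert (fwd["accepted"] == (fwd["delta_ofv"] > 3.84)).all()

    def test_empty_screening_returns_base_model(self, sparse_dataset,
                                                pop_final):
        ds, _ = sparse_dataset
        screening = ScreeningTable(pvalues=pd.DataFrame(
            {"ka": [0.9], "v": [0.8], "cl": [0.7]}, index=["age"]))
        settings = est.EstimationSettings(n_explore=60, n_smooth=30, seed=8,
                                          ofv_method="none",
                                          compute_rse=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final, trace = stepwise_build(ds, None, pop_final, screening,
                                          settings=settings)
        assert len(trace.steps) == 0
        assert final.covariate_model == {}

    def test_spurious_acceptance_rate_under_null(self, pop_final):
        """With no true covariate effect the stepwise procedure rarely
        admits a spurious covariate (well under a 20% bound across
        replicates; nominal is ~5% per tested candidate)."""
        rng = np.random.default_rng(9)
        n_accept = 0
        n_reps = 50
        truth = pop_final.replace(beta_cl_age=0.0)
        design = SamplingDesign(samples_range=(3, 3), samples_mean=3.0,
                                end_day=20)
        settings = est.EstimationSettings(n_explore=60, n_smooth=30,
                                          ofv_method="none",
                                          compute_rse=False)
        for rep in range(n_reps):
            cohort = generate_covariates(CohortSpec(n_subjects=40), rng)
            cohort["noise1"] = rng.standard_normal(len(cohort))
            ds = generate_tdm_dataset(cohort, design, truth,
                                      DosingRegimen(300.0), rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                base = est.fit(ds, init=truth, settings=est.EstimationSettings(
                    **{**settings.__dict__, "seed": rep}))
                screening = screen_covariates(base.ebes, cohort, ["noise1"])
                if not screening.significant():
                    continue
                final, trace = stepwise_build(
                    ds, None, truth, screening,
                    settings=est.EstimationSettings(
                        **{**settings.__dict__, "seed": rep}))
            if trace.steps["accepted"].any():
                n_accept += 1
        assert n_accept / n_reps < 0.20
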