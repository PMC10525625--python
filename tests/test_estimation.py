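"""NLME estimation: likelihood oracles, EBE behaviour, determinism."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from posapk import estimation as est
from posapk.cohort import (CohortSpec, SamplingDesign, TdmDataset,
                           generate_covariates, generate_tdm_dataset)
from posapk.pk import DosingRegimen, StructuralParams, conc_multidose
from posapk.population import PopulationParameters

FAST = est.EstimationSettings(n_explore=100, n_smooth=50, seed=0,
                              ofv_method="none", compute_rse=False)


def _single_subject_dataset(y_values, t_values, dose=300.0, n_doses=5,
                            age=56.0):
    rows = [(1, k * 24.0, 1, dose, np.nan, 0) for k in range(n_doses)]
    rows += [(1, t, 0, np.nan, y, 0) for t, y in zip(t_values, y_values)]
    df = pd.DataFrame(rows, columns=["ID", "TIME", "EVID", "AMT", "DV", "BLQ"])
    df = df.sort_values(["ID", "TIME", "EVID"], ascending=[True, True, False])
    cov = pd.DataFrame({"age": [age]}, index=pd.Index([1], name="ID"))
    return TdmDataset(df=df.reset_index(drop=True), covariates=cov)


class TestNoRandomEffects:
    def test_noise_free_recovery_within_one_percent(self, study_cohort):
        """With no IIV and no residual error the regression path recovers
        the generating fixed effects essentially exactly."""
        truth = PopulationParameters(omega_ka=0, omega_v=0, omega_cl=0,
                                     b_prop=0.0)
        rng = np.random.default_rng(0)
        design = SamplingDesign(samples_range=(6, 6), samples_mean=6.0)
        ds = generate_tdm_dataset(study_cohort, design, truth,
                                  DosingRegimen(300.0), rng)
        init = truth.replace(v_pop=300.0, cl_pop=6.0, b_prop=0.0)
        res = est.fit(ds, covariate_model={"cl": ["age"]}, init=init,
                      settings=FAST)
        assert res.method == "nls"
        assert res.pop.v_pop == pytest.approx(386.35, rel=0.01)
        assert res.pop.cl_pop == pytest.approx(8.8, rel=0.01)
        assert res.pop.beta_cl_age == pytest.approx(-0.009, rel=0.01)

    def test_saem_agrees_with_weighted_nls(self, study_cohort):
        """On data without inter-individual variability, SAEM's fixed
        effects agree with the proportional-error weighted NLS within 1%."""
        truth = PopulationParameters(beta_cl_age=0.0, omega_ka=0, omega_v=0,
                                     omega_cl=0, b_prop=0.10)
        rng = np.random.default_rng(1)
        # window opening just after the peak keeps V well identified
        design = SamplingDesign(samples_range=(8, 8), samples_mean=8.0,
                                window=(5.0, 24.0))
        ds = generate_tdm_dataset(study_cohort, design, truth,
                                  DosingRegimen(300.0), rng)
        nls = est.fit(ds, init=truth, settings=FAST)
        # freeze the omegas at a negligible value so the SAEM machinery
        # maximizes the same (no-IIV) objective as the weighted regression
        saem_init = truth.replace(omega_v=0.01, omega_cl=0.01)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            saem = est.fit(ds, init=saem_init, settings=est.EstimationSettings(
                n_explore=250, n_smooth=250, seed=2, ofv_method="none",
                compute_rse=False,
                freeze=("ka_pop", "omega_ka", "omega_v", "omega_cl")))
        assert saem.method == "saem" and nls.method == "nls"
        assert saem.pop.v_pop == pytest.approx(nls.pop.v_pop, rel=0.01)
        assert saem.pop.cl_pop == pytest.approx(nls.pop.cl_pop, rel=0.01)


class TestOfv:
    def test_closed_form_single_observation(self):
        """With all omegas zero the OFV is the plain Gaussian deviance."""
        p = StructuralParams(0.8, 386.35, 5.316)
        t, y, b = 96.0, 1.9, 0.29
        c = conc_multidose(t, DosingRegimen(300.0, 24.0, n_doses=5), p)
        ds = _single_subject_dataset([y], [t])
        pop = PopulationParameters(cl_pop=5.316, beta_cl_age=0.0,
                                   omega_ka=0, omega_v=0, omega_cl=0,
                                   b_prop=b)
        ofv = est.compute_ofv(ds, pop, method="is", seed=0)
        expected = -2 * stats.norm.logpdf(y, loc=c, scale=b * c)
        assert ofv == pytest.approx(expected, abs=1e-8)

    def test_importance_sampling_matches_quadrature(self):
        """IS marginal likelihood agrees with direct numerical integration
        over a single random effect to within 0.1 OFV points."""
        pop = PopulationParameters(cl_pop=5.316, beta_cl_age=0.0,
                                   omega_ka=0, omega_v=0, omega_cl=0.4,
                                   b_prop=0.25)
        t_obs = [84.0, 108.0]
        base = StructuralParams(0.8, 386.35, 5.316)
        y = [conc_multidose(t, DosingRegimen(300.0, 24.0, n_doses=6), base)
             * f for t, f in zip(t_obs, (1.1, 0.9))]
        ds = _single_subject_dataset(y, t_obs, n_doses=6)

        def integrand(eta):
            p = StructuralParams(0.8, 386.35, 5.316 * np.exp(eta))
            lik = 1.0
            for t, yy in zip(t_obs, y):
                c = conc_multidose(t, DosingRegimen(300.0, 24.0, n_doses=6), p)
                lik *= stats.norm.pdf(yy, loc=c, scale=0.25 * c)
            return lik * stats.norm.pdf(eta, scale=0.4)

        marg, _ = integrate.quad(integrand, -4, 4, epsabs=1e-14)
        oracle = -2 * np.log(marg)
        ofv = est.compute_ofv(ds, pop, method="is", n_is=4000, seed=3)
        assert ofv == pytest.approx(oracle, abs=0.1)
        lap = est.compute_ofv(ds, pop, method="laplace")
        assert lap == pytest.approx(oracle, abs=0.5)

    def test_subject_without_observations_ignored(self, sparse_dataset):
        ds, _ = sparse_dataset
        pop = PopulationParameters()
        ofv_ref = est.compute_ofv(ds, pop, covariate_model={"cl": ["age"]},
                                  method="laplace")
        extra = ds.df[ds.df["EVID"] == 1].copy()
        extra["ID"] = 999
        aug = TdmDataset(
            df=pd.concat([ds.df, extra], ignore_index=True),
            covariates=pd.concat([
                ds.covariates,
                ds.covariates.iloc[[0]].set_axis([999])]),
        )
        with pytest.warns(UserWarning, match="no usable"):
            ofv_aug = est.compute_ofv(aug, pop,
                                      covariate_model={"cl": ["age"]},
                                      method="laplace")
        assert ofv_aug == pytest.approx(ofv_ref, abs=1e-9)

    def test_fit_does_not_worsen_ofv(self, rich_dataset):
        """Descent: OFV at the SAEM estimates is no worse than at the
        (true-parameter) initial values."""
        ds, _ = rich_dataset
        init = PopulationParameters()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = est.fit(ds, covariate_model={"cl": ["age"]}, init=init,
                          settings=FAST)
        ofv_init = est.compute_ofv(ds, init, covariate_model={"cl": ["age"]},
                                   method="laplace")
        ofv_fit = est.compute_ofv(ds, res.pop,
                                  covariate_model={"cl": ["age"]},
                                  coefs=res.coefs, method="laplace")
        assert ofv_fit <= ofv_init + 1e-6


class TestEbes:
    def test_no_observations_gives_prior_mode(self, sparse_dataset):
        ds, _ = sparse_dataset
        extra = ds.df[ds.df["EVID"] == 1].copy()
        extra["ID"] = 999
        aug = TdmDataset(
            df=pd.concat([ds.df, extra], ignore_index=True),
            covariates=pd.concat([
                ds.covariates, ds.covariates.iloc[[0]].set_axis([999])]),
        )
        with pytest.warns(UserWarning, match="no usable"):
            ebes, _ = est.estimate_ebes(aug, PopulationParameters(),
                                        covariate_model={"cl": ["age"]})
        assert (ebes.loc[999] == 0.0).all()

    def test_rich_subject_recovers_clearance_eta(self, study_cohort):
        """With dense low-noise sampling the MAP eta_cl matches the
        generating value closely."""
        pop = PopulationParameters(omega_ka=0, omega_v=0, omega_cl=0.36,
                                   b_prop=0.02)
        rng = np.random.default_rng(4)
        design = SamplingDesign(samples_range=(12, 12), samples_mean=12.0,
                                end_day=30)
        cohort = study_cohort.iloc[:10]
        ds, truth = generate_tdm_dataset(cohort, design, pop,
                                         DosingRegimen(300.0), rng,
                                         return_truth=True)
        ebes, _ = est.estimate_ebes(ds, pop, covariate_model={"cl": ["age"]})
        got = ebes["eta_cl"].to_numpy()
        want = truth["eta_cl"].to_numpy()
        assert np.allclose(got, want, rtol=0.05, atol=0.02)

    def test_sparse_data_shrinks_etas(self, sparse_dataset, pop_final):
        """MAP estimates are smaller in magnitude than the generating etas
        on average (shrinkage toward the prior mode)."""
        ds, truth = sparse_dataset
        ebes, _ = est.estimate_ebes(ds, pop_final,
                                    covariate_model={"cl": ["age"]})
        for d in ("eta_ka", "eta_v", "eta_cl"):
            assert (ebes[d].abs().mean()
                    < truth.loc[ebes.index, d].abs().mean())


def test_seed_determinism(sparse_dataset):
    ds, _ = sparse_dataset
    kw = dict(covariate_model={"cl": ["age"]}, init=PopulationParameters(),
              settings=est.EstimationSettings(n_explore=60, n_smooth=30,
                                              seed=9, ofv_method="laplace",
                                              compute_rse=False))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = est.fit(ds, **kw)
        b = est.fit(ds, **kw)
    assert a.pop.to_dict() == b.pop.to_dict()
    assert a.ofv == b.ofv
    pd.testing.assert_frame_equal(a.ebes, b.ebes)
    pd.testing.assert_frame_equal(a.trace, b.trace)


def test_blq_observations_excluded_with_warning(study_cohort):
    pop = PopulationParameters(cl_pop=500.0, omega_ka=0, omega_v=0,
                               omega_cl=0)
    rng = np.random.default_rng(5)
    ds = generate_tdm_dataset(study_cohort, SamplingDesign(), pop,
                              DosingRegimen(300.0), rng)
    with pytest.raises(ValueError, match="no subjects"):
        # everything is BLQ here, so nothing remains to fit
        with pytest.warns(UserWarning, match="below-LLOQ"):
            est.ModelData(ds, None)
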