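"""Covariate screening and stepwise covariate model building.

Screening tests each candidate covariate against each individual PK
parameter: Pearson's correlation test (two-sided) for continuous
covariates on the log-parameter scale, a one-way ANOVA F test across
levels for categorical ones. Candidates with p < 0.05 then enter a
stepwise likelihood-ratio procedure: forward inclusion in ascending
screening-p order, a candidate being kept iff it drops the objective
function value by more than 3.84 points (chi-square, 1 df, p < 0.05),
followed by a backward elimination pass. No multiple-testing correction is
applied at screening.

On sparse designs the MAP empirical Bayes etas shrink toward zero, which
deflates screening power; when eta-shrinkage exceeds 30% the screen can be
run on conditional-distribution samples instead
(:func:`screen_covariates_conditional`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import estimation as est
from .cohort import TdmDataset
from .population import PopulationParameters

__all__ = [
    "ScreeningTable",
    "StepwiseTrace",
    "screen_covariates",
    "screen_covariates_conditional",
    "stepwise_build",
]

PARAMS = ("ka", "v", "cl")
DELTA_OFV = 3.84  # chi-square(1) critical value at p < 0.05
SHRINKAGE_GUIDELINE = 30.0  # % above which MAP-based screening is unreliable


@dataclass
class ScreeningTable:
    """p-values of covariate-parameter association tests."""

    pvalues: pd.DataFrame  # index: covariate; columns: ka, v, cl
    alpha: float = 0.05

    @property
    def flags(self) -> pd.DataFrame:
        return self.pvalues < self.alpha

    def significant(self) -> list[tuple[str, str, float]]:
        """(covariate, parameter, p) triples with p < alpha, ascending p."""
        out = []
        for cov in self.pvalues.index:
            for par in self.pvalues.columns:
                p = self.pvalues.loc[cov, par]
                if np.isfinite(p) and p < self.alpha:
                    out.append((cov, par, float(p)))
        return sorted(out, key=lambda t: t[2])

    def to_text(self) -> str:
        """Covariate-by-parameter table with significance stars."""
        lines = [f"{'Covariate':<24}" + "".join(f"{c:>10}" for c in
                                                ("Ka", "Vd/F", "CL/F"))]
        for cov in self.pvalues.index:
            cells = []
            for par in self.pvalues.columns:
                p = self.pvalues.loc[cov, par]
                cells.append("       NA " if not np.isfinite(p)
                             else f"{p:9.3f}{'*' if p < self.alpha else ' '}")
            lines.append(f"{cov:<24}" + "".join(cells))
        return "\n".join(lines)


@dataclass
class StepwiseTrace:
    """Record of each stepwise test: (phase, covariate, parameter,
    OFV of the base model, OFV of the extended model, delta, accepted)."""

    steps: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["phase", "covariate", "parameter", "ofv_base",
                 "ofv_extended", "delta_ofv", "accepted"]))

    def append(self, **kw) -> None:
        self.steps.loc[len(self.steps)] = kw


def _test_one(values: np.ndarray, cov: pd.Series) -> float:
    """Two-sided p for one covariate against one log-parameter vector."""
    if cov.nunique() <= 1:
        return np.nan
    if cov.dtype == bool or cov.dtype == object or isinstance(
            cov.dtype, pd.CategoricalDtype):
        groups = [values[(cov == lev).to_numpy()] for lev in cov.unique()]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) < 2:
            return np.nan
        return float(stats.f_oneway(*groups).pvalue)
    return float(stats.pearsonr(cov.to_numpy(float), values).pvalue)


def screen_covariates(
    ebes: pd.DataFrame,
    covariates: pd.DataFrame,
    candidates: list[str] | None = None,
    alpha: float = 0.05,
) -> ScreeningTable:
    """Univariate association screen of covariates against the per-subject
    parameter estimates.

    ``ebes`` carries one row per subject with columns ``eta_ka``, ``eta_v``,
    ``eta_cl`` (log-scale deviations; for a base model these are the
    individual log-parameters up to a constant, so the tests are
    equivalent). Constant covariates yield NaN with a warning.
    """
    candidates = list(covariates.columns) if candidates is None else candidates
    cov = covariates.loc[ebes.index, candidates]
    out = pd.DataFrame(index=candidates, columns=list(PARAMS), dtype=float)
    for c in candidates:
        if cov[c].nunique() <= 1:
            warnings.warn(f"covariate {c!r} is constant; p-value undefined")
        for par in PARAMS:
            out.loc[c, par] = _test_one(ebes[f"eta_{par}"].to_numpy(float),
                                        cov[c])
    return ScreeningTable(pvalues=out, alpha=alpha)


def screen_covariates_conditional(
    cond_samples: np.ndarray,
    ids,
    covariates: pd.DataFrame,
    candidates: list[str] | None = None,
    alpha: float = 0.05,
    n_reps: int = 20,
    rng: np.random.Generator | None = None,
) -> ScreeningTable:
    """Screen on conditional-distribution samples rather than MAP modes.

    Each repetition picks one conditional eta draw per subject and runs the
    univariate screen; the reported p-value per cell is the median over
    repetitions. Appropriate when eta-shrinkage is high (sparse data),
    where MAP estimates cluster at zero and mask true associations.
    """
    rng = rng or np.random.default_rng(0)
    n_subj, n_s, _ = cond_samples.shape
    candidates = list(covariates.columns) if candidates is None else candidates
    tables = []
    for _ in range(min(n_reps, n_s)):
        pick = rng.integers(0, n_s, size=n_subj)
        draw = cond_samples[np.arange(n_subj), pick, :]
        ebes = pd.DataFrame(draw, columns=[f"eta_{p}" for p in PARAMS],
                            index=ids)
        tables.append(screen_covariates(ebes, covariates, candidates,
                                        alpha).pvalues)
    med = pd.concat(tables).groupby(level=0).median().loc[candidates]
    return ScreeningTable(pvalues=med, alpha=alpha)


def _includable(cov: pd.Series) -> bool:
    """Only continuous or binary covariates enter linearly on the log scale."""
    if cov.dtype == object or isinstance(cov.dtype, pd.CategoricalDtype):
        return cov.nunique() <= 2
    return True


def stepwise_build(
    dataset: TdmDataset,
    base_model: dict | None,
    init: PopulationParameters,
    screening: ScreeningTable,
    settings: est.EstimationSettings | None = None,
    delta_ofv: float = DELTA_OFV,
    ofv_method: str = "laplace",
    backward: bool = True,
) -> tuple[est.EstimationResult, StepwiseTrace]:
    """Forward-then-backward stepwise construction of the covariate model.

    Starts from ``base_model`` (a dim -> covariate-list mapping), tests the
    screened candidates in ascending screening-p order, and keeps a
    candidate iff it lowers the OFV by more than ``delta_ofv``. The OFV
    backend defaults to the deterministic Laplace approximation so that
    nested comparisons are free of Monte Carlo noise. A failed refit skips
    the candidate with a warning.
    """
    settings = settings or est.EstimationSettings()
    settings = est.EstimationSettings(**{
        **settings.__dict__, "ofv_method": "none", "compute_rse": False})
    base_model = {k: list(v) for k, v in (base_model or {}).items()}

    def fit_and_ofv(model, warm=None):
        # warm-starting nested refits from the current estimates keeps the
        # two OFVs on a common footing, so their difference is the
        # likelihood-ratio signal rather than run-to-run SAEM noise
        init_i = warm.pop if warm is not None else init
        res = est.fit(dataset, covariate_model=model, init=init_i,
                      settings=settings,
                      init_coefs=warm.coefs if warm is not None else None)
        ofv = est.compute_ofv(dataset, res.pop, covariate_model=model,
                              coefs=res.coefs, method=ofv_method,
                              seed=settings.seed)
        return res, ofv

    base_res, base_ofv = fit_and_ofv(base_model)
    trace = StepwiseTrace()
    included: list[tuple[str, str]] = []

    for cov, par, _p in screening.significant():
        if cov in base_model.get(par, []):
            continue
        if not _includable(dataset.covariates[cov]):
            warnings.warn(f"covariate {cov!r} has >2 levels; screened only, "
                          "not entered in the stepwise model")
            continue
        model = {k: list(v) for k, v in base_model.items()}
        model.setdefault(par, []).append(cov)
        try:
            res, ofv = fit_and_ofv(model, warm=base_res)
        except Exception as e:  # refit failure: skip, keep going
            warnings.warn(f"refit with {cov} on {par} failed ({e}); skipped")
            continue
        delta = base_ofv - ofv
        accepted = delta > delta_ofv
        trace.append(phase="forward", covariate=cov, parameter=par,
                     ofv_base=base_ofv, ofv_extended=ofv, delta_ofv=delta,
                     accepted=accepted)
        if accepted:
            base_model, base_res, base_ofv = model, res, ofv
            included.append((cov, par))

    if backward:
        for cov, par in list(included):
            model = {k: [c for c in v if not (k == par and c == cov)]
                     for k, v in base_model.items()}
            try:
                res, ofv = fit_and_ofv(model, warm=base_res)
            except Exception as e:
                warnings.warn(f"backward refit without {cov} failed ({e})")
                continue
            delta = ofv - base_ofv  # OFV increase caused by removal
            keep = delta > delta_ofv
            trace.append(phase="backward", covariate=cov, parameter=par,
                         ofv_base=base_ofv, ofv_extended=ofv,
                         delta_ofv=delta, accepted=keep)
            if not keep:
                base_model, base_res, base_ofv = model, res, ofv
                included.remove((cov, par))

    return base_res, trace
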