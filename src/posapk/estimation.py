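"""Nonlinear mixed-effects estimation for sparse TDM data.

Maximum-likelihood estimation of the population model by a Stochastic
Approximation EM (SAEM) algorithm: a Metropolis-Hastings kernel samples the
per-subject random effects conditional on the data, stochastic averages of
the complete-data sufficient statistics drive closed-form M-step updates of
the fixed effects (weighted least squares on the log-individual parameters),
random-effect SDs and proportional-error magnitude. The exploratory phase
uses a simulated-annealing floor on the variance components to prevent
premature collapse.

Parameters are log-normally distributed: the sampled quantity for subject i
is phi_i = (log ka_i, log v_i, log cl_i) = X_i @ c + eta_i with a per-
dimension linear covariate design X_i on the log scale and independent
eta ~ N(0, diag(omega^2)).

The objective function value (OFV = -2 marginal log-likelihood) is computed
by per-subject importance sampling around the MAP random effects (Laplace
proposal), with a deterministic Laplace approximation as a fast backend.
Standard errors come from the empirical Fisher information built from
per-subject marginal score vectors (Louis' identity, posterior-sampled).

When every random-effect SD is fixed to zero the marginal model is a plain
proportional-error nonlinear regression and ``fit`` dispatches to
iteratively reweighted least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .cohort import TdmDataset
from .pk import _bateman
from .population import PopulationParameters

__all__ = [
    "EstimationSettings",
    "EstimationResult",
    "fit",
    "compute_ofv",
    "estimate_ebes",
]

DIMS = ("ka", "v", "cl")
_SD_FLOOR = 1e-10  # additive floor on the residual SD (mg/L)
_OMEGA_MIN = 1e-3  # lower bound for estimated omegas (keeps the kernel alive)
# below this omega the random effect is treated as degenerate and the
# intercept is driven by direct observed-data Newton steps
_DIRECT_UPDATE_OMEGA = 0.02


@dataclass(frozen=True)
class EstimationSettings:
    """SAEM run configuration.

    ``n_explore`` iterations use constant step size (gamma=1) with the
    annealing floor; ``n_smooth`` iterations decay the step as 1/k.
    ``freeze`` names population parameters held at their initial value
    (default: the absorption constant, which elimination-phase-only sampling
    cannot inform).
    """

    n_explore: int = 400
    n_smooth: int = 200
    n_kernel: int = 2          # MH sweeps per SAEM iteration
    n_is: int = 1000           # importance-sampling size per subject for OFV
    is_chunk: int = 200
    tol: float = 1e-3          # relative movement defining convergence
    seed: int = 12345
    freeze: tuple = ("ka_pop",)
    anneal_rate: float = 0.95
    ofv_method: str = "is"     # 'is' | 'laplace' | 'none'
    compute_rse: bool = True
    n_score_samples: int = 200  # posterior draws per subject for the FIM

    def __post_init__(self) -> None:
        if min(self.n_explore, self.n_smooth, self.n_kernel, self.n_is) <= 0:
            raise ValueError("iteration counts must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class EstimationResult:
    """Estimates, uncertainties and per-subject empirical Bayes output."""

    pop: PopulationParameters
    coefs: dict                 # dim -> {name: value} on the log scale
    omegas: dict                # dim -> omega
    b_prop: float
    rse: dict                   # natural-scale parameter name -> RSE %
    ofv: float
    ofv_se: float
    ebes: pd.DataFrame          # MAP eta per subject
    shrinkage: dict             # dim -> eta-shrinkage %
    trace: pd.DataFrame
    converged: bool
    method: str
    covariate_model: dict
    settings: EstimationSettings | None = None
    n_obs_used: int = 0


# ---------------------------------------------------------------------------
# model data plumbing

class ModelData:
    """Arrays extracted from a TdmDataset for vectorized likelihood work."""

    def __init__(self, dataset: TdmDataset, covariate_model: dict | None):
        covariate_model = covariate_model or {}
        obs = dataset.observations
        n_blq = int((obs["BLQ"] == 1).sum())
        if n_blq:
            warnings.warn(
                f"excluding {n_blq} below-LLOQ observation(s) from estimation"
            )
            obs = obs[obs["BLQ"] == 0]
        counts = obs.groupby("ID").size()
        empty = [sid for sid in dataset.subject_ids if sid not in counts.index]
        if empty:
            warnings.warn(
                f"dropping {len(empty)} subject(s) with no usable "
                f"observations: {empty[:5]}{'...' if len(empty) > 5 else ''}"
            )
        self.ids = [sid for sid in dataset.subject_ids if sid in counts.index]
        if not self.ids:
            raise ValueError("no subjects with usable observations")
        self.n_subj = len(self.ids)
        idx_of = {sid: i for i, sid in enumerate(self.ids)}
        obs = obs[obs["ID"].isin(idx_of)]
        self.y = obs["DV"].to_numpy(float)
        self.t_obs = obs["TIME"].to_numpy(float)
        self.subj_idx = obs["ID"].map(idx_of).to_numpy(int)
        self.n_obs = len(self.y)
        self.obs_per_subj = np.bincount(self.subj_idx, minlength=self.n_subj)

        doses = dataset.doses
        max_d = max(int(doses[doses["ID"] == sid].shape[0]) for sid in self.ids)
        self.dose_t = np.zeros((self.n_subj, max_d))
        self.dose_amt = np.zeros((self.n_subj, max_d))
        for sid, g in doses.groupby("ID"):
            if sid not in idx_of:
                continue
            i = idx_of[sid]
            k = len(g)
            self.dose_t[i, :k] = g["TIME"].to_numpy(float)
            self.dose_amt[i, :k] = g["AMT"].to_numpy(float)

        # Uniform dose trains (equal amounts, equal spacing) admit an O(1)
        # geometric-accumulation evaluation per observation; precompute the
        # per-observation dose count and time since last dose.
        self.uniform = True
        tau0, amt0 = None, None
        for i in range(self.n_subj):
            amts = self.dose_amt[i][self.dose_amt[i] > 0]
            ts = self.dose_t[i][: len(amts)]
            if len(amts) == 0 or not np.allclose(amts, amts[0]):
                self.uniform = False
                break
            if len(ts) > 1:
                gaps = np.diff(ts)
                if not np.allclose(gaps, gaps[0]):
                    self.uniform = False
                    break
                tau_i = gaps[0]
            else:
                tau_i = None
            if tau0 is None:
                tau0 = tau_i
            elif tau_i is not None and not np.isclose(tau_i, tau0):
                self.uniform = False
                break
        if self.uniform and tau0 is not None:
            self.tau = float(tau0)
            n_doses_subj = (self.dose_amt > 0).sum(axis=1)
            amt_subj = self.dose_amt[np.arange(self.n_subj), 0]
            n_given = np.minimum(
                np.floor(self.t_obs / self.tau).astype(int) + 1,
                n_doses_subj[self.subj_idx],
            )
            self.obs_n_given = n_given
            self.obs_t_last = self.t_obs - (n_given - 1) * self.tau
            self.obs_dose = amt_subj[self.subj_idx]
        else:
            self.uniform = False

        cov = dataset.covariates
        self.X: dict[str, np.ndarray] = {}
        self.coef_names: dict[str, list[str]] = {}
        for d in DIMS:
            names = ["intercept"] + list(covariate_model.get(d, []))
            cols = [np.ones(self.n_subj)]
            for nm in names[1:]:
                vals = cov.loc[self.ids, nm]
                if vals.dtype == bool or vals.dtype == object:
                    vals = pd.factorize(vals)[0]
                cols.append(np.asarray(vals, float))
            self.X[d] = np.column_stack(cols)
            self.coef_names[d] = names

    def predict(self, phi: np.ndarray) -> np.ndarray:
        """Concentrations at the observation times for log-params ``phi``
        of shape (n_subj, 3) or (n_subj, 3, m) for m parameter sets."""
        ka = np.exp(phi[..., 0, :] if phi.ndim == 3 else phi[:, 0])
        v = np.exp(phi[..., 1, :] if phi.ndim == 3 else phi[:, 1])
        cl = np.exp(phi[..., 2, :] if phi.ndim == 3 else phi[:, 2])
        ke = cl / v
        s = self.subj_idx
        if self.uniform:
            ka_o, ke_o, v_o = ka[s], ke[s], v[s]
            # nudge away from the removable ka = ke singularity
            degen = np.abs(ka_o - ke_o) / ke_o < 1e-6
            ka_o = np.where(degen, ke_o * (1.0 + 1e-5), ka_o)
            n, tl, tau = self.obs_n_given, self.obs_t_last, self.tau
            with np.errstate(over="ignore"):
                e_ke, e_ka = np.exp(-ke_o * tau), np.exp(-ka_o * tau)
                acc = (np.exp(-ke_o * tl) * (1 - e_ke**n) / (1 - e_ke)
                       - np.exp(-ka_o * tl) * (1 - e_ka**n) / (1 - e_ka))
            c = self.obs_dose * ka_o / (v_o * (ka_o - ke_o)) * acc
            return np.maximum(np.nan_to_num(c, nan=0.0, posinf=0.0), 0.0)
        tt = self.t_obs[:, None] - self.dose_t[s]          # (n_obs, max_d)
        c = _bateman(np.maximum(tt, 0.0), self.dose_amt[s],
                     ka[s][:, None], v[s][:, None], ke[s][:, None])
        c[tt <= 0] = 0.0
        return c.sum(axis=1)

    def obs_loglik(self, phi: np.ndarray, b: float) -> np.ndarray:
        """Per-subject observation log-likelihood for phi (n_subj, 3)."""
        c = self.predict(phi)
        sd = b * c + _SD_FLOOR
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((self.y - c) / sd) ** 2
        ll = np.where(np.isfinite(ll), ll, -1e30)
        return np.bincount(self.subj_idx, weights=ll, minlength=self.n_subj)

    def resid_sq_sum(self, phi: np.ndarray) -> float:
        """Sum over observations of ((y - c)/c)^2 (for the error M-step)."""
        c = np.maximum(self.predict(phi), 1e-12)
        return float(np.sum(((self.y - c) / c) ** 2))


def _coefs_from_pop(pop: PopulationParameters,
                    covariate_model: dict | None) -> dict:
    """Log-scale coefficient vectors implied by a PopulationParameters."""
    covariate_model = covariate_model or {}
    coefs = {
        "ka": {"intercept": np.log(pop.ka_pop)},
        "v": {"intercept": np.log(pop.v_pop)},
        "cl": {"intercept": np.log(pop.cl_pop)},
    }
    for d, names in covariate_model.items():
        for nm in names:
            if d == "cl" and nm == "age":
                coefs[d][nm] = pop.beta_cl_age
            else:
                coefs[d][nm] = 0.0
    return coefs


def _coef_arrays(md: ModelData, coefs: dict) -> dict:
    return {d: np.array([coefs[d].get(nm, 0.0) for nm in md.coef_names[d]])
            for d in DIMS}


def _pop_from_coefs(coefs: dict, omegas: dict, b: float) -> PopulationParameters:
    return PopulationParameters(
        ka_pop=float(np.exp(coefs["ka"]["intercept"])),
        v_pop=float(np.exp(coefs["v"]["intercept"])),
        cl_pop=float(np.exp(coefs["cl"]["intercept"])),
        beta_cl_age=float(coefs["cl"].get("age", 0.0)),
        omega_ka=omegas["ka"], omega_v=omegas["v"], omega_cl=omegas["cl"],
        b_prop=b,
    )


_FROZEN_MAP = {"ka_pop": ("ka", "intercept"), "v_pop": ("v", "intercept"),
               "cl_pop": ("cl", "intercept"),
               "omega_ka": ("omega", "ka"), "omega_v": ("omega", "v"),
               "omega_cl": ("omega", "cl"), "b_prop": ("error", "b")}


# ---------------------------------------------------------------------------
# SAEM

def fit(
    dataset: TdmDataset,
    covariate_model: dict | None = None,
    init: PopulationParameters | None = None,
    settings: EstimationSettings | None = None,
    init_coefs: dict | None = None,
) -> EstimationResult:
    """Fit the population model to a TDM dataset.

    ``covariate_model`` maps a parameter dimension ('ka', 'v', 'cl') to the
    covariate columns entering linearly on its log scale; the final model is
    ``{'cl': ['age']}``. ``init`` provides starting values and the values of
    frozen parameters; ``init_coefs`` (a dim -> {name: value} mapping, as in
    :attr:`EstimationResult.coefs`) overrides individual starting
    coefficients, which warm-starts nested refits. Random-effect SDs set to
    zero in ``init`` are treated as structurally absent (eta fixed at 0);
    if all three are zero the fit reduces to proportional-error nonlinear
    regression.
    """
    settings = settings or EstimationSettings()
    init = init or PopulationParameters()
    md = ModelData(dataset, covariate_model)
    covariate_model = covariate_model or {}

    omega_init = {"ka": init.omega_ka, "v": init.omega_v, "cl": init.omega_cl}
    active = [d for d in DIMS if omega_init[d] > 0]
    frozen = set(settings.freeze)
    if not active:
        return _fit_nls(md, covariate_model, init, settings, dataset)

    rng = np.random.default_rng(settings.seed)
    cdict = _coefs_from_pop(init, covariate_model)
    if init_coefs:
        for d, vals in init_coefs.items():
            for nm, v in vals.items():
                if nm in cdict[d] or nm == "intercept":
                    cdict[d][nm] = v
    coefs = _coef_arrays(md, cdict)
    omega = np.array([omega_init[d] for d in DIMS])
    b = init.b_prop if init.b_prop > 0 else 0.2
    act = np.array([d in active for d in DIMS])
    frozen_coef = {d: np.zeros(len(md.coef_names[d]), bool) for d in DIMS}
    frozen_om = np.zeros(3, bool)
    freeze_b = "b_prop" in frozen
    for name in frozen:
        kind = _FROZEN_MAP.get(name)
        if kind is None:
            raise ValueError(f"unknown frozen parameter {name!r}")
        if kind[0] in DIMS:
            frozen_coef[kind[0]][0] = True
        elif kind[0] == "omega":
            frozen_om[DIMS.index(kind[1])] = True
    frozen_om |= ~act  # structurally absent dims keep omega = 0

    mu = np.column_stack([md.X[d] @ coefs[d] for d in DIMS])  # (n, 3)
    eta = np.zeros((md.n_subj, 3))
    step = np.where(act, 0.4 * np.maximum(omega, 0.1), 0.0)
    cur_ll = md.obs_loglik(mu + eta, b)

    s_phi = (mu + eta).copy()
    s_phi2 = s_phi**2
    s_r2 = md.resid_sq_sum(mu + eta)
    trace_rows = []
    n_iter = settings.n_explore + settings.n_smooth

    for k in range(1, n_iter + 1):
        # --- E-step: MH sweeps on eta; a prior-independent proposal (which
        # handles the broad/multimodal eta_Ka posteriors that elimination-
        # phase sampling produces) followed by adaptive random walks
        cur_ll = _mh_sweep(md, mu, eta, cur_ll, omega, b, None, act, rng)
        for _ in range(settings.n_kernel):
            cur_ll = _mh_sweep(md, mu, eta, cur_ll, omega, b, step, act, rng)

        # --- stochastic approximation of sufficient statistics
        gamma = 1.0 if k <= settings.n_explore else 1.0 / (k - settings.n_explore)
        phi = mu + eta
        s_phi = (1 - gamma) * s_phi + gamma * phi
        s_phi2 = (1 - gamma) * s_phi2 + gamma * phi**2
        s_r2 = (1 - gamma) * s_r2 + gamma * md.resid_sq_sum(phi)

        # --- M-step
        new_omega2 = omega**2
        for j, d in enumerate(DIMS):
            X = md.X[d]
            fz = frozen_coef[d]
            if not fz.all():
                target = s_phi[:, j] - X[:, fz] @ coefs[d][fz]
                sol, *_ = np.linalg.lstsq(X[:, ~fz], target, rcond=None)
                coefs[d][~fz] = sol
            mu_j = X @ coefs[d]
            if not frozen_om[j]:
                v2 = np.mean(s_phi2[:, j] - 2 * mu_j * s_phi[:, j] + mu_j**2)
                new_omega2[j] = max(v2, _OMEGA_MIN**2)

        # Dimensions whose random effect is degenerate (omega at or near
        # zero) get no information through the phi regression — the eta
        # chain is pinned by the prior. For those, take a damped Newton
        # step on the observed-data likelihood for the intercept: this is
        # the EM update in the degenerate limit.
        for j, d in enumerate(DIMS):
            if frozen_coef[d][0] or omega[j] >= _DIRECT_UPDATE_OMEGA:
                continue
            h = 1e-3
            shift = np.zeros(3)
            lls = []
            for dlt in (-h, 0.0, h):
                shift[j] = dlt
                lls.append(md.obs_loglik(mu + eta + shift, b).sum())
            g = (lls[2] - lls[0]) / (2 * h)
            curv = (lls[2] - 2 * lls[1] + lls[0]) / h**2
            if curv < -1e-8:
                delta = np.clip(g / -curv, -0.2, 0.2)
            else:
                delta = np.clip(np.sign(g) * 0.02, -0.2, 0.2)
            coefs[d][0] += gamma * delta
        if k <= settings.n_explore:  # annealing floor
            new_omega2 = np.maximum(new_omega2,
                                    settings.anneal_rate * omega**2)
        omega = np.where(frozen_om, omega, np.sqrt(new_omega2))
        if not freeze_b:
            b_new2 = s_r2 / md.n_obs
            if k <= settings.n_explore:
                b_new2 = max(b_new2, settings.anneal_rate * b**2)
            b = float(np.sqrt(max(b_new2, 1e-6)))
        mu = np.column_stack([md.X[d] @ coefs[d] for d in DIMS])
        cur_ll = md.obs_loglik(mu + eta, b)

        row = {"iter": k}
        for d in DIMS:
            for nm, val in zip(md.coef_names[d], coefs[d]):
                key = f"{d}_pop" if nm == "intercept" else f"beta_{d}_{nm}"
                row[key] = np.exp(val) if nm == "intercept" else val
        row.update({"omega_ka": omega[0], "omega_v": omega[1],
                    "omega_cl": omega[2], "b_prop": b})
        trace_rows.append(row)

    trace = pd.DataFrame(trace_rows)
    converged = _check_convergence(trace, settings.tol)
    if not converged:
        warnings.warn("SAEM did not meet the convergence tolerance; "
                      "inspect the trace")

    coefs_out = {d: dict(zip(md.coef_names[d], map(float, coefs[d])))
                 for d in DIMS}
    omegas_out = dict(zip(DIMS, map(float, omega)))
    pop = _pop_from_coefs(coefs_out, omegas_out, b)

    ebes, _ = _map_etas(md, coefs, omega, b, act)
    shrink = {}
    for j, d in enumerate(DIMS):
        shrink[d] = (100.0 * (1.0 - ebes[:, j].std(ddof=1) / omega[j])
                     if act[j] and md.n_subj > 1 else np.nan)
    ebes_df = pd.DataFrame(ebes, columns=[f"eta_{d}" for d in DIMS],
                           index=pd.Index(md.ids, name="ID"))

    ofv, ofv_se = np.nan, np.nan
    if settings.ofv_method != "none":
        ofv, ofv_se = _ofv(md, coefs, omega, b, act,
                           method=settings.ofv_method, n_is=settings.n_is,
                           chunk=settings.is_chunk, seed=settings.seed + 1)
    rse = {}
    if settings.compute_rse:
        rse = _rse(md, coefs, omega, b, act, frozen_coef, frozen_om, freeze_b,
                   n_samples=settings.n_score_samples,
                   seed=settings.seed + 2)
    return EstimationResult(
        pop=pop, coefs=coefs_out, omegas=omegas_out, b_prop=float(b), rse=rse,
        ofv=float(ofv), ofv_se=float(ofv_se), ebes=ebes_df, shrinkage=shrink,
        trace=trace, converged=converged, method="saem",
        covariate_model=covariate_model, settings=settings,
        n_obs_used=md.n_obs,
    )


def _check_convergence(trace: pd.DataFrame, tol: float) -> bool:
    if len(trace) < 40:
        return False
    tail = trace.drop(columns="iter").tail(20)
    rel = (tail.max() - tail.min()) / tail.abs().mean().clip(lower=1e-8)
    return bool((rel < 50 * tol).all())


def _fit_nls(md: ModelData, covariate_model, init, settings, dataset):
    """Proportional-error nonlinear regression (no random effects)."""
    coefs = _coef_arrays(md, _coefs_from_pop(init, covariate_model))
    frozen = set(settings.freeze)
    free = []
    for d in DIMS:
        fz = np.zeros(len(md.coef_names[d]), bool)
        fz[0] = f"{d}_pop" in frozen
        free.append(~fz)

    def unpack(theta):
        out, k = {}, 0
        for j, d in enumerate(DIMS):
            c = coefs[d].copy()
            nfree = int(free[j].sum())
            c[free[j]] = theta[k:k + nfree]
            k += nfree
            out[d] = c
        return out

    def resid(theta):
        c = unpack(theta)
        phi = np.column_stack([md.X[d] @ c[d] for d in DIMS])
        pred = np.maximum(md.predict(phi), 1e-12)
        return (md.y - pred) / pred

    theta0 = np.concatenate([coefs[d][free[j]] for j, d in enumerate(DIMS)])
    sol = optimize.least_squares(resid, theta0, method="lm", xtol=1e-12,
                                 ftol=1e-12)
    c = unpack(sol.x)
    r = resid(sol.x)
    b = float(np.sqrt(np.mean(r**2)))
    phi = np.column_stack([md.X[d] @ c[d] for d in DIMS])
    ll = md.obs_loglik(phi, b).sum()
    coefs_out = {d: dict(zip(md.coef_names[d], map(float, c[d])))
                 for d in DIMS}
    omegas_out = {d: 0.0 for d in DIMS}
    pop = _pop_from_coefs(coefs_out, omegas_out, b)
    ebes_df = pd.DataFrame(np.zeros((md.n_subj, 3)),
                           columns=[f"eta_{d}" for d in DIMS],
                           index=pd.Index(md.ids, name="ID"))
    return EstimationResult(
        pop=pop, coefs=coefs_out, omegas=omegas_out, b_prop=b, rse={},
        ofv=float(-2 * ll), ofv_se=0.0, ebes=ebes_df,
        shrinkage={d: np.nan for d in DIMS},
        trace=pd.DataFrame({"iter": [1]}), converged=bool(sol.success),
        method="nls", covariate_model=covariate_model or {},
        settings=settings, n_obs_used=md.n_obs,
    )


def _mh_sweep(md, mu, eta, cur_ll, omega, b, step, act, rng):
    """One Metropolis-Hastings sweep over the active eta dimensions.

    ``step=None`` uses an independent proposal from the prior (the prior
    densities cancel in the acceptance ratio); otherwise an adaptive
    random walk with in-place step adjustment targeting ~30% acceptance.
    """
    for j in range(3):
        if not act[j]:
            continue
        prop = eta.copy()
        if step is None:
            prop[:, j] = omega[j] * rng.standard_normal(md.n_subj)
            d_prior = 0.0
        else:
            prop[:, j] = eta[:, j] + step[j] * rng.standard_normal(md.n_subj)
            d_prior = (eta[:, j] ** 2 - prop[:, j] ** 2) / (2 * omega[j] ** 2)
        new_ll = md.obs_loglik(mu + prop, b)
        accept = np.log(rng.uniform(size=md.n_subj)) < new_ll - cur_ll + d_prior
        eta[accept, j] = prop[accept, j]
        cur_ll = np.where(accept, new_ll, cur_ll)
        if step is not None:
            step[j] = np.clip(
                step[j] * np.exp(0.4 * (accept.mean() - 0.3)), 1e-3, 10.0)
    return cur_ll


# ---------------------------------------------------------------------------
# MAP / OFV / RSE machinery

def _subject_neg_logpost(md: ModelData, i: int, mu_i, omega, b, act_idx):
    """Factory: negative log joint density for subject i over active etas."""
    m = md.subj_idx == i
    y, t = md.y[m], md.t_obs[m]
    dt, da = md.dose_t[i], md.dose_amt[i]

    def f(eta_act):
        eta = np.zeros(3)
        eta[act_idx] = eta_act
        ka, v, cl = np.exp(mu_i + eta)
        tt = t[:, None] - dt[None, :]
        c = _bateman(np.maximum(tt, 0.0), da[None, :], ka, v, cl / v)
        c[tt <= 0] = 0.0
        c = c.sum(axis=1)
        sd = b * c + _SD_FLOOR
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.sum(-np.log(sd) - 0.5 * ((y - c) / sd) ** 2)
        if not np.isfinite(ll):
            return 1e30
        lp = -0.5 * np.sum((eta[act_idx] / omega[act_idx]) ** 2)
        return -(ll + lp)

    return f


def _map_etas(md, coefs, omega, b, act):
    """MAP random effects per subject; returns (etas (n,3), neg-logpost)."""
    act_idx = np.where(act)[0]
    mu = np.column_stack([md.X[d] @ coefs[d] for d in DIMS])
    etas = np.zeros((md.n_subj, 3))
    nlp = np.zeros(md.n_subj)
    for i in range(md.n_subj):
        f = _subject_neg_logpost(md, i, mu[i], omega, b, act_idx)
        if len(act_idx) == 0:
            nlp[i] = f(np.zeros(0))
            continue
        res = optimize.minimize(f, np.zeros(len(act_idx)), method="BFGS",
                                options={"gtol": 1e-7})
        etas[i, act_idx] = res.x
        nlp[i] = res.fun
    return etas, nlp


def _num_hessian(f, x, h=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for a in range(n):
        for c in range(a, n):
            ea, ec = np.zeros(n), np.zeros(n)
            ea[a], ec[c] = h, h
            H[a, c] = H[c, a] = (
                f(x + ea + ec) - f(x + ea) - f(x + ec) + f0
            ) / h**2
    return H


def _ofv(md, coefs, omega, b, act, method="is", n_is=1000, chunk=200,
         seed=0):
    """OFV = -2 log marginal likelihood, with its Monte Carlo SE.

    'is': importance sampling with a per-subject Gaussian proposal centred
    at the MAP eta with Laplace covariance. 'laplace': deterministic
    second-order approximation. Dimensions with omega = 0 are collapsed
    (eta fixed at 0), which integrates them out exactly.
    """
    act_idx = np.where(act)[0]
    n_act = len(act_idx)
    mu = np.column_stack([md.X[d] @ coefs[d] for d in DIMS])
    etas_map, nlp = _map_etas(md, coefs, omega, b, act)
    const = np.sum(-0.5 * np.log(2 * np.pi) * md.obs_per_subj)  # obs normal const
    prior_const = -0.5 * n_act * np.log(2 * np.pi) - np.sum(
        np.log(omega[act_idx])) if n_act else 0.0
    if n_act == 0:
        ll = -(nlp.sum()) + const
        return -2.0 * ll, 0.0

    rng = np.random.default_rng(seed)
    loglik = np.zeros(md.n_subj)
    mcvar = np.zeros(md.n_subj)
    for i in range(md.n_subj):
        f = _subject_neg_logpost(md, i, mu[i], omega, b, act_idx)
        x0 = etas_map[i, act_idx]
        H = _num_hessian(f, x0)
        # regularize to a valid covariance
        w, V = np.linalg.eigh(H)
        w = np.clip(w, 1e-6, None)
        Hinv = (V / w) @ V.T
        if method == "laplace":
            _, logdet = np.linalg.slogdet(Hinv)
            loglik[i] = (-nlp[i] + const * 0 + prior_const
                         + 0.5 * n_act * np.log(2 * np.pi) + 0.5 * logdet)
            continue
        L = np.linalg.cholesky(Hinv)
        logw = np.empty(n_is)
        done = 0
        while done < n_is:
            m = min(chunk, n_is - done)
            z = rng.standard_normal((m, n_act))
            x = x0 + z @ L.T
            # log target (joint, without obs normalization const)
            lt = np.array([-f(xx) for xx in x]) + prior_const
            # log proposal density
            lq = (-0.5 * np.sum(z**2, axis=1)
                  - 0.5 * n_act * np.log(2 * np.pi)
                  - np.sum(np.log(np.diag(L))))
            logw[done:done + m] = lt - lq
            done += m
        mx = np.max(logw)
        wgt = np.exp(logw - mx)
        loglik[i] = mx + np.log(np.mean(wgt))
        mcvar[i] = np.var(wgt) / (n_is * np.mean(wgt) ** 2)
    total_ll = loglik.sum() + const
    se_ll = float(np.sqrt(mcvar.sum()))
    return -2.0 * total_ll, 2.0 * se_ll


def _conditional_samples(md, coefs, omega, b, act, n_samples, seed,
                         thin=5, burn=100):
    """MH samples from each subject's conditional eta distribution.

    Returns array (n_subj, n_samples, 3)."""
    act_idx = np.where(act)[0]
    rng = np.random.default_rng(seed)
    mu = np.column_stack([md.X[d] @ coefs[d] for d in DIMS])
    eta, _ = _map_etas(md, coefs, omega, b, act)
    step = np.where(act, 0.5 * np.maximum(omega, 0.1), 0.0)
    cur_ll = md.obs_loglik(mu + eta, b)
    out = np.zeros((md.n_subj, n_samples, 3))
    total = burn + n_samples * thin
    got = 0
    for it in range(total):
        cur_ll = _mh_sweep(md, mu, eta, cur_ll, omega, b, None, act, rng)
        cur_ll = _mh_sweep(md, mu, eta, cur_ll, omega, b, step, act, rng)
        if it >= burn and (it - burn) % thin == 0:
            out[:, got, :] = eta
            got += 1
    return out


def _rse(md, coefs, omega, b, act, frozen_coef, frozen_om, freeze_b,
         n_samples, seed):
    """RSE (%) per parameter from the empirical Fisher information.

    Per-subject marginal scores are posterior expectations of the complete-
    data score (Louis' identity), estimated from conditional MH samples; the
    FIM is the sum of their outer products. Intercept SEs are reported on
    the natural (exponentiated) scale.
    """
    act_idx = np.where(act)[0]
    samples = _conditional_samples(md, coefs, omega, b, act,
                                   n_samples=n_samples, seed=seed)
    names, blocks = [], []
    for j, d in enumerate(DIMS):
        for ci, nm in enumerate(md.coef_names[d]):
            if frozen_coef[d][ci]:
                continue
            names.append(f"{d}_pop" if nm == "intercept" else f"beta_{d}_{nm}")
            blocks.append(("coef", j, d, ci))
    for j, d in enumerate(DIMS):
        if not frozen_om[j] and act[j]:
            names.append(f"omega_{d}")
            blocks.append(("omega", j, d, None))
    if not freeze_b:
        names.append("b_prop")
        blocks.append(("b", None, None, None))

    mu = np.column_stack([md.X[d] @ coefs[d] for d in DIMS])
    S = np.zeros((md.n_subj, len(blocks)))
    n_s = samples.shape[1]
    # residual score needs predictions per sample
    r2_by_subj = np.zeros((md.n_subj, n_s))
    n_by_subj = md.obs_per_subj.astype(float)
    for m in range(n_s):
        phi = mu + samples[:, m, :]
        c = np.maximum(md.predict(phi), 1e-12)
        r = (md.y - c) / (b * c)
        r2_by_subj[:, m] = np.bincount(md.subj_idx, weights=r**2,
                                       minlength=md.n_subj)
    for kblk, (kind, j, d, ci) in enumerate(blocks):
        if kind == "coef":
            e = samples[:, :, j]  # (n_subj, n_s) eta_j
            x = md.X[d][:, ci]
            S[:, kblk] = (e.mean(axis=1)) / omega[j] ** 2 * x
        elif kind == "omega":
            e2 = (samples[:, :, j] ** 2).mean(axis=1)
            S[:, kblk] = (e2 - omega[j] ** 2) / omega[j] ** 3
        else:  # b
            S[:, kblk] = (r2_by_subj.mean(axis=1) - n_by_subj) / b
    fim = S.T @ S
    try:
        cov = np.linalg.inv(fim)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(fim)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    rse = {}
    for nm, blk, s in zip(names, blocks, se):
        kind, j, d, ci = blk
        if kind == "coef" and ci == 0:
            rse[nm] = 100.0 * s  # SE of log-param = relative SE of param
        else:
            if kind == "omega":
                ref = omega[j]
            elif kind == "b":
                ref = b
            else:
                ref = abs(coefs[d][ci])
            rse[nm] = 100.0 * s / ref if ref > 0 else np.inf
    return rse


# ---------------------------------------------------------------------------
# public OFV / EBE entry points

def compute_ofv(
    dataset: TdmDataset,
    pop: PopulationParameters,
    covariate_model: dict | None = None,
    coefs: dict | None = None,
    method: str = "is",
    n_is: int = 1000,
    seed: int = 0,
    return_se: bool = False,
):
    """Objective function value (-2 log marginal likelihood) at ``pop``.

    Deterministic given ``seed``. ``coefs`` may override the log-scale
    coefficient dictionary for covariate models that
    :class:`PopulationParameters` cannot express.
    """
    md = ModelData(dataset, covariate_model)
    cdict = coefs or _coefs_from_pop(pop, covariate_model)
    carr = _coef_arrays(md, cdict)
    omega = np.array([pop.omega_ka, pop.omega_v, pop.omega_cl])
    act = omega > 0
    ofv, se = _ofv(md, carr, omega, pop.b_prop, act, method=method,
                   n_is=n_is, seed=seed)
    return (ofv, se) if return_se else ofv


def estimate_ebes(
    dataset: TdmDataset,
    pop: PopulationParameters,
    covariate_model: dict | None = None,
    coefs: dict | None = None,
    n_cond_samples: int = 0,
    seed: int = 0,
):
    """MAP empirical Bayes etas per subject (prior mode, i.e. 0, for
    subjects without observations), optionally with conditional-distribution
    MH samples of shape (n_subj, n_cond_samples, 3).
    """
    md = ModelData(dataset, covariate_model)
    cdict = coefs or _coefs_from_pop(pop, covariate_model)
    carr = _coef_arrays(md, cdict)
    omega = np.array([pop.omega_ka, pop.omega_v, pop.omega_cl])
    act = omega > 0
    etas, _ = _map_etas(md, carr, omega, pop.b_prop, act)
    ebes = pd.DataFrame(etas, columns=[f"eta_{d}" for d in DIMS],
                        index=pd.Index(md.ids, name="ID"))
    # subjects dropped for lack of observations sit at the prior mode
    all_ids = dataset.subject_ids
    missing = [sid for sid in all_ids if sid not in set(md.ids)]
    if missing:
        pad = pd.DataFrame(0.0, index=pd.Index(missing, name="ID"),
                           columns=ebes.columns)
        ebes = pd.concat([ebes, pad]).loc[all_ids]
    if n_cond_samples > 0:
        cond = _conditional_samples(md, carr, omega, pop.b_prop, act,
                                    n_samples=n_cond_samples, seed=seed)
        return ebes, cond
    return ebes, None
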