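"""Hierarchical population layer.

Maps population parameters, covariates and per-subject random effects to
individual structural PK parameters, and applies the residual error model.

The final model links individual parameters to the population values on the
log scale:

    log Ka_i   = log Ka_pop              + eta_Ka,i
    log Vd/F_i = log Vd/F_pop            + eta_V,i
    log CL/F_i = log CL/F_pop + beta*age + eta_CL,i

with eta ~ N(0, omega^2) independently per parameter, and a proportional
residual error  y = c_pred * (1 + b * eps),  eps ~ N(0, 1).

The age covariate enters UNCENTERED: ``cl_pop`` is the model intercept at
age 0 and the typical clearance of a 56-year-old is
8.8 * exp(-0.009 * 56) ~= 5.3 L/h. See docs/methods.md for why this reading
is the one consistent with the reported exposure medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .pk import StructuralParams

__all__ = [
    "PopulationParameters",
    "CovariateVector",
    "RandomEffects",
    "IndividualParameters",
    "individual_params",
    "sample_individual",
    "sample_etas",
    "apply_residual_error",
]


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects, covariate coefficient, random-effect SDs and error
    magnitude of the final population model.

    Defaults are the final-model estimates: Ka_pop fixed at 0.8 1/h,
    Vd/F_pop 386.35 L, CL/F_pop 8.8 L/h (intercept at age 0),
    beta_cl_age -0.009 per year on log CL/F, omegas 3.43 / 0.45 / 0.36,
    proportional error 0.29.
    """

    ka_pop: float = 0.8
    v_pop: float = 386.35
    cl_pop: float = 8.8
    beta_cl_age: float = -0.009
    omega_ka: float = 3.43
    omega_v: float = 0.45
    omega_cl: float = 0.36
    b_prop: float = 0.29

    def __post_init__(self) -> None:
        for name in ("ka_pop", "v_pop", "cl_pop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("omega_ka", "omega_v", "omega_cl", "b_prop"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kw) -> "PopulationParameters":
        vals = {f.name: getattr(self, f.name) for f in fields(self)}
        vals.update(kw)
        return PopulationParameters(**vals)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParameters":
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass(frozen=True)
class CovariateVector:
    """One subject's covariates. Only ``age`` enters the final model; the
    remaining fields are the screening candidates."""

    age: float
    sex: str = "M"
    height: float = 170.0
    weight: float = 69.0
    bmi: float = 24.4
    bsa: float = 1.81
    creatinine: float = 110.0
    egfr: float = 0.98
    alt: float = 0.72
    ast: float = 0.35
    ggt: float = 0.63
    cystic_fibrosis: bool = False
    indication: str = "ILD"
    comed_calcineurin: bool = True
    comed_mmf: bool = True
    comed_acid_suppressant: bool = True
    therapy_duration: float = 40.0

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValueError(f"age must be >= 18 (adult cohort), got {self.age!r}")
        for name in ("height", "weight", "bmi", "bsa", "creatinine", "egfr",
                     "alt", "ast", "ggt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class RandomEffects:
    """Per-subject log-scale deviations from the typical parameters."""

    eta_ka: float = 0.0
    eta_v: float = 0.0
    eta_cl: float = 0.0

    def __post_init__(self) -> None:
        for name in ("eta_ka", "eta_v", "eta_cl"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class IndividualParameters(StructuralParams):
    """Realized structural parameters plus their generating covariates and
    random effects."""

    covariates: CovariateVector = field(default=None)  # type: ignore[assignment]
    etas: RandomEffects = field(default_factory=RandomEffects)


def individual_params(
    pop: PopulationParameters,
    cov: CovariateVector,
    eta: RandomEffects = RandomEffects(),
) -> IndividualParameters:
    """Apply the log-scale link equations to obtain one subject's parameters."""
    ka = pop.ka_pop * np.exp(eta.eta_ka)
    v = pop.v_pop * np.exp(eta.eta_v)
    cl = pop.cl_pop * np.exp(pop.beta_cl_age * cov.age + eta.eta_cl)
    return IndividualParameters(ka=ka, v=v, cl=cl, covariates=cov, etas=eta)


def sample_etas(pop: PopulationParameters, n: int,
                rng: np.random.Generator) -> np.ndarray:
    """Draw n independent (eta_ka, eta_v, eta_cl) triples, shape (n, 3)."""
    om = np.array([pop.omega_ka, pop.omega_v, pop.omega_cl])
    return rng.standard_normal((n, 3)) * om


def sample_individual(
    pop: PopulationParameters,
    cov: CovariateVector,
    rng: np.random.Generator,
) -> IndividualParameters:
    """Draw one subject: etas ~ N(0, omega^2) independently per parameter."""
    e = sample_etas(pop, 1, rng)[0]
    return individual_params(pop, cov, RandomEffects(*e))


def apply_residual_error(c_pred, b_prop: float, eps):
    """Proportional residual error: y = c_pred * (1 + b * eps), floored at 0.

    ``c_pred`` and ``eps`` may be scalars or arrays (broadcast together).
    Concentrations are physical quantities, so draws that would go negative
    are truncated to zero.
    """
    c_pred = np.asarray(c_pred, dtype=float)
    if np.any(c_pred < 0):
        raise ValueError("c_pred must be >= 0")
    y = np.maximum(c_pred * (1.0 + b_prop * np.asarray(eps, dtype=float)), 0.0)
    return float(y) if y.ndim == 0 else y
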