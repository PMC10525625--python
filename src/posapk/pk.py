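"""One-compartment oral-absorption kinetics.

Closed-form concentration solutions for a one-compartment disposition model
with first-order absorption and first-order elimination, parametrized by the
apparent (oral) parameters: absorption rate constant ``ka`` (1/h), apparent
volume of distribution ``Vd/F`` (L) and apparent clearance ``CL/F`` (L/h).
Bioavailability F is unidentifiable after oral dosing and is folded into the
apparent parameters throughout.

Units are fixed: time in hours, amounts in mg, concentrations in mg/L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StructuralParams",
    "DosingRegimen",
    "AbsorptionDerivation",
    "conc_single_dose",
    "conc_multidose",
    "ss_trough",
    "ss_auc24",
    "solve_ka",
]

# Relative ka/ke proximity below which the absorption-limited Bateman form
# is replaced by its analytic limit (avoids catastrophic cancellation).
_DEGENERACY_TOL = 1e-6

# ka values above this cap are rejected by solve_ka (t_max -> 0 asymptote).
KA_CAP = 100.0


@dataclass(frozen=True)
class StructuralParams:
    """Individual structural PK parameters.

    Attributes
    ----------
    ka : float
        First-order absorption rate constant (1/h).
    v : float
        Apparent volume of distribution Vd/F (L).
    cl : float
        Apparent clearance CL/F (L/h).
    """

    ka: float
    v: float
    cl: float

    def __post_init__(self) -> None:
        for name in ("ka", "v", "cl"):
            val = getattr(self, name)
            if not np.isfinite(val) or val <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {val!r}")

    @property
    def ke(self) -> float:
        """Elimination rate constant CL/V (1/h)."""
        return self.cl / self.v

    @property
    def t_half(self) -> float:
        """Elimination half-life ln(2)/ke (h)."""
        return np.log(2.0) / self.ke


@dataclass(frozen=True)
class DosingRegimen:
    """Repeated oral dosing: ``dose`` mg every ``tau`` hours.

    ``n_doses=None`` marks steady state (an infinite dosing history).
    """

    dose: float
    tau: float = 24.0
    n_doses: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.dose) or self.dose < 0:
            raise ValueError(f"dose must be finite and >= 0, got {self.dose!r}")
        if not np.isfinite(self.tau) or self.tau <= 0:
            raise ValueError(f"tau must be finite and > 0, got {self.tau!r}")
        if self.n_doses is not None and self.n_doses < 1:
            raise ValueError(f"n_doses must be >= 1 when finite, got {self.n_doses!r}")

    @property
    def at_steady_state(self) -> bool:
        return self.n_doses is None


@dataclass(frozen=True)
class AbsorptionDerivation:
    """Inputs for deriving ka from summary kinetics: half-life and t_max (h)."""

    t_half: float
    t_max: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.t_half) or self.t_half <= 0:
            raise ValueError(f"t_half must be finite and > 0, got {self.t_half!r}")
        if not np.isfinite(self.t_max) or self.t_max <= 0:
            raise ValueError(f"t_max must be finite and > 0, got {self.t_max!r}")


def _bateman(t, dose, ka, v, ke):
    """Vectorized Bateman function; handles the ka ~= ke degeneracy.

    C(t) = D*ka / (V*(ka-ke)) * (exp(-ke t) - exp(-ka t)), with the limit
    D*ka*t*exp(-ka t)/V as ka -> ke.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros(np.broadcast(t, ka, ke).shape)
    pos = t > 0
    if not np.any(pos):
        return out
    ka_b, ke_b, v_b, dose_b = np.broadcast_arrays(
        np.asarray(ka, float), np.asarray(ke, float), np.asarray(v, float),
        np.asarray(dose, float),
    )
    ka_b, ke_b, v_b, dose_b, t_b = np.broadcast_arrays(ka_b, ke_b, v_b, dose_b, t)
    degen = np.abs(ka_b - ke_b) / ke_b < _DEGENERACY_TOL
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        reg = (
            dose_b * ka_b / (v_b * (ka_b - ke_b))
            * (np.exp(-ke_b * t_b) - np.exp(-ka_b * t_b))
        )
        lim = dose_b * ka_b * t_b * np.exp(-ka_b * t_b) / v_b
    vals = np.where(degen, lim, reg)
    out[pos] = vals[pos]
    return out


def conc_single_dose(t, dose: float, p: StructuralParams):
    """Concentration (mg/L) at time ``t`` hours after a single oral dose.

    Solves the two-state linear system (gut depot -> central compartment) in
    closed form. ``t`` may be a scalar or array; times before the dose
    contribute zero.
    """
    t = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError("t must be finite and >= 0")
    if not np.isfinite(dose) or dose < 0:
        raise ValueError(f"dose must be finite and >= 0, got {dose!r}")
    res = _bateman(t, dose, p.ka, p.v, p.ke)
    return float(res) if np.ndim(t) == 0 else res


def _accum_factor(rate, t_since_last, tau, n_doses):
    """exp(-rate*t') * (1 - exp(-n*rate*tau)) / (1 - exp(-rate*tau)).

    Finite (n doses) or infinite (n_doses=None, steady state) geometric
    accumulation of exp(-rate * time-since-dose) over a uniform dose train.
    """
    e_tau = np.exp(-rate * tau)
    if n_doses is None:
        num = 1.0
    else:
        num = 1.0 - e_tau**n_doses
    return np.exp(-rate * t_since_last) * num / (1.0 - e_tau)


def conc_multidose(t, regimen: DosingRegimen, p: StructuralParams):
    """Concentration under repeated dosing (superposition of Bateman terms).

    For a finite number of doses given at 0, tau, 2*tau, ... the value equals
    the sum of :func:`conc_single_dose` over all doses administered at or
    before ``t``; the geometric series is summed in closed form. With
    ``n_doses=None`` the infinite-history (steady-state) accumulation is used
    and ``t`` is interpreted as time within the dosing interval.
    """
    t = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError("t must be finite and >= 0")
    ka, ke, v = p.ka, p.ke, p.v
    tau = regimen.tau
    if regimen.at_steady_state:
        t_in = np.mod(t, tau)
        n_given = None
        t_last = t_in
    else:
        # doses at k*tau for k < n_doses, but only those already given by t
        n_given = np.minimum(np.floor(t / tau).astype(int) + 1, regimen.n_doses)
        t_last = t - (n_given - 1) * tau
    degen = abs(ka - ke) / ke < _DEGENERACY_TOL
    if degen:
        # sum the Bateman limit term dose-by-dose (no simple geometric form)
        if n_given is None:
            n_max = max(100, int(np.ceil(10.0 * p.t_half / tau)))
            k = np.arange(n_max)
            tt = np.expand_dims(t_in, -1) + k * tau  # infinite history
            mask = np.ones_like(tt, dtype=bool)
        else:
            n_max = int(np.max(n_given))
            k = np.arange(n_max)
            tt = np.expand_dims(t, -1) - k * tau
            mask = tt > 0
        tt_pos = np.where(mask, tt, 0.0)
        terms = np.where(
            mask, regimen.dose * ka * tt_pos * np.exp(-ka * tt_pos) / v, 0.0
        )
        res = terms.sum(axis=-1)
    else:
        pref = regimen.dose * ka / (v * (ka - ke))
        res = pref * (
            _accum_factor(ke, t_last, tau, n_given)
            - _accum_factor(ka, t_last, tau, n_given)
        )
    res = np.maximum(res, 0.0)
    return float(res) if np.ndim(t) == 0 else res


def ss_trough(regimen: DosingRegimen, p: StructuralParams) -> float:
    """Steady-state trough: concentration just before the next dose (mg/L).

    Uses the analytic infinite-accumulation factor, i.e. the value of the
    steady-state profile at t = tau.
    """
    if regimen.dose == 0:
        return 0.0
    ss = DosingRegimen(regimen.dose, regimen.tau, None)
    # mod(tau, tau) = 0 would read the instant *after* a dose; evaluate the
    # interval endpoint explicitly.
    ka, ke, v = p.ka, p.ke, p.v
    tau = regimen.tau
    if abs(ka - ke) / ke < _DEGENERACY_TOL:
        return float(conc_multidose(np.array([tau - 1e-9]), ss, p)[0])
    pref = regimen.dose * ka / (v * (ka - ke))
    val = pref * (
        _accum_factor(ke, tau, tau, None) - _accum_factor(ka, tau, tau, None)
    )
    return float(max(val, 0.0))


def ss_trough_vec(dose, tau, ka, v, cl):
    """Vectorized steady-state trough over arrays of individual parameters."""
    dose, ka, v, cl = np.broadcast_arrays(
        np.asarray(dose, float), np.asarray(ka, float),
        np.asarray(v, float), np.asarray(cl, float),
    )
    ke = cl / v
    degen = np.abs(ka - ke) / ke < _DEGENERACY_TOL
    ka_safe = np.where(degen, ke * (1.0 + 1e-5), ka)
    pref = dose * ka_safe / (v * (ka_safe - ke))
    val = pref * (
        np.exp(-ke * tau) / (1.0 - np.exp(-ke * tau))
        - np.exp(-ka_safe * tau) / (1.0 - np.exp(-ka_safe * tau))
    )
    return np.maximum(val, 0.0)


def ss_auc24(dose: float, p: StructuralParams) -> float:
    """Steady-state AUC over one 24-h dosing interval: dose / CL (mg*h/L).

    At steady state the amount absorbed per interval equals the amount
    eliminated, so the interval AUC is exactly dose/CL regardless of ka or V.
    """
    if not np.isfinite(dose) or dose < 0:
        raise ValueError(f"dose must be finite and >= 0, got {dose!r}")
    return dose / p.cl


def tmax_of_ka(ka: float, ke: float) -> float:
    """Time of peak concentration: (ln ka - ln ke) / (ka - ke)."""
    if abs(ka - ke) / ke < _DEGENERACY_TOL:
        return 1.0 / ke
    return (np.log(ka) - np.log(ke)) / (ka - ke)


def solve_ka(d: AbsorptionDerivation, ka_cap: float = KA_CAP) -> float:
    """Invert t_max = (ln ka - ln ke)/(ka - ke) for ka, on the ka > ke branch.

    The peak time decreases monotonically in ka on (ke, inf), from 1/ke down
    to 0, so a unique fast-absorption root exists iff 0 < t_max < 1/ke.
    ``ka_cap`` bounds the search; requesting a t_max so small that ka would
    exceed the cap is an error.

    Raises
    ------
    ValueError
        If no root with ke < ka <= ka_cap exists for the given t_max.
    """
    from scipy.optimize import brentq

    ke = np.log(2.0) / d.t_half
    t_max_upper = 1.0 / ke  # limit as ka -> ke+
    if d.t_max >= t_max_upper:
        raise ValueError(
            f"t_max={d.t_max:.4g} h is not attainable with ka > ke: feasible "
            f"range is (~0, {t_max_upper:.4g}) h for t_half={d.t_half:.4g} h"
        )
    lo = ke * (1.0 + 1e-9)
    if tmax_of_ka(ka_cap, ke) > d.t_max:
        raise ValueError(
            f"t_max={d.t_max:.4g} h requires ka > {ka_cap:.4g} 1/h (cap); "
            f"feasible t_max range at this cap is "
            f"[{tmax_of_ka(ka_cap, ke):.4g}, {t_max_upper:.4g}) h"
        )
    ka = brentq(lambda k: tmax_of_ka(k, ke) - d.t_max, lo, ka_cap,
                xtol=1e-14, rtol=1e-15)
    return float(ka)
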