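"""One-compartment kinetics: closed forms against numerical oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from posapk.pk import (AbsorptionDerivation, DosingRegimen, StructuralParams,
                       conc_multidose, conc_single_dose, solve_ka, ss_auc24,
                       ss_trough, ss_trough_vec, tmax_of_ka)

LLOQ = 0.1


def ode_conc(t_eval, dose, p):
    """Independent oracle: integrate the gut-depot/central ODE system."""

    def rhs(_t, y):
        a_gut, a_cent = y
        return [-p.ka * a_gut, p.ka * a_gut - p.ke * a_cent]

    sol = solve_ivp(rhs, (0.0, max(t_eval) + 1e-9), [dose, 0.0],
                    t_eval=t_eval, rtol=1e-10, atol=1e-12, method="LSODA")
    return sol.y[1] / p.v


def test_no_drug_at_time_zero(typical_56y):
    assert conc_single_dose(0.0, 300.0, typical_56y) == 0.0


def test_single_dose_matches_ode_at_24h(typical_56y):
    """The typical subject's concentration 24 h after one 300 mg dose."""
    t = np.array([24.0])
    expected = ode_conc(t, 300.0, typical_56y)[0]
    got = conc_single_dose(24.0, 300.0, typical_56y)
    assert got == pytest.approx(expected, rel=1e-8)
    assert got == pytest.approx(0.568, abs=0.001)


def test_closed_form_vs_ode_on_random_draws():
    """Bateman solution agrees with ODE integration to <1e-6 relative on
    200 random parameter draws at 20 time points each."""
    rng = np.random.default_rng(0)
    for _ in range(200):
        p = StructuralParams(
            ka=float(rng.uniform(0.05, 5.0)),
            v=float(rng.uniform(50, 800)),
            cl=float(rng.uniform(1, 30)),
        )
        dose = float(rng.uniform(50, 500))
        t = np.sort(rng.uniform(0.5, 96.0, size=20))
        ref = ode_conc(t, dose, p)
        got = conc_single_dose(t, dose, p)
        rel = np.abs(got - ref) / np.maximum(ref, LLOQ)
        assert rel.max() < 1e-6


def test_absorption_elimination_degeneracy():
    """At ka = ke the Bateman form collapses to D*ka*t*exp(-ka t)/V."""
    p_eq = StructuralParams(ka=0.1, v=100.0, cl=10.0)  # ke = 0.1 = ka
    got = conc_single_dose(10.0, 100.0, p_eq)
    assert got == pytest.approx(100 * 0.1 * 10 * np.exp(-1.0) / 100, rel=1e-9)
    assert got == pytest.approx(0.3679, abs=1e-4)
    # continuous with the nearby regular branch
    p_near = StructuralParams(ka=0.1 + 1e-8, v=100.0, cl=10.0)
    assert conc_single_dose(10.0, 100.0, p_near) == pytest.approx(got, rel=1e-6)


def test_input_validation(typical_56y):
    with pytest.raises(ValueError):
        conc_single_dose(-1.0, 300.0, typical_56y)
    with pytest.raises(ValueError):
        conc_single_dose(1.0, -5.0, typical_56y)
    with pytest.raises(ValueError):
        StructuralParams(ka=0.0, v=100.0, cl=5.0)
    with pytest.raises(ValueError):
        StructuralParams(ka=np.inf, v=100.0, cl=5.0)
    with pytest.raises(ValueError):
        DosingRegimen(dose=300.0, tau=0.0)


def test_multidose_superposition(typical_56y):
    """Multidose closed form equals the explicit dose-by-dose sum."""
    reg = DosingRegimen(300.0, 24.0, n_doses=7)
    t = np.linspace(0.5, 7 * 24.0, 37)
    naive = sum(conc_single_dose(np.maximum(t - k * 24.0, 0.0), 300.0,
                                 typical_56y) for k in range(7))
    got = conc_multidose(t, reg, typical_56y)
    assert np.allclose(got, naive, rtol=1e-10)
    # a single dose reduces to the single-dose solution
    one = DosingRegimen(300.0, 24.0, n_doses=1)
    assert conc_multidose(18.0, one, typical_56y) == pytest.approx(
        conc_single_dose(18.0, 300.0, typical_56y), rel=1e-12)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(ka=st.floats(0.05, 5.0), v=st.floats(50.0, 800.0),
       cl=st.floats(1.0, 30.0), dose=st.floats(0.0, 500.0),
       alpha=st.floats(0.0, 4.0))
def test_dose_linearity_and_auc_identity_property(ka, v, cl, dose, alpha):
    """Superposition linearity and the AUC-clearance identity hold for
    arbitrary parameter combinations."""
    p = StructuralParams(ka=ka, v=v, cl=cl)
    t = np.linspace(0.5, 48.0, 7)
    base = conc_single_dose(t, dose, p)
    scaled = conc_single_dose(t, alpha * dose, p)
    assert np.allclose(scaled, alpha * base, rtol=1e-9, atol=1e-12)
    assert ss_auc24(dose, p) * p.cl == pytest.approx(dose, rel=1e-12,
                                                     abs=1e-9)


def test_linearity_in_dose(typical_56y):
    t = np.linspace(1, 72, 10)
    reg1 = DosingRegimen(150.0, 24.0, n_doses=3)
    reg2 = DosingRegimen(300.0, 24.0, n_doses=3)
    assert np.allclose(2 * conc_multidose(t, reg1, typical_56y),
                       conc_multidose(t, reg2, typical_56y), rtol=1e-12)


def test_steady_state_trough(typical_56y):
    """Analytic accumulation matches a 100-dose truncated superposition and
    reproduces the typical-subject trough of ~2.02 mg/L at 300 mg daily."""
    reg = DosingRegimen(300.0, 24.0)
    got = ss_trough(reg, typical_56y)
    trunc = conc_multidose(100 * 24.0 - 1e-9,
                           DosingRegimen(300.0, 24.0, n_doses=100),
                           typical_56y)
    assert 100 * 24.0 > 10 * typical_56y.t_half
    assert got == pytest.approx(trunc, rel=1e-6)
    assert got == pytest.approx(2.02, abs=0.01)


def test_trough_limits_and_monotonicity(typical_56y):
    assert ss_trough(DosingRegimen(0.0, 24.0), typical_56y) == 0.0
    washout = StructuralParams(ka=0.8, v=386.35, cl=1000.0)
    assert ss_trough(DosingRegimen(300.0, 24.0), washout) < 0.01
    rng = np.random.default_rng(3)
    for _ in range(20):
        v = float(rng.uniform(100, 600))
        cl = float(rng.uniform(2, 12))
        lo = ss_trough(DosingRegimen(300.0), StructuralParams(0.8, v, cl))
        hi_dose = ss_trough(DosingRegimen(400.0), StructuralParams(0.8, v, cl))
        hi_cl = ss_trough(DosingRegimen(300.0),
                          StructuralParams(0.8, v, cl * 1.5))
        assert hi_dose > lo > hi_cl


def test_trough_vectorized_matches_scalar(typical_56y):
    rng = np.random.default_rng(4)
    ka = rng.uniform(0.05, 3, 50)
    v = rng.uniform(100, 600, 50)
    cl = rng.uniform(2, 12, 50)
    vec = ss_trough_vec(300.0, 24.0, ka, v, cl)
    for i in range(50):
        s = ss_trough(DosingRegimen(300.0),
                      StructuralParams(ka[i], v[i], cl[i]))
        assert vec[i] == pytest.approx(s, rel=1e-9)


def test_ss_auc24_closed_form():
    assert ss_auc24(300.0, StructuralParams(0.8, 386.35, 6.0)) == 50.0
    assert ss_auc24(200.0, StructuralParams(0.8, 386.35, 5.0)) == 40.0
    # independent of ka and v
    rng = np.random.default_rng(5)
    for _ in range(20):
        p = StructuralParams(float(rng.uniform(0.1, 3)),
                             float(rng.uniform(50, 700)), 7.0)
        assert ss_auc24(280.0, p) == 280.0 / 7.0


def test_auc_times_clearance_equals_dose():
    rng = np.random.default_rng(6)
    for _ in range(50):
        p = StructuralParams(float(rng.uniform(0.1, 3)),
                             float(rng.uniform(50, 700)),
                             float(rng.uniform(1, 20)))
        dose = float(rng.uniform(50, 500))
        assert ss_auc24(dose, p) * p.cl == pytest.approx(dose, rel=1e-12)


class TestSolveKa:
    def test_published_fixed_value_from_smpc_kinetics(self):
        """Half-life 26-31 h with the matching peak time gives ka = 0.80."""
        assert solve_ka(AbsorptionDerivation(30.0, 4.5626)) == pytest.approx(
            0.80, abs=0.005)
        assert solve_ka(AbsorptionDerivation(26.0, 4.3984)) == pytest.approx(
            0.80, abs=0.005)

    def test_round_trip_reproduces_tmax(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            t_half = float(rng.uniform(5, 60))
            ke = np.log(2) / t_half
            ka_true = float(rng.uniform(ke * 1.5, 50.0))
            t_max = tmax_of_ka(ka_true, ke)
            ka = solve_ka(AbsorptionDerivation(t_half, t_max))
            assert tmax_of_ka(ka, ke) == pytest.approx(t_max, rel=1e-8)
            assert ka == pytest.approx(ka_true, rel=1e-6)

    def test_infeasible_tmax_raises_with_range(self):
        # above the ka->ke limit 1/ke there is no fast-absorption root
        with pytest.raises(ValueError, match="feasible"):
            solve_ka(AbsorptionDerivation(t_half=30.0, t_max=50.0))

    def test_tiny_tmax_exceeds_cap(self):
        with pytest.raises(ValueError, match="cap"):
            solve_ka(AbsorptionDerivation(t_half=30.0, t_max=0.01))
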