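import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from equipopk.structural_pk import (
    ConcentrationProfile,
    DegenerateDispositionError,
    DoseEvent,
    MicroConstants,
    PKParameters,
    Regimen,
    disposition_exponents,
    micro_constants,
    secondary_parameters,
    simulate_profile,
    to_base_dose,
    to_salt_dose,
)
from oracles import ode_profile, random_parameters

positive = st.floats(min_value=0.05, max_value=20.0)


@pytest.mark.parametrize(
    "amount,salt,expected",
    [
        (20.0, "sulfate_dihydrate", 16.58),
        (5.0, "hydrochloride_monohydrate", 4.28),
        (22.0, "sulfate_dihydrate", 18.24),
        (0.0, "base", 0.0),
    ],
)
def test_salt_to_base_conversion(amount, salt, expected):
    assert to_base_dose(amount, salt) == pytest.approx(expected, abs=0.005)


@given(amount=positive, salt=st.sampled_from(
    ["sulfate_dihydrate", "hydrochloride_monohydrate", "base"]))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_salt_conversion_round_trips(amount, salt):
    assert to_salt_dose(to_base_dose(amount, salt), salt) == pytest.approx(
        amount, rel=1e-14)


def test_unknown_salt_rejected():
    with pytest.raises(ValueError, match="unknown salt"):
        to_base_dose(10.0, "gluconate")


def test_micro_constants_from_typical_values(table1):
    p, _, _ = table1
    m = micro_constants(p)
    assert m.k10 == pytest.approx(0.49 / 0.63)
    assert m.k31 == pytest.approx(2.44 / 3.68)
    unit = PKParameters(V1=1, V2=1, V3=1, CL=1, CL2=1, CL3=1, Kabs=1, F=1)
    mu = micro_constants(unit)
    assert [mu.k10, mu.k12, mu.k21, mu.k13, mu.k31] == [1.0] * 5


def test_parameter_validation():
    with pytest.raises(ValueError):
        PKParameters(V1=-1, V2=1, V3=1, CL=1, CL2=1, CL3=1, Kabs=1, F=0.5)
    with pytest.raises(ValueError, match="F"):
        PKParameters(V1=1, V2=1, V3=1, CL=1, CL2=1, CL3=1, Kabs=1, F=1.2)


def test_disposition_half_lives_match_published_table(table1):
    """The three eigen-rates reproduce the published half-lives at 2 dp."""
    p, _, _ = table1
    ex = disposition_exponents(micro_constants(p))
    assert math.log(2) / ex.gamma == pytest.approx(7.76, abs=0.005)
    assert math.log(2) / ex.beta == pytest.approx(0.31, abs=0.005)
    assert round(math.log(2) / ex.alpha, 2) == 0.06


def test_one_compartment_collapse():
    p = PKParameters(V1=0.63, V2=0.59, V3=3.68, CL=0.49, CL2=0.0, CL3=0.0,
                     Kabs=1.0, F=0.5)
    ex = disposition_exponents(micro_constants(p))
    assert len(ex.exponents) == 1
    assert ex.terminal_rate == pytest.approx(0.49 / 0.63)


def test_repeated_roots_reported():
    # vanishing exchange makes the two fast rates coincide at k10 = k21
    m = MicroConstants(k10=1.0, k12=1e-18, k21=1.0, k13=0.0, k31=0.0, ka=1.0)
    with pytest.raises(DegenerateDispositionError):
        disposition_exponents(m)


@given(seed=st.integers(min_value=0, max_value=10_000))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_disposition_cubic_identities(seed):
    """Eigen-rates satisfy the trace and determinant identities of the rate matrix."""
    p = random_parameters(np.random.default_rng(seed))
    m = micro_constants(p)
    ex = disposition_exponents(m)
    lam = ex.exponents
    assert lam.sum() == pytest.approx(
        m.k10 + m.k12 + m.k21 + m.k13 + m.k31, rel=1e-10)
    assert np.prod(lam) == pytest.approx(m.k10 * m.k21 * m.k31, rel=1e-10)
    assert ex.terminal_rate < min(m.k10, m.k31) + 1e-12
    assert ex.coefficients.sum() == pytest.approx(1.0, rel=1e-10)


def test_secondary_parameters(table1):
    p, _, _ = table1
    sec = secondary_parameters(p)
    assert sec["Vss"] == pytest.approx(4.90, abs=1e-12)
    assert sec["t_half_abs"] == pytest.approx(0.69, abs=0.005)
    assert sec["t_half_gamma"] == pytest.approx(7.76, abs=0.005)
    # printed MRT (10.12 h) comes from unrounded bootstrap medians
    assert sec["MRT"] == pytest.approx(10.12, rel=0.02)


def test_empty_regimen_gives_zero_profile(table1):
    p, _, _ = table1
    prof = simulate_profile(p, Regimen(events=()), np.linspace(0, 24, 50))
    assert np.all(prof.concentrations == 0)


def test_iv_bolus_limit(table1):
    """As t -> 0+, a bolus concentration approaches dose/V1."""
    p, _, _ = table1
    reg = Regimen(events=(DoseEvent(0.0, 4.28, "IV", "base", 0.0),))
    c0 = simulate_profile(p, reg, np.array([1e-9])).concentrations[0]
    assert c0 == pytest.approx(4.28 / p.V1, rel=1e-6)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_analytic_matches_ode_oracle(seed):
    p = random_parameters(np.random.default_rng(seed))
    reg = Regimen(events=(
        DoseEvent(0.0, 5.0, "IV", "hydrochloride_monohydrate", 5 / 60),
        DoseEvent(3.0, 20.0, "PO", "sulfate_dihydrate"),
        DoseEvent(9.0, 10.0, "PO", "sulfate_dihydrate"),
    ))
    times = np.linspace(0.02, 30, 60)
    a = simulate_profile(p, reg, times).concentrations
    b = ode_profile(p, reg, times)
    assert np.max(np.abs(a - b) / np.maximum(b, 1e-9)) < 1e-6


def test_dose_linearity_and_superposition(table1):
    p, _, _ = table1
    times = np.linspace(0.1, 36, 100)
    d1 = Regimen(events=(DoseEvent(0.0, 20.0, "PO", "sulfate_dihydrate"),))
    d2 = Regimen(events=(DoseEvent(6.0, 10.0, "PO", "sulfate_dihydrate"),))
    both = Regimen(events=d1.events + d2.events)
    c1 = simulate_profile(p, d1, times).concentrations
    c2 = simulate_profile(p, d2, times).concentrations
    c_both = simulate_profile(p, both, times).concentrations
    np.testing.assert_allclose(c_both, c1 + c2, rtol=1e-10)
    c_scaled = simulate_profile(p, d1.scaled(3.0), times).concentrations
    np.testing.assert_allclose(c_scaled, 3.0 * c1, rtol=1e-12)


@pytest.mark.parametrize(
    "route,salt,amount",
    [("PO", "sulfate_dihydrate", 20.0), ("IV", "hydrochloride_monohydrate", 5.0)],
)
def test_auc_equals_bioavailable_dose_over_clearance(table1, route, salt, amount):
    p, _, _ = table1
    reg = Regimen(events=(DoseEvent(0.0, amount, route, salt),))
    auc, _ = quad(
        lambda t: float(simulate_profile(p, reg, np.array([t])).concentrations[0]),
        1e-9, 600.0, limit=400,
    )
    d_base = to_base_dose(amount, salt)
    expected = (p.F if route == "PO" else 1.0) * d_base / p.CL
    assert auc == pytest.approx(expected, rel=1e-4)


def test_mass_balance_total_elimination(table1):
    """Integral of CL*C1 over all time equals the bioavailable dose."""
    p, _, _ = table1
    reg = Regimen(events=(DoseEvent(0.0, 20.0, "PO", "sulfate_dihydrate"),))
    eliminated, _ = quad(
        lambda t: p.CL
        * float(simulate_profile(p, reg, np.array([t])).concentrations[0]),
        1e-9, 600.0, limit=400,
    )
    assert eliminated == pytest.approx(
        p.F * to_base_dose(20.0, "sulfate_dihydrate"), rel=1e-4)


def test_terminal_slope_is_gamma(table1):
    p, _, _ = table1
    reg = Regimen(events=(DoseEvent(0.0, 20.0, "PO", "sulfate_dihydrate"),))
    times = np.linspace(24.0, 48.0, 30)
    conc = simulate_profile(p, reg, times).concentrations
    slope = np.polyfit(times, np.log(conc), 1)[0]
    assert math.log(2) / -slope == pytest.approx(7.76, abs=0.05)


def test_absorption_rate_equal_to_exponent_is_stable(table1):
    """ka coinciding with a disposition exponent uses the smooth limit form."""
    p, _, _ = table1
    ex = disposition_exponents(micro_constants(p))
    times = np.linspace(0.1, 24, 50)
    reg = Regimen(events=(DoseEvent(0.0, 20.0, "PO", "sulfate_dihydrate"),))
    exact_ka = PKParameters(**{**{n: getattr(p, n) for n in p.parameter_names()},
                               "Kabs": ex.beta})
    nearby = PKParameters(**{**{n: getattr(p, n) for n in p.parameter_names()},
                             "Kabs": ex.beta * (1 + 1e-6)})
    c_exact = simulate_profile(exact_ka, reg, times).concentrations
    c_near = simulate_profile(nearby, reg, times).concentrations
    assert np.all(np.isfinite(c_exact))
    np.testing.assert_allclose(c_exact, c_near, rtol=1e-4)


def test_profile_validation():
    with pytest.raises(ValueError):
        ConcentrationProfile(times=np.array([0.0, 0.0, 1.0]),
                             concentrations=np.zeros(3))
    with pytest.raises(ValueError):
        DoseEvent(time=0.0, amount=10.0, route="PO", infusion_duration=0.5)
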