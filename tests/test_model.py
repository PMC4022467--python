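"""Core dynamics: conservation, linear-system oracle, steady states and
residence-time arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.linalg import expm

from lymphkin import (
    ModelParameters,
    ParameterError,
    mean_residence_time,
    residence_time_distribution,
    simulate,
    steady_state,
)
from lymphkin.model import state_labels

from conftest import random_parameters

TIMES = np.array([1.0, 5.0, 30.0, 120.0, 720.0, 1440.0])


def oracle_states(params: ModelParameters, times: np.ndarray) -> np.ndarray:
    """Independent matrix-exponential solution of the same linear system.

    The rate matrix is assembled here from an explicit list of flows,
    independently of the package's own matrix builder, and propagated with
    the matrix exponential.  Valid only for the time-invariant system.
    """
    k = params.k
    labels = state_labels(k)
    ix = {name: i for i, name in enumerate(labels)}
    s, m = params.entry_rates, params.exit_rates
    f, mu, phi = params.thoracic_fraction, params.removal_rate, params.dying_fraction
    cann = params.cannulation_mode

    flows = [
        ("blood", "lung", s["lung"]),
        ("blood", "liver_live", s["liver"]),
        ("blood", "spleen", s["spleen"]),
        ("blood", "liver_dead", phi * mu),
        ("blood", "removed", (1 - phi) * mu),
        ("lung", "blood", m["lung"]),
        ("liver_live", "blood", m["liver"]),
        ("spleen", "blood", m["spleen"]),
    ]
    for organ in ("scln", "mln", "pp"):
        flows.append(("blood", f"{organ}_1", s[organ]))
        for stage in range(1, k):
            flows.append((f"{organ}_{stage}", f"{organ}_{stage + 1}", m[organ]))
    flows.append((f"pp_{k}", "mln_1", m["pp"]))
    if cann:
        flows.append((f"mln_{k}", "duct_collected", m["mln"]))
        flows.append((f"scln_{k}", "duct_collected", f * m["scln"]))
        flows.append((f"scln_{k}", "blood", (1 - f) * m["scln"]))
    else:
        flows.append((f"mln_{k}", "blood", m["mln"]))
        flows.append((f"scln_{k}", "blood", m["scln"]))

    A = np.zeros((len(labels), len(labels)))
    for src, dst, rate in flows:
        A[ix[dst], ix[src]] += rate
        A[ix[src], ix[src]] -= rate
    y0 = np.zeros(len(labels))
    y0[ix["blood"]] = 100.0
    return np.stack([expm(A * t) @ y0 for t in times])


def test_no_flow_identity():
    """With no exits from the blood, the bolus stays there forever."""
    params = ModelParameters(
        entry_rates=dict.fromkeys(("lung", "liver", "spleen", "scln", "mln", "pp"), 0.0),
        exit_rates=dict.fromkeys(("lung", "liver", "spleen", "scln", "mln", "pp"), 1.0),
        removal_rate=0.0,
    )
    traj = simulate(params, TIMES)
    assert np.allclose(traj.observable("blood"), 100.0, atol=1e-9)
    for organ in ("lung", "liver", "spleen", "scln", "mln", "pp"):
        assert np.allclose(traj.observable(organ), 0.0, atol=1e-9)


@pytest.mark.parametrize("method", ["expm", "lsoda"])
def test_mass_conservation_random_parameters(method):
    """Total accounted label stays at the injected 100% to 1e-6."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        params = random_parameters(rng)
        traj = simulate(params, TIMES, method=method)
        assert np.all(traj.states >= -1e-9)
        np.testing.assert_allclose(traj.total, 100.0, atol=1e-6)


rates = st.floats(min_value=1e-3, max_value=3.0, allow_nan=False)
fractions = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    s_lung=rates, s_spleen=rates, s_ln=rates, m_fast=rates, m_ln=rates,
    phi=fractions, f=fractions, k=st.integers(min_value=1, max_value=3),
    cannulation=st.booleans(),
)
def test_conservation_property(s_lung, s_spleen, s_ln, m_fast, m_ln, phi, f, k,
                               cannulation):
    """Label conservation holds for arbitrary valid parameter combinations,
    with or without cannulation harvesting."""
    params = ModelParameters(
        entry_rates={"lung": s_lung, "liver": s_lung, "spleen": s_spleen,
                     "scln": s_ln, "mln": s_ln, "pp": s_ln},
        exit_rates={"lung": m_fast, "liver": m_fast, "spleen": m_ln,
                    "scln": m_ln, "mln": m_ln, "pp": m_ln},
        removal_rate=0.003,
        dying_fraction=phi,
        thoracic_fraction=f,
        n_subcompartments=k,
        cannulation_mode=cannulation,
    )
    traj = simulate(params, np.array([1.0, 60.0, 1440.0]))
    np.testing.assert_allclose(traj.total, 100.0, atol=1e-6)


def test_cannulation_conservation_with_decline():
    """Conservation also holds in the time-varying cannulation system."""
    rng = np.random.default_rng(7)
    for _ in range(5):
        params = random_parameters(rng).replace(
            cannulation_mode=True, exit_decline_rate=6e-4
        )
        traj = simulate(params, TIMES)
        np.testing.assert_allclose(traj.total, 100.0, atol=1e-6)
        assert np.all(np.diff(traj.duct_collected) >= -1e-9)


@pytest.mark.parametrize("cannulation", [False, True])
def test_matrix_exponential_oracle(cannulation):
    """The ODE integration matches an independently assembled linear-algebra
    solution to 1e-8 relative error."""
    rng = np.random.default_rng(2024)
    times = np.sort(rng.uniform(0.5, 2000.0, size=20))
    for _ in range(5):
        params = random_parameters(rng, k=2).replace(cannulation_mode=cannulation)
        traj = simulate(params, times, method="lsoda")
        expected = oracle_states(params, times)
        np.testing.assert_allclose(traj.states, expected, rtol=1e-8, atol=1e-8)


def test_linearity_in_bolus_size():
    """Halving the injected bolus halves every compartment at every time."""
    rng = np.random.default_rng(3)
    params = random_parameters(rng)
    full = simulate(params, TIMES, initial_blood=100.0)
    half = simulate(params, TIMES, initial_blood=50.0)
    np.testing.assert_allclose(half.states, 0.5 * full.states, rtol=1e-9, atol=1e-12)


def test_steady_state_matches_long_run_simulation():
    """Closed-form balance equals the normalized trajectory at t = 1e6 min
    within 0.1 percentage points, over 100 random draws."""
    rng = np.random.default_rng(11)
    for _ in range(100):
        params = random_parameters(rng).replace(removal_rate=0.0, dying_fraction=0.0)
        ss = steady_state(params)
        traj = simulate(params, np.array([1e6]), method="expm")
        organs = ("blood", "lung", "liver", "spleen", "scln", "mln", "pp")
        longrun = {o: float(traj.observable(o)[-1]) for o in organs}
        total = sum(longrun.values())
        for organ in organs:
            assert abs(ss[organ] - 100.0 * longrun[organ] / total) < 0.1


def test_steady_state_no_entries_is_all_blood():
    params = ModelParameters(
        entry_rates=dict.fromkeys(("lung", "liver", "spleen", "scln", "mln", "pp"), 0.0),
        exit_rates=dict.fromkeys(("lung", "liver", "spleen", "scln", "mln", "pp"), 1.0),
    )
    ss = steady_state(params)
    assert ss["blood"] == pytest.approx(100.0)


def test_mean_residence_time_arithmetic(ref_params):
    """Reciprocal for single compartments, k/m for chains, additive chain
    scaling, and the reference blood transit of ~26 seconds."""
    assert mean_residence_time(ref_params.replace(n_subcompartments=1), "spleen") == \
        pytest.approx(1 / 0.007)
    k1 = ref_params.replace(n_subcompartments=1)
    k3 = ref_params.replace(n_subcompartments=3)
    assert mean_residence_time(k3, "scln") == pytest.approx(
        3 * mean_residence_time(k1, "scln")
    )
    blood_seconds = 60.0 * mean_residence_time(ref_params, "blood")
    assert blood_seconds == pytest.approx(26.0, abs=1.0)


def test_chain_residence_time_monte_carlo_oracle():
    """k/m equals the mean first-passage time through a k-stage chain of
    exponential stages, estimated by direct stochastic simulation."""
    m, k = 0.01, 3
    params = ModelParameters(
        entry_rates={"lung": 0.1, "liver": 0.1, "spleen": 0.01,
                     "scln": 0.01, "mln": 0.01, "pp": 0.01},
        exit_rates={"lung": 1.0, "liver": 1.0, "spleen": 0.01,
                    "scln": m, "mln": m, "pp": m},
        n_subcompartments=k,
    )
    rng = np.random.default_rng(99)
    passage = rng.exponential(scale=1.0 / m, size=(10**5, k)).sum(axis=1)
    assert mean_residence_time(params, "scln") == pytest.approx(
        passage.mean(), rel=0.02
    )


def test_residence_time_distribution(ref_params):
    """Exponential for k = 1 (mode at zero), gamma mode at (k-1)/m for
    chains, and unit total mass."""
    t = np.linspace(0.0, 5000.0, 2001)
    dens1 = residence_time_distribution(ref_params.replace(n_subcompartments=1), "scln", t)
    assert np.argmax(dens1) == 0

    k2 = ref_params  # k = 2, m = 0.0034
    dens2 = residence_time_distribution(k2, "scln", t)
    mode = t[np.argmax(dens2)]
    assert mode == pytest.approx((2 - 1) / 0.0034, abs=t[1] - t[0])

    mass, _ = quad(
        lambda x: residence_time_distribution(k2, "scln", np.array([x]))[0],
        0.0, np.inf,
    )
    assert mass == pytest.approx(1.0, abs=1e-6)


def test_liver_observable_includes_dead_cells(ref_params):
    traj = simulate(ref_params, TIMES)
    np.testing.assert_allclose(
        traj.observable("liver"), traj.pool("liver_live") + traj.pool("liver_dead")
    )
    assert traj.pool("liver_dead")[-1] > 0  # removal deposits dead cells


def test_validation_errors(ref_params):
    with pytest.raises(ValueError):
        simulate(ref_params, np.array([-1.0, 5.0]))
    with pytest.raises(ValueError):
        simulate(ref_params, np.array([5.0, 1.0]))
    with pytest.raises(ParameterError):
        ref_params.with_rates(entry={"lung": -1.0})
    with pytest.raises(ParameterError):
        ref_params.with_rates(entry={"lung": 1.0}, exit={"lung": 0.0})
    with pytest.raises(ParameterError):
        ref_params.replace(n_subcompartments=0)
    with pytest.raises(ParameterError):
        ref_params.replace(dying_fraction=1.5)
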