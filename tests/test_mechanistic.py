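"""Mechanistic simulator: closed forms, dilution events, conservation."""

import numpy as np
import pytest

from medlv import (
    CommunityConfig,
    DilutionPolicy,
    MediatorSpec,
    SpeciesSpec,
    build_rhs,
    phase_trace,
    read_trajectory,
    simulate,
    steady_state,
    write_trajectory,
)
from medlv.analytic import SingleMediatorParams

from conftest import single_mediator_config


def test_reusable_mediator_matches_closed_form(reusable_config):
    """With exponential production and no consumption,
    C1(t) = (beta/r10) S10 (exp(r10 t) - 1)."""
    cfg = reusable_config
    d = cfg.to_dict()
    d["dilution"] = {"mode": "none"}
    cfg = CommunityConfig.from_dict(d)
    traj = simulate(cfg, 10.0)
    beta, r10, s10 = 1e-4, 0.3, 5e6
    expected = (beta / r10) * s10 * (np.exp(r10 * traj.times) - 1.0)
    assert np.allclose(traj.mediator("C1"), expected, rtol=1e-6, atol=1e-3)


def test_unlinked_species_grow_exponentially():
    cfg = CommunityConfig(
        species=[SpeciesSpec("A", 0.4), SpeciesSpec("B", -0.2)],
        initial_densities={"A": 1e5, "B": 1e5},
        dilution=DilutionPolicy("none"),
    )
    traj = simulate(cfg, 8.0)
    assert np.allclose(traj.density("A"), 1e5 * np.exp(0.4 * traj.times), rtol=1e-6)
    assert np.allclose(traj.density("B"), 1e5 * np.exp(-0.2 * traj.times), rtol=1e-6)


def test_coexistence_steady_state_is_stationary(case2_config):
    """At (C1*, RS*) both species grow at the same rate and the mediator
    balance vanishes: dC1/dt = 0 and d(S2/S1)/dt = 0."""
    p = SingleMediatorParams.from_config(case2_config)
    c1_star, rs_star = steady_state(p)
    rhs = build_rhs(case2_config)
    s1 = 1e7
    y = np.array([s1, rs_star * s1, c1_star])
    dy = rhs(0.0, y)
    g1 = dy[0] / y[0]
    g2 = dy[1] / y[1]
    assert g1 == pytest.approx(g2, rel=1e-12)
    assert abs(dy[2]) < 1e-9 * p.betaC1S1 * s1


def test_turbidostat_interval_approaches_doubling_time():
    cfg = CommunityConfig(
        species=[SpeciesSpec("A", 0.5)],
        initial_densities={"A": 1e7},
        dilution=DilutionPolicy("turbidostat", threshold=1e8, reset_total=1e7),
    )
    traj = simulate(cfg, 60.0)
    gaps = np.diff(traj.dilution_times)
    assert np.allclose(gaps, np.log(10.0) / 0.5, rtol=1e-6)


def test_reusable_conservation_along_trajectory(reusable_config):
    """Without consumption, dC/dt - beta*S1 vanishes pointwise."""
    rhs = build_rhs(reusable_config)
    traj = simulate(reusable_config, 40.0)
    for i in range(0, len(traj.times), 200):
        y = np.array([traj.species[0][i], traj.species[1][i], traj.mediators[0][i]])
        dy = rhs(traj.times[i], y)
        assert dy[2] == pytest.approx(1e-4 * y[0], rel=1e-12)


def test_ratio_equation_identity(case2_config):
    """d(RS)/dt from the integrated trajectory matches
    (r20 + rS2C1 C1/(C1+K) - r10) RS pointwise."""
    p = SingleMediatorParams.from_config(case2_config)
    traj = simulate(case2_config, 30.0)
    t = traj.times
    rs = traj.density("S2") / traj.density("S1")
    c1 = traj.mediator("C1")
    # midpoints within one growth segment (avoid dilution kinks)
    mask = (t > 1.0) & (t < traj.dilution_times[0] - 0.1)
    idx = np.where(mask)[0][::10]
    drs = np.gradient(rs[mask], t[mask])[::10]
    pred = (p.r20 + p.rS2C1 * c1[idx] / (c1[idx] + p.KS2C1) - p.r10) * rs[idx]
    good = np.abs(pred) > 1e-6
    assert np.allclose(drs[good], pred[good], rtol=0.05)


def test_solver_refinement_leaves_terminal_fractions_unchanged():
    for cfg in (single_mediator_config(),
                single_mediator_config(r10=0.3, r20=0.1, rsc=0.3, KS2C1=1e4,
                                       beta=1e-4, kind="reusable",
                                       s1_0=5e6, s2_0=5e6,
                                       dilution=DilutionPolicy(
                                           "turbidostat", threshold=1e8,
                                           reset_total=1e7))):
        a = simulate(cfg, 60.0, rtol=1e-8, atol=1e-10)
        b = simulate(cfg, 60.0, rtol=5e-9, atol=5e-11)
        fa = a.fractions()[:, -1]
        fb = b.fractions()[:, -1]
        assert np.all(np.abs(fa - fb) / np.maximum(fb, 1e-12) < 1e-3)


def test_states_stay_nonnegative(case2_config):
    traj = simulate(case2_config, 60.0)
    assert traj.species.min() >= 0.0
    assert traj.mediators.min() >= 0.0
    assert np.all(np.diff(traj.times) > 0)


def test_phase_trace_zero_production():
    cfg = single_mediator_config(beta=0.0)
    tr = phase_trace(cfg, 10.0)
    assert np.all(tr.C1 == 0.0)


def test_phase_trace_consumer_takeover_drains_mediator():
    cfg = single_mediator_config(r10=0.2, r20=0.45, rsc=0.3, KS2C1=2e3,
                                 KC1S2=2e3, beta=3e-4, alpha=3e-4)
    tr = phase_trace(cfg, 100.0)
    assert tr.case == "III"
    assert tr.RS[-1] / tr.RS[0] > 10  # ratio grows without bound
    assert tr.C1[-1] < 0.2 * tr.C1.max()  # mediator drains toward zero


def test_trajectory_round_trip(tmp_path, reusable_config):
    traj = simulate(reusable_config, 20.0)
    path = tmp_path / "traj.csv"
    write_trajectory(traj, path)
    back = read_trajectory(path)
    assert back.species_ids == traj.species_ids
    assert np.allclose(back.species, traj.species)
    assert np.allclose(back.mediators, traj.mediators)
    assert np.allclose(back.dilution_times, traj.dilution_times)


def test_simulate_rejects_nonpositive_horizon(reusable_config):
    with pytest.raises(ValueError):
        simulate(reusable_config, 0.0)
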