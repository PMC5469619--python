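"""Pairwise model family: algebraic identities, limits, assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from medlv import ConfigError, PairwiseModelSpec, assemble_multispecies, simulate_pairwise
from medlv.pairwise import build_pairwise_rhs


def _spec(form, inter, r0=None, species=("S1", "S2"), **kw):
    r0 = r0 or {"S1": 0.4, "S2": 0.2}
    return PairwiseModelSpec(form, list(species), r0, inter, **kw)


def test_linear_without_interactions_is_exponential():
    spec = _spec("linear_lv", {})
    traj = simulate_pairwise(spec, {"S1": 1e5, "S2": 1e5}, 10.0)
    assert np.allclose(traj.density("S1"), 1e5 * np.exp(0.4 * traj.times), rtol=1e-6)


def test_logistic_single_species_closed_form():
    lam, r, s0 = 2e7, 0.3, 1e5
    spec = PairwiseModelSpec("logistic_lv", ["S1"], {"S1": r},
                             {("S1", "S1"): {"Lam": lam}})
    traj = simulate_pairwise(spec, {"S1": s0}, 40.0)
    t = traj.times
    expected = lam * s0 * np.exp(r * t) / (lam + s0 * (np.exp(r * t) - 1.0))
    assert np.allclose(traj.density("S1"), expected, rtol=1e-6)
    # at the carrying capacity the derivative vanishes
    rhs = build_pairwise_rhs(spec)
    assert rhs(0.0, np.array([lam]))[0] == pytest.approx(0.0, abs=1e-12)


def test_linear_parameters_reproduce_logistic_dynamics():
    """r_ij = -r_i0/Lam_ij maps the logistic form onto the linear form."""
    r0 = {"S1": 0.4, "S2": 0.2}
    lam = {("S1", "S1"): 2e7, ("S1", "S2"): 5e7,
           ("S2", "S1"): 4e7, ("S2", "S2"): 3e7}
    logi = _spec("logistic_lv", {k: {"Lam": v} for k, v in lam.items()}, r0)
    line = _spec("linear_lv",
                 {k: {"r": -r0[k[0]] / v} for k, v in lam.items()}, r0)
    a = simulate_pairwise(logi, {"S1": 1e5, "S2": 2e5}, 50.0,
                          t_eval=np.linspace(0, 50, 101))
    b = simulate_pairwise(line, {"S1": 1e5, "S2": 2e5}, 50.0,
                          t_eval=np.linspace(0, 50, 101))
    assert np.allclose(a.species, b.species, rtol=1e-7)


def test_saturable_half_maximal_effect_at_K():
    spec = _spec("saturable_lv", {("S2", "S1"): {"r": 0.3, "K": 1e6}})
    rhs = build_pairwise_rhs(spec)
    g2 = rhs(0.0, np.array([1e6, 1.0]))[1] / 1.0
    assert g2 == pytest.approx(0.2 + 0.3 / 2)


@given(r=st.floats(0.05, 0.5), K=st.floats(1e5, 1e8))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_saturable_approaches_linear_at_low_density(r, K):
    sat = _spec("saturable_lv", {("S2", "S1"): {"r": r, "K": K}})
    lin = _spec("linear_lv", {("S2", "S1"): {"r": r / K}})
    s1 = K / 1000.0
    y = np.array([s1, 1e3])
    g_sat = build_pairwise_rhs(sat)(0.0, y)[1]
    g_lin = build_pairwise_rhs(lin)(0.0, y)[1]
    assert g_sat == pytest.approx(g_lin, rel=0.01)


def test_alternative_effect_vanishes_for_large_psi():
    spec = _spec("alternative", {("S2", "S1"): {"r": 0.3, "omega": 1.0, "psi": 1e12}})
    rhs = build_pairwise_rhs(spec)
    g2 = rhs(0.0, np.array([1e6, 1e6]))[1] / 1e6
    assert g2 == pytest.approx(0.2, rel=1e-4)


def test_alternative_with_zero_omega_equals_divided_form():
    """omega = 0 collapses the divided-influence model to the rho form
    with rho = r/psi; trajectories agree to better than 1e-6."""
    r, psi = 0.4, 2.0
    alt = _spec("alternative", {("S2", "S1"): {"r": r, "omega": 0.0, "psi": psi}})
    div = _spec("divided_simplified", {("S2", "S1"): {"rho": r / psi}})
    grid = np.linspace(0, 30, 101)
    a = simulate_pairwise(alt, {"S1": 1e6, "S2": 2e6}, 30.0, t_eval=grid)
    b = simulate_pairwise(div, {"S1": 1e6, "S2": 2e6}, 30.0, t_eval=grid)
    assert np.allclose(a.species, b.species, rtol=1e-6)


def test_divided_form_ratio_settles_at_rho_over_gap():
    """Stationary consumer/producer ratio of the rho form is
    rho/(r10 - r20)."""
    rho, r10, r20 = 0.3, 0.4, 0.2
    spec = _spec("divided_simplified", {("S2", "S1"): {"rho": rho}},
                 r0={"S1": r10, "S2": r20})
    traj = simulate_pairwise(spec, {"S1": 1e5, "S2": 1e5}, 120.0)
    rs = traj.density("S2")[-1] / traj.density("S1")[-1]
    assert rs == pytest.approx(rho / (r10 - r20), rel=1e-3)


def test_classic_predator_prey_oscillates():
    spec = PairwiseModelSpec(
        "linear_lv", ["prey", "pred"], {"prey": 0.5, "pred": -0.3},
        {("prey", "pred"): {"r": -1e-5}, ("pred", "prey"): {"r": 5e-6}})
    traj = simulate_pairwise(spec, {"prey": 2e4, "pred": 2e4}, 120.0,
                             t_eval=np.linspace(0, 120, 2000))
    prey = traj.density("prey")
    # count maxima: sustained oscillation has several
    dp = np.diff(prey)
    peaks = np.sum((dp[:-1] > 0) & (dp[1:] < 0))
    assert peaks >= 3


def test_competitive_commensal_reduces_to_logistic():
    """r21 = 0 and d = 0 collapse the birth/death form onto logistic L-V."""
    bd = {"S1": (0.4, 0.0), "S2": (0.2, 0.0)}
    lam = {("S1", "S1"): 2e7, ("S1", "S2"): 5e7,
           ("S2", "S1"): 4e7, ("S2", "S2"): 3e7}
    cc = _spec("competitive_commensal_lv", {k: {"Lam": v} for k, v in lam.items()},
               r0={"S1": 0.0, "S2": 0.0}, birth_death=bd)
    logi = _spec("logistic_lv", {k: {"Lam": v} for k, v in lam.items()},
                 r0={"S1": 0.4, "S2": 0.2})
    grid = np.linspace(0, 40, 101)
    a = simulate_pairwise(cc, {"S1": 1e5, "S2": 2e5}, 40.0, t_eval=grid)
    b = simulate_pairwise(logi, {"S1": 1e5, "S2": 2e5}, 40.0, t_eval=grid)
    assert np.allclose(a.species, b.species, rtol=1e-7)


def test_competitive_commensal_birth_stops_at_resource_exhaustion():
    """When the shared resource is exhausted (crowding factor zero), the
    beneficiary's birth term is exactly zero however dense the partner."""
    bd = {"S1": (0.4, 0.1), "S2": (0.2, 0.05)}
    inter = {("S1", "S1"): {"Lam": 1e7}, ("S1", "S2"): {"Lam": 1e8},
             ("S2", "S1"): {"Lam": 2e7, "r": 1e-7}, ("S2", "S2"): {"Lam": 1e7}}
    spec = _spec("competitive_commensal_lv", inter, r0={"S1": 0.0, "S2": 0.0},
                 birth_death=bd)
    rhs = build_pairwise_rhs(spec)
    s1 = 1e7
    s2 = 1e7 * (1.0 - s1 / 2e7)  # 1 - S1/Lam21 - S2/Lam22 = 0
    dy = rhs(0.0, np.array([s1, s2]))
    assert dy[1] == pytest.approx(-0.05 * s2, rel=1e-12)


def test_assembly_without_interactions_is_independent_exponentials():
    pairs = [PairwiseModelSpec("saturable_lv", ["S1", "S2"],
                               {"S1": 0.3, "S2": 0.2}),
             PairwiseModelSpec("saturable_lv", ["S2", "S3"],
                               {"S2": 0.2, "S3": 0.1})]
    trio = assemble_multispecies(pairs, ["S1", "S2", "S3"])
    traj = simulate_pairwise(trio, {"S1": 1e5, "S2": 1e5, "S3": 1e5}, 10.0)
    for sid, r in (("S1", 0.3), ("S2", 0.2), ("S3", 0.1)):
        assert np.allclose(traj.density(sid), 1e5 * np.exp(r * traj.times),
                           rtol=1e-6)


def test_assembly_rejects_conflicting_basal_fitness():
    pairs = [PairwiseModelSpec("saturable_lv", ["S1", "S2"],
                               {"S1": 0.3, "S2": 0.2}),
             PairwiseModelSpec("saturable_lv", ["S2", "S3"],
                               {"S2": 0.25, "S3": 0.1})]
    with pytest.raises(ConfigError, match="conflicting basal fitness"):
        assemble_multispecies(pairs, ["S1", "S2", "S3"])


@pytest.mark.parametrize("form, inter, t_end", [
    ("linear_lv", {("S2", "S1"): {"r": -3e-9}}, 12.0),
    ("saturable_lv", {("S2", "S1"): {"r": -0.5, "K": 1e5}}, 12.0),
    ("alternative", {("S2", "S1"): {"r": -0.4, "omega": 0.5, "psi": 1.0}}, 12.0),
    # the divided form's inhibition runs away as the focal species
    # shrinks (capped at 50/h), so keep the horizon within float range
    ("divided_simplified", {("S2", "S1"): {"rho": -0.2}}, 0.4),
])
def test_positive_start_stays_positive(form, inter, t_end):
    """Multiplicative structure: densities never cross zero in finite
    time, even under strong inhibition (parameters keep the decay
    within floating-point resolution)."""
    spec = _spec(form, inter)
    traj = simulate_pairwise(spec, {"S1": 1e6, "S2": 1e6}, t_end)
    assert traj.species.min() > 0.0


def test_effect_terms_ignore_uninvolved_species():
    """Each fitness-effect term depends only on its own pair (plus the
    focal density for divided forms): perturbing a bystander leaves the
    focal growth rate unchanged."""
    pairs = [PairwiseModelSpec("saturable_lv", ["S1", "S2"],
                               {"S1": 0.3, "S2": 0.2},
                               {("S2", "S1"): {"r": 0.3, "K": 1e6}}),
             PairwiseModelSpec("alternative", ["S2", "S3"],
                               {"S2": 0.2, "S3": 0.1},
                               {("S3", "S2"): {"r": 0.2, "omega": 0.5, "psi": 1.0}})]
    trio = assemble_multispecies(pairs, ["S1", "S2", "S3"])
    rhs = trio.rhs()
    y = np.array([1e6, 2e6, 3e6])
    base = rhs(0.0, y)
    y2 = y.copy()
    y2[0] *= 10  # bystander for the S3<-S2 term
    assert rhs(0.0, y2)[2] / y2[2] == pytest.approx(base[2] / y[2], rel=1e-12)
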