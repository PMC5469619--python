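"""Closed-form theory: classification, steady states, t_f, reducibility."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from medlv import (
    DomainError,
    SingleMediatorParams,
    TwoMediatorParams,
    analyze,
    check_alt_convergence,
    classify_case,
    derive_alternative,
    derive_reusable_lv,
    divided_rho,
    estimate_tf,
    f_zero_isocline,
    steady_state,
    two_mediator_reducibility,
)
from medlv.analytic import alt_ratio_fixed_point, isocline_asymptote
from medlv.mechanistic import phase_trace
from medlv.pairwise import build_pairwise_rhs

from conftest import single_mediator_config


def _params(r10=0.5, r20=0.3, rsc=0.5, KS2C1=1e3, KC1S2=2e3, beta=3e-4,
            alpha=6e-4):
    return SingleMediatorParams(r10=r10, r20=r20, rS2C1=rsc, KS2C1=KS2C1,
                                betaC1S1=beta, alphaC1S2=alpha, KC1S2=KC1S2)


@pytest.mark.parametrize("r10, r20, rsc, expected", [
    (0.5, 0.1, 0.3, "I"),
    (0.5, 0.3, 0.5, "II"),
    (0.1, 0.5, 0.3, "III"),
    (0.5, 0.3, 0.2, "boundary"),  # r10 - r20 == rS2C1
    (0.4, 0.4, 0.3, "boundary"),
])
def test_case_classification(r10, r20, rsc, expected):
    assert classify_case(_params(r10=r10, r20=r20, rsc=rsc)) == expected


def test_classification_requires_positive_basal_fitness():
    with pytest.raises(DomainError):
        classify_case(_params(r10=-0.1))


@given(r10=st.floats(0.03, 0.7), r20=st.floats(0.03, 0.7),
       rsc=st.floats(0.03, 0.7))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_classification_partitions_parameter_space(r10, r20, rsc):
    case = classify_case(_params(r10=r10, r20=r20, rsc=rsc))
    assert case in ("I", "II", "III", "boundary")
    if case == "I":
        assert r10 - r20 > rsc
    elif case == "II":
        assert rsc > r10 - r20 > 0
    elif case == "III":
        assert r10 < r20


def test_steady_state_equalizes_growth_rates():
    p = _params()
    c1_star, rs_star = steady_state(p)
    g2 = p.r20 + p.rS2C1 * c1_star / (c1_star + p.KS2C1)
    assert g2 == pytest.approx(p.r10, rel=1e-12)
    assert rs_star == pytest.approx(
        (p.betaC1S1 / p.alphaC1S2) * (1 + p.KC1S2 / c1_star))


def test_steady_state_limit_as_fitness_gap_closes():
    c1_near, rs_near = steady_state(_params(r10=0.3 + 1e-6, r20=0.3))
    c1_far, rs_far = steady_state(_params(r10=0.4, r20=0.3))
    assert c1_near < 1e-2 * c1_far  # C1* -> 0
    assert rs_near > 1e2 * rs_far  # RS* -> infinity


def test_steady_state_outside_coexistence_raises():
    with pytest.raises(DomainError):
        steady_state(_params(r10=0.5, r20=0.1, rsc=0.3))


def test_derived_saturable_parameters_scale_with_release_rate():
    p1 = _params(beta=1e-4)
    p2 = _params(beta=2e-4)
    k1 = derive_reusable_lv(p1).interactions[("S2", "S1")]["K"]
    k2 = derive_reusable_lv(p2).interactions[("S2", "S1")]["K"]
    assert k1 == pytest.approx(2 * k2)
    assert derive_reusable_lv(p1).interactions[("S2", "S1")]["r"] == p1.rS2C1


def test_alternative_constants_and_rho():
    p = _params(KS2C1=1e3, KC1S2=1e3)
    spec = derive_alternative(p)
    inter = spec.interactions[("S2", "S1")]
    assert inter["omega"] == pytest.approx(0.0)
    assert inter["psi"] == pytest.approx(p.alphaC1S2 / p.betaC1S1)
    assert divided_rho(p) == pytest.approx(p.rS2C1 * p.betaC1S1 / p.alphaC1S2)


def test_alternative_form_matches_mediator_elimination_algebra():
    """The derived (omega, psi) reproduce the raw mediator-eliminated
    fitness term r*beta*Kc*S1 / (beta*(Kc-Ks)*S1 + alpha*Ks*S2)."""
    p = _params()
    spec = derive_alternative(p)
    rhs = build_pairwise_rhs(spec)
    for s1, s2 in ((1e6, 2e6), (5e7, 1e6), (1e4, 1e8)):
        raw = (p.rS2C1 * p.betaC1S1 * p.KC1S2 * s1 /
               (p.betaC1S1 * (p.KC1S2 - p.KS2C1) * s1
                + p.alphaC1S2 * p.KS2C1 * s2))
        g2 = rhs(0.0, np.array([s1, s2]))[1] / s2 - p.r20
        assert g2 == pytest.approx(raw, rel=1e-6)


def test_isocline_passes_through_steady_state_and_asymptotes():
    p = _params()
    assert f_zero_isocline(p, np.array([1.0]), scaled=True)[0] == pytest.approx(1.0)
    c1_star, _ = steady_state(p)
    k_hat = p.KC1S2 / c1_star
    assert isocline_asymptote(p, scaled=True) == pytest.approx(1 / (1 + k_hat))
    p3 = _params(r10=0.2, r20=0.45)
    assert isocline_asymptote(p3, scaled=False) == pytest.approx(
        p3.betaC1S1 / p3.alphaC1S2)
    big = f_zero_isocline(p3, np.array([1e9]), scaled=False)[0]
    assert big == pytest.approx(p3.betaC1S1 / p3.alphaC1S2, rel=1e-5)


def test_late_mechanistic_states_lie_on_the_isocline(case2_config):
    """Sampled at the pre-dilution phase (mediator fully re-equilibrated
    after the preceding dilution), the community sits on the isocline."""
    from medlv import simulate

    traj = simulate(case2_config, 60.0)
    tr = phase_trace(case2_config, 60.0, traj=traj)
    for td in traj.dilution_times:
        if td < 40.0:
            continue
        idx = np.searchsorted(traj.times, td) - 1
        assert abs(tr.f[idx]) < 0.05


def test_tf_halves_when_consumer_doubles():
    p = _params()
    _, rss = steady_state(p)
    rs0 = 100 * rss
    a = estimate_tf(p, 1e7, rs0 * 1e7)
    b = estimate_tf(p, 1e7, 2 * rs0 * 1e7)
    assert a.subcase == "II-1"
    assert a.t_f == pytest.approx(2 * b.t_f)


def test_tf_case3_grows_logarithmically_at_small_ratio():
    p = _params(r10=0.2, r20=0.45)
    ratio = p.betaC1S1 / p.alphaC1S2
    t1 = estimate_tf(p, 1e8, 1e8 * ratio / 100).t_f
    t2 = estimate_tf(p, 1e8, 1e8 * ratio / 1000).t_f
    assert t2 > t1
    assert (t2 - t1) == pytest.approx(math.log(10) / (p.r20 - p.r10), rel=1e-9)


def test_tf_case1_returns_acclimation_time():
    p = _params(r10=0.6, r20=0.05, rsc=0.3)
    est = estimate_tf(p, 5e6, 5e6)
    assert est.subcase == "I"
    assert est.t_f == pytest.approx(
        max(math.log(max(p.alphaC1S2 / p.betaC1S1, 1.0))
            / abs(p.r20 + p.rS2C1 - p.r10), 1 / p.r10))


def test_tf_indeterminate_between_subcases():
    p = _params()
    _, rss = steady_state(p)
    est = estimate_tf(p, 1e7, 1e7 * 4 * rss)  # between "comparable" and ">>"
    assert est.subcase == "indeterminate"
    assert math.isnan(est.t_f)


@pytest.mark.parametrize("omega, psi, rs0, case, expected", [
    (0.5, 0.25, 0.1, "II", "converges"),
    (0.5, 0.25, 10.0, "II", "converges"),
    (-1.0, 1.0, 0.5, "II", "false_extinction"),
    (-1.0, 1.0, 2.0, "II", "converges"),
    (0.8, 0.1, 1.0, "III", "unbounded_growth"),
    (-9.0, 5.0, 1.0, "III", "false_coexistence"),
    (-9.0, 5.0, 3.0, "III", "unbounded_growth"),
])
def test_alt_convergence_verdicts(omega, psi, rs0, case, expected):
    assert check_alt_convergence(omega, psi, rs0, case) == expected


def test_alt_fixed_point_formula():
    rs = alt_ratio_fixed_point(0.5, 0.3, 0.5, 0.5, 0.25)
    # r20 + r/(omega + psi rs) == r10 at the fixed point
    assert 0.3 + 0.5 / (0.5 + 0.25 * rs) == pytest.approx(0.5)


def test_two_mediator_reducibility_verdicts():
    base = dict(r10=0.5, r20=0.3, rS2C1=0.3, betaC1S1=1e-4, betaC2S1=1e-4)
    equal = TwoMediatorParams(KS2C1=0.2, KS2C2=0.2, rS2C2=0.2, **base)
    assert two_mediator_reducibility(equal).reducible
    dominated = TwoMediatorParams(KS2C1=0.2, KS2C2=20.0, rS2C2=0.0, **base)
    rep = two_mediator_reducibility(dominated)
    assert rep.reducible and "dominates" in rep.reason
    distinct = TwoMediatorParams(KS2C1=0.2, KS2C2=20.0, rS2C2=-0.35, **base)
    rep = two_mediator_reducibility(distinct)
    assert not rep.reducible
    assert rep.KC1 == pytest.approx(1e3) and rep.KC2 == pytest.approx(1e5)
    # combined effect: sum of the two saturable terms
    assert rep.combined_effect(1e3) == pytest.approx(
        0.3 * 0.5 - 0.35 * 1e3 / (1e3 + 1e5))


def test_analyze_recommends_form_by_regime(case2_config, reusable_config):
    rep = analyze(case2_config)
    assert rep.case == "II" and rep.recommended_form == "alternative"
    assert rep.C1_star is not None and rep.converges
    rep = analyze(reusable_config)
    assert rep.recommended_form == "saturable_lv"
    cfg1 = single_mediator_config(r10=0.6, r20=0.05, rsc=0.3, KS2C1=9e3,
                                  KC1S2=1e4, beta=1e-4, alpha=1e-4)
    rep = analyze(cfg1)
    assert rep.case == "I" and rep.recommended_form == "saturable_lv"
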