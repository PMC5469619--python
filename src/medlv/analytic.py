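"""Closed-form theory for single- and two-mediator commensal communities.

For a producer S1 releasing a consumable mediator C1 that stimulates a
consumer S2, the fate of the community is set by the basal fitnesses and
the maximal fitness effect:

* coexistence-impossible, producer wins ("Case I"):  r10 - r20 > rS2C1
* coexistence ("Case II"):                 rS2C1 > r10 - r20 > 0
* consumer wins ("Case III"):                        r10 < r20

In Case II the mediator and the species ratio RS = S2/S1 converge to

    C1* = K_S2C1 (r10 - r20) / (r20 + rS2C1 - r10)
    RS* = (beta_C1S1 / alpha_C1S2) (1 + K_C1S2 / C1*)

and near the f-zero-isocline (the curve in (C1, RS) space where net
mediator production vanishes) the mediator can be eliminated, yielding
the divided-influence ("alternative") pairwise model with

    omega = 1 - K_S2C1 / K_C1S2
    psi   = K_S2C1 alpha_C1S2 / (K_C1S2 beta_C1S1)

This module provides the regime classifier, the steady state, the
analytically derived pairwise specs, the isocline, convergence-time
estimates t_f for the tractable initial-condition subcases, the
convergence condition RS(0) > -omega/psi of the alternative model, and
the reducibility test for interactions carried by two reusable
mediators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .config import CommunityConfig, PairwiseModelSpec

__all__ = [
    "DomainError",
    "SingleMediatorParams",
    "TwoMediatorParams",
    "RegimeReport",
    "TfEstimate",
    "classify_case",
    "steady_state",
    "derive_reusable_lv",
    "derive_alternative",
    "f_zero_isocline",
    "isocline_asymptote",
    "estimate_tf",
    "check_alt_convergence",
    "integrate_alt_ratio",
    "alt_ratio_fixed_point",
    "two_mediator_reducibility",
    "ReducibilityReport",
    "analyze",
]


class DomainError(ValueError):
    """Inputs fall outside the domain of a closed-form result."""


# ---------------------------------------------------------------------------
# parameter extraction
# ---------------------------------------------------------------------------


@dataclass
class SingleMediatorParams:
    """Parameters of the canonical two-species single-mediator commensalism.

    ``alphaC1S2``/``KC1S2`` are ``None`` for a reusable mediator.
    """

    r10: float
    r20: float
    rS2C1: float
    KS2C1: float
    betaC1S1: float
    alphaC1S2: Optional[float] = None
    KC1S2: Optional[float] = None
    producer_id: str = "S1"
    consumer_id: str = "S2"
    mediator_id: str = "C1"
    consumable: bool = True

    @classmethod
    def from_config(cls, config: CommunityConfig) -> "SingleMediatorParams":
        if len(config.species) != 2 or len(config.mediators) != 1:
            raise DomainError(
                "single-mediator analysis needs exactly two species and one mediator"
            )
        med = config.mediators[0]
        producer = beta = None
        target = r_eff = K_eff = None
        alpha = K_cons = None
        for ln in config.links_for_mediator(med.id):
            if ln.producer is not None:
                producer, beta = ln.producer, ln.beta
            if ln.target is not None:
                target, r_eff, K_eff = ln.target, ln.r_effect, ln.K_effect
            if ln.consumer is not None:
                alpha, K_cons = ln.alpha, ln.K_consume
        if producer is None or target is None or producer == target:
            raise DomainError(
                "expected one species producing the mediator and the other influenced by it"
            )
        if med.kind == "consumable" and alpha is None:
            raise DomainError("consumable mediator must carry a consumption link")
        return cls(
            r10=config.species_spec(producer).r0,
            r20=config.species_spec(target).r0,
            rS2C1=r_eff,
            KS2C1=K_eff,
            betaC1S1=beta,
            alphaC1S2=alpha,
            KC1S2=K_cons,
            producer_id=producer,
            consumer_id=target,
            mediator_id=med.id,
            consumable=med.kind == "consumable",
        )


@dataclass
class TwoMediatorParams:
    """S1 releases two reusable mediators that additively affect S2."""

    r10: float
    r20: float
    rS2C1: float
    KS2C1: float
    betaC1S1: float
    rS2C2: float
    KS2C2: float
    betaC2S1: float

    @property
    def KC1(self) -> float:
        """Potency of mediator 1: producer density at half-maximal effect."""
        return self.KS2C1 * self.r10 / self.betaC1S1

    @property
    def KC2(self) -> float:
        return self.KS2C2 * self.r10 / self.betaC2S1


# ---------------------------------------------------------------------------
# regime classification and steady state
# ---------------------------------------------------------------------------


def classify_case(params: SingleMediatorParams) -> str:
    """Classify the consumable-mediator commensalism into Case I/II/III.

    Boundary equalities (r10 - r20 = rS2C1 or r10 = r20) are reported as
    ``"boundary"`` and excluded from the regime guarantees.
    """
    r10, r20, rs = params.r10, params.r20, params.rS2C1
    if r10 <= 0 or r20 <= 0:
        raise DomainError(
            f"basal fitnesses must be positive (r10={r10}, r20={r20}); "
            "otherwise species go extinct without any dilution"
        )
    if r10 == r20 or r10 - r20 == rs:
        return "boundary"
    if r10 < r20:
        return "III"
    if r10 - r20 > rs:
        return "I"
    return "II"


def steady_state(params: SingleMediatorParams) -> tuple:
    """Coexistence steady state (C1*, RS*); defined for Case II only."""
    if classify_case(params) != "II":
        raise DomainError("steady state (C1*, RS*) exists only in the coexistence case")
    r10, r20, rs = params.r10, params.r20, params.rS2C1
    c1_star = params.KS2C1 * (r10 - r20) / (r20 + rs - r10)
    rs_star = (params.betaC1S1 / params.alphaC1S2) * (1.0 + params.KC1S2 / c1_star)
    return c1_star, rs_star


# ---------------------------------------------------------------------------
# analytically derived pairwise specs
# ---------------------------------------------------------------------------


def derive_reusable_lv(params: SingleMediatorParams) -> PairwiseModelSpec:
    """Saturable L-V spec that exactly matches a reusable-mediator
    commensalism once the mediator has acclimated to C1 = (beta/r10) S1:

        r21 = rS2C1,   K21 = K_S2C1 * r10 / beta_C1S1
    """
    s1, s2 = params.producer_id, params.consumer_id
    return PairwiseModelSpec(
        form="saturable_lv",
        species=[s1, s2],
        r0={s1: params.r10, s2: params.r20},
        interactions={
            (s2, s1): {"r": params.rS2C1, "K": params.KS2C1 * params.r10 / params.betaC1S1}
        },
    )


def derive_alternative(params: SingleMediatorParams) -> PairwiseModelSpec:
    """Divided-influence spec from mediator elimination on the isocline."""
    if not params.consumable:
        raise DomainError("the divided-influence model requires a consumable mediator")
    omega = 1.0 - params.KS2C1 / params.KC1S2
    psi = params.KS2C1 * params.alphaC1S2 / (params.KC1S2 * params.betaC1S1)
    s1, s2 = params.producer_id, params.consumer_id
    return PairwiseModelSpec(
        form="alternative",
        species=[s1, s2],
        r0={s1: params.r10, s2: params.r20},
        interactions={(s2, s1): {"r": params.rS2C1, "omega": omega, "psi": psi}},
    )


def divided_rho(params: SingleMediatorParams) -> float:
    """Interaction strength of the fully simplified divided-influence
    model (valid when K_S2C1 = K_C1S2, i.e. omega = 0)."""
    return params.rS2C1 * params.betaC1S1 / params.alphaC1S2


# ---------------------------------------------------------------------------
# isocline
# ---------------------------------------------------------------------------


def f_zero_isocline(
    params: SingleMediatorParams, c1: np.ndarray, scaled: Optional[bool] = None
) -> np.ndarray:
    """Species ratio on the f-zero-isocline at mediator level ``c1``.

    With ``scaled=True`` (default in the coexistence case) both axes are
    normalized by the steady state: RS_hat(C1_hat).  Unscaled, the
    isocline is RS = (beta/alpha)(1 + K_C1S2/C1).
    """
    c1 = np.asarray(c1, dtype=float)
    if scaled is None:
        scaled = classify_case(params) == "II"
    if scaled:
        c1_star, _ = steady_state(params)
        k_hat = params.KC1S2 / c1_star
        return (1.0 + k_hat / c1) / (1.0 + k_hat)
    return (params.betaC1S1 / params.alphaC1S2) * (1.0 + params.KC1S2 / c1)


def isocline_asymptote(params: SingleMediatorParams, scaled: Optional[bool] = None) -> float:
    """Isocline level as C1 -> infinity: 1/(1 + K_hat) scaled, beta/alpha unscaled."""
    if scaled is None:
        scaled = classify_case(params) == "II"
    if scaled:
        c1_star, _ = steady_state(params)
        return 1.0 / (1.0 + params.KC1S2 / c1_star)
    return params.betaC1S1 / params.alphaC1S2


# ---------------------------------------------------------------------------
# convergence-time estimates
# ---------------------------------------------------------------------------


@dataclass
class TfEstimate:
    subcase: str  # "I", "II-1", "II-2", "II-3", "III-1", "III-2", "indeterminate"
    t_f: float  # hours; acclimation time for Case I; nan when indeterminate
    sufficient: Optional[bool]  # initial-density sufficiency verdict
    details: dict


def estimate_tf(
    params: SingleMediatorParams,
    S1_0: float,
    S2_0: float,
    sep: float = 10.0,
    comparable: float = 3.0,
) -> TfEstimate:
    """Estimate the time scale t_f to approach the f-zero-isocline.

    Assumes the mediator starts at zero concentration.  The subcase is
    chosen from the initial consumer-to-producer ratio; "much greater /
    much less than" thresholds are operationalized as a factor ``sep``
    separation, and "comparable to 1" as within a factor ``comparable``.
    Conditions on S1(0) are sufficient, not necessary.

    For Case I the isocline concept does not apply; the returned time is
    the acclimation scale after which C1 grows in proportion to S1.
    """
    if S1_0 <= 0 or S2_0 <= 0:
        raise DomainError("initial densities must be positive")
    rs0 = S2_0 / S1_0
    case = classify_case(params)
    r10, r20, rsc = params.r10, params.r20, params.rS2C1
    alpha, beta = params.alphaC1S2, params.betaC1S1
    Kc = params.KC1S2

    if case == "boundary":
        raise DomainError("boundary parameter sets are outside the regime analysis")

    if case == "I":
        rate = abs(r20 + rsc - r10)
        t_acc = max(math.log(max(alpha * rs0 / beta, 1.0)) / rate, 1.0 / r10)
        return TfEstimate("I", t_acc, True, {"RS0": rs0})

    if case == "II":
        c1_star, rs_star = steady_state(params)
        rs_hat0 = rs0 / rs_star
        ks_hat = params.KS2C1 / c1_star
        kc_hat = Kc / c1_star
        details = {"RS0": rs0, "RS_hat0": rs_hat0, "C1_star": c1_star, "RS_star": rs_star}
        if rs_hat0 >= sep * max(1.0, ks_hat - 1.0):
            t_f = Kc / (alpha * S2_0)
            sufficient = S1_0 >= sep * Kc * (r10 - r20) / (alpha * rs0)
            return TfEstimate("II-1", t_f, sufficient, details)
        if rs_hat0 <= 1.0 / (sep * (1.0 + kc_hat)):
            t_f = 1.0 / r10 + math.log(alpha * rs0 / beta) / (r10 - r20 - rsc)
            sufficient = beta * S1_0 >= sep * r10 * c1_star
            return TfEstimate("II-3", t_f, sufficient, details)
        if 1.0 / comparable <= rs_hat0 <= comparable:
            t_f = sep / r10
            sufficient = beta * S1_0 >= sep * (r10 - r20) * c1_star
            return TfEstimate("II-2", t_f, sufficient, details)
        return TfEstimate("indeterminate", float("nan"), None, details)

    # Case III
    ratio = beta / alpha
    details = {"RS0": rs0, "beta_over_alpha": ratio}
    if rs0 >= sep * ratio:
        t_f = Kc / (alpha * S2_0)
        sufficient = S1_0 >= sep * (r20 - r10) * Kc / (alpha * rs0)
        return TfEstimate("III-1", t_f, sufficient, details)
    if rs0 <= ratio / sep:
        t_f = math.log(ratio / rs0) / (r20 - r10)
        sufficient = beta * S1_0 >= sep * r10 * Kc
        return TfEstimate("III-2", t_f, sufficient, details)
    return TfEstimate("indeterminate", float("nan"), None, details)


# ---------------------------------------------------------------------------
# convergence of the alternative pairwise model
# ---------------------------------------------------------------------------


def check_alt_convergence(omega: float, psi: float, RS_0: float, case: str) -> str:
    """Verdict on whether the divided-influence model converges to the
    mechanistic outcome from ratio ``RS_0``.

    The RS equation has a singularity at RS = -omega/psi when omega < 0;
    initial ratios below it converge to the wrong attractor: a false
    extinction in the coexistence case, a false steady-state coexistence
    in the consumer-wins case.
    """
    if psi <= 0:
        raise DomainError(f"psi must be > 0, got {psi}")
    if case not in ("II", "III"):
        raise DomainError(f"convergence analysis applies to Cases II/III, got {case!r}")
    ok = omega >= 0 or RS_0 > -omega / psi
    if case == "II":
        return "converges" if ok else "false_extinction"
    return "unbounded_growth" if ok else "false_coexistence"


def alt_ratio_fixed_point(
    r10: float, r20: float, rS2C1: float, omega: float, psi: float
) -> float:
    """RS at which the divided-influence ratio dynamics is stationary:
    r20 + rS2C1/(omega + psi RS) = r10."""
    if r10 == r20:
        raise DomainError("no finite fixed point when r10 == r20")
    return (rS2C1 / (r10 - r20) - omega) / psi


def integrate_alt_ratio(
    r10: float,
    r20: float,
    rS2C1: float,
    omega: float,
    psi: float,
    RS_0: float,
    t_end: float,
    n: int = 400,
):
    """Directly integrate the one-dimensional ratio dynamics of the
    divided-influence model, dRS/dt = (r20 + rS2C1/(omega + psi RS) - r10) RS.

    Returns (t, RS).  Used as the independent check of the convergence
    verdicts.
    """

    def rhs(t, y):
        rs = y[0]
        denom = omega + psi * rs
        if denom == 0:
            denom = 1e-300
        return [(r20 + rS2C1 / denom - r10) * rs]

    t_eval = np.linspace(0.0, t_end, n)
    sol = solve_ivp(rhs, (0.0, t_end), [RS_0], t_eval=t_eval, rtol=1e-9, atol=1e-12,
                    method="LSODA")
    return sol.t, sol.y[0]


# ---------------------------------------------------------------------------
# two-mediator reducibility
# ---------------------------------------------------------------------------


@dataclass
class ReducibilityReport:
    reducible: bool
    reason: str
    KC1: float
    KC2: float
    combined_effect: Callable


def two_mediator_reducibility(
    params: TwoMediatorParams,
    s1_range: tuple = (1e2, 1e8),
    similarity_band: tuple = (1.0 / 3.0, 3.0),
    dominance: float = 0.05,
) -> ReducibilityReport:
    """Can two reusable mediators be folded into one saturable term?

    After acclimation each mediator's effect on S2 is a saturable
    function of the producer density with potency K_Ci = K_S2Ci r10 /
    beta_CiS1, so the combined effect is

        r_S2,C1C2(S1) = rS2C1 S1/(S1+K_C1) + rS2C2 S1/(S1+K_C2).

    The pair is declared reducible when the potencies are similar
    (ratio within ``similarity_band``) or when one term's magnitude is
    below ``dominance`` of the other across ``s1_range``; both
    thresholds are documented knobs.
    """
    kc1, kc2 = params.KC1, params.KC2

    def combined_effect(s1):
        s1 = np.asarray(s1, dtype=float)
        return params.rS2C1 * s1 / (s1 + kc1) + params.rS2C2 * s1 / (s1 + kc2)

    ratio = kc1 / kc2
    if similarity_band[0] <= ratio <= similarity_band[1]:
        return ReducibilityReport(True, "similar_potency", kc1, kc2, combined_effect)

    grid = np.geomspace(s1_range[0], s1_range[1], 200)
    t1 = np.abs(params.rS2C1 * grid / (grid + kc1))
    t2 = np.abs(params.rS2C2 * grid / (grid + kc2))
    if np.all(t2 <= dominance * np.maximum(t1, 1e-300)):
        return ReducibilityReport(True, "mediator_1_dominates", kc1, kc2, combined_effect)
    if np.all(t1 <= dominance * np.maximum(t2, 1e-300)):
        return ReducibilityReport(True, "mediator_2_dominates", kc1, kc2, combined_effect)
    return ReducibilityReport(False, "distinct_potencies", kc1, kc2, combined_effect)


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------


@dataclass
class RegimeReport:
    case: str
    subcase: str
    C1_star: Optional[float]
    RS_star: Optional[float]
    omega: Optional[float]
    psi: Optional[float]
    rho: Optional[float]
    t_f: Optional[float]
    sufficient: Optional[bool]
    converges: Optional[bool]
    recommended_form: str

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def analyze(config: CommunityConfig) -> RegimeReport:
    """Full closed-form report for a single-mediator commensal config."""
    p = SingleMediatorParams.from_config(config)
    if not p.consumable:
        return RegimeReport(
            case="reusable", subcase="reusable", C1_star=None, RS_star=None,
            omega=None, psi=None, rho=None, t_f=None, sufficient=None,
            converges=True, recommended_form="saturable_lv",
        )
    case = classify_case(p)
    s1_0 = config.initial_densities[p.producer_id]
    s2_0 = config.initial_densities[p.consumer_id]
    rs0 = s2_0 / s1_0 if s1_0 > 0 else float("inf")
    alt = derive_alternative(p)
    omega = alt.interactions[(p.consumer_id, p.producer_id)]["omega"]
    psi = alt.interactions[(p.consumer_id, p.producer_id)]["psi"]
    rho = divided_rho(p) if abs(omega) < 1e-12 else None
    c1_star = rs_star = None
    if case == "II":
        c1_star, rs_star = steady_state(p)
    tf = estimate_tf(p, s1_0, s2_0) if case != "boundary" else None
    converges = None
    if case in ("II", "III"):
        verdict = check_alt_convergence(omega, psi, rs0, case)
        converges = verdict in ("converges", "unbounded_growth")
    if case == "I":
        recommended = "saturable_lv"
    elif case in ("II", "III") and converges:
        recommended = "alternative"
    else:
        recommended = "none"
    return RegimeReport(
        case=case,
        subcase=tf.subcase if tf is not None else case,
        C1_star=c1_star,
        RS_star=rs_star,
        omega=omega,
        psi=psi,
        rho=rho,
        t_f=tf.t_f if tf is not None else None,
        sufficient=tf.sufficient if tf is not None else None,
        converges=converges,
        recommended_form=recommended,
    )
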