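"""Seeded sweep experiments over generated communities.

These are the replicated, quantitative companions to the one-off
scenarios: closed-form steady-state verification across many sampled
coexistence communities, isocline convergence-time checks for every
tractable initial-condition subcase, and within-model-class parameter
recovery for each pairwise form.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from . import analytic
from .config import DilutionPolicy, PairwiseModelSpec
from .fitting import Slot, TrainingWindow, fit_spec_params
from .generate import generate_regime_config, with_initial_state
from .mechanistic import phase_trace, simulate
from .pairwise import simulate_pairwise

__all__ = [
    "steady_state_experiment",
    "subcase_initial_conditions",
    "tf_experiment",
    "recovery_experiment",
    "RECOVERY_FORMS",
]


# ---------------------------------------------------------------------------
# coexistence steady state across sampled communities
# ---------------------------------------------------------------------------


def settle_to_steady_state(config, params=None, t_start: float = 150.0,
                           t_cap: float = 1200.0, rel_tol: float = 5e-4):
    """Run a coexistence community until its pre-dilution state is
    stationary; return (C1, RS) sampled just before the last dilution.

    The sample phase (end of a growth cycle) is where the mediator has
    fully re-equilibrated after the preceding dilution.
    """
    t_end, prev = t_start, None
    while True:
        traj = simulate(config, t_end)
        if len(traj.dilution_times) == 0:
            raise RuntimeError("community never reached the dilution threshold")
        i = np.searchsorted(traj.times, traj.dilution_times[-1]) - 1
        s1 = traj.density("S1")[i]
        s2 = traj.density("S2")[i]
        rs = s2 / s1
        c1 = traj.mediator("C1")[i]
        if (prev is not None and abs(rs / prev - 1) < rel_tol) or t_end >= t_cap:
            return c1, rs
        prev, t_end = rs, t_end * 1.5


def steady_state_experiment(n: int = 50, seed: int = 0) -> dict:
    """Compare simulated late-time (C1, RS) with the closed-form steady
    state across ``n`` generated coexistence communities."""
    errs_c1, errs_rs = [], []
    for k in range(n):
        cfg = generate_regime_config("caseII", seed + k)
        p = analytic.SingleMediatorParams.from_config(cfg)
        c1_star, rs_star = analytic.steady_state(p)
        c1, rs = settle_to_steady_state(cfg, p)
        errs_c1.append(abs(c1 / c1_star - 1) * 100)
        errs_rs.append(abs(rs / rs_star - 1) * 100)
    return {
        "n": n,
        "max_err_c1_pct": float(np.max(errs_c1)),
        "max_err_rs_pct": float(np.max(errs_rs)),
        "mean_err_c1_pct": float(np.mean(errs_c1)),
        "mean_err_rs_pct": float(np.mean(errs_rs)),
    }


# ---------------------------------------------------------------------------
# isocline convergence times
# ---------------------------------------------------------------------------

TF_SUBCASES = ("II-1", "II-3", "III-1", "III-2")


def subcase_initial_conditions(p: analytic.SingleMediatorParams, subcase: str,
                               sep: float = 10.0) -> tuple:
    """Initial (RS(0), S1(0)) placing a community deep inside a t_f
    subcase.

    The "much greater / much less than" thresholds are taken with
    strong margins (ratio placed 300x past the subcase threshold,
    producer density 1000x past the sufficiency bound) so the
    asymptotic estimates apply cleanly; this operationalizes the
    standing assumption that the producer starts sufficiently dense.
    """
    alpha, beta, Kc = p.alphaC1S2, p.betaC1S1, p.KC1S2
    if subcase == "II-1":
        c1s, rss = analytic.steady_state(p)
        ks_hat = p.KS2C1 / c1s
        rs0 = 300 * sep * max(1.0, ks_hat - 1.0) * rss
        s1 = max(1000 * sep * Kc * (p.r10 - p.r20) / (alpha * rs0), 1e6)
    elif subcase == "II-3":
        c1s, rss = analytic.steady_state(p)
        kc_hat = Kc / c1s
        rs0 = 0.5 * rss / (sep * (1.0 + kc_hat))
        s1 = 20 * sep * p.r10 * c1s / beta
    elif subcase == "III-1":
        rs0 = 300 * sep * beta / alpha
        s1 = max(1000 * sep * (p.r20 - p.r10) * Kc / (alpha * rs0), 1e6)
    elif subcase == "III-2":
        rs0 = beta / (1.5 * sep * alpha)
        s1 = 20 * sep * p.r10 * Kc / beta
    else:
        raise ValueError(f"unknown subcase {subcase!r}")
    return rs0, s1


def tf_experiment(n_per_subcase: int = 20, seed: int = 0,
                  f_tol: float = 0.05) -> dict:
    """For each tractable subcase, verify that the mechanistic phase
    trace reaches |f| < ``f_tol`` within three times the estimated t_f
    (without dilutions, matching the derivation's setting)."""
    out: dict = {"n_per_subcase": n_per_subcase}
    for subcase in TF_SUBCASES:
        regime = "caseII" if subcase in ("II-1", "II-3") else "caseIII"
        reached = 0
        for k in range(n_per_subcase):
            cfg = generate_regime_config(regime, seed + k)
            p = analytic.SingleMediatorParams.from_config(cfg)
            rs0, s1 = subcase_initial_conditions(p, subcase)
            cfg2 = with_initial_state(cfg, rs0=rs0, total=s1 * (1 + rs0),
                                      dilution=DilutionPolicy("none"))
            tf = analytic.estimate_tf(p, s1, s1 * rs0)
            if tf.subcase != subcase or not tf.sufficient:
                raise RuntimeError(
                    f"initial-condition placement failed: {tf.subcase} vs {subcase}")
            trace = phase_trace(cfg2, 3.0 * tf.t_f)
            reached += int(np.nanmin(np.abs(trace.f)) < f_tol)
        out[f"fraction_{subcase}"] = reached / n_per_subcase
    return out


# ---------------------------------------------------------------------------
# within-model-class parameter recovery
# ---------------------------------------------------------------------------

RECOVERY_FORMS = (
    "linear_lv",
    "logistic_lv",
    "saturable_lv",
    "alternative",
    "divided_simplified",
    "competitive_commensal_lv",
)

_TIGHT = dict(sim_rtol=1e-9, perfect_rms=1e-7, opt_tol=1e-13)


def _ref_sim(spec, init, t_end):
    """Noise-free reference sampled exactly on the fitting grid."""
    return simulate_pairwise(spec, init, t_end, rtol=1e-11, atol=1e-12,
                             t_eval=np.linspace(0.0, t_end, 101))


def _recover_once(form: str, seed: int) -> float:
    """Generate a noise-free trajectory from a known spec, refit the
    same form, and return the worst relative parameter error.

    For the divided-influence form the identifiable (gauge-fixed)
    combinations r/psi and omega/psi are compared, since a common
    rescaling of (r, omega, psi) leaves the dynamics unchanged.
    """
    rng = np.random.default_rng([seed, 7])
    if form == "linear_lv":
        r0 = {"S1": rng.uniform(0.2, 0.5), "S2": rng.uniform(0.1, 0.4)}
        r12 = rng.uniform(3e-9, 1e-8) * rng.choice([-1, 1])
        r21 = rng.uniform(3e-9, 1e-8) * rng.choice([-1, 1])
        true = PairwiseModelSpec(form, ["S1", "S2"], r0,
                                 {("S1", "S2"): {"r": r12}, ("S2", "S1"): {"r": r21}})
        ref = _ref_sim(true, {"S1": 1e6, "S2": 1e6}, 8.0)
        tmpl = PairwiseModelSpec(form, ["S1", "S2"], r0,
                                 {("S1", "S2"): {"r": 0.0}, ("S2", "S1"): {"r": 0.0}})
        fit = fit_spec_params(
            ref, tmpl,
            [Slot(("interactions", "S1<-S2", "r"), -3e-8, 3e-8),
             Slot(("interactions", "S2<-S1", "r"), -3e-8, 3e-8)],
            TrainingWindow(0.0, 8.0), seed=seed, n_starts=3, **_TIGHT)
        est = fit.spec.interactions
        return max(abs(est[("S1", "S2")]["r"] / r12 - 1),
                   abs(est[("S2", "S1")]["r"] / r21 - 1))

    if form == "logistic_lv":
        r0 = {"S1": rng.uniform(0.2, 0.5), "S2": rng.uniform(0.1, 0.4)}
        lam = {k: 10 ** rng.uniform(7, 8)
               for k in (("S1", "S1"), ("S2", "S2"), ("S1", "S2"), ("S2", "S1"))}
        true = PairwiseModelSpec(form, ["S1", "S2"], r0,
                                 {k: {"Lam": v} for k, v in lam.items()})
        ref = _ref_sim(true, {"S1": 1e5, "S2": 1e5}, 60.0)
        tmpl = PairwiseModelSpec(form, ["S1", "S2"], r0,
                                 {k: {"Lam": 1e7} for k in lam})
        fit = fit_spec_params(
            ref, tmpl,
            [Slot(("interactions", f"{a}<-{b}", "Lam"), 5, 10, log10=True)
             for a, b in lam],
            TrainingWindow(0.0, 60.0), seed=seed, n_starts=3, **_TIGHT)
        return max(abs(fit.spec.interactions[k]["Lam"] / v - 1)
                   for k, v in lam.items())

    if form == "saturable_lv":
        r0 = {"S1": rng.uniform(0.3, 0.5), "S2": rng.uniform(0.1, 0.3)}
        r21 = rng.uniform(0.1, 0.5) * rng.choice([-1, 1])
        K21 = 10 ** rng.uniform(6.5, 8)
        true = PairwiseModelSpec(form, ["S1", "S2"], r0,
                                 {("S2", "S1"): {"r": r21, "K": K21}})
        ref = _ref_sim(true, {"S1": 1e6, "S2": 1e6}, 16.0)
        tmpl = PairwiseModelSpec(form, ["S1", "S2"], r0,
                                 {("S2", "S1"): {"r": 0.1, "K": 1e6}})
        fit = fit_spec_params(
            ref, tmpl,
            [Slot(("interactions", "S2<-S1", "r"), -3, 3),
             Slot(("interactions", "S2<-S1", "K"), 2, 9, log10=True)],
            TrainingWindow(0.0, 16.0), seed=seed, n_starts=4,
            species=["S2"], **_TIGHT)
        est = fit.spec.interactions[("S2", "S1")]
        return max(abs(est["r"] / r21 - 1), abs(est["K"] / K21 - 1))

    if form == "alternative":
        r0 = {"S1": rng.uniform(0.3, 0.5), "S2": rng.uniform(0.1, 0.3)}
        r = rng.uniform(0.2, 0.6)
        om = rng.uniform(0.3, 1.2)
        true = PairwiseModelSpec(form, ["S1", "S2"], r0,
                                 {("S2", "S1"): {"r": r, "omega": om, "psi": 1.0}})
        ref = _ref_sim(true, {"S1": 1e6, "S2": 1e6}, 20.0)
        tmpl = PairwiseModelSpec(form, ["S1", "S2"], r0,
                                 {("S2", "S1"): {"r": 0.2, "omega": 0.0, "psi": 1.0}})
        fit = fit_spec_params(
            ref, tmpl,
            [Slot(("interactions", "S2<-S1", "r"), -3, 3),
             Slot(("interactions", "S2<-S1", "omega"), -5, 5)],
            TrainingWindow(0.0, 20.0), seed=seed, n_starts=6,
            species=["S2"], **_TIGHT)
        est = fit.spec.interactions[("S2", "S1")]
        return max(abs(est["r"] / r - 1), abs(est["omega"] / om - 1))

    if form == "divided_simplified":
        r0 = {"S1": rng.uniform(0.3, 0.5), "S2": rng.uniform(0.1, 0.3)}
        rho = rng.uniform(0.05, 0.4)
        true = PairwiseModelSpec(form, ["S1", "S2"], r0,
                                 {("S2", "S1"): {"rho": rho}})
        ref = _ref_sim(true, {"S1": 1e6, "S2": 2e6}, 20.0)
        tmpl = PairwiseModelSpec(form, ["S1", "S2"], r0,
                                 {("S2", "S1"): {"rho": 0.1}})
        fit = fit_spec_params(
            ref, tmpl, [Slot(("interactions", "S2<-S1", "rho"), -3, 3)],
            TrainingWindow(0.0, 20.0), seed=seed, n_starts=3,
            species=["S2"], **_TIGHT)
        return abs(fit.spec.interactions[("S2", "S1")]["rho"] / rho - 1)

    if form == "competitive_commensal_lv":
        bd = {"S1": (rng.uniform(0.2, 0.5), 0.05),
              "S2": (rng.uniform(0.1, 0.3), 0.05)}
        l11 = 10 ** rng.uniform(7.0, 7.5)
        l22 = 10 ** rng.uniform(7.0, 7.5)
        lam = {("S1", "S1"): l11, ("S2", "S2"): l22,
               ("S1", "S2"): l22 * 10 ** rng.uniform(0.3, 0.8),
               ("S2", "S1"): l11 * 10 ** rng.uniform(0.3, 0.8)}
        r21 = 10 ** rng.uniform(-8.3, -7.7)
        inter = {k: {"Lam": v} for k, v in lam.items()}
        inter[("S2", "S1")]["r"] = r21
        true = PairwiseModelSpec(form, ["S1", "S2"], {"S1": 0.0, "S2": 0.0},
                                 inter, birth_death=bd)
        ref = _ref_sim(true, {"S1": 1e5, "S2": 1e5}, 80.0)
        tmpl_inter = {k: {"Lam": 1e7} for k in lam}
        tmpl_inter[("S2", "S1")]["r"] = 1e-9
        tmpl = PairwiseModelSpec(form, ["S1", "S2"], {"S1": 0.0, "S2": 0.0},
                                 tmpl_inter, birth_death=bd)
        fit = fit_spec_params(
            ref, tmpl,
            [Slot(("interactions", f"{a}<-{b}", "Lam"), 5, 10, log10=True)
             for a, b in lam] +
            [Slot(("interactions", "S2<-S1", "r"), -10, -7, log10=True)],
            TrainingWindow(0.0, 80.0), seed=seed, n_starts=7, **_TIGHT)
        errs = [abs(fit.spec.interactions[k]["Lam"] / v - 1) for k, v in lam.items()]
        errs.append(abs(fit.spec.interactions[("S2", "S1")]["r"] / r21 - 1))
        return max(errs)

    raise ValueError(f"unknown form {form!r}")


def recovery_experiment(forms: Optional[Sequence[str]] = None,
                        n_per_form: int = 20, seed: int = 0) -> dict:
    """Noise-free self-consistency: parameters of every pairwise form
    are recovered from data generated by that same form."""
    out: dict = {"n_per_form": n_per_form}
    for form in forms or RECOVERY_FORMS:
        errs = [_recover_once(form, seed + k) for k in range(n_per_form)]
        out[f"max_err_pct_{form}"] = float(np.max(errs)) * 100
    return out
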