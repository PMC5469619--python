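"""The Lotka-Volterra pairwise model family.

Every form expresses the growth rate of a focal species as its basal
fitness plus additive fitness-effect terms:

* linear:      dSi/dt = (ri0 + sum_j rij Sj) Si
* logistic:    dSi/dt = ri0 (1 - sum_j Sj/Lam_ij) Si
* saturable:   dSi/dt = (ri0 + sum_j rij Sj/(Kij + Sj)) Si
* alternative (divided influence, consumable mediator):
               dS2/dt = (r20 + r21 S1/(omega S1 + psi S2)) S2
* divided_simplified (omega = 0):
               dS2/dt = (r20 + rho S1/S2) S2
* competitive_commensal:
               dS1/dt = b10 (1 - S1/Lam11 - S2/Lam12) S1 - d1 S1
               dS2/dt = (b20 + r21 S1)(1 - S1/Lam21 - S2/Lam22) S2 - d2 S2

Pairwise models integrate under the same dilution protocol and
extinction rules as mechanistic models so that D-bar comparisons are
like-for-like.  Multispecies models are assembled from two-species
components with additive combination of the fitness-effect terms; mixed
forms per pair are allowed, since different interaction mechanisms call
for different forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from ._engine import integrate_with_dilutions
from .config import ConfigError, DilutionPolicy, PairwiseModelSpec
from .mechanistic import Trajectory

__all__ = [
    "build_pairwise_rhs",
    "linear_lv_rhs",
    "logistic_lv_rhs",
    "saturable_lv_rhs",
    "alternative_rhs",
    "divided_simplified_rhs",
    "competitive_commensal_lv_rhs",
    "assemble_multispecies",
    "MultiPairwiseModel",
    "simulate_pairwise",
]


# ---------------------------------------------------------------------------
# fitness-effect terms
# ---------------------------------------------------------------------------


# per-term cap on |fitness effect| (1/h); far beyond any biological growth
# rate, it only tames the singular corners the divided-influence forms have
# (denominator crossing zero).  The cap is applied smoothly (tanh) and the
# denominator is regularized so the right-hand side stays C^1 there --
# otherwise the solver chatters on the singular manifold.
_EFFECT_CAP = 50.0
_EFFECT_LIN = 25.0  # identity below this; smooth saturation above


def _smooth_cap(val: float) -> float:
    a = val if val >= 0 else -val
    if a <= _EFFECT_LIN:
        return val
    span = _EFFECT_CAP - _EFFECT_LIN
    x = (a - _EFFECT_LIN) / span
    out = _EFFECT_LIN + span * (math.tanh(x) if x < 25 else 1.0)
    return out if val >= 0 else -out


def _term_closure(form: str, focal: int, infl: int, params: dict, r0_focal: float,
                  s_ext: float) -> Callable:
    """Return g(y) -> fitness contribution of influencer ``infl`` on ``focal``."""
    if form == "linear_lv":
        r = params["r"]
        return lambda y: r * y[infl]
    if form == "logistic_lv":
        lam = params["Lam"]
        return lambda y: -r0_focal * y[infl] / lam
    if form == "saturable_lv":
        r, K = params["r"], params["K"]
        return lambda y: r * y[infl] / (K + y[infl])
    if form == "alternative":
        r, omega, psi = params["r"], params["omega"], params["psi"]

        def g(y):
            scale = abs(omega) * y[infl] + psi * abs(y[focal])
            if y[infl] == 0.0 or scale == 0.0:
                return 0.0
            denom = omega * y[infl] + psi * y[focal]
            delta = 3e-4 * scale
            raw = r * y[infl] * denom / (denom * denom + delta * delta)
            return _smooth_cap(raw)

        return g
    if form == "divided_simplified":
        rho = params["rho"]

        def g_div(y):
            return _smooth_cap(rho * y[infl] / max(y[focal], s_ext))

        return g_div
    raise ConfigError(f"form {form!r} has no additive fitness-effect term")


def _additive_rhs(spec: PairwiseModelSpec, s_ext: float) -> Callable:
    idx = {sid: i for i, sid in enumerate(spec.species)}
    r0 = np.array([spec.r0[sid] for sid in spec.species])
    terms = [
        (idx[focal], _term_closure(spec.form, idx[focal], idx[infl], params,
                                   spec.r0[focal], s_ext))
        for (focal, infl), params in spec.interactions.items()
    ]

    def rhs(t, y):
        growth = r0.copy()
        for i, g in terms:
            growth[i] += g(y)
        return growth * y

    return rhs


def _competitive_commensal_rhs(spec: PairwiseModelSpec) -> Callable:
    idx = {sid: i for i, sid in enumerate(spec.species)}
    n = len(spec.species)
    b0 = np.array([spec.birth_death[sid][0] for sid in spec.species])
    d = np.array([spec.birth_death[sid][1] for sid in spec.species])
    inv_lam = np.zeros((n, n))
    boost = []  # (focal, influencer, r)
    for (focal, infl), params in spec.interactions.items():
        if "Lam" in params:
            inv_lam[idx[focal], idx[infl]] = 1.0 / params["Lam"]
        if "r" in params:
            boost.append((idx[focal], idx[infl], params["r"]))

    def rhs(t, y):
        crowding = 1.0 - inv_lam @ y
        birth = b0.copy()
        for i, j, r in boost:
            birth[i] += r * y[j]
        return (birth * crowding - d) * y

    return rhs


def build_pairwise_rhs(spec: PairwiseModelSpec, s_ext: float = 1e-2) -> Callable:
    """Derivative contract for any pairwise form: f(t, y) -> dy/dt."""
    if spec.form == "competitive_commensal_lv":
        return _competitive_commensal_rhs(spec)
    return _additive_rhs(spec, s_ext)


def _form_checked(spec: PairwiseModelSpec, form: str) -> Callable:
    if spec.form != form:
        raise ConfigError(f"expected form {form!r}, got {spec.form!r}")
    return build_pairwise_rhs(spec)


def linear_lv_rhs(spec: PairwiseModelSpec) -> Callable:
    return _form_checked(spec, "linear_lv")


def logistic_lv_rhs(spec: PairwiseModelSpec) -> Callable:
    return _form_checked(spec, "logistic_lv")


def saturable_lv_rhs(spec: PairwiseModelSpec) -> Callable:
    return _form_checked(spec, "saturable_lv")


def alternative_rhs(spec: PairwiseModelSpec) -> Callable:
    return _form_checked(spec, "alternative")


def divided_simplified_rhs(spec: PairwiseModelSpec) -> Callable:
    return _form_checked(spec, "divided_simplified")


def competitive_commensal_lv_rhs(spec: PairwiseModelSpec) -> Callable:
    return _form_checked(spec, "competitive_commensal_lv")


# ---------------------------------------------------------------------------
# multispecies assembly
# ---------------------------------------------------------------------------


@dataclass
class MultiPairwiseModel:
    """N-species pairwise model assembled from two-species components.

    dSi/dt = (ri0 + sum_j f_ij(Sj[, Si])) Si with additive combination of
    the per-pair fitness-effect terms.
    """

    species: list
    r0: dict
    pair_specs: list = field(default_factory=list)

    def rhs(self, s_ext: float = 1e-2) -> Callable:
        idx = {sid: i for i, sid in enumerate(self.species)}
        r0 = np.array([self.r0[sid] for sid in self.species])
        terms = []
        for spec in self.pair_specs:
            for (focal, infl), params in spec.interactions.items():
                terms.append(
                    (idx[focal],
                     _term_closure(spec.form, idx[focal], idx[infl], params,
                                   spec.r0[focal], s_ext))
                )

        def f(t, y):
            growth = r0.copy()
            for i, g in terms:
                growth[i] += g(y)
            return growth * y

        return f


def assemble_multispecies(
    pair_specs: Sequence[PairwiseModelSpec], species: Sequence[str]
) -> MultiPairwiseModel:
    """Combine fitted two-species pairwise models into an N-species model.

    Basal fitnesses shared across pair specs must agree; a conflict is an
    assembly error.  The competitive-commensal form is multiplicative and
    cannot be combined additively with other pairs.
    """
    r0: dict = {}
    for spec in pair_specs:
        if spec.form == "competitive_commensal_lv":
            raise ConfigError(
                "competitive_commensal_lv components cannot be assembled additively"
            )
        for sid, val in spec.r0.items():
            if sid not in species:
                raise ConfigError(f"pair spec references species {sid!r} not in assembly")
            if sid in r0 and not math.isclose(r0[sid], val, rel_tol=1e-9, abs_tol=1e-12):
                raise ConfigError(
                    f"conflicting basal fitness for {sid!r}: {r0[sid]} vs {val}"
                )
            r0[sid] = val
    missing = [sid for sid in species if sid not in r0]
    if missing:
        raise ConfigError(f"no basal fitness provided for species {missing}")
    return MultiPairwiseModel(species=list(species), r0=r0, pair_specs=list(pair_specs))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_pairwise(
    model,
    initial_densities: dict,
    t_end: float,
    dilution: Optional[DilutionPolicy] = None,
    s_ext: float = 1e-2,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    t0: float = 0.0,
    max_cycles: int = 100_000,
    t_eval=None,
) -> Trajectory:
    """Integrate a pairwise model (spec or assembled) under the same
    dilution protocol as the mechanistic simulator.

    ``t0`` places the start on the reference clock, e.g. when restarting
    from a mechanistic state at the opening of a training window.
    """
    if isinstance(model, MultiPairwiseModel):
        species = model.species
        rhs = model.rhs(s_ext)
        form = "assembled"
    else:
        species = model.species
        rhs = build_pairwise_rhs(model, s_ext)
        form = model.form
    y0 = np.array([initial_densities[sid] for sid in species], dtype=float)
    t, y, dil = integrate_with_dilutions(
        rhs, y0, t_end, len(species), dilution, s_ext,
        rtol=rtol, atol=atol, method=method, t0=t0, max_cycles=max_cycles,
        t_eval=t_eval,
    )
    return Trajectory(
        times=t,
        species_ids=list(species),
        species=y,
        mediator_ids=[],
        mediators=np.empty((0, len(t))),
        dilution_times=dil,
        provenance={"model": form, "solver": {"method": method, "rtol": rtol, "atol": atol}},
    )
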