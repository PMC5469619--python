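"""Mechanistic community dynamics: species plus explicit chemical mediators.

This module turns a :class:`~medlv.config.CommunityConfig` into an ODE
right-hand side and integrates it under the turbidostat dilution
protocol.  Mechanistic trajectories are the reference dynamics against
which every pairwise model in the package is trained and scored.

Model structure, per mediator kind:

* reusable:    dC/dt = supply + sum_j beta_Cj * Sj
* consumable:  additionally - sum_j alpha_Cj * C/(C + K_Cj) * Sj
  (kinetic consumption), or - alpha_Cj * g_j(C, ...) * Sj where g_j is
  the consumer's realized mediator-dependent growth term (yield-coupled
  consumption, used by the competitive-commensal community).

Species growth rate = basal fitness + additive saturable (or linear)
fitness effects from incoming mediator links, plus an optional
dual-resource co-limitation term when two essential resources jointly
limit growth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from ._engine import IntegrationError, integrate_with_dilutions
from .config import CommunityConfig, ConfigError

__all__ = [
    "Trajectory",
    "build_rhs",
    "simulate",
    "phase_trace",
    "PhaseTrace",
    "write_trajectory",
    "read_trajectory",
    "IntegrationError",
]


# ---------------------------------------------------------------------------
# trajectory container
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Time series of species densities and mediator concentrations.

    ``species`` has shape ``(n_species, n_times)`` in cells/ml;
    ``mediators`` has shape ``(n_mediators, n_times)``.
    """

    times: np.ndarray
    species_ids: list
    species: np.ndarray
    mediator_ids: list = field(default_factory=list)
    mediators: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    dilution_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    provenance: dict = field(default_factory=dict)

    def density(self, sid: str) -> np.ndarray:
        return self.species[self.species_ids.index(sid)]

    def mediator(self, mid: str) -> np.ndarray:
        return self.mediators[self.mediator_ids.index(mid)]

    def total(self) -> np.ndarray:
        return self.species.sum(axis=0)

    def fractions(self) -> np.ndarray:
        tot = self.total()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.species / tot, 0.0)

    def log10_density_at(self, sid: str, t: np.ndarray, floor: float) -> np.ndarray:
        """Floored log10 density interpolated to times ``t``.

        Interpolation is shape-preserving cubic (PCHIP) in log density,
        which is exact for exponential growth between solver steps and
        does not overshoot at dilution kinks or extinction floors.
        """
        from scipy.interpolate import PchipInterpolator

        s = np.clip(self.density(sid), floor, None)
        tt, idx = np.unique(self.times, return_index=True)
        if len(tt) < 3:
            return np.interp(t, self.times, np.log10(s))
        return PchipInterpolator(tt, np.log10(s[idx]), extrapolate=True)(t)

    def state_at(self, t: float) -> dict:
        """Species densities (linear interpolation in log space) at time t."""
        out = {}
        for sid in self.species_ids:
            s = self.density(sid)
            if np.all(s <= 0):
                out[sid] = 0.0
            else:
                floor = max(np.min(s[s > 0]) * 1e-6, 1e-300)
                out[sid] = float(10 ** self.log10_density_at(sid, np.array([t]), floor)[0])
                if np.interp(t, self.times, s) == 0.0:
                    out[sid] = 0.0
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, sid in enumerate(self.species_ids):
            rows.append(
                pd.DataFrame(
                    {"time": self.times, "variable": sid, "kind": "species",
                     "value": self.species[i]}
                )
            )
        for i, mid in enumerate(self.mediator_ids):
            rows.append(
                pd.DataFrame(
                    {"time": self.times, "variable": mid, "kind": "mediator",
                     "value": self.mediators[i]}
                )
            )
        return pd.concat(rows, ignore_index=True)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a tidy CSV plus a JSON metadata sidecar (``<path>.meta.json``)."""
    path = Path(path)
    traj.to_frame().to_csv(path, index=False)
    meta = {
        "species_ids": list(traj.species_ids),
        "mediator_ids": list(traj.mediator_ids),
        "dilution_times": [float(t) for t in traj.dilution_times],
        "provenance": traj.provenance,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    times = np.unique(df["time"].to_numpy())
    species = np.array(
        [df[df["variable"] == sid]["value"].to_numpy() for sid in meta["species_ids"]]
    )
    mediators = np.array(
        [df[df["variable"] == mid]["value"].to_numpy() for mid in meta["mediator_ids"]]
    )
    if mediators.size == 0:
        mediators = np.empty((0, len(times)))
    return Trajectory(
        times=times,
        species_ids=meta["species_ids"],
        species=species,
        mediator_ids=meta["mediator_ids"],
        mediators=mediators,
        dilution_times=np.asarray(meta["dilution_times"]),
        provenance=meta["provenance"],
    )


# ---------------------------------------------------------------------------
# right-hand side construction
# ---------------------------------------------------------------------------


def build_rhs(config: CommunityConfig) -> Callable:
    """Compile the community ODE right-hand side.

    State vector layout: species densities first (config order), then
    mediator concentrations.  Returns ``f(t, y) -> dy/dt``.
    """
    sids = config.species_ids
    mids = config.mediator_ids
    si = {s: i for i, s in enumerate(sids)}
    mi = {m: i for i, m in enumerate(mids)}
    ns, nm = len(sids), len(mids)

    r0 = np.array([s.r0 for s in config.species])
    supply = np.array([m.supply for m in config.mediators]) if nm else np.empty(0)

    intra = [
        (si[s.id], s.intra.r, s.intra.K) for s in config.species if s.intra is not None
    ]

    simple_effects = []  # (target, mediator, r, K, saturable?)
    colim_links: dict = {}  # target -> list of (mediator, r, K)
    productions = []  # (mediator, producer, beta)
    kinetic_cons = []  # (mediator, consumer, alpha, Kc)
    yield_cons = []  # (mediator, consumer, alpha)

    for ln in config.links:
        m = mi[ln.mediator]
        if ln.producer is not None and ln.beta > 0:
            productions.append((m, si[ln.producer], ln.beta))
        if ln.consumer is not None:
            if ln.consumption == "kinetic":
                kinetic_cons.append((m, si[ln.consumer], ln.alpha, ln.K_consume))
            else:
                yield_cons.append((m, si[ln.consumer], ln.alpha))
        if ln.target is not None:
            if ln.co_limitation:
                colim_links.setdefault(si[ln.target], []).append(
                    (m, ln.r_effect, ln.K_effect)
                )
            else:
                simple_effects.append(
                    (si[ln.target], m, ln.r_effect, ln.K_effect,
                     ln.effect_form == "saturable")
                )

    colim_groups = []  # (target, r, m1, K1, m2, K2)
    for tgt, entries in colim_links.items():
        if len(entries) != 2:
            raise ConfigError("co-limitation requires exactly two links per target")
        (m1, r, K1), (m2, _r2, K2) = entries
        colim_groups.append((tgt, r, m1, K1, m2, K2))

    def rhs(t, y):
        s = y[:ns]
        c = y[ns:]
        growth = r0.copy()
        gbasis = np.zeros((ns, nm)) if nm else None

        for i, r, K in intra:
            growth[i] += r * s[i] / (s[i] + K)

        for tgt, m, r, K, saturable in simple_effects:
            cm = c[m]
            term = r * cm / (cm + K) if saturable else r * cm / K
            growth[tgt] += term
            gbasis[tgt, m] += term

        for tgt, r, m1, K1, m2, K2 in colim_groups:
            c1h = c[m1] / K1
            c2h = c[m2] / K2
            denom = c1h + c2h
            if denom > 0:
                joint = r * (c1h * c2h / denom) * (1.0 / (c1h + 1.0) + 1.0 / (c2h + 1.0))
            else:
                joint = 0.0
            growth[tgt] += joint
            gbasis[tgt, m1] = joint
            gbasis[tgt, m2] = joint

        ds = growth * s
        if nm == 0:
            return ds

        dc = supply.copy()
        for m, p, beta in productions:
            dc[m] += beta * s[p]
        for m, con, alpha, Kc in kinetic_cons:
            cm = c[m]
            dc[m] -= alpha * cm / (cm + Kc) * s[con]
        for m, con, alpha in yield_cons:
            dc[m] -= alpha * gbasis[con, m] * s[con]
        return np.concatenate([ds, dc])

    return rhs


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate(
    config: CommunityConfig,
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    t_eval=None,
) -> Trajectory:
    """Integrate the mechanistic model to ``t_end`` hours.

    Dilution events multiply all species (and mediators when
    ``dilute_mediators``) by ``reset_total/threshold``; species below the
    extinction floor are zeroed at dilution events.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    rhs = build_rhs(config)
    sids = config.species_ids
    mids = config.mediator_ids
    y0 = np.array(
        [config.initial_densities[s] for s in sids]
        + [config.mediator_spec(m).C0 for m in mids]
    )
    t, y, dil = integrate_with_dilutions(
        rhs, y0, t_end, len(sids), config.dilution, config.S_ext,
        rtol=rtol, atol=atol, method=method, t_eval=t_eval,
    )
    return Trajectory(
        times=t,
        species_ids=sids,
        species=y[: len(sids)],
        mediator_ids=mids,
        mediators=y[len(sids):],
        dilution_times=dil,
        provenance={
            "config_hash": config.config_hash(),
            "solver": {"method": method, "rtol": rtol, "atol": atol},
            "t_end": t_end,
        },
    )


# ---------------------------------------------------------------------------
# phase-plane trace for the single-consumable-mediator topology
# ---------------------------------------------------------------------------


@dataclass
class PhaseTrace:
    """Community trajectory in mediator/species-ratio phase space.

    ``C1`` and ``RS`` are the raw mediator concentration and consumer-to-
    producer ratio; when the community falls in the coexistence regime
    they are also provided scaled by their steady-state values
    (``C1_hat``, ``RS_hat``).  ``f`` is the scaled net mediator
    production rate 1 - (alpha/beta) * C1/(C1+K_C1S2) * RS whose zero
    contour is the isocline on which mediator elimination is exact.
    """

    times: np.ndarray
    C1: np.ndarray
    RS: np.ndarray
    f: np.ndarray
    case: str
    C1_hat: Optional[np.ndarray] = None
    RS_hat: Optional[np.ndarray] = None


def phase_trace(
    config: CommunityConfig,
    t_end: float,
    traj: Optional[Trajectory] = None,
    **solver_opts,
) -> PhaseTrace:
    """Trace (C1, RS) along a mechanistic trajectory.

    Requires the canonical two-species, single-mediator commensal
    topology (producer S1, consumer/beneficiary S2).  For coexistence
    communities the scaled coordinates are attached.
    """
    from .analytic import SingleMediatorParams, classify_case, steady_state

    p = SingleMediatorParams.from_config(config)
    if traj is None:
        traj = simulate(config, t_end, **solver_opts)
    c1 = traj.mediator(p.mediator_id)
    s1 = traj.density(p.producer_id)
    s2 = traj.density(p.consumer_id)
    with np.errstate(divide="ignore", invalid="ignore"):
        rs = np.where(s1 > 0, s2 / np.where(s1 > 0, s1, 1.0), np.inf)
    if p.alphaC1S2 is not None and p.betaC1S1 > 0:
        with np.errstate(invalid="ignore"):
            f = 1.0 - (p.alphaC1S2 / p.betaC1S1) * c1 / (c1 + p.KC1S2) * rs
    else:
        f = np.full_like(c1, np.nan)
    case = classify_case(p)
    trace = PhaseTrace(times=traj.times, C1=c1, RS=rs, f=f, case=case)
    if case == "II":
        c1_star, rs_star = steady_state(p)
        if c1_star > 0 and rs_star > 0:
            trace.C1_hat = c1 / c1_star
            trace.RS_hat = rs / rs_star
    return trace
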