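"""Domain types for chemically mediated microbial communities.

A :class:`CommunityConfig` is the full parameterization of a mechanistic
community: species with basal net growth rates, chemical mediators
(reusable or consumable), influence links that wire production,
consumption and fitness effects together, initial densities, and the
dilution (turbidostat) protocol.  A :class:`PairwiseModelSpec` describes
one member of the Lotka-Volterra pairwise model family together with its
parameter set.

Units are fixed package-wide: time in hours, species densities in
cells/ml, mediator concentrations in arbitrary concentration units (only
ratios to half-saturation constants matter), production rates in
concentration*ml/cell/hour.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import yaml

__all__ = [
    "ConfigError",
    "IntraSpec",
    "BirthDeathSpec",
    "SpeciesSpec",
    "MediatorSpec",
    "InfluenceLink",
    "DilutionPolicy",
    "CommunityConfig",
    "PairwiseModelSpec",
    "PAIRWISE_FORMS",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    """A community or model specification violates its invariants."""


def _plainify(obj):
    """Recursively convert numpy scalars to plain Python types."""
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return type(obj)(_plainify(v) for v in obj)
    if hasattr(obj, "item") and not isinstance(obj, (str, bytes)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# species and mediators
# ---------------------------------------------------------------------------


@dataclass
class IntraSpec:
    """Saturable intra-species fitness effect: r * S/(S + K)."""

    r: float  # maximal intra-species fitness effect, per hour
    K: float  # half-saturation density, cells/ml

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ConfigError(f"IntraSpec.K must be > 0, got {self.K}")


@dataclass
class BirthDeathSpec:
    """Split of the net growth rate into birth and death components.

    Used by the competitive-commensal pairwise form, where the birth rate
    saturates with crowding while death proceeds at a constant rate.
    """

    b0: float  # maximal birth rate at vanishing density, per hour
    d: float  # constant death rate, per hour

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ConfigError(f"BirthDeathSpec.d must be >= 0, got {self.d}")


@dataclass
class SpeciesSpec:
    id: str
    r0: float  # basal fitness: net growth rate in isolation, per hour
    intra: Optional[IntraSpec] = None
    birth_death: Optional[BirthDeathSpec] = None


@dataclass
class MediatorSpec:
    """A chemical interaction mediator.

    ``kind`` is ``"reusable"`` (acts without being depleted, e.g. a
    signalling molecule) or ``"consumable"`` (depleted by its consumers,
    e.g. a metabolite).  ``supply`` is an optional constant environmental
    supply rate (concentration/hour).
    """

    id: str
    kind: str
    C0: float = 0.0
    supply: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("reusable", "consumable"):
            raise ConfigError(
                f"MediatorSpec.kind must be 'reusable' or 'consumable', got {self.kind!r}"
            )
        if self.C0 < 0:
            raise ConfigError(f"MediatorSpec.C0 must be >= 0, got {self.C0}")
        if self.supply < 0:
            raise ConfigError(f"MediatorSpec.supply must be >= 0, got {self.supply}")


@dataclass
class InfluenceLink:
    """One production / consumption / fitness-effect wiring of a mediator.

    Any subset of the three roles may be present on a single link; the
    mechanistic right-hand side aggregates over all links of a mediator.

    Production: mediator is released by ``producer`` at rate ``beta`` per
    producer cell.

    Consumption: ``consumer`` removes the mediator.  In ``"kinetic"``
    mode removal follows saturable (Monod) kinetics with maximal rate
    ``alpha`` and half-saturation ``K_consume``.  In ``"yield"`` mode
    ``alpha`` is the amount consumed per new consumer cell, so removal is
    coupled to the consumer's realized mediator-dependent growth term.

    Fitness effect: the mediator changes the growth rate of ``target`` by
    ``r_effect * C/(C + K_effect)`` (``effect_form="saturable"``) or
    ``r_effect * C/K_effect`` (``effect_form="linear"``).  Links with
    ``co_limitation=True`` and a common target are combined into the
    dual-resource co-limitation term (both resources must be present for
    growth) with a shared coefficient ``r_effect``.
    """

    mediator: str
    producer: Optional[str] = None
    beta: float = 0.0
    consumer: Optional[str] = None
    alpha: float = 0.0
    K_consume: Optional[float] = None
    consumption: str = "kinetic"
    target: Optional[str] = None
    r_effect: float = 0.0
    K_effect: Optional[float] = None
    effect_form: str = "saturable"
    co_limitation: bool = False

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ConfigError(f"InfluenceLink.beta must be >= 0, got {self.beta}")
        if self.alpha < 0:
            raise ConfigError(f"InfluenceLink.alpha must be >= 0, got {self.alpha}")
        if self.consumption not in ("kinetic", "yield"):
            raise ConfigError(
                f"InfluenceLink.consumption must be 'kinetic' or 'yield', got {self.consumption!r}"
            )
        if self.effect_form not in ("saturable", "linear"):
            raise ConfigError(
                f"InfluenceLink.effect_form must be 'saturable' or 'linear', got {self.effect_form!r}"
            )
        if self.consumer is not None and self.consumption == "kinetic":
            if self.K_consume is None or self.K_consume <= 0:
                raise ConfigError(
                    f"InfluenceLink.K_consume must be > 0 for kinetic consumption of "
                    f"{self.mediator!r}, got {self.K_consume}"
                )
        if self.target is not None:
            if self.K_effect is None or self.K_effect <= 0:
                raise ConfigError(
                    f"InfluenceLink.K_effect must be > 0 for a fitness effect of "
                    f"{self.mediator!r} on {self.target!r}, got {self.K_effect}"
                )


@dataclass
class DilutionPolicy:
    """Turbidostat protocol: whenever the total population reaches
    ``threshold`` the community is diluted back to ``reset_total``;
    mediators are rescaled by the same factor when ``dilute_mediators``.
    """

    mode: str = "none"
    threshold: float = 0.0
    reset_total: float = 0.0
    dilute_mediators: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("turbidostat", "none"):
            raise ConfigError(
                f"DilutionPolicy.mode must be 'turbidostat' or 'none', got {self.mode!r}"
            )
        if self.mode == "turbidostat":
            if self.reset_total <= 0:
                raise ConfigError(
                    f"DilutionPolicy.reset_total must be > 0, got {self.reset_total}"
                )
            if self.threshold <= self.reset_total:
                raise ConfigError(
                    "DilutionPolicy.threshold must exceed reset_total "
                    f"(threshold={self.threshold}, reset_total={self.reset_total})"
                )


@dataclass
class CommunityConfig:
    species: list = field(default_factory=list)
    mediators: list = field(default_factory=list)
    links: list = field(default_factory=list)
    initial_densities: dict = field(default_factory=dict)
    dilution: DilutionPolicy = field(default_factory=DilutionPolicy)
    S_ext: float = 1e-2  # extinction floor, cells/ml

    # -- validation --------------------------------------------------------

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        sids = [s.id for s in self.species]
        mids = [m.id for m in self.mediators]
        if len(set(sids)) != len(sids):
            raise ConfigError(f"duplicate species ids: {sids}")
        if len(set(mids)) != len(mids):
            raise ConfigError(f"duplicate mediator ids: {mids}")
        if self.S_ext <= 0:
            raise ConfigError(f"S_ext must be > 0, got {self.S_ext}")
        for sid, dens in self.initial_densities.items():
            if sid not in sids:
                raise ConfigError(f"initial_densities references unknown species {sid!r}")
            if dens < 0:
                raise ConfigError(f"initial density of {sid!r} must be >= 0, got {dens}")
        for sid in sids:
            if sid not in self.initial_densities:
                raise ConfigError(f"initial density missing for species {sid!r}")
        kind = {m.id: m.kind for m in self.mediators}
        consumed = set()
        for ln in self.links:
            if ln.mediator not in mids:
                raise ConfigError(f"link references unknown mediator {ln.mediator!r}")
            for role, sid in (
                ("producer", ln.producer),
                ("consumer", ln.consumer),
                ("target", ln.target),
            ):
                if sid is not None and sid not in sids:
                    raise ConfigError(
                        f"link {role} references unknown species {sid!r}"
                    )
            if ln.consumer is not None:
                if kind[ln.mediator] == "reusable":
                    raise ConfigError(
                        f"reusable mediator {ln.mediator!r} cannot have a consumption term"
                    )
                consumed.add(ln.mediator)
        for m in self.mediators:
            if m.kind == "consumable" and m.id not in consumed:
                raise ConfigError(
                    f"consumable mediator {m.id!r} has no consumer link"
                )
        # co-limitation groups: exactly two links per target, shared r_effect
        groups: dict = {}
        for ln in self.links:
            if ln.co_limitation and ln.target is not None:
                groups.setdefault(ln.target, []).append(ln)
        for tgt, lns in groups.items():
            if len(lns) != 2:
                raise ConfigError(
                    f"co_limitation on target {tgt!r} needs exactly two links, got {len(lns)}"
                )
            if lns[0].r_effect != lns[1].r_effect:
                raise ConfigError(
                    f"co_limitation links on target {tgt!r} must share r_effect"
                )

    # -- convenience -------------------------------------------------------

    @property
    def species_ids(self) -> list:
        return [s.id for s in self.species]

    @property
    def mediator_ids(self) -> list:
        return [m.id for m in self.mediators]

    def species_spec(self, sid: str) -> SpeciesSpec:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def mediator_spec(self, mid: str) -> MediatorSpec:
        for m in self.mediators:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def links_for_mediator(self, mid: str) -> list:
        return [ln for ln in self.links if ln.mediator == mid]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        # drop optional None/defaults for a tidy file
        for ln in d["links"]:
            for k in [k for k, v in ln.items() if v is None]:
                del ln[k]
        for sp in d["species"]:
            for k in [k for k, v in sp.items() if v is None]:
                del sp[k]
        return _plainify(d)

    @classmethod
    def from_dict(cls, d: dict) -> "CommunityConfig":
        try:
            species = [
                SpeciesSpec(
                    id=s["id"],
                    r0=float(s["r0"]),
                    intra=IntraSpec(**s["intra"]) if s.get("intra") else None,
                    birth_death=(
                        BirthDeathSpec(**s["birth_death"]) if s.get("birth_death") else None
                    ),
                )
                for s in d.get("species", [])
            ]
            mediators = [MediatorSpec(**m) for m in d.get("mediators", [])]
            links = [InfluenceLink(**ln) for ln in d.get("links", [])]
            dilution = DilutionPolicy(**d.get("dilution", {}))
        except TypeError as exc:  # unknown field names
            raise ConfigError(f"unrecognized field in config: {exc}") from exc
        return cls(
            species=species,
            mediators=mediators,
            links=links,
            initial_densities={k: float(v) for k, v in d.get("initial_densities", {}).items()},
            dilution=dilution,
            S_ext=float(d.get("S_ext", 1e-2)),
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# pairwise model specifications
# ---------------------------------------------------------------------------

PAIRWISE_FORMS = (
    "linear_lv",
    "logistic_lv",
    "saturable_lv",
    "alternative",
    "divided_simplified",
    "competitive_commensal_lv",
)

# required parameter keys of an interaction entry, per form
_FORM_KEYS = {
    "linear_lv": {"r"},
    "logistic_lv": {"Lam"},
    "saturable_lv": {"r", "K"},
    "alternative": {"r", "omega", "psi"},
    "divided_simplified": {"rho"},
    "competitive_commensal_lv": {"Lam"},  # plus optional "r" (linear commensal term)
}


@dataclass
class PairwiseModelSpec:
    """One pairwise model form plus its parameter set.

    ``interactions`` maps ordered pairs ``(focal, influencer)`` to
    parameter dicts whose required keys depend on ``form``:

    * ``linear_lv``: ``r`` -- fitness effect per influencer cell.
    * ``logistic_lv``: ``Lam`` -- carrying capacity imposed on the focal
      species by the influencer.
    * ``saturable_lv``: ``r`` (maximal fitness effect) and ``K``
      (influencer density at half-maximal effect).
    * ``alternative``: ``r``, ``omega``, ``psi`` -- divided-influence
      form r*Sj/(omega*Sj + psi*Si).
    * ``divided_simplified``: ``rho`` -- r20 + rho*Sj/Si.
    * ``competitive_commensal_lv``: ``Lam`` per ordered pair (including
      self pairs) plus optional ``r`` for the linear commensal boost of
      the birth rate; species carry ``birth_death`` entries.

    ``r0`` gives each species' basal fitness; self pairs ``(i, i)`` are
    permitted where the form supports them.
    """

    form: str
    species: list
    r0: dict
    interactions: dict = field(default_factory=dict)
    birth_death: dict = field(default_factory=dict)  # sid -> (b0, d), competitive form

    def __post_init__(self) -> None:
        if self.form not in PAIRWISE_FORMS:
            raise ConfigError(f"unknown pairwise form {self.form!r}")
        # normalize tuple keys (YAML round trips use 'focal<-influencer' strings)
        fixed = {}
        for key, params in self.interactions.items():
            if isinstance(key, str):
                focal, influencer = key.split("<-")
                key = (focal, influencer)
            fixed[tuple(key)] = dict(params)
        self.interactions = fixed
        for sid in self.species:
            if sid not in self.r0:
                raise ConfigError(f"basal fitness r0 missing for species {sid!r}")
        for (focal, influencer), params in self.interactions.items():
            for sid in (focal, influencer):
                if sid not in self.species:
                    raise ConfigError(f"interaction references unknown species {sid!r}")
            missing = _FORM_KEYS[self.form] - set(params)
            if self.form == "competitive_commensal_lv" and missing == {"Lam"} and "r" in params:
                missing = set()
            if missing:
                raise ConfigError(
                    f"form {self.form!r} interaction {focal}<-{influencer} missing {sorted(missing)}"
                )
            if "K" in params and params["K"] <= 0:
                raise ConfigError(f"K must be > 0 in {focal}<-{influencer}")
            if "Lam" in params and params["Lam"] <= 0:
                raise ConfigError(f"Lam must be > 0 in {focal}<-{influencer}")
            if "psi" in params and params["psi"] <= 0:
                raise ConfigError(f"psi must be > 0 in {focal}<-{influencer}")
        if self.form == "competitive_commensal_lv":
            for sid in self.species:
                if sid not in self.birth_death:
                    raise ConfigError(
                        f"competitive_commensal_lv needs birth_death for {sid!r}"
                    )

    def interaction(self, focal: str, influencer: str) -> Optional[dict]:
        return self.interactions.get((focal, influencer))

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "species": list(self.species),
            "r0": dict(self.r0),
            "interactions": {
                f"{focal}<-{influencer}": dict(p)
                for (focal, influencer), p in self.interactions.items()
            },
            "birth_death": {k: list(v) for k, v in self.birth_death.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PairwiseModelSpec":
        return cls(
            form=d["form"],
            species=list(d["species"]),
            r0={k: float(v) for k, v in d["r0"].items()},
            interactions=d.get("interactions", {}),
            birth_death={k: tuple(v) for k, v in d.get("birth_death", {}).items()},
        )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def load_config(path) -> CommunityConfig:
    """Load and validate a community configuration from a YAML file."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: config file must contain a mapping")
    return CommunityConfig.from_dict(d)


def save_config(config: CommunityConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=False, default_flow_style=False)
    )
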