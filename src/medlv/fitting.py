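"""Training pairwise models on mechanistic reference dynamics.

The dissimilarity metric is the species-averaged, time-averaged absolute
log10 fold-difference between two density trajectories,

    D-bar = (1/N) sum_i (1/T) int_T |log10(S_i,pair / S_i,mech)| dt,

with all densities floored at the extinction limit S_ext before taking
logs.  Fitting follows the staged procedure: monoculture parameters
first, then interaction parameters with the monoculture ones frozen,
using bounded trust-region nonlinear least squares on log10-density
residuals sampled on a uniform grid inside the training window
(pointwise minimization of the D-bar integrand).  Because the landscape
can be multimodal, fits are multi-started from seeded random points
inside the bounds; a start that reproduces the reference to numerical
precision ends the search early.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .config import ConfigError, DilutionPolicy, PairwiseModelSpec
from .mechanistic import Trajectory
from .pairwise import MultiPairwiseModel, simulate_pairwise

__all__ = [
    "TrainingWindow",
    "FitResult",
    "Slot",
    "OutcomeVerdict",
    "PredictionScore",
    "dbar",
    "fit_spec_params",
    "fit_monoculture",
    "fit_interaction",
    "predict_and_score",
    "classify_outcome",
]


@dataclass
class TrainingWindow:
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError(f"empty training window [{self.t_start}, {self.t_end}]")

    def grid(self, n: int) -> np.ndarray:
        return np.linspace(self.t_start, self.t_end, n)


@dataclass
class FitResult:
    spec: PairwiseModelSpec
    dbar_train: float
    window: TrainingWindow
    converged: bool
    n_iter: int
    dbar_test: Optional[float] = None
    cost: float = float("nan")


# ---------------------------------------------------------------------------
# the D-bar metric
# ---------------------------------------------------------------------------


def dbar(
    traj_pair: Trajectory,
    traj_mech: Trajectory,
    window: TrainingWindow,
    s_ext: float = 1e-2,
    n_grid: int = 201,
    species: Optional[Sequence[str]] = None,
) -> float:
    """Species- and time-averaged |log10| fold-difference over a window.

    Both trajectories must cover the window and share the compared
    species set.  Evaluated by the trapezoid rule on ``n_grid`` uniform
    points; densities are floored at ``s_ext``.
    """
    if species is None:
        if set(traj_pair.species_ids) != set(traj_mech.species_ids):
            raise ConfigError(
                f"species mismatch: {traj_pair.species_ids} vs {traj_mech.species_ids}"
            )
        species = traj_mech.species_ids
    for traj in (traj_pair, traj_mech):
        if window.t_start < traj.times[0] - 1e-9 or window.t_end > traj.times[-1] + 1e-9:
            raise ValueError("trajectory does not cover the scoring window")
    t = window.grid(n_grid)
    acc = 0.0
    for sid in species:
        la = traj_pair.log10_density_at(sid, t, s_ext)
        lb = traj_mech.log10_density_at(sid, t, s_ext)
        acc += np.trapezoid(np.abs(la - lb), t)
    return acc / (len(species) * (window.t_end - window.t_start))


# ---------------------------------------------------------------------------
# generic bounded least-squares over spec parameters
# ---------------------------------------------------------------------------


@dataclass
class Slot:
    """One free parameter of a spec being fitted.

    ``path`` addresses a value inside the spec dict produced by
    ``PairwiseModelSpec.to_dict()``: e.g. ``("interactions", "S2<-S1", "r")``
    or ``("birth_death", "S1", 0)`` or ``("r0", "S2")``.  ``log10``
    searches the decade scale (for half-saturation constants and
    carrying capacities); bounds are in search space.
    """

    path: tuple
    lo: float
    hi: float
    log10: bool = False
    init: Optional[float] = None  # natural-scale initial guess

    def to_search(self, value: float) -> float:
        return math.log10(value) if self.log10 else value

    def from_search(self, x: float) -> float:
        return 10 ** x if self.log10 else x


def _set_path(d: dict, path: tuple, value):
    node = d
    for key in path[:-1]:
        node = node[key]
    node[path[-1]] = value


def _spec_from_theta(template: dict, slots: Sequence[Slot], theta) -> PairwiseModelSpec:
    d = copy.deepcopy(template)
    for slot, x in zip(slots, theta):
        _set_path(d, slot.path, slot.from_search(float(x)))
    return PairwiseModelSpec.from_dict(d)


def fit_spec_params(
    reference: Trajectory,
    template: PairwiseModelSpec,
    slots: Sequence[Slot],
    window: TrainingWindow,
    dilution: Optional[DilutionPolicy] = None,
    s_ext: float = 1e-2,
    seed: int = 0,
    n_starts: int = 4,
    n_resid: int = 101,
    species: Optional[Sequence[str]] = None,
    sim_rtol: float = 1e-6,
    perfect_rms: float = 3e-5,
    opt_tol: float = 1e-9,
) -> FitResult:
    """Fit the ``slots`` of ``template`` to the reference trajectory.

    Residuals are log10-density differences for ``species`` (default:
    all) on a uniform grid inside the window; the model is restarted
    from the reference state at the window start and integrated under
    ``dilution``.  Multi-start: the template values (or slot inits)
    first, then seeded random starts within the bounds.
    """
    rng = np.random.default_rng(seed)
    tmpl = template.to_dict()
    species = list(species or template.species)
    t_grid = window.grid(n_resid)
    y_start = reference.state_at(window.t_start)
    init_dens = {sid: max(y_start.get(sid, 0.0), 0.0) for sid in template.species}
    ref_logs = np.array(
        [reference.log10_density_at(sid, t_grid, s_ext) for sid in species]
    )
    big = 1e3  # residual magnitude for failed integrations

    def residual(theta):
        spec = _spec_from_theta(tmpl, slots, theta)
        try:
            sim = simulate_pairwise(
                spec, init_dens, window.t_end, dilution=dilution, s_ext=s_ext,
                rtol=sim_rtol, atol=1e-9, t0=window.t_start, max_cycles=200,
                t_eval=t_grid,
            )
        except Exception:
            return np.full(ref_logs.size, big)
        if sim.times[-1] < window.t_end - 1e-9:
            return np.full(ref_logs.size, big)
        sim_logs = np.array(
            [sim.log10_density_at(sid, t_grid, s_ext) for sid in species]
        )
        res = (sim_logs - ref_logs).ravel()
        return np.where(np.isfinite(res), np.clip(res, -big, big), big)

    lo = np.array([s.lo for s in slots])
    hi = np.array([s.hi for s in slots])

    starts = []
    theta0 = []
    for s in slots:
        if s.init is not None:
            theta0.append(np.clip(s.to_search(s.init), s.lo, s.hi))
        else:
            node = tmpl
            try:
                for key in s.path:
                    node = node[key]
                theta0.append(np.clip(s.to_search(float(node)), s.lo, s.hi))
            except Exception:
                theta0.append(0.5 * (s.lo + s.hi))
    starts.append(np.array(theta0))
    for _ in range(max(n_starts - 1, 0)):
        starts.append(rng.uniform(lo, hi))

    best = None
    for x0 in starts:
        try:
            res = least_squares(
                residual, x0, bounds=(lo, hi), method="trf", x_scale="jac",
                xtol=opt_tol, ftol=opt_tol, gtol=opt_tol, max_nfev=200 * len(slots),
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        rms = math.sqrt(2.0 * best.cost / ref_logs.size)
        if rms < perfect_rms:
            break
    if best is None:
        raise RuntimeError("all optimizer starts failed")

    spec = _spec_from_theta(tmpl, slots, best.x)
    sim = simulate_pairwise(
        spec, init_dens, window.t_end, dilution=dilution, s_ext=s_ext,
        t0=window.t_start,
    )
    score = dbar(sim, reference, window, s_ext=s_ext, species=species)
    return FitResult(
        spec=spec,
        dbar_train=score,
        window=TrainingWindow(window.t_start, window.t_end),
        converged=bool(best.status > 0),
        n_iter=int(best.nfev),
        cost=float(best.cost),
    )


# ---------------------------------------------------------------------------
# the staged pipeline
# ---------------------------------------------------------------------------


def fit_monoculture(
    reference: Trajectory,
    form: str,
    window: TrainingWindow,
    species_id: Optional[str] = None,
    dilution: Optional[DilutionPolicy] = None,
    s_ext: float = 1e-2,
    seed: int = 0,
    n_starts: int = 4,
    fixed_death: float = 0.0,
) -> FitResult:
    """Step 1: monoculture parameters from a single-species reference.

    ``form``:

    * ``"exponential"``   -- basal fitness r0 only (r_ii fixed at 0, for
      scenarios without intra-species interactions);
    * ``"saturable_self"``-- r0 plus a saturable self term (r_ii, K_ii);
    * ``"logistic"``      -- r0 and the self carrying capacity;
    * ``"birth_death"``   -- maximal birth rate and self carrying
      capacity with the death rate fixed at ``fixed_death``.
    """
    if species_id is None:
        if len(reference.species_ids) != 1:
            raise ConfigError("monoculture fitting expects a single-species reference")
        species_id = reference.species_ids[0]
    sid = species_id
    s0 = reference.state_at(window.t_start)[sid]
    # crude growth-rate guess from the window endpoints
    s1 = reference.state_at(window.t_end)[sid]
    r_guess = (math.log(max(s1, s_ext)) - math.log(max(s0, s_ext))) / (
        window.t_end - window.t_start
    )

    if form == "exponential":
        template = PairwiseModelSpec("linear_lv", [sid], {sid: 0.1})
        slots = [Slot(("r0", sid), -10, 10, init=r_guess)]
    elif form == "saturable_self":
        template = PairwiseModelSpec(
            "saturable_lv", [sid], {sid: 0.1}, {(sid, sid): {"r": 0.0, "K": 1e6}}
        )
        slots = [
            Slot(("r0", sid), -10, 10, init=r_guess),
            Slot(("interactions", f"{sid}<-{sid}", "r"), -10, 10, init=0.0),
            Slot(("interactions", f"{sid}<-{sid}", "K"), -2, 12, log10=True, init=max(s1, 1.0)),
        ]
    elif form == "logistic":
        template = PairwiseModelSpec(
            "logistic_lv", [sid], {sid: 0.1}, {(sid, sid): {"Lam": 1e7}}
        )
        slots = [
            Slot(("r0", sid), 1e-3, 10, init=abs(r_guess) or 0.1),
            Slot(("interactions", f"{sid}<-{sid}", "Lam"), 2, 12, log10=True,
                 init=max(10 * s1, 1e3)),
        ]
    elif form == "birth_death":
        template = PairwiseModelSpec(
            "competitive_commensal_lv", [sid], {sid: 0.0},
            {(sid, sid): {"Lam": 1e7}},
            birth_death={sid: (0.3, fixed_death)},
        )
        slots = [
            Slot(("birth_death", sid, 0), 1e-4, 10, init=abs(r_guess) + fixed_death),
            Slot(("interactions", f"{sid}<-{sid}", "Lam"), 2, 12, log10=True,
                 init=max(10 * s1, 1e3)),
        ]
    else:
        raise ConfigError(f"unknown monoculture form {form!r}")

    return fit_spec_params(
        reference, template, slots, window, dilution=dilution, s_ext=s_ext,
        seed=seed, n_starts=n_starts, species=[sid],
    )


def fit_interaction(
    reference: Trajectory,
    template: PairwiseModelSpec,
    slots: Sequence[Slot],
    window: TrainingWindow,
    dilution: Optional[DilutionPolicy] = None,
    s_ext: float = 1e-2,
    seed: int = 0,
    n_starts: int = 4,
    species: Optional[Sequence[str]] = None,
) -> FitResult:
    """Step 2: interaction parameters with monoculture parameters frozen.

    The ``template`` carries the frozen basal fitnesses / monoculture
    terms (typically copied directly from the mechanistic config) and the
    ``slots`` select only interaction parameters, implementing the staged
    procedure.  ``species`` can restrict the residuals, e.g. to the only
    influenced species.
    """
    for slot in slots:
        if slot.path[0] == "r0":
            raise ConfigError("basal fitness is frozen during interaction fitting")
    return fit_spec_params(
        reference, template, slots, window, dilution=dilution, s_ext=s_ext,
        seed=seed, n_starts=n_starts, species=species,
    )


# ---------------------------------------------------------------------------
# prediction scoring and qualitative verdicts
# ---------------------------------------------------------------------------


@dataclass
class OutcomeVerdict:
    label: str  # "coexistence", "<id>_excludes", "collapse"
    survivors: tuple
    fractions: dict

    def __eq__(self, other) -> bool:  # verdict equality = label + survivors
        if isinstance(other, str):
            return self.label == other
        return (self.label, self.survivors) == (other.label, other.survivors)


def classify_outcome(
    traj: Trajectory,
    fraction_floor: float = 0.01,
    n_cycles: int = 3,
) -> OutcomeVerdict:
    """Qualitative outcome from terminal species fractions.

    Fractions are averaged over the final ``n_cycles`` dilution cycles
    (or the final 10% of the run when there are no dilutions); species
    sustaining a mean fraction below ``fraction_floor`` count as
    excluded.
    """
    if len(traj.dilution_times) > n_cycles:
        t_lo = traj.dilution_times[-(n_cycles + 1)]
    else:
        t_lo = traj.times[0] + 0.9 * (traj.times[-1] - traj.times[0])
    mask = traj.times >= t_lo
    fr = traj.fractions()[:, mask].mean(axis=1)
    fractions = dict(zip(traj.species_ids, fr))
    survivors = tuple(sid for sid, f in fractions.items() if f >= fraction_floor)
    if len(survivors) == 0:
        label = "collapse"
    elif len(survivors) == len(traj.species_ids):
        label = "coexistence"
    elif len(survivors) == 1:
        label = f"{survivors[0]}_excludes"
    else:
        label = "partial_coexistence"
    return OutcomeVerdict(label=label, survivors=survivors, fractions=fractions)


@dataclass
class PredictionScore:
    dbar_test: float
    verdict_model: OutcomeVerdict
    verdict_reference: OutcomeVerdict
    qualitative_match: bool
    trajectory: Trajectory = field(repr=False, default=None)


def predict_and_score(
    model,
    reference: Trajectory,
    test_window: TrainingWindow,
    dilution: Optional[DilutionPolicy] = None,
    s_ext: float = 1e-2,
    initial_densities: Optional[dict] = None,
    fraction_floor: float = 0.01,
    species: Optional[Sequence[str]] = None,
    t0: float = 0.0,
) -> PredictionScore:
    """Step 3: replay a fitted model outside the training window.

    The model (a :class:`PairwiseModelSpec`, :class:`FitResult` or
    assembled multispecies model) is simulated from the reference's
    initial state (or ``initial_densities``) under the shared dilution
    protocol; returns the test D-bar and the qualitative outcome
    comparison.
    """
    if isinstance(model, FitResult):
        model = model.spec
    if initial_densities is None:
        initial_densities = reference.state_at(t0 if t0 > reference.times[0] else reference.times[0])
    sim = simulate_pairwise(
        model, initial_densities, test_window.t_end, dilution=dilution, s_ext=s_ext,
        t0=t0,
    )
    score = dbar(sim, reference, test_window, s_ext=s_ext, species=species)
    v_model = classify_outcome(sim, fraction_floor=fraction_floor)
    v_ref = classify_outcome(reference, fraction_floor=fraction_floor)
    return PredictionScore(
        dbar_test=score,
        verdict_model=v_model,
        verdict_reference=v_ref,
        qualitative_match=(v_model.label, v_model.survivors)
        == (v_ref.label, v_ref.survivors),
        trajectory=sim,
    )
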