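# Methods

This note documents the models, the numerical choices, and the design
decisions behind `medlv`, in the spirit of a simulation package's model
documentation. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is asserted from
memory.

## 1. The mechanistic model

A community is a bipartite network of species and chemical mediators
(`medlv.config.CommunityConfig`). Units are fixed package-wide: time in
hours, species densities in cells/ml, mediator concentrations in
arbitrary concentration units (only ratios to half-saturation constants
enter the dynamics), production rates in concentration·ml/cell/hour.

Per mediator kind:

* **reusable** — released by producers, acts on targets without being
  depleted: `dC/dt = β0 + Σ_j β_CSj S_j`;
* **consumable** — additionally removed by consumers, either with
  saturable (Monod) kinetics `− Σ_j α_CSj C/(C+K_CSj) S_j`, or
  **yield-coupled**: `− α · g_j(C,…) · S_j` where `g_j` is the
  consumer's realized mediator-dependent growth term and `α` the amount
  consumed per new cell. Yield coupling is used for resource-limited
  growth (the competitive-commensal community), where consumption must
  stop exactly when growth stops.

Species grow at their basal fitness plus additive saturable (or linear)
effects from incoming mediators. Two essential resources that jointly
limit one species combine through a dual-resource co-limitation term

    g = r · (c1 c2/(c1+c2)) · (1/(c1+1) + 1/(c2+1)),   c_k = C_k/K_k,

which reduces to the Monod form in either single-limitation limit.

**Turbidostat protocol.** Integration proceeds in segments terminated
by an event (total density = threshold); the dilution is applied as a
discontinuous map multiplying species — and mediators, when
`dilute_mediators` (the default; dilution physically replaces medium) —
by `reset_total/threshold`. Species below the extinction floor
`S_ext` (default 1e-2 cells/ml) are zeroed at dilution events only, so
within-cycle dynamics stay smooth. Mediators default to zero initial
concentration (fresh, pre-washed medium).

**Solver.** `scipy.integrate.solve_ivp` with LSODA (stiff-capable),
rtol 1e-8 / atol 1e-10 by default. A terminal "blow-up" event (total
state > 1e100) converts divergent dynamics (e.g. linear L-V mutualism,
which genuinely blows up in finite time) into a clean integration
error. Optional `t_eval` sampling goes through the solver's dense
output, so sampled values carry solver accuracy rather than
interpolation error; this matters for fitting (below). Halving the
tolerances changes terminal species fractions by <0.1% on the shipped
scenarios (tested).

## 2. The pairwise model family

Six forms (`medlv.pairwise`): linear L-V, logistic L-V, saturable L-V,
the divided-influence ("alternative") form `r S1/(ω S1 + ψ S2)`, its
simplified `ρ S1/S2` variant, and a birth/death competition form
`(b_i0 + r_ij S_j)(1 − Σ S/Λ) S_i − d_i S_i`. Pairwise models integrate
under the same dilution protocol and extinction rules as mechanistic
models, so D̄ comparisons are like-for-like.

Multispecies pairwise models are assembled from two-species components
with additive combination of fitness-effect terms; mixed forms per pair
are allowed (the package's central subject is precisely that different
pairs need different forms). Conflicting basal fitnesses across
components are an assembly error. The multiplicative birth/death form
cannot be combined additively and is restricted to two-species use.

**Numerical guard.** The divided-influence forms are singular where
`ω S1 + ψ S2 = 0` (possible for ω < 0). The implementation regularizes
the denominator smoothly (relative width 3e-4) and caps each fitness
effect smoothly at ±50/h, exactly linear below 25/h. Biological rates
in this package are ≤ ~1/h, so the cap never engages on sensible
trajectories; it only prevents the integrator from chattering on the
singular manifold while an optimizer explores bad parameters. The
ω = 0 ↔ ρ-form identity holds to <1e-6 relative (tested).

## 3. Closed-form theory

For the canonical topology (producer S1, consumable mediator C1,
beneficiary/consumer S2), `medlv.analytic` implements:

* **Regime classification** — producer-wins ("I"), coexistence ("II"),
  consumer-wins ("III"); equalities are reported as `boundary` and
  excluded from the regime guarantees, since the theory treats strict
  inequalities only.
* **Coexistence steady state** `C1*, RS*` and the scaled phase plane
  `(Ĉ1, R̂S)` with the mediator-elimination isocline
  `R̂S = (1 + K̂_C1S2/Ĉ1)/(1 + K̂_C1S2)` (unscaled
  `RS = (β/α)(1 + K_C1S2/C1)` in the consumer-wins regime). Near this
  isocline the net mediator production rate f vanishes and the mediator
  can be eliminated, giving the divided-influence model with
  `ω = 1 − K_S2C1/K_C1S2`, `ψ = K_S2C1 α/(K_C1S2 β)`.
* **Convergence times** `t_f` for the tractable initial-condition
  subcases (consumer-heavy and consumer-light starts in both regimes),
  together with the producer-density sufficiency bounds. "Much greater
  than" thresholds are operationalized as a ≥10× separation; this
  factor is an explicit, documented knob (`sep`).
* **Convergence condition** of the divided-influence model:
  for ω < 0 the ratio equation has a singularity at `RS = −ω/ψ` and
  initial ratios below it converge to the wrong attractor — a false
  extinction in the coexistence regime, a false coexistence in the
  consumer-wins regime. Verdicts are cross-checked against direct
  integration of the one-dimensional ratio ODE.
* **Two-mediator reducibility.** Two reusable mediators with potencies
  `K_Ci = K_S2Ci r10/β_CiS1` fold into a single saturable term only if
  the potencies are similar (ratio within [1/3, 3]) or one term's
  magnitude is below 5% of the other across the density range of
  interest; both thresholds are documented knobs chosen once.

The producer-wins acclimation time is
`max(ln(α RS(0)/β)/|r20+r_S2C1−r10|, 1/r10)`; "after" is
operationalized as 10× this scale wherever a post-acclimation window is
needed. The coexistence subcase "comparable to 1" band is [1/3, 3],
and the `t_f` for that subcase is the conservative `10/r10`.

## 4. Fitting pipeline

D̄ is the species-averaged, time-averaged absolute log10
fold-difference, evaluated by the trapezoid rule on ≥200 uniform points
(grid-convergence tested to 0.1%), with densities floored at `S_ext`
before the logarithm.

Fitting follows the staged procedure: monoculture parameters first,
then interaction parameters with the monoculture ones frozen; basal
fitnesses are taken directly from the mechanistic configuration where
the workflow allows. The optimizer is bounded trust-region least
squares (`scipy.optimize.least_squares`, trf) on log10-density
residuals sampled on a uniform grid inside the training window — the
pointwise integrand of D̄. Because the landscape is multimodal, fits are
multi-started (template/heuristic start plus seeded random starts,
default 4); a start reproducing the reference to numerical precision
ends the search early. Rates are searched linearly in roughly
±[0–3]/h; half-saturation constants and carrying capacities on a log10
scale (decade bounds per scenario). Residual-grid values are obtained
through the solver's dense output on both sides; without this, the
interpolation error between solver steps floors residuals near 1e-4 in
log10 density and limits parameter recovery to the percent level.

Two identifiability facts shape the interfaces:

* The divided-influence parameters carry a gauge freedom — scaling
  (r, ω, ψ) by a common factor leaves the model invariant — so numeric
  fits fix ψ = 1 and estimate the invariant combinations r/ψ and ω/ψ.
  With a steady-state-only training window even the gauge-fixed pair is
  ridge-degenerate, and ridge members can carry spurious singularities;
  the coexistence scenario therefore uses an equal-half-saturation
  (ω = 0) community whose single divided-influence coefficient is
  uniquely identifiable from any window.
* In the birth/death competition form, `b_i0` and `d_i` are not jointly
  identifiable from a monoculture trajectory; death rates are taken
  from the mechanistic configuration and the remaining parameters
  fitted. The beneficiary of an obligate commensal resource gets
  `b_20 = 0` (it cannot be born without the partner's metabolite).

Qualitative outcomes are classified from species fractions averaged
over the final three dilution cycles (final 10% of the run without
dilutions); species below a 1% fraction floor count as excluded.

## 5. The regime generator as study conditions

`generate_regime_config` samples the community parameter sets each experiment draws on. It samples basal fitnesses 0.03–0.7/h, half-saturation
constants 3e2–3e4 concentration units, release rates 3e-5–3e-4
conc·ml/cell/h, consumption within 0.3–10× the release rate, a 10×
dilution threshold/reset ratio, and rejection-samples until the
regime's defining inequality holds with a 15% separation margin. All
sampling is deterministic per (regime, seed).

Coexistence-regime samples are additionally conditioned to be
*well-posed turbidostat experiments*: the stationary ratio RS* must lie
in [0.05, 20] (both species far from the extinction floor), the
linearized mediator relaxation toward the isocline must outpace growth
by ≥20× even at the reset density (the mediator re-equilibrates within
every dilution cycle, as in high-density experiments), and the slow
eigenvalue of the ratio dynamics must exceed 0.02/h (steady state
reached within a few hundred hours). Without these conditions a sampled
community can genuinely fail to converge under dilutions — the same
dilution-induced failure mode the low-density scenario demonstrates on
purpose — which is a different claim from the closed-form steady state
being wrong.

Three-species generators enforce the inequalities their conclusions
need: the mediator-removal topology keeps the third consumer's basal
fitness equal to the producer's (so its relative consumption capacity
persists) and verifies that the quasi-steady suppressed mediator level
leaves the beneficiary below the producer's fitness; the
shared-production topology requires that one producer's worth of
saturated mediator cannot sustain the beneficiary while the pairwise
doubled sum would.

The isocline convergence-time experiment places communities *deep* in
each subcase: the initial ratio 300× past the subcase threshold and the
producer density 1000× past the sufficiency bound. This is not
cosmetic: the consumer-heavy approach to the isocline is exponential
with time constant ≈ t_f, so |f| at 3·t_f is e⁻³ ≈ 0.0498 plus
corrections of order 1/margin; the derivation's "sufficiently high
initial producer density" must be taken strongly for the estimate to
apply cleanly.

**What the generator does and does not emulate.** Trajectories are
noise-free ODE solutions: no demographic stochasticity, measurement
error, lag phases, evolution, or spatial structure. Passing tests show
that the *model-reduction* claims (which pairwise form matches which
mechanism, and when none does) hold exactly in the idealized setting
they were derived for; they do not show that fitted pairwise models
behave this way on noisy experimental data, where identifiability is
strictly harder.

## 6. Scenario presets

Each scenario couples a fixed community (shipped as YAML under
`medlv/data/`), a protocol, and a declared qualitative expectation.
Problem sizes were chosen so each scenario completes in well under two
minutes on one CPU: two-species runs of 120–400 h (tens of dilution
cycles), three-species runs of 160–200 h, batch competitive-commensal
runs of 900 h with a 300 h training window (long enough to cover the
inoculation transient; the exclusion and fluctuating communities come
from the regime generator, seeds 1 and 3, the stable community is a
designed interior equilibrium at a 2:1 ratio). Training windows
follow the workflow's conventions: ~10 community doublings for
monoculture/early-window fits, a steady-state window for the
coexistence transfer experiment.

Known limitations: the fluctuating competitive-commensal fixture
demonstrates *a* fluctuating community on which the fitted L-V model
fails qualitatively, not a specific published parameter set; the
two-mediator fixture pairs a strong-potency stimulatory mediator with a
weak-potency inhibitory one so that the fitted interaction coefficient
flips sign between training densities — magnitudes of those
coefficients are properties of this parameterization, only the signs
and the qualitative transfer failure are general.
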