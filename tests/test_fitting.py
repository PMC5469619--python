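"""D-bar metric and the staged fitting pipeline."""

import numpy as np
import pytest

from medlv import (
    ConfigError,
    PairwiseModelSpec,
    Slot,
    TrainingWindow,
    Trajectory,
    classify_outcome,
    dbar,
    fit_interaction,
    fit_monoculture,
    predict_and_score,
    simulate,
)
from medlv.analytic import SingleMediatorParams, derive_reusable_lv
from medlv.pairwise import simulate_pairwise


def _flat_traj(values: dict, t_end=10.0, n=50):
    t = np.linspace(0.0, t_end, n)
    ids = list(values)
    arr = np.array([np.full(n, v) for v in values.values()], dtype=float)
    return Trajectory(times=t, species_ids=ids, species=arr)


def test_dbar_zero_on_identical_and_one_per_decade():
    a = _flat_traj({"S1": 1e6, "S2": 1e4})
    b = _flat_traj({"S1": 1e6, "S2": 1e4})
    w = TrainingWindow(0.0, 10.0)
    assert dbar(a, b, w) == pytest.approx(0.0, abs=1e-12)
    c = _flat_traj({"S1": 1e7, "S2": 1e5})  # uniformly 10x
    assert dbar(c, b, w) == pytest.approx(1.0, rel=1e-9)
    # pseudometric: symmetric, non-negative
    assert dbar(b, c, w) == pytest.approx(dbar(c, b, w))


def test_dbar_floors_densities_at_extinction_limit():
    a = _flat_traj({"S1": 1e-9})  # below the floor
    b = _flat_traj({"S1": 1e-2})
    assert dbar(a, b, TrainingWindow(0.0, 10.0), s_ext=1e-2) == pytest.approx(0.0)


def test_dbar_errors_on_species_mismatch_and_uncovered_window():
    a = _flat_traj({"S1": 1e6})
    b = _flat_traj({"S2": 1e6})
    with pytest.raises(ConfigError, match="mismatch"):
        dbar(a, b, TrainingWindow(0.0, 10.0))
    with pytest.raises(ValueError, match="cover"):
        dbar(a, _flat_traj({"S1": 1e6}), TrainingWindow(0.0, 20.0))


def test_dbar_quadrature_is_grid_converged(reusable_config):
    p = SingleMediatorParams.from_config(reusable_config)
    ref = simulate(reusable_config, 60.0)
    spec = derive_reusable_lv(p)
    pw = simulate_pairwise(spec, ref.state_at(40.0), 60.0,
                           dilution=reusable_config.dilution, t0=40.0)
    w = TrainingWindow(40.0, 60.0)
    coarse = dbar(pw, ref, w, n_grid=201)
    fine = dbar(pw, ref, w, n_grid=2001)
    assert coarse == pytest.approx(fine, rel=1e-3, abs=1e-6)


def test_monoculture_exponential_recovers_rate_to_four_digits():
    spec = PairwiseModelSpec("linear_lv", ["S1"], {"S1": 0.3217})
    ref = simulate_pairwise(spec, {"S1": 1e5}, 12.0,
                            t_eval=np.linspace(0, 12, 101))
    fit = fit_monoculture(ref, "exponential", TrainingWindow(0.0, 12.0))
    assert fit.spec.r0["S1"] == pytest.approx(0.3217, rel=1e-4)
    assert fit.converged


def test_monoculture_logistic_self_consistency():
    true = PairwiseModelSpec("logistic_lv", ["S1"], {"S1": 0.35},
                             {("S1", "S1"): {"Lam": 3e7}})
    ref = simulate_pairwise(true, {"S1": 1e5}, 40.0,
                            t_eval=np.linspace(0, 40, 101))
    fit = fit_monoculture(ref, "logistic", TrainingWindow(0.0, 40.0))
    assert fit.dbar_train < 1e-3
    assert fit.spec.r0["S1"] == pytest.approx(0.35, rel=1e-3)
    assert fit.spec.interactions[("S1", "S1")]["Lam"] == pytest.approx(3e7, rel=1e-2)


def test_interaction_fit_freezes_basal_fitness():
    ref = _flat_traj({"S1": 1e6, "S2": 1e6})
    tmpl = PairwiseModelSpec("saturable_lv", ["S1", "S2"],
                             {"S1": 0.3, "S2": 0.2},
                             {("S2", "S1"): {"r": 0.1, "K": 1e6}})
    with pytest.raises(ConfigError, match="frozen"):
        fit_interaction(ref, tmpl, [Slot(("r0", "S2"), -1, 1)],
                        TrainingWindow(0.0, 10.0))


def test_fit_after_acclimation_predicts_better_than_before(reusable_config):
    """A saturable fit trained before the mediator has acclimated to the
    producer density extrapolates worse than one trained after."""
    ref = simulate(reusable_config, 100.0)
    p = SingleMediatorParams.from_config(reusable_config)
    tmpl = derive_reusable_lv(p)
    slots = [Slot(("interactions", "S2<-S1", "r"), -3, 3, init=0.1),
             Slot(("interactions", "S2<-S1", "K"), 0, 9, log10=True, init=1e5)]
    test_w = TrainingWindow(60.0, 100.0)
    scores = {}
    for label, win in (("before", TrainingWindow(0.0, 8.0)),
                       ("after", TrainingWindow(40.0, 48.0))):
        fit = fit_interaction(ref, tmpl, slots, win,
                              dilution=reusable_config.dilution, seed=0,
                              species=["S2"])
        sc = predict_and_score(fit, ref, test_w,
                               dilution=reusable_config.dilution,
                               initial_densities=ref.state_at(test_w.t_start),
                               t0=test_w.t_start)
        scores[label] = sc.dbar_test
    assert scores["after"] < scores["before"]


def test_within_class_prediction_matches_training(case2_config):
    """A fit inside the generating model class predicts as well as it
    trains (both essentially zero)."""
    true = PairwiseModelSpec("saturable_lv", ["S1", "S2"],
                             {"S1": 0.4, "S2": 0.2},
                             {("S2", "S1"): {"r": 0.25, "K": 5e6}})
    ref = simulate_pairwise(true, {"S1": 1e6, "S2": 1e6}, 30.0,
                            t_eval=np.linspace(0, 30, 151))
    tmpl = PairwiseModelSpec("saturable_lv", ["S1", "S2"],
                             {"S1": 0.4, "S2": 0.2},
                             {("S2", "S1"): {"r": 0.1, "K": 1e6}})
    fit = fit_interaction(ref, tmpl,
                          [Slot(("interactions", "S2<-S1", "r"), -3, 3),
                           Slot(("interactions", "S2<-S1", "K"), 2, 9, log10=True)],
                          TrainingWindow(0.0, 15.0), seed=1, species=["S2"])
    sc = predict_and_score(fit, ref, TrainingWindow(15.0, 30.0))
    assert fit.dbar_train < 1e-4
    assert sc.dbar_test < 1e-3


def test_classify_outcome_labels():
    single = _flat_traj({"S1": 1e6})
    assert classify_outcome(single).label == "coexistence"
    skewed = _flat_traj({"S1": 1e6, "S2": 1.0})
    v = classify_outcome(skewed, fraction_floor=0.01)
    assert v.label == "S1_excludes" and v.survivors == ("S1",)


def test_training_window_must_be_ordered():
    with pytest.raises(ValueError):
        TrainingWindow(5.0, 5.0)
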