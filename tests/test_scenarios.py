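"""Scenario harness: cheap presets, report plumbing, determinism."""

import pandas as pd
import pytest

from medlv.scenarios import SCENARIOS, run_all, run_scenario

# scenarios cheap enough for the routine suite; the heavier ones are
# exercised by the acceptance tests
CHEAP = [
    "consumable_consumer_wins",
    "alt_convergence_quartet",
    "chain_three_species",
    "modification_mediator_removal",
    "control_no_removal",
    "modification_shared_production",
    "control_linear_effect",
]


@pytest.mark.parametrize("name", CHEAP)
def test_cheap_scenarios_meet_their_expectations(name):
    res = run_scenario(name, seed=0)
    assert res.passed, (res.expected, res.metrics, res.verdicts)


def test_unknown_scenario_raises():
    with pytest.raises(KeyError):
        run_scenario("no_such_scenario")


def test_run_all_empty_list_gives_empty_report(tmp_path):
    out = tmp_path / "report.csv"
    df = run_all(names=[], report_path=out)
    assert df.empty
    assert pd.read_csv(out).empty


def test_run_all_summarizes_and_is_deterministic(tmp_path):
    names = ["chain_three_species", "control_linear_effect"]
    df1 = run_all(names=names, seed=3, report_path=tmp_path / "r.csv")
    df2 = run_all(names=names, seed=3)
    assert list(df1["scenario"]) == names
    assert df1["passed"].all()
    pd.testing.assert_frame_equal(df1, df2)
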