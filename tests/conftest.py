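import pytest

from medlv import (
    CommunityConfig,
    DilutionPolicy,
    InfluenceLink,
    MediatorSpec,
    SpeciesSpec,
)


def single_mediator_config(r10=0.5, r20=0.3, rsc=0.5, KS2C1=1e3, KC1S2=2e3,
                           beta=3e-4, alpha=6e-4, kind="consumable",
                           s1_0=5e7, s2_0=5e7, dilution=None):
    """Canonical two-species commensalism: S1 releases C1, C1 boosts S2."""
    links = [InfluenceLink(
        "C1", producer="S1", beta=beta,
        consumer="S2" if kind == "consumable" else None,
        alpha=alpha if kind == "consumable" else 0.0,
        K_consume=KC1S2 if kind == "consumable" else None,
        target="S2", r_effect=rsc, K_effect=KS2C1,
    )]
    return CommunityConfig(
        species=[SpeciesSpec("S1", r10), SpeciesSpec("S2", r20)],
        mediators=[MediatorSpec("C1", kind)],
        links=links,
        initial_densities={"S1": s1_0, "S2": s2_0},
        dilution=dilution or DilutionPolicy("turbidostat", threshold=1e9,
                                            reset_total=1e8),
    )


@pytest.fixture
def case2_config():
    return single_mediator_config()


@pytest.fixture
def reusable_config():
    return single_mediator_config(r10=0.3, r20=0.1, rsc=0.3, KS2C1=1e4,
                                  beta=1e-4, kind="reusable",
                                  s1_0=5e6, s2_0=5e6,
                                  dilution=DilutionPolicy(
                                      "turbidostat", threshold=1e8,
                                      reset_total=1e7))
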