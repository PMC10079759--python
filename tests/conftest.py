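import pytest

from ploidynet import build_B, normalize, realize_profile, simplification_sequence


@pytest.fixture(scope="session")
def worked_profiles():
    """The small worked-example profiles used across the suite."""
    return {
        name: normalize(list(comps))
        for name, comps in {
            "doubled": (14, 12, 12, 10),
            "fig2": (7, 6, 6, 5),
            "simple77": (77, 1, 1, 1),
            "arcrich77": (77,),
            "corollary": (5, 3, 1),
            "weak63": (6, 3),
            "practical12": (12, 1, 1),
            "viola": (18, 14, 14, 10, 8, 8, 8, 4, 4, 2),
        }.items()
    }


@pytest.fixture(scope="session")
def worked_networks(worked_profiles):
    nets = {name: realize_profile(p) for name, p in worked_profiles.items()}
    nets["core_fig2"] = build_B(simplification_sequence(worked_profiles["fig2"]).terminal)
    nets["core77"] = build_B(worked_profiles["arcrich77"])
    nets["core_simple77"] = build_B(worked_profiles["simple77"])
    return nets
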