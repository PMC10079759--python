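"""Seeded profile generators and the worked-example fixtures.

The named fixtures are the small profiles used throughout the package's
documentation and tests, including the simplified Viola dataset whose
ploidy levels range from 2x to 18x.
"""

from __future__ import annotations

import random

from .corenet import build_B
from .netgraph import Network
from .profiles import PloidyProfile, ProfileError, normalize, simplification_sequence
from .realize import compose_scaled, realize_profile

__all__ = ["random_profile", "random_simple_profile", "worked_example_fixtures", "FIXTURE_PROFILES"]

FIXTURE_PROFILES: dict[str, tuple[int, ...]] = {
    "doubled": (14, 12, 12, 10),
    "fig2": (7, 6, 6, 5),
    "simple77": (77, 1, 1, 1),
    "arcrich77": (77,),
    "corollary": (5, 3, 1),
    "weak63": (6, 3),
    "practical12": (12, 1, 1),
    "composed": (40, 24, 8, 4, 2, 1),
    "viola": (18, 14, 14, 10, 8, 8, 8, 4, 4, 2),
}


def random_profile(n: int, max_component: int, seed: int) -> PloidyProfile:
    """Reproducible random profile on taxa x1..xn."""
    if n < 1 or max_component < 1:
        raise ProfileError("need n >= 1 and max_component >= 1")
    rng = random.Random(seed)
    comps = sorted((rng.randint(1, max_component) for _ in range(n)), reverse=True)
    return PloidyProfile(tuple(comps), tuple(f"x{i + 1}" for i in range(n)))


def random_simple_profile(max_m1: int, max_n: int, seed: int) -> PloidyProfile:
    """Reproducible random simple profile (m1 >= 2, all other taxa at 1)."""
    rng = random.Random(seed)
    m1 = rng.randint(2, max_m1)
    n = rng.randint(1, max_n)
    return PloidyProfile((m1,) + (1,) * (n - 1), tuple(f"x{i + 1}" for i in range(n)))


def worked_example_fixtures() -> dict[str, object]:
    """Profiles and pre-built networks for the worked examples."""
    profiles = {name: normalize(list(c)) for name, c in FIXTURE_PROFILES.items()}
    nets: dict[str, Network] = {
        "fig2": realize_profile(profiles["fig2"]),
        "core_simple77": build_B(profiles["simple77"]),
        "core_arcrich77": build_B(profiles["arcrich77"]),
        "core_fig2": build_B(simplification_sequence(profiles["fig2"]).terminal),
        "weak63": realize_profile(profiles["weak63"]),
        "composed": compose_scaled(realize_profile(profiles["corollary"]), 3),
        "viola": realize_profile(profiles["viola"]),
    }
    return {"profiles": profiles, "networks": nets}
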