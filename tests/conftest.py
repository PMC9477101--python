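import numpy as np
import pytest

from bttrees import (
    CovariateSpec,
    ItemSet,
    LeafSpec,
    Ranking,
    SimDesign,
)

# Worth vectors with a steep vs. a flat profile (renormalized printed
# estimates from a terminal-node table of the modeled study); used as
# planted subgroup truths throughout the simulation-based tests.
STEEP = np.array([0.593, 0.228, 0.106, 0.053, 0.018]) / 0.998
FLAT = np.array([0.280, 0.233, 0.230, 0.158, 0.099]) / 1.000
DOGS_NODE1 = np.array([0.415, 0.241, 0.143, 0.120, 0.081])


@pytest.fixture(scope="session")
def items5() -> ItemSet:
    return ItemSet(("a", "b", "c", "d", "e"), "abstraction", ("a", "b", "c", "d", "e"))


@pytest.fixture(scope="session")
def items3() -> ItemSet:
    return ItemSet(("a", "b", "c"))


def ranking(ordering: str, sid: str = "s1") -> Ranking:
    return Ranking(sid, tuple(ordering.split()))


def five_covariate_specs() -> list[CovariateSpec]:
    """Age + task time + a Likert + an IP-style Likert + gender."""
    return [
        CovariateSpec("age", "numeric", mean=15.35, sd=2.96, round=True, minimum=13),
        CovariateSpec("game_time", "numeric", mean=23.01, sd=10.26, lognormal=True),
        CovariateSpec(
            "S1", "ordinal", levels=(1, 2, 3, 4, 5),
            probs=(0.03, 0.08, 0.30, 0.41, 0.18),
        ),
        CovariateSpec(
            "IP", "ordinal", levels=(1, 2, 3, 4), probs=(0.10, 0.30, 0.36, 0.24)
        ),
        CovariateSpec("gender", "nominal", levels=("f", "m"), probs=(0.52, 0.48)),
    ]


FIVE_DECLS = [
    ("age", "numeric"),
    ("game_time", "numeric"),
    ("S1", "ordinal"),
    ("IP", "ordinal"),
    ("gender", "nominal"),
]


def planted_age_design(items: ItemSet, n: int, seed: int) -> SimDesign:
    """Two subgroups: steep worths up to age 15, flat above."""
    leaves = [
        LeafSpec([("age", "<=", 15)], STEEP),
        LeafSpec([("age", ">", 15)], FLAT),
    ]
    return SimDesign(items, five_covariate_specs(), leaves, n=n, seed=seed)


def homogeneous_design(items: ItemSet, n: int, seed: int) -> SimDesign:
    return SimDesign(
        items, five_covariate_specs(), [LeafSpec([], FLAT)], n=n, seed=seed
    )
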