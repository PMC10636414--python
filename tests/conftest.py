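import numpy as np
import pytest

from mpvmeta import builtin_table, effect_table
from mpvmeta.effect_size import EffectEstimate


@pytest.fixture(scope="session")
def table24():
    """The packaged 24-study MPV table."""
    return builtin_table()


@pytest.fixture(scope="session")
def effects24(table24):
    """Default-flavor (Hedges) effect estimates for the packaged table."""
    return effect_table(table24)


@pytest.fixture
def toy_effects():
    """Three equal-variance effects with a hand-computable DL solution."""
    return [
        EffectEstimate("a", 0.0, 0.04, "hedges"),
        EffectEstimate("b", 0.5, 0.04, "hedges"),
        EffectEstimate("c", 1.0, 0.04, "hedges"),
    ]


def make_effects(theta, variance, flavor="hedges"):
    """Helper: wrap parallel arrays into EffectEstimate objects."""
    return [
        EffectEstimate(f"s{i}", float(t), float(v), flavor)
        for i, (t, v) in enumerate(zip(np.atleast_1d(theta), np.atleast_1d(variance)))
    ]
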