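import numpy as np
import pytest

from epathcv import (
    AtomSelection, ToySystemSpec, make_toy_endstates, make_transition_trajectory,
)


@pytest.fixture(scope="session")
def toy_endstates():
    """Deterministic hinge-bend pair used across the suite."""
    return make_toy_endstates(ToySystemSpec(seed=7))


@pytest.fixture(scope="session")
def toy_selection(toy_endstates):
    return AtomSelection.all(toy_endstates[0].n_atoms)


@pytest.fixture(scope="session")
def toy_trajectory(toy_endstates):
    ina, act = toy_endstates
    return make_transition_trajectory(ina, act, n_frames=11, noise=0.0, seed=3)


def random_coords(rng: np.random.Generator, n: int, scale: float = 0.5) -> np.ndarray:
    return scale * rng.standard_normal((n, 3))
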