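import numpy as np
import pytest

import trdrep as t
from trdrep.simulate import DominantClone, SimParams


@pytest.fixture(scope="session")
def ref():
    return t.default_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_params():
    """Small but structured study: 3 samples, 3 public + private dominants."""
    return SimParams(seed=7, n_samples=3, depth=20_000, n_background_clones=300)


@pytest.fixture(scope="session")
def small_study(small_params):
    return t.run_study(small_params)


def make_private_params(seed=11, n_samples=3, depth=20_000, n_background=200):
    """Params with only private dominant clones (no public structure)."""
    clones = tuple(
        DominantClone(name=f"S{s}P{k}", freq=f, samples=(s,))
        for s in range(n_samples)
        for k, f in enumerate((0.2, 0.1, 0.05))
    )
    return SimParams(
        seed=seed,
        n_samples=n_samples,
        depth=depth,
        n_background_clones=n_background,
        dominant_clones=clones,
    )
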