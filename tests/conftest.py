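import numpy as np
import pytest

from lymphkin import ModelParameters, reference_parameters
from lymphkin.params import ORGANS


@pytest.fixture
def ref_params() -> ModelParameters:
    """Published rat TDL point estimates (k = 2)."""
    return reference_parameters()


@pytest.fixture
def ref_params_closed(ref_params) -> ModelParameters:
    """Reference rates with removal switched off (closed system)."""
    return ref_params.replace(removal_rate=0.0, dying_fraction=0.0)


def random_parameters(rng: np.random.Generator, k: int | None = None) -> ModelParameters:
    """A random physiologically-shaped parameter draw for property tests."""
    entry = {o: float(np.exp(rng.uniform(np.log(1e-3), np.log(2.0)))) for o in ORGANS}
    exit_ = {o: float(np.exp(rng.uniform(np.log(1e-3), np.log(3.0)))) for o in ORGANS}
    shared = float(np.exp(rng.uniform(np.log(1e-3), np.log(0.1))))
    for o in ("scln", "mln", "pp"):
        exit_[o] = shared
    return ModelParameters(
        entry_rates=entry,
        exit_rates=exit_,
        removal_rate=float(rng.uniform(0.0, 0.01)),
        dying_fraction=float(rng.uniform(0.0, 1.0)),
        thoracic_fraction=float(rng.uniform(0.0, 1.0)),
        n_subcompartments=int(k if k is not None else rng.integers(1, 4)),
    )
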