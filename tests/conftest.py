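import numpy as np
import pytest

from erythroquant import synth


@pytest.fixture(scope="session")
def small_field():
    """Noiseless 25-cell 415 nm field with its ground truth."""
    truth = synth.make_rbc_scene(25, radius=8.0, seed=1)
    img, truth = synth.generate_rbc_field(truth)
    return img, truth


@pytest.fixture(scope="session")
def single_cell_scene():
    """One intact discocyte, noiseless, well inside the frame."""
    cell = synth.CellSpec(center=(32.0, 32.0), radius=8.0)
    truth = synth.SceneTruth(shape=(64, 64), cells=(cell,))
    img, truth = synth.generate_rbc_field(truth)
    return img, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
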