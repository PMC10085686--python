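import numpy as np
import pytest

from mergenet import presets
from mergenet.merger_core import effective_merger_params, sensitivity_constant


@pytest.fixture(scope="session")
def ref_full():
    """Reference full-model parameters, no competitor."""
    return presets.reference_full_params()


@pytest.fixture(scope="session")
def ref_full_comp():
    """Reference full-model parameters with the resource competitor."""
    return presets.reference_full_params(with_competitor=True)


@pytest.fixture(scope="session")
def ref_broken_comp():
    """Broken-merging (untagged output) variant with the competitor."""
    return presets.reference_full_params(with_competitor=True,
                                         degradation_tag=False)


@pytest.fixture(scope="session")
def ref_lumped(ref_full):
    """Lumped minimal-model parameters implied by the reference circuit."""
    return effective_merger_params(ref_full, presets.X_GRID, presets.Y_GRID,
                                   presets.OPERATING_POINT)


@pytest.fixture(scope="session")
def ref_slope_uM(ref_lumped):
    """Reference sensitivity in uM per unit ratio (uncalibrated)."""
    return sensitivity_constant(ref_lumped)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
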