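import numpy as np
import pytest

from valvemorph.phantom import PhantomSpec, build_phantom, phantom_intensity


@pytest.fixture(scope="session")
def default_phantom():
    """Default closed-valve phantom: (spec, labels, truth)."""
    spec = PhantomSpec()
    labels, truth = build_phantom(spec)
    return spec, labels, truth


@pytest.fixture(scope="session")
def phantom_ct(default_phantom):
    spec, labels, _ = default_phantom
    return phantom_intensity(labels, spec)


@pytest.fixture(scope="session")
def root_mask(default_phantom):
    _, labels, _ = default_phantom
    return labels.with_values((labels.values >= 1).astype(np.uint8))


def cusp_mask(labels, code):
    return labels.with_values((labels.values == code).astype(np.uint8))
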