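import numpy as np
import pytest

from vnca_marrow.phantom import PhantomSpec

#: compact phantom used throughout the unit tests: 5 vertebrae on a
#: 32 x 32 x 168 grid at 1.5 mm isotropic spacing
SMALL_GEOMETRY = dict(
    grid_shape=(32, 32, 168),
    spacing_mm=(1.5, 1.5, 1.5),
    n_vertebrae=5,
    body_radius_mm=12.0,
    body_height_mm=20.0,
    gap_mm=4.0,
    cortical_thickness_mm=2.0,
    reference_rod_radius_mm=4.0,
)


@pytest.fixture
def small_spec():
    """Factory for small, fast phantoms with overridable parameters."""

    def make(**kw) -> PhantomSpec:
        return PhantomSpec(**{**SMALL_GEOMETRY, **kw})

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
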