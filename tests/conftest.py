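import numpy as np
import pytest

from afvtrial import conditions, substrate


@pytest.fixture(scope="session")
def wt_sr():
    return conditions.genotype_baseline("wild_type", "SR")


@pytest.fixture(scope="session")
def px_sr():
    return conditions.genotype_baseline("pitx2_deficient", "SR")


@pytest.fixture(scope="session")
def wt_af():
    return conditions.genotype_baseline("wild_type", "AF")


@pytest.fixture(scope="session")
def px_af():
    return conditions.genotype_baseline("pitx2_deficient", "AF")


@pytest.fixture(scope="session")
def small_substrate():
    """A 20x20 mm fibrotic substrate at 0.5 mm spacing (fast to build)."""
    return substrate.build_substrate(seed=7, size_mm=20.0, spacing=0.5,
                                     d_long=0.1, anisotropy=2.0)


@pytest.fixture(scope="session")
def uniform_substrate():
    """Fibrosis-free isotropic sheet for solver sanity checks."""
    geom = substrate.Geometry(nx=41, ny=41, spacing=0.5)
    return substrate.Substrate(
        geometry=geom,
        voltage=np.full(geom.shape, 5.0),
        fibrotic=np.zeros(geom.shape, dtype=bool),
        fiber_angle=np.zeros(geom.shape),
        d_long=0.1,
        anisotropy=1.0,
    )
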