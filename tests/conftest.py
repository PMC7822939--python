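import numpy as np
import pytest

from plaquemap.pipeline import quadrant_regions
from plaquemap.relaxometry import RelaxationMaps, fit_t1_vfa, fit_t2star
from plaquemap.synthetic import (
    DEFAULT_CLASSES,
    AcquisitionProtocol,
    PhantomSpec,
    Region,
    generate_phantom,
    simulate_acquisition,
)


def noiseless_vfa(**kw):
    base = dict(
        mode="vfa",
        tr=10.0,
        flip_angles=(5.0, 10.0, 20.0, 30.0, 40.0),
        te_fixed=2.0,
        noise_model="none",
    )
    base.update(kw)
    return AcquisitionProtocol(**base)


def noiseless_multiecho(**kw):
    base = dict(
        mode="multiecho",
        tr=22.0,
        echo_times=(4.0, 8.0, 12.0, 16.0, 20.0),
        flip_angle=10.0,
        noise_model="none",
    )
    base.update(kw)
    return AcquisitionProtocol(**base)


@pytest.fixture(scope="session")
def four_class_phantom():
    """All four tissue classes in quadrants on a (4, 40, 40) grid."""
    spec = PhantomSpec(
        grid_shape=(4, 40, 40),
        regions=quadrant_regions((4, 40, 40), list(DEFAULT_CLASSES)[:4]),
        seed=7,
        plaque_id="plaqueA",
    )
    return generate_phantom(spec, DEFAULT_CLASSES)


@pytest.fixture(scope="session")
def noiseless_maps(four_class_phantom):
    """Noiseless simulate -> fit on the four-class phantom."""
    t1res = fit_t1_vfa(simulate_acquisition(four_class_phantom, noiseless_vfa()))
    t2res = fit_t2star(simulate_acquisition(four_class_phantom, noiseless_multiecho()))
    return RelaxationMaps(t1=t1res, t2s=t2res)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def single_class_spec(label="fibrous", grid=(3, 12, 12), seed=0):
    return PhantomSpec(
        grid_shape=grid,
        regions=(
            Region(
                shape="box",
                label=label,
                center=tuple((g - 1) / 2 for g in grid),
                half_size=tuple(g / 2 for g in grid),
            ),
        ),
        seed=seed,
        plaque_id="p_single",
    )
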