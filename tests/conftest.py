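import numpy as np
import pytest

from ivdpipe.discgraph import GraphConfig, build_disc_graph
from ivdpipe.phantom import LEVELS, PhantomSpec, generate_patient
from ivdpipe.reconstruction import DiscPointCloud


@pytest.fixture(scope="session")
def small_spec():
    """Compact phantom geometry used across tests."""
    return PhantomSpec(
        n_patients=8, slices_per_patient=9, slice_shape=(96, 96),
        pixel_spacing_mm=(1.0, 1.0), slice_spacing_mm=3.0, seed=11,
    )


@pytest.fixture(scope="session")
def one_patient(small_spec):
    return generate_patient(small_spec, 0)


@pytest.fixture()
def toy_cloud():
    rng = np.random.default_rng(42)
    pts = rng.uniform(-4.0, 4.0, (80, 3)) * np.array([1.0, 0.3, 1.0])
    return DiscPointCloud(pts, "voxel", rng.uniform(0.2, 0.9, 80), ("P0000", LEVELS[0]))


@pytest.fixture()
def toy_graph(toy_cloud):
    return build_disc_graph(toy_cloud, grade=3, config=GraphConfig(radius=0.35))
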