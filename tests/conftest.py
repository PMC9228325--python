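import numpy as np
import pytest
import trimesh

from bovimetry import synthetic as syn


@pytest.fixture(scope="session")
def month12():
    """12-month preset mesh at measurement resolution, with ground truth."""
    mesh, truth = syn.build_heifer_mesh(syn.shape_preset("month12"), resolution=128)
    return mesh, truth


@pytest.fixture(scope="session")
def month12_coarse():
    mesh, truth = syn.build_heifer_mesh(syn.shape_preset("month12"), resolution=96)
    return mesh, truth


@pytest.fixture(scope="session")
def unit_sphere():
    return trimesh.creation.icosphere(subdivisions=4, radius=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
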