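import numpy as np
import pytest

from mshk.basis import BasisSpec
from mshk.dataset import build_training_set
from mshk.grid import GridSpec
from mshk.surrogate import (
    SIGMA_V_PERMUTATION,
    SurrogateReference,
    default_spec,
    generate_reference_dataset,
    template_geometry,
)


@pytest.fixture(scope="session")
def template():
    return template_geometry()


@pytest.fixture(scope="session")
def spec():
    return default_spec()


@pytest.fixture(scope="session")
def small_grid(template):
    """Coarse mirror-symmetric grid for fast unit tests."""
    centroid = tuple(template.coordinates.mean(axis=0))
    return GridSpec.centered(center=centroid, spacing=0.4, shape=(24, 20, 12))


@pytest.fixture(scope="session")
def small_basis(small_grid):
    return BasisSpec(small_grid, (7, 7, 5))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_raw(spec):
    """60 GS frames + 2 short excited trajectories (300 frames total)."""
    return generate_reference_dataset(
        spec, n_gs_frames=60, n_es_trajectories=2, es_steps=120, seed=11
    )


@pytest.fixture(scope="session")
def tiny_training_set(tiny_raw, template, small_grid, small_basis, spec):
    is_gs = (tiny_raw.provenance["source"] == "gs").to_numpy()
    gs = [g for g, t in zip(tiny_raw.geometries, is_gs) if t]
    es = [g for g, t in zip(tiny_raw.geometries, is_gs) if not t]
    return build_training_set(
        gs,
        es,
        reference=template,
        k=40,
        seed=3,
        reference_provider=SurrogateReference(spec),
        grid=small_grid,
        basis=small_basis,
        permutation=SIGMA_V_PERMUTATION,
    )


@pytest.fixture(scope="session")
def perturbed_geometries(template):
    r = np.random.default_rng(77)
    return [
        template.with_coordinates(
            template.coordinates + 0.05 * r.standard_normal((9, 3))
        )
        for _ in range(12)
    ]
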