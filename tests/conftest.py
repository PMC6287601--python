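import numpy as np
import pytest

from micrasym.landmark_io import LandmarkDataset, SpecimenRecord
from micrasym.simulate import _shape_projectors, default_base_shape
from micrasym.symmetry import standard_map


@pytest.fixture(scope="session")
def smap7():
    return standard_map(7)


@pytest.fixture(scope="session")
def base7():
    return default_base_shape(7)


@pytest.fixture(scope="session")
def project7(base7, smap7):
    """Projector onto the symmetric/asymmetric shape subspaces at the base."""
    return _shape_projectors(base7, smap7)


def make_single_species(base, project, n=8, r=2, delta=None, sigma_ind=0.0,
                        sigma_fa=0.0, sigma_me=0.0, seed=0, species="sp1"):
    """Hand-rolled single-species dataset with chosen variance components."""
    rng = np.random.default_rng(seed)
    k = base.shape[0]
    d = 2 * k
    records = []
    for i in range(n):
        latent = base.reshape(-1).copy()
        if delta is not None:
            latent = latent + np.asarray(delta, dtype=float).reshape(-1)
        if sigma_ind > 0:
            latent = latent + project(rng.normal(0.0, sigma_ind, d), "sym")
        if sigma_fa > 0:
            latent = latent + project(rng.normal(0.0, sigma_fa, d), "asym")
        for rep in range(1, r + 1):
            coords = latent + (rng.normal(0.0, sigma_me, d) if sigma_me > 0 else 0.0)
            records.append(
                SpecimenRecord(f"{species}_i{i + 1:03d}", species, rep,
                               coords.reshape(k, 2))
            )
    return LandmarkDataset(records)
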