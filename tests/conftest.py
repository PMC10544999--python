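import numpy as np
import pytest

import phycoexciton as px


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def obo_table():
    """Shared OBO lineshape (lambda=100, gamma=53 cm^-1, 300 K)."""
    return px.lineshape_function(px.SpectralDensity(lambda_c=100.0, gamma_c=53.0), 300.0)


@pytest.fixture(scope="session")
def slow_obo_table():
    """Slow-bath OBO (lambda=200, gamma=2 cm^-1): near-static broadening."""
    return px.lineshape_function(px.SpectralDensity(lambda_c=200.0, gamma_c=2.0), 300.0)


@pytest.fixture
def monomer():
    return px.build_system([px.PigmentSite("m", 15000.0, (0.0, 0.0, 2.0))], [[0.0]])


def make_torsion_frames(base, sigma, n_frames, seed):
    """StructureModel with frames drawn around `base` torsions (degrees)."""
    gen = np.random.default_rng(seed)
    base = np.asarray(base, float)
    model0, topo = px.gen_bilin_geometry(base)
    frames = []
    for _ in range(n_frames):
        m, _ = px.gen_bilin_geometry(base + sigma * gen.standard_normal(len(base)))
        frames.append(m.atoms.coord)
    return px.StructureModel(atoms=model0.atoms, frames=np.array(frames)), topo
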