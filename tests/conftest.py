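import pytest

from spinrelax.spin_physics import DiffusionTensor, make_field_context
from spinrelax.synthetic_data import simulate_vectors


@pytest.fixture(scope="session")
def fc900():
    return make_field_context(900.0)


@pytest.fixture(scope="session")
def fc800():
    return make_field_context(800.0)


@pytest.fixture(scope="session")
def truth_tensor():
    """Full-protein-like axial tensor: tauC 26.5 ns, anisotropy 1.375."""
    return DiffusionTensor(Dperp=0.56e7, Dpar=0.77e7, alpha=11.0, beta=59.0)


@pytest.fixture(scope="session")
def vectors116():
    return simulate_vectors(116)


@pytest.fixture(scope="session")
def toy_ensemble():
    from spinrelax.synthetic_data import EnsembleSimSpec, simulate_ensemble

    spec = EnsembleSimSpec(n_models=500, seed=11)
    return spec, simulate_ensemble(spec)
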