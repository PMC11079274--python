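import numpy as np
import pytest

from dohbperf import (
    PhantomSpec,
    build_phantom,
    build_protocol,
    make_gas_traces,
    simulate_bold,
)


@pytest.fixture(scope="session")
def default_protocol():
    return build_protocol()


@pytest.fixture(scope="session")
def gas160(default_protocol):
    """Default double-hypoxia gas traces extended to the 160-volume scan."""
    return make_gas_traces(default_protocol, n_samples=160)


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_truth(noiseless_spec):
    return build_phantom(noiseless_spec, seed=0)


@pytest.fixture(scope="session")
def noiseless_bold(noiseless_truth, gas160, noiseless_spec):
    return simulate_bold(noiseless_truth, gas160, noiseless_spec, seed=0)


@pytest.fixture(scope="session")
def tiny_spec():
    """A smaller phantom for fast unit tests (lesion shrunk to fit)."""
    return PhantomSpec(
        nx=16, ny=16, nz=8, n_volumes=80, noise_sd=0.0,
        lesion_radii_frac=(0.05, 0.08, 0.12),
    )


@pytest.fixture(scope="session")
def tiny_truth(tiny_spec):
    return build_phantom(tiny_spec, seed=0)


@pytest.fixture(scope="session")
def tiny_bold(tiny_truth, default_protocol, tiny_spec):
    gas = make_gas_traces(default_protocol, n_samples=tiny_spec.n_volumes)
    return simulate_bold(tiny_truth, gas, tiny_spec, seed=0)
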