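import numpy as np
import pytest

from fishbonewire import (
    SequenceSpec,
    build_hamiltonian,
    default_parameters,
    eigensystem,
    expansion_coefficients,
    homopolymer_spec,
)

#: 0.2 eV splitting of the isolated GG base-pair doublet, Hz.
TWO_LEVEL_FREQ_HZ = 0.2 / 4.135667696e-15


@pytest.fixture(scope="session")
def gg_two_level():
    """GG dimer with t_S = 0: the base pairs form an isolated two-level system."""
    params = default_parameters(0.0)
    h = build_hamiltonian(SequenceSpec("GG"), params)
    es = eigensystem(h)
    coeffs = expansion_coefficients(es, 2)
    return h, es, coeffs


@pytest.fixture(scope="session")
def g10_ts1():
    """G homopolymer, N=10, t_S = 1 eV — the workhorse polymer system."""
    params = default_parameters(1.0)
    h = build_hamiltonian(homopolymer_spec("G", 10), params)
    return h, eigensystem(h)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
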