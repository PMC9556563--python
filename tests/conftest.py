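import numpy as np
import pytest

from mcassembler.structio import ChainStructure, ResidueRecord


def make_chain(ca, chain_id="A", cb=None, plddt=90.0, seq=None, seq_id=None,
               indices=None):
    """Build a ChainStructure from raw coordinate arrays."""
    ca = np.asarray(ca, dtype=float)
    cb = ca.copy() if cb is None else np.asarray(cb, dtype=float)
    n = len(ca)
    if seq is None:
        seq = "A" * n
    if indices is None:
        indices = range(1, n + 1)
    plddts = np.full(n, plddt, dtype=float) if np.isscalar(plddt) else np.asarray(plddt)
    residues = [
        ResidueRecord(int(i), seq[k], ca[k], cb[k], float(plddts[k]))
        for k, i in enumerate(indices)
    ]
    return ChainStructure(chain_id, residues, seq_id=seq_id)


def random_chain(rng, n=30, scale=10.0, chain_id="A", seq_id=None, center=None):
    """Random blob chain: CA uniform in a cube, CB offset 1.5 A in a random direction."""
    ca = rng.uniform(-scale, scale, size=(n, 3))
    if center is not None:
        ca = ca + np.asarray(center, dtype=float)
    off = rng.normal(size=(n, 3))
    off = 1.5 * off / np.linalg.norm(off, axis=1, keepdims=True)
    return make_chain(ca, chain_id=chain_id, cb=ca + off, seq_id=seq_id)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def cyclic10():
    """Noiseless homomeric 10-ring ground truth with its native trimers."""
    from mcassembler.synthetic import FixtureSpec, generate_complex, slice_subcomponents

    truth = generate_complex(FixtureSpec("cyclic", 10, seed=1))
    subs = slice_subcomponents(truth, "native_trimers")
    return truth, subs


@pytest.fixture(scope="session")
def tree8():
    """Heteromeric 8-chain path fixture (the unique-spanning-path analogue)."""
    from mcassembler.synthetic import FixtureSpec, generate_complex, slice_subcomponents

    truth = generate_complex(FixtureSpec("linear_tree", 8, oligomer="hetero", seed=3))
    subs = slice_subcomponents(truth, "native_trimers")
    return truth, subs
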