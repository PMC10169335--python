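import numpy as np
import pytest

from hlaclust import (
    KernelParams,
    ResidueSimilarityMatrix,
    WeightTable,
    coarse_grain,
    make_random_structure,
    make_synthetic_pdb,
    read_pdb,
    superpose,
    trim_binding_domain,
)


@pytest.fixture(scope="session")
def params():
    return KernelParams(sigma=0.3, k=2.0)


@pytest.fixture(scope="session")
def simmatrix():
    return ResidueSimilarityMatrix.grantham_default()


@pytest.fixture(scope="session")
def rand_structure():
    """Factory for random coarse clouds; pass a seed for reproducibility."""

    def make(seed, **kwargs):
        return make_random_structure(seed=seed, **kwargs)

    return make


@pytest.fixture(scope="session")
def synthetic_pdb_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("pdbs")
    for i in range(3):
        make_synthetic_pdb(d / f"allele{i}.pdb", n_residues=200, seed=100 + i)
    return d


@pytest.fixture(scope="session")
def processed_pair(synthetic_pdb_dir):
    """Two synthetic structures run through the full processing stage,
    superposed onto the first as reference."""
    ref = trim_binding_domain(read_pdb(synthetic_pdb_dir / "allele0.pdb"))
    wt = WeightTable.default()
    out = []
    for i in range(2):
        raw = read_pdb(synthetic_pdb_dir / f"allele{i}.pdb")
        out.append(coarse_grain(superpose(trim_binding_domain(raw), ref), wt))
    return out


def random_rotation(rng):
    """Uniform random proper rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
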