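import numpy as np
import pytest

import emeth


@pytest.fixture(scope="session")
def small_reference():
    """Well-conditioned 60-CpG x 3-type reference for exact-recovery tests."""
    rng = np.random.default_rng(1234)
    vals = rng.uniform(0.05, 0.95, size=(60, 3))
    ids = tuple(f"cg{k:05d}" for k in range(60))
    return emeth.ReferenceMatrix(ids, ("alpha", "beta", "gamma"), vals)


@pytest.fixture(scope="session")
def immune_reference():
    """946-CpG, 7-type synthetic reference with the collinear CD4T/CD8T pair."""
    pool, reps = emeth.make_synthetic_reference(K_pool=2000, Q=7,
                                                collinear_pair_rho=0.96,
                                                seed=42)
    keep = emeth.select_cpgs(reps, 946)
    return emeth.ReferenceMatrix(tuple(pool.cpg_ids[k] for k in keep),
                                 pool.cell_types, pool.values[keep])


@pytest.fixture(scope="session")
def tiny_reference():
    """60-CpG, 4-type bimodal reference for fast simulator-driven tests."""
    pool, reps = emeth.make_synthetic_reference(K_pool=300, Q=4,
                                                collinear_pair_rho=0.9,
                                                seed=5)
    keep = emeth.select_cpgs(reps, 60)
    return emeth.ReferenceMatrix(tuple(pool.cpg_ids[k] for k in keep),
                                 pool.cell_types, pool.values[keep])


def make_noise_free_bulk(ref, rho, eta=None, nu0=None):
    """Exact mixture bulk matrix from known proportions."""
    rho = np.asarray(rho, float)
    z = ref.values @ rho
    if eta is not None:
        z = z + np.outer(nu0, eta)
    ids = tuple(f"s{i}" for i in range(rho.shape[1]))
    return emeth.BulkBetaMatrix(ref.cpg_ids, ids, np.clip(z, 0, 1))
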