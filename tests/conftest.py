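import warnings

import numpy as np
import pytest

import mkfbn


@pytest.fixture(autouse=True)
def _quiet_imputation_warnings():
    # tiny desk-scale graphs legitimately produce undefined Hr/Ar values
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        yield


@pytest.fixture()
def rng(request):
    # per-test deterministic stream, independent of execution order
    import zlib

    seed = zlib.crc32(request.node.nodeid.encode()) % (2**31)
    return np.random.default_rng(seed)


@pytest.fixture(scope="session")
def small_cohort():
    """12 regions, 5+5 subjects, two planted edges with a solid effect."""
    spec = mkfbn.CohortSpec(
        n_regions=12, n_timepoints=120, n_group_pos=5, n_group_neg=5,
        planted_edges=((0, 1), (2, 3)), effect_size=0.35, seed=11,
    )
    return spec, mkfbn.simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """Feature blocks for the small cohort on a coarse grid."""
    from mkfbn.io import compute_cohort_features

    _, cohort = small_cohort
    grid = mkfbn.SparsityGrid(0.10, 0.50, 0.10)
    feats, mats = compute_cohort_features(
        cohort, grid, mkfbn.NullModelConfig(3, 10, 0)
    )
    return feats, mats, grid


def random_graph(rng, n, p=0.4, ensure_edge=True):
    A = (rng.random((n, n)) < p).astype(np.uint8)
    A = np.triu(A, 1)
    A = A | A.T
    if ensure_edge and A.sum() == 0:
        A[0, 1] = A[1, 0] = 1
    return A
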