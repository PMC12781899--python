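import numpy as np
import pandas as pd
import pytest

from spotmap import AnnotatedSC, SpatialDataset, normalize
from spotmap import synthetic as syn


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale generator spec shared by the unit tests."""
    return syn.GeneratorSpec(n_cells=400, n_genes=400, n_types=6, seed=11)


@pytest.fixture(scope="session")
def small_sc(small_spec):
    sc = syn.make_sc(small_spec)
    normalize(sc)
    return sc


@pytest.fixture(scope="session")
def small_pair(small_sc):
    """Paired reference + spatially patterned template (pure-ish spots)."""
    st, truth = syn.simulate_st_poisson(
        small_sc, n_spots=100, lam=5, perturbation=0.01, seed=12, dominant_frac=0.7
    )
    normalize(st)
    return small_sc, st, truth


@pytest.fixture
def toy_sc():
    """3 genes x 4 cells, two types, hand-checkable numbers."""
    counts = np.array(
        [
            [10.0, 0.0, 2.0, 0.0],
            [0.0, 5.0, 1.0, 3.0],
            [1.0, 1.0, 1.0, 1.0],
        ]
    )
    return AnnotatedSC(
        counts=counts,
        gene_ids=np.array(["gA", "gB", "gC"], dtype=object),
        cell_ids=np.array(["c1", "c2", "c3", "c4"], dtype=object),
        cell_type=pd.Series(["T1", "T2", "T1", "T2"], index=["c1", "c2", "c3", "c4"]),
    )


@pytest.fixture
def toy_st():
    """3 genes x 3 spots on a line."""
    counts = np.array(
        [
            [4.0, 0.0, 2.0],
            [0.0, 6.0, 2.0],
            [1.0, 1.0, 1.0],
        ]
    )
    coords = pd.DataFrame(
        {"x": [0.0, 1.0, 2.0], "y": [0.0, 0.0, 0.0]}, index=["s1", "s2", "s3"]
    )
    return SpatialDataset(
        counts=counts,
        gene_ids=np.array(["gA", "gB", "gC"], dtype=object),
        spot_ids=np.array(["s1", "s2", "s3"], dtype=object),
        coords=coords,
    )
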