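import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from liverseq.datatypes import CountMatrix
from liverseq.simulate import SimDesign, simulate_counts


@pytest.fixture(scope="session")
def small_design() -> SimDesign:
    """Study-scale donor layout at reduced gene count and depth."""
    return SimDesign(n_genes=400, mean_library_size=2e5, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return simulate_counts(small_design)


@pytest.fixture()
def tiny_matrix() -> CountMatrix:
    """Hand-sized matrix: 6 genes, 2 PRE + 2 DCD-0h samples."""
    rng = np.random.default_rng(5)
    meta = pd.DataFrame(
        {
            "donor_id": ["p1", "p2", "d1", "d2"],
            "group": ["PRE", "PRE", "DCD", "DCD"],
            "timepoint": ["pre", "pre", "0h", "0h"],
            "batch": ["b1", "b1", "b1", "b1"],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(6, 4)),
        index=pd.Index([f"g{i}" for i in range(6)], name="gene"),
        columns=meta.index,
    )
    return CountMatrix(counts, meta)
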