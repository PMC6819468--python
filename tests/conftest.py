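import numpy as np
import pandas as pd
import pytest

from stemwall.expression import ExpressionMatrix
from stemwall.simulate import SimConfig, simulate


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples: two internodes, two replicates, one genotype."""
    counts = pd.DataFrame(
        {
            "s1": [50, 0, 200],
            "s2": [60, 0, 180],
            "s3": [10, 5, 400],
            "s4": [14, 3, 360],
        },
        index=["g1", "g2", "g3"],
    )
    meta = pd.DataFrame(
        {
            "internode": [9, 9, 4, 4],
            "replicate": [1, 2, 1, 2],
            "genotype": ["B73"] * 4,
        },
        index=["s1", "s2", "s3", "s4"],
    )
    libs = pd.Series(10_000_000.0, index=counts.columns)
    return ExpressionMatrix(counts=counts, sample_meta=meta, library_sizes=libs)


@pytest.fixture(scope="session")
def sim_default():
    """Synthetic dataset at generator defaults (2,000 genes)."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def sim_pattern():
    """2,000 genes with exactly 100 Secondary-pattern genes planted."""
    cfg = SimConfig(
        seed=11,
        n_genes=2000,
        pattern_proportions={
            "Elongation": 0.20,
            "TransitionI": 0.10,
            "TransitionII": 0.10,
            "Secondary": 0.05,
            "EarlyLate": 0.10,
            "Flat": 0.45,
        },
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def sim_inbred():
    """10,000-gene two-genotype dataset for fold-change and PAV recovery."""
    return simulate(SimConfig(seed=3, n_genes=10_000, with_promoters=False))


@pytest.fixture(scope="session")
def sim_motif():
    """Default-size dataset used for promoter-motif checks."""
    return simulate(SimConfig(seed=5, n_genes=2000))
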