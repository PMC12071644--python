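import numpy as np
import pandas as pd
import pytest

from reodeg import SimulationSpec, generate_normal_cohort


def background_as_dict(background) -> dict:
    """Package background -> {(gene_a, gene_b): (direction, support)} for oracle comparison."""
    out = {}
    for row in background.pairs.itertuples(index=False):
        out[(row.gene_a, row.gene_b)] = (row.direction, row.support)
    return out


@pytest.fixture
def tiny_spec():
    """Well-separated genes, moderate noise: most but not all pairs stable."""
    return SimulationSpec(n_genes=20, n_normal=30, n_tumor=10, n_pairs=10, noise_sd=0.2, seed=7)


@pytest.fixture
def tiny_normal(tiny_spec):
    return generate_normal_cohort(tiny_spec)


@pytest.fixture
def expr_3x2():
    return pd.DataFrame(
        [[5.0, 1.0], [3.0, 2.0], [1.0, 4.0]],
        index=["GA", "GB", "GC"],
        columns=["S1", "S2"],
    )
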