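import numpy as np
import pandas as pd
import pytest

from trapdecon.datamodel import ExpressionMatrix, GeneSet


@pytest.fixture
def small_expression():
    """4 genes x 4 samples with simple values and condition metadata."""
    data = pd.DataFrame(
        {
            "s1": [2.0, 3.0, 5.0, 1.0],
            "s2": [4.0, 3.0, 10.0, 1.0],
            "s3": [0.0, 3.0, 2.5, 1.0],
            "s4": [2.0, 6.0, 5.0, 1.0],
        },
        index=["m1", "m2", "gA", "gB"],
    )
    meta = pd.DataFrame(
        {"condition": ["ctl", "ctl", "les", "les"]},
        index=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data, unit="fpkm", sample_meta=meta)


@pytest.fixture
def marker_panel():
    return GeneSet("neg_markers", "non-astrocyte markers", ("m1", "m2"),
                   role="contamination_marker")


@pytest.fixture
def random_matrix():
    """Factory for random positive expression matrices."""

    def make(n_genes, n_samples, seed=0, n_markers=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_genes)]
        df = pd.DataFrame(
            np.exp(rng.normal(0.0, 1.0, (n_genes, n_samples))) * 10.0,
            index=genes,
            columns=[f"s{j}" for j in range(n_samples)],
        )
        E = ExpressionMatrix(df)
        if n_markers:
            return E, GeneSet("mk", "", tuple(genes[:n_markers]),
                              role="contamination_marker")
        return E

    return make
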