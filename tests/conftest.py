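import numpy as np
import pandas as pd
import pytest

from phylotai.data_model import ExpressionMatrix, GeneCatalog, InductionTable
from phylotai.synthetic_data import (
    ScenarioConfig,
    simulate_catalog,
    simulate_induction,
    toy_lineage_and_taxonomy,
)


@pytest.fixture(scope="session")
def toy_taxonomy():
    """13-stratum toy lineage with one leaf taxon branching per stratum."""
    return toy_lineage_and_taxonomy(13)


@pytest.fixture(scope="session")
def small_cfg():
    return ScenarioConfig(seed=101, n_genes=300)


@pytest.fixture(scope="session")
def small_catalog(small_cfg):
    return simulate_catalog(small_cfg)


@pytest.fixture(scope="session")
def small_induction(small_cfg, small_catalog):
    return simulate_induction(small_cfg, small_catalog)


@pytest.fixture()
def tiny_catalog():
    """Hand-sized catalog for exact-value tests."""
    return GeneCatalog(
        pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3"],
                "ps": [1, 2, 3],
                "kaks": [0.1, 0.5, np.nan],
                "ks": [0.3, 0.6, np.nan],
            }
        )
    )


def make_induction(rows):
    """rows: iterable of (gene, condition, timepoint, log2fc, padj)."""
    return InductionTable(
        pd.DataFrame(
            rows, columns=["gene_id", "condition", "timepoint", "log2fc", "padj"]
        )
    )


def make_expression(values: dict, samples: list):
    """values: gene -> list of TPM; samples: list of (name, cond, t, rep)."""
    sample_df = pd.DataFrame(
        samples, columns=["sample", "condition", "timepoint", "replicate"]
    ).set_index("sample")
    vals = pd.DataFrame.from_dict(values, orient="index", columns=sample_df.index)
    vals.index.name = "gene_id"
    return ExpressionMatrix(vals.astype(float), sample_df)
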