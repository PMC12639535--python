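import numpy as np
import pandas as pd
import pytest

from mycscreen import (ScreenConfig, SignatureMatrix, build_reference,
                       simulate_drug_matrix, simulate_gene_sets, simulate_reference)


@pytest.fixture
def small_config():
    """Desk-scale study conditions: 200 genes, 60 DEGs, 20 compounds x 2 reps."""
    return ScreenConfig(n_genes=200, n_deg=60, n_compounds=20,
                        replicates_per_compound=2, n_cell_lines=2,
                        n_antagonists=3, n_line_decoys=1, n_low_tas_decoys=4, seed=11)


@pytest.fixture
def small_reference(small_config):
    return simulate_reference(small_config)


@pytest.fixture
def small_matrix(small_config, small_reference):
    matrix, truth = simulate_drug_matrix(small_reference, small_config)
    return matrix, truth


@pytest.fixture
def small_gene_sets(small_config, small_reference):
    return simulate_gene_sets(small_reference, small_config, n_sets=4, extra_per_set=10)


@pytest.fixture
def tiny_reference():
    """Hand-sized reference: 6 genes, 4 DEGs (2 up, 2 down)."""
    genes = ["g1", "g2", "g3", "g4", "g5", "g6"]
    fc = pd.Series([2.0, 1.5, -2.0, -1.5, 0.2, 0.0], index=genes)
    pval = pd.Series([0.01, 0.01, 0.01, 0.01, 0.01, 0.5], index=genes)
    return build_reference(fc, pval)


def make_matrix(values: np.ndarray, genes, sigs, **meta) -> SignatureMatrix:
    """Build a SignatureMatrix from a raw array plus keyword metadata columns."""
    md = pd.DataFrame(index=pd.Index(sigs, name="signature_id"))
    for k, v in meta.items():
        md[k] = v
    return SignatureMatrix(pd.DataFrame(values, index=genes, columns=sigs), md)
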