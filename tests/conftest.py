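import numpy as np
import pytest
import scipy.sparse as sp

from sccurate import QCConfig, SimConfig, generate_corpus, run_qc
from sccurate.io import CellMatrix


@pytest.fixture(scope="session")
def default_corpus():
    """The default synthetic corpus with planted ground truth."""
    return generate_corpus(SimConfig(seed=0))


@pytest.fixture(scope="session")
def clean_corpus(default_corpus):
    """Default corpus after the full QC cascade, plus the report."""
    cells, annotation, metadata, truth = default_corpus
    clean, report = run_qc(cells, annotation, QCConfig())
    return clean, report


def make_matrix(counts, samples=None, organs=None, genes=None, species="other"):
    counts = np.asarray(counts)
    n, g = counts.shape
    return CellMatrix(
        counts=sp.csr_matrix(counts),
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        gene_symbols=np.array(genes if genes is not None else [f"g{j}" for j in range(g)], dtype=object),
        sample_of_cell=np.array(samples if samples is not None else ["s0"] * n, dtype=object),
        organ_of_cell=np.array(organs, dtype=object) if organs is not None else None,
        species=species,
    )
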