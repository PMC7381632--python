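import numpy as np
import pandas as pd
import pytest

from metacazprof import simulate_cohort
from metacazprof.core_model import GeneRecord, PeptideTable, ProteinCatalog


@pytest.fixture(scope="session")
def tiny_catalog() -> ProteinCatalog:
    """Hand-built catalog covering all annotation situations."""
    return ProteinCatalog(
        [
            GeneRecord("g1", "Bacteroides", frozenset({"K01184"}), "GH43", "Beta-xylosidase"),
            GeneRecord("g2", "Bacteroides", frozenset({"K01184"}), "GH43", "Beta-xylosidase"),
            GeneRecord("g3", "Prevotella", frozenset({"K01213"}), "GH3", "Xylan-1,4-beta-xylosidase"),
            GeneRecord("g4", None, frozenset(), None, None),
            GeneRecord("g5", None, frozenset(), "GH2", "Beta-galactosidase"),
            GeneRecord("g6", "Bacteroides", frozenset({"K01190"}), "GH2", "Beta-galactosidase"),
            GeneRecord("g7", "Prevotella", frozenset(), "GH43", "Alpha-L-arabinofuranosidase"),
            GeneRecord("g8", "Faecalibacterium", frozenset({"K01184", "K01213"}), None, None),
        ]
    )


@pytest.fixture(scope="session")
def tiny_table() -> PeptideTable:
    """Four samples, six peptides spanning the taxon classes."""
    intensity = pd.DataFrame(
        {
            "S1": [3.0, 5.0, 1.0, 2.0, 4.0, 0.0],
            "S2": [6.0, 0.0, 2.0, 3.0, 1.0, 2.0],
            "S3": [0.0, 2.0, 3.0, 0.0, 2.0, 1.0],
            "S4": [1.0, 1.0, 0.0, 1.0, 3.0, 4.0],
        },
        index=["pepA", "pepB", "pepC", "pepD", "pepE", "pepF"],
    )
    gene_map = {
        "pepA": frozenset({"g1", "g2"}),   # unique Bacteroides, GH43
        "pepB": frozenset({"g1", "g3"}),   # ambiguous Bacteroides/Prevotella
        "pepC": frozenset({"g4"}),         # unannotated, no CAZy
        "pepD": frozenset({"g6"}),         # unique Bacteroides, GH2
        "pepE": frozenset({"g7"}),         # unique Prevotella, GH43
        "pepF": frozenset({"g8"}),         # unique Faecalibacterium, no CAZy
    }
    return PeptideTable(intensity, gene_map)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter synthetic cohort, shared across tests."""
    return simulate_cohort(seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
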