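import numpy as np
import pytest

from g2e.containers import (
    GeneSetCatalog,
    GenomeGeneContent,
    ScoredLinkTable,
    SquareMatrix,
)
from g2e.network import build_reference_network, normalize_weights


def random_symmetric(rng, n, labels=None, diag=0.0):
    """Random symmetric SquareMatrix helper used across test modules."""
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, diag)
    return SquareMatrix(labels or [f"t{i}" for i in range(n)], m)


def random_content(rng, n_genomes=8, n_families=40, p=0.5):
    fams = [f"f{k}" for k in range(n_families)]
    membership = {}
    for g in range(n_genomes):
        present = [f for f in fams if rng.random() < p]
        if not present:
            present = [fams[0]]
        membership[f"g{g}"] = frozenset(present)
    return GenomeGeneContent(membership)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_content():
    return GenomeGeneContent(
        {
            "gA": frozenset({"f1", "f4", "f5", "f6", "f7", "f8"}),
            "gB": frozenset({"f2", "f3", "f6", "f7", "f8"}),
        }
    )


@pytest.fixture
def small_network():
    links = ScoredLinkTable.from_records(
        [
            ("f1", "f4", 900),
            ("f1", "f5", 800),
            ("f4", "f5", 700),
            ("f2", "f3", 850),
            ("f1", "f2", 600),
            ("f6", "f7", 950),
            ("f6", "f1", 500),
            ("f7", "f2", 480),
            ("f8", "f6", 990),
        ]
    )
    return normalize_weights(build_reference_network(links))


@pytest.fixture
def small_catalog():
    return GeneSetCatalog(
        {
            "GS1": frozenset({"f1", "f2", "f3", "f4"}),
            "GS2": frozenset({"f5", "f6", "f7", "f8"}),
            "GS3": frozenset({"f9", "f10"}),
        }
    )
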