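"""Ecological and phylogenetic matrices.

Jaccard co-occurrence between OTU presence/absence profiles, iterative
OTU/sample filtering, cophenetic (patristic) distances from a Newick
tree, and label alignment across matrices.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np

from .containers import OtuTable, SquareMatrix

__all__ = [
    "read_tree",
    "filter_otu_table",
    "jaccard_cooccurrence",
    "cophenetic_distances",
    "align_matrices",
]


def read_tree(source: str | Path | dendropy.Tree) -> dendropy.Tree:
    """Load a Newick tree (path or string); unrooted trees are fine
    since only path-length sums are consumed."""
    if isinstance(source, dendropy.Tree):
        return source
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    try:
        return dendropy.Tree.get(data=text, schema="newick")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate leaf names in tree: {exc}") from exc


def filter_otu_table(
    table: OtuTable,
    min_samples_per_otu: int = 3,
    min_otus_per_sample: int = 3,
) -> OtuTable:
    """Drop sparse OTUs and samples, iterating to a fixed point.

    Removing an OTU can push a sample below its minimum and vice
    versa, so filtering alternates until both rules hold. Raises if
    nothing survives.
    """
    m = table.matrix.astype(np.int64)
    otus = np.array(table.otu_ids, dtype=object)
    samples = np.array(table.sample_ids, dtype=object)
    while True:
        keep_otus = m.sum(axis=1) >= min_samples_per_otu
        m, otus = m[keep_otus], otus[keep_otus]
        keep_samples = m.sum(axis=0) >= min_otus_per_sample
        m, samples = m[:, keep_samples], samples[keep_samples]
        if keep_otus.all() and keep_samples.all():
            break
        if m.size == 0:
            break
    if m.size == 0 or m.shape[0] == 0 or m.shape[1] == 0:
        raise ValueError(
            "OTU table empty after filtering "
            f"(started with {table.shape[0]} OTUs x {table.shape[1]} samples)"
        )
    return OtuTable(list(otus), list(samples), m)


def jaccard_cooccurrence(table: OtuTable) -> SquareMatrix:
    """Pairwise Jaccard similarity between OTU presence profiles.

    J(i, j) = |samples with both| / |samples with either|; pairs with
    an empty union are undefined (NaN). Diagonal is 1 for any OTU
    present somewhere.
    """
    if len(table.otu_ids) < 2:
        raise ValueError("need at least 2 OTUs")
    m = table.matrix.astype(np.int64)
    inter = m @ m.T
    row = m.sum(axis=1)
    union = row[:, None] + row[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        j = np.where(union > 0, inter / np.maximum(union, 1), np.nan)
    return SquareMatrix(list(table.otu_ids), j)


def cophenetic_distances(
    tree: str | Path | dendropy.Tree,
) -> SquareMatrix:
    """Patristic distance (sum of branch lengths on the connecting
    path) between every leaf pair, in sorted leaf-label order."""
    t = read_tree(tree)
    labels = [leaf.taxon.label for leaf in t.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf names in tree")
    pdm = t.phylogenetic_distance_matrix()
    order = sorted(labels)
    taxa = {tx.label: tx for tx in t.taxon_namespace}
    n = len(order)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(
                taxa[order[i]], taxa[order[j]]
            )
    return SquareMatrix(order, d)


def align_matrices(matrices: list[SquareMatrix]) -> list[SquareMatrix]:
    """Restrict all matrices to their common labels in one shared
    (sorted) order. Requires an intersection of at least 3 labels."""
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices to align")
    common = set(matrices[0].labels)
    for m in matrices[1:]:
        common &= set(m.labels)
    order = sorted(common)
    if len(order) < 3:
        raise ValueError(
            f"label intersection has only {len(order)} ids (< 3)"
        )
    return [m.reindex(order) for m in matrices]
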