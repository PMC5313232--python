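"""Markov Clustering (MCL) of the weighted reference network.

MCL simulates flow on the graph: the column-stochastic transition
matrix is alternately *expanded* (squared, letting flow spread) and
*inflated* (raised entrywise to a power > 1 and renormalized,
strengthening strong flows and starving weak ones) until it reaches a
doubly-idempotent limit whose attractor structure defines a hard
partition of the nodes. A high inflation (default 4) yields
fine-grained clusters, the "putative pathways and complexes" used by
the genome content similarity index.

Implementation notes:

* A self-loop is added to every node with weight equal to its maximum
  incident edge weight before normalization; this damps parity
  effects and stabilizes convergence.
* Entries below ``prune_threshold`` are dropped after each inflation
  (then columns are renormalized) to keep the matrix sparse.
* Node order is sorted ids, so results are bit-reproducible.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp

from .containers import GeneSetCatalog, GenomeGeneContent
from .network import ReferenceNetwork

__all__ = ["mcl_cluster", "filter_catalog", "catalog_coverage"]

DEFAULT_INFLATION = 4.0
DEFAULT_MIN_SET_SIZE = 4


def _column_normalize(m: sp.csc_matrix) -> sp.csc_matrix:
    sums = np.asarray(m.sum(axis=0)).ravel()
    sums[sums == 0.0] = 1.0
    return m @ sp.diags(1.0 / sums)


def _transition_matrix(net: ReferenceNetwork, nodes: list[str]) -> sp.csc_matrix:
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    max_incident = np.zeros(n)
    for a, b, data in net.graph.edges(data=True):
        w = data.get("weight")
        if w is None:
            raise ValueError(
                "network has no normalized weights; run normalize_weights first"
            )
        if not 0.0 < w <= 1.0:
            raise ValueError(f"edge weight {w} outside (0, 1]")
        i, j = index[a], index[b]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
        max_incident[i] = max(max_incident[i], w)
        max_incident[j] = max(max_incident[j], w)
    # self-loops: max incident weight (1.0 for isolated nodes)
    max_incident[max_incident == 0.0] = 1.0
    rows += list(range(n))
    cols += list(range(n))
    vals += list(max_incident)
    m = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return _column_normalize(m)


def _inflate(m: sp.csc_matrix, inflation: float, prune: float) -> sp.csc_matrix:
    m = m.power(inflation)
    if prune > 0.0:
        m.data[m.data < prune] = 0.0
        m.eliminate_zeros()
    return _column_normalize(m)


def _extract_clusters(
    m: sp.csc_matrix, nodes: list[str], attractor_eps: float = 1e-5
) -> list[set[int]]:
    """Partition node indices from a converged MCL matrix.

    Attractors are nodes with positive diagonal flow; attractors
    connected through nonzero entries form one attractor system.
    Every other node joins the system it sends the most flow to
    (ties: system with the lexicographically smallest attractor id).
    """
    n = len(nodes)
    m = m.tocsc()
    diag = m.diagonal()
    attractors = np.flatnonzero(diag > attractor_eps)
    if attractors.size == 0:  # degenerate; treat max-per-column as attractor
        attractors = np.unique(
            [m.indices[m.indptr[j] + np.argmax(m.data[m.indptr[j]:m.indptr[j + 1]])]
             for j in range(n) if m.indptr[j] != m.indptr[j + 1]]
        )
    attr_set = set(attractors.tolist())
    # union attractor systems: attractors linked by any nonzero flow
    parent = {a: a for a in attr_set}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    coo = m.tocoo()
    for i, j, v in zip(coo.row, coo.col, coo.data):
        if v > attractor_eps and i in attr_set and j in attr_set and i != j:
            union(int(i), int(j))

    systems: dict[int, set[int]] = {}
    for a in attr_set:
        systems.setdefault(find(a), set()).add(a)
    sys_of_attr = {a: root for root, mem in systems.items() for a in mem}
    # smallest attractor node id per system, for deterministic tie-breaks
    sys_min = {root: min(nodes[a] for a in mem) for root, mem in systems.items()}

    clusters: dict[int, set[int]] = {root: set(mem) for root, mem in systems.items()}
    for j in range(n):
        if j in attr_set:
            continue
        # flow from column j into each attractor system
        col = m[:, [j]].tocoo()
        flow: dict[int, float] = {}
        for i, v in zip(col.row, col.data):
            if v > attractor_eps and int(i) in attr_set:
                root = sys_of_attr[int(i)]
                flow[root] = flow.get(root, 0.0) + float(v)
        if flow:
            best = min(
                flow, key=lambda r: (-flow[r], sys_min[r])
            )
            clusters[best].add(j)
        else:
            clusters.setdefault(-j - 1, {j})  # orphan -> singleton
    return [clusters[k] for k in sorted(clusters, key=lambda r: sys_min.get(r, nodes[-r - 1] if r < 0 else ""))]


def mcl_cluster(
    net: ReferenceNetwork,
    inflation: float = DEFAULT_INFLATION,
    max_iterations: int = 100,
    convergence_tol: float = 1e-6,
    prune_threshold: float = 1e-5,
) -> GeneSetCatalog:
    """Cluster a weighted reference network into disjoint gene sets.

    Parameters
    ----------
    net
        Network with normalized edge weights in (0, 1].
    inflation
        Inflation exponent (> 1). Higher values give finer clusters.
    max_iterations, convergence_tol
        Iteration stops when the largest entrywise change drops below
        ``convergence_tol``, or after ``max_iterations`` (with a
        warning; the current matrix is still interpreted).
    prune_threshold
        Entries below this are zeroed after each inflation.

    Returns
    -------
    GeneSetCatalog
        A true partition: every network node in exactly one set. Set
        ids are ``GS<k>`` numbered by each cluster's smallest member.
    """
    if inflation <= 1.0:
        raise ValueError("inflation must exceed 1")
    nodes = sorted(net.graph.nodes)
    if not nodes:
        return GeneSetCatalog({})
    m = _transition_matrix(net, nodes)
    converged = False
    for _ in range(max_iterations):
        prev = m.copy()
        m = _inflate((m @ m).tocsc(), inflation, prune_threshold)
        delta = abs(m - prev)
        if delta.nnz == 0 or delta.max() < convergence_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge in {max_iterations} iterations; "
            "interpreting current matrix",
            stacklevel=2,
        )
    clusters = _extract_clusters(m, nodes)
    named = sorted(
        (sorted(nodes[i] for i in cl) for cl in clusters),
        key=lambda members: members[0],
    )
    width = max(4, len(str(len(named))))
    return GeneSetCatalog(
        {
            f"GS{k:0{width}d}": frozenset(members)
            for k, members in enumerate(named, 1)
        }
    )


def filter_catalog(
    catalog: GeneSetCatalog, min_size: int = DEFAULT_MIN_SET_SIZE
) -> GeneSetCatalog:
    """Keep only gene sets with at least ``min_size`` families."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    return GeneSetCatalog(
        {s: m for s, m in catalog.sets.items() if len(m) >= min_size}
    )


def catalog_coverage(
    catalog: GeneSetCatalog,
    content: GenomeGeneContent,
    min_size: int = DEFAULT_MIN_SET_SIZE,
) -> dict[str, float]:
    """Per-genome fraction of its families that sit in retained sets.

    Mirrors the survey of how much of each genome's gene complement
    the clustered pathways capture at a given minimum set size.
    """
    retained = filter_catalog(catalog, min_size).member_families()
    out = {}
    for g in content.genome_ids:
        fams = content.families(g)
        if not fams:
            raise ValueError(f"genome {g!r} has no families")
        out[g] = len(fams & retained) / len(fams)
    return out
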