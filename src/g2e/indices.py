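"""Pairwise genomics-based indices of microbial association.

Two indices are computed for a pair of genomes A and B from gene-family
presence/absence:

**Genome content similarity.** For every clustered gene set (putative
pathway) of at least ``min_size`` families, the per-gene similarity is
the fraction of the set's families whose presence/absence state is
identical in A and B — joint absence counts as agreement. Per-set
normalization prevents large sets from dominating. The index is the
unweighted mean over sets *present* in at least one of the two genomes,
where a set counts as present in a genome holding at least 5% of its
families; sets absent from both genomes are excluded so shared absence
of whole pathways cannot inflate the score.

**Microbe-microbe functional association.** On the reference network
induced by the families of A ∪ B, each node is labeled A-only, B-only
or both. Among edges joining *exclusive* families (classes A–A, A–B,
B–B), the index is the fraction in class A–B: the edges that would have
to cross organismal boundaries for the functional link to be realized
in a two-species community. Edges are treated as unweighted.

Undefined values (zero denominators) propagate as NaN, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import GeneSetCatalog, GenomeGeneContent, SquareMatrix
from .mcl import filter_catalog
from .network import ReferenceNetwork

__all__ = [
    "EdgeClassCounts",
    "PairIndexResult",
    "gene_set_present",
    "gene_set_similarity",
    "genome_content_similarity",
    "classify_edges",
    "functional_association_index",
    "compute_pair_indices",
    "pairwise_index_matrix",
    "DEFAULT_PRESENCE_FRACTION",
]

DEFAULT_PRESENCE_FRACTION = 0.05
DEFAULT_MIN_SET_SIZE = 4


@dataclass(frozen=True)
class EdgeClassCounts:
    """Counts of the six undirected edge classes in a two-genome
    induced network (node labels: A-only, B-only, both)."""

    aa: int = 0
    bb: int = 0
    ab: int = 0
    both_a: int = 0
    both_b: int = 0
    both_both: int = 0

    def total(self) -> int:
        return (
            self.aa + self.bb + self.ab
            + self.both_a + self.both_b + self.both_both
        )

    def exclusive_total(self) -> int:
        """Edges whose both endpoints are exclusive to one genome."""
        return self.aa + self.ab + self.bb


@dataclass(frozen=True)
class PairIndexResult:
    genome_a: str
    genome_b: str
    genome_content_similarity: float  # NaN when undefined
    functional_association: float  # NaN when undefined
    n_sets_used: int
    edge_classes: EdgeClassCounts


def gene_set_present(
    genome_families: frozenset[str] | set[str],
    gene_set: frozenset[str] | set[str],
    presence_fraction: float = DEFAULT_PRESENCE_FRACTION,
) -> bool:
    """A gene set counts as present when the genome carries at least
    ``presence_fraction`` of its families (inclusive boundary)."""
    if not gene_set:
        raise ValueError("empty gene set")
    return len(genome_families & set(gene_set)) / len(gene_set) >= presence_fraction


def gene_set_similarity(
    gene_set: frozenset[str] | set[str],
    fam_a: frozenset[str] | set[str],
    fam_b: frozenset[str] | set[str],
) -> float:
    """Fraction of the set's families with identical presence/absence
    state in the two genomes (shared absence counts as a match)."""
    if not gene_set:
        raise ValueError("empty gene set")
    same = sum(1 for f in gene_set if (f in fam_a) == (f in fam_b))
    return same / len(gene_set)


def genome_content_similarity(
    a: str,
    b: str,
    content: GenomeGeneContent,
    catalog: GeneSetCatalog,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    presence_fraction: float = DEFAULT_PRESENCE_FRACTION,
) -> float:
    """Unweighted mean of per-set similarities over qualifying sets.

    A set qualifies when it has >= ``min_size`` families and is present
    (5% rule) in at least one of the two genomes. Returns NaN when no
    set qualifies.
    """
    fam_a = content.families(a)
    fam_b = content.families(b)
    sims = []
    for members in filter_catalog(catalog, min_size).sets.values():
        if gene_set_present(fam_a, members, presence_fraction) or gene_set_present(
            fam_b, members, presence_fraction
        ):
            sims.append(gene_set_similarity(members, fam_a, fam_b))
    return float(np.mean(sims)) if sims else float("nan")


def classify_edges(
    net: ReferenceNetwork,
    fam_a: frozenset[str] | set[str],
    fam_b: frozenset[str] | set[str],
) -> EdgeClassCounts:
    """Label nodes of the induced two-genome network and count edges
    per class. Every induced edge falls in exactly one of the six
    classes; edges are unweighted."""
    present = set(fam_a) | set(fam_b)
    counts = dict(aa=0, bb=0, ab=0, both_a=0, both_b=0, both_both=0)
    for u, v in net.graph.edges:
        if u not in present or v not in present:
            continue
        lu = (u in fam_a, u in fam_b)
        lv = (v in fam_a, v in fam_b)
        if lu == (True, True) and lv == (True, True):
            counts["both_both"] += 1
        elif (True, True) in (lu, lv):
            other = lv if lu == (True, True) else lu
            counts["both_a" if other == (True, False) else "both_b"] += 1
        elif lu == lv:
            counts["aa" if lu == (True, False) else "bb"] += 1
        else:
            counts["ab"] += 1
    return EdgeClassCounts(**counts)


def functional_association_index(
    net: ReferenceNetwork,
    fam_a: frozenset[str] | set[str],
    fam_b: frozenset[str] | set[str],
) -> float:
    """|A–B| / (|A–A| + |A–B| + |B–B|), NaN when no edge joins two
    exclusive families."""
    c = classify_edges(net, fam_a, fam_b)
    denom = c.exclusive_total()
    return c.ab / denom if denom else float("nan")


def compute_pair_indices(
    a: str,
    b: str,
    content: GenomeGeneContent,
    catalog: GeneSetCatalog,
    net: ReferenceNetwork,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    presence_fraction: float = DEFAULT_PRESENCE_FRACTION,
) -> PairIndexResult:
    """Both indices plus diagnostics for one genome pair."""
    fam_a = content.families(a)
    fam_b = content.families(b)
    filtered = filter_catalog(catalog, min_size)
    sims = []
    for members in filtered.sets.values():
        if gene_set_present(fam_a, members, presence_fraction) or gene_set_present(
            fam_b, members, presence_fraction
        ):
            sims.append(gene_set_similarity(members, fam_a, fam_b))
    classes = classify_edges(net, fam_a, fam_b)
    denom = classes.exclusive_total()
    return PairIndexResult(
        genome_a=a,
        genome_b=b,
        genome_content_similarity=(
            float(np.mean(sims)) if sims else float("nan")
        ),
        functional_association=(
            classes.ab / denom if denom else float("nan")
        ),
        n_sets_used=len(sims),
        edge_classes=classes,
    )


def _presence_matrix(
    content: GenomeGeneContent, genome_ids: list[str], families: list[str]
) -> np.ndarray:
    fam_index = {f: k for k, f in enumerate(families)}
    m = np.zeros((len(genome_ids), len(families)), dtype=bool)
    for gi, g in enumerate(genome_ids):
        for f in content.families(g):
            k = fam_index.get(f)
            if k is not None:
                m[gi, k] = True
    return m


def pairwise_index_matrix(
    content: GenomeGeneContent,
    catalog: GeneSetCatalog,
    net: ReferenceNetwork,
    genome_ids: list[str] | None = None,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    presence_fraction: float = DEFAULT_PRESENCE_FRACTION,
) -> tuple[SquareMatrix, SquareMatrix]:
    """Full pairwise similarity and association matrices.

    Vectorized over genome pairs; numerically identical to the
    per-pair functions. The similarity diagonal is 1 wherever defined;
    the association self-pair has no exclusive families and is
    recorded as missing (NaN).
    """
    if genome_ids is None:
        genome_ids = content.genome_ids
    n = len(genome_ids)
    if n < 2:
        raise ValueError("need at least 2 genomes")

    filtered = filter_catalog(catalog, min_size)
    # --- similarity: per set, matches = MM' + (1-M)(1-M)'
    sim_num = np.zeros((n, n))
    sim_den = np.zeros((n, n))
    for members in filtered.sets.values():
        fams = sorted(members)
        m = _presence_matrix(content, genome_ids, fams)
        size = len(fams)
        frac = m.sum(axis=1) / size
        present = frac >= presence_fraction
        qualifies = present[:, None] | present[None, :]
        mf = m.astype(float)
        matches = mf @ mf.T + (1.0 - mf) @ (1.0 - mf).T
        sim_num += np.where(qualifies, matches / size, 0.0)
        sim_den += qualifies
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(sim_den > 0, sim_num / np.maximum(sim_den, 1), np.nan)

    # --- association: per edge, boolean presence vectors over genomes
    edge_list = [
        (u, v) for u, v in net.graph.edges
    ]
    ab = np.zeros((n, n))
    excl = np.zeros((n, n))
    if edge_list:
        all_net_fams = sorted({f for e in edge_list for f in e})
        pres = _presence_matrix(content, genome_ids, all_net_fams)
        fidx = {f: k for k, f in enumerate(all_net_fams)}
        for u, v in edge_list:
            pu = pres[:, fidx[u]]
            pv = pres[:, fidx[v]]
            # for pair (i, j): u exclusive-to-i = pu[i] & ~pu[j]
            u_i = pu[:, None] & ~pu[None, :]   # u in i only
            u_j = ~pu[:, None] & pu[None, :]   # u in j only
            v_i = pv[:, None] & ~pv[None, :]
            v_j = ~pv[:, None] & pv[None, :]
            cross = (u_i & v_j) | (u_j & v_i)
            within = (u_i & v_i) | (u_j & v_j)
            ab += cross
            excl += cross + within
    with np.errstate(invalid="ignore", divide="ignore"):
        assoc = np.where(excl > 0, ab / np.maximum(excl, 1), np.nan)
    np.fill_diagonal(assoc, np.nan)

    if np.isnan(sim).all() and np.isnan(assoc).all():
        raise ValueError("all pairwise indices undefined")
    return (
        SquareMatrix(list(genome_ids), sim),
        SquareMatrix(list(genome_ids), assoc),
    )
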