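"""Sister-pair gene-set screen.

Finds gene sets whose content similarity distinguishes a co-occurring
focal genome pair from a non-co-occurring contrast pair: sets that are
large enough, substantially represented in the pair, and highly
similar for the focal pair — minus any set that also passes for the
contrast pair. Candidate drivers of co-occurrence fall out of the
difference.
"""

from __future__ import annotations

from dataclasses import dataclass

from .containers import GeneSetCatalog, GenomeGeneContent
from .indices import gene_set_similarity

__all__ = ["ScreenCriteria", "set_representation", "screen_gene_sets",
           "screen_details"]


@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds for the screen: minimum set size, minimum per-set
    similarity, minimum representation of the set in the pair's
    pooled gene content."""

    min_set_size: int = 8
    min_similarity: float = 0.6
    min_representation: float = 0.6

    def __post_init__(self) -> None:
        if self.min_set_size < 1:
            raise ValueError("min_set_size must be >= 1")
        for name in ("min_similarity", "min_representation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def set_representation(
    gene_set: frozenset[str] | set[str],
    fam_a: frozenset[str] | set[str],
    fam_b: frozenset[str] | set[str],
) -> float:
    """Fraction of the set's families present in the union of the two
    genomes — how much of the pathway the pair carries at all,
    independent of whether the genomes agree."""
    if not gene_set:
        raise ValueError("empty gene set")
    union = set(fam_a) | set(fam_b)
    return len(set(gene_set) & union) / len(gene_set)


def _passing_sets(
    catalog: GeneSetCatalog,
    content: GenomeGeneContent,
    pair: tuple[str, str],
    criteria: ScreenCriteria,
) -> set[str]:
    fam_a = content.families(pair[0])
    fam_b = content.families(pair[1])
    out = set()
    for sid, members in catalog.sets.items():
        if len(members) < criteria.min_set_size:
            continue
        if gene_set_similarity(members, fam_a, fam_b) < criteria.min_similarity:
            continue
        if set_representation(members, fam_a, fam_b) < criteria.min_representation:
            continue
        out.add(sid)
    return out


def screen_gene_sets(
    catalog: GeneSetCatalog,
    content: GenomeGeneContent,
    focal: tuple[str, str],
    contrast: tuple[str, str],
    criteria: ScreenCriteria = ScreenCriteria(),
) -> list[str]:
    """Set ids passing all criteria for the focal pair but not for the
    contrast pair, in deterministic (sorted) order."""
    if frozenset(focal) == frozenset(contrast):
        raise ValueError("focal and contrast pairs are identical")
    if not catalog.sets:
        raise ValueError("empty catalog")
    passing_focal = _passing_sets(catalog, content, focal, criteria)
    passing_contrast = _passing_sets(catalog, content, contrast, criteria)
    return sorted(passing_focal - passing_contrast)


def screen_details(
    catalog: GeneSetCatalog,
    content: GenomeGeneContent,
    focal: tuple[str, str],
    contrast: tuple[str, str],
    criteria: ScreenCriteria = ScreenCriteria(),
) -> list[dict]:
    """Per-hit similarity/representation for both pairs (CLI report)."""
    hits = screen_gene_sets(catalog, content, focal, contrast, criteria)
    fa, fb = (content.families(g) for g in focal)
    ca, cb = (content.families(g) for g in contrast)
    rows = []
    for sid in hits:
        members = catalog.sets[sid]
        rows.append(
            {
                "set": sid,
                "size": len(members),
                "focal_similarity": gene_set_similarity(members, fa, fb),
                "focal_representation": set_representation(members, fa, fb),
                "contrast_similarity": gene_set_similarity(members, ca, cb),
                "contrast_representation": set_representation(members, ca, cb),
            }
        )
    return rows
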