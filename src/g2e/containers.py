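"""Core in-memory containers shared across the pipeline.

All identifiers (genome, gene family, OTU, sample) are opaque,
case-sensitive strings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScoredLinkTable",
    "GenomeGeneContent",
    "OtuTable",
    "SquareMatrix",
    "GeneSetCatalog",
    "SYMMETRY_TOL",
]

#: absolute tolerance used when validating matrix symmetry
SYMMETRY_TOL = 1e-12


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order-free key for an unordered pair of ids."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ScoredLinkTable:
    """Scored functional links between gene families.

    Each record is one unordered family pair with an integer
    gene-neighbor evidence score in [0, 1000]. Construction
    canonicalizes pair order, drops self-links (with a warning) and
    deduplicates, keeping the maximum score for a pair.
    """

    records: tuple[tuple[str, str, int], ...]

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, int]]
    ) -> "ScoredLinkTable":
        best: dict[tuple[str, str], int] = {}
        n_self = 0
        n_dup = 0
        for a, b, score in records:
            score = int(score)
            if not 0 <= score <= 1000:
                raise ValueError(
                    f"link score {score} for ({a}, {b}) outside [0, 1000]"
                )
            if a == b:
                n_self += 1
                continue
            key = canonical_pair(a, b)
            if key in best:
                n_dup += 1
                if score > best[key]:
                    best[key] = score
            else:
                best[key] = score
        if n_self:
            warnings.warn(f"dropped {n_self} self-link(s)", stacklevel=2)
        if n_dup:
            warnings.warn(
                f"collapsed {n_dup} duplicate link(s), keeping max score",
                stacklevel=2,
            )
        recs = tuple(sorted((a, b, s) for (a, b), s in best.items()))
        return cls(records=recs)

    def __len__(self) -> int:
        return len(self.records)

    def scores(self) -> dict[tuple[str, str], int]:
        return {(a, b): s for a, b, s in self.records}


@dataclass(frozen=True)
class GenomeGeneContent:
    """Presence/absence of gene families per genome.

    ``membership`` maps each genome id to the non-empty set of gene
    families it encodes.
    """

    membership: Mapping[str, frozenset[str]]

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]]
    ) -> "GenomeGeneContent":
        acc: dict[str, set[str]] = {}
        for genome, family in pairs:
            if not genome or not family:
                raise ValueError("blank genome or family id")
            acc.setdefault(genome, set()).add(family)
        if not acc:
            raise ValueError("no genome/family pairs provided")
        return cls({g: frozenset(fams) for g, fams in acc.items()})

    def __post_init__(self) -> None:
        for g, fams in self.membership.items():
            if not fams:
                raise ValueError(f"genome {g!r} has an empty family set")

    @property
    def genome_ids(self) -> list[str]:
        return sorted(self.membership)

    def families(self, genome: str) -> frozenset[str]:
        try:
            return self.membership[genome]
        except KeyError:
            raise KeyError(f"unknown genome id {genome!r}") from None

    def all_families(self) -> frozenset[str]:
        out: set[str] = set()
        for fams in self.membership.values():
            out |= fams
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.membership)


@dataclass
class OtuTable:
    """Binary OTU x sample incidence table."""

    otu_ids: list[str]
    sample_ids: list[str]
    matrix: np.ndarray  # shape (n_otus, n_samples), values in {0, 1}

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match id lists")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        vals = np.unique(self.matrix)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(
                f"OTU table entries must be 0/1; found {vals[:5]}"
            )
        self.matrix = self.matrix.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=self.otu_ids, columns=self.sample_ids
        )


@dataclass
class SquareMatrix:
    """Labeled symmetric real matrix (similarities or distances).

    Missing (undefined) entries are NaN. Symmetry is enforced within
    ``SYMMETRY_TOL``; NaNs must also be placed symmetrically.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        nan = np.isnan(self.values)
        if not (nan == nan.T).all():
            raise ValueError("asymmetric missing-value pattern")
        diff = np.abs(self.values - self.values.T)
        if np.nanmax(diff, initial=0.0) > SYMMETRY_TOL:
            raise ValueError(
                "matrix asymmetric beyond tolerance "
                f"(max |m - m.T| = {np.nanmax(diff):g})"
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    def loc(self, a: str, b: str) -> float:
        return float(
            self.values[self.labels.index(a), self.labels.index(b)]
        )

    def reindex(self, labels: Sequence[str]) -> "SquareMatrix":
        """Restrict/reorder to ``labels`` (must all be present)."""
        idx = [self.labels.index(l) for l in labels]
        return SquareMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.labels, columns=self.labels
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SquareMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels differ")
        return cls([str(l) for l in df.index], df.to_numpy(dtype=float))


@dataclass(frozen=True)
class GeneSetCatalog:
    """Disjoint clusters of gene families ("putative pathways").

    ``sets`` maps a set id to the frozenset of member families; sets
    are pairwise disjoint (each family belongs to at most one set).
    """

    sets: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for sid, members in self.sets.items():
            for fam in members:
                if fam in seen:
                    raise ValueError(
                        f"family {fam!r} in both {seen[fam]!r} and {sid!r}"
                    )
                seen[fam] = sid

    @property
    def set_ids(self) -> list[str]:
        return sorted(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def sizes(self) -> dict[str, int]:
        return {sid: len(m) for sid, m in self.sets.items()}

    def member_families(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.sets.values():
            out |= m
        return frozenset(out)
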