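"""Readers and writers for every on-disk artifact the pipeline touches.

All tabular formats are TSV. Square matrices use ``NA`` for undefined
entries. Trees are Newick, handled in :mod:`g2e.ecology`.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    GeneSetCatalog,
    GenomeGeneContent,
    OtuTable,
    ScoredLinkTable,
    SquareMatrix,
)

__all__ = [
    "read_link_table",
    "read_genome_content",
    "write_genome_content",
    "read_otu_table",
    "write_otu_table",
    "read_square_matrix",
    "write_square_matrix",
    "read_catalog",
    "write_catalog",
    "write_link_table",
]


def _tsv_rows(path: str | Path):
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            yield lineno, row


def read_link_table(path: str | Path) -> ScoredLinkTable:
    """Read a scored gene-family link table.

    Expects >= 3 tab-separated columns: family_a, family_b, score
    (integer, 0-1000). A single header line is tolerated and skipped
    when its third field is not an integer. Pairs are canonicalized;
    duplicates keep the maximum score; self-links are dropped with a
    warning.
    """
    records: list[tuple[str, str, int]] = []
    for lineno, row in _tsv_rows(path):
        if len(row) < 3:
            raise ValueError(
                f"{path}: line {lineno}: expected >= 3 columns, "
                f"got {len(row)}"
            )
        a, b, raw = row[0].strip(), row[1].strip(), row[2].strip()
        try:
            score = int(raw)
        except ValueError:
            if lineno == 1:  # header line
                continue
            raise ValueError(
                f"{path}: line {lineno}: score {raw!r} is not an integer"
            ) from None
        if not a or not b:
            raise ValueError(f"{path}: line {lineno}: blank family id")
        if not 0 <= score <= 1000:
            raise ValueError(
                f"{path}: line {lineno}: score {score} outside [0, 1000]"
            )
        records.append((a, b, score))
    return ScoredLinkTable.from_records(records)


def write_link_table(links: ScoredLinkTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["family_a", "family_b", "score"])
        w.writerows(links.records)


def read_genome_content(path: str | Path) -> GenomeGeneContent:
    """Read a two-column (genome id, family id) membership table.

    Duplicate rows collapse. Raises on an empty file or blank ids.
    """
    pairs: list[tuple[str, str]] = []
    for lineno, row in _tsv_rows(path):
        if len(row) < 2:
            raise ValueError(
                f"{path}: line {lineno}: expected 2 columns"
            )
        g, f = row[0].strip(), row[1].strip()
        if lineno == 1 and (g.lower(), f.lower()) == ("genome", "family"):
            continue
        if not g or not f:
            raise ValueError(f"{path}: line {lineno}: blank id")
        pairs.append((g, f))
    if not pairs:
        raise ValueError(f"{path}: no genome/family rows")
    return GenomeGeneContent.from_pairs(pairs)


def write_genome_content(
    content: GenomeGeneContent, path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["genome", "family"])
        for g in content.genome_ids:
            for fam in sorted(content.families(g)):
                w.writerow([g, fam])


def read_otu_table(path: str | Path) -> OtuTable:
    """Read a binary OTU x sample table (row header = OTU ids,
    column header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if values.size and not np.isin(np.unique(values), (0, 1)).all():
        raise ValueError(f"{path}: OTU table entries must be 0/1")
    return OtuTable(
        otu_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        matrix=values.astype(np.int8),
    )


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t")


def read_square_matrix(path: str | Path) -> SquareMatrix:
    """Read a labeled square matrix; ``NA`` marks undefined entries.

    Raises if row/column labels disagree or the matrix is asymmetric
    beyond 1e-12.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    return SquareMatrix.from_frame(df)


def write_square_matrix(matrix: SquareMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", na_rep="NA")


def read_catalog(path: str | Path) -> GeneSetCatalog:
    """Read a gene-set catalog (TSV: set id, family id)."""
    acc: dict[str, set[str]] = {}
    for lineno, row in _tsv_rows(path):
        if len(row) < 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 columns")
        sid, fam = row[0].strip(), row[1].strip()
        if lineno == 1 and (sid.lower(), fam.lower()) == ("set", "family"):
            continue
        if not sid or not fam:
            raise ValueError(f"{path}: line {lineno}: blank id")
        acc.setdefault(sid, set()).add(fam)
    return GeneSetCatalog({s: frozenset(m) for s, m in acc.items()})


def write_catalog(catalog: GeneSetCatalog, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["set", "family"])
        for sid in catalog.set_ids:
            for fam in sorted(catalog.sets[sid]):
                w.writerow([sid, fam])
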