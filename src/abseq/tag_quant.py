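"""UMI deduplication, count-matrix construction and population calling.

PCR amplifies individual tag molecules unevenly, so raw read counts
overstate molecule numbers.  Each original molecule carries a random 8-nt
UMI that replicates with it; counting distinct UMIs per antibody within a
cell collapses the duplicates back to molecule-scale counts.  Cells are
then called positive for a marker when their UMI count reaches a
threshold, giving single-positive, double-positive and negative
population labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import scipy.io
import scipy.sparse

from .barcode_groups import BarcodeGroup

NEGATIVE = "negative"
DOUBLE_POSITIVE = "double_positive"


@dataclass
class CellProfile:
    """Per-cell antibody counts: raw reads and UMI-deduplicated molecules."""

    barcode: str
    umi_counts: dict[str, int] = field(default_factory=dict)
    raw_counts: dict[str, int] = field(default_factory=dict)
    label: Optional[str] = None


@dataclass
class PopulationSummary:
    """Cell counts and label fractions over a classified matrix."""

    n_cells: int
    counts: dict[str, int]
    fractions: dict[str, float]


def umi_dedup(group: BarcodeGroup, merge_hamming1: bool = False) -> CellProfile:
    """Collapse a barcode group's reads to distinct-UMI counts per antibody.

    ``umi_counts[a]`` is the number of distinct UMI sequences among reads
    of antibody ``a``; UMIs are never collapsed across antibodies.  With
    ``merge_hamming1`` (off by default) UMIs within one substitution of
    each other are additionally merged into connected components, guarding
    against UMI sequencing errors at the cost of true-collision
    undercounting.
    """
    per_ab_umis: dict[str, set[str]] = {}
    for antibody, umi in group.umi_records:
        per_ab_umis.setdefault(antibody, set()).add(umi)
    if merge_hamming1:
        from .hamming_filter import connected_components_h1

        umi_counts = {
            a: len(connected_components_h1(umis).clusters)
            for a, umis in per_ab_umis.items()
        }
    else:
        umi_counts = {a: len(umis) for a, umis in per_ab_umis.items()}
    return CellProfile(
        barcode=group.barcode,
        umi_counts=umi_counts,
        raw_counts=dict(group.per_antibody_read_counts),
    )


def build_matrix(profiles: Iterable[CellProfile], antibodies: list[str]) -> pd.DataFrame:
    """Cell x antibody UMI-count matrix (rows: barcodes, columns: panel order)."""
    profiles = list(profiles)
    barcodes = [p.barcode for p in profiles]
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes among profiles")
    data = [
        [p.umi_counts.get(a, 0) for a in antibodies] for p in profiles
    ]
    matrix = pd.DataFrame(data, index=pd.Index(barcodes, name="barcode"), columns=antibodies)
    return matrix.astype(int)


def classify_cells(
    matrix: pd.DataFrame, positive_threshold: int = 5
) -> tuple[pd.Series, PopulationSummary]:
    """Call each cell's population from thresholded UMI counts.

    A cell is positive for marker ``m`` iff its UMI count for ``m`` is at
    least ``positive_threshold``.  Cells positive for exactly one marker
    are labeled ``"<m>+"``, for two or more markers ``double_positive``,
    and for none ``negative`` (reported, not dropped).
    """
    if positive_threshold < 1:
        raise ValueError("positive_threshold must be >= 1")
    markers = list(matrix.columns)
    positive = matrix >= positive_threshold

    def _label(row) -> str:
        pos = [m for m in markers if row[m]]
        if not pos:
            return NEGATIVE
        if len(pos) == 1:
            return f"{pos[0]}+"
        return DOUBLE_POSITIVE

    labels = pd.Series(
        [_label(positive.loc[b]) for b in matrix.index],
        index=matrix.index,
        name="label",
        dtype=object,
    )
    canonical = [f"{m}+" for m in markers] + [DOUBLE_POSITIVE, NEGATIVE]
    counts = {lab: int((labels == lab).sum()) for lab in canonical}
    n = len(labels)
    fractions = {lab: (c / n if n else 0.0) for lab, c in counts.items()}
    return labels, PopulationSummary(n_cells=n, counts=counts, fractions=fractions)


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="barcode")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="barcode")


def write_matrix_mtx(matrix: pd.DataFrame, directory) -> None:
    """MatrixMarket triplet plus barcode/feature sidecars (cells x antibodies)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.csr_matrix(matrix.to_numpy())
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sparse)
    (directory / "barcodes.tsv").write_text("".join(f"{b}\n" for b in matrix.index))
    (directory / "features.tsv").write_text("".join(f"{a}\n" for a in matrix.columns))


def read_matrix_mtx(directory) -> pd.DataFrame:
    directory = Path(directory)
    sparse = scipy.io.mmread(str(directory / "matrix.mtx"))
    barcodes = (directory / "barcodes.tsv").read_text().splitlines()
    features = (directory / "features.tsv").read_text().splitlines()
    return pd.DataFrame(
        sparse.toarray().astype(int),
        index=pd.Index(barcodes, name="barcode"),
        columns=features,
    )
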