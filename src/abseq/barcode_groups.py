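"""Aggregation of accepted reads into cell-barcode groups and group filters.

True cell barcodes accumulate many reads while PCR/sequencing-error
barcodes accumulate few, so the descending read-count distribution over
barcode groups shows a knee separating cells from artifacts.  Two filters
act on the group table:

- the knee filter keeps the minimal prefix of descending-sorted groups
  holding ~95% of all reads (the printed criterion for the inflection
  point), and
- the mapping-fraction filter keeps groups whose reads map to known
  antibody tags at a rate strictly above 90%, removing groups dominated by
  contaminating DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .read_structures import ParsedRead, UNMAPPED

_DNA_SET = frozenset("ACGT")


def gc_content(sequence: str) -> float:
    """Fraction of G/C bases; raises on an empty or non-A/C/G/T string."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if not set(sequence) <= _DNA_SET:
        raise ValueError(f"sequence contains non-A/C/G/T characters: {sequence!r}")
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


@dataclass
class BarcodeGroup:
    """All accepted reads sharing one cell barcode."""

    barcode: str
    per_antibody_read_counts: dict[str, int] = field(default_factory=dict)
    unmapped_read_count: int = 0
    #: (antibody, UMI) pair for every mapped read, duplicates included.
    umi_records: list[tuple[str, str]] = field(default_factory=list)

    @property
    def mapped_read_count(self) -> int:
        return sum(self.per_antibody_read_counts.values())

    @property
    def read_count(self) -> int:
        return self.mapped_read_count + self.unmapped_read_count

    @property
    def mapping_fraction(self) -> float:
        return self.mapped_read_count / self.read_count

    @property
    def gc_fraction(self) -> float:
        return gc_content(self.barcode)


@dataclass
class GroupTable:
    """Barcode groups sorted by read count descending (ties: lexicographic)."""

    groups: list[BarcodeGroup]

    def __post_init__(self) -> None:
        barcodes = [g.barcode for g in self.groups]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("barcodes must be unique within a GroupTable")
        self.groups.sort(key=lambda g: (-g.read_count, g.barcode))
        self._by_barcode = {g.barcode: g for g in self.groups}

    @property
    def total_reads(self) -> int:
        return sum(g.read_count for g in self.groups)

    @property
    def barcodes(self) -> list[str]:
        return [g.barcode for g in self.groups]

    def __len__(self) -> int:
        return len(self.groups)

    def __getitem__(self, barcode: str) -> BarcodeGroup:
        return self._by_barcode[barcode]

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._by_barcode

    def to_dataframe(self, antibodies: Optional[list[str]] = None) -> pd.DataFrame:
        """Tabular view: one row per group, one column per antibody."""
        if antibodies is None:
            seen: set[str] = set()
            for g in self.groups:
                seen.update(g.per_antibody_read_counts)
            antibodies = sorted(seen)
        rows = []
        for g in self.groups:
            row = {
                "barcode": g.barcode,
                "read_count": g.read_count,
                "unmapped_read_count": g.unmapped_read_count,
                "mapping_fraction": g.mapping_fraction,
                "gc_fraction": g.gc_fraction,
            }
            for a in antibodies:
                row[a] = g.per_antibody_read_counts.get(a, 0)
            rows.append(row)
        columns = [
            "barcode",
            "read_count",
            *antibodies,
            "unmapped_read_count",
            "mapping_fraction",
            "gc_fraction",
        ]
        return pd.DataFrame(rows, columns=columns)


def group_by_barcode(reads: Iterable[ParsedRead]) -> GroupTable:
    """Aggregate accepted reads into barcode groups.

    Rejected reads in the input are ignored.  Every accepted read is
    counted in exactly one group; mapped reads additionally contribute an
    (antibody, UMI) record for downstream deduplication.
    """
    acc: dict[str, BarcodeGroup] = {}
    for r in reads:
        if not r.accepted:
            continue
        g = acc.get(r.cell_barcode)
        if g is None:
            g = acc[r.cell_barcode] = BarcodeGroup(r.cell_barcode)
        if r.antibody == UNMAPPED:
            g.unmapped_read_count += 1
        else:
            g.per_antibody_read_counts[r.antibody] = (
                g.per_antibody_read_counts.get(r.antibody, 0) + 1
            )
            g.umi_records.append((r.antibody, r.umi))
    return GroupTable(list(acc.values()))


def knee_select(table: GroupTable, cumulative_fraction: float = 0.95) -> set[str]:
    """Barcodes up to the knee of the descending read-count distribution.

    Returns the minimal prefix of the descending-sorted groups whose
    cumulative read share reaches ``cumulative_fraction`` (default 0.95,
    the ~95%-of-reads criterion).  The retained set is always a prefix, so
    it is monotone in the threshold.
    """
    if not 0 < cumulative_fraction <= 1:
        raise ValueError("cumulative_fraction must be in (0, 1]")
    if not table.groups:
        return set()
    target = cumulative_fraction * table.total_reads
    kept: set[str] = set()
    cum = 0
    for g in table.groups:
        kept.add(g.barcode)
        cum += g.read_count
        if cum >= target - 1e-9:  # guard float roundoff at exact boundaries
            break
    return kept


def knee_index_curvature(table: GroupTable) -> int:
    """Alternative knee: rank of maximal distance to the log-log chord.

    Offered as a curvature-based detector for exploratory use; the
    cumulative-share rule (:func:`knee_select`) is the default because it
    is deterministic and matches the stated retention criterion.  Returns
    the 0-based index of the knee group.
    """
    counts = np.array([g.read_count for g in table.groups], dtype=float)
    if counts.size == 0:
        raise ValueError("empty table has no knee")
    if counts.size < 3:
        return counts.size - 1
    x = np.log10(np.arange(1, counts.size + 1))
    y = np.log10(counts + 1.0)
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    # perpendicular distance of each point from the chord
    norm = np.hypot(x1 - x0, y1 - y0)
    dist = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0) / norm
    return int(np.argmax(dist))


def mapping_fraction_filter(table: GroupTable, min_fraction: float = 0.9) -> set[str]:
    """Barcodes whose mapped-read fraction is strictly above ``min_fraction``.

    The comparison is strict (">90%"), so a group sitting exactly at the
    threshold is removed.  The result is a set and does not depend on
    group order.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    return {g.barcode for g in table.groups if g.mapping_fraction > min_fraction}
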