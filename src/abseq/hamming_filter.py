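"""Isolation filtering of barcode groups in Hamming space.

PCR mutation of a cell barcode during amplification spawns satellite
barcode groups one substitution away from the parent.  Because true
barcodes are drawn sparsely from a large random space, genuine groups are
almost never within one substitution of each other, so any connected
component of size >= 2 in the Hamming-distance-1 graph is treated as a
mutation artifact and the whole component is discarded — no attempt is
made to rescue reads by merging children into parents.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .barcode_groups import GroupTable
from .read_structures import DNA_BASES, hamming as hamming_distance

__all__ = [
    "hamming_distance",
    "BarcodeClusterSet",
    "connected_components_h1",
    "select_isolated",
    "component_report",
]

_DNA_SET = frozenset(DNA_BASES)


@dataclass(frozen=True)
class BarcodeClusterSet:
    """Partition of a barcode set into Hamming-distance-1 components.

    ``isolated`` holds singleton components (well-isolated barcodes);
    ``discarded`` holds members of components of size >= 2.  Together they
    partition the input set.
    """

    clusters: tuple[frozenset[str], ...]
    isolated: frozenset[str]
    discarded: frozenset[str]

    def component_of(self, barcode: str) -> frozenset[str]:
        for c in self.clusters:
            if barcode in c:
                return c
        raise KeyError(barcode)


def connected_components_h1(barcodes) -> BarcodeClusterSet:
    """Connected components of the graph joining barcodes at Hamming distance 1.

    Edges are found by neighbor enumeration: every single-substitution
    variant of each barcode is looked up in the input set, which is
    equivalent to (and much faster than) the all-pairs construction.
    Barcodes must be unique, equal-length A/C/G/T strings.
    """
    bset = set(barcodes)
    if not bset:
        return BarcodeClusterSet((), frozenset(), frozenset())
    lengths = {len(b) for b in bset}
    if len(lengths) != 1:
        raise ValueError(f"barcodes must all have the same length, got {sorted(lengths)}")
    for b in bset:
        if not set(b) <= _DNA_SET:
            raise ValueError(f"barcode {b!r} contains non-A/C/G/T characters")
    graph = nx.Graph()
    graph.add_nodes_from(bset)
    for bc in bset:
        for i, base in enumerate(bc):
            for alt in DNA_BASES:
                if alt == base:
                    continue
                variant = bc[:i] + alt + bc[i + 1 :]
                if variant > bc and variant in bset:
                    graph.add_edge(bc, variant)
    components = [frozenset(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: min(c))
    isolated = frozenset(b for c in components for b in c if len(c) == 1)
    discarded = frozenset(b for c in components for b in c if len(c) >= 2)
    return BarcodeClusterSet(tuple(components), isolated, discarded)


def select_isolated(groups: GroupTable, retained: set[str]) -> set[str]:
    """Retained barcodes forming singleton components within the retained set.

    The isolation test runs on the post-knee, post-mapping-fraction
    retained set: only barcodes that survived the upstream filters can
    place each other under suspicion.
    """
    table_barcodes = set(groups.barcodes)
    if not set(retained) <= table_barcodes:
        missing = sorted(set(retained) - table_barcodes)[:5]
        raise ValueError(f"retained barcodes not present in table: {missing}")
    return set(connected_components_h1(retained).isolated)


def component_report(clusters: BarcodeClusterSet, groups: GroupTable) -> pd.DataFrame:
    """One row per component: id, size, member barcodes, total reads."""
    rows = []
    for i, comp in enumerate(clusters.clusters):
        members = sorted(comp)
        rows.append(
            {
                "component_id": i,
                "size": len(comp),
                "barcodes": ";".join(members),
                "total_reads": sum(
                    groups[b].read_count if b in groups else 0 for b in members
                ),
            }
        )
    return pd.DataFrame(rows, columns=["component_id", "size", "barcodes", "total_reads"])
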