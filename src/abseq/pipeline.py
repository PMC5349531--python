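"""End-to-end pipeline: FASTQ -> filtered barcode groups -> count matrix.

Stage order follows the bioinformatic workflow: parse and quality-filter
reads on the homology region, group by cell barcode, keep groups up to
the read-count knee, keep groups with >90% tag-mapping reads, discard
Hamming-connected barcode clusters, UMI-deduplicate the survivors and
classify cells.  Every stage writes its artifact and the summary JSON
accounts for every read and every barcode in exactly one bucket.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import barcode_groups, hamming_filter, tag_quant
from .read_structures import (
    AntibodyPanel,
    ParseSummary,
    ReadLayout,
    parse_fastq,
    write_accepted_tsv,
)

logger = logging.getLogger("abseq")


@dataclass
class PipelineConfig:
    """Validated parameters for one pipeline run."""

    layout: ReadLayout = field(default_factory=ReadLayout)
    panel: AntibodyPanel = field(default_factory=AntibodyPanel.default)
    cumulative_fraction: float = 0.95
    min_mapping_fraction: float = 0.9
    positive_threshold: int = 5
    tag_max_mismatches: int = 0
    knee_before_mapping: bool = True
    umi_merge_hamming1: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.cumulative_fraction <= 1:
            raise ValueError("cumulative_fraction must be in (0, 1]")
        if not 0 <= self.min_mapping_fraction <= 1:
            raise ValueError("min_mapping_fraction must be in [0, 1]")
        if self.positive_threshold < 1:
            raise ValueError("positive_threshold must be >= 1")
        if self.tag_max_mismatches < 0:
            raise ValueError("tag_max_mismatches must be >= 0")
        if self.panel.tag_length != self.layout.tag_length:
            raise ValueError(
                f"panel tag length {self.panel.tag_length} does not match "
                f"layout tag length {self.layout.tag_length}"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load layout/panel/filter settings from a YAML config file."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs = {}
        if "layout" in doc:
            kwargs["layout"] = ReadLayout(**doc["layout"])
        if "panel" in doc:
            kwargs["panel"] = AntibodyPanel.from_dict(doc["panel"])
        kwargs.update(doc.get("filters", {}))
        return cls(**kwargs)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["layout"] = dataclasses.asdict(self.layout)
        d["panel"] = {name: tag for tag, name in self.panel.entries}
        return d


@dataclass
class PipelineResult:
    summary: dict
    matrix: pd.DataFrame
    labels: pd.Series
    table: barcode_groups.GroupTable
    parse_summary: ParseSummary


def _write_barcode_list(barcodes, path) -> None:
    Path(path).write_text("".join(f"{b}\n" for b in sorted(barcodes)))


def run_pipeline(fastq_path, out_dir, config: Optional[PipelineConfig] = None) -> PipelineResult:
    """Run every stage on one FASTQ file, writing all artifacts to ``out_dir``.

    Artifacts: accepted_reads.tsv, groups.tsv, knee/mapping retained-barcode
    lists, components.tsv, isolated_barcodes.txt, matrix.tsv, an MTX
    directory with sidecars, labels.tsv, summary.json and the resolved
    configuration (pipeline_config.json).  An empty FASTQ produces an empty
    matrix and a clean exit with a warning.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "pipeline_config.json").write_text(
        json.dumps(config.to_jsonable(), indent=2, sort_keys=True)
    )

    logger.info("parsing %s", fastq_path)
    reads, parse_summary = parse_fastq(
        fastq_path, config.layout, config.panel, config.tag_max_mismatches
    )
    write_accepted_tsv(reads, out_dir / "accepted_reads.tsv")

    table = barcode_groups.group_by_barcode(reads)
    antibodies = config.panel.names
    table.to_dataframe(antibodies).to_csv(out_dir / "groups.tsv", sep="\t", index=False)
    logger.info(
        "%d/%d reads accepted across %d barcode groups",
        parse_summary.accepted,
        parse_summary.total,
        len(table),
    )

    if len(table) == 0:
        warnings.warn(f"no accepted reads in {fastq_path}; writing empty outputs")
        knee_kept: set[str] = set()
        mapping_kept: set[str] = set()
        retained: set[str] = set()
        isolated: set[str] = set()
        clusters = hamming_filter.connected_components_h1(set())
    else:
        knee_kept = barcode_groups.knee_select(table, config.cumulative_fraction)
        mapping_kept = barcode_groups.mapping_fraction_filter(
            table, config.min_mapping_fraction
        )
        if config.knee_before_mapping:
            retained = {b for b in knee_kept if b in mapping_kept}
        else:
            retained = {b for b in mapping_kept if b in knee_kept}
        clusters = hamming_filter.connected_components_h1(retained) if retained else (
            hamming_filter.connected_components_h1(set())
        )
        isolated = set(clusters.isolated)

    _write_barcode_list(knee_kept, out_dir / "knee_retained.txt")
    _write_barcode_list(mapping_kept, out_dir / "mapping_retained.txt")
    _write_barcode_list(isolated, out_dir / "isolated_barcodes.txt")
    hamming_filter.component_report(clusters, table).to_csv(
        out_dir / "components.tsv", sep="\t", index=False
    )

    profiles = [
        tag_quant.umi_dedup(table[b], config.umi_merge_hamming1)
        for b in sorted(isolated)
    ]
    matrix = tag_quant.build_matrix(profiles, antibodies)
    labels, populations = tag_quant.classify_cells(matrix, config.positive_threshold)
    tag_quant.write_matrix_tsv(matrix, out_dir / "matrix.tsv")
    tag_quant.write_matrix_mtx(matrix, out_dir / "mtx")
    labels.to_frame().to_csv(out_dir / "labels.tsv", sep="\t", index_label="barcode")

    n_groups = len(table)
    if config.knee_before_mapping:
        first_kept, second_kept = knee_kept, retained
        first_name, second_name = "knee", "mapping_fraction"
    else:
        first_kept, second_kept = mapping_kept, retained
        first_name, second_name = "mapping_fraction", "knee"
    summary = {
        "reads": parse_summary.as_dict(),
        "barcodes": {
            "n_groups": n_groups,
            f"removed_{first_name}": n_groups - len(first_kept),
            f"removed_{second_name}": len(first_kept) - len(second_kept),
            "removed_hamming": len(retained) - len(isolated),
            "retained_after_filters": len(retained),
            "isolated": len(isolated),
        },
        "cells": {
            "n_cells": populations.n_cells,
            "counts": populations.counts,
            "fractions": populations.fractions,
        },
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return PipelineResult(
        summary=summary,
        matrix=matrix,
        labels=labels,
        table=table,
        parse_summary=parse_summary,
    )
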