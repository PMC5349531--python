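"""Synthetic droplet-barcoding experiments with full ground truth.

The generator emulates the study conditions end to end: droplet merge
events load cells at ~1 per 30 droplets and clonal barcode droplets at
~1 per 10 droplets (both Poisson); cells are a 69:31 two-type mixture
("jurkat"-like CD3-high vs "raji"-like CD19-high) with near-binary marker
expression (on-target mean 20 molecules, off-target 0.2); every molecule
carries an 8-nt random UMI; PCR amplification duplicates each molecule a
shifted-geometric number of times, optionally biased by barcode GC
content; and per-base substitution errors can be applied per PCR copy and
again at sequencing.  Every emitted read traces to exactly one truth
molecule, so any pipeline stage can be scored exactly.

All randomness flows from a single seeded generator: a fixed seed yields
byte-identical FASTQ and truth files.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .barcode_groups import gc_content
from .read_structures import AntibodyPanel, DNA_BASES, ReadLayout


def _default_antibody_means() -> dict[str, dict[str, float]]:
    return {
        "jurkat": {"CD3": 20.0, "CD19": 0.2},
        "raji": {"CD3": 0.2, "CD19": 20.0},
    }


@dataclass
class SimParams:
    """Knobs of the synthetic experiment; defaults are the study conditions."""

    n_merge_events: int = 100_000
    lambda_cell: float = 1 / 30
    lambda_barcode: float = 1 / 10
    mixture_p: float = 0.69  # P(cell is the first type in cell_types)
    cell_types: tuple[str, str] = ("jurkat", "raji")
    antibody_means: dict[str, dict[str, float]] = field(
        default_factory=_default_antibody_means
    )
    layout: ReadLayout = field(default_factory=ReadLayout)
    panel: AntibodyPanel = field(default_factory=AntibodyPanel.default)
    amplification_mean: float = 30.0  # mean extra PCR copies per molecule
    gc_bias: float = 0.0  # linear GC coefficient on the amplification mean
    pcr_substitution_rate: float = 0.0  # per base, per copy
    seq_error_rate: float = 0.0  # per base, per read
    total_reads_target: Optional[int] = None
    quality_char: str = "?"  # Phred+33 Q30
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_merge_events <= 0:
            raise ValueError("n_merge_events must be > 0")
        if self.lambda_cell <= 0 or self.lambda_barcode <= 0:
            raise ValueError("loading rates must be > 0")
        if not 0 <= self.mixture_p <= 1:
            raise ValueError("mixture_p must be in [0, 1]")
        for rate in (self.pcr_substitution_rate, self.seq_error_rate):
            if not 0 <= rate <= 1:
                raise ValueError("error rates must be in [0, 1]")
        if self.amplification_mean < 0:
            raise ValueError("amplification_mean must be >= 0")
        panel_names = set(self.panel.names)
        for ctype in self.cell_types:
            means = self.antibody_means.get(ctype)
            if means is None:
                raise ValueError(f"no antibody means for cell type {ctype!r}")
            if not set(means) <= panel_names:
                raise ValueError(f"antibody means for {ctype!r} outside the panel")
            if any(m < 0 for m in means.values()):
                raise ValueError("antibody means must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass(frozen=True)
class DropletEvent:
    """One productive merge event (>=1 cell and >=1 barcode droplet)."""

    event_index: int
    cell_types: tuple[str, ...]
    barcodes: tuple[str, ...]


@dataclass
class EncapsulationResult:
    """Per-event loading outcomes plus barcode assignments for productive events."""

    cell_count: np.ndarray  # cells per merge event
    type1_count: np.ndarray  # cells of the first type, per event
    barcode_count: np.ndarray  # barcode droplets per event
    productive_index: np.ndarray  # events with >=1 cell and >=1 barcode
    event_barcodes: list[tuple[str, ...]]  # aligned with productive_index

    @property
    def n_events(self) -> int:
        return self.cell_count.size

    @property
    def occupied_count(self) -> int:
        """Events containing at least one cell."""
        return int((self.cell_count > 0).sum())

    @property
    def mixed_count(self) -> int:
        """Cell-containing events holding both cell types."""
        mixed = (self.type1_count > 0) & (self.type1_count < self.cell_count)
        return int(mixed.sum())

    def mixed_fraction_among_occupied(self) -> float:
        occ = self.occupied_count
        if occ == 0:
            return 0.0
        return self.mixed_count / occ

    def iter_productive_events(self, cell_types: tuple[str, str]) -> Iterator[DropletEvent]:
        t1, t2 = cell_types
        for idx, barcodes in zip(self.productive_index, self.event_barcodes):
            k = int(self.cell_count[idx])
            n1 = int(self.type1_count[idx])
            yield DropletEvent(
                event_index=int(idx),
                cell_types=(t1,) * n1 + (t2,) * (k - n1),
                barcodes=barcodes,
            )


@dataclass(frozen=True)
class Molecule:
    """One original (pre-PCR) tagged molecule: the unit UMIs count."""

    molecule_id: str
    event_index: int
    cell_id: str
    cell_type: str
    barcode: str
    antibody: str
    umi: str


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str


@dataclass
class SimTruth:
    """Ground truth of one simulated run, as tidy tables."""

    events: pd.DataFrame  # one row per productive merge event
    cells: pd.DataFrame  # one row per encapsulated, barcoded cell
    molecules: pd.DataFrame  # one row per original molecule

    def clean_singlets(self) -> pd.DataFrame:
        """Cells from events with exactly one cell and exactly one barcode.

        These are the cells the pipeline should recover perfectly under
        zero noise: no co-encapsulation mixing and no split of one cell's
        molecules across two barcode groups.
        """
        mask = (self.cells["n_cells_in_event"] == 1) & (
            self.cells["n_barcodes_in_event"] == 1
        )
        return self.cells[mask]


@dataclass
class SimRun:
    params: SimParams
    reads: list[SimRead]
    truth: SimTruth


def _int_to_seq(value: int, length: int) -> str:
    out = []
    for _ in range(length):
        out.append(DNA_BASES[value & 3])
        value >>= 2
    return "".join(reversed(out))


def _draw_unique_barcodes(k: int, length: int, rng: np.random.Generator) -> list[str]:
    """k distinct random barcodes, uniform without replacement over 4^length."""
    space = 4**length
    if k > space:
        raise ValueError("more barcodes requested than the sequence space holds")
    seen: set[int] = set()
    out: list[int] = []
    while len(out) < k:
        for v in rng.integers(0, space, size=k - len(out)):
            v = int(v)
            if v not in seen:
                seen.add(v)
                out.append(v)
    return [_int_to_seq(v, length) for v in out]


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(DNA_BASES[i] for i in rng.integers(0, 4, size=length))


def simulate_encapsulation(
    params: SimParams, rng: np.random.Generator
) -> EncapsulationResult:
    """Draw Poisson cell/barcode loadings for every merge event.

    Cell counts are Poisson(lambda_cell), barcode-droplet counts
    Poisson(lambda_barcode), and each cell's type an independent
    Bernoulli(mixture_p) draw.  Events with at least one cell and one
    barcode are productive and receive distinct random barcode sequences.
    """
    n = params.n_merge_events
    cell_count = rng.poisson(params.lambda_cell, size=n)
    type1_count = rng.binomial(cell_count, params.mixture_p)
    barcode_count = rng.poisson(params.lambda_barcode, size=n)
    productive = np.flatnonzero((cell_count > 0) & (barcode_count > 0))
    total_barcodes = int(barcode_count[productive].sum())
    pool = _draw_unique_barcodes(total_barcodes, params.layout.barcode_length, rng)
    event_barcodes: list[tuple[str, ...]] = []
    cursor = 0
    for idx in productive:
        k = int(barcode_count[idx])
        event_barcodes.append(tuple(pool[cursor : cursor + k]))
        cursor += k
    return EncapsulationResult(
        cell_count=cell_count,
        type1_count=type1_count,
        barcode_count=barcode_count,
        productive_index=productive,
        event_barcodes=event_barcodes,
    )


def simulate_molecules(
    event: DropletEvent, params: SimParams, rng: np.random.Generator
) -> list[Molecule]:
    """Draw the tagged molecules released in one productive merge event.

    Per cell and antibody the molecule count is Poisson with the mean for
    that cell type; each molecule receives an independent uniform random
    UMI.  When the event holds several barcode droplets, molecules are
    assigned to barcodes uniformly at random (the split-cell artifact).
    """
    molecules: list[Molecule] = []
    n_bc = len(event.barcodes)
    for ci, ctype in enumerate(event.cell_types):
        cell_id = f"e{event.event_index}c{ci}"
        means = params.antibody_means[ctype]
        for antibody in params.panel.names:
            mean = means.get(antibody, 0.0)
            count = int(rng.poisson(mean)) if mean > 0 else 0
            for mi in range(count):
                if n_bc == 1:
                    barcode = event.barcodes[0]
                else:
                    barcode = event.barcodes[int(rng.integers(0, n_bc))]
                molecules.append(
                    Molecule(
                        molecule_id=f"{cell_id}:{antibody}:{mi}",
                        event_index=event.event_index,
                        cell_id=cell_id,
                        cell_type=ctype,
                        barcode=barcode,
                        antibody=antibody,
                        umi=_random_seq(params.layout.umi_length, rng),
                    )
                )
    return molecules


def _mutate(seq: str, n_sub: int, rng: np.random.Generator) -> str:
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    chars = list(seq)
    for pos in positions:
        current = chars[pos]
        alternatives = [b for b in DNA_BASES if b != current]
        chars[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def amplify_and_read(
    molecules: list[Molecule], params: SimParams, rng: np.random.Generator
) -> tuple[list[SimRead], np.ndarray]:
    """PCR-amplify molecules and emit error-bearing reads.

    Each molecule yields 1 + Geometric extra copies whose mean is
    ``amplification_mean * (1 + gc_bias * (gc(barcode) - 0.5))`` (clamped
    at zero), reproducing faster amplification of GC-rich barcodes when
    ``gc_bias`` > 0.  Every copy independently substitutes bases across
    the whole amplicon at ``pcr_substitution_rate``, then again at
    ``seq_error_rate``.  If ``total_reads_target`` is set the read pool is
    subsampled uniformly without replacement.

    Returns the reads plus the pre-subsampling copy count per molecule.
    """
    if not molecules:
        return [], np.zeros(0, dtype=int)
    tag_of = params.panel.tag_of
    gc = np.array([gc_content(m.barcode) for m in molecules])
    means = params.amplification_mean * np.maximum(
        0.0, 1.0 + params.gc_bias * (gc - 0.5)
    )
    # shifted geometric: rng.geometric(p) has support >=1 and mean 1/p,
    # so subtracting 1 gives the extra-copy count with mean (1-p)/p.
    p_geom = 1.0 / (1.0 + means)
    copies = rng.geometric(p_geom).astype(int)  # = 1 + extras, mean 1 + means
    templates = [
        m.barcode + params.layout.homology_sequence + m.umi + tag_of[m.antibody]
        for m in molecules
    ]
    read_mol = np.repeat(np.arange(len(molecules)), copies)
    n_reads = read_mol.size
    read_len = len(templates[0])
    n_pcr = (
        rng.binomial(read_len, params.pcr_substitution_rate, size=n_reads)
        if params.pcr_substitution_rate > 0
        else np.zeros(n_reads, dtype=int)
    )
    n_seq = (
        rng.binomial(read_len, params.seq_error_rate, size=n_reads)
        if params.seq_error_rate > 0
        else np.zeros(n_reads, dtype=int)
    )
    reads: list[SimRead] = []
    copy_counter: dict[int, int] = {}
    for r in range(n_reads):
        mol_idx = int(read_mol[r])
        copy_idx = copy_counter.get(mol_idx, 0)
        copy_counter[mol_idx] = copy_idx + 1
        seq = templates[mol_idx]
        if n_pcr[r]:
            seq = _mutate(seq, int(n_pcr[r]), rng)
        if n_seq[r]:
            seq = _mutate(seq, int(n_seq[r]), rng)
        reads.append(SimRead(f"{molecules[mol_idx].molecule_id}:{copy_idx}", seq))
    if params.total_reads_target is not None and n_reads > params.total_reads_target:
        keep = np.sort(rng.choice(n_reads, size=params.total_reads_target, replace=False))
        reads = [reads[i] for i in keep]
    return reads, copies


def simulate_run(params: SimParams) -> SimRun:
    """Run the full generative model: encapsulation -> molecules -> reads."""
    rng = params.rng()
    encaps = simulate_encapsulation(params, rng)
    all_molecules: list[Molecule] = []
    event_rows = []
    cell_rows = []
    for event in encaps.iter_productive_events(params.cell_types):
        mols = simulate_molecules(event, params, rng)
        all_molecules.extend(mols)
        event_rows.append(
            {
                "event_index": event.event_index,
                "n_cells": len(event.cell_types),
                "n_type1": sum(t == params.cell_types[0] for t in event.cell_types),
                "n_barcodes": len(event.barcodes),
                "barcodes": ";".join(event.barcodes),
            }
        )
        per_cell_counts: dict[str, dict[str, int]] = {}
        for m in mols:
            per_cell_counts.setdefault(m.cell_id, {}).setdefault(m.antibody, 0)
            per_cell_counts[m.cell_id][m.antibody] += 1
        for ci, ctype in enumerate(event.cell_types):
            cell_id = f"e{event.event_index}c{ci}"
            row = {
                "cell_id": cell_id,
                "event_index": event.event_index,
                "cell_type": ctype,
                "n_cells_in_event": len(event.cell_types),
                "n_barcodes_in_event": len(event.barcodes),
                "barcodes": ";".join(event.barcodes),
            }
            for antibody in params.panel.names:
                row[f"n_molecules_{antibody}"] = per_cell_counts.get(cell_id, {}).get(
                    antibody, 0
                )
            cell_rows.append(row)
    reads, copies = amplify_and_read(all_molecules, params, rng)
    sequenced = pd.Series(
        [r.read_id.rsplit(":", 1)[0] for r in reads], dtype=object
    ).value_counts()
    mol_rows = []
    for i, m in enumerate(all_molecules):
        mol_rows.append(
            {
                "molecule_id": m.molecule_id,
                "event_index": m.event_index,
                "cell_id": m.cell_id,
                "cell_type": m.cell_type,
                "barcode": m.barcode,
                "antibody": m.antibody,
                "umi": m.umi,
                "copies_emitted": int(copies[i]),
                "copies_sequenced": int(sequenced.get(m.molecule_id, 0)),
            }
        )
    event_cols = ["event_index", "n_cells", "n_type1", "n_barcodes", "barcodes"]
    cell_cols = [
        "cell_id",
        "event_index",
        "cell_type",
        "n_cells_in_event",
        "n_barcodes_in_event",
        "barcodes",
    ] + [f"n_molecules_{a}" for a in params.panel.names]
    mol_cols = [
        "molecule_id",
        "event_index",
        "cell_id",
        "cell_type",
        "barcode",
        "antibody",
        "umi",
        "copies_emitted",
        "copies_sequenced",
    ]
    truth = SimTruth(
        events=pd.DataFrame(event_rows, columns=event_cols),
        cells=pd.DataFrame(cell_rows, columns=cell_cols),
        molecules=pd.DataFrame(mol_rows, columns=mol_cols),
    )
    return SimRun(params=params, reads=reads, truth=truth)


def _params_to_jsonable(params: SimParams) -> dict:
    d = dataclasses.asdict(params)
    d["layout"] = dataclasses.asdict(params.layout)
    d["panel"] = {name: tag for tag, name in params.panel.entries}
    return d


def write_run(run: SimRun, out_dir, gzip_fastq: bool = False) -> dict[str, Path]:
    """Write reads.fastq(.gz), truth tables and full parameter provenance.

    Re-reading the FASTQ reproduces the read sequences exactly; the truth
    tables are sufficient to score any pipeline output against the
    generative ground truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fastq_path = out_dir / ("reads.fastq.gz" if gzip_fastq else "reads.fastq")
    opener = gzip.open if gzip_fastq else open
    try:
        with opener(fastq_path, "wt") as fh:
            q = run.params.quality_char
            for read in run.reads:
                fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{q * len(read.sequence)}\n")
    except OSError as exc:
        raise OSError(f"cannot write FASTQ to {fastq_path}: {exc}") from exc
    paths = {"fastq": fastq_path}
    for name, frame in (
        ("truth_events", run.truth.events),
        ("truth_cells", run.truth.cells),
        ("truth_molecules", run.truth.molecules),
    ):
        path = out_dir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        paths[name] = path
    params_path = out_dir / "params.json"
    params_path.write_text(json.dumps(_params_to_jsonable(run.params), indent=2, sort_keys=True))
    paths["params"] = params_path
    return paths
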