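"""Read layout definition and decomposition of chimeric amplicon reads.

Each sequencing read covers a chimeric SOE-PCR product in which a clonally
amplified cell barcode has been spliced onto an antibody-derived tag through
a constant homology region::

    5'-[cell barcode][homology region][UMI][antibody tag]-3'

The homology region doubles as the read quality filter: a read is kept only
if some offset aligns it to the constant sequence with at most
``max_homology_mismatches`` substitutions.  The barcode is read off
immediately upstream of that offset and the UMI and tag immediately
downstream.  All coordinates are 0-based, half-open.

Matching is substitution-only (no indels) so that every decision is a pure
Hamming comparison and the leftmost minimal-mismatch offset is a
deterministic anchor.
"""

from __future__ import annotations

import gzip
import os
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from Bio import SeqIO

DNA_BASES = "ACGT"
_DNA_SET = frozenset(DNA_BASES)

#: Marker used for accepted reads whose tag matches no panel entry.
UNMAPPED = "unmapped"

#: Reject reasons carried by :class:`ParsedRead`.
HOMOLOGY_NOT_FOUND = "homology_not_found"
TRUNCATED_FLANK = "truncated_flank"
AMBIGUOUS_BASE = "ambiguous_base"
REJECT_REASONS = (HOMOLOGY_NOT_FOUND, TRUNCATED_FLANK, AMBIGUOUS_BASE)


class FastqFormatError(ValueError):
    """Raised when a FASTQ record cannot be parsed (truncated or malformed)."""


@dataclass(frozen=True)
class ReadLayout:
    """Segment order and lengths of the chimeric amplicon read.

    Parameters
    ----------
    barcode_length
        Length of the random cell barcode in nt (default 10).
    homology_sequence
        The constant region shared by barcode and tag amplicons; its
        fidelity is the read quality filter.
    umi_length
        Length of the unique molecular identifier in nt (default 8).
    tag_length
        Length of the antibody tag in nt (default 7).
    max_homology_mismatches
        Maximum substitutions tolerated in the homology region (default 2).
    """

    barcode_length: int = 10
    homology_sequence: str = "GCAGTGGTATCAACGCAGAG"
    umi_length: int = 8
    tag_length: int = 7
    max_homology_mismatches: int = 2

    def __post_init__(self) -> None:
        if not self.homology_sequence or not set(self.homology_sequence) <= _DNA_SET:
            raise ValueError("homology_sequence must be a non-empty A/C/G/T string")
        for name in ("barcode_length", "umi_length", "tag_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.max_homology_mismatches < len(self.homology_sequence):
            raise ValueError(
                "max_homology_mismatches must be >= 0 and < homology length"
            )

    @property
    def read_length(self) -> int:
        """Total length of a perfectly structured read."""
        return (
            self.barcode_length
            + len(self.homology_sequence)
            + self.umi_length
            + self.tag_length
        )


@dataclass(frozen=True)
class AntibodyPanel:
    """Mapping from antibody-tag sequences to antibody names.

    Tags must be unique and of identical length.  A warning is emitted if
    any pair of tags sits at Hamming distance < 2, since a single
    substitution could then convert one tag into another.
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("panel must contain at least one entry")
        tags = [tag for tag, _ in self.entries]
        if len(set(tags)) != len(tags):
            raise ValueError("panel tag sequences must be unique")
        lengths = {len(t) for t in tags}
        if len(lengths) != 1:
            raise ValueError("panel tag sequences must all have the same length")
        for tag in tags:
            if not set(tag) <= _DNA_SET:
                raise ValueError(f"tag {tag!r} contains non-A/C/G/T characters")
        for i, a in enumerate(tags):
            for b in tags[i + 1 :]:
                if hamming(a, b) < 2:
                    warnings.warn(
                        f"panel tags {a!r} and {b!r} are within Hamming distance 1; "
                        "a single substitution can convert one into the other",
                        stacklevel=2,
                    )

    @classmethod
    def from_dict(cls, mapping: dict[str, str]) -> "AntibodyPanel":
        """Build a panel from ``{antibody_name: tag_sequence}``."""
        return cls(tuple((tag, name) for name, tag in mapping.items()))

    @classmethod
    def default(cls) -> "AntibodyPanel":
        """The two-marker CD3/CD19 panel used for T/B-cell discrimination."""
        return cls((("TTATAAC", "CD3"), ("TTAATTG", "CD19")))

    @property
    def tag_length(self) -> int:
        return len(self.entries[0][0])

    @property
    def names(self) -> list[str]:
        return [name for _, name in self.entries]

    @property
    def tag_of(self) -> dict[str, str]:
        """antibody name -> tag sequence."""
        return {name: tag for tag, name in self.entries}

    def match(self, tag: str, max_mismatches: int = 0) -> Optional[str]:
        """Return the antibody name for ``tag`` or None if unmapped.

        With ``max_mismatches`` 0 (the default) matching is exact.  With a
        positive budget the closest panel tag wins, provided it is unique at
        that distance and within budget.
        """
        exact = {t: n for t, n in self.entries}
        if max_mismatches == 0:
            return exact.get(tag)
        hit = exact.get(tag)
        if hit is not None:
            return hit
        best_name, best_d, best_ties = None, max_mismatches + 1, 0
        for t, n in self.entries:
            if len(t) != len(tag):
                continue
            d = hamming(t, tag)
            if d < best_d:
                best_name, best_d, best_ties = n, d, 1
            elif d == best_d:
                best_ties += 1
        if best_d <= max_mismatches and best_ties == 1:
            return best_name
        return None


@dataclass(frozen=True)
class HomologyMatch:
    """Location of the homology region within a read."""

    position: int  # 0-based offset of the homology start
    mismatches: int


@dataclass(frozen=True)
class ParsedRead:
    """One read decomposed into its segments, or a rejection record."""

    read_id: str
    cell_barcode: str = ""
    umi: str = ""
    tag_sequence: str = ""
    antibody: str = ""
    status: str = "accepted"  # "accepted" | "rejected"
    reject_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status == "rejected" and self.reject_reason not in REJECT_REASONS:
            raise ValueError("rejected reads must carry exactly one reject_reason")
        if self.status == "accepted" and self.reject_reason is not None:
            raise ValueError("accepted reads carry no reject_reason")

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


@dataclass
class ParseSummary:
    """Bookkeeping for a parsing run: total = accepted + sum(rejected)."""

    total: int = 0
    accepted: int = 0
    rejected: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "accepted": self.accepted,
            "rejected": {reason: self.rejected.get(reason, 0) for reason in REJECT_REASONS},
        }


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def locate_homology(read_sequence: str, layout: ReadLayout) -> Optional[HomologyMatch]:
    """Find the leftmost minimal-mismatch placement of the homology region.

    Scans all substitution-only alignments of ``layout.homology_sequence``
    against ``read_sequence`` and returns the leftmost offset achieving the
    minimum mismatch count, provided that minimum does not exceed
    ``layout.max_homology_mismatches``.  ``N`` bases always count as
    mismatches.  Returns None when no acceptable placement exists.
    """
    if not read_sequence:
        raise ValueError("read_sequence must be non-empty")
    hom = layout.homology_sequence
    n, m = len(read_sequence), len(hom)
    if m > n:
        return None
    # Fast path: an exact occurrence is necessarily the global minimum, and
    # str.find returns the leftmost one.
    pos = read_sequence.find(hom)
    if pos != -1:
        return HomologyMatch(pos, 0)
    best_pos: Optional[int] = None
    best_mm = layout.max_homology_mismatches + 1
    for off in range(n - m + 1):
        mm = 0
        window = read_sequence[off : off + m]
        for x, y in zip(window, hom):
            if x != y:
                mm += 1
                if mm >= best_mm:
                    break
        if mm < best_mm:
            best_pos, best_mm = off, mm
    if best_pos is None:
        return None
    return HomologyMatch(best_pos, best_mm)


def parse_read(
    read_id: str,
    read_sequence: str,
    layout: ReadLayout,
    panel: AntibodyPanel,
    tag_max_mismatches: int = 0,
) -> ParsedRead:
    """Decompose one read into (cell barcode, UMI, tag) or reject it.

    The homology region anchors the layout: the barcode is the
    ``barcode_length`` bases ending at the homology start, the UMI and tag
    follow the homology.  Rejections (in order of precedence):

    - ``homology_not_found`` — no placement within the mismatch budget;
    - ``truncated_flank`` — too few bases up- or downstream of the homology;
    - ``ambiguous_base`` — an N or other non-A/C/G/T base inside the
      barcode, UMI or tag segment.

    An empty sequence signals a corrupt input record and raises.
    """
    if not read_sequence:
        raise FastqFormatError(f"empty sequence for read {read_id!r}")
    seq = read_sequence.upper()
    match = locate_homology(seq, layout)
    if match is None:
        return ParsedRead(read_id, status="rejected", reject_reason=HOMOLOGY_NOT_FOUND)
    p = match.position
    hom_len = len(layout.homology_sequence)
    end = p + hom_len + layout.umi_length + layout.tag_length
    if p < layout.barcode_length or end > len(seq):
        return ParsedRead(read_id, status="rejected", reject_reason=TRUNCATED_FLANK)
    barcode = seq[p - layout.barcode_length : p]
    umi = seq[p + hom_len : p + hom_len + layout.umi_length]
    tag = seq[p + hom_len + layout.umi_length : end]
    if not (set(barcode) | set(umi) | set(tag)) <= _DNA_SET:
        return ParsedRead(read_id, status="rejected", reject_reason=AMBIGUOUS_BASE)
    antibody = panel.match(tag, tag_max_mismatches) or UNMAPPED
    return ParsedRead(
        read_id,
        cell_barcode=barcode,
        umi=umi,
        tag_sequence=tag,
        antibody=antibody,
    )


def _open_text(path):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def parse_fastq(
    path,
    layout: ReadLayout,
    panel: AntibodyPanel,
    tag_max_mismatches: int = 0,
) -> tuple[list[ParsedRead], ParseSummary]:
    """Parse every record of a (possibly gzipped) single-end FASTQ file.

    Returns one :class:`ParsedRead` per input record plus a
    :class:`ParseSummary` whose counts conserve
    (``total == accepted + sum(rejected)``).  A truncated or malformed
    record raises :class:`FastqFormatError` naming the record index.
    """
    reads: list[ParsedRead] = []
    summary = ParseSummary()
    with _open_text(path) as handle:
        records = SeqIO.parse(handle, "fastq")
        index = 0
        while True:
            try:
                rec = next(records)
            except StopIteration:
                break
            except ValueError as exc:
                raise FastqFormatError(
                    f"malformed FASTQ record {index + 1} in {path}: {exc}"
                ) from exc
            index += 1
            parsed = parse_read(rec.id, str(rec.seq), layout, panel, tag_max_mismatches)
            reads.append(parsed)
            summary.total += 1
            if parsed.accepted:
                summary.accepted += 1
            else:
                summary.rejected[parsed.reject_reason] += 1
    return reads, summary


def write_accepted_tsv(reads: Iterable[ParsedRead], path) -> int:
    """Write accepted reads as TSV (read_id, barcode, umi, tag, antibody)."""
    n = 0
    with open(path, "w") as fh:
        fh.write("read_id\tcell_barcode\tumi\ttag_sequence\tantibody\n")
        for r in reads:
            if not r.accepted:
                continue
            fh.write(
                f"{r.read_id}\t{r.cell_barcode}\t{r.umi}\t{r.tag_sequence}\t{r.antibody}\n"
            )
            n += 1
    return n
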