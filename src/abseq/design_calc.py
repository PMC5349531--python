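"""Sequencing-capacity, amplicon and Poisson-encapsulation arithmetic.

The experiment's scale is governed by simple budget identities.  A
sequencer of capacity C reads supports N_c cells at N_r reads per cell
(C = N_c x N_r); spreading those reads over N_a antibodies sets the
per-antibody per-cell dynamic range C / (N_c x N_a).  Droplet loading is
Poisson: cells at ~1 per 30 droplets and barcode molecules at ~1 per 10
droplets, which fixes both the usable-droplet yield and the multiplet
(double-encapsulation) rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class DynamicRange:
    """Counts per antibody per cell and its log10 ("decades")."""

    counts: float

    @property
    def decades(self) -> float:
        return math.log10(self.counts)


@dataclass(frozen=True)
class Occupancy:
    """Poisson droplet occupancy probabilities at loading rate lambda."""

    p_zero: float
    p_at_least_one: float
    p_multiple_given_occupied: float


def capacity(n_cells: float, reads_per_cell: float) -> float:
    """Total sequencer reads needed: C = N_c x N_r."""
    if n_cells <= 0 or reads_per_cell <= 0:
        raise ValueError("inputs must be positive")
    return n_cells * reads_per_cell


def reads_per_cell(total_reads: float, n_cells: float) -> float:
    """Reads available per cell: N_r = C / N_c."""
    if total_reads <= 0 or n_cells <= 0:
        raise ValueError("inputs must be positive")
    return total_reads / n_cells


def dynamic_range_per_antibody(
    total_reads: float, n_cells: float, n_antibodies: float
) -> DynamicRange:
    """Counts resolvable per antibody per cell: C / (N_c x N_a)."""
    if total_reads <= 0 or n_cells <= 0 or n_antibodies <= 0:
        raise ValueError("inputs must be positive")
    return DynamicRange(total_reads / (n_cells * n_antibodies))


def tag_space(length: int) -> int:
    """Number of distinct DNA tags of a given length: 4**length."""
    if length < 0:
        raise ValueError("length must be >= 0")
    return 4**length


def spliced_length(barcode_amplicon: int, tag_amplicon: int, overlap: int) -> int:
    """Length of the overlap-extension product of two amplicons.

    The shared homology region is counted once:
    ``barcode_amplicon + tag_amplicon - overlap``.
    """
    if barcode_amplicon <= 0 or tag_amplicon <= 0 or overlap < 0:
        raise ValueError("amplicon lengths must be positive and overlap >= 0")
    if overlap > min(barcode_amplicon, tag_amplicon):
        raise ValueError("overlap cannot exceed either amplicon length")
    return barcode_amplicon + tag_amplicon - overlap


def poisson_occupancy(lam: float) -> Occupancy:
    """Droplet occupancy under Poisson loading at rate ``lam``.

    Returns P(0), P(>=1) and the multiplet rate among occupied droplets
    P(>=2 | >=1) = (1 - e^-lam - lam e^-lam) / (1 - e^-lam).
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    p0 = math.exp(-lam)
    p_ge1 = -math.expm1(-lam)  # 1 - e^-lam, stable for tiny lam
    p_ge2 = p_ge1 - lam * p0
    return Occupancy(p0, p_ge1, p_ge2 / p_ge1)


def expected_mixed_multiplet_fraction(lam: float, mixture_p: float) -> float:
    """Expected fraction of occupied droplets holding cells of both types.

    Each encapsulated cell's type is an independent Bernoulli(p) draw, so a
    droplet with k cells is mixed with probability 1 - p**k - (1-p)**k.
    The Poisson series over k >= 2 is truncated when terms fall below
    1e-12, far beyond any reported precision.
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if not 0 <= mixture_p <= 1:
        raise ValueError("mixture_p must be in [0, 1]")
    p, q = mixture_p, 1.0 - mixture_p
    pmf = math.exp(-lam)  # P(k=0)
    total = 0.0
    k = 0
    while True:
        k += 1
        pmf *= lam / k
        if k >= 2:
            term = pmf * (1.0 - p**k - q**k)
            total += term
            if pmf < 1e-12:
                break
    return total / (1.0 - math.exp(-lam))
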