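"""Generative-model checks: loading statistics, amplification, determinism."""

import gzip
import math

import numpy as np
import pytest

from abseq.design_calc import expected_mixed_multiplet_fraction, poisson_occupancy
from abseq.read_structures import parse_fastq
from abseq.simulator import (
    DropletEvent,
    Molecule,
    SimParams,
    amplify_and_read,
    simulate_encapsulation,
    simulate_molecules,
    simulate_run,
    write_run,
)


class TestEncapsulation:
    def test_loading_statistics_match_closed_forms(self):
        params = SimParams(n_merge_events=200_000, rng_seed=3)
        enc = simulate_encapsulation(params, params.rng())
        occ = poisson_occupancy(params.lambda_cell)
        p_hat = enc.occupied_count / enc.n_events
        se = math.sqrt(p_hat * (1 - p_hat) / enc.n_events)
        assert abs(p_hat - occ.p_at_least_one) < 3 * se
        frac = enc.mixed_fraction_among_occupied()
        expected = expected_mixed_multiplet_fraction(params.lambda_cell, params.mixture_p)
        se_mixed = math.sqrt(expected * (1 - expected) / enc.occupied_count)
        assert abs(frac - expected) < 3 * se_mixed

    def test_dilute_limit_has_no_mixed_droplets(self):
        params = SimParams(n_merge_events=100_000, lambda_cell=1e-4, rng_seed=5)
        enc = simulate_encapsulation(params, params.rng())
        assert enc.mixed_count == 0

    def test_fixed_seed_reproduces_events(self):
        params = SimParams(n_merge_events=20_000, rng_seed=17)
        a = simulate_encapsulation(params, params.rng())
        b = simulate_encapsulation(params, params.rng())
        assert np.array_equal(a.cell_count, b.cell_count)
        assert np.array_equal(a.barcode_count, b.barcode_count)
        assert a.event_barcodes == b.event_barcodes

    def test_productive_events_have_cells_and_barcodes(self):
        params = SimParams(n_merge_events=50_000, rng_seed=19)
        enc = simulate_encapsulation(params, params.rng())
        for event in enc.iter_productive_events(params.cell_types):
            assert len(event.cell_types) >= 1
            assert len(event.barcodes) >= 1

    def test_barcodes_unique_across_run(self):
        params = SimParams(n_merge_events=50_000, rng_seed=19)
        enc = simulate_encapsulation(params, params.rng())
        flat = [b for bcs in enc.event_barcodes for b in bcs]
        assert len(flat) == len(set(flat))


class TestMolecules:
    def _event(self, cell_types, barcodes, index=0):
        return DropletEvent(index, tuple(cell_types), tuple(barcodes))

    def test_poisson_means_recovered(self):
        params = SimParams(rng_seed=29)
        rng = params.rng()
        counts = {"CD3": [], "CD19": []}
        for i in range(1000):
            mols = simulate_molecules(self._event(["jurkat"], ["A" * 10], i), params, rng)
            for antibody in counts:
                counts[antibody].append(sum(m.antibody == antibody for m in mols))
        for antibody, mean in (("CD3", 20.0), ("CD19", 0.2)):
            got = np.mean(counts[antibody])
            se = math.sqrt(mean / 1000)  # Poisson variance = mean
            assert abs(got - mean) < 3 * se

    def test_zero_mean_zero_molecules(self):
        params = SimParams(
            antibody_means={"jurkat": {"CD3": 0.0}, "raji": {"CD19": 0.0}}, rng_seed=1
        )
        mols = simulate_molecules(self._event(["jurkat"], ["A" * 10]), params, params.rng())
        assert mols == []

    def test_split_cell_conserves_molecules(self):
        params = SimParams(rng_seed=31)
        rng = params.rng()
        mols = simulate_molecules(
            self._event(["jurkat"], ["A" * 10, "C" * 10]), params, rng
        )
        by_barcode = {"A" * 10: 0, "C" * 10: 0}
        for m in mols:
            by_barcode[m.barcode] += 1
        assert sum(by_barcode.values()) == len(mols)
        assert set(by_barcode) == {"A" * 10, "C" * 10}


def _molecule(i, barcode, antibody="CD3", umi="AAAAAAAA"):
    return Molecule(f"m{i}", 0, "c0", "jurkat", barcode, antibody, umi)


class TestAmplifyAndRead:
    def test_no_amplification_no_errors_one_perfect_read_each(self):
        params = SimParams(amplification_mean=0.0, rng_seed=2)
        mols = [_molecule(i, "ACGTACGTAC") for i in range(20)]
        reads, copies = amplify_and_read(mols, params, params.rng())
        assert len(reads) == 20
        assert copies.tolist() == [1] * 20
        layout = params.layout
        expected = "ACGTACGTAC" + layout.homology_sequence + "AAAAAAAA" + "TTATAAC"
        assert all(r.sequence == expected for r in reads)

    def test_read_count_equals_total_copies(self):
        params = SimParams(rng_seed=4)
        mols = [_molecule(i, "ACGTACGTAC") for i in range(200)]
        reads, copies = amplify_and_read(mols, params, params.rng())
        assert len(reads) == copies.sum()

    def test_gc_bias_increases_amplification_monotonically(self):
        """Mean copies rise strictly with barcode GC when the bias is on."""
        params = SimParams(gc_bias=0.8, rng_seed=6)
        rng = params.rng()
        means = []
        for barcode in ("A" * 10, "G" * 5 + "A" * 5, "G" * 10):  # GC 0, 0.5, 1
            mols = [_molecule(i, barcode) for i in range(1000)]
            _, copies = amplify_and_read(mols, params, rng)
            means.append(copies.mean())
        assert means[0] < means[1] < means[2]

    def test_pcr_errors_spawn_hamming1_mutant_barcodes(self, noisy_run):
        truth_barcodes = set(noisy_run.truth.molecules["barcode"])
        layout = noisy_run.params.layout
        hom = layout.homology_sequence
        observed = set()
        for read in noisy_run.reads:
            pos = read.sequence.find(hom)
            if pos == layout.barcode_length:
                observed.add(read.sequence[:pos])
        mutants = observed - truth_barcodes
        assert mutants
        from abseq.hamming_filter import hamming_distance

        assert any(
            min(hamming_distance(m, t) for t in truth_barcodes) == 1 for m in mutants
        )

    def test_subsampling_hits_target(self):
        params = SimParams(total_reads_target=500, rng_seed=8)
        mols = [_molecule(i, "ACGTACGTAC") for i in range(100)]
        reads, copies = amplify_and_read(mols, params, params.rng())
        assert len(reads) == 500
        assert copies.sum() > 500  # subsampled from the full pool


class TestRunDeterminism:
    def test_same_seed_same_reads_and_truth(self):
        params = SimParams(n_merge_events=5_000, rng_seed=77)
        a, b = simulate_run(params), simulate_run(params)
        assert a.reads == b.reads
        assert a.truth.molecules.equals(b.truth.molecules)
        assert a.truth.cells.equals(b.truth.cells)
        assert a.truth.events.equals(b.truth.events)

    def test_written_files_byte_identical(self, tmp_path):
        params = SimParams(n_merge_events=5_000, rng_seed=77)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_run(simulate_run(params), d1)
        write_run(simulate_run(params), d2)
        for name in ("reads.fastq", "truth_cells.tsv", "truth_molecules.tsv", "params.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_reads_trace_to_truth_molecules(self, zero_noise_run):
        mol_ids = set(zero_noise_run.truth.molecules["molecule_id"])
        for read in zero_noise_run.reads:
            assert read.read_id.rsplit(":", 1)[0] in mol_ids

    def test_emitted_reads_equal_summed_copies(self, zero_noise_run):
        assert (
            zero_noise_run.truth.molecules["copies_emitted"].sum()
            == len(zero_noise_run.reads)
        )


class TestWriteRun:
    def test_fastq_four_line_records(self, tmp_path):
        params = SimParams(n_merge_events=3_000, rng_seed=15)
        run = simulate_run(params)
        paths = write_run(run, tmp_path)
        lines = paths["fastq"].read_text().splitlines()
        assert len(lines) == 4 * len(run.reads)
        assert lines[0].startswith("@") and lines[2] == "+"
        assert len(lines[1]) == len(lines[3]) == params.layout.read_length

    def test_gzip_output_parses(self, tmp_path, layout, panel):
        params = SimParams(n_merge_events=3_000, rng_seed=15)
        run = simulate_run(params)
        paths = write_run(run, tmp_path, gzip_fastq=True)
        assert paths["fastq"].suffix == ".gz"
        with gzip.open(paths["fastq"], "rt") as fh:
            assert fh.readline().startswith("@")
        reads, summary = parse_fastq(paths["fastq"], layout, panel)
        assert summary.total == len(run.reads)
        assert summary.accepted == summary.total  # zero-noise round trip
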