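import pytest

from abseq.pipeline import PipelineConfig, run_pipeline
from abseq.read_structures import AntibodyPanel, ReadLayout
from abseq.simulator import SimParams, simulate_run, write_run


@pytest.fixture
def layout():
    return ReadLayout()


@pytest.fixture
def panel():
    return AntibodyPanel.default()


@pytest.fixture(scope="session")
def zero_noise_run():
    """Error-free simulated run at the default loading rates (~100 cells)."""
    return simulate_run(SimParams(n_merge_events=30_000, rng_seed=11))


@pytest.fixture(scope="session")
def zero_noise_dir(zero_noise_run, tmp_path_factory):
    d = tmp_path_factory.mktemp("zero_noise")
    write_run(zero_noise_run, d)
    return d


@pytest.fixture(scope="session")
def zero_noise_result(zero_noise_dir):
    """Pipeline output on the error-free run.

    With no error process there is no artifact tail in the read-count
    distribution, so the knee threshold is 1.0 (every group is genuine).
    """
    return run_pipeline(
        zero_noise_dir / "reads.fastq",
        zero_noise_dir / "out",
        PipelineConfig(cumulative_fraction=1.0),
    )


@pytest.fixture(scope="session")
def noisy_run():
    """Run with GC-biased amplification plus PCR/sequencing substitutions."""
    return simulate_run(
        SimParams(
            n_merge_events=20_000,
            gc_bias=1.5,
            pcr_substitution_rate=0.003,
            seq_error_rate=0.001,
            rng_seed=23,
        )
    )
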