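import numpy as np
import pytest

from asmqual.flags import accuracy_metrics, flag_errors
from asmqual.mapping import map_reads
from asmqual.simulate import (
    ReadProfile,
    random_assembly,
    simulate_reads,
    synthetic_metrics_table,
)


@pytest.fixture(scope="session")
def perfect_run():
    """A 50 kbp gapless genome with perfect 20x reads, mapped and flagged."""
    genome = random_assembly(1, 50_000, seed=101)
    reads = simulate_reads(genome, ReadProfile(coverage=20), seed=102)
    aln = map_reads(genome, reads)
    tracks = flag_errors(aln, genome)
    acc = accuracy_metrics(tracks, aln)
    return {"genome": genome, "reads": reads, "aln": aln,
            "tracks": tracks, "acc": acc}


@pytest.fixture(scope="session")
def synthetic_table():
    """400-row parametric metrics table with noise sd 5."""
    return synthetic_metrics_table(n=400, noise_sd=5.0, seed=1)


@pytest.fixture(scope="session")
def small_training_table():
    """A small end-to-end training table (7 genomes x 3 levels)."""
    from asmqual.simulate import ErrorProfile, generate_training_set

    gradient = (
        ErrorProfile(label="lvl0"),
        ErrorProfile(snp_rate=0.05, indel_rate=0.002, fragmentation=2, label="lvl5"),
        ErrorProfile(snp_rate=0.15, indel_rate=0.006, gap_events=2,
                     fragmentation=5, label="lvl15"),
    )
    return generate_training_set(
        n_genomes=7, quality_gradient=gradient, ref_length=15_000, seed=42
    )
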