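import numpy as np
import pytest

from slamkit.simulate import (
    BulkSimConfig,
    InjurySimConfig,
    simulate_bulk_timecourse,
    simulate_sc_injury,
)


@pytest.fixture(scope="session")
def bulk_sim():
    """Small read-level bulk time course shared across tests."""
    return simulate_bulk_timecourse(BulkSimConfig(n_genes=10, mean_molecules=40, seed=11))


@pytest.fixture(scope="session")
def sc_sim():
    """Small paired sham/injured single-cell simulation."""
    return simulate_sc_injury(
        InjurySimConfig(n_genes=200, n_cells_per_type=60, n_induced=15, seed=7)
    )


def random_read(rng, read_id="r0", max_len=100, strand=None, gene_id="g0"):
    """Random AlignedReadRecord for oracle-equivalence testing."""
    from slamkit.conversions import AlignedReadRecord

    n = int(rng.integers(1, max_len + 1))
    start = int(rng.integers(0, 1000))
    bases = "ACGTN"
    ref = "".join(bases[i] for i in rng.choice(5, size=n, p=[0.2, 0.15, 0.15, 0.45, 0.05]))
    read = list(ref)
    for i in range(n):
        if rng.random() < 0.15:
            read[i] = bases[int(rng.integers(0, 5))]
    quals = rng.integers(2, 41, size=n).tolist()
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    return AlignedReadRecord(
        read_id=read_id,
        ref_positions=list(range(start, start + n)),
        ref_bases=ref,
        read_bases="".join(read),
        base_quals=quals,
        gene_id=gene_id,
        genome_strand_of_gene=strand,
    )


def brute_force_tc(read, masked=frozenset(), min_qual=20):
    """Independent per-position string-comparison oracle for count_tc."""
    sense_ref = "T" if read.genome_strand_of_gene == "+" else "A"
    sense_alt = "C" if read.genome_strand_of_gene == "+" else "G"
    n_t, n_tc = 0, 0
    for pos, rb, qb, q in zip(
        read.ref_positions, read.ref_bases, read.read_bases, read.base_quals
    ):
        if rb == sense_ref and q >= min_qual and pos not in masked and qb != "N":
            n_t += 1
            if qb == sense_alt:
                n_tc += 1
    return n_t, n_tc
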