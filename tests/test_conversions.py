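"""Conversion extraction, counting, tallying and SNV blacklisting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slamkit.conversions import (
    AlignedReadRecord,
    ConfigError,
    ConversionCall,
    PositionTally,
    ReadParseError,
    SNVBlacklist,
    build_position_tally,
    call_snv_blacklist,
    conversion_rate,
    count_tc,
    extract_mismatches,
    substitution_spectrum,
)

from conftest import brute_force_tc, random_read


def make_read(ref, read, quals=None, strand="+", positions=None, **kw):
    n = len(ref)
    return AlignedReadRecord(
        read_id=kw.pop("read_id", "r"),
        ref_positions=positions if positions is not None else list(range(n)),
        ref_bases=ref,
        read_bases=read,
        base_quals=quals if quals is not None else [30] * n,
        genome_strand_of_gene=strand,
        **kw,
    )


class TestExtractMismatches:
    def test_identity_read_yields_no_events(self):
        assert extract_mismatches(make_read("ACGT", "ACGT")) == []

    def test_events_at_substituted_positions(self):
        # ref T T G A vs read T C G G: T>C at index 1, A>G at index 3
        events = extract_mismatches(make_read("TTGA", "TCGG"))
        assert events == [(1, "T", "C", 30), (3, "A", "G", 30)]

    def test_n_bases_never_yield_events(self):
        assert extract_mismatches(make_read("NT", "CT")) == []
        assert extract_mismatches(make_read("TT", "NT")) == []

    def test_length_mismatch_is_structured_error(self):
        bad = AlignedReadRecord("rbad", [0, 1], "AC", "A", [30, 30])
        with pytest.raises(ReadParseError, match="rbad"):
            extract_mismatches(bad)


class TestCountTc:
    def test_plus_strand_t_run(self):
        call = count_tc(make_read("TTTT", "TCTC"))
        assert (call.n_t_covered, call.n_tc) == (4, 2)

    def test_quality_mask_removes_numerator_and_denominator(self):
        call = count_tc(make_read("TTTT", "TCTC", quals=[30, 19, 30, 19]))
        assert (call.n_t_covered, call.n_tc) == (2, 0)

    def test_minus_strand_counts_genomic_a_to_g(self):
        call = count_tc(make_read("AAAA", "AGAG", strand="-"))
        assert (call.n_t_covered, call.n_tc) == (4, 2)

    def test_blacklisted_position_excluded_from_both(self):
        bl = SNVBlacklist(positions=frozenset({1}))
        call = count_tc(make_read("TTTT", "TCTT"), blacklist=bl)
        assert (call.n_t_covered, call.n_tc) == (3, 0)

    def test_unknown_strand_errors_in_strand_aware_mode(self):
        read = make_read("TT", "TC", strand=None)
        with pytest.raises(ValueError, match="strand"):
            count_tc(read)

    def test_empty_read_gives_zero_call(self):
        call = count_tc(make_read("", "", quals=[]))
        assert (call.n_t_covered, call.n_tc) == (0, 0)

    def test_strict_mode_masks_low_coverage_positions(self):
        bl = SNVBlacklist(low_coverage_positions=frozenset({0}))
        relaxed = count_tc(make_read("TT", "CC"), blacklist=bl)
        strict = count_tc(make_read("TT", "CC"), blacklist=bl, strict_low_coverage=True)
        assert (relaxed.n_t_covered, relaxed.n_tc) == (2, 2)
        assert (strict.n_t_covered, strict.n_tc) == (1, 1)

    def test_oracle_equivalence_randomized(self):
        """count_tc equals brute-force string comparison on random reads."""
        rng = np.random.default_rng(42)
        for i in range(300):
            read = random_read(rng, read_id=f"r{i}")
            masked = frozenset(
                int(p) for p in rng.choice(read.ref_positions, size=min(3, len(read.ref_positions)), replace=False)
            ) if rng.random() < 0.5 else frozenset()
            mq = int(rng.integers(0, 41))
            call = count_tc(read, SNVBlacklist(positions=masked), min_qual=mq)
            assert (call.n_t_covered, call.n_tc) == brute_force_tc(read, masked, mq)

    def test_strand_symmetry(self):
        """Reverse-complementing ref and read and flipping strand preserves counts."""
        comp = str.maketrans("ACGTN", "TGCAN")
        rng = np.random.default_rng(3)
        for i in range(50):
            read = random_read(rng, read_id=f"s{i}", strand="+")
            rc = AlignedReadRecord(
                read_id=read.read_id,
                ref_positions=read.ref_positions,
                ref_bases=read.ref_bases[::-1].translate(comp),
                read_bases=read.read_bases[::-1].translate(comp),
                base_quals=read.base_quals[::-1],
                genome_strand_of_gene="-",
            )
            a, b = count_tc(read), count_tc(rc)
            assert (a.n_t_covered, a.n_tc) == (b.n_t_covered, b.n_tc)

    @given(min_q1=st.integers(0, 40), min_q2=st.integers(0, 40), seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_quality_threshold_monotonicity(self, min_q1, min_q2, seed):
        """Raising min_qual never increases n_tc or n_t_covered."""
        lo, hi = sorted((min_q1, min_q2))
        read = random_read(np.random.default_rng(seed))
        a, b = count_tc(read, min_qual=lo), count_tc(read, min_qual=hi)
        assert b.n_t_covered <= a.n_t_covered and b.n_tc <= a.n_tc

    def test_invalid_call_counts_rejected(self):
        with pytest.raises(ValueError):
            ConversionCall(n_t_covered=1, n_tc=2)


class TestPositionTally:
    def test_identical_reads_accumulate(self):
        reads = [make_read("TT", "TC", read_id=f"r{i}") for i in range(3)]
        tally = build_position_tally(reads)
        assert tally.coverage == {0: 3, 1: 3}
        assert tally.conversions == {1: 3}

    def test_order_invariance_and_additivity(self):
        rng = np.random.default_rng(5)
        reads = [random_read(rng, read_id=f"r{i}") for i in range(30)]
        fwd = build_position_tally(reads)
        rev = build_position_tally(reads[::-1])
        assert fwd.coverage == rev.coverage and fwd.conversions == rev.conversions
        # per-position conversions sum to the sum of per-read calls
        total = sum(count_tc(r).n_tc for r in reads)
        assert sum(fwd.conversions.values()) == total

    def test_empty_stream(self):
        tally = build_position_tally([])
        assert tally.coverage == {} and tally.conversions == {}


class TestSNVBlacklist:
    @pytest.mark.parametrize(
        "cov,conv,in_snv,in_low",
        [
            (20, 5, True, False),   # exactly 25%
            (20, 4, False, False),  # 20% below threshold
            (10, 3, True, False),   # boundary coverage, 30%
            (9, 9, False, True),    # all converted but under-covered
            (10, 2, False, False),  # 20% at boundary coverage
            (11, 3, True, False),   # 27%
        ],
    )
    def test_membership_matches_predicate(self, cov, conv, in_snv, in_low):
        tally = PositionTally(coverage={100: cov}, conversions={100: conv})
        bl = call_snv_blacklist(tally)
        assert (100 in bl.positions) is in_snv
        assert (100 in bl.low_coverage_positions) is in_low

    def test_exhaustive_grid_matches_predicate(self):
        tally = PositionTally()
        expected_snv, expected_low = set(), set()
        pos = 0
        for cov in range(1, 31):
            for conv in range(0, cov + 1):
                tally.coverage[pos] = cov
                if conv:
                    tally.conversions[pos] = conv
                if cov < 10:
                    expected_low.add(pos)
                elif conv / cov >= 0.25:
                    expected_snv.add(pos)
                pos += 1
        bl = call_snv_blacklist(tally)
        assert set(bl.positions) == expected_snv
        assert set(bl.low_coverage_positions) == expected_low

    def test_config_domain_errors(self):
        with pytest.raises(ConfigError):
            call_snv_blacklist(PositionTally(), min_frac=0.0)
        with pytest.raises(ConfigError):
            call_snv_blacklist(PositionTally(), min_cov=0)


class TestConversionRate:
    def test_conversion_free_reads_rate_zero(self):
        reads = [make_read("TTTT", "TTTT", read_id=f"r{i}", gene_id="g") for i in range(4)]
        tab = conversion_rate(reads, scope="global")
        assert tab["rate"].iloc[0] == 0.0

    def test_global_rate_is_pooled_not_averaged(self):
        calls = [
            (ConversionCall(50, 2), "g1", None),
            (ConversionCall(50, 0), "g2", None),
        ]
        tab = conversion_rate(calls, scope="global")
        assert tab["rate"].iloc[0] == pytest.approx(0.02)

    def test_per_gene_numerators_conserve_global(self):
        rng = np.random.default_rng(9)
        reads = [random_read(rng, read_id=f"r{i}", gene_id=f"g{i % 4}") for i in range(40)]
        per_gene = conversion_rate(reads, scope="per_gene")
        glob = conversion_rate(reads, scope="global")
        assert per_gene["n_tc"].sum() == glob["n_tc"].iloc[0]

    def test_zero_denominator_group_is_missing_not_zero(self):
        calls = [(ConversionCall(0, 0), "g1", None)]
        tab = conversion_rate(calls, scope="per_gene")
        assert np.isnan(tab["rate"].iloc[0])


class TestSubstitutionSpectrum:
    def test_counts_each_type_transcript_sense(self):
        # plus strand: one A>G and one T>C among 2 A sites and 1 T site
        reads = [make_read("AAT", "AGC")]
        spec = substitution_spectrum(reads)
        assert spec.loc["A>G", "n_events"] == 1
        assert spec.loc["T>C", "n_events"] == 1
        assert spec.loc["A>G", "n_sites"] == 2
        # minus strand: genomic A>G is transcript-sense T>C
        spec2 = substitution_spectrum([make_read("A", "G", strand="-")])
        assert spec2.loc["T>C", "n_events"] == 1
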