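"""T-to-C conversion calling from aligned reads.

SLAM-seq chemistry marks 4sU-labeled transcripts with transcript-sense
thymine-to-cytosine substitutions.  On the genome these appear as T>C for
plus-strand genes and A>G for minus-strand genes.  This module extracts
mismatch events from aligned reads, applies base-quality and SNV-blacklist
masks, tallies per-position coverage/conversion counts, and calls the SNV
blacklist from those tallies.

Coordinates are 0-based half-open throughout; conversion from SAM's 1-based
convention happens at ingest (:mod:`slamkit.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")

# transcript-sense T-to-C as seen on the genome, keyed by gene strand
_SENSE_REF = {"+": "T", "-": "A"}
_SENSE_ALT = {"+": "C", "-": "G"}


class ReadParseError(ValueError):
    """Raised when an aligned read record is internally inconsistent."""

    def __init__(self, read_id: str, message: str):
        self.read_id = read_id
        super().__init__(f"read {read_id!r}: {message}")


class ConfigError(ValueError):
    """Raised for parameter values outside their documented domain."""


@dataclass
class AlignedReadRecord:
    """One aligned read with per-base mismatch information.

    ``ref_positions[i]`` is the genomic coordinate (0-based) of the i-th
    aligned base; ``ref_bases[i]`` / ``read_bases[i]`` / ``base_quals[i]``
    are the reference base, read base and Phred quality at that position.
    Insertions do not appear (no reference coordinate); deleted reference
    bases do not appear (no read base) — only aligned substitution-capable
    positions are recorded.
    """

    read_id: str
    ref_positions: Sequence[int]
    ref_bases: str
    read_bases: str
    base_quals: Sequence[int]
    gene_id: str | None = None
    genome_strand_of_gene: str | None = None
    cell_barcode: str | None = None
    umi: str | None = None

    def validate(self) -> "AlignedReadRecord":
        n = len(self.ref_positions)
        if not (len(self.ref_bases) == len(self.read_bases) == len(self.base_quals) == n):
            raise ReadParseError(
                self.read_id,
                "aligned-base fields have unequal lengths "
                f"(positions={n}, ref={len(self.ref_bases)}, "
                f"read={len(self.read_bases)}, quals={len(self.base_quals)})",
            )
        pos = np.asarray(self.ref_positions)
        if n > 1 and not np.all(np.diff(pos) > 0):
            raise ReadParseError(self.read_id, "reference positions not strictly increasing")
        for b in self.ref_bases + self.read_bases:
            if b not in "ACGTN":
                raise ReadParseError(self.read_id, f"invalid base {b!r}")
        if self.genome_strand_of_gene not in (None, "+", "-"):
            raise ReadParseError(
                self.read_id, f"invalid strand {self.genome_strand_of_gene!r}"
            )
        return self


@dataclass
class ConversionCall:
    """Per-read (or per-molecule) conversion summary.

    ``n_t_covered`` counts transcript-sense T positions that pass the quality
    and blacklist masks and carry an informative (non-N) read base; ``n_tc``
    counts the subset showing transcript-sense T-to-C.
    """

    n_t_covered: int
    n_tc: int
    converted_positions: tuple[int, ...] = ()

    def __post_init__(self):
        if not 0 <= self.n_tc <= self.n_t_covered:
            raise ValueError(f"invalid call: n_tc={self.n_tc}, n_t_covered={self.n_t_covered}")


@dataclass
class PositionTally:
    """Per-genomic-position read coverage and conversion counts.

    Coverage counts reads covering a transcript-sense T position with base
    quality >= the filter; conversions counts the subset showing
    transcript-sense T-to-C.
    """

    coverage: dict[int, int] = field(default_factory=dict)
    conversions: dict[int, int] = field(default_factory=dict)

    def add(self, position: int, converted: bool) -> None:
        self.coverage[position] = self.coverage.get(position, 0) + 1
        if converted:
            self.conversions[position] = self.conversions.get(position, 0) + 1

    def to_frame(self) -> pd.DataFrame:
        positions = sorted(self.coverage)
        return pd.DataFrame(
            {
                "position": positions,
                "coverage": [self.coverage[p] for p in positions],
                "conversions": [self.conversions.get(p, 0) for p in positions],
            }
        )


@dataclass
class SNVBlacklist:
    """Genomic positions masked as likely single-nucleotide variants.

    ``positions`` hold confident SNV calls (high apparent conversion fraction
    at adequate coverage); ``low_coverage_positions`` hold positions with too
    few reads to classify.  In strict mode the latter are masked too.
    """

    positions: frozenset[int] = frozenset()
    low_coverage_positions: frozenset[int] = frozenset()

    def __post_init__(self):
        overlap = set(self.positions) & set(self.low_coverage_positions)
        if overlap:
            raise ValueError(f"positions classified both ways: {sorted(overlap)[:5]}")

    def masked(self, strict_low_coverage: bool = False) -> frozenset[int]:
        if strict_low_coverage:
            return self.positions | self.low_coverage_positions
        return self.positions


EMPTY_BLACKLIST = SNVBlacklist()


def extract_mismatches(
    read: AlignedReadRecord,
) -> list[tuple[int, str, str, int]]:
    """Return (position, ref_base, read_base, qual) for every substitution.

    Positions where either base is ``N`` never yield events.
    """
    read.validate()
    events = []
    for pos, rb, qb, q in zip(
        read.ref_positions, read.ref_bases, read.read_bases, read.base_quals
    ):
        if rb != qb and rb in VALID_BASES and qb in VALID_BASES:
            events.append((int(pos), rb, qb, int(q)))
    return events


def count_tc(
    read: AlignedReadRecord,
    blacklist: SNVBlacklist = EMPTY_BLACKLIST,
    min_qual: int = 20,
    strand_aware: bool = True,
    strict_low_coverage: bool = False,
) -> ConversionCall:
    """Count transcript-sense T-to-C conversions on one read.

    For plus-strand genes this counts genomic T>C; for minus-strand genes,
    genomic A>G.  Positions below ``min_qual``, in the blacklist, or with an
    uninformative (N) read base are excluded from both numerator and
    denominator, keeping the conversion rate a per-eligible-site estimate.
    """
    read.validate()
    if strand_aware:
        strand = read.genome_strand_of_gene
        if strand is None:
            raise ValueError(
                f"read {read.read_id!r}: gene strand unknown but strand-aware "
                "counting requested"
            )
    else:
        strand = "+"
    sense_ref = _SENSE_REF[strand]
    sense_alt = _SENSE_ALT[strand]
    masked = blacklist.masked(strict_low_coverage)

    n_t = 0
    converted: list[int] = []
    for pos, rb, qb, q in zip(
        read.ref_positions, read.ref_bases, read.read_bases, read.base_quals
    ):
        if rb != sense_ref or q < min_qual or pos in masked or qb == "N":
            continue
        n_t += 1
        if qb == sense_alt:
            converted.append(int(pos))
    return ConversionCall(n_t_covered=n_t, n_tc=len(converted), converted_positions=tuple(converted))


def build_position_tally(
    reads: Iterable[AlignedReadRecord],
    min_qual: int = 20,
    strand_aware: bool = True,
) -> PositionTally:
    """Aggregate per-position coverage and conversion counts over reads.

    Only transcript-sense T positions passing the quality filter contribute;
    the result is independent of read order.
    """
    tally = PositionTally()
    for read in reads:
        call = count_tc(read, min_qual=min_qual, strand_aware=strand_aware)
        conv = set(call.converted_positions)
        strand = read.genome_strand_of_gene if strand_aware else "+"
        sense_ref = _SENSE_REF[strand]
        for pos, rb, qb, q in zip(
            read.ref_positions, read.ref_bases, read.read_bases, read.base_quals
        ):
            if rb != sense_ref or q < min_qual or qb == "N":
                continue
            tally.add(int(pos), int(pos) in conv)
    return tally


def call_snv_blacklist(
    tally: PositionTally,
    min_frac: float = 0.25,
    min_cov: int = 10,
) -> SNVBlacklist:
    """Call the SNV blacklist from a position tally.

    A position is blacklisted when coverage >= ``min_cov`` and the apparent
    conversion fraction is >= ``min_frac`` — such sites reflect a genetic
    variant rather than labeling.  Positions with coverage below ``min_cov``
    cannot be classified and are reported separately.
    """
    if not (0 < min_frac <= 1):
        raise ConfigError(f"min_frac must be in (0, 1], got {min_frac}")
    if min_cov < 1:
        raise ConfigError(f"min_cov must be >= 1, got {min_cov}")
    snv = set()
    low_cov = set()
    for pos, cov in tally.coverage.items():
        if cov < min_cov:
            low_cov.add(pos)
        elif tally.conversions.get(pos, 0) / cov >= min_frac:
            snv.add(pos)
    return SNVBlacklist(positions=frozenset(snv), low_coverage_positions=frozenset(low_cov))


def conversion_rate(
    calls: Iterable[tuple[ConversionCall, str | None, str | None]]
    | Iterable[AlignedReadRecord],
    scope: str = "global",
    blacklist: SNVBlacklist = EMPTY_BLACKLIST,
    min_qual: int = 20,
    strand_aware: bool = True,
) -> pd.DataFrame:
    """Compute pooled conversion rates at the requested grouping.

    ``calls`` may be AlignedReadRecords (calls are computed here) or
    pre-computed ``(ConversionCall, gene_id, cell_barcode)`` triples.
    Rate = sum(n_tc) / sum(n_t_covered) within each group; groups with zero
    covered T positions get a missing (NaN) rate, never 0.

    Returns a DataFrame with columns group, n_tc, n_t_covered, rate.
    """
    if scope not in ("global", "per_gene", "per_cell"):
        raise ConfigError(f"unknown scope {scope!r}")
    rows = []
    for item in calls:
        if isinstance(item, AlignedReadRecord):
            call = count_tc(item, blacklist, min_qual, strand_aware)
            gene, cell = item.gene_id, item.cell_barcode
        else:
            call, gene, cell = item
        if scope == "global":
            key = "all"
        elif scope == "per_gene":
            if gene is None:  # ambiguous/unassigned reads stay out of per-gene tallies
                continue
            key = gene
        else:
            if cell is None:
                continue
            key = cell
        rows.append((key, call.n_tc, call.n_t_covered))
    if not rows:
        return pd.DataFrame(columns=["group", "n_tc", "n_t_covered", "rate"])
    df = (
        pd.DataFrame(rows, columns=["group", "n_tc", "n_t_covered"])
        .groupby("group", as_index=False)
        .sum()
        .sort_values("group", kind="stable")
        .reset_index(drop=True)
    )
    denom = df["n_t_covered"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        df["rate"] = np.where(denom > 0, df["n_tc"] / denom, np.nan)
    return df


def substitution_spectrum(
    reads: Iterable[AlignedReadRecord],
    min_qual: int = 20,
    strand_aware: bool = True,
) -> pd.DataFrame:
    """Tally all 12 transcript-sense substitution types and eligible sites.

    Used by the background model: the 11 non-(T>C) rates estimate the
    sequencing/chemistry error floor.  Returns a DataFrame indexed by
    substitution label ('T>C', 'A>G', ...) with columns n_events and
    n_sites (eligible reference occurrences of the source base).
    """
    comp = str.maketrans("ACGT", "TGCA")
    events: dict[str, int] = {}
    sites: dict[str, int] = {b: 0 for b in "ACGT"}
    for read in reads:
        read.validate()
        strand = read.genome_strand_of_gene if strand_aware else "+"
        if strand is None:
            raise ValueError(f"read {read.read_id!r}: unknown strand")
        for rb, qb, q in zip(read.ref_bases, read.read_bases, read.base_quals):
            if q < min_qual or rb not in VALID_BASES or qb not in VALID_BASES:
                continue
            if strand == "-":
                rb, qb = rb.translate(comp), qb.translate(comp)
            sites[rb] += 1
            if rb != qb:
                key = f"{rb}>{qb}"
                events[key] = events.get(key, 0) + 1
    labels = [f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b]
    return pd.DataFrame(
        {
            "n_events": [events.get(lab, 0) for lab in labels],
            "n_sites": [sites[lab[0]] for lab in labels],
        },
        index=pd.Index(labels, name="substitution"),
    )
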