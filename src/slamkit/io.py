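"""Readers and writers for the pipeline's on-disk formats.

SAM/BAM alignment records round-trip through :class:`AlignedReadRecord`
using MD-tag mismatch reconstruction (or a supplied reference when the MD
tag is absent).  Count matrices are written as a Matrix Market pair
(labeled.mtx / unlabeled.mtx) with shared features.tsv and barcodes.tsv.
SNV blacklists are BED (0-based half-open).  All TSV outputs carry a header
row and a comment line with the tool version and config hash.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import pysam
from scipy import io as spio
from scipy import sparse

from . import __version__
from .conversions import AlignedReadRecord, ReadParseError, SNVBlacklist
from .quantify import LabeledMatrices

DEFAULT_TAGS = {"cell": "CB", "umi": "UB", "gene": "GX"}


def _md_string(ref_bases: str, read_bases: str) -> str:
    """MD tag for a gapless alignment: match-run lengths and mismatched ref bases."""
    parts = []
    run = 0
    for rb, qb in zip(ref_bases, read_bases):
        if rb == qb:
            run += 1
        else:
            parts.append(str(run))
            parts.append(rb)
            run = 0
    parts.append(str(run))
    return "".join(parts)


def write_sam(
    reads: Iterable[AlignedReadRecord],
    path: str,
    reference: Mapping[str, str],
    contig: str = "chrS",
    tags: Mapping[str, str] = DEFAULT_TAGS,
) -> int:
    """Write records as a SAM file with MD tags; returns the record count.

    Records are assumed gapless (contiguous reference positions), which is
    what the simulators emit.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in reference.items()],
    }
    n = 0
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for read in reads:
            read.validate()
            pos = list(read.ref_positions)
            if len(pos) > 1 and pos[-1] - pos[0] != len(pos) - 1:
                raise ValueError(f"read {read.read_id!r}: gapped records not supported by writer")
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.read_id
            seg.query_sequence = read.read_bases
            seg.reference_id = out.header.get_tid(contig)
            seg.reference_start = pos[0]
            seg.cigarstring = f"{len(pos)}M"
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in read.base_quals)
            )
            seg.mapping_quality = 255
            seg.set_tag("MD", _md_string(read.ref_bases, read.read_bases))
            if read.gene_id is not None:
                seg.set_tag(tags["gene"], read.gene_id)
            if read.cell_barcode is not None:
                seg.set_tag(tags["cell"], read.cell_barcode)
            if read.umi is not None:
                seg.set_tag(tags["umi"], read.umi)
            out.write(seg)
            n += 1
    return n


def read_alignments(
    path: str,
    gene_strands: Mapping[str, str] | None = None,
    reference: Mapping[str, str] | None = None,
    tags: Mapping[str, str] = DEFAULT_TAGS,
) -> Iterator[AlignedReadRecord]:
    """Lazily yield validated AlignedReadRecords from a SAM/BAM file.

    Mismatch information is reconstructed from the MD tag; when a record has
    no MD tag, reference bases are looked up in ``reference`` (contig name ->
    sequence).  A record with neither raises with a remediation hint.
    ``gene_strands`` maps gene id -> strand so downstream counting can be
    transcript-sense; unmapped genes yield strand None.
    """
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as f:
        for seg in f:
            if seg.is_unmapped or seg.query_sequence is None:
                continue
            has_md = seg.has_tag("MD")
            if not has_md and reference is None:
                raise ValueError(
                    f"record {seg.query_name!r} has no MD tag and no reference was "
                    "supplied; run 'samtools calmd' or pass a reference FASTA"
                )
            if has_md:
                pairs = seg.get_aligned_pairs(matches_only=True, with_seq=True)
                positions = [rp for _, rp, _ in pairs]
                ref_bases = "".join(rb.upper() for _, _, rb in pairs)
                qpos = [qp for qp, _, _ in pairs]
            else:
                contig_seq = reference[seg.reference_name]
                pairs = seg.get_aligned_pairs(matches_only=True)
                positions = [rp for _, rp in pairs]
                ref_bases = "".join(contig_seq[rp].upper() for _, rp in pairs)
                qpos = [qp for qp, _ in pairs]
            seq = seg.query_sequence
            quals = seg.query_qualities
            gene = seg.get_tag(tags["gene"]) if seg.has_tag(tags["gene"]) else None
            strand = gene_strands.get(gene) if (gene_strands and gene is not None) else None
            record = AlignedReadRecord(
                read_id=seg.query_name,
                ref_positions=positions,
                ref_bases=ref_bases,
                read_bases="".join(seq[q] for q in qpos),
                base_quals=[int(quals[q]) for q in qpos],
                gene_id=gene,
                genome_strand_of_gene=strand,
                cell_barcode=seg.get_tag(tags["cell"]) if seg.has_tag(tags["cell"]) else None,
                umi=seg.get_tag(tags["umi"]) if seg.has_tag(tags["umi"]) else None,
            )
            yield record.validate()


def write_blacklist_bed(blacklist: SNVBlacklist, path: str, contig: str = "chrS") -> None:
    """BED (0-based half-open) of blacklisted positions; low-coverage sites
    are emitted with name 'low_coverage' for transparency."""
    with open(path, "w") as fh:
        for pos in sorted(blacklist.positions):
            fh.write(f"{contig}\t{pos}\t{pos + 1}\tsnv\n")
        for pos in sorted(blacklist.low_coverage_positions):
            fh.write(f"{contig}\t{pos}\t{pos + 1}\tlow_coverage\n")


def read_blacklist_bed(path: str) -> SNVBlacklist:
    snv, low = set(), set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            start = int(fields[1])
            (low if len(fields) > 3 and fields[3] == "low_coverage" else snv).add(start)
    return SNVBlacklist(positions=frozenset(snv), low_coverage_positions=frozenset(low))


def write_tsv(df: pd.DataFrame, path: str, config_hash: str = "none") -> None:
    """TSV with a header row and a tool-version/config-hash comment line."""
    with open(path, "w") as fh:
        fh.write(f"# slamkit v{__version__} config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_matrices_mtx(m: LabeledMatrices, out_dir: str, config_hash: str = "none") -> None:
    """Matrix Market pair labeled.mtx / unlabeled.mtx with shared index files."""
    os.makedirs(out_dir, exist_ok=True)
    spio.mmwrite(os.path.join(out_dir, "labeled.mtx"), sparse.csr_matrix(m.labeled.to_numpy()))
    spio.mmwrite(os.path.join(out_dir, "unlabeled.mtx"), sparse.csr_matrix(m.unlabeled.to_numpy()))
    pd.Series(m.genes).to_csv(os.path.join(out_dir, "features.tsv"), sep="\t", index=False, header=False)
    pd.Series(m.units).to_csv(os.path.join(out_dir, "barcodes.tsv"), sep="\t", index=False, header=False)


def read_matrices_mtx(out_dir: str) -> LabeledMatrices:
    genes = pd.read_csv(os.path.join(out_dir, "features.tsv"), sep="\t", header=None)[0]
    units = pd.read_csv(os.path.join(out_dir, "barcodes.tsv"), sep="\t", header=None)[0]
    lab = spio.mmread(os.path.join(out_dir, "labeled.mtx")).toarray().astype(np.int64)
    unl = spio.mmread(os.path.join(out_dir, "unlabeled.mtx")).toarray().astype(np.int64)
    gene_index = pd.Index(genes, name="gene")
    unit_index = pd.Index(units, name="unit")
    return LabeledMatrices(
        pd.DataFrame(lab, index=gene_index, columns=unit_index),
        pd.DataFrame(unl, index=gene_index, columns=unit_index),
    )


def read_gene_sets(path: str) -> dict[str, tuple[str, ...]]:
    """Gene sets from GMT (name, description, genes...) or two-column TSV."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        is_gmt = path.endswith(".gmt") or len(first.rstrip("\n").split("\t")) > 2
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields or not fields[0]:
                continue
            if is_gmt:
                sets.setdefault(fields[0], []).extend(g for g in fields[2:] if g)
            else:
                sets.setdefault(fields[0], []).append(fields[1])
    return {k: tuple(v) for k, v in sets.items()}
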