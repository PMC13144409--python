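"""Stage orchestration: run pipeline stages over files, with a run manifest.

Each stage reads/writes the formats defined in :mod:`slamkit.io`; a run
writes its effective config (YAML), a JSON manifest, and stage outputs into
the artifact directory.  Deterministic stages are bit-identical on rerun
with identical config and inputs.
"""

from __future__ import annotations

import json
import logging
import os
import time
from collections import defaultdict
from typing import Sequence

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .conversions import build_position_tally, call_snv_blacklist, conversion_rate, SNVBlacklist
from .injury import ConditionPair, estimate_background, injury_response
from .kinetics import fit_all_genes, summarize_halflives
from .quantify import build_matrices, classify_molecule, labeled_fraction
from . import io as skio

log = logging.getLogger("slamkit")


def _manifest(out_dir: str, stage: str, cfg: PipelineConfig, extra: dict | None = None) -> None:
    payload = {
        "tool": "slamkit",
        "version": __version__,
        "stage": stage,
        "config_hash": cfg.hash(),
        "finished_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    }
    payload.update(extra or {})
    with open(os.path.join(out_dir, f"manifest_{stage}.json"), "w") as fh:
        json.dump(payload, fh, indent=2)


def stage_convcall(
    sam_path: str,
    genes_tsv: str,
    out_dir: str,
    cfg: PipelineConfig,
    blacklist: SNVBlacklist | None = None,
) -> pd.DataFrame:
    """Conversion-rate tables (global, per gene) from an alignment file."""
    os.makedirs(out_dir, exist_ok=True)
    genes = skio.read_tsv(genes_tsv)
    strands = dict(zip(genes["gene_id"], genes["strand"]))
    bl = blacklist if blacklist is not None else SNVBlacklist()
    reads = list(skio.read_alignments(sam_path, gene_strands=strands))
    h = cfg.hash()
    for scope, name in (("global", "rates_global.tsv"), ("per_gene", "rates_per_gene.tsv")):
        table = conversion_rate(reads, scope=scope, blacklist=bl, min_qual=cfg.min_qual)
        skio.write_tsv(table, os.path.join(out_dir, name), h)
    _manifest(out_dir, "convcall", cfg, {"n_reads": len(reads)})
    return conversion_rate(reads, scope="global", blacklist=bl, min_qual=cfg.min_qual)


def stage_snv(sam_path: str, genes_tsv: str, out_dir: str, cfg: PipelineConfig) -> SNVBlacklist:
    """Build the SNV blacklist from one library and write it as BED."""
    os.makedirs(out_dir, exist_ok=True)
    genes = skio.read_tsv(genes_tsv)
    strands = dict(zip(genes["gene_id"], genes["strand"]))
    tally = build_position_tally(
        skio.read_alignments(sam_path, gene_strands=strands), min_qual=cfg.min_qual
    )
    bl = call_snv_blacklist(tally, min_frac=cfg.snv_min_frac, min_cov=cfg.snv_min_cov)
    skio.write_blacklist_bed(bl, os.path.join(out_dir, "blacklist.bed"))
    _manifest(out_dir, "snv", cfg, {"n_blacklisted": len(bl.positions)})
    return bl


def stage_quant(
    sam_path: str,
    genes_tsv: str,
    out_dir: str,
    cfg: PipelineConfig,
    blacklist: SNVBlacklist | None = None,
    sample_id: str = "sample",
):
    """Classify molecules and write the labeled/unlabeled matrix pair.

    Reads sharing a (cell, umi, gene) key are grouped into one molecule;
    bulk reads (no cell/UMI tags) each count as one molecule of the given
    sample.
    """
    os.makedirs(out_dir, exist_ok=True)
    genes = skio.read_tsv(genes_tsv)
    strands = dict(zip(genes["gene_id"], genes["strand"]))
    bl = blacklist if blacklist is not None else SNVBlacklist()
    groups = defaultdict(list)
    for read in skio.read_alignments(sam_path, gene_strands=strands):
        if read.gene_id is None:
            continue
        key = (read.cell_barcode, read.umi, read.gene_id)
        groups[key].append(read)
    calls = []
    for (cell, umi, gene), reads in groups.items():
        if umi is None:  # bulk: every read is its own molecule
            for read in reads:
                c = classify_molecule([read], bl, min_qual=cfg.min_qual, k_min=cfg.k_min)
                if cell is None:
                    c.unit = sample_id
                calls.append(c)
        else:
            call = classify_molecule(reads, bl, min_qual=cfg.min_qual, k_min=cfg.k_min)
            if cell is None:
                call.unit = sample_id
            calls.append(call)
    m = build_matrices(calls)
    skio.write_matrices_mtx(m, out_dir, cfg.hash())
    frac = labeled_fraction(m, scope="global")
    skio.write_tsv(frac, os.path.join(out_dir, "labeled_fraction.tsv"), cfg.hash())
    _manifest(out_dir, "quant", cfg, {"n_molecules": int(m.total().to_numpy().sum())})
    return m


def stage_decay(ratios_tsv: str, out_dir: str, cfg: PipelineConfig) -> pd.DataFrame:
    """Fit per-gene decay kinetics from a (gene, time, replicate, labeled,
    unlabeled) table and write fits plus a summary."""
    os.makedirs(out_dir, exist_ok=True)
    counts = skio.read_tsv(ratios_tsv)
    total = counts["labeled"] + counts["unlabeled"]
    points = counts.assign(
        f_obs=counts["labeled"] / total.where(total > 0), n_molecules=total
    ).dropna(subset=["f_obs"])
    fits = fit_all_genes(points, tau_bounds=cfg.tau_bounds_h)
    skio.write_tsv(fits, os.path.join(out_dir, "decay_fits.tsv"), cfg.hash())
    summary = summarize_halflives(fits, r2_min=cfg.r2_min, tau_bounds=cfg.tau_bounds_h)
    summary_df = pd.DataFrame(
        {
            "n_genes": [summary["n_genes"]],
            "mean_tau_h": [summary["mean_tau_h"]],
            "median_tau_h": [summary["median_tau_h"]],
        }
    )
    skio.write_tsv(summary_df, os.path.join(out_dir, "halflife_summary.tsv"), cfg.hash())
    _manifest(out_dir, "decay", cfg, {"n_genes_pass": summary["n_genes"]})
    return fits


def stage_response(
    sham_dir: str,
    injured_dir: str,
    annotations_tsv: str,
    out_dir: str,
    cfg: PipelineConfig,
    cell_types: Sequence[str] | None = None,
    epsilon_hat: float = 0.0,
    nbar_t: float = 50.0,
) -> pd.DataFrame:
    """Injury-response tables per cell type from MTX matrix pairs.

    ``annotations_tsv`` columns: barcode, cell_type, condition.
    """
    os.makedirs(out_dir, exist_ok=True)
    sham = skio.read_matrices_mtx(sham_dir)
    injured = skio.read_matrices_mtx(injured_dir)
    ann = skio.read_tsv(annotations_tsv)
    sham_ann = ann[ann["condition"] == "sham"].set_index("barcode")["cell_type"]
    inj_ann = ann[ann["condition"] == "injured"].set_index("barcode")["cell_type"]
    pair = ConditionPair(sham, injured, sham_ann, inj_ann)
    from .injury import BackgroundModel

    bg = BackgroundModel(epsilon_hat=epsilon_hat, nbar_t=nbar_t)
    cts = cell_types if cell_types else sorted(sham_ann.unique())
    tables = []
    for ct in cts:
        tables.append(
            injury_response(
                pair, bg, cell_type=ct, pi=cfg.pi, n_perm=cfg.n_perm, seed=cfg.seed
            )
        )
    result = pd.concat(tables, ignore_index=True)
    skio.write_tsv(result, os.path.join(out_dir, "injury_response.tsv"), cfg.hash())
    ranked = result[result["tested"]].sort_values("log2_r", ascending=False)
    skio.write_tsv(
        ranked[["gene_id", "cell_type", "log2_r", "p_perm", "q"]],
        os.path.join(out_dir, "ranked_genes.tsv"),
        cfg.hash(),
    )
    _manifest(out_dir, "response", cfg, {"n_tested": int(result["tested"].sum())})
    return result
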