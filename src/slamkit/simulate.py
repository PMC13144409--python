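"""Ground-truth-bearing synthetic data for every pipeline stage.

Two generators:

* :func:`simulate_bulk_timecourse` — read-level bulk SLAM-seq time course.
  Genes live on one synthetic contig with known strand and reference
  sequence; per timepoint, steady-state molecule counts are Poisson with
  mean k_g / lambda_g, each molecule is labeled with probability
  1 - exp(-lambda_g * t) (optionally damped by 4sU exhaustion), and each
  molecule emits one aligned read in which transcript-sense thymines convert
  to C with probability p_c (labeled) or epsilon (unlabeled).  A uniform
  per-substitution-type sequencing error epsilon applies to all bases, so
  the background is estimable from the non-T>C spectrum.  Optional SNV
  positions show conversions in every read regardless of labeling.

* :func:`simulate_sc_injury` — molecule-level paired sham/injured
  single-cell labeled/unlabeled UMI matrices over multiple cell types, with
  a known injury-induced gene set (transcription fold F during the labeling
  window), individually varying pre-existing unlabeled pools, detection
  thinning by the conversion false-negative rate and false labeling by the
  error background.

All randomness flows through one ``numpy.random.Generator`` per simulation,
constructed from the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .conversions import AlignedReadRecord
from .quantify import LabeledMatrices

LN2 = float(np.log(2.0))
_NON_SENSE = {"+": "ACG", "-": "CGT"}  # non-T alphabet per strand (transcript sense)
_BASES = "ACGT"


@dataclass
class BulkSimConfig:
    """Study conditions for the read-level bulk time course.

    Defaults reflect a labeling experiment in adult heart tissue: single 4sU
    injection, triplicate sampling over 0.5-12 h, per-thymine conversion
    probability 0.037 in labeled molecules over a ~50-thymine read, and a
    low uniform sequencing-error floor.
    """

    n_genes: int = 50
    timepoints_h: tuple[float, ...] = (0.5, 1.0, 3.0, 6.0, 12.0)
    replicates: int = 3
    tau_range_h: tuple[float, float] = (0.5, 48.0)  # log-uniform per gene
    mean_molecules: float = 100.0  # steady-state molecules per gene per sample
    p_c: float = 0.037
    epsilon: float = 0.0002  # per substitution type
    read_len: int = 100
    nbar_t: float = 50.0
    gene_len: int = 500
    base_qual: int = 37
    fourSU_halflife_h: float | None = None  # exhaustion off by default
    n_snv: int = 0
    seed: int = 0

    def validate(self) -> "BulkSimConfig":
        if self.n_genes < 1 or self.mean_molecules <= 0:
            raise ValueError("n_genes and mean_molecules must be positive")
        if not (0 <= self.epsilon <= self.p_c <= 1):
            raise ValueError("need 0 <= epsilon <= p_c <= 1")
        if not (0 < self.nbar_t <= self.read_len):
            raise ValueError("nbar_t must be in (0, read_len]")
        if self.read_len > self.gene_len:
            raise ValueError("read_len must not exceed gene_len")
        if any(t < 0 for t in self.timepoints_h):
            raise ValueError("timepoints must be >= 0")
        return self


@dataclass
class SimTruth:
    """Ground truth serialized alongside simulated outputs."""

    genes: pd.DataFrame  # gene_id, strand, start, end, tau_h, k_per_h
    molecules: pd.DataFrame  # read/molecule-level labels
    snv_positions: tuple[int, ...] = ()
    induced: pd.DataFrame | None = None  # sc only: gene_id, fold
    seed: int = 0


@dataclass
class BulkSimResult:
    reads: list[AlignedReadRecord]
    truth: SimTruth
    reference: dict[str, str]
    config: BulkSimConfig = field(repr=False, default=None)


def effective_labeling_time(t: float, fourSU_halflife_h: float | None) -> float:
    """Integrated 4sU availability up to time t.

    With exhaustion, availability decays as a(s) = 2^(-s / h); the labeling
    probability becomes 1 - exp(-lambda * T_eff) with
    T_eff = (1 - e^(-mu t)) / mu, mu = ln2 / h.  Without exhaustion
    T_eff = t.
    """
    if fourSU_halflife_h is None:
        return t
    mu = LN2 / fourSU_halflife_h
    return float(-np.expm1(-mu * t) / mu)


def _gene_reference(rng: np.random.Generator, cfg: BulkSimConfig, strand: str) -> str:
    """Reference sequence with transcript-sense T density nbar_t / read_len.

    The T count per gene is fixed at its nominal value (random placement), so
    the mean thymines-per-read condition holds exactly rather than drifting
    with per-gene composition noise.
    """
    n_t = int(round(cfg.gene_len * cfg.nbar_t / cfg.read_len))
    sense_t = "T" if strand == "+" else "A"
    t_sites = set(rng.choice(cfg.gene_len, size=n_t, replace=False).tolist())
    others = rng.integers(0, 3, size=cfg.gene_len)
    alphabet = _NON_SENSE[strand]
    return "".join(
        sense_t if i in t_sites else alphabet[others[i]] for i in range(cfg.gene_len)
    )


def simulate_bulk_timecourse(config: BulkSimConfig) -> BulkSimResult:
    """Simulate the bulk labeling time course at read level."""
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)

    strands = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    taus = np.exp(rng.uniform(np.log(cfg.tau_range_h[0]), np.log(cfg.tau_range_h[1]), cfg.n_genes))
    lams = LN2 / taus
    ks = lams * cfg.mean_molecules  # so steady-state count k/lambda = mean_molecules

    gene_rows = []
    refs = []
    for g in range(cfg.n_genes):
        start = g * cfg.gene_len
        refs.append(_gene_reference(rng, cfg, strands[g]))
        gene_rows.append(
            (f"gene{g:04d}", strands[g], start, start + cfg.gene_len, taus[g], ks[g])
        )
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "strand", "start", "end", "tau_h", "k_per_h"]
    )
    contig_seq = "".join(refs)

    snv_positions: list[int] = []
    if cfg.n_snv > 0:
        sense_sites = [
            i
            for i, b in enumerate(contig_seq)
            if b == ("T" if strands[i // cfg.gene_len] == "+" else "A")
        ]
        snv_positions = sorted(
            rng.choice(sense_sites, size=min(cfg.n_snv, len(sense_sites)), replace=False).tolist()
        )
    snv_set = set(snv_positions)

    reads: list[AlignedReadRecord] = []
    mol_rows = []
    read_counter = 0
    for t in cfg.timepoints_h:
        t_eff = effective_labeling_time(t, cfg.fourSU_halflife_h)
        p_lab = -np.expm1(-lams * t_eff)
        for rep in range(1, cfg.replicates + 1):
            n_mol = rng.poisson(cfg.mean_molecules, size=cfg.n_genes)
            for g in range(cfg.n_genes):
                gene_id, strand = genes.at[g, "gene_id"], strands[g]
                gstart = g * cfg.gene_len
                ref = refs[g]
                labeled_flags = rng.random(n_mol[g]) < p_lab[g]
                starts = rng.integers(0, cfg.gene_len - cfg.read_len + 1, size=n_mol[g])
                for labeled, s in zip(labeled_flags, starts):
                    read_id = f"r{read_counter:08d}"
                    read_counter += 1
                    reads.append(
                        _emit_read(
                            rng, cfg, read_id, gene_id, strand, gstart, ref, int(s),
                            bool(labeled), snv_set,
                        )
                    )
                    mol_rows.append((read_id, gene_id, float(t), rep, bool(labeled)))

    molecules = pd.DataFrame(
        mol_rows, columns=["read_id", "gene_id", "time_h", "replicate", "labeled"]
    )
    truth = SimTruth(
        genes=genes, molecules=molecules, snv_positions=tuple(snv_positions), seed=cfg.seed
    )
    return BulkSimResult(reads=reads, truth=truth, reference={"chrS": contig_seq}, config=cfg)


def _emit_read(
    rng: np.random.Generator,
    cfg: BulkSimConfig,
    read_id: str,
    gene_id: str,
    strand: str,
    gene_start: int,
    gene_ref: str,
    offset: int,
    labeled: bool,
    snv_set: set[int],
) -> AlignedReadRecord:
    ref_seg = gene_ref[offset : offset + cfg.read_len]
    positions = list(range(gene_start + offset, gene_start + offset + cfg.read_len))
    sense_t = "T" if strand == "+" else "A"
    sense_c = "C" if strand == "+" else "G"
    p_conv = cfg.p_c if labeled else cfg.epsilon

    read_bases = list(ref_seg)
    u = rng.random(cfg.read_len)
    # uniform per-type sequencing error at every base (3 alternatives each)
    err = u < 3 * cfg.epsilon
    err_choice = rng.integers(0, 3, size=cfg.read_len)
    # labeling conversions only at transcript-sense T positions
    u2 = rng.random(cfg.read_len)
    for i, rb in enumerate(ref_seg):
        pos = gene_start + offset + i
        if rb == sense_t and pos in snv_set:
            read_bases[i] = sense_c
        elif rb == sense_t and labeled and u2[i] < p_conv:
            read_bases[i] = sense_c
        elif err[i]:
            alts = [b for b in _BASES if b != rb]
            read_bases[i] = alts[err_choice[i]]
    return AlignedReadRecord(
        read_id=read_id,
        ref_positions=positions,
        ref_bases=ref_seg,
        read_bases="".join(read_bases),
        base_quals=[cfg.base_qual] * cfg.read_len,
        gene_id=gene_id,
        genome_strand_of_gene=strand,
    )


# ---------------------------------------------------------------------------
# matrix-level time-course counts (for kinetics recovery at scale)

def simulate_timecourse_counts(
    taus_h: Sequence[float],
    timepoints_h: Sequence[float] = (0.5, 1.0, 3.0, 6.0, 12.0),
    replicates: int = 3,
    n_molecules: int = 500,
    alpha: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Binomially sampled labeled/unlabeled counts straight from the kinetics.

    For each gene with half-life tau, each of ``n_molecules`` molecules per
    timepoint per replicate is labeled with probability
    alpha * (1 - e^(-t ln2 / tau)).  Returns a long table (gene_id, time_h,
    replicate, labeled, unlabeled) ready for ratio computation and fitting.
    """
    rng = np.random.default_rng(seed)
    taus = np.asarray(taus_h, dtype=float)
    rows = []
    for t in timepoints_h:
        p = alpha * -np.expm1(-LN2 * t / taus)
        for rep in range(1, replicates + 1):
            lab = rng.binomial(n_molecules, p)
            for g, nl in enumerate(lab):
                rows.append((f"gene{g:04d}", float(t), str(rep), int(nl), n_molecules - int(nl)))
    return pd.DataFrame(rows, columns=["gene_id", "time_h", "replicate", "labeled", "unlabeled"])


# ---------------------------------------------------------------------------
# paired sham/injured single-cell simulation

@dataclass
class InjurySimConfig:
    """Study conditions for the paired sham/injured single-cell experiment.

    Both conditions share a ~7 h labeling window (4sU injected 1 h before
    sham or cryoinjury, sampling 6 h later).  Injury multiplies the
    transcription of induced genes by ``fold`` during the labeling window in
    the injured condition only.  Pre-existing (unlabeled) pools are drawn
    with condition-specific scale factors so that statistics claiming
    independence from the old-RNA pool are exercised, not assumed.
    """

    n_genes: int = 500
    cell_types: tuple[str, ...] = ("macrophage", "endothelial", "cardiomyocyte")
    n_cells_per_type: int = 100  # per condition
    labeling_time_h: float = 7.0
    tau_range_h: tuple[float, float] = (0.5, 48.0)
    mean_expression: float = 5.0  # mean total molecules per gene per cell
    n_induced: int = 25
    fold: float = 4.0
    induced_cell_types: tuple[str, ...] | None = ("macrophage",)  # None = all
    p_c: float = 0.037
    nbar_t: float = 50.0
    epsilon: float = 0.0002
    unlabeled_scale: dict = field(default_factory=lambda: {"sham": 1.0, "injured": 1.0})
    seed: int = 0

    def validate(self) -> "InjurySimConfig":
        if len(self.cell_types) < 2:
            raise ValueError("need >= 2 cell types")
        if self.n_induced < 0 or self.n_induced > self.n_genes:
            raise ValueError("n_induced out of range")
        if self.fold <= 0:
            raise ValueError("fold must be > 0")
        if not (0 <= self.epsilon <= self.p_c <= 1):
            raise ValueError("need 0 <= epsilon <= p_c <= 1")
        return self


@dataclass
class InjurySimResult:
    sham: LabeledMatrices
    injured: LabeledMatrices
    sham_cell_types: pd.Series
    injured_cell_types: pd.Series
    truth: SimTruth
    config: InjurySimConfig = field(repr=False, default=None)


def _truncated_poisson_detect(p: float, nbar_t: float) -> float:
    """E[1 - (1-p)^N] for N ~ Poisson(nbar_t) truncated at >= 1."""
    if p <= 0:
        return 0.0
    # E[(1-p)^N | N>=1] = (e^(-nbar p') - e^(-nbar)) / (1 - e^(-nbar)), p' via pgf
    e_full = np.exp(-nbar_t * p)  # Poisson pgf at (1-p)
    e0 = np.exp(-nbar_t)
    return float(1.0 - (e_full - e0) / (1.0 - e0))


def simulate_sc_injury(config: InjurySimConfig) -> InjurySimResult:
    """Simulate paired sham/injured labeled+unlabeled UMI matrices."""
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes
    gene_ids = [f"gene{g:04d}" for g in range(G)]

    taus = np.exp(rng.uniform(np.log(cfg.tau_range_h[0]), np.log(cfg.tau_range_h[1]), G))
    f_lab = -np.expm1(-LN2 * cfg.labeling_time_h / taus)

    # per-cell-type baseline expression from steady state: abundance = k * tau
    # (up to ln2), with gamma-distributed transcription rates k.  Long-lived
    # transcripts therefore dominate the pre-existing pool, which keeps the
    # emergent labeled fraction at a short labeling window realistically low.
    base = {}
    for ct in cfg.cell_types:
        k = rng.gamma(shape=2.0, scale=1.0, size=G)
        abundance = k * taus
        base[ct] = abundance * (cfg.mean_expression / abundance.mean())
    induced_idx = rng.choice(G, size=cfg.n_induced, replace=False) if cfg.n_induced else np.array([], dtype=int)
    fold_vec = np.ones(G)
    fold_vec[induced_idx] = cfg.fold

    p_detect = _truncated_poisson_detect(cfg.p_c, cfg.nbar_t)
    p_false = _truncated_poisson_detect(cfg.epsilon, cfg.nbar_t)

    matrices = {}
    annotations = {}
    for cond in ("sham", "injured"):
        scale_old = cfg.unlabeled_scale.get(cond, 1.0)
        cols = []
        lab_blocks, unl_blocks, ct_labels = [], [], []
        for ct in cfg.cell_types:
            n_cells = cfg.n_cells_per_type
            mean_new = np.outer(base[ct] * f_lab, np.ones(n_cells))
            if cond == "injured" and (
                cfg.induced_cell_types is None or ct in cfg.induced_cell_types
            ):
                mean_new = mean_new * fold_vec[:, None]
            mean_old = np.outer(base[ct] * (1.0 - f_lab) * scale_old, np.ones(n_cells))
            true_new = rng.poisson(mean_new)
            true_old = rng.poisson(mean_old)
            # detection thinning and error-driven false labeling
            obs_lab_from_new = rng.binomial(true_new, p_detect)
            obs_lab_from_old = rng.binomial(true_old, p_false)
            lab = obs_lab_from_new + obs_lab_from_old
            unl = (true_new - obs_lab_from_new) + (true_old - obs_lab_from_old)
            lab_blocks.append(lab)
            unl_blocks.append(unl)
            prefix = "S" if cond == "sham" else "I"
            cols += [f"{prefix}_{ct[:4]}_{i:04d}" for i in range(n_cells)]
            ct_labels += [ct] * n_cells
        gene_index = pd.Index(gene_ids, name="gene")
        col_index = pd.Index(cols, name="unit")
        matrices[cond] = LabeledMatrices(
            pd.DataFrame(np.concatenate(lab_blocks, axis=1), index=gene_index, columns=col_index),
            pd.DataFrame(np.concatenate(unl_blocks, axis=1), index=gene_index, columns=col_index),
        )
        annotations[cond] = pd.Series(ct_labels, index=col_index, name="cell_type")

    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "tau_h": taus,
            "labeled_fraction_true": f_lab,
        }
    )
    induced = pd.DataFrame(
        {"gene_id": [gene_ids[i] for i in induced_idx], "fold": cfg.fold}
    )
    truth = SimTruth(
        genes=genes,
        molecules=pd.DataFrame(),
        induced=induced,
        seed=cfg.seed,
    )
    return InjurySimResult(
        sham=matrices["sham"],
        injured=matrices["injured"],
        sham_cell_types=annotations["sham"],
        injured_cell_types=annotations["injured"],
        truth=truth,
        config=cfg,
    )
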