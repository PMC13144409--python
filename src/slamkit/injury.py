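"""Background-corrected injury-response statistic from paired labeled matrices.

The design: sham and injured animals receive identical 4sU injections and
identical labeling windows, so for a gene whose decay rate is unchanged by
injury, the ratio of (normalized, background-corrected) labeled RNA in the
injured sample over the sham sample directly measures the change in
transcription after injury — independent of the pre-existing unlabeled pool
and of decay rates.

The background model accounts for unlabeled molecules miscalled labeled by
sequencing/chemistry errors: the per-thymine error-conversion probability
epsilon is estimated from the 11 non-(T>C) substitution rates, and the
expected falsely-labeled count U * (1 - (1 - epsilon)^n_t) is subtracted from
each pseudo-bulk labeled count before the ratio.  Significance is empirical:
condition labels are permuted across cells and the ratio recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .quantify import LabeledMatrices

TC_LABEL = "T>C"


class ConfigError(ValueError):
    pass


@dataclass
class ConditionPair:
    """Paired sham/injured matrices with per-cell cell-type annotations."""

    sham: LabeledMatrices
    injured: LabeledMatrices
    sham_cell_types: pd.Series  # index: cell barcode -> cell type
    injured_cell_types: pd.Series
    labeling_time_h: float = 7.0

    def __post_init__(self):
        if not self.sham.genes.equals(self.injured.genes):
            raise ValueError("sham and injured matrices must share the gene index")
        for m, ann, name in (
            (self.sham, self.sham_cell_types, "sham"),
            (self.injured, self.injured_cell_types, "injured"),
        ):
            missing = m.units.difference(ann.index)
            if len(missing):
                raise ValueError(f"{name}: {len(missing)} cells lack a cell-type annotation")

    def cells_of(self, condition: str, cell_type: str) -> list[str]:
        ann = self.sham_cell_types if condition == "sham" else self.injured_cell_types
        m = self.sham if condition == "sham" else self.injured
        return [c for c in m.units if ann[c] == cell_type]


@dataclass
class BackgroundModel:
    """Error-driven false-labeling model.

    ``epsilon_hat`` is the per-thymine background conversion probability
    (median of the non-T>C substitution rates); ``nbar_t`` the mean thymines
    per molecule read.  ``p_false`` is the chance an unlabeled molecule shows
    >= 1 error conversion and is miscalled labeled.
    """

    epsilon_hat: float
    nbar_t: float = 50.0

    def __post_init__(self):
        if not 0.0 <= self.epsilon_hat <= 0.05:
            raise ValueError(f"epsilon_hat outside [0, 0.05]: {self.epsilon_hat}")

    @property
    def p_false(self) -> float:
        return float(1.0 - (1.0 - self.epsilon_hat) ** self.nbar_t)

    def expected_false_labeled(self, unlabeled_counts: np.ndarray) -> np.ndarray:
        return np.asarray(unlabeled_counts, dtype=float) * self.p_false


ZERO_BACKGROUND = BackgroundModel(epsilon_hat=0.0)


def estimate_background(spectrum: pd.DataFrame, nbar_t: float = 50.0) -> BackgroundModel:
    """Estimate the background model from a substitution spectrum.

    ``spectrum`` is the 12-row table from
    :func:`slamkit.conversions.substitution_spectrum`.  T>C carries the
    labeling signal, so epsilon is the median rate of the other 11
    substitution types (transcript sense).
    """
    others = spectrum.drop(index=TC_LABEL)
    informative = others[others["n_sites"] > 0]
    if informative.empty:
        raise ValueError("no non-T>C sites observed; background not estimable")
    rates = informative["n_events"] / informative["n_sites"]
    return BackgroundModel(epsilon_hat=float(rates.median()), nbar_t=nbar_t)


def _corrected_pseudobulk(
    labeled: np.ndarray, unlabeled: np.ndarray, bg: BackgroundModel
) -> np.ndarray:
    """Background-subtracted pseudo-bulk labeled counts, floored at zero."""
    corrected = labeled.astype(float) - bg.expected_false_labeled(unlabeled)
    return np.maximum(corrected, 0.0)


def _normalized_labeled(corrected: np.ndarray, pi: float) -> np.ndarray:
    """Depth-normalized labeled expression with a pseudocount.

    Counts are scaled to counts-per-ten-thousand of the cell type's corrected
    labeled library, then offset by the pseudocount.  Applying the pseudocount
    on the normalized scale (rather than to raw counts) makes the statistic
    exactly invariant to global labeled library-size scaling.
    """
    lib = corrected.sum()
    if lib <= 0:
        raise ValueError("corrected labeled library size is zero")
    return 1e4 * corrected / lib + pi


def injury_response(
    pair: ConditionPair,
    bg: BackgroundModel = ZERO_BACKGROUND,
    cell_type: str | None = None,
    pi: float = 1.0,
    min_count: float = 5.0,
    min_cells: int = 2,
    n_perm: int = 1000,
    seed: int | None = 0,
    fdr_alpha: float = 0.05,
    log2r_min: float = 1.0,
) -> pd.DataFrame:
    """Per-gene injury-response table for one cell type.

    For each condition, labeled counts are pseudo-bulked over the cell type's
    cells, background-subtracted, normalized and pseudocounted; the response
    ratio is R = l_hat_injured / l_hat_sham.  Genes whose summed corrected
    labeled counts fall below ``min_count`` are reported with tested=False
    (never silently dropped).  When ``n_perm`` > 0, an empirical permutation
    p-value and BH-adjusted q are attached, and ``responsive`` flags genes
    with q < fdr_alpha and log2 R > log2r_min.
    """
    if pi < 0:
        raise ConfigError(f"pseudocount must be >= 0, got {pi}")
    sham_cells = pair.cells_of("sham", cell_type) if cell_type else list(pair.sham.units)
    inj_cells = pair.cells_of("injured", cell_type) if cell_type else list(pair.injured.units)
    if len(sham_cells) == 0 or len(inj_cells) == 0:
        raise ValueError(f"cell type {cell_type!r} absent in one condition")
    if len(sham_cells) < min_cells or len(inj_cells) < min_cells:
        raise ValueError(
            f"cell type {cell_type!r} has fewer than {min_cells} cells in a condition"
        )

    genes = pair.sham.genes
    L_s = pair.sham.labeled[sham_cells].to_numpy(dtype=float)
    U_s = pair.sham.unlabeled[sham_cells].to_numpy(dtype=float)
    L_i = pair.injured.labeled[inj_cells].to_numpy(dtype=float)
    U_i = pair.injured.unlabeled[inj_cells].to_numpy(dtype=float)

    c_s = _corrected_pseudobulk(L_s.sum(axis=1), U_s.sum(axis=1), bg)
    c_i = _corrected_pseudobulk(L_i.sum(axis=1), U_i.sum(axis=1), bg)
    lhat_s = _normalized_labeled(c_s, pi)
    lhat_i = _normalized_labeled(c_i, pi)
    R = lhat_i / lhat_s
    tested = (c_s + c_i) >= min_count

    out = pd.DataFrame(
        {
            "gene_id": genes,
            "cell_type": cell_type if cell_type else "all",
            "l_hat_sham": lhat_s,
            "l_hat_inj": lhat_i,
            "response_ratio": R,
            "log2_r": np.log2(R),
            "tested": tested,
            "pi": pi,
        }
    )

    if n_perm > 0:
        pvals = permutation_test(
            pair, cell_type=cell_type, bg=bg, pi=pi, n_perm=n_perm, seed=seed
        )
        out["p_perm"] = pvals
        q = np.full(len(out), np.nan)
        if tested.any():
            q[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
        out["q"] = q
        out["responsive"] = tested & (out["q"] < fdr_alpha) & (out["log2_r"] > log2r_min)
    return out


def permutation_test(
    pair: ConditionPair,
    cell_type: str | None,
    bg: BackgroundModel = ZERO_BACKGROUND,
    pi: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = 0,
    exhaustive: bool = False,
) -> np.ndarray:
    """Empirical per-gene p-values for |log2 R| by condition-label permutation.

    Cells of the cell type are pooled across conditions; each permutation
    reassigns condition labels (preserving group sizes) and recomputes the
    full statistic, background correction included.  p = (1 + #{|log2
    R_null| >= |log2 R_obs|}) / (1 + n_perm).  With ``exhaustive=True`` all
    distinct assignments are enumerated instead (small groups only) and
    p = #{} / #assignments, observed assignment included.
    """
    if not exhaustive and n_perm < 10:
        raise ConfigError(f"n_perm must be >= 10, got {n_perm}")
    sham_cells = pair.cells_of("sham", cell_type) if cell_type else list(pair.sham.units)
    inj_cells = pair.cells_of("injured", cell_type) if cell_type else list(pair.injured.units)
    if len(sham_cells) < 2 or len(inj_cells) < 2:
        raise ValueError("need >= 2 cells per condition for the permutation test")

    L = np.concatenate(
        [
            pair.sham.labeled[sham_cells].to_numpy(dtype=float),
            pair.injured.labeled[inj_cells].to_numpy(dtype=float),
        ],
        axis=1,
    )
    U = np.concatenate(
        [
            pair.sham.unlabeled[sham_cells].to_numpy(dtype=float),
            pair.injured.unlabeled[inj_cells].to_numpy(dtype=float),
        ],
        axis=1,
    )
    n_s = len(sham_cells)
    n_cells = L.shape[1]

    def log2_ratio(sham_mask: np.ndarray) -> np.ndarray:
        c_s = _corrected_pseudobulk(L[:, sham_mask].sum(axis=1), U[:, sham_mask].sum(axis=1), bg)
        c_i = _corrected_pseudobulk(
            L[:, ~sham_mask].sum(axis=1), U[:, ~sham_mask].sum(axis=1), bg
        )
        return np.log2(_normalized_labeled(c_i, pi)) - np.log2(_normalized_labeled(c_s, pi))

    obs_mask = np.zeros(n_cells, dtype=bool)
    obs_mask[:n_s] = True
    obs = np.abs(log2_ratio(obs_mask))

    if exhaustive:
        from itertools import combinations

        count = np.zeros_like(obs)
        total = 0
        for idx in combinations(range(n_cells), n_s):
            mask = np.zeros(n_cells, dtype=bool)
            mask[list(idx)] = True
            count += np.abs(log2_ratio(mask)) >= obs - 1e-12
            total += 1
        return count / total

    # Monte-Carlo permutations, batched as matrix products: for a batch of
    # permutation indicator columns M, pseudo-bulk sums are L @ M and the
    # complement totals follow by subtraction.
    rng = np.random.default_rng(seed)
    Lsum = L.sum(axis=1, keepdims=True)
    Usum = U.sum(axis=1, keepdims=True)
    p_false = bg.p_false
    count = np.zeros_like(obs)
    batch = 200
    for start in range(0, n_perm, batch):
        b = min(batch, n_perm - start)
        M = np.zeros((n_cells, b))
        for j in range(b):
            M[rng.permutation(n_cells)[:n_s], j] = 1.0
        Ls, Us = L @ M, U @ M
        c_s = np.maximum(Ls - p_false * Us, 0.0)
        c_i = np.maximum((Lsum - Ls) - p_false * (Usum - Us), 0.0)
        lhat_s = 1e4 * c_s / c_s.sum(axis=0, keepdims=True) + pi
        lhat_i = 1e4 * c_i / c_i.sum(axis=0, keepdims=True) + pi
        null_abs = np.abs(np.log2(lhat_i) - np.log2(lhat_s))
        count += (null_abs >= obs[:, None] - 1e-12).sum(axis=1)
    return (1.0 + count) / (1.0 + n_perm)


@dataclass
class GeneSetLayer:
    """A named gene set representing one layer of a signaling pathway."""

    name: str
    gene_ids: tuple[str, ...]
    layer: str = "receptors"

    def __post_init__(self):
        if not self.gene_ids:
            raise ValueError(f"gene set {self.name!r} is empty")
        if self.layer not in ("receptors", "adaptors", "effectors"):
            raise ValueError(f"unknown layer {self.layer!r}")


def pathway_layer_score(
    matrix: pd.DataFrame,
    layer: GeneSetLayer,
    groups: pd.Series | Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-group mean +/- SEM of the per-cell percent of counts in a gene set.

    ``matrix`` is gene x cell counts.  Per cell the score is
    100 * (counts in layer genes) / (total counts); cells with zero total are
    excluded with a warning.  Returns a DataFrame with columns group, n_cells,
    mean_percent, sem_percent.
    """
    import warnings

    present = [g for g in layer.gene_ids if g in matrix.index]
    missing = set(layer.gene_ids) - set(present)
    if missing:
        warnings.warn(
            f"{len(missing)} of {len(layer.gene_ids)} genes of {layer.name!r} not in matrix",
            stacklevel=2,
        )
    if not present:
        raise ValueError(f"no genes of {layer.name!r} present in the matrix")
    totals = matrix.sum(axis=0)
    nonzero = totals > 0
    if (~nonzero).any():
        warnings.warn(f"excluding {(~nonzero).sum()} cells with zero total counts", stacklevel=2)
    pct = 100.0 * matrix.loc[present, nonzero].sum(axis=0) / totals[nonzero]
    if groups is None:
        grp = pd.Series("all", index=pct.index)
    else:
        grp = pd.Series(groups).reindex(pct.index)
    df = pd.DataFrame({"percent": pct, "group": grp})
    agg = df.groupby("group")["percent"].agg(
        n_cells="size", mean_percent="mean", sem_percent="sem"
    )
    return agg.reset_index()
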