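"""Molecule-level labeling calls, labeled/unlabeled count matrices, and the
conversion-detection model.

A molecule (a UMI in single-cell data, a read in bulk data) is called
*labeled* when it shows at least ``k_min`` distinct quality-passing
transcript-sense T-to-C conversions.  Because a labeled molecule with few
thymines can show zero conversions by chance, detection is imperfect; the
:class:`DetectionModel` quantifies that false-negative rate, and
:func:`estimate_pc_zero_truncated` recovers the per-thymine conversion
probability from labeled-called molecules (which are conditioned on >= k_min
conversions, hence zero-truncated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .conversions import AlignedReadRecord, SNVBlacklist, EMPTY_BLACKLIST, count_tc


@dataclass
class MoleculeCall:
    """Labeling call for one (cell, umi, gene) molecule (or one bulk read)."""

    gene_id: str
    unit: str  # cell barcode (single-cell) or sample id (bulk)
    molecule_id: str  # UMI or read id
    n_tc_distinct: int
    n_t_covered: int
    labeled: bool


@dataclass
class LabeledMatrices:
    """Paired labeled and unlabeled gene x unit count matrices.

    ``labeled + unlabeled`` equals total molecule counts entrywise; the gene
    and unit indexes are shared.  Units are cell barcodes (single-cell) or
    sample ids (bulk).
    """

    labeled: pd.DataFrame
    unlabeled: pd.DataFrame

    def __post_init__(self):
        if not self.labeled.index.equals(self.unlabeled.index) or not self.labeled.columns.equals(
            self.unlabeled.columns
        ):
            raise ValueError("labeled and unlabeled matrices must share gene and unit indexes")
        if (self.labeled.to_numpy() < 0).any() or (self.unlabeled.to_numpy() < 0).any():
            raise ValueError("count matrices must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.labeled.index

    @property
    def units(self) -> pd.Index:
        return self.labeled.columns

    def total(self) -> pd.DataFrame:
        return self.labeled + self.unlabeled

    def subset_units(self, units: Sequence[str]) -> "LabeledMatrices":
        return LabeledMatrices(self.labeled[list(units)], self.unlabeled[list(units)])


@dataclass
class DetectionModel:
    """Per-thymine conversion model for labeled-molecule detection.

    ``p_c`` is the per-thymine conversion probability in a labeled molecule,
    ``epsilon`` the background per-thymine error-conversion probability, and
    ``n_t`` the thymine count per molecule read: either a fixed integer or a
    ``(values, weights)`` distribution.
    """

    p_c: float
    n_t: int | tuple[Sequence[int], Sequence[float]] = 50
    epsilon: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.p_c <= 1.0:
            raise ValueError(f"p_c must be in [0, 1], got {self.p_c}")
        if not 0.0 <= self.epsilon <= self.p_c:
            raise ValueError(
                f"epsilon must satisfy 0 <= epsilon <= p_c, got {self.epsilon} vs {self.p_c}"
            )


def classify_molecule(
    reads: Sequence[AlignedReadRecord],
    blacklist: SNVBlacklist = EMPTY_BLACKLIST,
    min_qual: int = 20,
    k_min: int = 1,
) -> MoleculeCall:
    """Call one molecule labeled/unlabeled from all of its reads.

    All reads must share the same (cell_barcode, umi, gene_id) key.  The
    molecule's conversion evidence is the union of distinct converted genomic
    positions across its reads — reads sample the same underlying molecule.
    """
    if not reads:
        raise ValueError("classify_molecule requires at least one read")
    keys = {(r.cell_barcode, r.umi, r.gene_id) for r in reads}
    if len(keys) > 1:
        raise ValueError(f"reads span multiple (cell, umi, gene) keys: {sorted(map(str, keys))}")
    cell, umi, gene = next(iter(keys))
    converted: set[int] = set()
    n_t_total = 0
    for read in reads:
        call = count_tc(read, blacklist, min_qual)
        converted.update(call.converted_positions)
        n_t_total += call.n_t_covered
    n_distinct = len(converted)
    return MoleculeCall(
        gene_id=gene if gene is not None else "",
        unit=cell if cell is not None else "",
        molecule_id=umi if umi is not None else reads[0].read_id,
        n_tc_distinct=n_distinct,
        n_t_covered=n_t_total,
        labeled=n_distinct >= k_min,
    )


def build_matrices(calls: Iterable[MoleculeCall]) -> LabeledMatrices:
    """Accumulate molecule calls into paired labeled/unlabeled count matrices.

    Calls must be deduplicated per (unit, molecule, gene) upstream; a
    duplicate key raises.  Gene and unit orderings are sorted, so the result
    is independent of input order.
    """
    seen: set[tuple[str, str, str]] = set()
    counts: dict[tuple[str, str], list[int]] = {}
    for call in calls:
        key = (call.unit, call.molecule_id, call.gene_id)
        if key in seen:
            raise ValueError(f"duplicate molecule key {key}; deduplicate upstream")
        seen.add(key)
        slot = counts.setdefault((call.gene_id, call.unit), [0, 0])
        slot[0 if call.labeled else 1] += 1
    if not counts:
        empty = pd.DataFrame(dtype=np.int64)
        return LabeledMatrices(empty, empty.copy())
    genes = sorted({g for g, _ in counts})
    units = sorted({u for _, u in counts})
    lab = pd.DataFrame(0, index=pd.Index(genes, name="gene"), columns=pd.Index(units, name="unit"), dtype=np.int64)
    unl = lab.copy()
    for (g, u), (nl, nu) in counts.items():
        lab.loc[g, u] = nl
        unl.loc[g, u] = nu
    return LabeledMatrices(lab, unl)


def labeled_fraction(m: LabeledMatrices, scope: str = "global") -> pd.DataFrame:
    """Fraction of molecules labeled, globally or per unit / per gene.

    Groups with zero total molecules are reported missing (NaN), never 0.
    Returns a DataFrame with columns group, labeled, total, fraction.
    """
    lab, tot = m.labeled, m.total()
    if scope == "global":
        groups = pd.DataFrame(
            {"labeled": [lab.to_numpy().sum()], "total": [tot.to_numpy().sum()]},
            index=pd.Index(["all"], name="group"),
        )
    elif scope == "per_unit":
        groups = pd.DataFrame({"labeled": lab.sum(axis=0), "total": tot.sum(axis=0)})
        groups.index.name = "group"
    elif scope == "per_gene":
        groups = pd.DataFrame({"labeled": lab.sum(axis=1), "total": tot.sum(axis=1)})
        groups.index.name = "group"
    else:
        raise ValueError(f"unknown scope {scope!r}")
    total = groups["total"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        groups["fraction"] = np.where(total > 0, groups["labeled"] / total, np.nan)
    return groups.reset_index()


def detection_probability(model: DetectionModel, k_min: int = 1) -> tuple[float, float]:
    """Probability that a truly labeled molecule is detected, and the FNR.

    For a fixed thymine count n_t, detection requires >= k_min binomial
    conversions: p_detect = P[Binom(n_t, p_c) >= k_min]; for k_min = 1 this
    is 1 - (1 - p_c)^n_t.  With an n_t distribution the expectation is taken
    over it.  fnr = 1 - p_detect.
    """
    from scipy.stats import binom

    if isinstance(model.n_t, (int, np.integer)):
        values, weights = np.array([model.n_t]), np.array([1.0])
    else:
        values, weights = (np.asarray(v, dtype=float) for v in model.n_t)
        weights = weights / weights.sum()
    if k_min == 1:
        p_detect = float(np.sum(weights * (1.0 - (1.0 - model.p_c) ** values)))
    else:
        p_detect = float(np.sum(weights * binom.sf(k_min - 1, values, model.p_c)))
    return p_detect, 1.0 - p_detect


def truncated_poisson_nt(mean: float = 50.0, upper: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Thymines-per-read distribution: Poisson(mean) truncated at >= 1."""
    from scipy.stats import poisson

    values = np.arange(1, upper + 1)
    weights = poisson.pmf(values, mean)
    return values, weights / weights.sum()


def estimate_pc_zero_truncated(
    n_tc: Sequence[int],
    n_t: Sequence[int] | int,
    truncated: bool = True,
) -> float:
    """Maximum-likelihood per-thymine conversion probability.

    With ``truncated=True`` the counts are assumed conditioned on >= 1
    conversion (molecules called labeled at k_min = 1), and the likelihood is
    the zero-truncated binomial; with ``truncated=False`` the plain binomial
    MLE sum(k) / sum(n) is returned.

    Raises ValueError when the counts carry no information (all zero under
    truncation is impossible; p at the boundary is returned as exactly 1.0).
    """
    k = np.asarray(n_tc, dtype=float)
    if np.isscalar(n_t):
        n = np.full_like(k, float(n_t))
    else:
        n = np.asarray(n_t, dtype=float)
    if np.any(n < 1):
        raise ValueError("all molecules must have n_t >= 1")
    if not truncated:
        return float(k.sum() / n.sum())
    if np.any(k < 1):
        raise ValueError("zero-truncated counts must all be >= 1")
    if k.sum() == 0:
        raise ValueError("no conversions observed; p_c not estimable")
    if np.all(k == n):
        return 1.0  # boundary: every covered thymine converted

    def neg_loglik(p: float) -> float:
        # log ZTB likelihood up to the p-free binomial coefficient
        return -float(
            np.sum(k * np.log(p) + (n - k) * np.log1p(-p) - np.log1p(-((1.0 - p) ** n)))
        )

    res = optimize.minimize_scalar(neg_loglik, bounds=(1e-9, 1 - 1e-9), method="bounded")
    return float(res.x)
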