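"""Per-gene RNA decay kinetics from a metabolic-labeling time course.

Under steady-state transcription with first-order decay at rate lambda, the
fraction of molecules synthesized (hence labeled) within a labeling window of
length t is

    f(t) = alpha * (1 - exp(-lambda * t)),      tau = ln(2) / lambda

where alpha <= 1 is the labeling plateau, absorbing incomplete 4sU
incorporation and detection false negatives.  Fitting f(t) to observed
labeled/total ratios across a time course yields per-gene decay rates and
half-lives.

Late timepoints can violate the model when 4sU availability is exhausted
(labeling flattens); by default timepoints beyond 12 h are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

LN2 = float(np.log(2.0))


@dataclass
class DecayFit:
    """One gene's kinetic fit: tau = ln2 / lambda exactly, by construction."""

    gene_id: str
    lam: float
    tau: float
    alpha: float
    r2: float
    n_points: int
    converged: bool
    ci_tau: tuple[float, float] = (np.nan, np.nan)


def timecourse_ratios(
    matrices_by_time: Mapping[tuple[float, str], "object"],
) -> pd.DataFrame:
    """Labeled/total ratios per gene from per-(time, replicate) matrices.

    ``matrices_by_time`` maps (time_h, replicate_id) to a LabeledMatrices
    whose counts are summed over units.  Genes with zero total molecules at a
    timepoint yield no row (a missing point, never f_obs = 0).  Replicates
    are kept separate; averaging before fitting would discard weight
    information.
    """
    rows = []
    for (t, rep), m in matrices_by_time.items():
        lab = m.labeled.sum(axis=1)
        tot = lab + m.unlabeled.sum(axis=1)
        for gene in m.genes:
            n = int(tot[gene])
            if n == 0:
                continue
            rows.append((gene, float(t), str(rep), int(lab[gene]) / n, n))
    return pd.DataFrame(rows, columns=["gene_id", "time_h", "replicate", "f_obs", "n_molecules"])


def saturation_curve(t: np.ndarray, lam: float, alpha: float = 1.0) -> np.ndarray:
    """Model labeled fraction alpha * (1 - e^(-lambda t))."""
    return alpha * -np.expm1(-lam * np.asarray(t, dtype=float))


def fit_decay(
    points: pd.DataFrame,
    gene_id: str | None = None,
    tau_bounds: tuple[float, float] = (0.5, 48.0),
    alpha_mode: str = "free",
    max_time_h: float | None = 12.0,
    weighted: bool = True,
    n_starts: int = 5,
) -> DecayFit:
    """Fit the saturation model to one gene's time-course points.

    Weighted (by molecule count) nonlinear least squares with a
    deterministic multi-start grid of lambda initializations log-spaced over
    the tau bounds — no RNG involved.  ``alpha_mode`` is ``"free"``
    (alpha in (0.05, 1], the default: absorbs incomplete incorporation and
    detection losses) or ``"fixed_1"`` (textbook model, alpha = 1).

    Requires >= 4 points at >= 3 distinct times; fewer yields an explicit
    unfittable record (converged=False, NaN estimates), never a silent drop.
    ``converged`` is False when the optimizer lands on a parameter bound or
    the data carry no variance (SS_tot = 0).
    """
    if alpha_mode not in ("free", "fixed_1"):
        raise ValueError(f"unknown alpha_mode {alpha_mode!r}")
    gid = gene_id if gene_id is not None else (
        str(points["gene_id"].iloc[0]) if len(points) and "gene_id" in points else ""
    )
    pts = points.dropna(subset=["f_obs"])
    if max_time_h is not None:
        pts = pts[pts["time_h"] <= max_time_h]
    t = pts["time_h"].to_numpy(dtype=float)
    f = pts["f_obs"].to_numpy(dtype=float)
    w = (
        np.sqrt(pts["n_molecules"].to_numpy(dtype=float))
        if weighted and "n_molecules" in pts
        else np.ones_like(f)
    )
    n_pts = len(f)
    unfittable = DecayFit(gid, np.nan, np.nan, np.nan, np.nan, n_pts, False)
    if n_pts < 4 or len(np.unique(t)) < 3:
        return unfittable

    lam_lo, lam_hi = LN2 / tau_bounds[1], LN2 / tau_bounds[0]
    free_alpha = alpha_mode == "free"
    alpha_lo, alpha_hi = (0.05, 1.0) if free_alpha else (1.0, 1.0)

    def residuals(theta: np.ndarray) -> np.ndarray:
        lam = np.exp(theta[0])
        alpha = theta[1] if free_alpha else 1.0
        return w * (saturation_curve(t, lam, alpha) - f)

    log_bounds = (np.log(lam_lo), np.log(lam_hi))
    best = None
    alpha0 = min(max(float(f.max()), alpha_lo + 1e-3), 1.0) if free_alpha else 1.0
    for log_lam0 in np.linspace(*log_bounds, n_starts):
        x0 = np.array([log_lam0, alpha0]) if free_alpha else np.array([log_lam0])
        if free_alpha:
            lb, ub = [log_bounds[0], alpha_lo], [log_bounds[1], alpha_hi]
        else:
            lb, ub = [log_bounds[0]], [log_bounds[1]]
        sol = least_squares(
            lambda th: residuals(th if free_alpha else np.array([th[0], 1.0])),
            x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol

    lam = float(np.exp(best.x[0]))
    alpha = float(best.x[1]) if free_alpha else 1.0
    tau = LN2 / lam

    fhat = saturation_curve(t, lam, alpha)
    ss_res = float(np.sum((w * (f - fhat)) ** 2))
    fbar = float(np.sum(w**2 * f) / np.sum(w**2))
    ss_tot = float(np.sum((w * (f - fbar)) ** 2))
    if ss_tot <= 0:
        return DecayFit(gid, lam, tau, alpha, np.nan, n_pts, False)
    r2 = 1.0 - ss_res / ss_tot

    eps = 1e-6
    at_bound = (
        best.x[0] <= log_bounds[0] + eps
        or best.x[0] >= log_bounds[1] - eps
        or (free_alpha and alpha <= alpha_lo + eps)
    )

    ci = _tau_ci(best, t, w, lam, alpha, free_alpha, n_pts)
    return DecayFit(gid, lam, tau, alpha, r2, n_pts, not at_bound, ci)


def _tau_ci(sol, t, w, lam, alpha, free_alpha, n_pts) -> tuple[float, float]:
    """Delta-method 95% CI for tau from the least-squares Jacobian."""
    n_par = 2 if free_alpha else 1
    dof = n_pts - n_par
    if dof <= 0:
        return (np.nan, np.nan)
    J = sol.jac
    try:
        cov = np.linalg.inv(J.T @ J) * (2 * sol.cost / dof)
    except np.linalg.LinAlgError:
        return (np.nan, np.nan)
    se_loglam = float(np.sqrt(max(cov[0, 0], 0.0)))
    # tau = ln2 * exp(-log_lam): |d tau / d log_lam| = tau
    from scipy.stats import t as t_dist

    half = t_dist.ppf(0.975, dof) * se_loglam
    tau = LN2 / lam
    return (tau * np.exp(-half), tau * np.exp(half))


def fit_all_genes(
    points: pd.DataFrame,
    **kwargs,
) -> pd.DataFrame:
    """Fit every gene in a long-format ratio table; returns one row per gene."""
    fits = [
        fit_decay(grp, gene_id=str(gene), **kwargs)
        for gene, grp in points.groupby("gene_id", sort=True)
    ]
    return pd.DataFrame(
        {
            "gene_id": [f.gene_id for f in fits],
            "lambda_per_h": [f.lam for f in fits],
            "tau_h": [f.tau for f in fits],
            "alpha": [f.alpha for f in fits],
            "r2": [f.r2 for f in fits],
            "n_points": [f.n_points for f in fits],
            "converged": [f.converged for f in fits],
            "ci_tau_lo": [f.ci_tau[0] for f in fits],
            "ci_tau_hi": [f.ci_tau[1] for f in fits],
        }
    )


def summarize_halflives(
    fits: pd.DataFrame,
    r2_min: float = 0.7,
    tau_bounds: tuple[float, float] = (0.5, 48.0),
) -> dict:
    """Summary over fits passing quality filters.

    Only converged fits with r2 > r2_min and tau within bounds contribute.
    Returns gene count, mean/median tau, and a decile table of tau.
    """
    ok = fits[
        fits["converged"]
        & (fits["r2"] > r2_min)
        & fits["tau_h"].between(tau_bounds[0], tau_bounds[1])
    ]
    taus = ok["tau_h"].to_numpy(dtype=float)
    if taus.size == 0:
        return {"n_genes": 0, "mean_tau_h": np.nan, "median_tau_h": np.nan, "deciles": pd.Series(dtype=float)}
    deciles = pd.Series(
        np.quantile(taus, np.linspace(0, 1, 11)), index=[f"q{10 * i}" for i in range(11)]
    )
    return {
        "n_genes": int(len(taus)),
        "mean_tau_h": float(taus.mean()),
        "median_tau_h": float(np.median(taus)),
        "deciles": deciles,
    }
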