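"""Association scan: partial correlations between network phenotypes and PRS.

Each test is a partial Pearson correlation between one network phenotype and
one PRS, controlling for sex and diffusion scan type (and optionally ancestry
principal components).  Influential observations are removed once beforehand
using Cook's distance from the least-squares regression of the phenotype on
the score plus covariates (cutoff: three times the mean distance).  Within
each p-value threshold, Benjamini-Hochberg FDR is applied over the family of
all phenotype x score tests; across the eight thresholds, family-wise error
is controlled with the permutation-based minP procedure, which compares each
observed p-value with the permutation distribution of the minimum p-value
over the (correlated) threshold family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .prs import P_THRESHOLDS, PATHWAYS, PRSConfig

DEFAULT_COOKS_FACTOR = 3.0
DEFAULT_N_PERM = 10_000

#: the ten score definitions entering the scan families (APOE included)
SCAN_SCORE_DEFS = tuple((name, True) for name in ("genome_wide",) + PATHWAYS)


class PartialCorrelation(NamedTuple):
    """Partial correlation coefficient, two-sided p-value and residual df."""

    r: float
    p: float
    df: int


def _design(covariates: np.ndarray, n: int) -> np.ndarray:
    C = np.column_stack([np.ones(n), covariates]) if covariates.size else np.ones((n, 1))
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    return C


def _p_from_r(r, df):
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    return 2.0 * sps.t.sf(np.abs(t), df)


def partial_correlation(x, y, covariates=None) -> PartialCorrelation:
    """Pearson correlation of x and y after linear adjustment for covariates.

    The p-value uses the t-distribution with ``n - k - 2`` degrees of
    freedom, ``k`` the number of covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    cov = np.empty((n, 0)) if covariates is None else np.atleast_2d(
        np.asarray(covariates, dtype=float))
    if cov.shape[0] != n and cov.shape[1] == n:
        cov = cov.T
    k = cov.shape[1]
    if n <= k + 3:
        raise ValueError(f"need n > k + 3 (n={n}, k={k})")
    C = _design(cov, n)
    coef, *_ = np.linalg.lstsq(C, np.column_stack([x, y]), rcond=None)
    rx, ry = (np.column_stack([x, y]) - C @ coef).T
    sx, sy = rx.std(), ry.std()
    if sx <= 1e-10 * max(1.0, float(np.std(x))) or sy <= 1e-10 * max(1.0, float(np.std(y))):
        raise ValueError("zero residual variance: correlation undefined")
    r = float(np.dot(rx, ry) / (n * sx * sy))
    df = n - k - 2
    return PartialCorrelation(r, float(_p_from_r(r, df)), df)


def cooks_filter(x, y, covariates=None, factor: float = DEFAULT_COOKS_FACTOR) -> np.ndarray:
    """Boolean mask of observations retained after Cook's-distance screening.

    Cook's distances come from the OLS regression of ``y`` on ``x`` plus the
    covariates; observations with ``D > factor * mean(D)`` are removed in a
    single pass.  Saturated fits (too few residual df) skip the filter with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    cov = np.empty((n, 0)) if covariates is None else np.atleast_2d(
        np.asarray(covariates, dtype=float))
    if cov.shape[0] != n and cov.shape[1] == n:
        cov = cov.T
    X = np.column_stack([np.ones(n), x, cov])
    p = X.shape[1]
    if n <= p + 1:
        warnings.warn("too few observations for Cook's filter; keeping all", stacklevel=2)
        return np.ones(n, dtype=bool)
    XtX_inv = np.linalg.pinv(X.T @ X)
    h = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
    e = y - X @ (XtX_inv @ (X.T @ y))
    s2 = e @ e / (n - p)
    if s2 == 0:
        return np.ones(n, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = e * e / (p * s2) * h / (1.0 - h) ** 2
    d = np.where(np.isfinite(d), d, np.inf)
    return d <= factor * d.mean() if np.isfinite(d.mean()) else ~np.isinf(d)


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    flags, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return flags


# ---------------------------------------------------------------------------
# minP permutation correction
# ---------------------------------------------------------------------------

def _residual_projector(covariates: np.ndarray, n: int) -> np.ndarray:
    C = _design(covariates, n)
    Q, _ = np.linalg.qr(C)
    return Q


def minp_correction(phenotype, scores, covariates=None,
                    n_perm: int = DEFAULT_N_PERM, seed=0,
                    observed_p=None) -> pd.DataFrame:
    """Permutation minP correction across a family of correlated thresholds.

    ``scores`` is an n x T matrix (one column per p-value threshold of the
    same score definition).  Participant rows of the phenotype are permuted
    while scores stay attached to the covariates; each permutation records
    the minimum p over the T partial correlations, and the corrected p for a
    test equals ``(1 + #{perm min-p <= observed p}) / (n_perm + 1)``.

    ``observed_p`` overrides the internally computed (unfiltered) observed
    p-values, e.g. with Cook's-filtered ones from the main scan.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    y = np.asarray(phenotype, dtype=float)
    n, T = S.shape
    cov = np.empty((n, 0)) if covariates is None else np.atleast_2d(
        np.asarray(covariates, dtype=float))
    if cov.shape[0] != n and cov.shape[1] == n:
        cov = cov.T
    k = cov.shape[1]
    df = n - k - 2
    Q = _residual_projector(cov, n)

    def _norm_resid(M):
        R = M - Q @ (Q.T @ M)
        norms = np.linalg.norm(R, axis=0)
        norms[norms == 0] = np.inf
        return R / norms

    Sn = _norm_resid(S)
    yn = _norm_resid(y[:, None])[:, 0]
    r_obs = yn @ Sn
    p_obs = _p_from_r(r_obs, df)
    if observed_p is not None:
        p_obs = np.asarray(observed_p, dtype=float)

    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    Yp = _norm_resid(y[perms].T)          # n x n_perm permuted, residualised
    R = Yp.T @ Sn                          # n_perm x T
    p_perm_min = _p_from_r(R, df).min(axis=1)
    corrected = (1.0 + (p_perm_min[:, None] <= p_obs[None, :]).sum(axis=0)) / (n_perm + 1.0)
    return pd.DataFrame({"raw_p": p_obs, "minp_corrected_p": corrected})


# ---------------------------------------------------------------------------
# The full scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Outcome of one association scan."""

    table: pd.DataFrame
    q: float
    n_perm: int


def _check_alignment(*frames: pd.DataFrame) -> pd.Index:
    index = frames[0].index
    for f in frames[1:]:
        if not f.index.equals(index):
            offenders = sorted(set(index).symmetric_difference(f.index))[:10]
            raise ValueError(f"participant ids misaligned; offenders include {offenders}")
    return index


def run_scan(phenotypes: pd.DataFrame, scores: pd.DataFrame,
             covariates: pd.DataFrame,
             score_defs: Sequence[tuple[str, bool]] = SCAN_SCORE_DEFS,
             thresholds: Sequence[float] = P_THRESHOLDS,
             q: float = 0.05, cooks_factor: float | None = DEFAULT_COOKS_FACTOR,
             n_perm: int = DEFAULT_N_PERM, seed: int = 0,
             minp: str = "flagged") -> ScanResult:
    """Scan every (phenotype, score definition) pair at every threshold.

    Per test: Cook's filter, then partial correlation controlling for the
    covariates.  BH-FDR runs within each threshold's family (all phenotypes x
    all score definitions).  minP permutation correction runs across the
    thresholds of each pair — for every pair (``minp='all'``), only for pairs
    with at least one FDR flag (``'flagged'``, mirroring two-tier practice),
    or not at all (``'none'``).

    ``cooks_factor=None`` disables the outlier filter.  Note that trimming by
    Cook's distance and then testing at unadjusted df is anticonservative on
    clean data (it removes exactly the points that weaken a fit); calibration
    experiments on outlier-free synthetic data should disable it.
    """
    if minp not in ("all", "flagged", "none"):
        raise ValueError("minp must be 'all', 'flagged' or 'none'")
    _check_alignment(phenotypes, scores, covariates)
    # constant or collinear covariate columns (possible in tiny cohorts)
    # carry no adjustment information; drop them rather than fail every test
    dropped_cov = []
    n_obs = len(covariates)
    design = np.ones((n_obs, 1))
    keep_cols = []
    for c in covariates.columns:
        cand = np.column_stack([design, covariates[c].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand) > design.shape[1]:
            design = cand
            keep_cols.append(c)
        else:
            dropped_cov.append(c)
    if dropped_cov:
        warnings.warn(f"dropping constant/collinear covariate column(s) {dropped_cov}",
                      stacklevel=2)
        covariates = covariates[keep_cols]
    cov = covariates.to_numpy(dtype=float)
    n = len(phenotypes)
    rows = []
    for pt in thresholds:
        for pheno_name in phenotypes.columns:
            y = phenotypes[pheno_name].to_numpy(dtype=float)
            for score_name, include_apoe in score_defs:
                col = PRSConfig(score_name, include_apoe, pt).column
                if col not in scores.columns:
                    raise ValueError(f"score panel lacks column {col}")
                x = scores[col].to_numpy(dtype=float)
                if cooks_factor is None:
                    keep = np.ones(n, dtype=bool)
                else:
                    keep = cooks_filter(x, y, cov, factor=cooks_factor)
                sub_cov = cov[keep]
                # filtering can leave a covariate constant in tiny cohorts
                informative = [j for j in range(sub_cov.shape[1])
                               if np.unique(sub_cov[:, j]).size > 1]
                pc = partial_correlation(x[keep], y[keep], sub_cov[:, informative])
                rows.append({
                    "phenotype": pheno_name,
                    "score": score_name,
                    "include_apoe": include_apoe,
                    "p_threshold": pt,
                    "r": pc.r,
                    "p": pc.p,
                    "n_retained": int(keep.sum()),
                    "n_removed": int(n - keep.sum()),
                })
    table = pd.DataFrame(rows)
    table["fdr_significant"] = False
    for pt in thresholds:
        fam = table["p_threshold"] == pt
        table.loc[fam, "fdr_significant"] = fdr_bh(table.loc[fam, "p"].to_numpy(), q=q)
    table["minp_corrected_p"] = np.nan
    if minp != "none" and n_perm > 0 and len(thresholds) > 0:
        for i, (pheno_name, score_name, include_apoe) in enumerate(
                table[["phenotype", "score", "include_apoe"]].drop_duplicates().itertuples(index=False)):
            sel = ((table["phenotype"] == pheno_name)
                   & (table["score"] == score_name)
                   & (table["include_apoe"] == include_apoe))
            if minp == "flagged" and not table.loc[sel, "fdr_significant"].any():
                continue
            sub = table.loc[sel].set_index("p_threshold").loc[list(thresholds)]
            cols = [PRSConfig(score_name, include_apoe, pt).column for pt in thresholds]
            out = minp_correction(
                phenotypes[pheno_name].to_numpy(dtype=float),
                scores[cols].to_numpy(dtype=float), cov,
                n_perm=n_perm, seed=seed + i,
                observed_p=sub["p"].to_numpy())
            table.loc[sel, "minp_corrected_p"] = out["minp_corrected_p"].to_numpy()
    return ScanResult(table=table, q=q, n_perm=n_perm)
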