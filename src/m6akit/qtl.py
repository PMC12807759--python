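"""m6A-QTL stage: M-level quantification, normalization, and cis mapping.

The phenotype is the depth-normalized log-odds methylation level
``M = log[(IP/sum(IP)) / (Input/sum(Input))]``.  The normalization chain is
missingness filtering (rows then columns), MA-like correction against a
pseudo-reference profile, natural-cubic-spline GC correction, row z-scoring
followed by column quantile normalization, and SVD latent-factor estimation.
Cis associations are tested by OLS with covariates; per-site empirical
p-values come from phenotype permutations with a maximum-likelihood Beta
approximation of the permutation null (FastQTL-style).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# M-levels and missingness
# ---------------------------------------------------------------------------

@dataclass
class MLevelMatrix:
    """Sites × samples log-odds methylation levels with a missing mask."""

    values: np.ndarray
    site_ids: list
    sample_ids: list
    gc: np.ndarray | None = None  # per-site GC content of a flanking window

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.sample_ids)


def compute_m_levels(ip_counts, input_counts, site_ids=None, sample_ids=None,
                     pseudocount: float = 0.5) -> MLevelMatrix:
    """Natural-log M-levels from paired IP/input count matrices.

    A cell is missing (NaN) when IP + Input coverage is zero; when exactly
    one side is zero, ``pseudocount`` is added to both sides to keep the
    log-odds finite.  Column sums use the raw counts.
    """
    ip = np.asarray(ip_counts, dtype=float)
    inp = np.asarray(input_counts, dtype=float)
    if ip.shape != inp.shape:
        raise ValueError("IP and Input matrices must have the same shape (unpaired sample?)")
    sum_ip = ip.sum(axis=0)
    sum_inp = inp.sum(axis=0)
    if np.any(sum_ip <= 0) or np.any(sum_inp <= 0):
        raise ValueError("every IP and Input column must have positive total counts")
    zero_cell = (ip + inp) == 0
    needs_pc = ((ip == 0) | (inp == 0)) & ~zero_cell
    ip_adj = np.where(needs_pc, ip + pseudocount, ip)
    inp_adj = np.where(needs_pc, inp + pseudocount, inp)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log((ip_adj / sum_ip) / (inp_adj / sum_inp))
    m[zero_cell] = np.nan
    if site_ids is None:
        site_ids = [f"site{i}" for i in range(ip.shape[0])]
    if sample_ids is None:
        sample_ids = [f"sample{j}" for j in range(ip.shape[1])]
    return MLevelMatrix(m, list(site_ids), list(sample_ids))


def filter_missingness(matrix: MLevelMatrix, row_max: float = 0.20,
                       col_max: float = 0.80) -> MLevelMatrix:
    """Remove rows with missing fraction > row_max, then columns > col_max.

    The column pass is evaluated on the row-filtered matrix; both
    thresholds are strict inequalities.
    """
    miss = matrix.missing
    row_keep = miss.mean(axis=1) <= row_max
    if not row_keep.any():
        raise ValueError("all rows removed by missingness filter")
    vals = matrix.values[row_keep]
    col_keep = np.isnan(vals).mean(axis=0) <= col_max
    out_gc = matrix.gc[row_keep] if matrix.gc is not None else None
    return MLevelMatrix(
        vals[:, col_keep],
        [s for s, k in zip(matrix.site_ids, row_keep) if k],
        [s for s, k in zip(matrix.sample_ids, col_keep) if k],
        out_gc,
    )


# ---------------------------------------------------------------------------
# MA-like normalization
# ---------------------------------------------------------------------------

@dataclass
class MAState:
    """Pseudo-reference and per-sample MA regression coefficients."""

    reference: np.ndarray
    intercepts: np.ndarray
    slopes: np.ndarray

    def refit(self, corrected: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Re-fit M' on A' per sample against the stored pseudo-reference."""
        slopes = np.zeros(corrected.shape[1])
        intercepts = np.zeros(corrected.shape[1])
        for j in range(corrected.shape[1]):
            x = corrected[:, j]
            ok = ~np.isnan(x) & ~np.isnan(self.reference)
            mvals = x[ok] - self.reference[ok]
            avals = (x[ok] + self.reference[ok]) / 2.0
            if np.ptp(avals) < 1e-12:
                intercepts[j] = mvals.mean()
                continue
            slopes[j], intercepts[j] = np.polyfit(avals, mvals, 1)
        return slopes, intercepts


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def ma_normalize(matrix: MLevelMatrix) -> tuple[MLevelMatrix, MAState]:
    """Remove intensity-dependent bias per sample via MA regression.

    Each sample is compared to the pseudo-reference (row-wise mean across
    samples): M' = x − r, A' = (x + r)/2, an OLS line of M' on A' is fitted
    over non-missing cells and its prediction subtracted from the sample.
    """
    vals = matrix.values
    if vals.shape[1] < 2:
        raise ValueError("MA normalization needs >= 2 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        reference = np.nanmean(vals, axis=1)
    out = vals.copy()
    slopes = np.zeros(vals.shape[1])
    intercepts = np.zeros(vals.shape[1])
    for j in range(vals.shape[1]):
        x = vals[:, j]
        ok = ~np.isnan(x) & ~np.isnan(reference)
        mvals = x[ok] - reference[ok]
        avals = (x[ok] + reference[ok]) / 2.0
        if np.ptp(avals) < 1e-12:
            warnings.warn(f"constant A' for sample {matrix.sample_ids[j]}; subtracting mean(M')", RuntimeWarning)
            intercepts[j] = mvals.mean()
            out[ok, j] = x[ok] - intercepts[j]
            continue
        slopes[j], intercepts[j] = _ols_line(avals, mvals)
        out[ok, j] = x[ok] - (intercepts[j] + slopes[j] * avals)
    state = MAState(reference, intercepts, slopes)
    return MLevelMatrix(out, matrix.site_ids, matrix.sample_ids, matrix.gc), state


# ---------------------------------------------------------------------------
# GC spline correction
# ---------------------------------------------------------------------------

def natural_spline_basis(x: np.ndarray, df: int = 4) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns (no intercept).

    Boundary knots at the data range, internal knots at quantiles; the
    standard truncated-power construction with linearity constraints beyond
    the boundaries.
    """
    x = np.asarray(x, dtype=float)
    knots = np.quantile(x, np.linspace(0, 1, df + 1))
    knots = np.unique(knots)
    if knots.size < df + 1:
        raise ValueError(f"df={df} requires more distinct values than available")
    K = knots.size

    def d(k):
        return (np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - knots[K - 1], 0, None) ** 3) / (
            knots[K - 1] - knots[k]
        )

    cols = [x]
    for k in range(K - 2):
        cols.append(d(k) - d(K - 2))
    return np.column_stack(cols)


def gc_correct(matrix: MLevelMatrix, gc=None, df: int = 4) -> MLevelMatrix:
    """Remove per-sample GC-content trends with a natural cubic spline fit.

    Per sample, values are regressed on a spline basis of per-site GC with
    ``df`` degrees of freedom; the fitted curve is subtracted and the
    result mean-centered.
    """
    gc = matrix.gc if gc is None else np.asarray(gc, dtype=float)
    if gc is None:
        raise ValueError("per-site GC content is required")
    if gc.shape[0] != matrix.values.shape[0]:
        raise ValueError("gc must be defined on all retained sites")
    if np.unique(gc).size <= df:
        raise ValueError(f"df={df} must be < number of distinct GC values")
    basis = natural_spline_basis(gc, df)
    out = matrix.values.copy()
    for j in range(out.shape[1]):
        x = out[:, j]
        ok = ~np.isnan(x)
        X = np.column_stack([np.ones(ok.sum()), basis[ok]])
        coef, *_ = np.linalg.lstsq(X, x[ok], rcond=None)
        resid = x[ok] - X @ coef
        out[ok, j] = resid - resid.mean()
    return MLevelMatrix(out, matrix.site_ids, matrix.sample_ids, gc)


# ---------------------------------------------------------------------------
# z-score + quantile normalization
# ---------------------------------------------------------------------------

def zscore_rows(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale rows to mean 0 / sample SD 1 (missing ignored).

    Returns ``(scaled, keep)`` where ``keep`` flags rows with positive
    variance; zero-variance rows are excluded from ``scaled``.
    """
    vals = np.asarray(vals, dtype=float)
    n_ok = (~np.isnan(vals)).sum(axis=1)
    if np.any(n_ok < 2):
        raise ValueError("each row needs >= 2 non-missing values")
    mean = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance rows", RuntimeWarning)
    return (vals[keep] - mean[keep]) / sd[keep], keep


def zscore_rows_then_quantile_columns(matrix: MLevelMatrix) -> MLevelMatrix:
    """Row-wise z-scoring followed by column-wise quantile normalization.

    The quantile step uses the classical sorted-mean reference with
    average-rank tie handling.
    """
    vals, keep = zscore_rows(matrix.values)
    site_ids = [s for s, k in zip(matrix.site_ids, keep) if k]
    gc = matrix.gc[keep] if matrix.gc is not None else None
    out = _quantile_normalize_columns(vals)
    return MLevelMatrix(out, site_ids, matrix.sample_ids, gc)


def _quantile_normalize_columns(vals: np.ndarray) -> np.ndarray:
    """Classical quantile normalization across columns, NaN-tolerant."""
    n, m = vals.shape
    complete = not np.isnan(vals).any()
    if complete:
        reference = np.sort(vals, axis=0).mean(axis=1)
        out = np.empty_like(vals)
        for j in range(m):
            ranks = stats.rankdata(vals[:, j], method="average")  # 1-based
            out[:, j] = np.interp(ranks, np.arange(1, n + 1), reference)
        return out
    # with missing cells, map each column's ranks onto reference quantiles
    ref_parts = []
    for j in range(m):
        col = vals[~np.isnan(vals[:, j]), j]
        q = (np.arange(1, col.size + 1) - 0.5) / col.size
        ref_parts.append(np.interp(np.linspace(0.005, 0.995, 100), q, np.sort(col)))
    reference = np.mean(ref_parts, axis=0)
    ref_q = np.linspace(0.005, 0.995, 100)
    out = np.full_like(vals, np.nan)
    for j in range(m):
        ok = ~np.isnan(vals[:, j])
        col = vals[ok, j]
        q = (stats.rankdata(col, method="average") - 0.5) / col.size
        out[ok, j] = np.interp(q, ref_q, reference)
    return out


# ---------------------------------------------------------------------------
# Latent factors
# ---------------------------------------------------------------------------

def _residualize(Y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Project out columns of C (plus intercept) from each row of Y."""
    X = np.column_stack([np.ones(Y.shape[1]), C]) if C is not None and C.size else np.ones((Y.shape[1], 1))
    Q, _ = np.linalg.qr(X)
    return Y - (Y @ Q) @ Q.T


def estimate_latent_factors(matrix, known_covariates=None, B: int = 20,
                            alpha: float = 0.10, seed: int | None = 0) -> np.ndarray:
    """Permutation-calibrated SVD factor count and factor matrix.

    After residualizing on known covariates, k is the length of the leading
    run of singular-value variance proportions exceeding the (1 − alpha)
    quantile of B within-row-permutation nulls; the first k right singular
    vectors (samples × k, orthonormal) are returned.
    """
    vals = matrix.values if isinstance(matrix, MLevelMatrix) else np.asarray(matrix, dtype=float)
    vals = vals.copy()
    if np.isnan(vals).any():  # mean-impute residual missing cells
        row_mean = np.nanmean(vals, axis=1)
        idx = np.where(np.isnan(vals))
        vals[idx] = row_mean[idx[0]]
    C = np.asarray(known_covariates, dtype=float) if known_covariates is not None else None
    resid = _residualize(vals, C)
    resid = resid - resid.mean(axis=1, keepdims=True)

    def var_props(mat):
        s = np.linalg.svd(mat, compute_uv=False)
        s2 = s**2
        return s2 / s2.sum()

    obs = var_props(resid)
    rng = np.random.default_rng(seed)
    null = np.empty((B, obs.size))
    for b in range(B):
        perm = np.array([rng.permutation(row) for row in resid])
        null[b] = var_props(perm)
    thresh = np.quantile(null, 1.0 - alpha, axis=0)
    k = 0
    for i in range(obs.size):
        if obs[i] > thresh[i]:
            k += 1
        else:
            break
    if k == 0:
        return np.empty((vals.shape[1], 0))
    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    return vt[:k].T


# ---------------------------------------------------------------------------
# Cis windows and QTL mapping
# ---------------------------------------------------------------------------

def define_cis_window(gene_start: int, gene_end: int, strand: str,
                      chrom_length: int | None = None,
                      upstream: int = 2000, downstream: int = 200) -> list[tuple[int, int]]:
    """Union of the gene body and the strand-aware promoter interval.

    Promoter is [TSS − upstream, TSS + downstream] on "+" (reflected on
    "−"); intervals are 1-based inclusive, merged, and clamped to
    [1, chrom_length].
    """
    if strand == "+":
        tss = gene_start
        promoter = (tss - upstream, tss + downstream)
    elif strand == "-":
        tss = gene_end
        promoter = (tss - downstream, tss + upstream)
    else:
        raise ValueError(f"invalid strand {strand!r}")
    intervals = sorted([(gene_start, gene_end), promoter])
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    out = []
    for s, e in merged:
        s = max(s, 1)
        if chrom_length is not None:
            e = min(e, chrom_length)
        if e >= s:
            out.append((s, e))
    return out


@dataclass
class QTLAssociation:
    """Best cis association for one site."""

    site_id: str
    variant_id: str
    variant_pos: int
    slope: float
    nominal_p: float
    empirical_p_direct: float
    empirical_p_beta: float | None
    beta_shape1: float | None
    beta_shape2: float | None
    n_variants: int
    threshold_low: float | None = None
    threshold_high: float | None = None


def _beta_mle(pvals: np.ndarray) -> tuple[float, float]:
    eps = 1.0 / (2 * pvals.size)
    clipped = np.clip(pvals, eps, 1 - eps)
    a, b, _, _ = stats.beta.fit(clipped, floc=0, fscale=1)
    return float(a), float(b)


def map_cis_qtl(
    phenotypes: pd.DataFrame,
    genotypes: pd.DataFrame,
    variant_pos: pd.Series,
    windows: dict,
    covariates: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int | None = 0,
    low: float = 0.1,
    high: float = 0.05,
) -> pd.DataFrame:
    """Per-site cis-QTL scan with permutation empirical p-values.

    Parameters
    ----------
    phenotypes
        sites × samples normalized M-levels (rows indexed by site_id).
    genotypes
        variants × samples dosage matrix in [0, 2]; missing dosages are
        mean-imputed per variant.
    variant_pos
        per-variant genomic position (same chromosome space as windows).
    windows
        site_id → list of (start, end) 1-based inclusive cis intervals.
    covariates
        samples × c matrix of known covariates plus latent factors.

    For each site, phenotype and dosages are residualized on the
    covariates; the best nominal p across cis variants is compared to
    ``n_perm`` permutations of the residualized phenotype.  The direct
    empirical p is ``(1 + #{perm best <= obs best}) / (1 + n_perm)``; a
    Beta(a, b) MLE fit to the permutation best-p values gives the
    beta-approximated empirical p and the per-site nominal thresholds at
    the ``low``/``high`` target levels (beta quantiles).  Monomorphic
    variants are excluded; sites left with < 2 cis variants get the direct
    permutation p only.
    """
    if list(phenotypes.columns) != list(genotypes.columns):
        raise ValueError("phenotype and genotype sample columns must be aligned")
    samples = list(phenotypes.columns)
    n = len(samples)
    C = np.asarray(covariates, dtype=float) if covariates is not None else None
    n_cov = 0 if C is None or C.size == 0 else C.shape[1]
    X = np.column_stack([np.ones(n), C]) if n_cov else np.ones((n, 1))
    Q, _ = np.linalg.qr(X)
    dof = n - 2 - n_cov
    if dof < 1:
        raise ValueError("not enough samples for the covariate model")

    G = genotypes.values.astype(float)
    for i in range(G.shape[0]):  # mean-impute missing dosages per variant
        miss = np.isnan(G[i])
        if miss.any():
            G[i, miss] = G[i, ~miss].mean()
    pos = variant_pos.values
    rng = np.random.default_rng(seed)

    rows = []
    for site_id in phenotypes.index:
        win = windows.get(site_id)
        if win is None:
            logger.warning("site %s has no cis window; skipped", site_id)
            continue
        in_cis = np.zeros(G.shape[0], dtype=bool)
        for s, e in win:
            in_cis |= (pos >= s) & (pos <= e)
        cis_idx = np.flatnonzero(in_cis)
        if cis_idx.size == 0:
            continue
        g = G[cis_idx]
        poly = g.std(axis=1) > 0
        cis_idx = cis_idx[poly]
        g = g[poly]
        if cis_idx.size == 0:
            continue

        y = phenotypes.loc[site_id].values.astype(float)
        y_res = y - Q @ (Q.T @ y)
        y_norm = y_res / np.linalg.norm(y_res)
        g_res = g - (g @ Q) @ Q.T
        g_norm = g_res / np.linalg.norm(g_res, axis=1, keepdims=True)

        r = g_norm @ y_norm
        r = np.clip(r, -0.999999, 0.999999)
        tstat = r * np.sqrt(dof / (1.0 - r**2))
        pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
        best = int(np.argmin(pvals))
        obs_p = float(pvals[best])
        obs_r = float(abs(r[best]))
        slope = float((g_res[best] @ y_res) / (g_res[best] @ g_res[best]))

        perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
        Yp = y_norm[perm_idx].T  # n × n_perm
        Rp = np.abs(g_norm @ Yp)  # variants × perms
        best_r = Rp.max(axis=0)
        emp_direct = float((1 + np.sum(best_r >= obs_r)) / (1 + n_perm))

        emp_beta = a = b = thr_low = thr_high = None
        if cis_idx.size >= 2:
            best_t = best_r * np.sqrt(dof / (1.0 - best_r**2))
            best_p = 2.0 * stats.t.sf(best_t, dof)
            a, b = _beta_mle(best_p)
            emp_beta = float(stats.beta.cdf(obs_p, a, b))
            thr_low = float(stats.beta.ppf(low, a, b))
            thr_high = float(stats.beta.ppf(high, a, b))

        rows.append(QTLAssociation(
            site_id=str(site_id),
            variant_id=str(genotypes.index[cis_idx[best]]),
            variant_pos=int(pos[cis_idx[best]]),
            slope=slope,
            nominal_p=obs_p,
            empirical_p_direct=emp_direct,
            empirical_p_beta=emp_beta,
            beta_shape1=a,
            beta_shape2=b,
            n_variants=int(cis_idx.size),
            threshold_low=thr_low,
            threshold_high=thr_high,
        ))
    return pd.DataFrame([vars(r) for r in rows])
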