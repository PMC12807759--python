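"""Reproducibility-based orthogonal validation.

Paired methylation profiles from two technically orthogonal assays are
compared on the rank scale with a two-component Gaussian copula mixture
(the irreproducible-discovery-rate model): a correlated "reproducible"
component N((mu, mu), sigma^2, corr rho) against independent standard-normal
noise.  A site is orthogonally validated when its global IDR is below
threshold AND the binomial caller flags it in both techniques.

The differential variant feeds per-technique beta-value differences
(treated − control) into the same model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calling import aggregated_binomial_calls
from .matrix import MethylationMatrix, CATEGORIES

logger = logging.getLogger(__name__)

DEFAULT_IDR_INIT = {"mu": 0.1, "sigma": 1.0, "rho": 0.2, "p": 0.5}


def is_orthogonal(category1: str, category2: str, technique1: str = "", technique2: str = "") -> bool:
    """Whether two assay categories rest on distinct biochemical principles.

    Categories must differ, except the direct-RNA/antibody pair which is
    non-orthogonal (the direct-RNA caller is trained on antibody data).
    """
    for c in (category1, category2):
        if c not in CATEGORIES:
            raise ValueError(f"unknown category {c!r}; expected one of {CATEGORIES}")
    if category1 == category2:
        return False
    if {category1, category2} == {"direct", "antibody"}:
        return False
    return True


def aggregate_counts(matrix: MethylationMatrix, baseline_only: bool = True,
                     condition: str | None = None, cell_or_tissue: str | None = None):
    """Sum the count layers over a selected subset of samples.

    Default selection is all baseline (non-perturbation, non-IVT) samples;
    ``condition`` / ``cell_or_tissue`` restrict further.
    """
    idx = []
    for j, rec in enumerate(matrix.samples):
        if rec.is_ivt:
            continue
        if baseline_only and not rec.is_baseline:
            continue
        if condition is not None and rec.condition != condition:
            continue
        if cell_or_tissue is not None and rec.cell_or_tissue != cell_or_tissue:
            continue
        idx.append(j)
    if not idx:
        raise ValueError("sample selection is empty")
    m6a = matrix.layers["m6a_count"][:, idx].sum(axis=1)
    total = matrix.layers["total_count"][:, idx].sum(axis=1)
    return m6a, total


@dataclass
class BetaProfile:
    """Per-site beta-values (methylated / total coverage) with totals kept.

    ``beta`` is NaN where total coverage is zero; when ``jittered`` the
    stored values carry the tie-breaking perturbation.
    """

    beta: np.ndarray
    total: np.ndarray
    jittered: bool = False
    jitter_seed: int | None = None


def _jitter(values: np.ndarray, factor: float, rng: np.random.Generator) -> np.ndarray:
    """Tie-breaking jitter: multiplicative uniform on (1-f, 1+f).

    Exact zeros cannot be perturbed multiplicatively; they receive a tiny
    additive uniform draw scaled to the smallest positive magnitude so they
    stay at the bottom of the ranking.
    """
    out = values * rng.uniform(1.0 - factor, 1.0 + factor, size=values.shape)
    zero = values == 0.0
    if zero.any():
        finite = np.abs(values[np.isfinite(values) & (values != 0.0)])
        scale = finite.min() if finite.size else 1.0
        out[zero] = rng.uniform(0.0, factor, size=int(zero.sum())) * scale
    return out


def compute_beta(m6a, total, jitter_factor: float = 0.0001, seed: int | None = 0) -> BetaProfile:
    """Beta-values ``m6a / total`` with deterministic tie-breaking jitter.

    Set ``jitter_factor=0`` (or ``seed=None``) to skip jitter.
    """
    m6a = np.asarray(m6a, dtype=float)
    total = np.asarray(total, dtype=float)
    if np.any(m6a < 0) or np.any(total < 0):
        raise ValueError("counts must be non-negative")
    if np.any(m6a > total):
        raise ValueError("m6a must be <= total")
    beta = np.full(m6a.shape, np.nan)
    covered = total > 0
    beta[covered] = m6a[covered] / total[covered]
    if jitter_factor > 0 and seed is not None:
        rng = np.random.default_rng(seed)
        beta[covered] = _jitter(beta[covered], jitter_factor, rng)
        return BetaProfile(beta, total.astype(np.int64), jittered=True, jitter_seed=seed)
    return BetaProfile(beta, total.astype(np.int64), jittered=False, jitter_seed=None)


def pairwise_coverage_filter(total1, total2, min_cov: int = 20) -> np.ndarray:
    """Row indices with total coverage >= min_cov in both techniques."""
    total1 = np.asarray(total1)
    total2 = np.asarray(total2)
    if total1.shape != total2.shape:
        raise ValueError("coverage vectors must have equal length")
    return np.flatnonzero((total1 >= min_cov) & (total2 >= min_cov))


# ---------------------------------------------------------------------------
# Gaussian copula mixture IDR
# ---------------------------------------------------------------------------

@dataclass
class IDRFit:
    """Fitted copula mixture with per-site local idr and global IDR."""

    mu: float
    sigma: float
    rho: float
    p: float
    idr_local: np.ndarray = field(repr=False, default=None)
    idr_global: np.ndarray = field(repr=False, default=None)
    loglik_trace: list = field(default_factory=list, repr=False)
    converged: bool = False
    n_iter: int = 0
    degenerate: bool = False


def _marginal_pseudo_values(u: np.ndarray, mu: float, sigma: float, p: float) -> np.ndarray:
    """Invert the marginal mixture CDF G(z) = p*Phi((z-mu)/sigma) + (1-p)*Phi(z)."""
    lo = min(mu - 6.0 * sigma, -6.0)
    hi = max(mu + 6.0 * sigma, 6.0)
    grid = np.linspace(lo, hi, 4001)
    cdf = p * stats.norm.cdf((grid - mu) / sigma) + (1.0 - p) * stats.norm.cdf(grid)
    return np.interp(u, cdf, grid)


def _bivariate_logpdf(z1, z2, mu, sigma, rho):
    """Log pdf of N((mu,mu), sigma^2 [[1,rho],[rho,1]])."""
    det = sigma**4 * (1.0 - rho**2)
    a = (z1 - mu) / sigma
    b = (z2 - mu) / sigma
    quad = (a * a - 2.0 * rho * a * b + b * b) / (1.0 - rho**2)
    return -np.log(2.0 * np.pi) - 0.5 * np.log(det) - 0.5 * quad


def _em_gaussian_copula(z1, z2, mu, sigma, rho, p, tol, max_iter):
    trace = []
    converged = False
    it = 0
    log_noise = _bivariate_logpdf(z1, z2, 0.0, 1.0, 1e-12)  # independent std normal
    for it in range(1, max_iter + 1):
        log_sig = np.log(p) + _bivariate_logpdf(z1, z2, mu, sigma, rho)
        log_noi = np.log1p(-p) + log_noise
        norm = np.logaddexp(log_sig, log_noi)
        trace.append(float(norm.sum()))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        g = np.exp(log_sig - norm)  # responsibility of the reproducible component
        sg = g.sum()
        if sg < 1e-12:
            break
        p = float(np.clip(g.mean(), 1e-4, 1 - 1e-4))
        mu = float((g * (z1 + z2)).sum() / (2.0 * sg))
        d1 = z1 - mu
        d2 = z2 - mu
        ss = (g * (d1 * d1 + d2 * d2)).sum()
        sigma = float(np.sqrt(max(ss / (2.0 * sg), 1e-6)))
        rho = float(np.clip(2.0 * (g * d1 * d2).sum() / max(ss, 1e-12), 1e-4, 0.999))
        sigma = max(sigma, 1e-3)
    return mu, sigma, rho, p, trace, converged, it


MIN_SIGNAL_RHO = 0.1


def _collapsed(mu: float, rho: float, p: float) -> bool:
    """Detect the degenerate no-signal fit.

    On pure-noise input the EM absorbs everything into the "reproducible"
    component (p -> 1) while that component stays uncorrelated and centred
    like the noise; a "reproducible" component separated neither by
    correlation nor by location carries no evidence of reproducibility.
    """
    return p > 0.99 and rho < MIN_SIGNAL_RHO and abs(mu) < 0.5


def _global_from_local(local: np.ndarray) -> np.ndarray:
    """Global IDR_i = mean local idr over sites with local idr <= local_i."""
    order = np.argsort(local, kind="mergesort")
    sorted_local = local[order]
    cummean = np.cumsum(sorted_local) / np.arange(1, local.size + 1)
    # for ties, use the value at the rightmost occurrence so equal locals share a global
    pos = np.searchsorted(sorted_local, local, side="right") - 1
    return cummean[pos]


def fit_idr(
    x,
    y,
    init: dict | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_outer: int = 500,
    outer_tol: float = 1e-4,
) -> IDRFit:
    """Fit the 2-D Gaussian copula mixture to paired signal vectors.

    Margins are rank-transformed (``rank/(n+1)``), mapped to pseudo-values
    through the inverse of the fitted marginal mixture CDF, and a latent
    two-component EM updates (mu, sigma, rho, p); pseudo-values are
    re-derived each outer iteration until the pseudo-likelihood stabilizes.
    Local idr is the posterior noise probability; global IDR at a site is
    the expected irreproducible rate among all sites ranked at or better.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 100:
        raise ValueError(f"need >= 100 sites for IDR fitting, got {n}")
    params = dict(DEFAULT_IDR_INIT)
    if init:
        params.update(init)
    mu, sigma, rho, p = params["mu"], params["sigma"], params["rho"], params["p"]

    degenerate = bool(np.unique(x).size == 1 or np.unique(y).size == 1)
    if degenerate:
        warnings.warn("degenerate IDR input: a margin is constant (all ties)", RuntimeWarning)
        local = np.ones(n)
        return IDRFit(mu, sigma, rho, p, local, _global_from_local(local),
                      [], False, 0, degenerate=True)

    u = stats.rankdata(x, method="average") / (n + 1)
    v = stats.rankdata(y, method="average") / (n + 1)

    trace_all: list[float] = []
    converged = False
    no_signal = False
    total_iter = 0
    z1 = z2 = None
    inner_cap = min(max_iter, 100)
    for outer_i in range(n_outer):
        z1 = _marginal_pseudo_values(u, mu, sigma, p)
        z2 = _marginal_pseudo_values(v, mu, sigma, p)
        old = (mu, sigma, rho, p)
        mu, sigma, rho, p, trace, _, iters = _em_gaussian_copula(
            z1, z2, mu, sigma, rho, p, tol, inner_cap)
        trace_all.extend(trace)
        total_iter += iters
        # the pseudo-likelihood is not comparable across pseudo-value
        # refreshes, so the outer loop stops on parameter stability
        if max(abs(a - b) for a, b in zip(old, (mu, sigma, rho, p))) < outer_tol:
            converged = True
            break
        if _collapsed(mu, rho, p) or (outer_i >= 50 and rho < 0.05 and abs(mu) < 0.5):
            no_signal = True  # mixture is absorbing noise into "signal"
            break
    if not (converged or no_signal):
        warnings.warn("IDR outer loop did not converge", RuntimeWarning)

    if no_signal or _collapsed(mu, rho, p) or (rho < 0.05 and abs(mu) < 0.5):
        # the fitted signal component is indistinguishable from noise:
        # nothing is reproducible
        warnings.warn("IDR signal component collapsed onto noise; no reproducible sites", RuntimeWarning)
        local = np.ones(n)
        return IDRFit(mu, sigma, rho, p, local, _global_from_local(local),
                      trace_all, converged, total_iter, degenerate=True)

    log_sig = np.log(p) + _bivariate_logpdf(z1, z2, mu, sigma, rho)
    log_noi = np.log1p(-p) + _bivariate_logpdf(z1, z2, 0.0, 1.0, 1e-12)
    local = np.exp(log_noi - np.logaddexp(log_sig, log_noi))
    local = np.clip(local, 0.0, 1.0)
    return IDRFit(mu, sigma, rho, p, local, _global_from_local(local),
                  trace_all, converged, total_iter)


# ---------------------------------------------------------------------------
# Validation decisions
# ---------------------------------------------------------------------------

@dataclass
class OrthogonalValidationResult:
    """Per-site three-criterion validation outcome for a technique pair."""

    table: pd.DataFrame
    technique_pair: tuple = ("tech1", "tech2")
    condition: str = "baseline"
    idr_alpha: float = 0.05

    @property
    def validated(self) -> np.ndarray:
        return self.table["validated"].values

    @property
    def n_validated(self) -> int:
        return int(self.table["validated"].sum())


def validate_sites(
    idr_fit: IDRFit,
    calls1,
    calls2,
    site_ids=None,
    idr_alpha: float = 0.05,
    technique_pair=("tech1", "tech2"),
    condition: str = "baseline",
) -> OrthogonalValidationResult:
    """Conjunction of the three validation criteria.

    validated = (global IDR < idr_alpha) AND call in technique 1 AND call
    in technique 2, over an aligned site index.
    """
    calls1 = np.asarray(calls1, dtype=bool)
    calls2 = np.asarray(calls2, dtype=bool)
    n = idr_fit.idr_global.size
    if calls1.size != n or calls2.size != n:
        raise ValueError("calls and IDR vectors must share the site index")
    if site_ids is None:
        site_ids = [str(i) for i in range(n)]
    elif len(site_ids) != n:
        raise ValueError("site_ids length mismatch")
    validated = (idr_fit.idr_global < idr_alpha) & calls1 & calls2
    table = pd.DataFrame(
        {
            "site_id": list(site_ids),
            "idr_local": idr_fit.idr_local,
            "idr_global": idr_fit.idr_global,
            "call_tech1": calls1,
            "call_tech2": calls2,
            "validated": validated,
        }
    )
    return OrthogonalValidationResult(table, tuple(technique_pair), condition, idr_alpha)


def validate_pair(
    m6a1, total1, m6a2, total2,
    site_ids=None,
    min_cov: int = 20,
    idr_alpha: float = 0.05,
    call_alpha: float = 0.05,
    jitter_factor: float = 0.0001,
    seed: int = 0,
    technique_pair=("tech1", "tech2"),
    condition: str = "baseline",
):
    """Full pairwise pipeline on aggregated counts of two techniques.

    Computes jittered beta profiles, applies the pairwise coverage filter,
    fits IDR on the filtered betas, runs binomial calling on the same
    aggregated, filtered site set, and returns the validation result
    together with the fit and the filtered index.
    """
    m6a1, total1 = np.asarray(m6a1), np.asarray(total1)
    m6a2, total2 = np.asarray(m6a2), np.asarray(total2)
    keep = pairwise_coverage_filter(total1, total2, min_cov)
    if site_ids is None:
        site_ids = [str(i) for i in range(total1.size)]
    beta1 = compute_beta(m6a1[keep], total1[keep], jitter_factor, seed)
    beta2 = compute_beta(m6a2[keep], total2[keep], jitter_factor, seed + 1)
    fit = fit_idr(beta1.beta, beta2.beta)
    _, _, calls1 = aggregated_binomial_calls(m6a1[keep], total1[keep], alpha=call_alpha)
    _, _, calls2 = aggregated_binomial_calls(m6a2[keep], total2[keep], alpha=call_alpha)
    result = validate_sites(
        fit, calls1, calls2, [site_ids[i] for i in keep],
        idr_alpha=idr_alpha, technique_pair=technique_pair, condition=condition,
    )
    result.table["beta_tech1"] = beta1.beta
    result.table["beta_tech2"] = beta2.beta
    return result, fit, keep


@dataclass
class DifferentialIDRResult:
    """Validated differential-methylation decision for a technique pair."""

    fit: IDRFit
    index: np.ndarray
    delta1: np.ndarray
    delta2: np.ndarray
    validated: np.ndarray
    degenerate: bool = False

    def to_frame(self, site_ids=None) -> pd.DataFrame:
        ids = [str(i) for i in self.index] if site_ids is None else [site_ids[i] for i in self.index]
        return pd.DataFrame(
            {
                "site_id": ids,
                "delta_beta_tech1": self.delta1,
                "delta_beta_tech2": self.delta2,
                "idr_local": self.fit.idr_local,
                "idr_global": self.fit.idr_global,
                "validated": self.validated,
            }
        )


def differential_idr(
    beta_treated1: BetaProfile,
    beta_control1: BetaProfile,
    beta_treated2: BetaProfile,
    beta_control2: BetaProfile,
    min_cov: int = 20,
    idr_alpha: float = 0.05,
    jitter_factor: float = 0.0001,
    seed: int = 0,
) -> DifferentialIDRResult:
    """IDR on per-technique beta differences (treated − control).

    Sites must pass the coverage filter on all four totals; validated
    differentially methylated sites have global IDR < ``idr_alpha``.
    """
    profiles = (beta_treated1, beta_control1, beta_treated2, beta_control2)
    n = profiles[0].beta.size
    if any(p.beta.size != n for p in profiles):
        raise ValueError("all four beta profiles must share the site index")
    keep = np.flatnonzero(
        (beta_treated1.total >= min_cov) & (beta_control1.total >= min_cov)
        & (beta_treated2.total >= min_cov) & (beta_control2.total >= min_cov)
    )
    if keep.size == 0:
        raise ValueError("no sites pass the coverage filter in all four profiles")
    d1 = beta_treated1.beta[keep] - beta_control1.beta[keep]
    d2 = beta_treated2.beta[keep] - beta_control2.beta[keep]
    if np.unique(d1).size == 1 or np.unique(d2).size == 1:
        warnings.warn("degenerate differential input (all ties before jitter)", RuntimeWarning)
        local = np.ones(keep.size)
        fit = IDRFit(0.0, 1.0, 0.2, 0.5, local, _global_from_local(local), [], False, 0, True)
        return DifferentialIDRResult(fit, keep, d1, d2, np.zeros(keep.size, bool), True)
    rng = np.random.default_rng(seed)
    d1j = _jitter(d1, jitter_factor, rng) if jitter_factor > 0 else d1
    d2j = _jitter(d2, jitter_factor, rng) if jitter_factor > 0 else d2
    fit = fit_idr(d1j, d2j)
    validated = fit.idr_global < idr_alpha
    return DifferentialIDRResult(fit, keep, d1, d2, validated)
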