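"""Uniform site calling.

Two complementary classifiers over the count layers:

* a one-sided binomial test of each site's methylated fraction against the
  sample-wide background rate ``p0 = sum(m6a) / sum(total)``, with
  Benjamini–Hochberg correction restricted to covered sites, and
* a two-component beta-binomial mixture (EM-fitted) yielding per-site
  posterior probabilities of membership in the methylated foreground,
  thresholded at 0.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import betaln, gammaln, logsumexp, expit, logit

from .matrix import MethylationMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Binomial route
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackgroundRate:
    """Sample-wide expected methylation proportion."""

    p0: float

    def __post_init__(self):
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0 must be in [0, 1], got {self.p0}")


def estimate_background_rate(matrix: MethylationMatrix, sample_id: str) -> BackgroundRate:
    """``p0 = sum(m6a_count) / sum(total_count)`` over all sites of a sample."""
    j = matrix.sample_index(sample_id)
    total = int(matrix.layers["total_count"][:, j].sum())
    if total == 0:
        raise ValueError(f"sample {sample_id!r} has zero total coverage")
    return BackgroundRate(int(matrix.layers["m6a_count"][:, j].sum()) / total)


def binomial_test_site(k, n, p0) -> np.ndarray | float:
    """Exact one-sided (greater) binomial tail P(X >= k), X ~ Bin(n, p0).

    ``n = 0`` yields p = 1.  Vectorized over ``k`` and ``n``.
    """
    k_arr = np.atleast_1d(np.asarray(k, dtype=np.int64))
    n_arr = np.broadcast_to(np.atleast_1d(np.asarray(n, dtype=np.int64)), k_arr.shape)
    if np.any(k_arr < 0) or np.any(k_arr > n_arr):
        raise ValueError("require 0 <= k <= n")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    # sf(k-1) is the exact upper tail including k
    p = stats.binom.sf(k_arr - 1, n_arr, p0)
    p = np.where(n_arr == 0, 1.0, p)
    p = np.clip(p, 0.0, 1.0)
    return float(p[0]) if np.isscalar(k) or np.asarray(k).ndim == 0 else p


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, returned in input order.

    ``adj_(i) = min_{j >= i} (p_(j) * m / j)`` capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")[::-1]  # descending
    ranks = np.arange(m, 0, -1)  # m, m-1, ..., 1
    scaled = p[order] * m / ranks
    adj_desc = np.minimum.accumulate(scaled)
    adj = np.empty(m)
    adj[order] = np.minimum(adj_desc, 1.0)
    return adj


def call_sites_binomial(matrix: MethylationMatrix, alpha: float = 0.05) -> MethylationMatrix:
    """Per-sample binomial site calling with BH correction.

    Adds layers ``p_value``, ``bh_p`` and ``binomial_call`` to (a copy of)
    the matrix.  Sites with zero total coverage get p = 1 and are excluded
    from the BH family of their column.
    """
    out = matrix.copy()
    n_sites, n_samples = out.shape
    pval = np.ones((n_sites, n_samples))
    bh = np.ones((n_sites, n_samples))
    call = np.zeros((n_sites, n_samples))
    k_all = out.layers["m6a_count"]
    n_all = out.layers["total_count"]
    for j in range(n_samples):
        n = n_all[:, j]
        covered = n > 0
        if not covered.any():
            continue
        p0 = estimate_background_rate(out, out.sample_ids[j]).p0
        pv = binomial_test_site(k_all[covered, j], n[covered], p0)
        pval[covered, j] = pv
        bh[covered, j] = bh_adjust(pv)
        call[covered, j] = bh[covered, j] < alpha
    out.add_layer("p_value", pval)
    out.add_layer("bh_p", bh)
    out.add_layer("binomial_call", call)
    return out


def aggregated_binomial_calls(k: np.ndarray, n: np.ndarray, alpha: float = 0.05):
    """Binomial calling on one aggregated (k, n) column.

    Returns ``(p_value, bh_p, call)`` vectors; uncovered sites get p = 1,
    bh_p = 1, call = False and do not enter the BH family.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    total = n.sum()
    if total == 0:
        raise ValueError("zero total coverage in aggregated column")
    p0 = k.sum() / total
    pval = np.ones(k.size)
    bh = np.ones(k.size)
    covered = n > 0
    pval[covered] = binomial_test_site(k[covered], n[covered], p0)
    bh[covered] = bh_adjust(pval[covered])
    return pval, bh, bh < alpha


# ---------------------------------------------------------------------------
# Beta-binomial mixture (BBmix)
# ---------------------------------------------------------------------------

@dataclass
class BBmixFit:
    """Fitted two-component beta-binomial mixture.

    Components are ordered so that ``mu_fg > mu_bg``; ``pi`` is the mixing
    weight of the foreground (methylated) component.
    """

    pi: float
    mu_bg: float
    mu_fg: float
    phi_bg: float
    phi_fg: float
    loglik_trace: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    degenerate: bool = False

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1] if self.loglik_trace else -np.inf


def _bb_logpmf(k, n, mu, phi):
    """Beta-binomial log pmf in (mean, concentration) parameterization."""
    a = mu * phi
    b = (1.0 - mu) * phi
    return (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + betaln(k + a, n - k + b) - betaln(a, b)
    )


def _weighted_bb_mle(k, n, w, mu0, phi0):
    """Maximize the w-weighted beta-binomial log-likelihood over (mu, phi)."""

    def neg(params):
        mu = expit(params[0])
        phi = np.exp(params[1])
        return -np.sum(w * _bb_logpmf(k, n, mu, phi))

    x0 = np.array([logit(np.clip(mu0, 1e-4, 1 - 1e-4)), np.log(max(phi0, 1e-3))])
    res = optimize.minimize(neg, x0, method="L-BFGS-B",
                            bounds=[(-12.0, 12.0), (-6.0, 9.0)])
    mu = float(expit(res.x[0]))
    phi = float(np.exp(res.x[1]))
    return mu, phi


def _bbmix_em(k, n, pi, mu, phi, tol, max_iter):
    """EM on fixed initial values; returns (pi, mu[2], phi[2], trace, converged, iters)."""
    trace = []
    pi = float(np.clip(pi, 1e-6, 1 - 1e-6))
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_bg = _bb_logpmf(k, n, mu[0], phi[0]) + np.log1p(-pi)
        log_fg = _bb_logpmf(k, n, mu[1], phi[1]) + np.log(pi)
        norm = logsumexp(np.vstack([log_bg, log_fg]), axis=0)
        ll = float(norm.sum())
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        gamma_fg = np.exp(log_fg - norm)
        pi = float(np.clip(gamma_fg.mean(), 1e-6, 1 - 1e-6))
        mu[0], phi[0] = _weighted_bb_mle(k, n, 1.0 - gamma_fg, mu[0], phi[0])
        mu[1], phi[1] = _weighted_bb_mle(k, n, gamma_fg, mu[1], phi[1])
    return pi, mu, phi, trace, converged, it


def fit_bbmix(
    k,
    n,
    init: tuple | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int | None = 0,
    n_restarts: int = 5,
) -> BBmixFit:
    """EM fit of the two-component beta-binomial mixture.

    Initialization uses the 10th/90th percentiles of k/n with concentration
    10; ``n_restarts`` randomly perturbed restarts (keyed to ``seed``) are
    run and the best-likelihood fit kept.  Components are relabeled so the
    foreground has the larger mean.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    if k.shape != n.shape or k.ndim != 1:
        raise ValueError("k and n must be 1-D vectors of equal length")
    if np.any(k > n) or np.any(k < 0):
        raise ValueError("require 0 <= k <= n")
    keep = n > 0
    k, n = k[keep], n[keep]
    if k.size < 50:
        raise ValueError(f"need >= 50 sites with coverage, got {k.size}")

    degenerate = bool(np.all(k == 0) or np.all(k == n))
    rng = np.random.default_rng(seed)
    ratio = k / n
    if init is not None:
        pi0, mu0, phi0 = init
        mu0 = np.asarray(mu0, dtype=float)
        phi0 = np.asarray(phi0, dtype=float)
    else:
        pi0 = 0.5
        mu0 = np.clip(np.percentile(ratio, [10, 90]), 1e-3, 1 - 1e-3)
        if mu0[1] - mu0[0] < 1e-3:
            mu0 = np.clip(mu0 + np.array([-0.05, 0.05]), 1e-3, 1 - 1e-3)
        phi0 = np.array([10.0, 10.0])

    best = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            pi_i, mu_i, phi_i = pi0, mu0.copy(), phi0.copy()
        else:
            pi_i = float(np.clip(pi0 + rng.uniform(-0.2, 0.2), 0.05, 0.95))
            mu_i = np.sort(np.clip(mu0 * rng.uniform(0.5, 1.5, 2), 1e-3, 1 - 1e-3))
            phi_i = phi0 * rng.uniform(0.5, 2.0, 2)
        pi_f, mu_f, phi_f, trace, conv, iters = _bbmix_em(k, n, pi_i, mu_i, phi_i, tol, max_iter)
        if best is None or trace[-1] > best[3][-1]:
            best = (pi_f, mu_f, phi_f, trace, conv, iters)

    pi_f, mu_f, phi_f, trace, conv, iters = best
    if mu_f[1] < mu_f[0]:  # relabel so foreground has the larger mean
        mu_f = mu_f[::-1]
        phi_f = phi_f[::-1]
        pi_f = 1.0 - pi_f
    if not conv:
        warnings.warn("BBmix EM did not converge within max_iter", RuntimeWarning)
    if degenerate:
        warnings.warn("degenerate BBmix input (all k at a boundary); pi forced to boundary", RuntimeWarning)
        pi_f = 1e-6 if np.all(k == 0) else 1 - 1e-6
    return BBmixFit(
        pi=pi_f, mu_bg=float(mu_f[0]), mu_fg=float(mu_f[1]),
        phi_bg=float(phi_f[0]), phi_fg=float(phi_f[1]),
        loglik_trace=trace, converged=conv, n_iter=iters, degenerate=degenerate,
    )


def bbmix_posterior(fit: BBmixFit, k, n) -> np.ndarray:
    """Posterior probability that each site belongs to the foreground.

    Sites with ``n = 0`` carry no information and receive the prior ``pi``.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    post = np.full(k.shape, fit.pi, dtype=float)
    covered = n > 0
    if covered.any():
        log_fg = np.log(fit.pi) + _bb_logpmf(k[covered], n[covered], fit.mu_fg, fit.phi_fg)
        log_bg = np.log1p(-fit.pi) + _bb_logpmf(k[covered], n[covered], fit.mu_bg, fit.phi_bg)
        post[covered] = np.exp(log_fg - np.logaddexp(log_fg, log_bg))
    if not covered.all():
        logger.info("%d sites with n = 0 received the prior posterior", int((~covered).sum()))
    return np.clip(post, 0.0, 1.0)


def bbmix_classify(fit: BBmixFit, k, n, threshold: float = 0.5) -> np.ndarray:
    """Classify sites as methylated at posterior > threshold."""
    return bbmix_posterior(fit, k, n) > threshold
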