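"""Per-sample quality-control metrics.

Summary statistics, beta-density shape, motif-association ANOVA R-squared,
truth-set accuracy (MCC), and p-value calibration (QQ data).  Report
generation is pure and deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats


def motif_anova_r2(beta, motifs) -> float:
    """ANOVA R-squared of beta grouped by 5-mer motif identity.

    R^2 = between-group SS / total SS; requires >= 2 motif groups with
    >= 2 observations each.
    """
    beta = np.asarray(beta, dtype=float)
    motifs = np.asarray(motifs)
    if beta.shape != motifs.shape:
        raise ValueError("beta and motifs must be aligned")
    ok = ~np.isnan(beta)
    beta, motifs = beta[ok], motifs[ok]
    groups, counts = np.unique(motifs, return_counts=True)
    valid = groups[counts >= 2]
    if valid.size < 2:
        raise ValueError("need >= 2 motif groups with >= 2 observations each")
    keep = np.isin(motifs, valid)
    beta, motifs = beta[keep], motifs[keep]
    grand = beta.mean()
    ss_total = float(((beta - grand) ** 2).sum())
    if ss_total == 0:
        return 0.0
    ss_between = 0.0
    for g in valid:
        sub = beta[motifs == g]
        ss_between += sub.size * (sub.mean() - grand) ** 2
    return float(ss_between / ss_total)


def mcc(calls, truth) -> float:
    """Matthews correlation coefficient of two aligned boolean vectors.

    Returns 0 (with a warning) when any confusion-table marginal is zero.
    """
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have equal length")
    tp = float(np.sum(calls & truth))
    tn = float(np.sum(~calls & ~truth))
    fp = float(np.sum(calls & ~truth))
    fn = float(np.sum(~calls & truth))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        warnings.warn("zero marginal in confusion table; MCC set to 0", RuntimeWarning)
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


@dataclass
class QQData:
    """Expected vs observed p-value quantiles under a uniform null."""

    expected_p: np.ndarray
    observed_p: np.ndarray

    @property
    def expected_neglog10(self) -> np.ndarray:
        return -np.log10(self.expected_p)

    @property
    def observed_neglog10(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return -np.log10(self.observed_p)


def qq_data(p_values) -> QQData:
    """Ranked (expected, observed) pairs; expected = (i − 0.5)/m."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    observed = np.sort(p)
    return QQData(expected, observed)


def bimodality_coefficient(x) -> float:
    """Sarle's bimodality coefficient (BC > ~0.555 suggests bimodality)."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 4:
        raise ValueError("need >= 4 observations")
    g = stats.skew(x, bias=False)
    k = stats.kurtosis(x, bias=False)  # excess kurtosis
    return float((g**2 + 1) / (k + 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


@dataclass
class QCReport:
    """Aggregated per-sample quality metrics."""

    sample_id: str
    n_sites_covered: int
    median_total_coverage: float
    beta_histogram: dict = field(default_factory=dict)
    bimodality: float | None = None
    gc_beta_pearson_r: float | None = None
    motif_r2: float | None = None
    mcc_vs_truth: float | None = None
    qq_expected: list = field(default_factory=list)
    qq_observed: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def qc_report(
    sample_id: str,
    m6a: np.ndarray,
    total: np.ndarray,
    motifs=None,
    gc=None,
    truth=None,
    calls=None,
    p_values=None,
    n_bins: int = 20,
) -> QCReport:
    """Assemble the QC report for a single sample (pure function)."""
    m6a = np.asarray(m6a, dtype=float)
    total = np.asarray(total, dtype=float)
    covered = total > 0
    beta = np.full(m6a.shape, np.nan)
    beta[covered] = m6a[covered] / total[covered]

    density, edges = np.histogram(beta[covered], bins=n_bins, range=(0, 1), density=True)
    report = QCReport(
        sample_id=sample_id,
        n_sites_covered=int(covered.sum()),
        median_total_coverage=float(np.median(total[covered])) if covered.any() else 0.0,
        beta_histogram={"density": density.tolist(), "edges": edges.tolist()},
    )
    if covered.sum() >= 4:
        report.bimodality = bimodality_coefficient(beta[covered])
    if gc is not None:
        gc = np.asarray(gc, dtype=float)
        ok = covered & ~np.isnan(gc)
        if ok.sum() >= 3:
            report.gc_beta_pearson_r = float(stats.pearsonr(gc[ok], beta[ok])[0])
    if motifs is not None:
        try:
            report.motif_r2 = motif_anova_r2(beta, np.asarray(motifs))
        except ValueError:
            report.motif_r2 = None
    if truth is not None and calls is not None:
        report.mcc_vs_truth = mcc(calls, truth)
    if p_values is not None:
        qq = qq_data(p_values)
        report.qq_expected = qq.expected_p.tolist()
        report.qq_observed = qq.observed_p.tolist()
    return report


def feature_fit_summary(features: pd.DataFrame, target, kind: str = "linear") -> pd.DataFrame:
    """Generic feature-table regression hook (user-supplied features).

    ``kind='linear'`` fits OLS of a continuous target on each standardized
    feature; ``kind='logistic'`` scores each feature by the point-biserial
    association with a boolean target.  Returns per-feature coefficient and
    p-value.
    """
    target = np.asarray(target, dtype=float)
    rows = []
    for col in features.columns:
        x = features[col].values.astype(float)
        ok = ~np.isnan(x) & ~np.isnan(target)
        if ok.sum() < 3 or np.std(x[ok]) == 0:
            continue
        if kind == "linear":
            r, p = stats.pearsonr(x[ok], target[ok])
            coef = r * np.std(target[ok]) / np.std(x[ok])
        elif kind == "logistic":
            r, p = stats.pointbiserialr(target[ok].astype(bool), x[ok])
            coef = r
        else:
            raise ValueError(f"unknown kind {kind!r}")
        rows.append({"feature": col, "coef": float(coef), "p_value": float(p)})
    return pd.DataFrame(rows)
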