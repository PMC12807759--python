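"""IVT negative-control calibration.

In-vitro-transcribed (IVT) samples are modification-free, so any site the
binomial caller flags in them is a technique artifact.  Counts at those
sites are zeroed across every sample of the technique, making the masked
rows drop out of all downstream aggregation self-consistently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .calling import aggregated_binomial_calls
from .matrix import MethylationMatrix

logger = logging.getLogger(__name__)


@dataclass
class FalsePositiveMask:
    """Boolean per-site mask of IVT-flagged false-positive sites."""

    mask: np.ndarray
    ivt_sample_ids: list = field(default_factory=list)
    alpha: float = 0.05
    technique: str = "unknown"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())


def flag_ivt_false_positives(
    matrix: MethylationMatrix, ivt_sample_ids, alpha: float = 0.05
) -> FalsePositiveMask:
    """Binomial site-calling on counts aggregated over the IVT samples.

    Multiple IVT samples are aggregated by summation before calling; the
    mask holds the BH-called sites.
    """
    ivt_sample_ids = list(ivt_sample_ids)
    if not ivt_sample_ids:
        raise ValueError("no IVT samples given")
    for sid in ivt_sample_ids:
        rec = matrix.get_sample(sid)
        if not rec.is_ivt:
            raise ValueError(f"sample {sid!r} is not flagged is_ivt")
    idx = [matrix.sample_index(s) for s in ivt_sample_ids]
    k = matrix.layers["m6a_count"][:, idx].sum(axis=1)
    n = matrix.layers["total_count"][:, idx].sum(axis=1)
    technique = matrix.get_sample(ivt_sample_ids[0]).technique
    if n.sum() == 0:
        logger.warning("IVT samples have zero coverage everywhere; empty mask")
        mask = np.zeros(len(matrix.site_ids), dtype=bool)
    else:
        _, _, mask = aggregated_binomial_calls(k, n, alpha=alpha)
    return FalsePositiveMask(mask, ivt_sample_ids, alpha, technique)


def mask_sites(matrix: MethylationMatrix, mask: FalsePositiveMask | np.ndarray) -> MethylationMatrix:
    """Zero both count layers at masked rows for every sample (idempotent)."""
    vec = mask.mask if isinstance(mask, FalsePositiveMask) else np.asarray(mask, dtype=bool)
    if vec.shape != (len(matrix.site_ids),):
        raise ValueError(f"mask length {vec.shape} does not match {len(matrix.site_ids)} sites")
    out = matrix.copy()
    out.layers["m6a_count"][vec, :] = 0
    out.layers["total_count"][vec, :] = 0
    return out
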