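"""Sites × samples count container and sample metadata.

The :class:`MethylationMatrix` holds the two integer count layers
(``m6a_count`` and ``total_count``) plus any derived real-valued layers
(p-values, posteriors) over a shared row space of site ids and a column
space of :class:`SampleRecord`.  Count layers are dense — zeros, not gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("antibody", "enzyme", "chemical", "direct")

COUNT_LAYERS = ("m6a_count", "total_count")


@dataclass
class SampleRecord:
    """Metadata for one sequencing sample."""

    sample_id: str
    technique: str = "unknown"
    category: str = "chemical"
    condition: str = "baseline"
    is_baseline: bool = True
    is_ivt: bool = False
    cell_or_tissue: str = "unknown"
    paired_input_id: str | None = None
    stranded: bool = True

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}, got {self.category!r}")


class MethylationMatrix:
    """Dense sites × samples container with named layers.

    Invariants enforced at construction and on layer assignment: counts are
    non-negative integers, ``m6a_count <= total_count`` elementwise, and all
    layers share the same shape.
    """

    def __init__(
        self,
        site_ids: Sequence[str],
        samples: Sequence[SampleRecord],
        m6a_count: np.ndarray,
        total_count: np.ndarray,
    ):
        self.site_ids = list(site_ids)
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("duplicate site_id in row space")
        self.samples = list(samples)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in column space")
        shape = (len(self.site_ids), len(self.samples))
        m6a = np.asarray(m6a_count)
        tot = np.asarray(total_count)
        if m6a.shape != shape or tot.shape != shape:
            raise ValueError(f"count layers must have shape {shape}")
        if np.any(m6a < 0) or np.any(tot < 0):
            raise ValueError("counts must be non-negative")
        if np.any(m6a > tot):
            raise ValueError("m6a_count must be <= total_count elementwise")
        self.layers: dict[str, np.ndarray] = {
            "m6a_count": m6a.astype(np.int64),
            "total_count": tot.astype(np.int64),
        }

    # -- basic accessors ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.site_ids), len(self.samples))

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample_id {sample_id!r}") from None

    def get_sample(self, sample_id: str) -> SampleRecord:
        return self.samples[self.sample_index(sample_id)]

    def add_layer(self, name: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise ValueError(f"layer {name!r} must have shape {self.shape}")
        self.layers[name] = values

    def layer(self, name: str) -> np.ndarray:
        return self.layers[name]

    # -- views -------------------------------------------------------------
    def subset_samples(self, sample_ids: Iterable[str]) -> "MethylationMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        out = MethylationMatrix(
            self.site_ids,
            [self.samples[i] for i in idx],
            self.layers["m6a_count"][:, idx],
            self.layers["total_count"][:, idx],
        )
        for name, vals in self.layers.items():
            if name not in COUNT_LAYERS:
                out.layers[name] = vals[:, idx]
        return out

    def copy(self) -> "MethylationMatrix":
        out = MethylationMatrix(
            self.site_ids, list(self.samples),
            self.layers["m6a_count"].copy(), self.layers["total_count"].copy(),
        )
        for name, vals in self.layers.items():
            if name not in COUNT_LAYERS:
                out.layers[name] = vals.copy()
        return out

    def layer_frame(self, name: str) -> pd.DataFrame:
        return pd.DataFrame(self.layers[name], index=self.site_ids, columns=self.sample_ids)

    # -- serialization -----------------------------------------------------
    def to_tsv(self, prefix) -> None:
        """Write each layer to ``<prefix>.<layer>.tsv`` plus sample metadata CSV."""
        prefix = Path(prefix)
        for name in self.layers:
            self.layer_frame(name).to_csv(f"{prefix}.{name}.tsv", sep="\t", index_label="site_id")
        pd.DataFrame([asdict(s) for s in self.samples]).to_csv(f"{prefix}.samples.csv", index=False)

    @classmethod
    def from_tsv(cls, prefix, extra_layers: Sequence[str] = ()) -> "MethylationMatrix":
        prefix = Path(prefix)
        m6a = pd.read_csv(f"{prefix}.m6a_count.tsv", sep="\t", index_col="site_id")
        tot = pd.read_csv(f"{prefix}.total_count.tsv", sep="\t", index_col="site_id")
        meta = pd.read_csv(f"{prefix}.samples.csv")
        meta = meta.where(pd.notna(meta), None)
        samples = [SampleRecord(**{k: rec[k] for k in rec.index}) for _, rec in meta.iterrows()]
        out = cls(list(m6a.index), samples, m6a.values, tot.values)
        for name in extra_layers:
            df = pd.read_csv(f"{prefix}.{name}.tsv", sep="\t", index_col="site_id")
            out.add_layer(name, df.values)
        return out


def assemble_matrix(
    count_vectors: dict[str, tuple[np.ndarray, np.ndarray]],
    site_ids: Sequence[str],
    samples: Sequence[SampleRecord],
) -> MethylationMatrix:
    """Column-bind per-sample (m6a, total) vectors into a matrix.

    ``count_vectors`` maps sample_id to its pair of length-``len(site_ids)``
    vectors; samples are bound in the order of ``samples``.
    """
    n = len(site_ids)
    m6a = np.zeros((n, len(samples)), dtype=np.int64)
    tot = np.zeros((n, len(samples)), dtype=np.int64)
    for j, rec in enumerate(samples):
        if rec.sample_id not in count_vectors:
            raise ValueError(f"missing count vectors for sample {rec.sample_id!r}")
        k, t = count_vectors[rec.sample_id]
        k, t = np.asarray(k), np.asarray(t)
        if k.shape != (n,) or t.shape != (n,):
            raise ValueError(f"count vector length mismatch for {rec.sample_id!r}: expected {n}")
        m6a[:, j] = k
        tot[:, j] = t
    return MethylationMatrix(site_ids, samples, m6a, tot)
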