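"""Reference adenosine site sets.

Builds the universal row space for all downstream matrices: strand-aware,
single-base adenosine loci carrying their sense-strand 5-mer context.  Sites
come from two sources — a DRACH consensus scan over (canonical) exons, and
externally supplied site lists imported verbatim — and are merged by the
(chrom, pos, strand) key.

Coordinate conventions: in-memory positions are 1-based (the position of the
A on its strand's sense sequence); BED I/O converts to 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

# D=[AGT], R=[AG], A (methylated, center), C, H=[ACT]; lookahead for overlaps
_DRACH_RE = re.compile(r"(?=([AGT][AG]AC[ACT]))")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

MOTIF_LEN = 5
MOTIF_CENTER = 2  # 0-based index of the methylated A


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicSite:
    """A single-base adenosine locus on a strand's sense sequence."""

    chrom: str
    pos: int  # 1-based
    strand: str
    motif: str = "NNANN"
    site_id: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.motif) != MOTIF_LEN or self.motif[MOTIF_CENTER].upper() not in "AN":
            raise ValueError(f"motif must be a 5-mer centered on A, got {self.motif!r}")
        if not self.site_id:
            object.__setattr__(self, "site_id", f"{self.chrom}:{self.pos}:{self.strand}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.strand)


class ReferenceSiteSet:
    """Ordered, de-duplicated collection of :class:`GenomicSite`.

    Sites are unique by (chrom, pos, strand) and kept sorted by that key.
    Each site carries a provenance label (e.g. ``"DRACH-exonic"``,
    ``"external"``); merging concatenates labels with ``","``.
    """

    def __init__(self, sites: Iterable[GenomicSite] = (), provenance: Iterable[str] | str = "unknown"):
        sites = list(sites)
        if isinstance(provenance, str):
            provenance = [provenance] * len(sites)
        else:
            provenance = list(provenance)
        if len(provenance) != len(sites):
            raise ValueError("provenance length must match number of sites")
        seen: dict[tuple, int] = {}
        kept_sites: list[GenomicSite] = []
        kept_prov: list[str] = []
        for s, p in zip(sites, provenance):
            if s.key in seen:
                continue
            seen[s.key] = len(kept_sites)
            kept_sites.append(s)
            kept_prov.append(p)
        order = sorted(range(len(kept_sites)), key=lambda i: kept_sites[i].key)
        self._sites = [kept_sites[i] for i in order]
        self._provenance = [kept_prov[i] for i in order]
        ids = [s.site_id for s in self._sites]
        if len(set(ids)) != len(ids):
            raise ValueError("site_id values must be unique within a set")
        self._index = {s.key: i for i, s in enumerate(self._sites)}

    def __len__(self) -> int:
        return len(self._sites)

    def __iter__(self) -> Iterator[GenomicSite]:
        return iter(self._sites)

    def __getitem__(self, i: int) -> GenomicSite:
        return self._sites[i]

    def __contains__(self, site: GenomicSite) -> bool:
        return site.key in self._index

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReferenceSiteSet):
            return NotImplemented
        return [s.key for s in self._sites] == [s.key for s in other._sites]

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self._sites]

    @property
    def provenance(self) -> list[str]:
        return list(self._provenance)

    def provenance_of(self, site: GenomicSite) -> str:
        return self._provenance[self._index[site.key]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self._sites],
                "pos": [s.pos for s in self._sites],
                "strand": [s.strand for s in self._sites],
                "motif": [s.motif for s in self._sites],
                "site_id": [s.site_id for s in self._sites],
                "provenance": self._provenance,
            }
        )


def _canonical_transcripts(exons: pd.DataFrame) -> pd.DataFrame:
    """Restrict an exon table to canonical transcripts.

    Uses the boolean ``canonical`` column when present; otherwise falls back
    to the longest transcript (summed exon length) per gene.
    """
    if "canonical" in exons.columns and exons["canonical"].any():
        return exons[exons["canonical"].astype(bool)]
    lengths = (
        exons.assign(_len=exons["end"] - exons["start"] + 1)
        .groupby(["gene_id", "transcript_id"])["_len"]
        .sum()
        .reset_index()
    )
    best = lengths.sort_values(["gene_id", "_len", "transcript_id"]).groupby("gene_id").tail(1)
    return exons[exons["transcript_id"].isin(best["transcript_id"])]


def scan_drach(genome: Mapping[str, str], exons: pd.DataFrame) -> ReferenceSiteSet:
    """Scan canonical exon sequences for DRACH motifs.

    Parameters
    ----------
    genome
        Mapping of chromosome name to forward-strand sequence (or any object
        with dict-like ``[]`` access returning strings, e.g. an open FASTA).
    exons
        Columns ``chrom, start, end, strand, transcript_id, gene_id`` with
        1-based inclusive coordinates, plus optional boolean ``canonical``.

    Returns every exonic position whose sense-strand 5-mer matches
    ``[AGT][AG]AC[ACT]``; minus-strand exons are scanned on the reverse
    complement and the site is reported at the genomic coordinate of the A.
    Motif windows incomplete at exon edges are skipped; duplicates across
    overlapping transcripts collapse to one site.
    """
    required = {"chrom", "start", "end", "strand", "transcript_id", "gene_id"}
    missing = required - set(exons.columns)
    if missing:
        raise ValueError(f"exon table missing columns: {sorted(missing)}")
    exons = _canonical_transcripts(exons)
    found: dict[tuple, GenomicSite] = {}
    for row in exons.itertuples(index=False):
        chrom_seq = genome[row.chrom]
        if row.start < 1 or row.end > len(chrom_seq):
            raise ValueError(
                f"exon {row.chrom}:{row.start}-{row.end} outside sequence bounds (len={len(chrom_seq)})"
            )
        genomic = chrom_seq[row.start - 1 : row.end].upper()
        if re.search(r"[^ACGTN]", genomic):
            logger.warning("non-ACGTN characters in %s:%s-%s; positions skipped", row.chrom, row.start, row.end)
        sense = genomic if row.strand == "+" else reverse_complement(genomic)
        for m in _DRACH_RE.finditer(sense):
            motif = m.group(1)
            i = m.start()  # offset of motif start in sense sequence
            if row.strand == "+":
                pos = row.start + i + MOTIF_CENTER
            else:
                pos = row.end - (i + MOTIF_CENTER)
            site = GenomicSite(row.chrom, pos, row.strand, motif)
            found.setdefault(site.key, site)
    return ReferenceSiteSet(found.values(), "DRACH-exonic")


def merge_site_sets(a: ReferenceSiteSet, b: ReferenceSiteSet) -> ReferenceSiteSet:
    """Union of two site sets keyed by (chrom, pos, strand).

    Provenance labels are concatenated at shared keys; on motif conflict the
    motif from ``a`` wins (with a warning).
    """
    merged: dict[tuple, GenomicSite] = {}
    prov: dict[tuple, str] = {}
    for s in a:
        merged[s.key] = s
        prov[s.key] = a.provenance_of(s)
    for s in b:
        p = b.provenance_of(s)
        if s.key in merged:
            if merged[s.key].motif != s.motif:
                logger.warning("motif conflict at %s: keeping %r", s.key, merged[s.key].motif)
            labels = prov[s.key].split(",")
            if p not in labels:
                prov[s.key] = prov[s.key] + "," + p
        else:
            merged[s.key] = s
            prov[s.key] = p
    keys = sorted(merged)
    return ReferenceSiteSet([merged[k] for k in keys], [prov[k] for k in keys])


def write_sites_bed(sites: ReferenceSiteSet, path) -> None:
    """Write a site set as BED6 (0-based half-open single-base intervals)."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{s.site_id}\t0\t{s.strand}\n")


def read_sites_bed(path, provenance: str = "external") -> ReferenceSiteSet:
    """Read a BED6 file of single-base sites; output is sorted in memory."""
    sites = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{ln}: BED6 requires 6 columns (strand missing?)")
            chrom, start, end, name, _score, strand = fields[:6]
            start, end = int(start), int(end)
            if end - start != 1:
                raise ValueError(f"{path}:{ln}: interval width must be 1, got {end - start}")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{ln}: invalid strand {strand!r}")
            sites.append(GenomicSite(chrom, start + 1, strand, site_id=name or ""))
    return ReferenceSiteSet(sites, provenance)


def read_gtf_exons(path) -> pd.DataFrame:
    """Extract an exon table from a GTF file.

    Returns columns ``chrom, start, end, strand, transcript_id, gene_id,
    canonical`` (1-based inclusive, per GTF). A transcript is flagged
    canonical when any of its exon lines carries ``tag "canonical"``.
    """
    rows = []
    attr_re = re.compile(r'(\w+) "([^"]*)"')
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            attrs = dict(attr_re.findall(f[8]))
            canonical = 'tag "canonical"' in f[8] or attrs.get("tag") == "canonical"
            rows.append(
                {
                    "chrom": f[0],
                    "start": int(f[3]),
                    "end": int(f[4]),
                    "strand": f[6],
                    "transcript_id": attrs.get("transcript_id", ""),
                    "gene_id": attrs.get("gene_id", ""),
                    "canonical": canonical,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "transcript_id", "gene_id", "canonical"])


def read_fasta(path) -> dict[str, str]:
    """Load a (small) FASTA file into a name → sequence dict."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}
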