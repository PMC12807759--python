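"""Per-site read counting under the two technique contracts, plus RPKM.

Two counting modes map alignments onto a reference site set:

* ``count_ip_input`` — enrichment assays: the m6a signal is the number of IP
  fragments overlapping the single-base site, and the total is the IP count
  plus the analogous count from the paired input sample.
* ``count_conversion_pileup`` — base-conversion chemistries: a per-site
  pileup where the read base observed at the site (on the site's sense
  strand) decides whether the read is methylated evidence.

No post-alignment MAPQ or duplicate filtering is applied here; upstream
filtering is the caller's responsibility.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager

import numpy as np
import pysam

from .sites import ReferenceSiteSet, _COMPLEMENT

logger = logging.getLogger(__name__)

DEFAULT_CONVERSION_RULE = {"m6a_bases": frozenset("A"), "total_bases": frozenset("AG")}


@contextmanager
def _open_alignments(alignments):
    if isinstance(alignments, pysam.AlignmentFile):
        yield alignments
    else:
        mode = "rb" if str(alignments).endswith(".bam") else "r"
        af = pysam.AlignmentFile(str(alignments), mode, check_sq=False)
        try:
            yield af
        finally:
            af.close()


def _site_lookup(sites: ReferenceSiteSet):
    """Index sites by (chrom, strand) -> (sorted positions, row indices)."""
    by_key: dict[tuple, list] = {}
    for i, s in enumerate(sites):
        by_key.setdefault((s.chrom, s.strand), []).append((s.pos, i))
    out = {}
    for key, pairs in by_key.items():
        pairs.sort()
        out[key] = (np.array([p for p, _ in pairs]), np.array([i for _, i in pairs]))
    return out


def _warn_missing_chroms(af: pysam.AlignmentFile, sites: ReferenceSiteSet) -> None:
    refs = set(af.references or ())
    missing = {s.chrom for s in sites} - refs
    if missing and refs:
        logger.warning("site chromosomes absent from alignment header: %s (counted as 0)", sorted(missing))


def _iter_fragments(af: pysam.AlignmentFile):
    """Yield (chrom, start1, end1, strand) fragment spans, mates unified.

    Properly-paired mates are merged into one template span and yielded once
    (at the leftmost mate); single-end and non-properly-paired reads are
    yielded individually.
    """
    for read in af:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        chrom = read.reference_name
        if read.is_paired and read.is_proper_pair and read.template_length != 0:
            if read.template_length < 0:
                continue  # rightmost mate: the leftmost one emits the fragment
            start1 = read.reference_start + 1
            end1 = read.reference_start + read.template_length
            # library strand taken from read1 orientation
            fwd = (read.is_read1 and not read.is_reverse) or (read.is_read2 and read.is_reverse)
            strand = "+" if fwd else "-"
        else:
            start1 = read.reference_start + 1
            end1 = read.reference_end
            strand = "-" if read.is_reverse else "+"
        yield chrom, start1, end1, strand


def _count_overlaps(alignments, sites: ReferenceSiteSet, stranded: bool) -> np.ndarray:
    lookup = _site_lookup(sites)
    counts = np.zeros(len(sites), dtype=np.int64)
    with _open_alignments(alignments) as af:
        _warn_missing_chroms(af, sites)
        for chrom, start1, end1, strand in _iter_fragments(af):
            strands = (strand,) if stranded else ("+", "-")
            for st in strands:
                entry = lookup.get((chrom, st))
                if entry is None:
                    continue
                pos, rows = entry
                lo = np.searchsorted(pos, start1, side="left")
                hi = np.searchsorted(pos, end1, side="right")
                if hi > lo:
                    counts[rows[lo:hi]] += 1
    return counts


def count_ip_input(
    ip_alignments,
    input_alignments,
    sites: ReferenceSiteSet,
    stranded: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Fragment-overlap counting for IP/input assay pairs.

    Returns ``(m6a, total)`` where ``m6a`` is the per-site IP fragment count
    and ``total = m6a + input fragment count``.  Paired mates of one fragment
    are counted once.
    """
    m6a = _count_overlaps(ip_alignments, sites, stranded)
    inp = _count_overlaps(input_alignments, sites, stranded)
    return m6a, m6a + inp


def count_conversion_pileup(
    alignments,
    sites: ReferenceSiteSet,
    rule: dict = None,
    stranded: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-base pileup counting for conversion chemistries.

    ``rule`` names the read bases (on the site's sense strand) counting as
    methylated evidence (``m6a_bases``) and as informative coverage
    (``total_bases``).  Reads with a deletion or N at the site are excluded
    from both counts; minus-strand sites are read complement-aware.
    """
    rule = dict(DEFAULT_CONVERSION_RULE if rule is None else rule)
    m6a_bases = {b.upper() for b in rule["m6a_bases"]}
    total_bases = {b.upper() for b in rule["total_bases"]}
    if not m6a_bases or not total_bases:
        raise ValueError("conversion rule base sets must be non-empty")

    lookup = _site_lookup(sites)
    strands = [s.strand for s in sites]
    m6a = np.zeros(len(sites), dtype=np.int64)
    total = np.zeros(len(sites), dtype=np.int64)
    with _open_alignments(alignments) as af:
        _warn_missing_chroms(af, sites)
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            read_strand = "-" if read.is_reverse else "+"
            site_strands = (read_strand,) if stranded else ("+", "-")
            seq = read.query_sequence
            if seq is None:
                continue
            pairs = None
            for st in site_strands:
                entry = lookup.get((read.reference_name, st))
                if entry is None:
                    continue
                pos, rows = entry
                lo = np.searchsorted(pos, read.reference_start + 1, side="left")
                hi = np.searchsorted(pos, read.reference_end, side="right")
                if hi <= lo:
                    continue
                if pairs is None:
                    pairs = {rpos + 1: qpos for qpos, rpos in read.get_aligned_pairs() if rpos is not None}
                for p, row in zip(pos[lo:hi], rows[lo:hi]):
                    qpos = pairs.get(int(p))
                    if qpos is None:
                        continue  # deletion at the site
                    base = seq[qpos].upper()
                    if base == "N":
                        continue
                    if strands[row] == "-":
                        base = base.translate(_COMPLEMENT)
                    if base in total_bases:
                        total[row] += 1
                        if base in m6a_bases:
                            m6a[row] += 1
    return m6a, total


def compute_rpkm(gene_counts, gene_lengths_bp, library_size) -> np.ndarray:
    """RPKM = count / (length/1000 * library_size/1e6)."""
    counts = np.asarray(gene_counts, dtype=float)
    lengths = np.asarray(gene_lengths_bp, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return counts / (lengths / 1e3 * library_size / 1e6)
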