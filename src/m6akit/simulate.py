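"""Synthetic fixture generators.

Every downstream stage gets a closed-loop test bed: a toy genome with
annotation, beta-binomial methylation count matrices with planted truth,
expression-matched IVT nulls, correlated two-technique profiles with a
reproducible component, simulated aligned reads, and genotype cohorts with
planted cis effects.  All generators are deterministic given (parameters,
seed) and record a :class:`SimulationTruth` sidecar.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import MethylationMatrix, SampleRecord, assemble_matrix
from .sites import GenomicSite, ReferenceSiteSet, reverse_complement, _DRACH_RE

_DRACH_ALPHABET = ("AGT", "AG", "A", "C", "ACT")


@dataclass
class SimulationTruth:
    """Planted ground truth plus the generator parameters and seed."""

    generator: str
    seed: int | None
    params: dict = field(default_factory=dict)
    data: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, (np.bool_,)):
                return bool(o)
            raise TypeError(type(o))

        text = json.dumps({"generator": self.generator, "seed": self.seed,
                           "params": self.params, "data": self.data}, default=default)
        if path is not None:
            Path(path).write_text(text)
        return text


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    """Negative-binomial depths with var = mean + dispersion * mean^2."""
    if dispersion <= 0:
        return np.full(size, int(round(mean)), dtype=np.int64)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size).astype(np.int64)


# ---------------------------------------------------------------------------
# Toy genome + annotation
# ---------------------------------------------------------------------------

def _scan_exon_drach(seq: str, start: int, end: int, strand: str):
    """Generator-side oracle: regex scan of one exon's sense sequence."""
    genomic = seq[start - 1:end].upper()
    sense = genomic if strand == "+" else reverse_complement(genomic)
    out = []
    for m in _DRACH_RE.finditer(sense):
        i = m.start()
        pos = start + i + 2 if strand == "+" else end - (i + 2)
        out.append((pos, m.group(1)))
    return out


def make_toy_genome(
    n_chrom: int = 2,
    length: int = 50000,
    n_genes: int = 20,
    seed: int | None = 0,
    fasta_path=None,
    gtf_path=None,
):
    """Random toy genome with planted DRACH motifs and a valid gene model.

    Returns ``(genome: dict, exons: DataFrame, truth)``; truth records all
    DRACH sites inside canonical exons (found by an independent regex scan
    over each exon, both strands handled).  Optionally writes FASTA/GTF.
    """
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    for c in range(n_chrom):
        seq = rng.choice(list("ACGT"), size=length)
        genome[f"chr{c + 1}"] = "".join(seq)

    # plant explicit DRACH motifs at random spots so every genome has signal
    planted = []
    for chrom in genome:
        arr = list(genome[chrom])
        for _ in range(max(5, length // 2000)):
            start = int(rng.integers(0, length - 5))
            motif = "".join(rng.choice(list(a)) for a in _DRACH_ALPHABET)
            arr[start:start + 5] = motif
            planted.append((chrom, start + 1, motif))
        genome[chrom] = "".join(arr)

    exon_rows = []
    gid = 0
    for chrom in genome:
        genes_here = n_genes // n_chrom + (1 if chrom == "chr1" else 0) * (n_genes % n_chrom)
        if genes_here == 0:
            continue
        span = length // max(genes_here, 1)
        for g in range(genes_here):
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            g_start = g * span + int(rng.integers(1, max(2, span // 10)))
            g_end = min((g + 1) * span - 1, length)
            if g_end - g_start < 300:
                continue
            n_exons = int(rng.integers(1, 6))
            cuts = np.sort(rng.integers(g_start, g_end, size=2 * n_exons))
            for e in range(n_exons):
                s, t = int(cuts[2 * e]), int(cuts[2 * e + 1])
                if t - s < 20:
                    t = min(s + 20, g_end)
                t = min(t, length - 1)
                exon_rows.append({
                    "chrom": chrom, "start": s + 1, "end": t + 1,
                    "strand": strand, "transcript_id": f"tx{gid}",
                    "gene_id": f"gene{gid}", "canonical": True,
                })
    exons = pd.DataFrame(
        exon_rows,
        columns=["chrom", "start", "end", "strand", "transcript_id", "gene_id", "canonical"],
    )

    drach_sites: dict[tuple, str] = {}
    for row in exons.itertuples(index=False):
        for pos, motif in _scan_exon_drach(genome[row.chrom], row.start, row.end, row.strand):
            drach_sites.setdefault((row.chrom, pos, row.strand), motif)

    truth = SimulationTruth(
        "make_toy_genome", seed,
        {"n_chrom": n_chrom, "length": length, "n_genes": n_genes},
        {
            "planted_motifs": [list(p) for p in planted],
            "exonic_drach_sites": sorted([list(k) + [v] for k, v in drach_sites.items()]),
        },
    )

    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for chrom, seq in genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
    if gtf_path is not None:
        write_gtf(exons, gtf_path)
    return genome, exons, truth


def write_gtf(exons: pd.DataFrame, path) -> None:
    """Write an exon table as GTF (canonical flag emitted as a tag)."""
    with open(path, "w") as fh:
        for row in exons.itertuples(index=False):
            tag = ' tag "canonical";' if getattr(row, "canonical", False) else ""
            attrs = f'gene_id "{row.gene_id}"; transcript_id "{row.transcript_id}";{tag}'
            fh.write(
                f"{row.chrom}\ttoy\texon\t{row.start}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Methylome count matrices
# ---------------------------------------------------------------------------

def simulate_methylome(
    n_sites: int = 1000,
    n_samples: int = 1,
    pi: float = 0.2,
    theta_fg=(6.0, 4.0),
    theta_bg=(1.0, 50.0),
    depth_mean: float = 50.0,
    depth_dispersion: float = 0.3,
    seed: int | None = 0,
    site_ids=None,
    sample_prefix: str = "sim",
    technique: str = "GLORI",
    category: str = "chemical",
) -> tuple[MethylationMatrix, SimulationTruth]:
    """Beta-binomial methylome with a planted foreground component.

    Each site is foreground with probability ``pi``; its true theta is drawn
    from Beta(*theta_fg*) (foreground) or Beta(*theta_bg*) (background) —
    pass a float instead of a tuple for a fixed theta.  Depths are
    negative-binomial; ``k ~ Binomial(n, theta)`` per cell.
    """
    rng = np.random.default_rng(seed)
    state = rng.random(n_sites) < pi

    def draw_theta(spec, size):
        if np.isscalar(spec):
            return np.full(size, float(spec))
        return rng.beta(spec[0], spec[1], size=size)

    theta = np.where(state, draw_theta(theta_fg, n_sites), draw_theta(theta_bg, n_sites))
    if site_ids is None:
        site_ids = [f"s{i}" for i in range(n_sites)]
    vectors = {}
    samples = []
    for j in range(n_samples):
        n = _nb_depth(rng, depth_mean, depth_dispersion, n_sites)
        k = rng.binomial(n, theta)
        sid = f"{sample_prefix}{j}"
        vectors[sid] = (k, n)
        samples.append(SampleRecord(sid, technique=technique, category=category))
    matrix = assemble_matrix(vectors, site_ids, samples)
    truth = SimulationTruth(
        "simulate_methylome", seed,
        {"n_sites": n_sites, "n_samples": n_samples, "pi": pi,
         "theta_fg": theta_fg, "theta_bg": theta_bg,
         "depth_mean": depth_mean, "depth_dispersion": depth_dispersion},
        {"foreground": state, "theta": theta},
    )
    return matrix, truth


def simulate_ivt(
    total_profile,
    error_rate: float = 0.01,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Modification-free IVT sample matched to an expression profile.

    ``k ~ Binomial(n, error_rate)`` with n taken from ``total_profile``.
    """
    n = np.asarray(total_profile, dtype=np.int64)
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    k = rng.binomial(n, error_rate)
    return k, n


# ---------------------------------------------------------------------------
# Read-level simulation (SAM)
# ---------------------------------------------------------------------------

_SAM_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def simulate_reads(
    site: GenomicSite,
    k: int,
    n: int,
    genome: dict,
    read_len: int = 50,
    converted_base: str = "G",
    seed: int | None = 0,
) -> list[str]:
    """SAM records for one site's pileup cell: k methylated of n reads.

    Methylated reads show the sense-strand A at the site; converted reads
    show ``converted_base`` (default G, the A→G chemistry).  Reads are
    all-match CIGAR, placed at random offsets covering the site, written in
    genomic (forward) orientation with the FLAG carrying strand.
    """
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    rng = np.random.default_rng(seed)
    chrom_seq = genome[site.chrom].upper()
    records = []
    for i in range(n):
        methylated = i < k
        max_start = min(site.pos, len(chrom_seq) - read_len + 1)
        min_start = max(1, site.pos - read_len + 1)
        start = int(rng.integers(min_start, max_start + 1))
        seq = list(chrom_seq[start - 1:start - 1 + read_len])
        sense_base = "A" if methylated else converted_base.upper()
        genomic_base = sense_base if site.strand == "+" else sense_base.translate(_SAM_COMPLEMENT)
        seq[site.pos - start] = genomic_base
        flag = 0 if site.strand == "+" else 16
        records.append(
            f"read_{site.site_id}_{i}\t{flag}\t{site.chrom}\t{start}\t60\t{read_len}M\t*\t0\t0\t"
            f"{''.join(seq)}\t{'I' * read_len}"
        )
    return records


def write_sam(records: list[str], genome: dict, path) -> None:
    """Write SAM records with an @SQ header derived from the genome dict."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, seq in genome.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(seq)}\n")
        for rec in records:
            fh.write(rec + "\n")


def simulate_overlap_reads(
    site: GenomicSite,
    n_ip: int,
    n_input: int,
    genome: dict,
    read_len: int = 50,
    seed: int | None = 0,
) -> tuple[list[str], list[str]]:
    """Single-end IP and input reads overlapping a site (for IP/input mode)."""
    rng = np.random.default_rng(seed)
    chrom_seq = genome[site.chrom].upper()

    def make(count, label):
        out = []
        for i in range(count):
            max_start = min(site.pos, len(chrom_seq) - read_len + 1)
            min_start = max(1, site.pos - read_len + 1)
            start = int(rng.integers(min_start, max_start + 1))
            seq = chrom_seq[start - 1:start - 1 + read_len]
            out.append(
                f"{label}_{site.site_id}_{i}\t0\t{site.chrom}\t{start}\t60\t{read_len}M\t*\t0\t0\t"
                f"{seq}\t{'I' * read_len}"
            )
        return out

    return make(n_ip, "ip"), make(n_input, "inp")


# ---------------------------------------------------------------------------
# Correlated technique pairs
# ---------------------------------------------------------------------------

def simulate_technique_pair(
    n_sites: int = 5000,
    reproducible_fraction: float = 0.2,
    depth1: float = 50.0,
    depth2: float = 50.0,
    depth_dispersion: float = 0.3,
    noise_sd: float = 0.0,
    theta_signal=(6.0, 4.0),
    theta_noise=(1.0, 50.0),
    seed: int | None = 0,
):
    """Two aggregated count vectors sharing a reproducible component.

    Reproducible sites share one theta (from Beta(*theta_signal*)) across
    both techniques (optionally perturbed by logit-normal noise of SD
    ``noise_sd``); the rest draw independent thetas from Beta(*theta_noise*)
    per technique.  Returns ``((k1, n1), (k2, n2), truth)``.
    """
    rng = np.random.default_rng(seed)
    reproducible = rng.random(n_sites) < reproducible_fraction
    theta_shared = rng.beta(*theta_signal, size=n_sites)

    def technique_counts(depth):
        theta_ind = rng.beta(*theta_noise, size=n_sites)
        theta = np.where(reproducible, theta_shared, theta_ind)
        if noise_sd > 0:
            logits = np.log(theta / (1 - theta)) + rng.normal(0, noise_sd, n_sites)
            theta = np.where(reproducible, 1 / (1 + np.exp(-logits)), theta)
        n = _nb_depth(rng, depth, depth_dispersion, n_sites)
        k = rng.binomial(n, theta)
        return k, n

    pair1 = technique_counts(depth1)
    pair2 = technique_counts(depth2)
    truth = SimulationTruth(
        "simulate_technique_pair", seed,
        {"n_sites": n_sites, "reproducible_fraction": reproducible_fraction,
         "depth1": depth1, "depth2": depth2, "noise_sd": noise_sd},
        {"reproducible": reproducible, "theta_shared": theta_shared},
    )
    return pair1, pair2, truth


def simulate_dm_pair(
    n_sites: int = 1000,
    n_dm: int = 100,
    delta: float = -0.5,
    theta_control: float = 0.6,
    depth: float = 100.0,
    depth_dispersion: float = 0.1,
    seed: int | None = 0,
):
    """Perturbation contrast shared by two techniques with planted delta-beta.

    The first ``n_dm`` sites shift their methylation by ``delta`` between
    control and treated in BOTH techniques; the rest keep theta unchanged.
    Returns per-technique (treated, control) count pairs plus truth.
    """
    rng = np.random.default_rng(seed)
    dm = np.zeros(n_sites, dtype=bool)
    dm[:n_dm] = True
    theta_c = np.clip(rng.beta(8, 8, n_sites) * 0 + theta_control
                      + rng.normal(0, 0.05, n_sites), 0.05, 0.95)
    theta_t = np.clip(np.where(dm, theta_c + delta, theta_c), 0.01, 0.99)

    def counts(theta):
        n = _nb_depth(rng, depth, depth_dispersion, n_sites)
        return rng.binomial(n, theta), n

    tech1 = {"treated": counts(theta_t), "control": counts(theta_c)}
    tech2 = {"treated": counts(theta_t), "control": counts(theta_c)}
    truth = SimulationTruth(
        "simulate_dm_pair", seed,
        {"n_sites": n_sites, "n_dm": n_dm, "delta": delta,
         "theta_control": theta_control, "depth": depth},
        {"dm": dm, "theta_control": theta_c, "theta_treated": theta_t},
    )
    return tech1, tech2, truth


# ---------------------------------------------------------------------------
# QTL cohorts
# ---------------------------------------------------------------------------

def simulate_qtl_cohort(
    n_samples: int = 100,
    n_sites: int = 50,
    n_variants_per_window: int = 30,
    maf_range: tuple = (0.05, 0.5),
    effect_sd: float = 0.0,
    fixed_effect: float | None = None,
    n_covariates: int = 2,
    window_half_width: int = 5000,
    seed: int | None = 0,
):
    """Genotypes, phenotypes, and cis windows with planted effects.

    Dosages are Hardy–Weinberg draws ``Binomial(2, maf)``; each site owns a
    window of variants, and when ``effect_sd > 0`` one causal variant per
    site contributes ``dosage * effect`` with ``effect ~ N(0, effect_sd)``
    (sign recorded).  ``fixed_effect`` plants that exact effect size (in
    phenotype-noise SD units) instead of a random draw.  Phenotype =
    covariate effects + genetic effect + standard normal noise.
    """
    rng = np.random.default_rng(seed)
    site_ids = [f"qs{i}" for i in range(n_sites)]
    sample_ids = [f"ind{j}" for j in range(n_samples)]

    covariates = rng.normal(size=(n_samples, n_covariates)) if n_covariates else np.zeros((n_samples, 0))
    cov_beta = rng.normal(0, 0.5, size=(n_covariates, n_sites)) if n_covariates else np.zeros((0, n_sites))

    geno_rows = []
    variant_ids = []
    positions = []
    windows = {}
    causal = {}
    pheno = covariates @ cov_beta + rng.normal(size=(n_samples, n_sites))
    for i, sid in enumerate(site_ids):
        center = (i + 1) * (4 * window_half_width)
        windows[sid] = [(center - window_half_width, center + window_half_width)]
        offsets = np.sort(rng.integers(-window_half_width, window_half_width, n_variants_per_window))
        mafs = rng.uniform(*maf_range, size=n_variants_per_window)
        g = rng.binomial(2, mafs[:, None], size=(n_variants_per_window, n_samples)).astype(float)
        start = len(variant_ids)
        for v in range(n_variants_per_window):
            variant_ids.append(f"var_{sid}_{v}")
            positions.append(int(center + offsets[v]))
        geno_rows.append(g)
        if effect_sd > 0 or fixed_effect is not None:
            causal_v = int(rng.integers(0, n_variants_per_window))
            if fixed_effect is not None:
                effect = float(fixed_effect)
            else:
                effect = float(rng.normal(0, effect_sd))
                while abs(effect) < 0.1 * effect_sd:  # avoid degenerate near-zero plants
                    effect = float(rng.normal(0, effect_sd))
            pheno[:, i] += g[causal_v] * effect
            causal[sid] = {"variant_id": variant_ids[start + causal_v], "effect": effect}

    genotypes = pd.DataFrame(np.vstack(geno_rows), index=variant_ids, columns=sample_ids)
    variant_pos = pd.Series(positions, index=variant_ids)
    phenotypes = pd.DataFrame(pheno.T, index=site_ids, columns=sample_ids)
    truth = SimulationTruth(
        "simulate_qtl_cohort", seed,
        {"n_samples": n_samples, "n_sites": n_sites,
         "n_variants_per_window": n_variants_per_window,
         "maf_range": list(maf_range), "effect_sd": effect_sd},
        {"causal": causal},
    )
    return {
        "phenotypes": phenotypes,
        "genotypes": genotypes,
        "variant_pos": variant_pos,
        "windows": windows,
        "covariates": covariates,
        "truth": truth,
    }
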