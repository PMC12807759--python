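# m6akit

A toolkit for consistent, base-resolution quantification and validation of
m⁶A (N⁶-methyladenosine) methylomes across sequencing techniques:

- **Reference sites** (`m6akit.sites`) — strand-aware scanning of canonical
  exonic DRACH motifs from FASTA + GTF, merging with external site lists,
  BED6 I/O.
- **Quantification** (`m6akit.quantify`) — per-site counting from SAM/BAM
  under two technique contracts: IP/input fragment overlap (antibody
  assays) and single-base conversion pileup (chemical/enzymatic
  chemistries), plus gene-level RPKM.
- **Site calling** (`m6akit.calling`) — one-sided binomial test against the
  sample-wide background rate with Benjamini–Hochberg correction, and a
  two-component beta-binomial mixture (EM) posterior classifier.
- **IVT calibration** (`m6akit.calibration`) — false-positive masking from
  in-vitro-transcribed (modification-free) negative controls.
- **Orthogonal validation** (`m6akit.integration`) — irreproducible
  discovery rate (2-D Gaussian copula mixture) on beta-value profiles of
  technically orthogonal technique pairs; three-criterion validated-site
  decision; differential-methylation variant on beta differences.
- **QTL stage** (`m6akit.qtl`) — log-odds M-levels, missingness filtering,
  MA-plot normalization, natural-cubic-spline GC correction, z-score +
  quantile normalization, permutation-calibrated SVD latent factors, and
  cis-QTL mapping with permutation empirical p-values (MLE Beta
  approximation).
- **QC** (`m6akit.qc`) — motif ANOVA R², Matthews correlation against a
  truth set, QQ data, bimodality, feature-regression hooks.
- **Synthetic data** (`m6akit.simulate`) — deterministic fixture
  generators with planted ground truth for every stage: toy genome/GTF,
  beta-binomial methylomes, SAM reads, correlated technique pairs, IVT
  nulls, perturbation contrasts, and genotype cohorts with cis effects.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance criteria
(exact-oracle equivalence, null calibration, parameter recovery, end-to-end
planted-truth recovery), one test per criterion.

The acceptance report script (no numeric targets are defined for this
build, so it emits an empty target map):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## CLI

Everything is reachable through the `m6akit` entry point:

```bash
# reference sites
m6akit sites scan --fasta genome.fa --gtf genes.gtf --out sites.bed
m6akit sites merge a.bed b.bed --out merged.bed

# counting
m6akit quantify ip-input --ip ip.bam --input input.bam --sites sites.bed --out counts.tsv
m6akit quantify pileup --alignments sample.bam --sites sites.bed --out counts.tsv
m6akit quantify rpkm --counts genes.tsv --library-size 10000000 --out rpkm.tsv

# calling + calibration (matrices are TSV layer files sharing a prefix)
m6akit call binomial --matrix mat --alpha 0.05 --out called
m6akit call bbmix --matrix mat --sample s1 --seed 0 --restarts 5 --out post.tsv
m6akit calibrate ivt --matrix mat --ivt-samples ivt1,ivt2 --out masked

# orthogonal validation
m6akit integrate pair --matrix1 glori --matrix2 etam --min-cov 20 --idr-alpha 0.05 --out validated.csv
m6akit integrate diff --matrix1 glori --matrix2 etam --treated FTO --control WT --out dm.csv

# QTL mapping
m6akit qtl map --phenotypes m.tsv --genotypes g.tsv --windows w.json \
    --perm 1000 --seed 0 --low 0.1 --high 0.05 --out qtl.csv

# QC and synthetic fixtures
m6akit qc report --matrix mat --sample s1 --out qc.json
m6akit simulate genome --fasta toy.fa --gtf toy.gtf --seed 0
m6akit simulate methylome --n-sites 5000 --pi 0.2 --out mat
m6akit simulate qtl-cohort --n-samples 100 --effect-sd 1.0 --out-prefix cohort
```

## Data model

`MethylationMatrix` is the central container: a dense sites × samples
object with integer layers `m6a_count` and `total_count` (zeros, never
gaps), optional derived layers (`p_value`, `bh_p`, `posterior_m6a`), a
`ReferenceSiteSet` row space, and `SampleRecord` column metadata
(technique, category, condition, IVT flag, IP/input pairing).  Matrices
serialize to per-layer TSV files plus a sample-metadata CSV.
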