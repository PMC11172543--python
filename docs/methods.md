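# Methods

## Problem and scope

Genebanks conserve large germplasm collections whose accessions
accumulate deleterious mutations. Given a genome-wide SNP panel for a
collection (genotyping-by-sequencing scale: tens of thousands of
markers, mostly homozygous inbred samples), per-variant functional
annotations, and a positional evolutionary-constraint track, the
pipeline (i) identifies predicted deleterious SNPs (dSNPs), (ii)
estimates a per-sample mutation burden, (iii) characterizes the burden
across germplasm groups, and (iv) relates burden to each sample's
genetic distinctness so that curators can target material that is both
distinct and lightly burdened.

## Deleterious-SNP identification

A biallelic SNP is called deleterious when all three predicates hold:

1. it has a **missense** annotation on a **canonical transcript**
   (`canonical_only=True`; collapsing to canonical transcripts avoids
   counting one substitution once per isoform);
2. its **SIFT score ≤ 0.05**. The comparison is inclusive by default
   because the SIFT deleteriousness class is defined as "0.05 or
   less"; `sift_strict=True` switches to a strict `<` for
   compatibility with tools that use the open interval. At machine
   precision the choice only matters for scores exactly at the
   threshold;
3. its position has a **GERP rejected-substitution score RS > 0**
   (strict). A position absent from the constraint track *fails* this
   criterion: published RS tracks enumerate only the constrained
   (RS > 0) positions, so absence means unconstrained.

The deleterious allele is taken to be the alternate allele of the
annotated variant. True "derived" status would require ancestral-state
polarization against an outgroup, which the consumed inputs do not
carry; no repolarization is attempted. Annotations are joined to loci
by `(chrom, pos, alt)` — including the allele avoids mispairing at
positions with multiple annotated alleles. When several annotations of
one locus qualify, the one with the lowest SIFT score is reported; the
membership decision is unaffected.

Consequence tallies support two row semantics: per annotation row
(every (variant, transcript) pair counts) and per SNP (each variant
contributes its single most severe consequence under the standard
annotator severity ranking, most-severe-first, as listed in
`burdenscan.dsnp.SEVERITY_ORDER`). The loss-of-function aggregate is
the sum over the seven classes in `burdenscan.dsnp.LOF_CLASSES`.

## Burden model

For a sample with `h` homozygous and `e` heterozygous genotypes over
the `L` identified dSNP loci:

    B_hom = 2h / (2L)        homozygous burden per deleterious locus
    B_het = e  / (2L)        heterozygous burden per deleterious locus
    B_tot = (2h + e) / (2L)  total burden per deleterious locus

The numerator of `B_tot` is the number of deleterious alleles the
sample carries; dividing by `2L` (the number of genotyped chromosomes
at deleterious loci) bounds it in [0, 1]. `B_tot = B_hom + B_het`
holds exactly: the implementation computes the total as the sum of the
two components, which is the same rational value and keeps the
identity exact in floating point. A zero-burden sample is one with
`B_tot = 0` exactly (no deleterious allele called).

**Missing genotypes** at dSNP loci contribute zero deleterious alleles
and leave the denominator at `2L` (`missing_policy="zero"`). This is
the right default for panels imputed upstream, where residual
missingness is minimal; `missing_policy="drop_locus_for_sample"`
instead uses a per-sample denominator of twice the called loci, which
is preferable when missingness is heavy and informative.

**Carrier frequency** of a dSNP is carriers / N, the fraction of
samples with dosage ≥ 1 — not the allele count over 2N chromosomes.
In a highly selfing crop nearly every carrier is homozygous, and the
carrier fraction is the quantity on which rarity statements
("present in one sample", "in at most 20 samples") are made; it is
reported at 6 decimals.

## Genetic distinctness (APD)

The pairwise distance between two samples is the allele-sharing
mismatch: mean over co-genotyped loci of |a − b| / 2, where a, b are
alternate-allele dosages. It is 0 for identical genotypes, 1 for
opposite homozygotes everywhere, and symmetric. Missing calls are
handled by pairwise deletion. A `simple_matching` alternative (any
dosage difference counts 1) is pluggable through the `distance`
option, since published distinctness analyses do not always state
whether heterozygote mismatches are half-weighted.

A sample's APD is its mean distance to the other N − 1 samples. The
computation is blockwise: per dosage value v the indicator matrix
I_v is formed, and the summed mismatch between all samples and a block
is assembled from the products I_u · I_vᵀ with weights |u − v|, with
co-genotyped counts from the non-missing indicator product. This runs
through BLAS at O(N²M) flops with memory O(N · block) and is verified
against the naive double loop.

## Group characterization

Group summaries report n, mean, sample SD (n − 1 denominator; NA for
single-sample groups), min and max of `B_tot`. Display rounding is
half away from zero on the decimal value: 3 decimals for cohort-level
summaries, 5 for per-country tables, 6 for carrier frequencies. The
half-up rule was chosen because it reproduces published burden tables
digit-for-digit (e.g. mean(0.00246, 0.00491) must print 0.00369);
round-half-even would print 0.00368.

The omnibus test is one-way fixed-effects ANOVA,
F = (SSB/(k−1)) / (SSW/(n−k)), with the p-value from the F
distribution; it matches `scipy.stats.f_oneway` and is invariant to
shifting and positive rescaling of the burdens. "Unknown" labels
appear in summary tables but are excluded from the test by default
(configurable), since an unknown-origin pool is not a meaningful
factor level. No post-hoc multiple-comparison tests are run.

Burden–APD association is the Pearson correlation with the t-transform
p-value. At genebank cohort sizes (N ≈ 2·10⁴) any |r| > 0.02 is
formally significant, so reports emphasize r itself. The selection
target zone is the rectangle `apd ≥ apd_min` and `B_tot ≤ burden_max`;
zone thresholds default to the cohort medians when not supplied.

## Synthetic data generator

The generator emulates the marginal structure the pipeline consumes;
defaults (a `SyntheticConfig`):

| parameter | default | rationale |
|---|---|---|
| `selfing_rate` | 0.99 | probability a carrier is homozygous; domesticated barley is highly inbred (observed ≈ 0.05 heterozygous vs 4.7 homozygous deleterious calls per sample) |
| `missing_rate` | 0.029 | per-genotype missing-call rate of the emulated GBS panel |
| `zipf_exponent` | 1.8 | truncated-zipf carrier counts; concentrates most deleterious alleles in very few carriers |
| `carrier_max_fraction` | 0.3 | carrier counts capped below fixation — deleterious alleles are rare (real-panel mean carrier fraction ≈ 1%), and the cap keeps weighted carrier placement from saturating a group |
| `target_rare_fraction` | off | when set, the zipf exponent is solved by bisection so the expected fraction of dSNPs with carrier fraction ≤ 0.001 hits the target; infeasible when 1/N > 0.001 |
| `n_dsnp`, `n_loci` | 40, 2000 | desk-scale panel with a small deleterious fraction |

Planted dSNP loci get a canonical missense annotation with SIFT drawn
uniform on [0, 0.05] and an RS score uniform on (0, 5]; every decoy
locus fails exactly one predicate class (tolerated SIFT, non-canonical
transcript, non-positive or absent RS, or a non-missense consequence),
so the identified set must equal the planted set exactly.

Genotypes at deleterious loci are drawn **per locus from exact carrier
counts**: carriers are placed by weighted sampling without replacement
(weight 1 + group effect), each carrier homozygous with probability
`selfing_rate`. Locus-level truth is therefore exact, not expected.
Group effects act multiplicatively on the expected carrier load; a
planted effect of 0.5 yields an expected group burden ratio of 1.5
when carrier counts are small relative to the cohort (the
without-replacement draw compresses the ratio as counts approach the
cap). Planted zero-burden samples are excluded from carrier placement
and from missing-call masking, so they stay exactly at `B_tot = 0`.
Truth tables are recomputed from the final dosage matrix (after
duplication and masking), so planted-recovery checks are exact
identities.

What the generator does **not** emulate: linkage disequilibrium,
demography, population structure in the neutral markers, genotyping
error, or within-accession heterogeneity. Passing planted-recovery
tests therefore demonstrates the correctness of the counting and
filtering machinery, not robustness to those real-data features.

## Numerical and design choices

* Dosage is int8 with −1 for missing; phased and unphased calls are
  equivalent; multi-allelic or indel records are a hard error by
  default (`skip_nonbiallelic` downgrades to skip-with-warning).
* All tables are written atomically (temp file + rename) with fixed
  decimal formatting, UTF-8 and LF endings, so reruns are
  byte-identical and diffable across platforms.
* Degenerate inputs: `L = 0` (no dSNPs) is an error for burden
  estimation; ANOVA with all-identical values returns F = 0, p = 1;
  zero within-group variance with a nonzero between-group contrast
  returns p = 0 with a warning; APD requires N ≥ 2 and at least one
  co-genotyped locus per pair.
* Determinism: all randomness flows through one
  `numpy.random.default_rng(seed)` per generator call; identical
  config gives byte-identical bundles.

## Problem sizes used in the checks

Unit and property checks run on cohorts of up to 50 samples (where
brute-force oracles are exact); end-to-end planted-recovery runs on a
500 × 2,000 bundle; ANOVA null calibration uses 200 seeded replicates
of a 300-sample, 150-locus cohort; the acceptance script runs the full
pipeline on an 800 × 3,000 bundle and calibrates the carrier spectrum
at the genebank scale (N = 19,778) using counts only. These sizes give
stable stochastic checks while keeping a full run inside a few
minutes on one CPU.

## Known limitations

* No SIFT or GERP computation — their outputs are inputs here, and any
  paralog-induced annotation bias propagates through.
* No ancestral-allele polarization: "deleterious allele" means the
  annotated alternate allele.
* The published distinctness statistic may differ in detail from the
  allele-sharing APD implemented here; the distance is pluggable for
  that reason.
* Carrier frequency below 1/N is unrepresentable, so rarity targets
  tighter than 1/N are rejected as infeasible rather than silently
  clipped.
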