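"""Synthetic input bundles with planted truth.

Generates internally consistent genotype / annotation / constraint /
passport bundles that mimic the marginal structure of a genebank-scale
inbred SNP panel:

* mostly homozygous genotypes (a high selfing rate keeps heterozygotes
  rare, as in domesticated barley),
* a small planted set of deleterious loci whose annotations — and only
  whose annotations — pass the missense + canonical + SIFT + RS filter
  cascade, while every decoy locus fails at least one predicate,
* a strongly skewed carrier-count spectrum (truncated zipf), so most
  deleterious alleles are carried by a handful of samples,
* optional group structure (additive shifts in expected carrier load),
  planted zero-burden samples, duplicate sample pairs, and missing
  calls at a configurable per-marker rate.

Genotypes at deleterious loci are drawn per locus from exact carrier
counts (carriers are placed by weighted sampling without replacement),
so the locus-level truth is exact rather than expected.  Truth tables
record the realized per-sample (h, e) counts, per-locus carrier and
allele counts, planted loci and group assignments, all recomputed from
the final dosage matrix (after duplication and missing-call masking).

No linkage, demography or coalescent realism is attempted: the
generator targets only the marginal structure the pipeline consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .variant_io import (
    MISSING,
    AnnotationRecord,
    ConstraintTrack,
    GenotypeMatrix,
    Locus,
    PassportTable,
    atomic_write_text,
    write_annotations,
    write_constraint,
    write_genotypes,
    write_passport,
)

CHROMOSOMES = ("1H", "2H", "3H", "4H", "5H", "6H", "7H")

_BASES = np.array(list("ACGT"))

#: Countries used for passport plumbing, with their geographic regions.
COUNTRY_REGIONS = {
    "Ethiopia": "Ethiopian Centre",
    "Turkey": "Near Eastern Centre",
    "Syria": "Near Eastern Centre",
    "Spain": "Mediterranean Centre",
    "Italy": "Mediterranean Centre",
    "Afghanistan": "Middle Asian Centre",
    "Japan": "East Asiatic Centre",
    "China": "East Asiatic Centre",
    "Germany": "European-Siberian Centre",
    "Sweden": "European-Siberian Centre",
    "Mexico": "New World Centre",
    "Unknown": "Unknown",
}

_NONMISSENSE = (
    "synonymous_variant",
    "intron_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intergenic_variant",
    "3_prime_UTR_variant",
    "5_prime_UTR_variant",
    "splice_region_variant",
    "stop_gained",
    "non_coding_transcript_exon_variant",
)


@dataclass(frozen=True)
class GroupSpec:
    """One planted group: label, size and additive carrier-load effect.

    ``effect`` shifts a member's relative propensity to carry a
    deleterious allele: carriers are drawn with weight 1 + effect, so
    two groups with effects 0 and 0.5 have expected carrier loads in
    ratio 1 : 1.5.
    """

    label: str
    n: int
    effect: float = 0.0


@dataclass
class SyntheticConfig:
    """Generator configuration.

    Defaults mirror the structure of a genebank GBS panel at desk
    scale: inbred samples (selfing_rate 0.99, so roughly one
    heterozygous deleterious call per hundred carriers), 2.9% missing
    calls per marker, and a zipf carrier spectrum whose default
    exponent concentrates most deleterious alleles in very few
    carriers.
    """

    n_samples: int = 500
    n_loci: int = 2000
    n_dsnp: int = 40
    zipf_exponent: float = 1.8
    carrier_max_fraction: float = 0.3  # deleterious alleles never near fixation
    target_rare_fraction: float | None = None  # fraction with carrier freq <= 0.001
    selfing_rate: float = 0.99
    missing_rate: float = 0.029
    group_field: str = "material_type"
    groups: tuple[GroupSpec, ...] = ()
    n_zero_burden: int = 0
    n_duplicate_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dsnp > self.n_loci:
            raise ValueError("n_dsnp exceeds n_loci")
        for rate in (self.selfing_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        total = sum(g.n for g in self.groups)
        if self.groups and total != self.n_samples:
            raise ValueError(
                f"group sizes sum to {total}, expected n_samples={self.n_samples}"
            )
        if self.n_zero_burden > self.n_samples:
            raise ValueError("n_zero_burden exceeds n_samples")


@dataclass
class Bundle:
    """A generated input bundle plus its truth tables."""

    genotypes: GenotypeMatrix
    annotations: list[AnnotationRecord]
    constraint: ConstraintTrack
    passport: PassportTable
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "genotypes.vcf",
            "annotations": outdir / "annotations.tsv",
            "constraint": outdir / "constraint.tsv",
            "passport": outdir / "passport.csv",
            "truth": outdir / "truth.json",
        }
        write_genotypes(self.genotypes, paths["vcf"])
        write_annotations(self.annotations, paths["annotations"])
        write_constraint(self.constraint, paths["constraint"])
        write_passport(self.passport, paths["passport"])
        atomic_write_text(paths["truth"], json.dumps(self.truth, indent=1, sort_keys=True))
        return paths


# ---------------------------------------------------------------------------
# carrier spectrum


def _zipf_pmf(exponent: float, nmax: int) -> np.ndarray:
    k = np.arange(1, nmax + 1, dtype=np.float64)
    w = k**-exponent
    return w / w.sum()


def solve_zipf_exponent(
    target_fraction: float, threshold: int, nmax: int
) -> float:
    """Exponent of a zipf law truncated to [1, nmax] whose CDF at
    ``threshold`` equals ``target_fraction`` (bisection)."""
    lo, hi = 0.01, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _zipf_pmf(mid, nmax)[:threshold].sum() < target_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def plant_spectrum(
    n_dsnp: int,
    n_samples: int,
    rng: np.random.Generator,
    zipf_exponent: float = 1.8,
    target_rare_fraction: float | None = None,
    rare_threshold: float = 0.001,
    max_fraction: float = 0.3,
) -> np.ndarray:
    """Draw per-dSNP carrier counts from a truncated zipf law.

    Counts span [1, max_fraction * N]: a deleterious allele always has
    at least one carrier and never approaches fixation.  With
    ``target_rare_fraction`` set, the exponent is solved so that the
    expected fraction of loci with carrier fraction <=
    ``rare_threshold`` hits the target; since a carrier count of 1
    forces a frequency of 1/N, the target is infeasible when
    1/N > rare_threshold.
    """
    if n_dsnp == 0:
        return np.zeros(0, dtype=np.int64)
    nmax = max(1, int(max_fraction * n_samples))
    if target_rare_fraction is not None:
        if not 0.0 < target_rare_fraction < 1.0:
            raise ValueError("target_rare_fraction must lie in (0, 1)")
        threshold = int(np.floor(rare_threshold * n_samples))
        if threshold < 1:
            raise ValueError(
                f"carrier fraction <= {rare_threshold} is infeasible with "
                f"{n_samples} samples (minimum nonzero frequency is 1/{n_samples})"
            )
        zipf_exponent = solve_zipf_exponent(target_rare_fraction, threshold, nmax)
    pmf = _zipf_pmf(zipf_exponent, nmax)
    return rng.choice(np.arange(1, nmax + 1), size=n_dsnp, p=pmf).astype(np.int64)


# ---------------------------------------------------------------------------
# groups and passport


def plant_groups(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[list[str], np.ndarray, PassportTable]:
    """Per-sample group labels, carrier weights, and a passport table.

    Carrier weight 1 + effect realizes the additive shift in expected
    carrier load; the remaining passport fields are filled with
    plausible categories so the bundle exercises every grouping column.
    """
    if config.groups:
        labels: list[str] = []
        weights: list[float] = []
        for g in config.groups:
            labels.extend([g.label] * g.n)
            weights.extend([1.0 + g.effect] * g.n)
    else:
        pool = ("Landrace", "Cultivar", "Breeding_material")
        labels = [pool[i % 3] for i in range(config.n_samples)]
        weights = [1.0] * config.n_samples
    samples = [f"S{i + 1:05d}" for i in range(config.n_samples)]
    countries = list(COUNTRY_REGIONS)
    records = {}
    for i, sid in enumerate(samples):
        country = countries[rng.integers(len(countries))]
        rec = {
            "panel": ("Genebank_A", "Genebank_B")[int(rng.integers(2))],
            "material_type": "Unknown",
            "growth_habit": ("Spring", "Winter", "Intermediate")[int(rng.integers(3))],
            "row_type": ("Two-rowed", "Six-rowed")[int(rng.integers(2))],
            "country": country,
            "region": COUNTRY_REGIONS[country],
            "core_flag": ("Core", "Non-core")[int(rng.integers(2))],
        }
        rec[config.group_field] = labels[i]
        records[sid] = rec
    return labels, np.asarray(weights), PassportTable(records)


# ---------------------------------------------------------------------------
# genotypes


def _place_carriers(
    n_samples: int,
    carrier_counts: np.ndarray,
    weights: np.ndarray,
    eligible: np.ndarray,
    selfing_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Dosage submatrix (n_samples x len(counts)) from exact carrier counts."""
    dosage = np.zeros((n_samples, len(carrier_counts)), dtype=np.int8)
    idx = np.flatnonzero(eligible)
    w = weights[idx]
    p = w / w.sum()
    for j, c in enumerate(carrier_counts):
        c = min(int(c), len(idx))
        carriers = rng.choice(idx, size=c, replace=False, p=p)
        hom = rng.random(c) < selfing_rate
        dosage[carriers, j] = np.where(hom, 2, 1)
    return dosage


def simulate_group_burdens(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[list[str], np.ndarray]:
    """Fast path: group labels and total burdens, deleterious loci only.

    Skips decoy loci, annotations and file output; used to study the
    sampling behaviour of group contrasts over many replicates.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    labels, weights, _ = plant_groups(config, rng)
    counts = plant_spectrum(
        config.n_dsnp,
        config.n_samples,
        rng,
        config.zipf_exponent,
        config.target_rare_fraction,
        max_fraction=config.carrier_max_fraction,
    )
    eligible = np.ones(config.n_samples, dtype=bool)
    dosage = _place_carriers(
        config.n_samples, counts, weights, eligible, config.selfing_rate, rng
    )
    L = config.n_dsnp
    b_tot = (2 * np.sum(dosage == 2, axis=1) + np.sum(dosage == 1, axis=1)) / (2 * L)
    return labels, b_tot


# ---------------------------------------------------------------------------
# full bundle


def _distinct_positions(n: int, rng: np.random.Generator, span: int = 5_000_000) -> np.ndarray:
    pos: np.ndarray = np.unique(rng.integers(1, span, size=2 * n + 16))
    while len(pos) < n:
        pos = np.unique(np.concatenate([pos, rng.integers(1, span, size=n)]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def _make_loci(config: SyntheticConfig, rng: np.random.Generator) -> list[Locus]:
    loci = []
    per_chrom = np.array_split(np.arange(config.n_loci), len(CHROMOSOMES))
    for chrom, block in zip(CHROMOSOMES, per_chrom):
        if len(block) == 0:
            continue
        pos = _distinct_positions(len(block), rng)
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            loci.append(Locus(chrom, int(p), str(_BASES[ref]), str(_BASES[alt])))
    return loci


def _annotate(
    loci: Sequence[Locus],
    dsnp_mask: np.ndarray,
    rng: np.random.Generator,
) -> tuple[list[AnnotationRecord], ConstraintTrack]:
    """One annotation row per locus; planted loci pass all filters,
    decoys fail at least one (wrong consequence, non-canonical transcript,
    tolerated SIFT, or a non-positive / absent RS score)."""
    records = []
    rs_entries: dict[tuple[str, int], float] = {}
    for i, loc in enumerate(loci):
        gene = f"GENE{i:05d}"
        transcript = f"{gene}.1"
        if dsnp_mask[i]:
            sift = float(rng.uniform(0.0, 0.05))
            records.append(
                AnnotationRecord(
                    locus_key=loc.key,
                    transcript_id=transcript,
                    consequence="missense_variant",
                    canonical=True,
                    sift_class="deleterious",
                    sift_score=sift,
                    gene=gene,
                )
            )
            rs_entries[(loc.chrom, loc.pos)] = float(rng.uniform(1e-6, 5.0))
            continue
        mode = rng.integers(4)
        if mode == 0:  # tolerated missense
            records.append(
                AnnotationRecord(
                    locus_key=loc.key,
                    transcript_id=transcript,
                    consequence="missense_variant",
                    canonical=True,
                    sift_class="tolerated",
                    sift_score=float(rng.uniform(0.051, 1.0)),
                    gene=gene,
                )
            )
            rs_entries[(loc.chrom, loc.pos)] = float(rng.uniform(1e-6, 5.0))
        elif mode == 1:  # deleterious missense on a non-canonical transcript
            records.append(
                AnnotationRecord(
                    locus_key=loc.key,
                    transcript_id=f"{gene}.2",
                    consequence="missense_variant",
                    canonical=False,
                    sift_class="deleterious",
                    sift_score=float(rng.uniform(0.0, 0.05)),
                    gene=gene,
                )
            )
            rs_entries[(loc.chrom, loc.pos)] = float(rng.uniform(1e-6, 5.0))
        elif mode == 2:  # deleterious missense at an unconstrained position
            records.append(
                AnnotationRecord(
                    locus_key=loc.key,
                    transcript_id=transcript,
                    consequence="missense_variant",
                    canonical=True,
                    sift_class="deleterious",
                    sift_score=float(rng.uniform(0.0, 0.05)),
                    gene=gene,
                )
            )
            if rng.random() < 0.5:  # explicit non-positive score, else absent
                rs_entries[(loc.chrom, loc.pos)] = float(rng.uniform(-3.0, 0.0))
        else:  # non-missense consequence
            records.append(
                AnnotationRecord(
                    locus_key=loc.key,
                    transcript_id=transcript,
                    consequence=_NONMISSENSE[int(rng.integers(len(_NONMISSENSE)))],
                    canonical=bool(rng.integers(2)),
                    gene=gene,
                )
            )
            if rng.random() < 0.5:
                rs_entries[(loc.chrom, loc.pos)] = float(rng.uniform(-3.0, 5.0))
    return records, ConstraintTrack(rs_entries)


def generate_bundle(config: SyntheticConfig) -> Bundle:
    """Generate a complete input bundle with truth tables.

    Identical config (including seed) yields identical output,
    byte-for-byte once written.
    """
    rng = np.random.default_rng(config.seed)
    labels, weights, passport = plant_groups(config, rng)
    samples = [f"S{i + 1:05d}" for i in range(config.n_samples)]

    loci = _make_loci(config, rng)
    dsnp_idx = np.sort(rng.choice(config.n_loci, size=config.n_dsnp, replace=False))
    dsnp_mask = np.zeros(config.n_loci, dtype=bool)
    dsnp_mask[dsnp_idx] = True
    annotations, constraint = _annotate(loci, dsnp_mask, rng)

    # zero-burden samples: the last n_zero_burden samples never carry
    eligible = np.ones(config.n_samples, dtype=bool)
    zero_ids: list[str] = []
    if config.n_zero_burden:
        eligible[config.n_samples - config.n_zero_burden :] = False
        zero_ids = samples[config.n_samples - config.n_zero_burden :]

    planted_counts = plant_spectrum(
        config.n_dsnp,
        config.n_samples,
        rng,
        config.zipf_exponent,
        config.target_rare_fraction,
        max_fraction=config.carrier_max_fraction,
    )
    planted_counts = np.minimum(planted_counts, int(eligible.sum()))
    dosage = np.zeros((config.n_samples, config.n_loci), dtype=np.int8)
    dosage[:, dsnp_idx] = _place_carriers(
        config.n_samples, planted_counts, weights, eligible, config.selfing_rate, rng
    )

    # decoy loci: skewed low alternate-allele frequencies, inbred genotypes
    decoy_idx = np.flatnonzero(~dsnp_mask)
    q = rng.beta(0.4, 4.0, size=len(decoy_idx)) * 0.5
    for j, col in enumerate(decoy_idx):
        n_carriers = int(rng.binomial(config.n_samples, q[j]))
        if n_carriers == 0:
            continue
        carriers = rng.choice(config.n_samples, size=n_carriers, replace=False)
        hom = rng.random(n_carriers) < config.selfing_rate
        dosage[carriers, col] = np.where(hom, 2, 1)

    # duplicate pairs (genotype copies) among unreserved samples
    n_free = config.n_samples - config.n_zero_burden
    if config.n_duplicate_pairs:
        if 2 * config.n_duplicate_pairs > n_free:
            raise ValueError("too many duplicate pairs for the free samples")
        picks = rng.choice(n_free, size=2 * config.n_duplicate_pairs, replace=False)
        for a, b in picks.reshape(-1, 2):
            dosage[b] = dosage[a]

    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        if config.n_zero_burden:  # keep planted zero-burden rows fully called
            mask[config.n_samples - config.n_zero_burden :, :] = False
        dosage[mask] = MISSING

    genotypes = GenotypeMatrix(samples, loci, dosage)

    # truth recomputed from the final matrix so planted values are exact
    sub = dosage[:, dsnp_idx]
    h = np.sum(sub == 2, axis=1)
    e = np.sum(sub == 1, axis=1)
    carrier_counts = np.sum(sub >= 1, axis=0)
    allele_counts = np.sum(np.where(sub > 0, sub, 0), axis=0)
    truth = {
        "dsnp_keys": [list(loci[i].key) for i in dsnp_idx],
        "samples": samples,
        "h": h.tolist(),
        "e": e.tolist(),
        "carrier_counts": carrier_counts.tolist(),
        "allele_counts": allele_counts.tolist(),
        "planted_carrier_counts": planted_counts.tolist(),
        "group_field": config.group_field,
        "group_labels": labels,
        "group_effects": {g.label: g.effect for g in config.groups},
        "zero_burden_samples": zero_ids,
        "seed": config.seed,
    }
    return Bundle(genotypes, annotations, constraint, passport, truth)
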