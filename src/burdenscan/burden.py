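"""Per-sample mutation-burden estimation and the carrier spectrum.

For each sample, ``h`` counts dSNP loci carried in the homozygous state
(dosage 2) and ``e`` counts heterozygous carriers (dosage 1).  With
``L`` identified dSNP loci the three burden statistics per deleterious
locus are

    B_hom = 2h / (2L),   B_het = e / (2L),   B_tot = (2h + e) / (2L),

so that B_tot = B_hom + B_het exactly and 0 <= B_tot <= 1.  The
numerator of B_tot is the number of deleterious alleles the sample
carries; the denominator is twice the number of deleterious loci.

Missing genotypes at dSNP loci contribute zero deleterious alleles and
leave the denominator at 2L (``missing_policy="zero"``, the default for
panels imputed upstream); ``missing_policy="drop_locus_for_sample"``
instead shrinks the denominator to twice the number of called loci for
that sample.

A locus's carrier frequency is carriers / N — the fraction of samples
with dosage >= 1 — not the allele frequency over 2N chromosomes; rare
deleterious alleles in inbred germplasm are reported on this scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .variant_io import MISSING, GenotypeMatrix, atomic_write_text
from .dsnp import DeleteriousSet
from .rounding import FREQUENCY_DECIMALS, fmt


@dataclass(frozen=True)
class BurdenEstimate:
    """Burden statistics for one sample."""

    sample_id: str
    n_het: int  # e
    n_hom: int  # h
    hom_burden: float
    het_burden: float
    total_burden: float
    L: int


@dataclass
class CarrierSpectrum:
    """Per-dSNP carrier counts and frequencies over N samples."""

    keys: list[tuple[str, int, str]]
    carrier_counts: np.ndarray  # int, per locus
    n_samples: int

    @property
    def carrier_frequencies(self) -> np.ndarray:
        return self.carrier_counts / self.n_samples

    def rare_fraction(self, max_frequency: float = 0.001) -> float:
        """Fraction of dSNPs with carrier frequency <= ``max_frequency``."""
        if len(self.carrier_counts) == 0:
            return float("nan")
        return float(np.mean(self.carrier_frequencies <= max_frequency))

    def count_at_most(self, max_carriers: int) -> int:
        """Number of dSNPs carried by at most ``max_carriers`` samples."""
        return int(np.sum(self.carrier_counts <= max_carriers))


def _dsnp_submatrix(genotypes: GenotypeMatrix, dset: DeleteriousSet) -> np.ndarray:
    cols = []
    for key in dset.keys():
        idx = genotypes.locus_index(key)
        if idx is None:
            raise KeyError(f"dSNP locus {key[0]}:{key[1]} ({key[2]}) absent from genotype matrix")
        cols.append(idx)
    return genotypes.dosage[:, cols] if cols else np.empty(
        (genotypes.n_samples, 0), dtype=np.int8
    )


def count_deleterious_genotypes(
    genotypes: GenotypeMatrix, dset: DeleteriousSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample (h, e, n_called) over the dSNP loci.

    h counts dosage-2 calls, e counts dosage-1 calls, n_called counts
    non-missing calls (used by the per-sample-denominator policy).
    """
    sub = _dsnp_submatrix(genotypes, dset)
    h = np.sum(sub == 2, axis=1).astype(np.int64)
    e = np.sum(sub == 1, axis=1).astype(np.int64)
    n_called = np.sum(sub != MISSING, axis=1).astype(np.int64)
    return h, e, n_called


def burden(h: int, e: int, L: int) -> tuple[float, float, float]:
    """(B_hom, B_het, B_tot) for deleterious genotype counts h, e over L loci."""
    if L <= 0:
        raise ValueError("no dSNP loci identified (L = 0); burden is undefined")
    if h < 0 or e < 0 or h + e > L:
        raise ValueError(f"invalid counts h={h}, e={e} for L={L}")
    denom = 2 * L
    b_hom = 2 * h / denom
    b_het = e / denom
    # summing the components keeps B_tot = B_hom + B_het exact in floats
    return b_hom, b_het, b_hom + b_het


def estimate_burdens(
    genotypes: GenotypeMatrix,
    dset: DeleteriousSet,
    missing_policy: str = "zero",
) -> list[BurdenEstimate]:
    """Burden estimates for every sample in the matrix."""
    if missing_policy not in ("zero", "drop_locus_for_sample"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if dset.L == 0:
        raise ValueError("no dSNP loci identified (L = 0); burden is undefined")
    h, e, n_called = count_deleterious_genotypes(genotypes, dset)
    out = []
    for i, sid in enumerate(genotypes.samples):
        if missing_policy == "drop_locus_for_sample":
            L_i = int(n_called[i])
            if L_i == 0:
                raise ValueError(f"sample {sid} has no called dSNP genotypes")
        else:
            L_i = dset.L
        b_hom, b_het, b_tot = burden(int(h[i]), int(e[i]), L_i)
        out.append(
            BurdenEstimate(
                sample_id=sid,
                n_het=int(e[i]),
                n_hom=int(h[i]),
                hom_burden=b_hom,
                het_burden=b_het,
                total_burden=b_tot,
                L=L_i,
            )
        )
    return out


def carrier_spectrum(genotypes: GenotypeMatrix, dset: DeleteriousSet) -> CarrierSpectrum:
    """Carrier count and frequency per dSNP locus (carriers = dosage >= 1)."""
    sub = _dsnp_submatrix(genotypes, dset)
    carriers = np.sum(sub >= 1, axis=0).astype(np.int64)
    return CarrierSpectrum(dset.keys(), carriers, genotypes.n_samples)


def zero_burden_samples(estimates: Sequence[BurdenEstimate]) -> list[str]:
    """Samples with exactly zero total burden (no deleterious alleles called)."""
    return [est.sample_id for est in estimates if est.total_burden == 0.0]


def write_burdens(estimates: Sequence[BurdenEstimate], tsv_path) -> None:
    lines = ["sample\tn_het\tn_hom\thom_burden\thet_burden\ttotal_burden"]
    for est in estimates:
        lines.append(
            f"{est.sample_id}\t{est.n_het}\t{est.n_hom}"
            f"\t{fmt(est.hom_burden, FREQUENCY_DECIMALS)}"
            f"\t{fmt(est.het_burden, FREQUENCY_DECIMALS)}"
            f"\t{fmt(est.total_burden, FREQUENCY_DECIMALS)}"
        )
    atomic_write_text(tsv_path, "\n".join(lines) + "\n")


def write_spectrum(spectrum: CarrierSpectrum, tsv_path) -> None:
    lines = ["chrom\tpos\talt\tcarriers\tcarrier_frequency"]
    for (chrom, pos, alt), c in zip(spectrum.keys, spectrum.carrier_counts):
        f = c / spectrum.n_samples
        lines.append(f"{chrom}\t{pos}\t{alt}\t{int(c)}\t{fmt(f, FREQUENCY_DECIMALS)}")
    atomic_write_text(tsv_path, "\n".join(lines) + "\n")
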