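"""Deleterious-SNP identification.

A SNP is called deleterious (a dSNP) when, on a canonical transcript, it
carries a missense annotation with a SIFT score at or below the
deleteriousness threshold (default 0.05, inclusive — the worded SIFT
definition is "0.05 or less"; a strict ``<`` mode is available) AND its
position is evolutionarily constrained, i.e. has a rejected-substitution
(RS) score strictly greater than ``rs_min`` (default 0).  A position
absent from the constraint track fails the RS criterion: published RS
tracks list only the constrained (RS > 0) positions, so absence means
non-qualifying.

The deleterious allele is the alternate allele of the annotated variant;
no ancestral-state repolarization is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .variant_io import (
    CONSEQUENCE_CLASSES,
    SIFT_CLASSES,
    AnnotationRecord,
    ConstraintTrack,
    atomic_write_text,
)

#: The seven loss-of-function consequence classes.
LOF_CLASSES: tuple[str, ...] = (
    "splice_region_variant",
    "stop_gained",
    "splice_donor_variant",
    "start_lost",
    "splice_acceptor_variant",
    "stop_lost",
    "stop_retained_variant",
)

#: Most-severe-first ranking used to collapse a SNP's multiple
#: annotations to one consequence (standard annotator ordering,
#: restricted to the classes a SNP-only panel can produce).
SEVERITY_ORDER: tuple[str, ...] = (
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "missense_variant",
    "splice_region_variant",
    "stop_retained_variant",
    "synonymous_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intergenic_variant",
    "other",
)

_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}


@dataclass
class ConsequenceTally:
    """Counts per consequence class, with the loss-of-function aggregate."""

    counts: dict[str, int]

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "ConsequenceTally":
        unknown = set(counts) - set(CONSEQUENCE_CLASSES) - {"other"}
        if unknown:
            raise ValueError(f"unknown consequence classes {sorted(unknown)}")
        return cls({c: int(counts.get(c, 0)) for c in (*CONSEQUENCE_CLASSES, "other")})

    @property
    def total(self) -> int:
        """Total count over the 16 known classes ("other" excluded)."""
        return sum(self.counts[c] for c in CONSEQUENCE_CLASSES)

    @property
    def lof_total(self) -> int:
        """Sum over the seven loss-of-function classes."""
        return sum(self.counts[c] for c in LOF_CLASSES)


@dataclass(frozen=True)
class DeleteriousLocus:
    """One identified dSNP: position, deleterious allele and its scores."""

    chrom: str
    pos: int
    alt: str  # the deleterious allele
    sift_score: float
    rs_score: float
    gene: str = ""
    transcript_id: str = ""


@dataclass
class DeleteriousSet:
    """The identified dSNP loci; ``L`` is the burden denominator."""

    loci: list[DeleteriousLocus] = field(default_factory=list)

    @property
    def L(self) -> int:
        return len(self.loci)

    def keys(self) -> list[tuple[str, int, str]]:
        return [(d.chrom, d.pos, d.alt) for d in self.loci]


def tally_consequences(
    annotations: Iterable[AnnotationRecord], per_snp: bool = False
) -> ConsequenceTally:
    """Tally consequence classes over annotation rows.

    With ``per_snp=True`` each SNP contributes once, through its single
    most severe consequence under :data:`SEVERITY_ORDER`; otherwise every
    (variant, transcript) row counts.
    """
    counts = {c: 0 for c in (*CONSEQUENCE_CLASSES, "other")}
    if per_snp:
        best: dict[tuple[str, int, str], str] = {}
        for rec in annotations:
            cur = best.get(rec.locus_key)
            if cur is None or _SEVERITY_RANK[rec.consequence] < _SEVERITY_RANK[cur]:
                best[rec.locus_key] = rec.consequence
        for consequence in best.values():
            counts[consequence] += 1
    else:
        for rec in annotations:
            counts[rec.consequence] += 1
    return ConsequenceTally(counts)


def tally_sift(annotations: Iterable[AnnotationRecord]) -> dict[str, int]:
    """Counts per SIFT class plus their sum under key "total"."""
    counts = {c: 0 for c in SIFT_CLASSES}
    for rec in annotations:
        if rec.sift_class is not None:
            counts[rec.sift_class] += 1
    counts["total"] = sum(counts[c] for c in SIFT_CLASSES)
    return counts


def _passes(
    rec: AnnotationRecord,
    constraint: ConstraintTrack,
    sift_max: float,
    rs_min: float,
    canonical_only: bool,
    sift_strict: bool,
) -> bool:
    if rec.consequence != "missense_variant":
        return False
    if canonical_only and not rec.canonical:
        return False
    if rec.sift_score is None:
        return False
    if sift_strict:
        if not rec.sift_score < sift_max:
            return False
    elif not rec.sift_score <= sift_max:
        return False
    rs = constraint.get(rec.locus_key[0], rec.locus_key[1])
    return rs is not None and rs > rs_min


def identify_dsnps(
    annotations: Sequence[AnnotationRecord],
    constraint: ConstraintTrack,
    sift_max: float = 0.05,
    rs_min: float = 0.0,
    canonical_only: bool = True,
    sift_strict: bool = False,
) -> DeleteriousSet:
    """Apply the SIFT + canonical + constraint filter cascade.

    A SNP is retained iff at least one of its annotations is a
    (canonical, when ``canonical_only``) missense record with a
    qualifying SIFT score, and its position has RS strictly above
    ``rs_min``.  One entry per locus, ordered by (chrom, pos).
    """
    chosen: dict[tuple[str, int, str], AnnotationRecord] = {}
    for rec in annotations:
        if not _passes(rec, constraint, sift_max, rs_min, canonical_only, sift_strict):
            continue
        cur = chosen.get(rec.locus_key)
        # keep the most deleterious (lowest) SIFT score among qualifying rows
        if cur is None or rec.sift_score < cur.sift_score:
            chosen[rec.locus_key] = rec
    loci = [
        DeleteriousLocus(
            chrom=k[0],
            pos=k[1],
            alt=k[2],
            sift_score=rec.sift_score,
            rs_score=constraint.get(k[0], k[1]),
            gene=rec.gene,
            transcript_id=rec.transcript_id,
        )
        for k, rec in chosen.items()
    ]
    loci.sort(key=lambda d: (d.chrom, d.pos, d.alt))
    return DeleteriousSet(loci)


def per_chromosome_counts(dset: DeleteriousSet) -> dict[str, int]:
    """dSNP count per chromosome; values sum to ``dset.L``."""
    counts: dict[str, int] = {}
    for d in dset.loci:
        counts[d.chrom] = counts.get(d.chrom, 0) + 1
    return counts


def write_dsnps(dset: DeleteriousSet, tsv_path) -> None:
    lines = ["chrom\tpos\talt\tgene\ttranscript\tsift_score\trs_score"]
    for d in dset.loci:
        lines.append(
            f"{d.chrom}\t{d.pos}\t{d.alt}\t{d.gene}\t{d.transcript_id}"
            f"\t{d.sift_score:.4f}\t{d.rs_score:.4f}"
        )
    atomic_write_text(tsv_path, "\n".join(lines) + "\n")


def read_dsnps(tsv_path) -> DeleteriousSet:
    import csv

    loci = []
    with open(tsv_path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            loci.append(
                DeleteriousLocus(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    alt=row["alt"],
                    sift_score=float(row["sift_score"]),
                    rs_score=float(row["rs_score"]),
                    gene=row.get("gene", ""),
                    transcript_id=row.get("transcript", ""),
                )
            )
    return DeleteriousSet(loci)
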