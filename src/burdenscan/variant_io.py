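"""Readers and writers for the four pipeline inputs.

The pipeline consumes four artifacts:

* biallelic SNP genotypes in VCF 4.x (plain or bgzipped),
* a per-(variant, transcript) annotation table in the tab-separated
  dialect of a variant-effect annotator (``Location``, ``Allele``,
  ``Gene``, ``Feature``, ``Consequence``, ``CANONICAL`` as YES/blank,
  ``SIFT`` as ``class(score)`` or blank),
* a positional constraint track (``chrom``, ``pos``, ``score`` TSV)
  carrying rejected-substitution (RS) scores,
* a passport CSV with one row of categorical descriptors per sample.

All coordinates are 1-based (VCF convention); the constraint track must
use the same convention and the same assembly as the VCF.  All writers
emit UTF-8 with LF line endings.
"""

from __future__ import annotations

import csv
import os
import re
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

#: Dosage code for a missing genotype call.
MISSING: int = -1

#: Closed consequence vocabulary (the 16 coding/non-coding classes the
#: annotator emits for a SNP-only panel) plus the catch-all "other".
CONSEQUENCE_CLASSES: tuple[str, ...] = (
    "missense_variant",
    "splice_region_variant",
    "stop_gained",
    "splice_donor_variant",
    "start_lost",
    "splice_acceptor_variant",
    "stop_lost",
    "stop_retained_variant",
    "synonymous_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intergenic_variant",
)

SIFT_CLASSES: tuple[str, ...] = (
    "deleterious",
    "deleterious_low_confidence",
    "tolerated",
    "tolerated_low_confidence",
)

PASSPORT_FIELDS: tuple[str, ...] = (
    "panel",
    "material_type",
    "growth_habit",
    "row_type",
    "country",
    "region",
    "core_flag",
)

_BASES = frozenset("ACGT")

_SIFT_RE = re.compile(r"^(?P<cls>[a-z_]+)\((?P<score>[0-9.eE+-]+)\)$")


class VariantIOError(ValueError):
    """Raised when an input artifact violates the documented format."""


@dataclass(frozen=True, order=True)
class Locus:
    """A biallelic SNP locus (1-based coordinates)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantIOError(f"position must be >= 1, got {self.pos}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise VariantIOError(
                f"{self.chrom}:{self.pos} is not a SNP (ref={self.ref!r}, alt={self.alt!r})"
            )
        if self.ref == self.alt:
            raise VariantIOError(f"{self.chrom}:{self.pos} ref equals alt ({self.ref})")

    @property
    def key(self) -> tuple[str, int, str]:
        """The (chrom, pos, alt) join key used to pair annotations to loci."""
        return (self.chrom, self.pos, self.alt)


class GenotypeMatrix:
    """N samples x M loci of alternate-allele dosages in {0, 1, 2, MISSING}.

    Sample and locus order are preserved exactly as read from the VCF.
    Dosage is stored as an ``int8`` array with :data:`MISSING` (=-1)
    marking uncalled genotypes.
    """

    def __init__(self, samples: Sequence[str], loci: Sequence[Locus], dosage: np.ndarray):
        dosage = np.asarray(dosage, dtype=np.int8)
        if dosage.shape != (len(samples), len(loci)):
            raise VariantIOError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(samples)} samples x {len(loci)} loci"
            )
        bad = ~np.isin(dosage, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise VariantIOError(
                f"invalid dosage {dosage[i, j]} for sample {samples[i]} at locus index {j}"
            )
        self.samples = list(samples)
        self.loci = list(loci)
        self.dosage = dosage
        self._locus_index = {loc.key: m for m, loc in enumerate(self.loci)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, key: tuple[str, int, str]) -> int | None:
        return self._locus_index.get(key)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.loci == other.loci
            and np.array_equal(self.dosage, other.dosage)
        )


@dataclass(frozen=True)
class AnnotationRecord:
    """One (variant, transcript) row of the annotation table."""

    locus_key: tuple[str, int, str]  # (chrom, pos, alt)
    transcript_id: str
    consequence: str
    canonical: bool
    sift_class: str | None = None
    sift_score: float | None = None
    gene: str = ""

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCE_CLASSES and self.consequence != "other":
            raise VariantIOError(f"unknown consequence class {self.consequence!r}")
        if (self.sift_class is None) != (self.sift_score is None):
            raise VariantIOError(
                f"SIFT class and score must be jointly present or absent "
                f"({self.locus_key}, {self.transcript_id})"
            )


class ConstraintTrack:
    """Positional RS scores: a map from (chrom, 1-based pos) to a real score."""

    def __init__(self, entries: Mapping[tuple[str, int], float] | None = None):
        self._entries: dict[tuple[str, int], float] = dict(entries or {})

    def get(self, chrom: str, pos: int) -> float | None:
        """Score at a position, or None when the track has no entry there."""
        return self._entries.get((chrom, pos))

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()


class PassportTable:
    """Per-sample categorical descriptors; "Unknown" marks absent values."""

    def __init__(self, records: Mapping[str, dict[str, str]]):
        self._records = {
            sid: {f: (rec.get(f) or "Unknown") for f in PASSPORT_FIELDS}
            for sid, rec in records.items()
        }

    def get(self, sample_id: str) -> dict[str, str] | None:
        return self._records.get(sample_id)

    def labels(self, samples: Sequence[str], field: str) -> list[str]:
        """Group labels for the given samples; unlisted samples get "Unknown"."""
        if field not in PASSPORT_FIELDS:
            raise VariantIOError(f"unknown passport field {field!r}")
        return [
            (self._records[s][field] if s in self._records else "Unknown") for s in samples
        ]

    def __len__(self) -> int:
        return len(self._records)

    def items(self):
        return self._records.items()


# ---------------------------------------------------------------------------
# readers


def read_genotypes(vcf_path: str | Path, skip_nonbiallelic: bool = False) -> GenotypeMatrix:
    """Load a VCF into a :class:`GenotypeMatrix`.

    Dosage is the count of alternate alleles in the GT call; ``./.`` maps
    to :data:`MISSING`.  Phased and unphased calls are treated
    identically.  Multi-allelic or non-SNP records raise
    :class:`VariantIOError` unless ``skip_nonbiallelic`` downgrades them
    to a skip-with-warning.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if not samples:
        raise VariantIOError(f"{vcf_path}: VCF contains no samples")
    loci: list[Locus] = []
    rows: list[np.ndarray] = []
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    code = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            msg = (
                f"{vcf_path}: record {v.CHROM}:{v.POS} ({v.REF}->{','.join(v.ALT) or '.'}) "
                f"is not a biallelic SNP"
            )
            if skip_nonbiallelic:
                warnings.warn(msg + "; skipped")
                continue
            raise VariantIOError(msg)
        gt = v.gt_types
        if gt is None or len(gt) != len(samples):
            raise VariantIOError(
                f"{vcf_path}: record {v.CHROM}:{v.POS} lacks GT calls for all samples"
            )
        loci.append(Locus(v.CHROM, v.POS, v.REF, v.ALT[0], v.ID))
        rows.append(code[np.asarray(gt, dtype=np.int64)])
    dosage = (
        np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, loci, dosage)


def _parse_sift(raw: str, line_no: int) -> tuple[str | None, float | None]:
    raw = raw.strip()
    if raw in ("", "-", "."):
        return None, None
    m = _SIFT_RE.match(raw)
    if not m:
        raise VariantIOError(f"line {line_no}: malformed SIFT field {raw!r}")
    cls = m.group("cls")
    if cls not in SIFT_CLASSES:
        raise VariantIOError(f"line {line_no}: unknown SIFT class {cls!r}")
    score = float(m.group("score"))
    if not 0.0 <= score <= 1.0:
        raise VariantIOError(f"line {line_no}: SIFT score {score} outside [0, 1]")
    return cls, score


def read_annotations(tsv_path: str | Path) -> list[AnnotationRecord]:
    """Parse the annotator's tab-separated output into annotation records.

    Expected header columns: ``Location`` (chrom:pos), ``Allele``,
    ``Gene``, ``Feature`` (transcript id), ``Consequence``, ``CANONICAL``
    (YES or blank), ``SIFT`` (``class(score)`` or blank).  A consequence
    outside the closed vocabulary is mapped to "other" with a warning.
    """
    records: list[AnnotationRecord] = []
    with open(tsv_path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"Location", "Allele", "Feature", "Consequence", "CANONICAL", "SIFT"}
        missing_cols = required - set(reader.fieldnames or [])
        if missing_cols:
            raise VariantIOError(f"{tsv_path}: missing columns {sorted(missing_cols)}")
        for line_no, row in enumerate(reader, start=2):
            try:
                chrom, pos_s = row["Location"].rsplit(":", 1)
                pos = int(pos_s)
            except (ValueError, AttributeError) as exc:
                raise VariantIOError(
                    f"{tsv_path} line {line_no}: bad Location {row.get('Location')!r}"
                ) from exc
            consequence = row["Consequence"].strip()
            if consequence not in CONSEQUENCE_CLASSES:
                warnings.warn(
                    f"{tsv_path} line {line_no}: consequence {consequence!r} "
                    f"outside the known vocabulary; mapped to 'other'"
                )
                consequence = "other"
            sift_class, sift_score = _parse_sift(row["SIFT"] or "", line_no)
            records.append(
                AnnotationRecord(
                    locus_key=(chrom, pos, row["Allele"].strip()),
                    transcript_id=row["Feature"].strip(),
                    consequence=consequence,
                    canonical=row["CANONICAL"].strip() == "YES",
                    sift_class=sift_class,
                    sift_score=sift_score,
                    gene=(row.get("Gene") or "").strip(),
                )
            )
    return records


def read_constraint(tsv_path: str | Path) -> ConstraintTrack:
    """Load the (chrom, pos, score) constraint TSV into a lookup track.

    Duplicate positions with identical scores collapse silently; a
    conflicting duplicate is an error.
    """
    entries: dict[tuple[str, int], float] = {}
    with open(tsv_path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"chrom", "pos", "score"}
        missing_cols = required - set(reader.fieldnames or [])
        if missing_cols:
            raise VariantIOError(f"{tsv_path}: missing columns {sorted(missing_cols)}")
        for line_no, row in enumerate(reader, start=2):
            key = (row["chrom"].strip(), int(row["pos"]))
            score = float(row["score"])
            if key in entries and entries[key] != score:
                raise VariantIOError(
                    f"{tsv_path} line {line_no}: conflicting scores for "
                    f"{key[0]}:{key[1]} ({entries[key]} vs {score})"
                )
            entries[key] = score
    return ConstraintTrack(entries)


def read_passport(
    csv_path: str | Path,
    country_to_region: Mapping[str, str] | None = None,
    genotyped_samples: Iterable[str] | None = None,
) -> PassportTable:
    """Load the passport CSV; blank fields become "Unknown".

    A blank region is derived from the country through
    ``country_to_region`` when a mapping is supplied.  Samples absent
    from ``genotyped_samples`` (when given) are retained with a warning.
    """
    genotyped = set(genotyped_samples) if genotyped_samples is not None else None
    records: dict[str, dict[str, str]] = {}
    with open(csv_path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if "sample" not in (reader.fieldnames or []):
            raise VariantIOError(f"{csv_path}: missing 'sample' column")
        for row in reader:
            sid = row["sample"].strip()
            rec = {f: (row.get(f) or "").strip() for f in PASSPORT_FIELDS}
            if not rec["region"] and country_to_region is not None:
                rec["region"] = country_to_region.get(rec["country"], "")
            records[sid] = rec
            if genotyped is not None and sid not in genotyped:
                warnings.warn(f"{csv_path}: passport sample {sid} absent from genotypes")
    return PassportTable(records)


# ---------------------------------------------------------------------------
# writers


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text to ``path`` via a temp file + rename (never a partial file)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes(matrix: GenotypeMatrix, vcf_path: str | Path) -> None:
    """Write the matrix as a plain-text VCF 4.2 file."""
    contigs = dict.fromkeys(loc.chrom for loc in matrix.loci)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        *(f"##contig=<ID={c}>" for c in contigs),
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples),
    ]
    for m, loc in enumerate(matrix.loci):
        calls = "\t".join(_GT[int(d)] for d in matrix.dosage[:, m])
        lines.append(
            f"{loc.chrom}\t{loc.pos}\t{loc.id or '.'}\t{loc.ref}\t{loc.alt}\t.\t.\t.\tGT\t{calls}"
        )
    atomic_write_text(vcf_path, "\n".join(lines) + "\n")


def write_annotations(records: Sequence[AnnotationRecord], tsv_path: str | Path) -> None:
    lines = ["Location\tAllele\tGene\tFeature\tConsequence\tCANONICAL\tSIFT"]
    for r in records:
        chrom, pos, alt = r.locus_key
        sift = f"{r.sift_class}({r.sift_score:g})" if r.sift_class is not None else "-"
        canonical = "YES" if r.canonical else "-"
        lines.append(
            f"{chrom}:{pos}\t{alt}\t{r.gene}\t{r.transcript_id}\t{r.consequence}\t{canonical}\t{sift}"
        )
    atomic_write_text(tsv_path, "\n".join(lines) + "\n")


def write_constraint(track: ConstraintTrack, tsv_path: str | Path) -> None:
    lines = ["chrom\tpos\tscore"]
    for (chrom, pos), score in sorted(track.items()):
        lines.append(f"{chrom}\t{pos}\t{score:g}")
    atomic_write_text(tsv_path, "\n".join(lines) + "\n")


def write_passport(table: PassportTable, csv_path: str | Path) -> None:
    lines = ["sample," + ",".join(PASSPORT_FIELDS)]
    for sid, rec in table.items():
        lines.append(sid + "," + ",".join(rec[f] for f in PASSPORT_FIELDS))
    atomic_write_text(csv_path, "\n".join(lines) + "\n")
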