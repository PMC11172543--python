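"""End-to-end pipeline orchestration.

Runs identify -> burden -> spectrum -> apd -> summarize -> correlate ->
zone from one configuration, writing every stage table plus a JSON run
report with parameter values, input checksums and headline numbers.
All outputs are written atomically (temp file + rename), so a failed
run never leaves a truncated table behind.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import variant_io
from .variant_io import atomic_write_text
from .dsnp import identify_dsnps, per_chromosome_counts, write_dsnps
from .burden import (
    carrier_spectrum,
    estimate_burdens,
    write_burdens,
    write_spectrum,
    zero_burden_samples,
)
from .distinctness import apd_vector, write_apd
from .cohort import (
    anova_oneway,
    correlate_burden_apd,
    group_summary,
    selection_zone,
    write_group_table,
)
from .rounding import fmt

logger = logging.getLogger("burdenscan")


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """All inputs and thresholds for one pipeline run."""

    vcf: str
    annotations: str
    constraint: str
    passport: str
    outdir: str
    sift_max: float = 0.05
    sift_strict: bool = False
    rs_min: float = 0.0
    canonical_only: bool = True
    missing_policy: str = "zero"
    distance: str = "allele_sharing"
    group_fields: tuple[str, ...] = ("material_type", "growth_habit", "region")
    exclude_labels: tuple[str, ...] = ("Unknown",)
    zone_apd_min: float | None = None  # default: cohort median APD
    zone_burden_max: float | None = None  # default: cohort median burden
    skip_nonbiallelic: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("group_fields", "exclude_labels"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        logger.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage label
            raise StageError(name, exc) from exc

    stage_names = {
        "vcf": "read_genotypes",
        "annotations": "read_annotations",
        "constraint": "read_constraint",
        "passport": "read_passport",
    }
    checksums = {
        name: stage(stage_names[name], _sha256, getattr(config, name))
        for name in stage_names
    }
    genotypes = stage(
        "read_genotypes",
        variant_io.read_genotypes,
        config.vcf,
        skip_nonbiallelic=config.skip_nonbiallelic,
    )
    annotations = stage("read_annotations", variant_io.read_annotations, config.annotations)
    constraint = stage("read_constraint", variant_io.read_constraint, config.constraint)
    passport = stage("read_passport", variant_io.read_passport, config.passport)

    dset = stage(
        "identify",
        identify_dsnps,
        annotations,
        constraint,
        sift_max=config.sift_max,
        rs_min=config.rs_min,
        canonical_only=config.canonical_only,
        sift_strict=config.sift_strict,
    )
    write_dsnps(dset, outdir / "dsnps.tsv")

    estimates = stage("burden", estimate_burdens, genotypes, dset, config.missing_policy)
    write_burdens(estimates, outdir / "burdens.tsv")
    spectrum = stage("spectrum", carrier_spectrum, genotypes, dset)
    write_spectrum(spectrum, outdir / "spectrum.tsv")
    apd = stage("apd", apd_vector, genotypes, config.distance)
    write_apd(apd, outdir / "apd.tsv")

    b_tot = np.array([est.total_burden for est in estimates])
    exclude = set(config.exclude_labels)
    group_tables = {}
    for field_name in config.group_fields:
        labels = passport.labels(genotypes.samples, field_name)
        summaries = stage(f"summarize:{field_name}", group_summary, b_tot, labels)
        try:
            anova = anova_oneway(b_tot, labels, exclude=exclude)
        except ValueError:
            anova = None
        write_group_table(summaries, outdir / f"group_{field_name}.tsv", anova)
        group_tables[field_name] = {
            "groups": {g: s.n for g, s in summaries.items()},
            "anova_p": anova.p_value if anova else None,
            "anova_F": anova.F if anova else None,
        }

    r, p = stage("correlate", correlate_burden_apd, b_tot, apd.apd)
    apd_min = (
        config.zone_apd_min if config.zone_apd_min is not None else float(np.median(apd.apd))
    )
    burden_max = (
        config.zone_burden_max
        if config.zone_burden_max is not None
        else float(np.median(b_tot))
    )
    zone = stage(
        "zone", selection_zone, b_tot, apd.apd, genotypes.samples, apd_min, burden_max
    )
    atomic_write_text(outdir / "zone.txt", "\n".join(zone.members) + "\n")

    zero = zero_burden_samples(estimates)
    report = {
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()
        },
        "input_checksums": checksums,
        "n_samples": genotypes.n_samples,
        "n_loci": genotypes.n_loci,
        "L": dset.L,
        "per_chromosome": per_chromosome_counts(dset),
        "burden_mean": float(b_tot.mean()),
        "burden_min": float(b_tot.min()),
        "burden_max": float(b_tot.max()),
        "zero_burden_count": len(zero),
        "rare_fraction_0.001": spectrum.rare_fraction(0.001),
        "burden_apd_r": r,
        "burden_apd_p": p,
        "zone": {"apd_min": apd_min, "burden_max": burden_max, "n_members": len(zone.members)},
        "groups": group_tables,
    }
    atomic_write_text(outdir / "run_report.json", json.dumps(report, indent=1, sort_keys=True))
    logger.info(
        "done: L=%d, mean burden %s, %d zero-burden samples, r=%.3f",
        dset.L,
        fmt(report["burden_mean"], 3),
        len(zero),
        r,
    )
    return report
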