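"""Group-wise burden characterization.

Summaries (n, mean, SD, min, max of total burden per group), one-way
fixed-effects ANOVA across groups, the Pearson correlation between
burden and genetic distinctness (APD), and the rectangular
selection-target-zone filter used to pick germplasm that is both
genetically distinct (high APD) and lightly burdened (low B_tot).

SD uses the sample (n - 1) denominator and is reported as NA for
single-sample groups.  "Unknown" categories appear in summary tables
but are excluded from ANOVA by default; the exclusion set is
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .variant_io import atomic_write_text
from .rounding import COUNTRY_DECIMALS, fmt


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive statistics of total burden for one group."""

    label: str
    n: int
    mean: float
    sd: float | None  # None (printed NA) when n == 1
    min: float
    max: float


@dataclass(frozen=True)
class AnovaResult:
    """One-way fixed-effects ANOVA across groups."""

    F: float
    df_between: int
    df_within: int
    p_value: float


@dataclass
class SelectionZone:
    """Samples inside the rectangle apd >= apd_min and burden <= burden_max."""

    apd_min: float
    burden_max: float
    members: list[str]


def group_summary(
    burdens: Sequence[float], labels: Sequence[str]
) -> dict[str, GroupSummary]:
    """Per-group n/mean/sd/min/max, keyed by group label."""
    if len(burdens) == 0:
        raise ValueError("no burden values supplied")
    if len(burdens) != len(labels):
        raise ValueError("burdens and labels differ in length")
    values: dict[str, list[float]] = {}
    for b, g in zip(burdens, labels):
        values.setdefault(g, []).append(float(b))
    out = {}
    for g, vals in values.items():
        arr = np.asarray(vals)
        out[g] = GroupSummary(
            label=g,
            n=len(arr),
            mean=float(arr.mean()),
            sd=float(arr.std(ddof=1)) if len(arr) > 1 else None,
            min=float(arr.min()),
            max=float(arr.max()),
        )
    return out


def anova_oneway(
    burdens: Sequence[float],
    labels: Sequence[str],
    exclude: frozenset[str] | set[str] = frozenset({"Unknown"}),
) -> AnovaResult:
    """Standard one-way ANOVA: F = (SSB / (k-1)) / (SSW / (n-k)).

    Groups named in ``exclude`` are dropped before testing.  When every
    value is identical (SSB = SSW = 0) the statistic is 0; SSW = 0 with
    SSB > 0 yields p = 0 with a warning.
    """
    groups: dict[str, list[float]] = {}
    for b, g in zip(burdens, labels):
        if g in exclude:
            continue
        groups.setdefault(g, []).append(float(b))
    k = len(groups)
    n = sum(len(v) for v in groups.values())
    if k < 2:
        raise ValueError("ANOVA requires at least two groups after exclusion")
    if n <= k:
        raise ValueError("ANOVA requires more observations than groups")
    all_vals = np.concatenate([np.asarray(v) for v in groups.values()])
    grand = all_vals.mean()
    ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
    ssw = sum(float(np.sum((np.asarray(v) - np.mean(v)) ** 2)) for v in groups.values())
    df_b, df_w = k - 1, n - k
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0)
        import warnings

        warnings.warn("zero within-group variance with nonzero between-group variance")
        return AnovaResult(float("inf"), df_b, df_w, 0.0)
    F = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), df_b, df_w, p)


def correlate_burden_apd(
    burdens: Sequence[float], apds: Sequence[float]
) -> tuple[float, float]:
    """Pearson r between burden and APD, with the two-sided t-transform p.

    At genebank cohort sizes (tens of thousands) even tiny r is
    significant, so r itself is the quantity of interest.
    """
    burdens = np.asarray(burdens, dtype=np.float64)
    apds = np.asarray(apds, dtype=np.float64)
    if burdens.shape != apds.shape:
        raise ValueError("paired vectors differ in length")
    if len(burdens) < 3:
        raise ValueError("correlation requires at least three pairs")
    if np.std(burdens) == 0 or np.std(apds) == 0:
        raise ValueError("zero variance in one of the paired vectors")
    r, p = stats.pearsonr(burdens, apds)
    return float(r), float(p)


def selection_zone(
    burdens: Sequence[float],
    apds: Sequence[float],
    samples: Sequence[str],
    apd_min: float,
    burden_max: float,
) -> SelectionZone:
    """Members of the rectangle apd >= apd_min AND burden <= burden_max."""
    if not (np.isfinite(apd_min) and np.isfinite(burden_max)):
        raise ValueError("zone thresholds must be finite")
    members = [
        s
        for s, b, a in zip(samples, burdens, apds)
        if a >= apd_min and b <= burden_max
    ]
    return SelectionZone(apd_min, burden_max, members)


def write_group_table(
    summaries: Mapping[str, GroupSummary],
    tsv_path,
    anova: AnovaResult | None = None,
    decimals: int = COUNTRY_DECIMALS,
) -> None:
    lines = ["group\tcount\tmean\tsd\tmin\tmax"]
    for g in sorted(summaries, key=lambda g: (g == "Unknown", summaries[g].mean)):
        s = summaries[g]
        sd = fmt(s.sd, decimals) if s.sd is not None else "NA"
        lines.append(
            f"{g}\t{s.n}\t{fmt(s.mean, decimals)}\t{sd}"
            f"\t{fmt(s.min, decimals)}\t{fmt(s.max, decimals)}"
        )
    if anova is not None:
        lines.append(
            f"# ANOVA F={anova.F:.4f} df=({anova.df_between},{anova.df_within}) "
            f"p={anova.p_value:.4g}"
        )
    atomic_write_text(tsv_path, "\n".join(lines) + "\n")
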