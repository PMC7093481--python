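"""RM-epiallele statistics and the surrounding descriptive toolkit.

The central quantity is the *RM (reduced-methylation) allele*: a sequenced
clone whose shore-region (S) CpGs are at least 75% unmethylated -- with
the canonical nine S CpGs, at least 7 of 9.  The RM allele ratio of a
sample (per allele) estimates the fraction of cells whose allele sits in
the transcriptionally permissive hypomethylated epiallele state; for a
heterozygous-knockout cell population only the wild-type allele's RM
ratio tracks functional mRNA, because knockout transcripts are removed by
nonsense-mediated decay after splicing.

Proportions get Wilson score intervals; group comparisons use the classic
pooled-variance two-sample t-test; correlations are Pearson by default
with Spearman behind a flag.  No multiple-testing correction is applied
(single-locus assay, alpha = 0.05 per test).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .pipeline import METHYLATED, MISSING, UNMETHYLATED, MethylationCall

__all__ = [
    "StatsError",
    "IncompleteSRegionError",
    "RMSummary",
    "DeltaRecord",
    "CorrelationResult",
    "TTestResult",
    "VarianceComparison",
    "rm_threshold_count",
    "classify_rm",
    "rm_allele_ratio",
    "summarize_rm",
    "passage_delta",
    "direction_concordance",
    "correlate",
    "methylation_level",
    "variance_by_allele",
    "ttest_two_sample",
]

logger = logging.getLogger(__name__)

DEFAULT_RM_FRACTION = 0.75


class StatsError(ValueError):
    pass


class IncompleteSRegionError(StatsError):
    """Raised when RM classification sees a missing S-region call."""


def rm_threshold_count(n_cpgs: int, threshold_fraction: float = DEFAULT_RM_FRACTION) -> int:
    """Smallest count k with k/n_cpgs >= threshold_fraction, i.e. ceil(f*n).

    With the canonical nine shore CpGs and the 75% rule this is 7.
    """
    if n_cpgs <= 0:
        raise StatsError("n_cpgs must be positive")
    if not (0.0 < threshold_fraction <= 1.0):
        raise StatsError("threshold_fraction must be in (0, 1]")
    k = math.ceil(threshold_fraction * n_cpgs)
    # Guard against float representation drift around exact multiples.
    while k > 1 and (k - 1) / n_cpgs >= threshold_fraction:
        k -= 1
    while k / n_cpgs < threshold_fraction:
        k += 1
    return k


def classify_rm(
    s_calls: Sequence[str], threshold_fraction: float = DEFAULT_RM_FRACTION
) -> bool:
    """Is this read an RM allele, given its S-region call vector?

    ``s_calls`` holds one ``"M"``/``"U"`` call per S-region CpG; the read
    is RM iff the unmethylated count reaches ``ceil(f * n)``.  A missing
    call is an error -- the caller must already have excluded reads with
    an incompletely called S region, since the rule's denominator is the
    full region.
    """
    if not s_calls:
        raise IncompleteSRegionError("incomplete_s_region: empty call vector")
    for c in s_calls:
        if c not in (METHYLATED, UNMETHYLATED):
            raise IncompleteSRegionError(
                f"incomplete_s_region: call {c!r} is not M/U"
            )
    cutoff = rm_threshold_count(len(s_calls), threshold_fraction)
    return sum(1 for c in s_calls if c == UNMETHYLATED) >= cutoff


@dataclass(frozen=True)
class RMSummary:
    """Per-sample, per-allele RM allele ratio with a Wilson 95% interval."""

    sample_id: str
    passage_label: str
    allele: str
    n_reads: int
    n_rm: int
    ratio: float
    ci_low: float
    ci_high: float


def rm_allele_ratio(
    rm_flags: Sequence[bool],
    sample_id: str = "",
    passage_label: str = "",
    allele: str = "",
    alpha: float = 0.05,
) -> RMSummary:
    """Summarize RM classifications into a ratio with a Wilson score interval.

    With no evaluable reads the ratio and interval are NaN-flagged.
    """
    n = len(rm_flags)
    n_rm = int(sum(bool(f) for f in rm_flags))
    if n == 0:
        return RMSummary(
            sample_id, passage_label, allele, 0, 0,
            float("nan"), float("nan"), float("nan"),
        )
    low, high = proportion_confint(n_rm, n, alpha=alpha, method="wilson")
    return RMSummary(
        sample_id, passage_label, allele, n, n_rm, n_rm / n, float(low), float(high)
    )


def summarize_rm(
    calls: Iterable[MethylationCall],
    s_positions: Sequence[int],
    threshold_fraction: float = DEFAULT_RM_FRACTION,
    alleles: Sequence[str] = ("WT", "KO"),
) -> list[RMSummary]:
    """Group QC-passing reads by (sample, passage, allele) and compute RM ratios.

    Reads with an ambiguous allele or any missing S-region CpG are
    excluded from the ratios (logged); the denominator of each summary is
    the evaluable read count only.
    """
    groups: dict[tuple[str, str, str], list[bool]] = {}
    n_incomplete = 0
    for c in calls:
        if not c.qc_pass or c.allele not in alleles:
            continue
        s_calls = [c.calls.get(p, MISSING) for p in s_positions]
        if any(v not in (METHYLATED, UNMETHYLATED) for v in s_calls):
            n_incomplete += 1
            continue
        key = (c.sample_id, c.passage_label, c.allele)
        groups.setdefault(key, []).append(classify_rm(s_calls, threshold_fraction))
    if n_incomplete:
        logger.info("summarize_rm: %d reads excluded (incomplete S region)", n_incomplete)
    return [
        rm_allele_ratio(flags, sample_id=s, passage_label=p, allele=a)
        for (s, p, a), flags in sorted(groups.items())
    ]


@dataclass(frozen=True)
class DeltaRecord:
    """Signed late-minus-early change in RM ratio and expression for one line."""

    sample_id: str
    allele: str
    delta_rm: float
    delta_expr: float


def passage_delta(
    early: Sequence[RMSummary],
    late: Sequence[RMSummary],
    expression_deltas: Mapping[str, float] | None = None,
) -> list[DeltaRecord]:
    """Pair early/late summaries per (sample, allele) and take differences.

    Samples lacking one passage are omitted with a warning; duplicate
    (sample, allele) summaries within a passage are an error.
    """

    def keyed(summaries: Sequence[RMSummary], label: str) -> dict[tuple[str, str], RMSummary]:
        out: dict[tuple[str, str], RMSummary] = {}
        for s in summaries:
            key = (s.sample_id, s.allele)
            if key in out:
                raise StatsError(f"duplicate {label} summary for {key}")
            out[key] = s
        return out

    early_map = keyed(early, "early")
    late_map = keyed(late, "late")
    records = []
    for key in sorted(early_map.keys() | late_map.keys()):
        if key not in early_map or key not in late_map:
            logger.warning("passage_delta: %s present in only one passage; omitted", key)
            continue
        sample_id, allele = key
        d_expr = float("nan")
        if expression_deltas is not None:
            d_expr = float(expression_deltas.get(sample_id, float("nan")))
        records.append(
            DeltaRecord(
                sample_id=sample_id,
                allele=allele,
                delta_rm=late_map[key].ratio - early_map[key].ratio,
                delta_expr=d_expr,
            )
        )
    return records


def _sign(x: float) -> str:
    if x > 0:
        return "+"
    if x < 0:
        return "-"
    return "0"


def direction_concordance(deltas: Sequence[DeltaRecord]) -> pd.DataFrame:
    """Tabulate the direction of expression vs RM-ratio change per line.

    A line is concordant when both deltas have the same nonzero sign;
    exact-zero deltas are reported as their own ``"0"`` category and never
    count as concordant.
    """
    if not deltas:
        raise StatsError("direction_concordance requires at least one delta")
    rows = []
    for d in deltas:
        s_expr, s_rm = _sign(d.delta_expr), _sign(d.delta_rm)
        rows.append(
            {
                "sample_id": d.sample_id,
                "allele": d.allele,
                "sign_expr": s_expr,
                "sign_rm": s_rm,
                "concordant": s_expr == s_rm and s_expr != "0",
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    method: str
    defined: bool = True


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> CorrelationResult:
    """Pearson (default) or Spearman correlation with a two-sided p-value.

    Requires at least three finite pairs; a zero-variance series yields
    an undefined (NaN-flagged) result rather than an exception.
    """
    xs = np.asarray(x, dtype=float)
    ys = np.asarray(y, dtype=float)
    if xs.shape != ys.shape:
        raise StatsError("x and y must have equal length")
    if xs.size < 3:
        raise StatsError("correlation requires at least 3 pairs")
    if not (np.isfinite(xs).all() and np.isfinite(ys).all()):
        raise StatsError("correlation requires finite values")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return CorrelationResult(float("nan"), float("nan"), xs.size, method, defined=False)
    if method == "pearson":
        res = sps.pearsonr(xs, ys)
    elif method == "spearman":
        res = sps.spearmanr(xs, ys)
    else:
        raise StatsError(f"unknown correlation method {method!r}")
    return CorrelationResult(float(res.statistic), float(res.pvalue), xs.size, method)


def methylation_level(
    calls: Iterable[Mapping[int, str]], positions: Sequence[int]
) -> float:
    """Pooled fraction of methylated CpG observations over ``positions``.

    Missing calls are excluded from both numerator and denominator; with
    no called observation the level is NaN (undefined).
    """
    n_meth = n_total = 0
    for call_map in calls:
        for p in positions:
            v = call_map.get(p, MISSING)
            if v == METHYLATED:
                n_meth += 1
                n_total += 1
            elif v == UNMETHYLATED:
                n_total += 1
    if n_total == 0:
        logger.warning("methylation_level: no called CpG observations; undefined")
        return float("nan")
    return n_meth / n_total


@dataclass(frozen=True)
class VarianceComparison:
    variances: dict[str, float]
    f_ratio: float  # KO / WT by convention
    n: dict[str, int]


def variance_by_allele(
    ratios_by_allele: Mapping[str, Sequence[float]],
    wt_label: str = "WT",
    ko_label: str = "KO",
) -> VarianceComparison:
    """Unbiased cross-line variances of RM ratios per allele and their ratio.

    The F-ratio is KO variance over WT variance -- the direction in which
    a more dispersed knockout allele exceeds 1.  Descriptive only; no
    significance is attached by default.
    """
    variances: dict[str, float] = {}
    counts: dict[str, int] = {}
    for allele, values in ratios_by_allele.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise StatsError(f"variance for allele {allele!r} needs >= 2 lines")
        variances[allele] = float(np.var(arr, ddof=1))
        counts[allele] = int(arr.size)
    f_ratio = float("nan")
    if wt_label in variances and ko_label in variances and variances[wt_label] > 0:
        f_ratio = variances[ko_label] / variances[wt_label]
    return VarianceComparison(variances=variances, f_ratio=f_ratio, n=counts)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p_value: float
    df: int
    degenerate: bool = False


def ttest_two_sample(
    group_a: Sequence[float], group_b: Sequence[float]
) -> TTestResult:
    """Classic pooled-variance (Student's) two-sample t-test, two-sided.

    Degenerate inputs with zero pooled variance return t=0, p=1 when the
    means coincide and a sign-infinite, degenerate-flagged result when
    they differ.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs n >= 2")
    df = int(a.size + b.size - 2)
    pooled = ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)) / df
    if pooled == 0:
        if np.mean(a) == np.mean(b):
            return TTestResult(0.0, 1.0, df)
        return TTestResult(
            math.copysign(float("inf"), float(np.mean(a) - np.mean(b))),
            0.0,
            df,
            degenerate=True,
        )
    res = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(res.statistic), float(res.pvalue), df)
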