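"""Semi-quantitative expression normalization and mRNA/preRNA bookkeeping.

Expression enters as a post-densitometry intensity table (arbitrary
units) with one row per sample x passage x target x replicate, the
targets being the assayed gene's mature mRNA, its unspliced preRNA and a
housekeeping reference (GAPDH).  Normalization is replicate-paired:
replicate i of a target is divided by replicate i of the reference, so a
triplicate stays a triplicate for downstream t-tests; the summary is
mean +/- SD (n-1 denominator).

The mRNA/preRNA ratio estimates the fraction of transcribed RNA that
survives to mature message.  In a heterozygous-knockout setting the
knockout allele contributes preRNA but no mature mRNA (nonsense-mediated
decay), so functional-mRNA accounting uses wild-type-linked quantities
only -- the knockout allele's methylation state never enters that column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionError",
    "NormalizedLevel",
    "RatioSummary",
    "normalize",
    "mrna_prerna_ratio",
    "expression_delta",
    "read_expression_table",
    "normalize_table",
    "mrna_prerna_table",
    "expression_deltas",
]

logger = logging.getLogger(__name__)

REFERENCE_TARGET = "reference"


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizedLevel:
    """Reference-normalized level of one target in one sample x passage."""

    sample_id: str
    passage_label: str
    target: str
    mean: float
    sd: float
    n: int
    ratios: tuple[float, ...]


def normalize(
    target_intensities,
    reference_intensities,
    sample_id: str = "",
    passage_label: str = "",
    target: str = "",
) -> NormalizedLevel:
    """Replicate-paired target/reference ratios summarized as mean +/- SD.

    Raises on mismatched replicate counts or a zero/negative reference.
    Scale-invariant: rescaling both series by a common factor leaves the
    result unchanged.
    """
    t = np.asarray(target_intensities, dtype=float)
    r = np.asarray(reference_intensities, dtype=float)
    if t.size != r.size:
        raise ExpressionError(
            f"unmatched replicate counts: {t.size} target vs {r.size} reference"
        )
    if t.size == 0:
        raise ExpressionError("no replicates")
    if (t < 0).any():
        raise ExpressionError("negative target intensity")
    bad = np.nonzero(r <= 0)[0]
    if bad.size:
        raise ExpressionError(f"non-positive reference intensity in replicate(s) {bad.tolist()}")
    ratios = t / r
    sd = float(np.std(ratios, ddof=1)) if t.size > 1 else float("nan")
    return NormalizedLevel(
        sample_id=sample_id,
        passage_label=passage_label,
        target=target,
        mean=float(np.mean(ratios)),
        sd=sd,
        n=int(t.size),
        ratios=tuple(float(x) for x in ratios),
    )


@dataclass(frozen=True)
class RatioSummary:
    """Per-replicate mRNA/preRNA ratios, summarized."""

    sample_id: str
    passage_label: str
    mean: float
    sd: float
    n: int
    ratios: tuple[float, ...]
    n_undefined: int = 0


def mrna_prerna_ratio(
    mrna: NormalizedLevel, prerna: NormalizedLevel
) -> RatioSummary:
    """Per-replicate mRNA over preRNA; a zero-preRNA replicate is flagged NaN."""
    if mrna.n != prerna.n:
        raise ExpressionError("mRNA and preRNA replicate counts differ")
    ratios = []
    n_undef = 0
    for m, p in zip(mrna.ratios, prerna.ratios):
        if p == 0:
            ratios.append(float("nan"))
            n_undef += 1
        else:
            ratios.append(m / p)
    defined = [x for x in ratios if not np.isnan(x)]
    mean = float(np.mean(defined)) if defined else float("nan")
    sd = float(np.std(defined, ddof=1)) if len(defined) > 1 else float("nan")
    if n_undef:
        logger.warning(
            "mrna_prerna_ratio: %d undefined replicate(s) in %s/%s",
            n_undef, mrna.sample_id, mrna.passage_label,
        )
    return RatioSummary(
        sample_id=mrna.sample_id,
        passage_label=mrna.passage_label,
        mean=mean,
        sd=sd,
        n=len(defined),
        ratios=tuple(ratios),
        n_undefined=n_undef,
    )


def expression_delta(early: NormalizedLevel, late: NormalizedLevel) -> float:
    """Signed change mean(late) - mean(early) of a normalized level."""
    return late.mean - early.mean


# ---------------------------------------------------------------------------
# Table-level interface (TSV contract)


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Load the intensity TSV (sample_id, passage_label, target, replicate, intensity)."""
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "passage_label": str, "target": str},
    )
    required = {"sample_id", "passage_label", "target", "replicate", "intensity"}
    missing = required - set(table.columns)
    if missing:
        raise ExpressionError(f"expression table missing columns: {sorted(missing)}")
    return table


def normalize_table(table: pd.DataFrame) -> list[NormalizedLevel]:
    """Normalize every non-reference target per sample x passage.

    Replicates are paired by their index; each sample x passage must carry
    reference rows for every replicate of its targets.
    """
    levels = []
    for (sample, passage), group in table.groupby(
        ["sample_id", "passage_label"], sort=True
    ):
        ref = group[group["target"] == REFERENCE_TARGET].sort_values("replicate")
        if ref.empty:
            raise ExpressionError(f"no reference rows for {sample}/{passage}")
        ref_by_rep = dict(zip(ref["replicate"], ref["intensity"]))
        for target, tgroup in group[group["target"] != REFERENCE_TARGET].groupby(
            "target", sort=True
        ):
            tgroup = tgroup.sort_values("replicate")
            missing_reps = set(tgroup["replicate"]) - set(ref_by_rep)
            if missing_reps:
                raise ExpressionError(
                    f"{sample}/{passage}/{target}: no reference for replicate(s) "
                    f"{sorted(missing_reps)}"
                )
            ref_vals = [ref_by_rep[r] for r in tgroup["replicate"]]
            levels.append(
                normalize(
                    tgroup["intensity"].to_numpy(),
                    ref_vals,
                    sample_id=str(sample),
                    passage_label=str(passage),
                    target=str(target),
                )
            )
    return levels


def mrna_prerna_table(levels: list[NormalizedLevel]) -> list[RatioSummary]:
    """Pair mRNA and preRNA levels per sample x passage into ratio summaries."""
    by_key: dict[tuple[str, str], dict[str, NormalizedLevel]] = {}
    for lev in levels:
        by_key.setdefault((lev.sample_id, lev.passage_label), {})[lev.target] = lev
    out = []
    for key in sorted(by_key):
        pair = by_key[key]
        if "mRNA" in pair and "preRNA" in pair:
            out.append(mrna_prerna_ratio(pair["mRNA"], pair["preRNA"]))
    return out


def expression_deltas(
    levels: list[NormalizedLevel],
    target: str = "mRNA",
    early: str = "P6",
    late: str = "P20",
) -> dict[str, float]:
    """Per-sample signed change of a target's normalized mean, late - early.

    Samples missing either passage are omitted with a warning.
    """
    by_sample: dict[str, dict[str, NormalizedLevel]] = {}
    for lev in levels:
        if lev.target == target:
            by_sample.setdefault(lev.sample_id, {})[lev.passage_label] = lev
    out = {}
    for sample in sorted(by_sample):
        passages = by_sample[sample]
        if early not in passages or late not in passages:
            logger.warning(
                "expression_deltas: %s lacks passage %s or %s; omitted",
                sample, early, late,
            )
            continue
        out[sample] = expression_delta(passages[early], passages[late])
    return out
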