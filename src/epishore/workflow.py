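"""End-to-end orchestration: clone pipeline -> RM statistics -> expression joins.

This module ties the stages into the three analyses the assay supports:

1. cell-line passage analysis -- per line x passage x allele RM ratios,
   P6->P20 deltas joined with expression deltas, direction concordance
   and the delta-vs-delta correlation per allele;
2. tissue-style analysis -- the same RM machinery on samples without a
   passage structure (falls out of the per-sample summaries);
3. probe-table correlation -- methylation beta vs expression across cell
   lines for annotated probes.

Everything is deterministic given the inputs; outputs are TSVs plus
plain-text lollipop matrices and a JSON manifest whose read accounting
reconciles exactly with the QC report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version, PackageNotFoundError
from pathlib import Path

import pandas as pd
import yaml

from . import expression as expr
from . import stats
from .pipeline import (
    PipelineConfig,
    calls_to_frame,
    load_reads,
    lollipop_text,
    qc_reports_to_frame,
    read_sample_sheet,
    run_sample,
)
from .reference import load_amplicon

__all__ = ["RunConfig", "run_analysis", "probe_correlation_report"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds for a full analysis run."""

    reference_fasta: Path
    amplicon_config: Path
    sample_sheet: Path
    expression_table: Path | None = None
    probe_table: Path | None = None
    rm_fraction: float = stats.DEFAULT_RM_FRACTION
    correlation_method: str = "pearson"
    early_passage: str = "P6"
    late_passage: str = "P20"
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        base = Path(path).parent
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}

        def resolve(key: str, required: bool = True) -> Path | None:
            if key not in cfg or cfg[key] is None:
                if required:
                    raise ValueError(f"run config missing key: {key}")
                return None
            p = Path(cfg[key])
            return p if p.is_absolute() else base / p

        if not (0.0 < float(cfg.get("rm_fraction", stats.DEFAULT_RM_FRACTION)) <= 1.0):
            raise ValueError("rm_fraction must be in (0, 1]")
        pipeline = PipelineConfig(
            min_conversion=float(cfg.get("min_conversion", 0.95)),
            min_identity=float(cfg.get("min_identity", 0.8)),
        )
        return cls(
            reference_fasta=resolve("reference_fasta"),
            amplicon_config=resolve("amplicon_config"),
            sample_sheet=resolve("sample_sheet"),
            expression_table=resolve("expression_table", required=False),
            probe_table=resolve("probe_table", required=False),
            rm_fraction=float(cfg.get("rm_fraction", stats.DEFAULT_RM_FRACTION)),
            correlation_method=str(cfg.get("correlation_method", "pearson")),
            early_passage=str(cfg.get("early_passage", "P6")),
            late_passage=str(cfg.get("late_passage", "P20")),
            pipeline=pipeline,
        )


def _package_version() -> str:
    try:
        return version("epishore")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep=".")


def run_analysis(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline and write the output bundle.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "lollipop").mkdir(exist_ok=True)

    if not Path(config.sample_sheet).exists():
        raise FileNotFoundError(f"sample sheet not found: {config.sample_sheet}")
    spec = load_amplicon(config.reference_fasta, config.amplicon_config)
    sheet = read_sample_sheet(config.sample_sheet)
    sheet_base = Path(config.sample_sheet).parent

    all_calls = []
    reports = []
    for row in sheet.itertuples(index=False):
        read_path = Path(row.read_file)
        if not read_path.is_absolute():
            read_path = sheet_base / read_path
        reads = load_reads(read_path, row.sample_id, row.passage_label, row.orientation)
        calls, report = run_sample(
            reads, spec, config.pipeline,
            sample_id=row.sample_id, passage_label=row.passage_label,
        )
        all_calls.extend(calls)
        reports.append(report)
        text = lollipop_text(calls, spec)
        (outdir / "lollipop" / f"{row.sample_id}_{row.passage_label}.txt").write_text(text)

    _write_tsv(calls_to_frame(all_calls, spec.cpg_index), outdir / "calls.tsv")
    _write_tsv(qc_reports_to_frame(reports), outdir / "qc_report.tsv")

    s_positions = spec.s_region_positions()
    summaries = stats.summarize_rm(all_calls, s_positions, config.rm_fraction)
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "passage_label": s.passage_label,
                    "allele": s.allele,
                    "n_reads": s.n_reads,
                    "n_rm": s.n_rm,
                    "ratio": s.ratio,
                    "ci_low": s.ci_low,
                    "ci_high": s.ci_high,
                }
                for s in summaries
            ]
        ),
        outdir / "rm_summary.tsv",
    )

    # Expression normalization and the passage joins
    expression_deltas: dict[str, float] = {}
    levels = []
    if config.expression_table is not None:
        table = expr.read_expression_table(config.expression_table)
        levels = expr.normalize_table(table)
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "sample_id": l.sample_id,
                        "passage_label": l.passage_label,
                        "target": l.target,
                        "mean": l.mean,
                        "sd": l.sd,
                        "n": l.n,
                    }
                    for l in levels
                ]
            ),
            outdir / "expression_normalized.tsv",
        )
        ratios = expr.mrna_prerna_table(levels)
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "sample_id": r.sample_id,
                        "passage_label": r.passage_label,
                        "mean": r.mean,
                        "sd": r.sd,
                        "n": r.n,
                    }
                    for r in ratios
                ]
            ),
            outdir / "mrna_prerna.tsv",
        )
        expression_deltas = expr.expression_deltas(
            levels, early=config.early_passage, late=config.late_passage
        )

    early = [s for s in summaries if s.passage_label == config.early_passage]
    late = [s for s in summaries if s.passage_label == config.late_passage]
    deltas = []
    correlations = []
    if early and late:
        deltas = stats.passage_delta(early, late, expression_deltas or None)
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "sample_id": d.sample_id,
                        "allele": d.allele,
                        "delta_rm": d.delta_rm,
                        "delta_expr": d.delta_expr,
                    }
                    for d in deltas
                ]
            ),
            outdir / "deltas.tsv",
        )
        if deltas:
            conc = stats.direction_concordance(deltas)
            _write_tsv(conc, outdir / "concordance.tsv")
            for allele, group in conc.groupby("allele"):
                logger.info(
                    "%s allele: %d/%d lines concordant",
                    allele, int(group["concordant"].sum()), len(group),
                )
        for allele in ("WT", "KO"):
            sub = [d for d in deltas if d.allele == allele]
            xs = [d.delta_expr for d in sub]
            ys = [d.delta_rm for d in sub]
            if len(sub) >= 3 and all(pd.notna(xs)):
                res = stats.correlate(xs, ys, method=config.correlation_method)
                correlations.append(
                    {
                        "comparison": f"delta_mRNA_vs_delta_RM_{allele}",
                        "allele": allele,
                        "n": res.n,
                        "r": res.r,
                        "p_value": res.p_value,
                        "method": res.method,
                    }
                )
        # Functional-mRNA accounting: WT-linked quantities only.  The KO
        # allele's RM ratio is deliberately absent from this column.
        functional = [
            {
                "sample_id": s.sample_id,
                "passage_label": s.passage_label,
                "functional_allele": "WT",
                "wt_rm_ratio": s.ratio,
            }
            for s in summaries
            if s.allele == "WT"
        ]
        _write_tsv(pd.DataFrame(functional), outdir / "functional_mrna.tsv")

    if correlations:
        _write_tsv(pd.DataFrame(correlations), outdir / "correlations.tsv")

    # Cross-line variance comparison of RM ratios per allele and passage
    variance_rows = []
    for passage in sorted({s.passage_label for s in summaries}):
        per_allele = {
            a: [s.ratio for s in summaries if s.allele == a and s.passage_label == passage]
            for a in ("WT", "KO")
        }
        if all(len(v) >= 2 for v in per_allele.values()):
            comp = stats.variance_by_allele(per_allele)
            variance_rows.append(
                {
                    "passage_label": passage,
                    "var_WT": comp.variances["WT"],
                    "var_KO": comp.variances["KO"],
                    "f_ratio_KO_over_WT": comp.f_ratio,
                }
            )
    if variance_rows:
        _write_tsv(pd.DataFrame(variance_rows), outdir / "variance_by_allele.tsv")

    manifest = {
        "epishore_version": _package_version(),
        "inputs": {
            "reference_fasta": str(config.reference_fasta),
            "amplicon_config": str(config.amplicon_config),
            "sample_sheet": str(config.sample_sheet),
            "expression_table": (
                str(config.expression_table) if config.expression_table else None
            ),
        },
        "rm_fraction": config.rm_fraction,
        "n_samples": len(reports),
        "n_reads_input": int(sum(r.n_input for r in reports)),
        "n_reads_pass": int(sum(r.n_pass for r in reports)),
        "n_reads_rejected": int(sum(sum(r.rejections.values()) for r in reports)),
        "allele_counts": {
            a: int(sum(r.allele_counts.get(a, 0) for r in reports))
            for a in ("WT", "KO", "ambiguous")
        },
    }
    assert (
        manifest["n_reads_input"]
        == manifest["n_reads_pass"] + manifest["n_reads_rejected"]
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def probe_correlation_report(
    table: pd.DataFrame,
    probe_id: str | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate methylation beta with expression per probe across cell lines.

    With ``probe_id=None`` every probe in the table is reported.  Raises
    if a requested probe is absent (listing what is available) or has
    fewer than three lines with both measurements.
    """
    required = {"cell_line", "probe_id", "beta", "expression"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    available = sorted(table["probe_id"].unique())
    if probe_id is not None:
        if probe_id not in available:
            raise ValueError(
                f"probe {probe_id!r} not in table; available: {available}"
            )
        probes = [probe_id]
    else:
        probes = available
    rows = []
    for probe in probes:
        sub = table[table["probe_id"] == probe].dropna(subset=["beta", "expression"])
        if len(sub) < 3:
            raise ValueError(f"probe {probe!r}: fewer than 3 cell lines")
        res = stats.correlate(
            sub["beta"].to_numpy(), sub["expression"].to_numpy(), method=method
        )
        rows.append(
            {
                "probe_id": probe,
                "n": res.n,
                "r": res.r,
                "p_value": res.p_value,
                "method": res.method,
                "defined": res.defined,
            }
        )
    return pd.DataFrame(rows)
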