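"""Ground-truthed synthetic data for the allele-resolved bisulfite assay.

The generator emulates a diploid heterozygous-knockout cell population in
which each cell carries one wild-type (WT) and one knockout (KO) allele,
tagged on the assayed strand by a G/A SNP in the CpG island shore.  Each
allele is independently in a latent hypo- or hyper-methylated epiallele
state; conditional on the state, shore (S) CpGs are methylated as
independent Bernoulli draws with probability ``m_low`` (hypo) or
``m_high`` (hyper), while the outside (O) region is constitutively
hyper-biased and the island (I) constitutively hypo-biased regardless of
state.  Clone reads are alleles sampled with replacement from the pooled
2 x n_cells alleles, bisulfite-converted in silico, then degraded by an
optional conversion-failure probability (an unmethylated C survives as C)
and per-base substitution errors.  Expression couples the mature-mRNA
level to the fraction of cells whose *WT* allele is in the hypo state
(the knockout allele contributes no mature message), while preRNA is
state-independent and the housekeeping reference is constant.

All generators are pure functions of (config, seed): the same seed
reproduces the same cohort byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bisulfite import convert_strand
from .pipeline import CloneRead, METHYLATED, UNMETHYLATED
from .reference import AmpliconSpec, SnpSpec, write_amplicon
from .stats import rm_threshold_count

__all__ = [
    "PopulationConfig",
    "CohortConfig",
    "Population",
    "SimulatedSample",
    "make_fixture_reference",
    "generate_population",
    "emit_clone_reads",
    "emit_expression",
    "simulate_cohort",
    "write_cohort",
    "sample_epiallele_reads",
    "emit_probe_table",
    "DEFAULT_PROBE_ANNOTATION",
]

logger = logging.getLogger(__name__)

ALLELES = ("WT", "KO")

#: Probe annotation mirroring a three-probe promoter layout around a CpG
#: island: one probe outside the shore, one in the shore, one inside the
#: island.
DEFAULT_PROBE_ANNOTATION = {
    "cg01529092": "outside",
    "cg14164380": "shore",
    "cg15385562": "island",
}


@dataclass(frozen=True)
class PopulationConfig:
    """Generative truth for one sample (cell population).

    ``p_hypo_wt`` / ``p_hypo_ko`` are the probabilities that a given
    cell's WT / KO allele is in the hypomethylated epiallele state.
    ``m_low`` / ``m_high`` are per-CpG methylation probabilities under the
    hypo / hyper state (defaults 0.1 / 0.9 -- repo conventions for
    strongly contrasted epialleles).  With ``region_state_scope="shore"``
    the latent state drives only S-region CpGs; O CpGs draw from
    ``m_high`` and I CpGs from ``m_low`` regardless of state.
    ``conversion_failure`` is the probability an unmethylated C escapes
    conversion; ``error_rate`` is a per-base substitution probability.
    Expression: per replicate, mRNA intensity is
    ``max(0, baseline + slope * WT-hypo-fraction + N(0, noise_sd))``;
    preRNA is state-independent; the reference (housekeeping) intensity
    is constant.
    """

    n_cells: int = 400
    p_hypo_wt: float = 0.5
    p_hypo_ko: float = 0.5
    m_low: float = 0.1
    m_high: float = 0.9
    region_state_scope: str = "shore"  # "shore" or "all"
    conversion_failure: float = 0.0
    error_rate: float = 0.0
    n_reads: int = 40
    expr_baseline: float = 0.1
    expr_slope: float = 1.0
    expr_noise_sd: float = 0.02
    prerna_level: float = 1.0
    reference_level: float = 1.0
    n_replicates: int = 3

    def __post_init__(self) -> None:
        for name in (
            "p_hypo_wt", "p_hypo_ko", "m_low", "m_high",
            "conversion_failure", "error_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.m_low >= self.m_high:
            raise ValueError("m_low must be below m_high")
        if self.region_state_scope not in ("shore", "all"):
            raise ValueError("region_state_scope must be 'shore' or 'all'")
        if self.n_cells <= 0 or self.n_reads < 0 or self.n_replicates < 1:
            raise ValueError("invalid population sizes")


@dataclass
class Population:
    """Latent states and true methylation maps of one simulated population."""

    spec: AmpliconSpec
    cpg_positions: tuple[int, ...]
    hypo_state: dict[str, np.ndarray]  # allele -> bool[n_cells], True = hypo
    methylation: dict[str, np.ndarray]  # allele -> bool[n_cells, n_cpgs]

    @property
    def n_cells(self) -> int:
        return self.hypo_state["WT"].size

    @property
    def wt_hypo_fraction(self) -> float:
        """Realized fraction of cells with a hypomethylated WT allele."""
        return float(self.hypo_state["WT"].mean())

    def hypo_fraction(self, allele: str) -> float:
        return float(self.hypo_state[allele].mean())

    def true_calls(self, allele: str, cell: int) -> dict[int, str]:
        row = self.methylation[allele][cell]
        return {
            p: METHYLATED if row[j] else UNMETHYLATED
            for j, p in enumerate(self.cpg_positions)
        }

    def true_rm_ratio(
        self, allele: str, s_positions: Sequence[int], threshold_fraction: float = 0.75
    ) -> float:
        """Population-scale RM allele ratio: the RM rule applied to every allele.

        This is the quantity a finite clone sample estimates.
        """
        idx = [self.cpg_positions.index(p) for p in s_positions]
        meth = self.methylation[allele][:, idx]
        unmeth_counts = (~meth).sum(axis=1)
        cutoff = rm_threshold_count(len(idx), threshold_fraction)
        return float((unmeth_counts >= cutoff).mean())


def generate_population(
    config: PopulationConfig, spec: AmpliconSpec, rng: np.random.Generator
) -> Population:
    """Draw latent epiallele states and per-CpG methylation for every cell."""
    positions = spec.cpg_index.positions
    regions = [spec.cpg_index.region_of[p] for p in positions]
    pops: dict[str, np.ndarray] = {}
    meth: dict[str, np.ndarray] = {}
    p_hypo = {"WT": config.p_hypo_wt, "KO": config.p_hypo_ko}
    for allele in ALLELES:
        states = rng.random(config.n_cells) < p_hypo[allele]
        state_prob = np.where(states, config.m_low, config.m_high)  # [n_cells]
        prob = np.empty((config.n_cells, len(positions)))
        for j, reg in enumerate(regions):
            if config.region_state_scope == "all" or reg == "S":
                prob[:, j] = state_prob
            elif reg == "O":
                prob[:, j] = config.m_high
            elif reg == "I":
                prob[:, j] = config.m_low
            else:  # unassigned CpGs follow the latent state
                prob[:, j] = state_prob
        meth[allele] = rng.random((config.n_cells, len(positions))) < prob
        pops[allele] = states
    return Population(
        spec=spec, cpg_positions=positions, hypo_state=pops, methylation=meth
    )


_OTHER_BASES = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def emit_clone_reads(
    population: Population,
    spec: AmpliconSpec,
    config: PopulationConfig,
    rng: np.random.Generator,
    sample_id: str,
    passage_label: str,
) -> tuple[list[CloneRead], pd.DataFrame]:
    """Sample clone reads from the allele pool and bisulfite-convert them.

    Alleles are drawn uniformly *with replacement* from the pooled
    2 x n_cells alleles (cloning resamples molecules).  Conversion
    failures keep an unmethylated C as C with probability
    ``conversion_failure``; substitution errors hit each base with
    probability ``error_rate``.  Returns the reads plus a truth table
    (read_id, allele, latent state, true per-CpG calls).
    """
    n_pool = 2 * population.n_cells
    draws = rng.integers(0, n_pool, size=config.n_reads)
    cpg_set = set(population.cpg_positions)
    reads: list[CloneRead] = []
    truth_rows = []
    for i, draw in enumerate(draws):
        allele = ALLELES[int(draw) // population.n_cells]
        cell = int(draw) % population.n_cells
        meth_row = population.methylation[allele][cell]
        meth_map = dict(zip(population.cpg_positions, (bool(x) for x in meth_row)))
        allele_seq = spec.allele_sequence(allele)
        converted = list(convert_strand(allele_seq, meth_map))
        if config.conversion_failure > 0:
            for j, base in enumerate(allele_seq):
                if base == "C" and not (j in cpg_set and meth_map[j]):
                    if rng.random() < config.conversion_failure:
                        converted[j] = "C"
        if config.error_rate > 0:
            err = rng.random(len(converted)) < config.error_rate
            for j in np.nonzero(err)[0]:
                converted[j] = _OTHER_BASES[converted[j]][rng.integers(0, 3)]
        read_id = f"{sample_id}_{passage_label}_r{i:04d}"
        reads.append(
            CloneRead(
                read_id=read_id,
                sample_id=sample_id,
                passage_label=passage_label,
                sequence="".join(converted),
            )
        )
        truth_rows.append(
            {
                "read_id": read_id,
                "sample_id": sample_id,
                "passage_label": passage_label,
                "allele": allele,
                "latent_state": "hypo" if population.hypo_state[allele][cell] else "hyper",
                "true_calls": "".join(
                    METHYLATED if m else UNMETHYLATED for m in meth_row
                ),
            }
        )
    return reads, pd.DataFrame(truth_rows)


def emit_expression(
    population: Population,
    config: PopulationConfig,
    rng: np.random.Generator,
    sample_id: str,
    passage_label: str,
) -> pd.DataFrame:
    """Expression intensity rows coupled to the WT hypomethylated fraction."""
    frac = population.wt_hypo_fraction
    rows = []
    for rep in range(1, config.n_replicates + 1):
        mrna = max(
            0.0,
            config.expr_baseline
            + config.expr_slope * frac
            + rng.normal(0.0, config.expr_noise_sd),
        )
        prerna = max(0.0, config.prerna_level + rng.normal(0.0, config.expr_noise_sd))
        for target, value in (
            ("mRNA", mrna),
            ("preRNA", prerna),
            ("reference", config.reference_level),
        ):
            rows.append(
                {
                    "sample_id": sample_id,
                    "passage_label": passage_label,
                    "target": target,
                    "replicate": rep,
                    "intensity": value,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixture reference


def _spacer(rng: np.random.Generator) -> str:
    """A/T run with exactly one non-CpG C (C is always followed by A/T)."""
    head = "".join(rng.choice(["A", "T"], size=int(rng.integers(2, 5))))
    tail = str(rng.choice(["A", "T"]))
    return head + "C" + tail


def make_fixture_reference(
    layout: tuple[int, int, int] = (2, 9, 13),
    seed: int = 0,
    name: str = "synthetic_shore_amplicon",
) -> AmpliconSpec:
    """Construct a synthetic amplicon with the requested O/S/I CpG counts.

    The sequence is assembled from per-CpG blocks (an A/T spacer carrying
    one non-CpG cytosine, then ``CG``), so the CpG layout is exact by
    construction, every spacer contributes a conversion-QC site, and no
    accidental CpG can arise.  One G/A SNP (WT -> G, KO -> A) is planted
    mid-shore in non-CpG context.  Deterministic under ``seed``.
    """
    if len(layout) != 3 or any(c <= 0 for c in layout):
        raise ValueError("layout must give positive CpG counts for O, S, I")
    rng = np.random.default_rng(seed)
    pieces: list[str] = []
    pos = 0
    regions: dict[str, tuple[int, int]] = {}
    snp_position = -1

    def add(s: str) -> None:
        nonlocal pos
        pieces.append(s)
        pos += len(s)

    for label, count in zip(("O", "S", "I"), layout):
        start = pos
        for j in range(count):
            add(_spacer(rng))
            if label == "S" and j == count // 2:
                add("A")
                snp_position = pos
                add("G")
                add("A")
            add("CG")
        add("".join(rng.choice(["A", "T"], size=3)))
        regions[label] = (start, pos)
    sequence = "".join(pieces)
    spec = AmpliconSpec(
        name=name,
        sequence=sequence,
        regions=regions,
        snp=SnpSpec(position=snp_position, alleles={"WT": "G", "KO": "A"}),
    )
    # Internal consistency: the construction must realize the layout.
    counts = tuple(len(spec.cpg_index.in_region(lab)) for lab in ("O", "S", "I"))
    if counts != tuple(layout):
        raise RuntimeError(f"fixture construction produced {counts}, wanted {layout}")
    return spec


# ---------------------------------------------------------------------------
# Cohorts (multiple lines x passages)


@dataclass(frozen=True)
class CohortConfig:
    """A multi-line, two-passage cohort mirroring a passage experiment.

    Per line and allele, the hypo-state probability at the early passage
    is drawn from ``p_hypo_range`` (``p_hypo_range_ko``, when set, gives
    the KO allele its own -- e.g. wider -- range); the late-passage value
    is the early one plus a Normal(``drift_mean``, ``drift_sd``)
    perturbation clipped to ``p_hypo_bounds``.  The negative default
    drift mean reproduces the tendency of shore methylation to accrete
    (RM ratios to fall) under prolonged culture, while the sizable drift
    SD lets individual lines move either way.
    """

    n_lines: int = 6
    passages: tuple[str, str] = ("P6", "P20")
    p_hypo_range: tuple[float, float] = (0.1, 0.9)
    p_hypo_range_ko: tuple[float, float] | None = None
    drift_mean: float = -0.08
    drift_sd: float = 0.3
    p_hypo_bounds: tuple[float, float] = (0.02, 0.98)
    line_prefix: str = "KO-line"
    population: PopulationConfig = field(default_factory=PopulationConfig)


@dataclass
class SimulatedSample:
    """One line x passage: latent population, reads + truth, expression."""

    line_id: str
    passage_label: str
    p_hypo: dict[str, float]
    population: Population
    reads: list[CloneRead]
    truth: pd.DataFrame
    expression: pd.DataFrame


def simulate_cohort(
    spec: AmpliconSpec,
    cohort: CohortConfig,
    seed: int,
    with_reads: bool = True,
) -> list[SimulatedSample]:
    """Simulate every line x passage of a cohort; pure function of the seed."""
    rng = np.random.default_rng(seed)
    ranges = {
        "WT": cohort.p_hypo_range,
        "KO": cohort.p_hypo_range_ko or cohort.p_hypo_range,
    }
    blo, bhi = cohort.p_hypo_bounds
    samples: list[SimulatedSample] = []
    for line in range(1, cohort.n_lines + 1):
        line_id = f"{cohort.line_prefix}-{line}"
        p_early = {a: float(rng.uniform(*ranges[a])) for a in ALLELES}
        p_late = {
            a: float(np.clip(p_early[a] + rng.normal(cohort.drift_mean, cohort.drift_sd), blo, bhi))
            for a in ALLELES
        }
        for passage, p_hypo in zip(cohort.passages, (p_early, p_late)):
            cfg = dataclasses.replace(
                cohort.population, p_hypo_wt=p_hypo["WT"], p_hypo_ko=p_hypo["KO"]
            )
            population = generate_population(cfg, spec, rng)
            if with_reads:
                reads, truth = emit_clone_reads(
                    population, spec, cfg, rng, line_id, passage
                )
            else:
                reads, truth = [], pd.DataFrame()
            expression = emit_expression(population, cfg, rng, line_id, passage)
            samples.append(
                SimulatedSample(
                    line_id=line_id,
                    passage_label=passage,
                    p_hypo=dict(p_hypo),
                    population=population,
                    reads=reads,
                    truth=truth,
                    expression=expression,
                )
            )
    return samples


def write_cohort(
    samples: list[SimulatedSample],
    spec: AmpliconSpec,
    outdir: str | Path,
    seed: int,
) -> dict:
    """Write a simulated cohort to disk in the formats the pipeline consumes.

    Produces amplicon.fasta + amplicon.yaml, one reads FASTA per
    line x passage, sample_sheet.tsv, expression.tsv, per-sample truth
    TSVs and a manifest recording the seed.  Returns the manifest dict.
    """
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    write_amplicon(spec, outdir / "amplicon.fasta", outdir / "amplicon.yaml")
    sheet_rows = []
    expression_frames = []
    for s in samples:
        stem = f"{s.line_id}_{s.passage_label}"
        fasta = outdir / "reads" / f"{stem}.fasta"
        with open(fasta, "w") as fh:
            for read in s.reads:
                fh.write(f">{read.read_id}\n{read.sequence}\n")
        truth_path = outdir / "truth" / f"truth_{stem}.tsv"
        with open(truth_path, "w") as fh:
            fh.write(f"# seed={seed}\n")
            s.truth.to_csv(fh, sep="\t", index=False)
        sheet_rows.append(
            {
                "read_file": str(Path("reads") / f"{stem}.fasta"),
                "sample_id": s.line_id,
                "passage_label": s.passage_label,
                "orientation": "forward",
            }
        )
        expression_frames.append(s.expression)
    pd.DataFrame(sheet_rows).to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    pd.concat(expression_frames, ignore_index=True).to_csv(
        outdir / "expression.tsv", sep="\t", index=False
    )
    manifest = {
        "seed": seed,
        "n_samples": len(samples),
        "n_reads_total": int(sum(len(s.reads) for s in samples)),
        "amplicon": spec.name,
        "truth_files": sorted(
            str(p.relative_to(outdir)) for p in (outdir / "truth").glob("*.tsv")
        ),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def sample_epiallele_reads(
    rng: np.random.Generator,
    n_reads: int,
    p_hypo: float,
    m_low: float = 0.1,
    m_high: float = 0.9,
    n_cpgs: int = 9,
) -> tuple[np.ndarray, np.ndarray]:
    """Fast path: S-region unmethylated-CpG counts for ``n_reads`` clones.

    Each read's allele is hypo with probability ``p_hypo``; its
    unmethylated count is Binomial(n_cpgs, 1 - m_state).  Returns
    (unmethylated counts, latent hypo states).  Statistically identical
    to sequencing noise-free reads through the full generator and calling
    them, without constructing sequences; used for large simulation
    studies of the RM-ratio estimator.
    """
    states = rng.random(n_reads) < p_hypo
    p_unmeth = np.where(states, 1.0 - m_low, 1.0 - m_high)
    counts = rng.binomial(n_cpgs, p_unmeth)
    return counts, states


def emit_probe_table(
    rng: np.random.Generator,
    n_lines: int = 12,
    annotation: dict[str, str] = DEFAULT_PROBE_ANNOTATION,
    shore_beta_range: tuple[float, float] = (0.19, 0.70),
    expression_baseline: float = 3.0,
    coupling_slope: float = -2.5,
    expression_noise_sd: float = 0.1,
) -> pd.DataFrame:
    """Probe-level beta/expression table emulating a 450K-style promoter assay.

    The outside probe is near-fully methylated, the island probe near-
    unmethylated, and the shore probe varies across cell lines within
    ``shore_beta_range``; expression is negatively coupled to the shore
    beta (hypermethylated shore, less message).  Columns: cell_line,
    probe_id, beta, expression.
    """
    rows = []
    for i in range(1, n_lines + 1):
        line = f"iPS-{i:02d}"
        shore_beta = float(rng.uniform(*shore_beta_range))
        betas = {
            "outside": float(np.clip(rng.normal(0.85, 0.04), 0, 1)),
            "shore": shore_beta,
            "island": float(np.clip(rng.normal(0.05, 0.03), 0, 1)),
        }
        expression = max(
            0.0,
            expression_baseline
            + coupling_slope * shore_beta
            + rng.normal(0.0, expression_noise_sd),
        )
        for probe_id, location in annotation.items():
            rows.append(
                {
                    "cell_line": line,
                    "probe_id": probe_id,
                    "beta": round(betas[location], 6),
                    "expression": round(expression, 6),
                }
            )
    return pd.DataFrame(rows)
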