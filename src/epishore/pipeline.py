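"""Clone-read processing: alignment, QC, methylation calling, allele assignment.

Each sequenced bisulfite clone is globally aligned to the unconverted
amplicon reference with bisulfite-aware scoring (reference C against read
T is a match, because every unmethylated C reads as T after conversion;
read C against reference T stays a mismatch).  From the alignment the
pipeline derives:

* a conversion-efficiency estimate from non-CpG reference cytosines,
  which must essentially all read as T in a well-converted clone;
* a per-CpG methylation call (C = methylated, T = unmethylated,
  gap/other = missing);
* the allele label, from the read base at the conversion-surviving SNP.

Reads failing length, alignment-identity or conversion QC are rejected
with a coded reason; ambiguous-SNP reads are retained in the QC report
but excluded from per-allele statistics.  Count conservation holds
throughout: inputs = passes + rejections, passes = WT + KO + ambiguous.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .reference import AMBIGUOUS, AmpliconSpec, CpGIndex, SnpSpec

__all__ = [
    "PipelineConfig",
    "CloneRead",
    "AlignedRead",
    "MethylationCall",
    "QCReport",
    "ReadRejected",
    "METHYLATED",
    "UNMETHYLATED",
    "MISSING",
    "align_read",
    "call_methylation",
    "assess_conversion",
    "assign_allele",
    "run_sample",
    "read_sample_sheet",
    "load_reads",
    "calls_to_frame",
    "qc_reports_to_frame",
    "lollipop_text",
]

logger = logging.getLogger(__name__)

METHYLATED = "M"
UNMETHYLATED = "U"
MISSING = "."

_ALPHABET = "ACGTN"


class ReadRejected(Exception):
    """A read failed pre-alignment or alignment QC; ``reason`` is a code."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable QC and alignment parameters.

    The defaults are fixture-validated conventions for near-full-length
    amplicon clones, not values taken from any particular dataset:
    conversion below 95% rejects a clone (community convention for clone
    bisulfite data), alignment identity below 0.8 rejects, and the
    bisulfite-asymmetric scoring is +1 match / -2 mismatch with affine
    gaps (-4 open, -1 extend).
    """

    min_conversion: float = 0.95
    min_identity: float = 0.8
    length_tolerance: float = 0.2
    match_score: float = 1.0
    mismatch_score: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class CloneRead:
    """One sequenced bisulfite clone in assayed-strand orientation."""

    read_id: str
    sample_id: str
    passage_label: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")


@dataclass(frozen=True)
class AlignedRead:
    """A clone read registered against the reference.

    ``ref_bases[i]`` is the read base aligned to reference position ``i``
    or ``None`` at a deletion/unaligned position.
    """

    read: CloneRead
    ref_bases: tuple[str | None, ...]
    identity: float


@dataclass
class MethylationCall:
    """Per-read result: allele, per-CpG calls and QC outcome."""

    read_id: str
    sample_id: str
    passage_label: str
    allele: str
    calls: dict[int, str]
    conversion_rate: float
    qc_pass: bool
    qc_reasons: tuple[str, ...] = ()


@dataclass
class QCReport:
    """Read accounting for one sample x passage."""

    sample_id: str
    passage_label: str
    n_input: int = 0
    n_pass: int = 0
    rejections: Counter = field(default_factory=Counter)
    allele_counts: Counter = field(default_factory=Counter)

    def conserved(self) -> bool:
        return (
            self.n_input == self.n_pass + sum(self.rejections.values())
            and self.n_pass == sum(self.allele_counts.values())
        )


def build_aligner(config: PipelineConfig = PipelineConfig()) -> Align.PairwiseAligner:
    """Global pairwise aligner with asymmetric bisulfite scoring.

    The substitution matrix is indexed [reference base, read base]:
    ref C vs read T scores as a match (conversion), read C vs ref T does
    not, N is neutral against everything.
    """
    mat = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in "ACGT":
        for b in "ACGT":
            mat[a, b] = config.match_score if a == b else config.mismatch_score
    mat["C", "T"] = config.match_score
    for b in _ALPHABET:
        mat["N", b] = 0.0
        mat[b, "N"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = config.gap_open
    aligner.extend_gap_score = config.gap_extend
    return aligner


def _trimmed(read: CloneRead, spec: AmpliconSpec) -> str:
    t5, t3 = spec.primer_trim
    seq = read.sequence
    return seq[t5 : len(seq) - t3] if t3 else seq[t5:]


def align_read(
    read: CloneRead,
    spec: AmpliconSpec,
    config: PipelineConfig = PipelineConfig(),
    aligner: Align.PairwiseAligner | None = None,
) -> AlignedRead:
    """Globally align a clone read to the unconverted reference.

    Raises
    ------
    ReadRejected
        With reason ``length_out_of_range`` if the (trimmed) read length
        deviates from the amplicon length by more than
        ``config.length_tolerance``, or ``unalignable`` if the
        bisulfite-aware identity falls below ``config.min_identity``.
    """
    ref = spec.sequence
    seq = _trimmed(read, spec).upper()
    if not seq or abs(len(seq) - len(ref)) > config.length_tolerance * len(ref):
        raise ReadRejected(
            "length_out_of_range",
            f"read {read.read_id}: {len(seq)} vs amplicon {len(ref)}",
        )
    if any(b not in _ALPHABET for b in seq):
        seq = "".join(b if b in _ALPHABET else "N" for b in seq)
    if aligner is None:
        aligner = build_aligner(config)
    alignment = aligner.align(ref, seq)[0]
    ref_bases: list[str | None] = [None] * len(ref)
    target_blocks, query_blocks = alignment.aligned
    for (ts, te), (qs, _qe) in zip(target_blocks, query_blocks):
        for k in range(te - ts):
            ref_bases[ts + k] = seq[qs + k]
    compatible = sum(
        1
        for i, b in enumerate(ref_bases)
        if b is not None and (b == ref[i] or (ref[i] == "C" and b == "T"))
    )
    identity = compatible / len(ref)
    if identity < config.min_identity:
        raise ReadRejected(
            "unalignable", f"read {read.read_id}: identity {identity:.3f}"
        )
    return AlignedRead(read=read, ref_bases=tuple(ref_bases), identity=identity)


def call_methylation(aligned: AlignedRead, index: CpGIndex) -> dict[int, str]:
    """Call each CpG from the read base at its C position.

    C is methylated, T unmethylated; gaps and any other base (including
    degenerate codes) become missing.
    """
    calls: dict[int, str] = {}
    for p in index.positions:
        b = aligned.ref_bases[p]
        if b == "C":
            calls[p] = METHYLATED
        elif b == "T":
            calls[p] = UNMETHYLATED
        else:
            calls[p] = MISSING
    return calls


def assess_conversion(
    aligned: AlignedRead,
    spec: AmpliconSpec,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[float, list[str]]:
    """Estimate bisulfite conversion efficiency from non-CpG cytosines.

    Non-CpG reference C sites (the SNP position excluded) should all read
    as T in a fully converted clone; the rate is
    converted / (converted + unconverted) over sites read as C or T.
    The QC threshold comparison is inclusive (rate >= min passes).
    """
    cpg_set = set(spec.cpg_index.positions)
    converted = unconverted = 0
    for i, ref_base in enumerate(spec.sequence):
        if ref_base != "C" or i in cpg_set or i == spec.snp.position:
            continue
        b = aligned.ref_bases[i]
        if b == "T":
            converted += 1
        elif b == "C":
            unconverted += 1
    total = converted + unconverted
    if total == 0:
        return float("nan"), ["no_conversion_sites"]
    rate = converted / total
    reasons = [] if rate >= config.min_conversion else ["incomplete_conversion"]
    return rate, reasons


def assign_allele(aligned: AlignedRead, snp: SnpSpec) -> str:
    """Label the read by the base at the SNP position, or ``ambiguous``."""
    base = aligned.ref_bases[snp.position]
    if base is None:
        return AMBIGUOUS
    return snp.base_to_label.get(base, AMBIGUOUS)


def run_sample(
    reads: Sequence[CloneRead],
    spec: AmpliconSpec,
    config: PipelineConfig = PipelineConfig(),
    sample_id: str | None = None,
    passage_label: str | None = None,
) -> tuple[list[MethylationCall], QCReport]:
    """Process one sample's clone reads: align, QC, assign allele, call CpGs.

    Rejected reads (unalignable, length, incomplete conversion) appear
    only in the QC report; the returned calls are the QC-passing reads.
    """
    if reads:
        sample_id = sample_id or reads[0].sample_id
        passage_label = passage_label or reads[0].passage_label
    report = QCReport(sample_id=sample_id or "", passage_label=passage_label or "")
    if not reads:
        logger.warning("run_sample: empty read set for %s/%s", sample_id, passage_label)
        return [], report
    aligner = build_aligner(config)
    calls: list[MethylationCall] = []
    for read in reads:
        report.n_input += 1
        try:
            aligned = align_read(read, spec, config, aligner=aligner)
        except ReadRejected as rej:
            report.rejections[rej.reason] += 1
            continue
        rate, reasons = assess_conversion(aligned, spec, config)
        if reasons:
            report.rejections[reasons[0]] += 1
            continue
        allele = assign_allele(aligned, spec.snp)
        per_cpg = call_methylation(aligned, spec.cpg_index)
        report.n_pass += 1
        report.allele_counts[allele] += 1
        calls.append(
            MethylationCall(
                read_id=read.read_id,
                sample_id=read.sample_id,
                passage_label=read.passage_label,
                allele=allele,
                calls=per_cpg,
                conversion_rate=rate,
                qc_pass=True,
            )
        )
    assert report.conserved()
    return calls, report


# ---------------------------------------------------------------------------
# I/O helpers


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Load the TSV sample sheet (read_file, sample_id, passage_label, orientation)."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"read_file", "sample_id", "passage_label", "orientation"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    bad = set(sheet["orientation"]) - {"forward", "reverse_complement"}
    if bad:
        raise ValueError(f"sample sheet has unknown orientations: {sorted(bad)}")
    return sheet


def load_reads(
    fasta_path: str | Path,
    sample_id: str,
    passage_label: str,
    orientation: str = "forward",
) -> list[CloneRead]:
    """Load clone reads from FASTA, reverse-complementing if declared."""
    reads = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(record.seq).upper()
        if orientation == "reverse_complement":
            seq = str(Seq(seq).reverse_complement())
        reads.append(
            CloneRead(
                read_id=record.id,
                sample_id=sample_id,
                passage_label=passage_label,
                sequence=seq,
            )
        )
    return reads


def calls_to_frame(calls: Iterable[MethylationCall], index: CpGIndex) -> pd.DataFrame:
    """Tabulate per-read calls: one row per read, one column per CpG position."""
    rows = []
    for c in calls:
        row: dict[str, object] = {
            "read_id": c.read_id,
            "sample_id": c.sample_id,
            "passage_label": c.passage_label,
            "allele": c.allele,
            "conversion_rate": round(c.conversion_rate, 6),
            "qc_pass": c.qc_pass,
            "qc_reasons": ";".join(c.qc_reasons) if c.qc_reasons else ".",
        }
        for p in index.positions:
            row[f"cpg_{p}"] = c.calls.get(p, MISSING)
        rows.append(row)
    columns = [
        "read_id",
        "sample_id",
        "passage_label",
        "allele",
        "conversion_rate",
        "qc_pass",
        "qc_reasons",
        *[f"cpg_{p}" for p in index.positions],
    ]
    return pd.DataFrame(rows, columns=columns)


def qc_reports_to_frame(reports: Iterable[QCReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {
            "sample_id": r.sample_id,
            "passage_label": r.passage_label,
            "n_input": r.n_input,
            "n_pass": r.n_pass,
            "n_rejected": sum(r.rejections.values()),
        }
        for reason, n in sorted(r.rejections.items()):
            row[f"rejected_{reason}"] = n
        for allele, n in sorted(r.allele_counts.items()):
            row[f"allele_{allele}"] = n
        rows.append(row)
    return pd.DataFrame(rows).fillna(0)


_LOLLIPOP = {METHYLATED: "#", UNMETHYLATED: "o", MISSING: "."}


def lollipop_text(
    calls: Sequence[MethylationCall], spec: AmpliconSpec, width: int = 24
) -> str:
    """Text methylation matrix: rows are reads grouped by allele, columns CpGs.

    ``#`` methylated, ``o`` unmethylated, ``.`` missing; ``|`` separates
    the O, S and I region blocks.
    """
    index = spec.cpg_index
    boundaries = set()
    prev = None
    order = []
    for p in index.positions:
        reg = index.region_of[p]
        if prev is not None and reg != prev:
            boundaries.add(p)
        prev = reg
        order.append(p)

    def row_string(c: MethylationCall) -> str:
        parts = []
        for p in order:
            if p in boundaries:
                parts.append("|")
            parts.append(_LOLLIPOP[c.calls.get(p, MISSING)])
        return "".join(parts)

    header_parts = []
    for p in order:
        if p in boundaries:
            header_parts.append("|")
        header_parts.append(index.region_of[p][0])
    lines = [" " * width + "".join(header_parts)]
    allele_order = [*spec.snp.alleles.keys(), AMBIGUOUS]
    for allele in allele_order:
        group = [c for c in calls if c.allele == allele]
        if not group:
            continue
        lines.append(f"-- {allele} ({len(group)} reads) --")
        for c in group:
            lines.append(c.read_id[:width].ljust(width) + row_string(c))
    return "\n".join(lines) + "\n"
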