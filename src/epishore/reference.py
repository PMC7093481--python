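"""Amplicon reference model for allele-resolved bisulfite sequencing.

A bisulfite PCR amplicon is represented by its *unconverted* sequence in
assayed-strand orientation, a partition of the amplicon into three
methylation domains -- O (constitutively hypermethylated outside region),
S (the variably methylated CpG island shore core) and I (constitutively
hypomethylated CpG island) -- and a single allele-tagging SNP.

The SNP is the crux of the assay: bisulfite conversion turns every
unmethylated cytosine into thymine, so a C/T polymorphism collapses on the
converted strand and carries no allele information.  The complementary
strand of the same site is a G/A polymorphism, which survives conversion
untouched; amplifying that strand keeps the wild-type (G) and knockout (A)
alleles distinguishable in every sequenced clone.
:func:`snp_bisulfite_visibility` encodes this logic for arbitrary base
pairs.

Coordinates are 0-based and region intervals are half-open.  A CpG is
located by the offset of its C on the assayed strand, and region
membership is decided by that single offset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Mapping, Sequence

import yaml
from Bio import SeqIO

__all__ = [
    "AmpliconError",
    "AmpliconSpec",
    "CpGIndex",
    "SnpSpec",
    "REGION_LABELS",
    "UNASSIGNED",
    "DISTINGUISHABLE",
    "AMBIGUOUS",
    "index_cpg_sites",
    "partition_cpgs",
    "snp_bisulfite_visibility",
    "load_amplicon",
    "write_amplicon",
]

REGION_LABELS = ("O", "S", "I")
UNASSIGNED = "unassigned"

DISTINGUISHABLE = "distinguishable"
AMBIGUOUS = "ambiguous"

_NON_ACGT = re.compile(r"[^ACGT]")


class AmpliconError(ValueError):
    """Invalid amplicon specification or sequence."""


def index_cpg_sites(sequence: str) -> list[int]:
    """Return sorted 0-based offsets of the C of every CpG dinucleotide.

    Parameters
    ----------
    sequence
        Uppercase DNA containing only A/C/G/T.

    Raises
    ------
    AmpliconError
        If the sequence contains a non-ACGT character (the offending
        offset is named in the message).
    """
    bad = _NON_ACGT.search(sequence)
    if bad is not None:
        raise AmpliconError(
            f"non-ACGT character {bad.group()!r} at offset {bad.start()}"
        )
    # CG cannot overlap CG, so non-overlapping finditer is exhaustive.
    return [m.start() for m in re.finditer("CG", sequence)]


@dataclass(frozen=True)
class SnpSpec:
    """An allele-distinguishing single-nucleotide polymorphism.

    Attributes
    ----------
    position
        0-based offset on the assayed strand.
    alleles
        Mapping of allele label to base for exactly two alleles,
        e.g. ``{"WT": "G", "KO": "A"}``.
    strand
        Which genomic strand the assay reads ("top" or "bottom");
        bookkeeping only.
    """

    position: int
    alleles: Mapping[str, str]
    strand: str = "bottom"

    def __post_init__(self) -> None:
        if self.position < 0:
            raise AmpliconError("SNP position must be non-negative")
        if len(self.alleles) != 2:
            raise AmpliconError("SNP requires exactly two allele labels")
        labels = list(self.alleles)
        bases = list(self.alleles.values())
        if any(not lab for lab in labels):
            raise AmpliconError("allele labels must be non-empty")
        if any(b not in "ACGT" or len(b) != 1 for b in bases):
            raise AmpliconError(f"allele bases must be single A/C/G/T: {bases}")
        if bases[0] == bases[1]:
            raise AmpliconError("the two allele bases must differ")
        if self.strand not in ("top", "bottom"):
            raise AmpliconError("strand must be 'top' or 'bottom'")
        object.__setattr__(self, "alleles", dict(self.alleles))

    @property
    def base_to_label(self) -> dict[str, str]:
        return {b: lab for lab, b in self.alleles.items()}


@dataclass(frozen=True)
class CpGIndex:
    """Positions of CpG sites and their region assignments."""

    positions: tuple[int, ...]
    region_of: Mapping[int, str]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise AmpliconError("CpG positions must be strictly increasing")
        if set(self.region_of) != set(self.positions):
            raise AmpliconError("region_of keys must equal CpG positions")

    def in_region(self, label: str) -> list[int]:
        return [p for p in self.positions if self.region_of[p] == label]


@dataclass
class AmpliconSpec:
    """A bisulfite amplicon: sequence, O/S/I regions, SNP, primer trim.

    ``sequence`` is the pre-conversion assayed strand, written in the
    state of the allele whose base appears at the SNP position.
    """

    name: str
    sequence: str
    regions: Mapping[str, tuple[int, int]]
    snp: SnpSpec
    primer_trim: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        cpgs = index_cpg_sites(self.sequence)  # also validates the alphabet
        if set(self.regions) != set(REGION_LABELS):
            raise AmpliconError(
                f"regions must be labeled exactly {REGION_LABELS}, "
                f"got {sorted(self.regions)}"
            )
        ivals = []
        for label in REGION_LABELS:
            start, end = self.regions[label]
            if not (0 <= start < end <= n):
                raise AmpliconError(
                    f"region {label} interval [{start}, {end}) outside sequence"
                )
            ivals.append((start, end, label))
        ivals.sort()
        for (s0, e0, l0), (s1, e1, l1) in zip(ivals, ivals[1:]):
            if s1 < e0:
                raise AmpliconError(f"regions {l0} and {l1} overlap")
        if not (0 <= self.snp.position < n):
            raise AmpliconError("SNP position outside sequence")
        for p in cpgs:
            if self.snp.position in (p, p + 1):
                raise AmpliconError(
                    f"SNP at {self.snp.position} lies inside the CpG at {p}; "
                    "its methylation state would confound allele calls"
                )
        ref_base = self.sequence[self.snp.position]
        if ref_base not in self.snp.alleles.values():
            raise AmpliconError(
                f"reference base {ref_base!r} at SNP position is not one of "
                f"the allele bases {sorted(self.snp.alleles.values())}"
            )
        t5, t3 = self.primer_trim
        if t5 < 0 or t3 < 0:
            raise AmpliconError("primer_trim values must be non-negative")
        self.regions = {lab: tuple(self.regions[lab]) for lab in REGION_LABELS}

    @cached_property
    def cpg_index(self) -> CpGIndex:
        positions = tuple(index_cpg_sites(self.sequence))
        region_of: dict[int, str] = {}
        for p in positions:
            region_of[p] = UNASSIGNED
            for label in REGION_LABELS:
                start, end = self.regions[label]
                if start <= p < end:
                    region_of[p] = label
                    break
        return CpGIndex(positions=positions, region_of=region_of)

    @property
    def reference_allele(self) -> str:
        """Label of the allele whose base the reference sequence carries."""
        return self.snp.base_to_label[self.sequence[self.snp.position]]

    def allele_sequence(self, label: str) -> str:
        """The unconverted sequence with the SNP base of allele ``label``."""
        base = self.snp.alleles[label]
        p = self.snp.position
        return self.sequence[:p] + base + self.sequence[p + 1 :]

    def s_region_positions(self) -> list[int]:
        return self.cpg_index.in_region("S")


def partition_cpgs(index: CpGIndex, spec: AmpliconSpec) -> dict[str, list[int]]:
    """Assign each CpG to the O/S/I region containing its C.

    Returns a mapping with keys ``O``, ``S``, ``I`` and ``unassigned``;
    the concatenated values are a permutation of ``index.positions``.
    """
    out: dict[str, list[int]] = {lab: [] for lab in (*REGION_LABELS, UNASSIGNED)}
    for p in index.positions:
        assigned = UNASSIGNED
        for label in REGION_LABELS:
            start, end = spec.regions[label]
            if start <= p < end:
                assigned = label
                break
        out[assigned].append(p)
    return out


def _post_conversion_bases(base: str, cpg_context: bool) -> frozenset[str]:
    """Bases a fully bisulfite-converted read may show for ``base``.

    A cytosine outside CpG context is always unmethylated in somatic
    mammalian DNA and reads as T; a CpG cytosine reads as C or T depending
    on its methylation state.  A, G and T are untouched by conversion.
    """
    if base == "C":
        return frozenset({"C", "T"}) if cpg_context else frozenset({"T"})
    return frozenset({base})


def snp_bisulfite_visibility(
    base_a: str, base_b: str, cpg_context: bool = False
) -> str:
    """Decide whether a SNP survives bisulfite conversion.

    Returns ``"distinguishable"`` if the post-conversion read alphabets of
    the two alleles are disjoint, ``"ambiguous"`` if they can overlap.
    A C/T SNP outside CpG context is the canonical ambiguous case (the
    unmethylated C converts to T); a G/A SNP is always distinguishable.

    Raises
    ------
    AmpliconError
        If the two bases are identical or not A/C/G/T.
    """
    for b in (base_a, base_b):
        if b not in "ACGT" or len(b) != 1:
            raise AmpliconError(f"invalid base {b!r}")
    if base_a == base_b:
        raise AmpliconError("SNP bases must differ")
    set_a = _post_conversion_bases(base_a, cpg_context)
    set_b = _post_conversion_bases(base_b, cpg_context)
    return DISTINGUISHABLE if set_a.isdisjoint(set_b) else AMBIGUOUS


def load_amplicon(fasta_path: str | Path, config_path: str | Path) -> AmpliconSpec:
    """Build an :class:`AmpliconSpec` from a single-record FASTA + YAML config.

    The config file uses the keys::

        name: optional label (defaults to the FASTA record id)
        regions: {O: [start, end], S: [start, end], I: [start, end]}
        snp: {position: int, alleles: {LABEL: BASE, LABEL: BASE}, strand: bottom}
        primer_trim: [five_prime, three_prime]    # optional, default [0, 0]
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise AmpliconError(
            f"reference FASTA must contain exactly one record, found {len(records)}"
        )
    record = records[0]
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise AmpliconError("amplicon config must be a mapping")
    try:
        regions = {
            lab: (int(iv[0]), int(iv[1])) for lab, iv in cfg["regions"].items()
        }
        snp_cfg = cfg["snp"]
        snp = SnpSpec(
            position=int(snp_cfg["position"]),
            alleles={str(k): str(v).upper() for k, v in snp_cfg["alleles"].items()},
            strand=str(snp_cfg.get("strand", "bottom")),
        )
    except KeyError as exc:
        raise AmpliconError(f"amplicon config missing key: {exc}") from exc
    trim = cfg.get("primer_trim", (0, 0))
    return AmpliconSpec(
        name=str(cfg.get("name", record.id)),
        sequence=str(record.seq).upper(),
        regions=regions,
        snp=snp,
        primer_trim=(int(trim[0]), int(trim[1])),
    )


def write_amplicon(
    spec: AmpliconSpec, fasta_path: str | Path, config_path: str | Path
) -> None:
    """Write an amplicon back out as FASTA + YAML config (inverse of load)."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{spec.name}\n")
        seq = spec.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    cfg = {
        "name": spec.name,
        "regions": {lab: list(spec.regions[lab]) for lab in REGION_LABELS},
        "snp": {
            "position": spec.snp.position,
            "alleles": dict(spec.snp.alleles),
            "strand": spec.snp.strand,
        },
        "primer_trim": list(spec.primer_trim),
    }
    with open(config_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
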