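"""Deterministic in-silico bisulfite conversion.

Sodium bisulfite deaminates unmethylated cytosine to uracil, which PCR
amplifies as thymine; 5-methylcytosine resists the reaction.  On the
assayed strand this means: a methylated CpG cytosine stays C, every other
cytosine (unmethylated CpG C and all non-CpG C) becomes T, and A/G/T are
untouched.  Non-CpG methylation is assumed absent (mammalian somatic
context), so non-CpG cytosines always convert.

Only the assayed strand is modeled; callers supply sequences already in
assayed-strand orientation.  After conversion the two genomic strands are
no longer complementary, so one orientation is all a single-amplicon assay
needs.
"""

from __future__ import annotations

from typing import Mapping

from .reference import AmpliconSpec, index_cpg_sites

__all__ = ["BisulfiteError", "MethylationMap", "convert_strand", "expected_read_alphabet"]

#: Maps CpG position (offset of the C) to True (methylated) / False
#: (unmethylated).  Must cover every CpG of the sequence it is applied to.
MethylationMap = Mapping[int, bool]


class BisulfiteError(ValueError):
    """Invalid conversion input (typically an incomplete methylation map)."""


def convert_strand(sequence: str, methylation: MethylationMap) -> str:
    """Bisulfite-convert ``sequence`` given per-CpG methylation states.

    Every C at a CpG position marked methylated is retained as C; every
    other C becomes T; all other bases are unchanged.  Output length
    equals input length.

    Raises
    ------
    BisulfiteError
        If ``methylation`` is missing any CpG position of the sequence
        (the missing offsets are listed).
    """
    cpgs = index_cpg_sites(sequence)
    missing = [p for p in cpgs if p not in methylation]
    if missing:
        raise BisulfiteError(f"methylation map missing CpG positions {missing}")
    retained = {p for p in cpgs if methylation[p]}
    return "".join(
        "C" if (b == "C" and i in retained) else ("T" if b == "C" else b)
        for i, b in enumerate(sequence)
    )


def expected_read_alphabet(spec: AmpliconSpec) -> tuple[frozenset[str], ...]:
    """Per-position admissible bases for a fully converted read of either allele.

    CpG C positions admit {C, T} (methylation-dependent); non-CpG C
    positions admit {T} only; the SNP position admits the post-conversion
    images of the two allele bases; every other position admits the
    reference base.  Used as an alignment/QC target.
    """
    cpg_set = set(spec.cpg_index.positions)
    out = []
    for i, base in enumerate(spec.sequence):
        if i == spec.snp.position:
            admissible: frozenset[str] = frozenset()
            for allele_base in spec.snp.alleles.values():
                # The SNP is outside CpG context by spec invariant.
                if allele_base == "C":
                    admissible |= {"T"}
                else:
                    admissible |= {allele_base}
            out.append(frozenset(admissible))
        elif base == "C":
            out.append(frozenset({"C", "T"}) if i in cpg_set else frozenset({"T"}))
        else:
            out.append(frozenset({base}))
    return tuple(out)
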