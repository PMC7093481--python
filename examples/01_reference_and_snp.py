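"""Build the synthetic shore amplicon and inspect its CpG layout and SNP.

The amplicon carries three methylation domains -- O (outside,
constitutively hypermethylated), S (shore core, variably methylated) and
I (CpG island, constitutively hypomethylated) -- plus one G/A SNP that
tags the wild-type (G) vs knockout (A) allele.  The script also shows why
the assay must read this strand: a C/T polymorphism would be erased by
bisulfite conversion, while G/A survives.
"""

from epishore import make_fixture_reference, partition_cpgs, snp_bisulfite_visibility

spec = make_fixture_reference(seed=11)
parts = partition_cpgs(spec.cpg_index, spec)

print(f"amplicon '{spec.name}', {len(spec.sequence)} bp")
for label in ("O", "S", "I"):
    print(f"  region {label} {spec.regions[label]}: {len(parts[label])} CpGs")
print(f"  SNP at offset {spec.snp.position}: {spec.snp.alleles}")

print("\nSNP visibility after bisulfite conversion:")
print("  C/T on the top strand :", snp_bisulfite_visibility("C", "T"))
print("  G/A on this strand    :", snp_bisulfite_visibility("G", "A"))
# 'ambiguous' means the two alleles can read identically after conversion,
# so the complementary-strand G/A SNP is the one that keeps allele identity.
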