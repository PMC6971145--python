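"""Name the standard B haplotypes from sequence alone.

Builds the deterministic standard-haplotype fixture (sequences realising the
known identity/variant relations among B2..B19), runs the full curation
pipeline and prints the resulting catalogue: canonical allele names, the
shorthand haplotype string and the Bfbl name per haplotype.
"""

from bfbl import curate, standard_fixture

fx = standard_fixture()
result = curate(fx.records, fx.evidence, null_slots=fx.null_slots)

print(f"{'hap':>4}  {'haplotype string':<22} {'Bfbl':<6} canonical")
for hap in ["B2", "B4", "B5", "B6", "B8", "B12", "B13", "B14", "B15", "B19"]:
    print(
        f"{hap:>4}  {result.haplotype_string(hap):<22} "
        f"{result.bfbl_name(hap):<6} {result.haplotype_string(hap, canonical=True)}"
    )

# What the numbers mean: the B2 haplotype reads 2-2-2-2 because every gene
# carries the allele group anchored to B2; B6's 2-5-6-6 shows its BLB1 shared
# with B2 and BLB2 shared with B5; B8's 2-8-5:02-5:02 carries BF variants
# (second field 02) of the B5 alleles; and B19's 12-12:02-12:02-15:02 is the
# B12/B15 hybrid. B13 shares B4's BF2 on a different background, so its Bfbl
# name takes the provisional letter suffix 4b.
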