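# bfbl

A curation engine and sequence-based allele nomenclature for the chicken
MHC (the BF-BL region of the B locus), for database curators and avian
immunogenetics researchers.

The chicken classical MHC holds two class I genes (BF1, BF2) and two
class II B genes (BLB1, BLB2). Alleles were historically named after
serologically defined standard B haplotypes, but recombination inside the
region (B19 is a B12 × B15 hybrid), sequences shared between haplotypes and
even between loci, and a flood of partial unreplicated PCR sequences broke
that scheme. `bfbl` names alleles by sequence instead:

* **validation** — a sequence is valid only with ≥2 independent isolations
  (distinct PCR/bird/line/study sources); once-seen sequences 1–2 nt from a
  valid allele are flagged as likely PCR errors and left unnamed;
* **distances** — Hamming counts over the peptide-binding exons (BLB
  exon 2; BF exons 2+3), with per-domain splits for BF;
* **grouping** — single-linkage allele groups under the cutoff of ≤4 amino
  acid differences per domain (≤8 total for BF); 5–9 differences per exon
  is a curator-review zone, never auto-merged;
* **naming** — `locus*group:variant:synonym[:noncoding]`
  (e.g. `BF2*015:02:01`) assigned in haplotype order, numbering new groups
  from 30 (locus-ambiguous class II B from 101); shorthand drops trailing
  `:01` fields, haplotypes render as `BLB1-BLB2-BF1-BF2` strings
  (`2-8-5:02-5:02`), and the Bfbl haplotype name is the BF2 shorthand;
* **registry** — append-only: a sequence keeps one name forever, regardless
  of haplotype; conflicts are hard errors; every allocation is audited;
* **trees** — neighbour-joining with seeded bootstrap (advisory; the
  distance matrices decide groups);
* **synthetic data** — a generator that plants locus/group/variant
  structure, recombinants, cross-locus shares and PCR-error singletons with
  a full truth table, plus a deterministic fixture of the standard B
  haplotypes.

## Worked example

```python
from bfbl import curate, standard_fixture

fx = standard_fixture()
result = curate(fx.records, fx.evidence, null_slots=fx.null_slots)
for hap in ("B2", "B6", "B8", "B13", "B19"):
    print(hap, result.haplotype_string(hap), "| Bfbl", result.bfbl_name(hap))
```

prints

```
B2 2-2-2-2 | Bfbl 2
B6 2-5-6-6 | Bfbl 6
B8 2-8-5:02-5:02 | Bfbl 5:02
B13 4-4:02-4-4 | Bfbl 4b
B19 12-12:02-12:02-15:02 | Bfbl 15:02
```

Reading the strings: B2 anchors the 2-series at all four loci. B6 shares
its BLB1 with B2 and its BLB2 with B5, while its BF genes found the
6-series. B8 carries BF variants (second field `:02`) of the B5 alleles.
B13 matches B4 everywhere in the peptide-binding exons but carries a BLB2
protein variant (`4:02`), and since it shares B4's BF2 on a distinct
background its Bfbl name takes the provisional suffix `4b`. B19's string
exposes it as a mosaic: three slots from the 12-series, BF2 from the
15-series (`BF2*015:02:01`, seven amino acids from the B15 allele).

The `examples/` directory holds one short script per capability
(standard-haplotype naming, synthetic recovery, trees and bootstrap, mosaic
detection, registry growth). A thin CLI wraps the same pipeline:

```
bfbl synth --out-dir data --standard
bfbl assign data/standard.fasta data/standard.tsv data/evidence.tsv \
     --null-slot B14:BF1 --out-dir registry
bfbl haplotypes registry
```

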