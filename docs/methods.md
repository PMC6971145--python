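# Methods

## The problem

The chicken MHC (the BF-BL region of the B locus) holds two classical
class I genes (BF1, BF2) and two classical class II B genes (BLB1, BLB2).
Historically, alleles were named after serologically defined "standard" B
haplotypes (B1–B29), so every gene in the B12 haplotype carried the number
12 regardless of sequence. Recombination within the BF-BL region (the B19
haplotype is a B12 × B15 hybrid), identical sequences shared across
haplotypes (B4 and B13 are nearly identical in the BF-BL genes), and a flood
of partial PCR-derived sequences in public databases make haplotype-based
names untenable. `bfbl` implements a sequence-based nomenclature: each
genetic locus has a list of sequence alleles, a sequence has one name
forever, and a haplotype is named by the alleles it carries.

## Sequence handling

Inputs are nucleotide sequences of the polymorphic exons (BLB exon 2; BF
exons 2+3) with a metadata sidecar carrying locus claim, haplotype label,
provenance keys and a 1-based-inclusive exon map; an optional per-exon frame
offset (default 0) accommodates amplicons that start mid-codon. The
peptide-binding regions are exon 2 (the beta-1 domain) for BLB and the
exon 2 + exon 3 concatenation (alpha-1 + alpha-2, intron removed) for BF; a
BF record lacking either exon is rejected as incomplete and excluded from BF
analyses. Translation uses the standard code; any codon containing an IUPAC
ambiguity symbol becomes X (with a warning flag) rather than a rejection,
because validity is decided by replication, not by sequence quality alone;
an internal stop flags the record as a putative null or artefact but keeps
it. Two trimming presets exist: matrices use untrimmed consensus domains;
trees trim the primer-affected termini (7 residues from each end for BF,
2 from the start for BLB).

## Validation by replication

A sequence identity class (the set of observed sequences identical over the
comparison region — the concatenated coding exons available) is *valid* only
with at least two independent isolations: distinct
(source kind, source key) evidence pairs, where kinds are PCR replicate,
bird, line and study. Two birds within one study count as independent; two
rows citing the same PCR do not. Everything else is *provisional*.
A provisional class within 1–2 nucleotides of a valid class is flagged as a
likely PCR mis-incorporation; the flag is advisory — flags never rename or
delete. Only valid classes receive names; provisional classes keep their
digest as a reserved placeholder.

## Distances and grouping

Distances are raw Hamming counts over the peptide-binding region at amino-
acid or nucleotide level; no evolutionary-model correction, because the
grouping rule is stated in counted differences. Positions masked on either
sequence (X / non-ACGT) are excluded and the masked count is reported, so
ambiguity cannot inflate a difference. BF matrices carry per-domain splits.
Counts are binned for display the way curation matrices are coloured:
BF 0 / 1–4 / 5–8 / >8 and BLB 0 / 1–2 / 3–4 / >4.

Two sequences are variants of one allele group when they differ by at most
4 aa per domain — and, for BF, at most 8 in total; the conjunction of the
per-domain and total rules is deliberately the stricter reading. Counts of
5–9 per exon fall in a review zone: recorded as review edges for curators,
never merged on their own. Exactly 5 differences is review, not variant
(conservative; it is where the yellow display bin starts). Clustering is
single linkage over variant edges, mirroring merge-by-clade-then-vet-by-
matrix practice; a component containing an internal pair above the cutoff is
marked `chained`, surfacing the transitivity risk single linkage carries.
Clustering is deterministic, order-invariant and idempotent.

Locus assignment prefers anchored metadata (between-gene PCR or genomic
context): a single anchored claim wins outright; attestation at both BLB
loci makes the class location-ambiguous. Unanchored queries are assigned to
the locus of the nearest reference by amino-acid count, with a margin
(nearest other-locus minus nearest same-locus distance); a margin below
`locus_margin_tau` = 5 aa (under one variant-width; chosen because near-ties
must go to curators) is ambiguous. Ambiguous class II B classes are named in
the temporary 101-series and rendered in parentheses; ambiguous BF classes
are only flagged, since no parallel series is defined for class I.

## Trees

Neighbour joining (Saitou–Nei) on count distances normalised by length, with
an optional Poisson correction; ties in the Q criterion break on the
lexicographically smallest pair of subtree keys, so output is invariant to
row order. Negative branch lengths are clamped to zero and logged. Bootstrap
resamples alignment columns with replacement (default 500 replicates,
seeded) and reports per-bipartition percentages on the point-estimate tree.
Trees are advisory: when tree and matrix disagree, the matrix thresholds
decide (matrix precedence), and curator overrides belong in the audit log.
JTT-corrected distances are out of scope: clade structure at these
divergences (≥20 aa between BF groups, ≥12 between BLB groups) is robust to
the model, and grouping rests on counts, not the tree metric.

## Naming

A name is `<locus>*<group>:<variant>:<synonym>[:<noncoding>]`, group
zero-padded to three digits. Assignment is in haplotype order: a group
containing a standard-haplotype sequence takes the lowest member haplotype
number as its first field (applied uniformly, even if that haplotype's line
is extinct — logged); within a group the protein variant carried by the
lowest-numbered haplotype is `:01`, synonymous nucleotide classes order the
third field the same way, and classes without standard haplotypes follow in
deterministic registration order (sorted digests). Groups with no standard
member number from 30 upwards; location-ambiguous BLB groups from 101.
Fourth fields default to 01 with a `noncoding-data-absent` completeness
flag, because most literature sequences are exon-only. A parity mode (odd
first fields for BLB1-predominant sequences, even for BLB2) exists behind a
flag, default off — it is a possibility, not a rule.

Shorthand drops trailing `:01` fields and the zero padding, haplotypes
render as `BLB1-BLB2-BF1-BF2` shorthand strings with `null`, `?` and
parenthesised tokens, and the Bfbl haplotype name is the BF2 shorthand.
Haplotypes sharing a BF2 allele on distinct backgrounds get letter suffixes
(`4b`), assigned in haplotype-number-then-lexicographic order and recomputed
over the whole catalogue — they are explicitly provisional, and adding a
lower-numbered background later can shift them. Old "r"-number recombinant
names are parsed for backward compatibility but never emitted.

The registry is append-only: allocations conflicting with an issued name
are hard errors; re-running on identical input allocates nothing; superset
runs only add (old `registry.tsv` rows are bit-identical). Haplotype
catalogue entries may gain information (an unknown slot becoming known) and
are updated with an audit row. Audit rows carry a monotonic event counter
rather than wall-clock time so outputs are byte-reproducible.

Mosaic detection works at gene resolution: each slot's allele group is
attributed to the registered haplotypes carrying that group, and the
smallest covering parent set is reported (B19 resolves to {B12, B15}).
Sub-gene breakpoints are out of scope.

## Synthetic data

`generate()` plants structure rather than evolving it: no coalescent, no
selection, no alignment noise — so passing tests demonstrate the engine's
bookkeeping and thresholds, not robustness to indels, chimeras or
misalignment, which real curation would still face. Defaults are the study
conditions used throughout: 3 allele groups per locus, 2–3 protein variants
per group (1–2 substitutions each, placed on disjoint codons so within-group
pairs respect the cutoffs; for BF at most 2 per domain), a 25% chance of an
extra synonymous class per variant, 8 haplotypes, 10% PCR-error singleton
rate (1–2 nt off a parent, one evidence row), and between-group floors of
20 aa (BF) / 12 aa (BLB) — the separations real allele groups show. Region
lengths are fixed conventions: 270 nt for BLB exon 2 (plus a 240 nt non-PB
exon 3 so synonymous/CDS logic is exercised) and 270 + 276 nt for BF exons
2+3; nothing downstream depends on the exact values. Group founders are
drawn as random stop-free codon strings and accepted only if they clear the
floor against every founder of the same gene family (infeasible requests
fail before emission); real records default to anchored locus claims
(emulating genomic anchoring of references), while cross-locus-shared BLB
sequences are planted with claims at both loci and PCR errors arrive
unanchored. Every emitted record is covered by a truth table.

`standard_fixture()` is deterministic (fixed internal seed) and realises the
printed standard-haplotype relations: B6 BLB1 ≡ B2, B6 BLB2 ≡ B5, B8 BLB1 ≡
B2, B8 BF1/BF2 variants of B5, B13 ≡ B4 in the peptide-binding exons with
one amino-acid change in BLB2 exon 3, B19 = B12 background + a BF2 seven
amino acids from B15 (planted as a 4 + 3 per-domain split, inside the
conjunction rule — how the real pair splits across domains is not published,
so a real 5+2 split would be excluded by the rule; the fixture flags the
assumption rather than guessing), B15 BF1 = a B4 variant, and B14 BF1 null.
The fixture carries one record set per haplotype, so it plants the
B14-null case and not the alternative B15-null line.

## Numerical and procedural choices

* NJ tie-break: lexicographic on subtree keys after a 1e-12 Q tolerance.
* Identity classes are keyed by a SHA-1 digest of gene family + coding
  sequence; classes with different exon coverage are distinct by
  construction and reported rather than silently merged.
* Problem sizes in tests and the acceptance script (≤10 haplotypes, ≤8 taxa
  per tree, 500 bootstrap replicates, exhaustive topology oracles up to six
  taxa) are chosen so every check is exact or near-exact at desk scale.
* Degenerate inputs: n < 3 taxa refuse a tree; empty evidence is
  provisional (`no-evidence`); a locus with a single class forms a
  singleton group; records failing region extraction are excluded with
  named errors, never dropped silently.

## Known limitations

* Locus inference is only as good as the anchored reference set; a novel
  group with no anchored member at its true locus will be flagged
  ambiguous rather than guessed.
* Suffix letters and the 101-series are provisional by design and may be
  reassigned when the catalogue is rebuilt from scratch (never within an
  append-only registry lineage).
* No chimera detection; no automatic rejection of suspect sequences; no
  modelling of inversion/gene-conversion mechanisms; no Rfp-Y (YF/YLB) or
  CD1 naming; no sub-gene recombination breakpoints.
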