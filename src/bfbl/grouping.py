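"""Locus assignment and allele-group clustering.

Validated sequences are assigned to one of the four classical loci (BLB1,
BLB2, BF1, BF2) and clustered into allele groups using amino-acid difference
thresholds over the peptide-binding region:

* two sequences are variants of one allele group when they differ by at most
  four amino acids per domain, totalled to at most eight for BF sequences
  (which have two domains, alpha1 and alpha2);
* pairs with five to nine differences per exon/domain fall in a review zone:
  they are never merged on their own evidence, only recorded for curator
  follow-up;
* larger differences separate groups.

Clustering is single linkage over the variant edges, because curation merges
by clade membership and then vets pairs with the matrix; a component that
contains an internal pair above the cutoff is marked ``chained`` to surface
the transitivity risk.

Locus inference for unanchored sequences is nearest-reference by amino-acid
count, with a safety margin: when the gap between the nearest same-locus and
nearest other-locus reference is below ``locus_margin_tau`` (default 5 aa,
under one variant-width), the assignment is flagged ambiguous and routed to
curators. Metadata locus claims backed by between-gene PCR evidence override
sequence inference and are recorded as anchored; a sequence attested at both
class II B loci is ambiguous by definition and is named in the temporary
101-series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .distances import DistanceMatrix, count_diffs
from .seqio import CurationError


@dataclass(frozen=True)
class GroupingConfig:
    variant_max_per_domain: int = 4  # aa, per domain/exon
    bf_total_max: int = 8  # aa, alpha1 + alpha2
    review_lo: int = 5
    review_hi: int = 9
    locus_margin_tau: int = 5  # aa

    def __post_init__(self) -> None:
        if self.review_lo <= self.variant_max_per_domain:
            raise ValueError("review_lo must exceed variant_max_per_domain")
        if self.review_hi >= 10:
            raise ValueError("review_hi must be below 10")


@dataclass(frozen=True)
class LocusAssignment:
    seq_id: str
    locus: str | None
    nearest_reference: str | None
    margin: int | None
    ambiguous: bool
    anchored: bool = False


@dataclass(frozen=True)
class AlleleGroup:
    """A single-linkage component of identity classes at one locus."""

    locus: str
    members: tuple[str, ...]
    chained: bool
    review_edges: tuple[tuple[str, str, int], ...]


def pair_zone(
    total: int,
    domains: Sequence[int] | None,
    locus_class: str,
    config: GroupingConfig = GroupingConfig(),
) -> str:
    """Classify one pairwise comparison: 'variant', 'review' or 'beyond'.

    BLB uses the single beta1 exon count; BF requires BOTH per-domain counts
    at most 4 AND the total at most 8 (the conjunction is the stricter, safer
    curation rule). Counts of exactly 5 differences per exon fall in the
    review zone, not the variant zone.
    """
    if locus_class == "BLB":
        per_exon = (total,)
    else:
        if domains is None:
            raise CurationError("BF pair classification requires per-domain counts")
        per_exon = tuple(domains)
        if sum(per_exon) != total:
            raise CurationError("domain counts do not sum to the total")
    vmax = config.variant_max_per_domain
    if all(c <= vmax for c in per_exon) and (locus_class == "BLB" or total <= config.bf_total_max):
        return "variant"
    if all(c <= config.review_hi for c in per_exon):
        return "review"
    return "beyond"


def cluster(
    members: Sequence[str],
    dm: DistanceMatrix,
    locus: str,
    config: GroupingConfig = GroupingConfig(),
) -> list[AlleleGroup]:
    """Single-linkage allele groups over the variant edges.

    Deterministic and order-invariant: members are processed sorted, and the
    returned groups are sorted by their (sorted) member tuples. Review-zone
    pairs are recorded on every group touching them but never merge groups.
    """
    locus_class = "BF" if locus.startswith("BF") else "BLB"
    ids = sorted(members)
    parent = {m: m for m in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    zones: dict[tuple[str, str], tuple[str, int]] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            total = dm.get_pair(a, b)
            domains = dm.domain_pair(a, b) if locus_class == "BF" else None
            zone = pair_zone(total, domains, locus_class, config)
            zones[(a, b)] = (zone, total)
            if zone == "variant":
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    comps: dict[str, list[str]] = {}
    for m in ids:
        comps.setdefault(find(m), []).append(m)

    groups: list[AlleleGroup] = []
    for root in sorted(comps):
        mem = tuple(sorted(comps[root]))
        mset = set(mem)
        chained = False
        review: list[tuple[str, str, int]] = []
        for (a, b), (zone, total) in zones.items():
            touches = a in mset or b in mset
            if not touches:
                continue
            if zone == "review":
                review.append((a, b, total))
            if a in mset and b in mset and zone != "variant":
                chained = True
        groups.append(AlleleGroup(locus, mem, chained, tuple(sorted(review))))
    return groups


def assign_locus(
    seq_id: str,
    query_aa: str,
    references: Sequence[tuple[str, str, str]],
    config: GroupingConfig = GroupingConfig(),
    anchored_claim: str | None = None,
    attested_loci: Sequence[str] = (),
) -> LocusAssignment:
    """Infer the genetic locus of a query from labelled reference sequences.

    ``references`` are (label, locus, aa_string) over the same comparison
    region. The locus of the nearest reference wins; the margin is the
    distance to the nearest other-locus reference minus the distance to the
    nearest same-locus reference. Anchored metadata claims (between-gene PCR
    evidence) override inference; attestation at more than one locus makes
    the assignment ambiguous regardless.
    """
    attested = tuple(sorted(set(attested_loci)))
    if anchored_claim is not None:
        return LocusAssignment(
            seq_id,
            anchored_claim if len(attested) <= 1 else None,
            None,
            None,
            ambiguous=len(attested) > 1,
            anchored=True,
        )
    if not references:
        raise CurationError(f"{seq_id}: no references available for locus inference")
    loci = sorted({locus for _, locus, _ in references})
    if len(loci) < 2:
        raise CurationError(
            f"{seq_id}: references must cover both candidate loci, got {loci}"
        )
    best: dict[str, tuple[int, str]] = {}
    for label, locus, aa in sorted(references):
        d, _ = count_diffs(query_aa, aa, "aa")
        if locus not in best or d < best[locus][0]:
            best[locus] = (d, label)
    ranked = sorted(best.items(), key=lambda kv: (kv[1][0], kv[0]))
    (locus, (d_same, nearest)), (_, (d_other, _)) = ranked[0], ranked[1]
    margin = d_other - d_same
    ambiguous = margin < config.locus_margin_tau or len(attested) > 1
    return LocusAssignment(seq_id, locus, nearest, margin, ambiguous)
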