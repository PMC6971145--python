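"""End-to-end curation: records -> evidence -> grouping -> names -> haplotypes.

The pipeline reproduces the curation workflow: collapse observed sequences
into identity classes over the comparison region (the concatenated coding
exons available for the record), decide validity from replication evidence,
flag likely PCR-error singletons, resolve each class to a genetic locus
(anchored metadata claims first, sequence inference otherwise), cluster the
valid classes of each locus into allele groups with the amino-acid cutoffs,
assign names in haplotype order, and assemble per-haplotype strings.

Only valid classes receive names; provisional classes keep their class
digest as a reserved placeholder and are reported with their flags.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import distances as dist
from . import evidence as ev
from . import grouping as grp
from . import naming as nm
from .seqio import LOCI, RegionSpec, SequenceRecord, extract_region, translate

logger = logging.getLogger("bfbl")


def _digest(text: str) -> str:
    return hashlib.sha1(text.encode()).hexdigest()[:12]


@dataclass
class IdentityClass:
    """Observed sequences identical over the comparison region."""

    digest: str
    locus_class: str  # BF | BLB
    nt: str  # concatenated coding exons
    aa: str
    pb_nt: str  # peptide-binding region, nucleotide
    pb_aa: str
    pb_domains: tuple[int, ...] | None  # aa length of alpha1 for BF
    member_ids: tuple[str, ...] = ()
    haplotypes: tuple[str, ...] = ()
    claims: tuple[str, ...] = ()  # specific locus claims (anchored)
    status: ev.ValidationStatus | None = None
    locus: str | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class CurationResult:
    registry: nm.Registry
    classes: dict[str, IdentityClass]
    groups: dict[str, list[grp.AlleleGroup]]
    haplotypes: dict[str, nm.HaplotypeRecord]
    suspect_flags: dict[str, str]
    allocations: list[tuple[str, nm.AlleleName]]

    def haplotype_string(self, hap_id: str, canonical: bool = False) -> str:
        return nm.haplotype_string(self.haplotypes[hap_id], canonical)

    def bfbl_name(self, hap_id: str) -> str:
        return nm.bfbl_name(self.haplotypes[hap_id])

    def name_of(self, hap_id: str, locus: str) -> str | None:
        slot = self.haplotypes[hap_id].slot(locus)
        return slot.render() if isinstance(slot, nm.AlleleName) else slot


def _pb_spec(locus_class: str, level: str) -> RegionSpec:
    region = "alpha1_2" if locus_class == "BF" else "beta1"
    return RegionSpec(locus_class, region, "none", level)


def build_identity_classes(records: Sequence[SequenceRecord]) -> dict[str, IdentityClass]:
    """Collapse records into identity classes keyed by a sequence digest.

    The digest covers the locus class and the concatenated coding exons, so
    identical sequences in different haplotypes (or at both BLB loci) land in
    one class and will receive a single name.
    """
    classes: dict[str, IdentityClass] = {}
    for rec in sorted(records, key=lambda r: r.seq_id):
        lc = rec.locus_class
        if lc is None:
            logger.warning("%s: locus class unknown, record excluded", rec.seq_id)
            continue
        cds_nt = extract_region(rec, RegionSpec(lc, "CDS", "none", "nt"))
        pb_nt = extract_region(rec, _pb_spec(lc, "nt"))
        key = _digest(f"{lc}|{cds_nt}")
        cls = classes.get(key)
        if cls is None:
            boundary = None
            if lc == "BF":
                ex2 = rec.exon("exon2")
                assert ex2 is not None
                boundary = ((ex2.end - ex2.start + 1 - ex2.frame) // 3,)
            cls = IdentityClass(
                digest=key,
                locus_class=lc,
                nt=cds_nt,
                aa=translate(cds_nt, 0, record=rec),
                pb_nt=pb_nt,
                pb_aa=extract_region(rec, _pb_spec(lc, "aa")),
                pb_domains=boundary,
            )
            classes[key] = cls
        cls.member_ids = tuple(sorted(set(cls.member_ids) | {rec.seq_id}))
        if rec.haplotype:
            cls.haplotypes = tuple(sorted(set(cls.haplotypes) | {rec.haplotype}))
        if rec.locus_claim in LOCI:
            cls.claims = tuple(sorted(set(cls.claims) | {rec.locus_claim}))
        for f in rec.flags:
            if f not in cls.flags:
                cls.flags.append(f)
    return classes


def _family_matrix(
    classes: Sequence[IdentityClass], locus_class: str, level: str
) -> dist.DistanceMatrix | None:
    """Pairwise matrix over the peptide-binding region for one gene family."""
    members = [c for c in classes if c.locus_class == locus_class]
    if len(members) < 2:
        return None
    strings = [c.pb_nt if level == "nt" else c.pb_aa for c in members]
    if len({len(s) for s in strings}) > 1:
        # records with differing exon coverage cannot share one block
        majority = max({len(s) for s in strings}, key=[len(s) for s in strings].count)
        members = [c for c, s in zip(members, strings) if len(s) == majority]
        strings = [s for s in strings if len(s) == majority]
    spec = _pb_spec(locus_class, level)
    block = dist.AlignedBlock(
        spec,
        tuple(c.digest for c in members),
        tuple(strings),
        domain_boundary=(members[0].pb_domains[0] * (3 if level == "nt" else 1))
        if locus_class == "BF" and members[0].pb_domains
        else None,
    )
    return dist.matrix(block)


def _resolve_locus(
    cls: IdentityClass,
    references: Mapping[str, list[tuple[str, str, str]]],
    config: grp.GroupingConfig,
) -> None:
    """Set cls.locus (or the ambiguous pseudo-locus / None) from claims or inference."""
    claims = [c for c in cls.claims if c in LOCI]
    if len(claims) == 1:
        cls.locus = claims[0]
        return
    if len(claims) > 1:
        # attested at both loci by between-gene PCR evidence
        cls.flags.append("locus-ambiguous(attested=" + ",".join(claims) + ")")
        cls.locus = nm.AMBIGUOUS_BLB if cls.locus_class == "BLB" else None
        return
    refs = references.get(cls.locus_class, [])
    if not refs or len({locus for _, locus, _ in refs}) < 2:
        cls.flags.append("locus-unresolved(no-references)")
        cls.locus = None
        return
    assignment = grp.assign_locus(cls.digest, cls.pb_aa, refs, config)
    if assignment.ambiguous:
        cls.flags.append(f"locus-ambiguous(margin={assignment.margin})")
        cls.locus = nm.AMBIGUOUS_BLB if cls.locus_class == "BLB" else None
    else:
        cls.locus = assignment.locus


def curate(
    records: Sequence[SequenceRecord],
    evidence: Sequence[ev.EvidenceRecord],
    registry: nm.Registry | None = None,
    null_slots: Mapping[str, Sequence[str]] | None = None,
    grouping_config: grp.GroupingConfig = grp.GroupingConfig(),
    naming_config: nm.NamingConfig = nm.NamingConfig(),
) -> CurationResult:
    """Run the full curation pipeline and return the updated registry.

    ``null_slots`` marks haplotype slots attested as lacking a gene (the BF1
    null alleles); slots with neither a sequence nor a null attestation
    render as unknown ('?').
    """
    registry = registry if registry is not None else nm.Registry()
    classes = build_identity_classes(records)
    ordered = sorted(classes.values(), key=lambda c: c.digest)

    # 1. replication evidence
    for cls in ordered:
        cls.status = ev.validate(cls.member_ids, evidence)

    # 2. advisory PCR-error flags (nucleotide distances per gene family)
    suspect_flags: dict[str, str] = {}
    for lc in ("BLB", "BF"):
        fam = [c for c in ordered if c.locus_class == lc]
        ntm = _family_matrix(fam, lc, "nt")
        if ntm is None:
            continue
        statuses = {c.digest: c.status for c in fam if c.digest in ntm.labels}
        suspect_flags.update(ev.flag_suspect_singletons(statuses, ntm))
    for cid, flag in suspect_flags.items():
        classes[cid].flags.append(flag)

    # 3. locus resolution (anchored references are the valid claimed classes)
    references: dict[str, list[tuple[str, str, str]]] = {"BF": [], "BLB": []}
    for cls in ordered:
        if cls.status.is_valid and len(cls.claims) == 1:
            references[cls.locus_class].append((cls.digest, cls.claims[0], cls.pb_aa))
    for cls in ordered:
        _resolve_locus(cls, references, grouping_config)

    # 4. allele-group clustering per locus over valid classes
    groups_by_locus: dict[str, list[grp.AlleleGroup]] = {}
    for locus in LOCI + (nm.AMBIGUOUS_BLB,):
        members = [c for c in ordered if c.locus == locus and c.status.is_valid]
        if not members:
            continue
        lc = members[0].locus_class
        aam = _family_matrix(members, lc, "aa")
        if aam is None:
            dm = dist.DistanceMatrix(
                (members[0].digest,), [[0]], "aa", len(members[0].pb_aa)
            )
        else:
            dm = aam.submatrix([c.digest for c in members if c.digest in aam.labels])
        groups_by_locus[locus] = grp.cluster(list(dm.labels), dm, locus, grouping_config)

    # 5. names in haplotype order
    views = {
        c.digest: nm.ClassView(
            digest=c.digest,
            aa_digest=_digest(c.aa),
            haplotypes=c.haplotypes,
            sort_key=c.digest,
            full_data=False,
        )
        for c in ordered
    }
    allocations = nm.assign_names(groups_by_locus, views, registry, naming_config)

    # 6. haplotype assembly
    null_slots = {k: set(v) for k, v in (null_slots or {}).items()}
    haplotypes: dict[str, nm.HaplotypeRecord] = {}
    hap_ids = sorted({h for c in ordered for h in c.haplotypes})
    for hap_id in hap_ids:
        hap = nm.HaplotypeRecord(hap_id)
        for locus in LOCI:
            carriers = [
                c
                for c in ordered
                if hap_id in c.haplotypes and c.locus == locus and c.digest in registry.entries
            ]
            if len(carriers) > 1:
                logger.warning(
                    "haplotype %s has %d classes at %s; keeping the first by digest",
                    hap_id,
                    len(carriers),
                    locus,
                )
            if carriers:
                hap.slots[locus] = registry.entries[carriers[0].digest].name
            elif locus in null_slots.get(hap_id, set()):
                hap.slots[locus] = nm.NULL
            else:
                hap.slots[locus] = None
        amb = [
            c
            for c in ordered
            if hap_id in c.haplotypes and c.locus == nm.AMBIGUOUS_BLB and c.digest in registry.entries
        ]
        if amb and hap.slots.get("BLB1") is None and hap.slots.get("BLB2") is None:
            hap.ambiguous_blb = registry.entries[amb[0].digest].name
        registry.register_haplotype(hap)
        haplotypes[hap_id] = hap

    nm.assign_provisional_suffixes(registry.haplotypes)

    return CurationResult(registry, classes, groups_by_locus, haplotypes, suspect_flags, allocations)
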