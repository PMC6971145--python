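"""Allele names, haplotype strings, Bfbl names and the append-only registry.

An allele name is ``<locus>*<group>:<variant>:<synonym>[:<noncoding>]``, e.g.
``BF2*015:02:01``: the first field is the allele group (three digits,
zero-padded), the second the nonsynonymous protein variant within the group,
the third the synonymous nucleotide variant within the protein variant, and
the optional fourth the non-coding variant when such data exist.

Names are assigned in haplotype order: the allele group containing the
sequence of the lowest-numbered standard haplotype takes that haplotype's
number as its first field, and within a group the variant carried by the
lowest-numbered haplotype is ``:01``. Groups with no standard-haplotype
member take the next free number from 30 upwards; class II B sequences
without a clear genetic location (attested at both BLB loci) are temporarily
numbered from 101 and shown in parentheses in haplotype strings.

The shorthand drops trailing fields equal to the first-described variant
(``:01``) and the leading zeros of the group number, so ``BF1*002:01:01`` is
just ``2`` and ``BF1*005:02:01`` is ``5:02``. A haplotype renders as its four
slots in the order BLB1-BLB2-BF1-BF2, with the tokens ``null`` (attested
absent gene), ``?`` (unknown) and ``( - )`` (location-ambiguous class II B)
allowed; the Bfbl haplotype name is the BF2 shorthand, plus a letter suffix
for provisional haplotypes sharing that BF2 on a distinct background.

The registry is append-only: a name, once issued, is never reassigned or
altered, and the same sequence identity class always maps to the same name
regardless of haplotype. Conflicting allocations are hard errors for
curators; every allocation appends an audit row.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .grouping import AlleleGroup
from .seqio import CurationError, LOCI

#: pseudo-locus for class II B sequences without a clear genetic location
AMBIGUOUS_BLB = "BLB"

NULL = "null"

_STD_HAP = re.compile(r"B(\d+)$")


class NameConflictError(CurationError):
    """Same identity class proposed under two different names."""


@dataclass(frozen=True)
class NamingConfig:
    new_allele_base: int = 30
    ambiguous_blb_base: int = 101
    parity_mode: bool = False  # odd numbers for BLB1-predominant, even for BLB2


@dataclass(frozen=True, order=True)
class AlleleName:
    locus: str
    f1: int
    f2: int = 1
    f3: int = 1
    f4: int | None = None

    def __post_init__(self) -> None:
        if min(self.f1, self.f2, self.f3) < 1 or (self.f4 is not None and self.f4 < 1):
            raise ValueError("allele name fields must be >= 1")

    def render(self) -> str:
        s = f"{self.locus}*{self.f1:03d}:{self.f2:02d}:{self.f3:02d}"
        if self.f4 is not None:
            s += f":{self.f4:02d}"
        return s

    def shorthand(self) -> str:
        fields = [self.f1, self.f2, self.f3] + ([self.f4] if self.f4 is not None else [])
        while len(fields) > 1 and fields[-1] == 1:
            fields.pop()
        return str(fields[0]) + "".join(f":{x:02d}" for x in fields[1:])

    @property
    def group_key(self) -> tuple[str, int]:
        return (self.locus, self.f1)


_NAME_RE = re.compile(r"(BLB1|BLB2|BF1|BF2|BLB)\*(\d{3}):(\d{2}):(\d{2})(?::(\d{2}))?$")


def parse_allele_name(text: str) -> AlleleName:
    m = _NAME_RE.match(text.strip())
    if m is None:
        raise CurationError(f"cannot parse allele name {text!r}")
    f4 = int(m.group(5)) if m.group(5) else None
    return AlleleName(m.group(1), int(m.group(2)), int(m.group(3)), int(m.group(4)), f4)


def std_hap_number(label: str | None) -> int | None:
    """Standard-haplotype number from a label like 'B12', else None."""
    if label is None:
        return None
    m = _STD_HAP.match(label.strip())
    return int(m.group(1)) if m else None


# --------------------------------------------------------------------------
# haplotype records and strings


@dataclass
class HaplotypeRecord:
    """One BF-BL haplotype: four slots in the order BLB1-BLB2-BF1-BF2.

    A slot holds an AlleleName, the string 'null' (attested absent), or None
    (unknown, rendered '?'). ``ambiguous_blb`` replaces both BLB slots with a
    parenthesised pair when one class II B sequence cannot be located.
    """

    hap_id: str
    slots: dict[str, "AlleleName | str | None"] = field(default_factory=dict)
    ambiguous_blb: AlleleName | None = None
    provisional_suffix: str | None = None

    def slot(self, locus: str) -> "AlleleName | str | None":
        return self.slots.get(locus)


def _slot_token(value: "AlleleName | str | None", canonical: bool) -> str:
    if value is None:
        return "?"
    if value == NULL:
        return NULL
    assert isinstance(value, AlleleName)
    return value.render() if canonical else value.shorthand()


def haplotype_string(hap: HaplotypeRecord, canonical: bool = False) -> str:
    """Hyphen-joined haplotype string, shorthand by default.

    Examples of the grammar: '2-2-2-2', '2-8-5:02-5:02', '9-34-null-33',
    '?-?-9:02-9' and '(109-109)-23:02-38'.
    """
    parts: list[str] = []
    if hap.ambiguous_blb is not None:
        t = _slot_token(hap.ambiguous_blb, canonical)
        parts.append(f"({t}-{t})")
    else:
        parts.append(_slot_token(hap.slot("BLB1"), canonical))
        parts.append(_slot_token(hap.slot("BLB2"), canonical))
    parts.append(_slot_token(hap.slot("BF1"), canonical))
    parts.append(_slot_token(hap.slot("BF2"), canonical))
    return "-".join(parts)


def bfbl_name(hap: HaplotypeRecord) -> str:
    """The Bfbl haplotype name: BF2 shorthand plus any provisional suffix."""
    token = _slot_token(hap.slot("BF2"), canonical=False)
    return token + (hap.provisional_suffix or "")


_PAREN_TOKEN = re.compile(r"\(([^)]*)\)|([^-]+)")


def parse_haplotype_string(text: str, hap_id: str = "") -> HaplotypeRecord:
    """Parse a haplotype string back into a record (shorthand tokens only).

    Shorthand carries no locus prefix, so slots are reconstructed from
    position; a shorthand field list like '5:02' maps to f1=5, f2=2.
    Old 'r'-number recombinant names are not produced by this package but a
    bare token is accepted as an opaque group number where possible.
    """
    tokens: list[tuple[bool, str]] = []
    for m in _PAREN_TOKEN.finditer(text.strip()):
        if m.group(1) is not None:
            tokens.append((True, m.group(1)))
        else:
            tokens.append((False, m.group(2)))
    hap = HaplotypeRecord(hap_id)

    def to_name(locus: str, tok: str) -> "AlleleName | str | None":
        if tok == "?":
            return None
        if tok == NULL:
            return NULL
        fields = [int(x) for x in tok.split(":")]
        fields += [1] * (3 - len(fields))
        return AlleleName(locus, *fields[:3], *( [fields[3]] if len(fields) > 3 else []))

    if tokens and tokens[0][0]:
        inner = tokens[0][1].split("-")
        hap.ambiguous_blb = to_name(AMBIGUOUS_BLB, inner[0])  # type: ignore[assignment]
        rest = tokens[1:]
    else:
        if len(tokens) != 4:
            raise CurationError(f"haplotype string {text!r} does not have four slots")
        hap.slots["BLB1"] = to_name("BLB1", tokens[0][1])
        hap.slots["BLB2"] = to_name("BLB2", tokens[1][1])
        rest = tokens[2:]
    if len(rest) != 2:
        raise CurationError(f"haplotype string {text!r} does not have four slots")
    hap.slots["BF1"] = to_name("BF1", rest[0][1])
    hap.slots["BF2"] = to_name("BF2", rest[1][1])
    return hap


# --------------------------------------------------------------------------
# registry


@dataclass(frozen=True)
class RegistryEntry:
    digest: str  # identity-class digest (nt over the comparison region)
    name: AlleleName
    aa_digest: str  # protein digest, ties synonymous classes to a variant
    flags: tuple[str, ...] = ()


class Registry:
    """Append-only catalogue of issued names, haplotypes and audit rows."""

    def __init__(self) -> None:
        self.entries: dict[str, RegistryEntry] = {}
        self.haplotypes: dict[str, HaplotypeRecord] = {}
        self.audit: list[dict[str, str]] = []

    # -- allocation ---------------------------------------------------------

    def lookup(self, digest: str) -> RegistryEntry | None:
        return self.entries.get(digest)

    def entries_at(self, locus: str) -> list[RegistryEntry]:
        return sorted(
            (e for e in self.entries.values() if e.name.locus == locus),
            key=lambda e: (e.name, e.digest),
        )

    def used_group_numbers(self, locus: str) -> set[int]:
        return {e.name.f1 for e in self.entries.values() if e.name.locus == locus}

    def allocate(
        self, digest: str, name: AlleleName, aa_digest: str, flags: Sequence[str] = (), why: str = ""
    ) -> bool:
        """Issue a name; returns False when the identical allocation exists.

        A different name for an already-registered class is a hard error
        requiring curator action (names are never reassigned).
        """
        existing = self.entries.get(digest)
        if existing is not None:
            if existing.name == name:
                return False
            raise NameConflictError(
                f"class {digest} already named {existing.name.render()}, "
                f"conflicting allocation {name.render()}"
            )
        for e in self.entries.values():
            if e.name == name:
                raise NameConflictError(
                    f"name {name.render()} already issued to class {e.digest}"
                )
        self.entries[digest] = RegistryEntry(digest, name, aa_digest, tuple(flags))
        self.audit.append(
            {
                "event": f"{len(self.audit):06d}",
                "action": "allocate",
                "digest": digest,
                "name": name.render(),
                "why": why,
            }
        )
        return True

    def register_haplotype(self, hap: HaplotypeRecord) -> bool:
        """Add or update a haplotype catalogue entry (audited).

        Unlike allele names, haplotype strings may gain information (an
        unknown slot becoming known), so updates are allowed and audited
        rather than rejected.
        """
        old = self.haplotypes.get(hap.hap_id)
        if old is not None and haplotype_string(old, True) == haplotype_string(hap, True):
            return False
        self.haplotypes[hap.hap_id] = hap
        self.audit.append(
            {
                "event": f"{len(self.audit):06d}",
                "action": "haplotype" if old is None else "haplotype-update",
                "digest": hap.hap_id,
                "name": haplotype_string(hap, True),
                "why": "" if old is None else f"was {haplotype_string(old, True)}",
            }
        )
        return True

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "registry.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(("digest", "name", "aa_digest", "flags"))
            for digest in sorted(self.entries):
                e = self.entries[digest]
                w.writerow((e.digest, e.name.render(), e.aa_digest, ";".join(e.flags)))
        with open(directory / "haplotypes.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(("haplotype", "string", "shorthand", "bfbl"))
            for hap_id in sorted(self.haplotypes):
                hap = self.haplotypes[hap_id]
                w.writerow(
                    (hap_id, haplotype_string(hap, True), haplotype_string(hap), bfbl_name(hap))
                )
        with open(directory / "audit.json", "w") as fh:
            json.dump(self.audit, fh, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, directory: str | Path) -> "Registry":
        directory = Path(directory)
        reg = cls()
        with open(directory / "registry.tsv", newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                reg.entries[row["digest"]] = RegistryEntry(
                    row["digest"],
                    parse_allele_name(row["name"]),
                    row["aa_digest"],
                    tuple(f for f in row["flags"].split(";") if f),
                )
        hap_path = directory / "haplotypes.tsv"
        if hap_path.exists():
            with open(hap_path, newline="") as fh:
                for row in csv.DictReader(fh, delimiter="\t"):
                    reg.haplotypes[row["haplotype"]] = _parse_canonical_string(
                        row["string"], row["haplotype"]
                    )
        audit_path = directory / "audit.json"
        if audit_path.exists():
            with open(audit_path) as fh:
                reg.audit = json.load(fh)
        # suffixes are derived state: recompute over the loaded catalogue
        assign_provisional_suffixes(reg.haplotypes)
        return reg


def _parse_canonical_string(text: str, hap_id: str) -> HaplotypeRecord:
    hap = HaplotypeRecord(hap_id)
    m = re.match(r"\(([^)]*)\)-(.+)$", text)
    if m:
        inner = m.group(1).split("-")[0]
        hap.ambiguous_blb = parse_allele_name(inner)
        bf_tokens = m.group(2).split("-")
        loci = ["BF1", "BF2"]
    else:
        bf_tokens = text.split("-")
        loci = ["BLB1", "BLB2", "BF1", "BF2"]
    for locus, tok in zip(loci, bf_tokens):
        if tok == "?":
            hap.slots[locus] = None
        elif tok == NULL:
            hap.slots[locus] = NULL
        else:
            hap.slots[locus] = parse_allele_name(tok)
    return hap


# --------------------------------------------------------------------------
# name assignment


@dataclass(frozen=True)
class ClassView:
    """What the naming step needs to know about one identity class."""

    digest: str
    aa_digest: str
    haplotypes: tuple[str, ...] = ()
    sort_key: str = ""  # deterministic fallback ordering (e.g. nt digest)
    full_data: bool = False  # noncoding data available (f4 resolvable)


def _min_hap(views: Iterable[ClassView]) -> int | None:
    nums = [n for v in views for n in (std_hap_number(h) for h in v.haplotypes) if n is not None]
    return min(nums) if nums else None


def assign_names(
    groups_by_locus: Mapping[str, Sequence[AlleleGroup]],
    classes: Mapping[str, ClassView],
    registry: Registry,
    config: NamingConfig = NamingConfig(),
) -> list[tuple[str, AlleleName]]:
    """Assign names to every identity class in the given groups.

    Deterministic; respects names already in the registry (stability), so a
    re-run on identical input allocates nothing and a superset run only adds.
    Returns the new (digest, name) allocations in the order issued.
    """
    allocations: list[tuple[str, AlleleName]] = []
    for locus in sorted(groups_by_locus, key=lambda l: (LOCI + (AMBIGUOUS_BLB,)).index(l)):
        ambiguous = locus == AMBIGUOUS_BLB
        base = config.ambiguous_blb_base if ambiguous else config.new_allele_base
        taken = registry.used_group_numbers(locus)

        def group_order(g: AlleleGroup) -> tuple:
            views = [classes[d] for d in g.members]
            h = _min_hap(views)
            return (0, h, g.members) if h is not None else (1, 0, g.members)

        for group in sorted(groups_by_locus[locus], key=group_order):
            views = {d: classes[d] for d in group.members}
            registered = {
                d: registry.entries[d] for d in group.members if d in registry.entries
            }
            f1s = {e.name.f1 for e in registered.values()}
            if len(f1s) > 1:
                raise NameConflictError(
                    f"group {group.members} spans registered group numbers {sorted(f1s)}"
                )
            if f1s:
                f1 = f1s.pop()
            else:
                h = _min_hap(views.values())
                if h is not None and not ambiguous:
                    f1 = h
                    if f1 in taken:
                        raise NameConflictError(
                            f"{locus} group number {f1} already issued to another group"
                        )
                else:
                    f1 = base
                    while f1 in taken:
                        f1 += 1
                    if config.parity_mode and locus in ("BLB1", "BLB2"):
                        want_odd = locus == "BLB1"
                        while f1 in taken or (f1 % 2 == 1) != want_odd:
                            f1 += 1
            taken.add(f1)

            # protein variants within the group
            by_aa: dict[str, list[ClassView]] = {}
            for d in sorted(group.members):
                by_aa.setdefault(views[d].aa_digest, []).append(views[d])
            existing_f2 = {
                e.aa_digest: e.name.f2
                for e in registry.entries.values()
                if e.name.group_key == (locus, f1)
            }
            used_f2 = set(existing_f2.values())

            def variant_order(aa_digest: str) -> tuple:
                h = _min_hap(by_aa[aa_digest])
                keys = tuple(sorted(v.sort_key for v in by_aa[aa_digest]))
                return (0, h, keys) if h is not None else (1, 0, keys)

            next_f2 = 1
            for aa_digest in sorted(by_aa, key=variant_order):
                if aa_digest in existing_f2:
                    f2 = existing_f2[aa_digest]
                else:
                    while next_f2 in used_f2:
                        next_f2 += 1
                    f2 = next_f2
                    used_f2.add(f2)

                used_f3 = {
                    e.name.f3
                    for e in registry.entries.values()
                    if e.name.group_key == (locus, f1) and e.name.f2 == f2
                }

                def class_order(v: ClassView) -> tuple:
                    h = _min_hap([v])
                    return (0, h, v.sort_key) if h is not None else (1, 0, v.sort_key)

                next_f3 = 1
                for view in sorted(by_aa[aa_digest], key=class_order):
                    if view.digest in registry.entries:
                        continue
                    while next_f3 in used_f3:
                        next_f3 += 1
                    f3 = next_f3
                    used_f3.add(f3)
                    flags = [] if view.full_data else ["noncoding-data-absent"]
                    if ambiguous:
                        flags.append("locus-ambiguous")
                    name = AlleleName(locus, f1, f2, f3)
                    registry.allocate(
                        view.digest,
                        name,
                        aa_digest,
                        flags,
                        why=f"haplotypes={','.join(view.haplotypes) or '-'}",
                    )
                    allocations.append((view.digest, name))
    return allocations


def assign_provisional_suffixes(haplotypes: Mapping[str, HaplotypeRecord]) -> None:
    """Letter suffixes for haplotypes sharing a BF2 allele on distinct backgrounds.

    The Bfbl name is the BF2 shorthand; when several haplotypes carry that
    BF2 on different backgrounds, the lowest-numbered (then lexicographic)
    background keeps the bare name and later distinct backgrounds get
    'b', 'c', ... in order. Haplotypes with identical strings share a Bfbl
    name and hence a suffix. Suffixes are provisional and recomputed over
    the whole catalogue.
    """
    by_bf2: dict[str, list[HaplotypeRecord]] = {}
    for hap in haplotypes.values():
        bf2 = hap.slot("BF2")
        if isinstance(bf2, AlleleName):
            by_bf2.setdefault(bf2.shorthand(), []).append(hap)
    for haps in by_bf2.values():
        haps.sort(key=lambda h: (std_hap_number(h.hap_id) or 10**6, h.hap_id))
        backgrounds: list[tuple[str, str]] = []  # (suffix-free string, suffix)
        for hap in haps:
            hap.provisional_suffix = None
            s = haplotype_string(hap, canonical=True)
            for bg, suffix in backgrounds:
                if bg == s:
                    hap.provisional_suffix = suffix or None
                    break
            else:
                suffix = "" if not backgrounds else chr(ord("a") + len(backgrounds))
                backgrounds.append((s, suffix))
                hap.provisional_suffix = suffix or None


# --------------------------------------------------------------------------
# mosaic detection


@dataclass(frozen=True)
class MosaicReport:
    hap_id: str
    slot_parents: Mapping[str, tuple[str, ...]]  # locus -> registered haps sharing the group
    parents: tuple[str, ...] | None  # minimal covering parent set
    is_mosaic: bool


def detect_mosaic(hap: HaplotypeRecord, registry: Registry) -> MosaicReport:
    """Attribute each slot's allele group to registered haplotypes.

    Gene-level resolution only: a parent haplotype 'covers' a slot when it
    carries an allele of the same group (locus and first field) there. The
    report lists, per slot, all registered haplotypes sharing that group, and
    the smallest parent set covering every slot that can be attributed (ties
    broken lexicographically). ``is_mosaic`` requires every named slot to be
    attributed and more than one parent; a haplotype covered by a single
    parent, or with unattributable (unique) slots, is not called a mosaic.
    """
    from itertools import combinations

    candidates = sorted(h for h in registry.haplotypes if h != hap.hap_id)
    slot_parents: dict[str, tuple[str, ...]] = {}
    attributable: list[str] = []
    for locus in LOCI:
        value = hap.slot(locus)
        if not isinstance(value, AlleleName):
            continue
        attributable.append(locus)
        parents = []
        for cand in candidates:
            other = registry.haplotypes[cand].slot(locus)
            if isinstance(other, AlleleName) and other.group_key == value.group_key:
                parents.append(cand)
        slot_parents[locus] = tuple(parents)

    coverable = [l for l in attributable if slot_parents[l]]
    best: tuple[str, ...] | None = None
    pool = sorted({p for l in coverable for p in slot_parents[l]})
    for r in range(1, len(pool) + 1):
        for combo in combinations(pool, r):
            if all(any(p in combo for p in slot_parents[l]) for l in coverable):
                best = combo
                break
        if best is not None:
            break
    full_cover = best is not None and len(coverable) == len(attributable) and attributable
    return MosaicReport(
        hap.hap_id,
        slot_parents,
        best,
        is_mosaic=bool(full_cover and best is not None and len(best) > 1),
    )
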