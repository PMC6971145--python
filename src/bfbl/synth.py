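"""Synthetic sequence sets with planted structure, and the standard fixture.

Two generators live here.

``generate`` emits noisy sequence sets with planted locus / allele-group /
variant structure: allele groups are separated by at least 20 amino acids
over the peptide-binding region for class I (BF) and at least 12 for
class II B (BLB), matching the separations seen between real allele groups;
variants within a group differ by one to four amino-acid substitutions
(respecting the per-domain cutoff for BF); optional recombinant haplotypes,
cross-locus-shared class II B sequences and once-observed PCR-error
singletons (one or two nucleotides off a real allele, single evidence
record) are planted on top. Structure is planted, not evolved: there is no
population-genetic realism. Every emitted record is covered by a truth
table.

``standard_fixture`` deterministically realises the identity/variant
relations among the standard B haplotypes that drive the worked naming
examples: B6 shares its BLB1 with B2 and its BLB2 with B5; B8 shares BLB1
with B2 and carries BF variants of B5; B13 matches B4 in the peptide-binding
exons with a single amino-acid change in BLB2 exon 3; B19 is a B12
background carrying a BF2 variant of B15 (seven amino acids apart, four in
alpha1 and three in alpha2); B14 lacks BF1 (null). The expected names and
haplotype strings ship with the fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import count_diffs
from .evidence import EvidenceRecord, write_evidence
from .naming import AMBIGUOUS_BLB
from .seqio import (
    LOCI,
    CurationError,
    Exon,
    SequenceRecord,
    translate,
    write_records,
)

_CODONS = sorted(
    c
    for c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3))
    if translate(c) != "*"
)
_BY_AA: dict[str, list[str]] = {}
for _c in _CODONS:
    _BY_AA.setdefault(translate(_c), []).append(_c)


class InfeasibleConfigError(CurationError):
    """The requested structure cannot be realised at the distance floor."""


@dataclass(frozen=True)
class RecombinantSpec:
    """A planted recombinant: donor_a background with one slot from donor_b."""

    name: str
    donor_a: str
    donor_b: str
    slot: str  # locus taken from donor_b


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    groups_per_locus: int = 3
    variants_per_group: tuple[int, int] = (2, 3)  # inclusive range
    syn_variant_prob: float = 0.25
    n_haplotypes: int = 8
    recombinants: tuple[RecombinantSpec, ...] = ()
    cross_locus_shares: int = 0
    pcr_error_rate: float = 0.10
    bf_between_min: int = 20  # aa over alpha1+alpha2
    blb_between_min: int = 12  # aa over beta1
    blb_exon2_nt: int = 270
    bf_exon2_nt: int = 270
    bf_exon3_nt: int = 276
    max_attempts: int = 500


@dataclass
class SynthResult:
    records: list[SequenceRecord]
    evidence: list[EvidenceRecord]
    truth: pd.DataFrame
    config: SynthConfig

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_records(self.records, directory / "records.fasta", directory / "records.tsv")
        write_evidence(self.evidence, directory / "evidence.tsv")
        self.truth.to_csv(directory / "truth.tsv", sep="\t", index=False)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(_CODONS[i] for i in rng.integers(0, len(_CODONS), size=n_codons))


def _nonsyn_point(seq: str, codon_idx: int, rng: np.random.Generator) -> str:
    """One-nucleotide change in the given codon that alters the amino acid."""
    start = 3 * codon_idx
    codon = seq[start : start + 3]
    aa = translate(codon)
    options = []
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            cand = codon[:pos] + nt + codon[pos + 1 :]
            cand_aa = translate(cand)
            if cand_aa not in ("*", aa):
                options.append(cand)
    if not options:  # cannot happen with the standard code, defensive
        raise InfeasibleConfigError(f"no nonsynonymous point change for codon {codon}")
    new = options[rng.integers(0, len(options))]
    return seq[:start] + new + seq[start + 3 :]


def _syn_point(seq: str, rng: np.random.Generator) -> str:
    """A synonymous single-nucleotide change at a random eligible codon."""
    idxs = list(rng.permutation(len(seq) // 3))
    for codon_idx in idxs:
        start = 3 * codon_idx
        codon = seq[start : start + 3]
        aa = translate(codon)
        sibs = [
            c for c in _BY_AA[aa] if sum(a != b for a, b in zip(c, codon)) == 1
        ]
        if sibs:
            new = sibs[rng.integers(0, len(sibs))]
            return seq[:start] + new + seq[start + 3 :]
    raise InfeasibleConfigError("no synonymous change available")


def _pcr_error(seq: str, n_subs: int, taken: set[str], rng: np.random.Generator) -> str:
    """1-2 random non-stop point changes, avoiding collisions with real classes."""
    for _ in range(200):
        s = seq
        positions = rng.choice(len(seq), size=n_subs, replace=False)
        ok = True
        for pos in sorted(int(p) for p in positions):
            codon_idx = pos // 3
            start = 3 * codon_idx
            old = s[start : start + 3]
            nts = [n for n in "ACGT" if n != s[pos]]
            nt = nts[rng.integers(0, 3)]
            cand = s[:pos] + nt + s[pos + 1 :]
            if translate(cand[start : start + 3]) == "*":
                ok = False
                break
            s = cand
        if ok and s not in taken and s != seq:
            return s
    raise InfeasibleConfigError("could not place PCR-error substitutions")


def _pb_aa(locus: str, seq: str, cfg: SynthConfig) -> str:
    if locus.startswith("BF"):
        return translate(seq)  # whole region is alpha1+alpha2
    return translate(seq[: cfg.blb_exon2_nt])  # beta1 only


@dataclass
class _PlantedClass:
    class_id: str
    locus: str
    group: int
    variant: int
    syn: int
    seq: str


def _plant_locus(
    locus: str, cfg: SynthConfig, rng: np.random.Generator, class_pool: dict[str, list[str]]
) -> list[_PlantedClass]:
    lc = "BF" if locus.startswith("BF") else "BLB"
    n_codons = (
        (cfg.bf_exon2_nt + cfg.bf_exon3_nt) // 3 if lc == "BF" else (cfg.blb_exon2_nt // 3)
    )
    floor = cfg.bf_between_min if lc == "BF" else cfg.blb_between_min
    pb_len = n_codons if lc == "BF" else cfg.blb_exon2_nt // 3
    if floor > pb_len:
        raise InfeasibleConfigError(
            f"between-group floor {floor} exceeds region length {pb_len} aa"
        )
    blb_extra = 0 if lc == "BF" else 240  # BLB records also carry an exon 3 (non-PB)

    classes: list[_PlantedClass] = []
    pool = class_pool.setdefault(lc, [])  # pb aa strings of all bases in this gene family
    for g in range(cfg.groups_per_locus):
        base = None
        for _ in range(cfg.max_attempts):
            cand = _random_cds(rng, n_codons + blb_extra // 3)
            cand_pb = _pb_aa(locus, cand, cfg)
            if all(count_diffs(cand_pb, other, "aa")[0] >= floor for other in pool):
                base = cand
                break
        if base is None:
            raise InfeasibleConfigError(
                f"could not place {cfg.groups_per_locus} groups at floor {floor} aa ({locus})"
            )
        pool.append(_pb_aa(locus, base, cfg))

        nv = int(rng.integers(cfg.variants_per_group[0], cfg.variants_per_group[1] + 1))
        # disjoint substitution positions keep within-group pairs under the cutoff
        e2_codons = cfg.bf_exon2_nt // 3 if lc == "BF" else cfg.blb_exon2_nt // 3
        e2_pool = list(rng.permutation(e2_codons))
        e3_pool = (
            list(rng.permutation(np.arange(e2_codons, n_codons))) if lc == "BF" else []
        )
        variants = [base]
        for _v in range(1, nv):
            seq = variants[0]
            if lc == "BLB":
                n_subs = int(rng.integers(1, 3))  # 1-2 aa, pairwise <= 4
                for _ in range(n_subs):
                    seq = _nonsyn_point(seq, int(e2_pool.pop()), rng)
            else:
                d1 = int(rng.integers(0, 3))
                d2 = int(rng.integers(0 if d1 else 1, 3))
                for _ in range(d1):
                    seq = _nonsyn_point(seq, int(e2_pool.pop()), rng)
                for _ in range(d2):
                    seq = _nonsyn_point(seq, int(e3_pool.pop()), rng)
            variants.append(seq)
        for v, seq in enumerate(variants):
            classes.append(_PlantedClass(f"{locus}-G{g}-V{v}-S0", locus, g, v, 0, seq))
            if rng.random() < cfg.syn_variant_prob:
                classes.append(
                    _PlantedClass(
                        f"{locus}-G{g}-V{v}-S1", locus, g, v, 1, _syn_point(seq, rng)
                    )
                )
    return classes


def generate(config: SynthConfig = SynthConfig()) -> SynthResult:
    """Emit records + evidence + truth table realising the planted structure.

    Deterministic for a fixed seed (byte-identical files via
    ``SynthResult.write``). Raises InfeasibleConfigError before emission when
    the requested structure cannot be realised.
    """
    rng = np.random.default_rng(config.seed)
    class_pool: dict[str, list[str]] = {}
    planted: dict[str, list[_PlantedClass]] = {}
    for locus in LOCI:
        planted[locus] = _plant_locus(locus, config, rng, class_pool)

    # verify the planted geometry before emission
    for locus, classes in planted.items():
        lc = "BF" if locus.startswith("BF") else "BLB"
        floor = config.bf_between_min if lc == "BF" else config.blb_between_min
        for i, a in enumerate(classes):
            for b in classes[i + 1 :]:
                d, _ = count_diffs(
                    _pb_aa(locus, a.seq, config), _pb_aa(locus, b.seq, config), "aa"
                )
                if a.group != b.group and d < floor:
                    raise InfeasibleConfigError(
                        f"planted groups too close: {a.class_id} vs {b.class_id} = {d}"
                    )
                if a.group == b.group and d > 4 * (2 if lc == "BF" else 1):
                    raise InfeasibleConfigError(
                        f"planted variants too far: {a.class_id} vs {b.class_id} = {d}"
                    )

    # haplotype composition
    hap_ids = [f"H{i + 1:02d}" for i in range(config.n_haplotypes)]
    choices: dict[str, dict[str, _PlantedClass]] = {}
    for h in hap_ids:
        choices[h] = {
            locus: planted[locus][int(rng.integers(0, len(planted[locus])))] for locus in LOCI
        }
    for rec_spec in config.recombinants:
        if rec_spec.donor_a not in choices or rec_spec.donor_b not in choices:
            raise InfeasibleConfigError(f"recombinant donors {rec_spec} not among haplotypes")
        combo = dict(choices[rec_spec.donor_a])
        combo[rec_spec.slot] = choices[rec_spec.donor_b][rec_spec.slot]
        choices[rec_spec.name] = combo
        hap_ids.append(rec_spec.name)

    shared_ids: set[str] = set()
    for _ in range(config.cross_locus_shares):
        donor_hap = hap_ids[int(rng.integers(0, config.n_haplotypes))]
        target_hap = hap_ids[int(rng.integers(0, config.n_haplotypes))]
        shared = choices[donor_hap]["BLB1"]
        choices[target_hap]["BLB2"] = shared
        shared_ids.add(shared.class_id)

    donors = {r.name: f"{r.donor_a}+{r.donor_b}" for r in config.recombinants}

    records: list[SequenceRecord] = []
    evidence: list[EvidenceRecord] = []
    truth_rows: list[dict] = []

    def exon_map(locus: str, seq: str) -> tuple[Exon, ...]:
        if locus.startswith("BF"):
            return (
                Exon("exon2", 1, config.bf_exon2_nt),
                Exon("exon3", config.bf_exon2_nt + 1, config.bf_exon2_nt + config.bf_exon3_nt),
            )
        return (
            Exon("exon2", 1, config.blb_exon2_nt),
            Exon("exon3", config.blb_exon2_nt + 1, len(seq)),
        )

    def emit(hap: str, locus: str, cls: _PlantedClass, err_seq: str | None = None) -> None:
        is_err = err_seq is not None
        seq = err_seq if is_err else cls.seq
        seq_id = f"{hap}_{locus}" + ("_e" if is_err else "")
        claim = (
            f"{'BF' if locus.startswith('BF') else 'BLB'}_unassigned" if is_err else locus
        )
        records.append(
            SequenceRecord(
                seq_id=seq_id,
                locus_claim=claim,
                haplotype=hap,
                line=f"line-{hap}",
                study_id="synthetic-typing",
                nt_seq=seq,
                exons=exon_map(locus, seq),
            )
        )
        if is_err:
            evidence.append(EvidenceRecord(seq_id, "pcr_replicate", f"{seq_id}-pcr1"))
        else:
            evidence.append(EvidenceRecord(seq_id, "study", f"study-{hap}"))
            evidence.append(EvidenceRecord(seq_id, "bird", f"{hap}-bird1"))
        true_locus = AMBIGUOUS_BLB if cls.class_id in shared_ids else locus
        truth_rows.append(
            {
                "seq_id": seq_id,
                "haplotype": hap,
                "locus": true_locus,
                "class_id": cls.class_id,
                "group": f"{cls.locus}-G{cls.group}",
                "variant": f"{cls.locus}-G{cls.group}-V{cls.variant}",
                "is_pcr_error": is_err,
                "donors": donors.get(hap, ""),
            }
        )

    for hap in hap_ids:
        for locus in LOCI:
            emit(hap, locus, choices[hap][locus])

    taken_seqs = {c.seq for classes in planted.values() for c in classes}
    emitted = {
        (hap, locus): choices[hap][locus] for hap in hap_ids for locus in LOCI
    }
    for (hap, locus), cls in sorted(emitted.items()):
        if rng.random() < config.pcr_error_rate:
            n_subs = int(rng.integers(1, 3))
            err = _pcr_error(cls.seq, n_subs, taken_seqs, rng)
            taken_seqs.add(err)
            emit(hap, locus, cls, err_seq=err)

    truth = pd.DataFrame(truth_rows)
    return SynthResult(records, evidence, truth, config)


# --------------------------------------------------------------------------
# recovery scoring against the truth table


def score_recovery(result, truth: pd.DataFrame) -> dict[str, float]:
    """Compare a CurationResult against a generator truth table.

    All scores are percentages over valid (non-error) identity classes:
    locus recovery (assigned locus equals the true one, with cross-locus
    shares expected at the ambiguous pseudo-locus), group recovery (the
    recovered allele group contains exactly the classes of the planted
    group) and variant recovery (same, at protein-variant level). PCR-error
    metrics report how many planted singletons were flagged and whether any
    was named.
    """
    seq_to_class = {}
    for cls in result.classes.values():
        for sid in cls.member_ids:
            seq_to_class[sid] = cls

    real = truth[~truth.is_pcr_error]
    errors = truth[truth.is_pcr_error]

    # digest-level truth
    digest_truth: dict[str, dict] = {}
    for row in real.itertuples():
        cls = seq_to_class[row.seq_id]
        digest_truth.setdefault(
            cls.digest, {"locus": row.locus, "group": row.group, "variant": row.variant}
        )

    n = len(digest_truth)
    locus_ok = sum(
        1
        for d, t in digest_truth.items()
        if result.classes[d].locus == t["locus"]
    )

    def partition_ok(key: str, recovered: Mapping[str, frozenset]) -> int:
        true_sets: dict[str, set[str]] = {}
        for d, t in digest_truth.items():
            true_sets.setdefault(t[key], set()).add(d)
        ok = 0
        for d, t in digest_truth.items():
            rec = recovered.get(d)
            if rec is not None and rec == frozenset(true_sets[t[key]]):
                ok += 1
        return ok

    recovered_groups: dict[str, frozenset] = {}
    for locus, groups in result.groups.items():
        for g in groups:
            for d in g.members:
                recovered_groups[d] = frozenset(g.members)

    recovered_variants: dict[str, frozenset] = {}
    by_variant: dict[tuple, set[str]] = {}
    for d in digest_truth:
        entry = result.registry.lookup(d)
        if entry is not None:
            by_variant.setdefault((entry.name.locus, entry.name.f1, entry.name.f2), set()).add(d)
    for key, members in by_variant.items():
        for d in members:
            recovered_variants[d] = frozenset(members)

    err_digests = {seq_to_class[r.seq_id].digest for r in errors.itertuples()}
    flagged = sum(1 for d in err_digests if d in result.suspect_flags)
    named_errors = sum(1 for d in err_digests if result.registry.lookup(d) is not None)

    def pct(k: int, total: int) -> float:
        return 100.0 * k / total if total else 100.0

    return {
        "n_classes": float(n),
        "locus_recovery_pct": pct(locus_ok, n),
        "group_recovery_pct": pct(partition_ok("group", recovered_groups), n),
        "variant_recovery_pct": pct(partition_ok("variant", recovered_variants), n),
        "n_pcr_errors": float(len(err_digests)),
        "pcr_errors_flagged_pct": pct(flagged, len(err_digests)),
        "pcr_errors_named": float(named_errors),
    }


# --------------------------------------------------------------------------
# the standard-haplotype fixture


@dataclass
class StandardFixture:
    records: list[SequenceRecord]
    evidence: list[EvidenceRecord]
    null_slots: dict[str, tuple[str, ...]]
    expected_names: dict[str, dict[str, str]]  # hap -> locus -> canonical name or 'null'
    expected_strings: dict[str, str]  # hap -> shorthand haplotype string
    expected_bfbl: dict[str, str]  # hap -> Bfbl name

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_records(self.records, directory / "standard.fasta", directory / "standard.tsv")
        write_evidence(self.evidence, directory / "evidence.tsv")


def standard_fixture() -> StandardFixture:
    """Deterministic sequences realising the standard-haplotype relations."""
    rng = np.random.default_rng(20191118)
    cfg = SynthConfig()  # region lengths only
    blb_codons = cfg.blb_exon2_nt // 3 + 80  # beta1 + an 80-codon exon 3
    bf_codons = (cfg.bf_exon2_nt + cfg.bf_exon3_nt) // 3
    bf_e2_codons = cfg.bf_exon2_nt // 3

    def make_bases(locus: str, founders: Sequence[str], n_codons: int, floor: int, pb_codons: int):
        bases: dict[str, str] = {}
        pool: list[str] = []
        for hap in founders:
            for _ in range(cfg.max_attempts):
                cand = _random_cds(rng, n_codons)
                pb = translate(cand[: 3 * pb_codons])
                if all(count_diffs(pb, p, "aa")[0] >= floor for p in pool):
                    bases[hap] = cand
                    pool.append(pb)
                    break
            else:  # pragma: no cover - astronomically unlikely at these lengths
                raise InfeasibleConfigError(f"could not seed bases for {locus}")
        return bases

    def nonsyn_at(seq: str, codon_idxs: Sequence[int]) -> str:
        for idx in codon_idxs:
            seq = _nonsyn_point(seq, idx, rng)
        return seq

    # BLB1: B6 and B8 identical to B2; B13 identical to B4; B19 identical to B12
    blb1 = make_bases("BLB1", ["B2", "B4", "B5", "B12", "B14", "B15"], blb_codons, 12, 90)
    blb1_seqs = dict(blb1)
    blb1_seqs.update({"B6": blb1["B2"], "B8": blb1["B2"], "B13": blb1["B4"], "B19": blb1["B12"]})

    # BLB2: B6 identical to B5; B13 = B4 + one aa in exon 3; B19 = B12 + two aa in exon 2
    blb2 = make_bases("BLB2", ["B2", "B4", "B5", "B8", "B12", "B14", "B15"], blb_codons, 12, 90)
    blb2_seqs = dict(blb2)
    blb2_seqs["B6"] = blb2["B5"]
    blb2_seqs["B13"] = nonsyn_at(blb2["B4"], [97])  # exon 3 codon: PB-identical variant
    blb2_seqs["B19"] = nonsyn_at(blb2["B12"], [11, 47])

    # BF1: B13 identical to B4; B15 = B4 variant; B8 = B5 variant; B19 = B12 variant;
    # B14 has a null BF1 (no sequence)
    bf1 = make_bases("BF1", ["B2", "B4", "B5", "B6", "B12"], bf_codons, 20, bf_codons)
    bf1_seqs = dict(bf1)
    bf1_seqs["B13"] = bf1["B4"]
    bf1_seqs["B15"] = nonsyn_at(bf1["B4"], [23])
    bf1_seqs["B8"] = nonsyn_at(bf1["B5"], [10, 40, bf_e2_codons + 30])
    bf1_seqs["B19"] = nonsyn_at(bf1["B12"], [61])

    # BF2: B13 identical to B4; B8 = B5 variant; B19 = B15 + 7 aa (4 alpha1, 3 alpha2)
    bf2 = make_bases("BF2", ["B2", "B4", "B5", "B6", "B12", "B14", "B15"], bf_codons, 20, bf_codons)
    bf2_seqs = dict(bf2)
    bf2_seqs["B13"] = bf2["B4"]
    bf2_seqs["B8"] = nonsyn_at(bf2["B5"], [5, 33, bf_e2_codons + 12])
    bf2_seqs["B19"] = nonsyn_at(
        bf2["B15"], [8, 22, 51, 77, bf_e2_codons + 9, bf_e2_codons + 44, bf_e2_codons + 70]
    )

    haps = ["B2", "B4", "B5", "B6", "B8", "B12", "B13", "B14", "B15", "B19"]
    seqs = {"BLB1": blb1_seqs, "BLB2": blb2_seqs, "BF1": bf1_seqs, "BF2": bf2_seqs}
    null_slots = {"B14": ("BF1",)}

    records: list[SequenceRecord] = []
    evidence: list[EvidenceRecord] = []
    for hap in haps:
        for locus in LOCI:
            if locus in null_slots.get(hap, ()):
                continue
            seq = seqs[locus][hap]
            seq_id = f"{hap}_{locus}"
            if locus.startswith("BF"):
                exons = (
                    Exon("exon2", 1, cfg.bf_exon2_nt),
                    Exon("exon3", cfg.bf_exon2_nt + 1, cfg.bf_exon2_nt + cfg.bf_exon3_nt),
                )
            else:
                exons = (
                    Exon("exon2", 1, cfg.blb_exon2_nt),
                    Exon("exon3", cfg.blb_exon2_nt + 1, len(seq)),
                )
            records.append(
                SequenceRecord(
                    seq_id=seq_id,
                    locus_claim=locus,
                    haplotype=hap,
                    line=f"line-{hap}",
                    study_id="standard-haplotype-survey",
                    nt_seq=seq,
                    exons=exons,
                )
            )
            evidence.append(EvidenceRecord(seq_id, "study", "genomic-survey"))
            evidence.append(EvidenceRecord(seq_id, "bird", f"{hap}-bird1"))

    expected_names = {
        "B2": dict(BLB1="BLB1*002:01:01", BLB2="BLB2*002:01:01", BF1="BF1*002:01:01", BF2="BF2*002:01:01"),
        "B4": dict(BLB1="BLB1*004:01:01", BLB2="BLB2*004:01:01", BF1="BF1*004:01:01", BF2="BF2*004:01:01"),
        "B5": dict(BLB1="BLB1*005:01:01", BLB2="BLB2*005:01:01", BF1="BF1*005:01:01", BF2="BF2*005:01:01"),
        "B6": dict(BLB1="BLB1*002:01:01", BLB2="BLB2*005:01:01", BF1="BF1*006:01:01", BF2="BF2*006:01:01"),
        "B8": dict(BLB1="BLB1*002:01:01", BLB2="BLB2*008:01:01", BF1="BF1*005:02:01", BF2="BF2*005:02:01"),
        "B12": dict(BLB1="BLB1*012:01:01", BLB2="BLB2*012:01:01", BF1="BF1*012:01:01", BF2="BF2*012:01:01"),
        "B13": dict(BLB1="BLB1*004:01:01", BLB2="BLB2*004:02:01", BF1="BF1*004:01:01", BF2="BF2*004:01:01"),
        "B14": dict(BLB1="BLB1*014:01:01", BLB2="BLB2*014:01:01", BF1="null", BF2="BF2*014:01:01"),
        "B15": dict(BLB1="BLB1*015:01:01", BLB2="BLB2*015:01:01", BF1="BF1*004:02:01", BF2="BF2*015:01:01"),
        "B19": dict(BLB1="BLB1*012:01:01", BLB2="BLB2*012:02:01", BF1="BF1*012:02:01", BF2="BF2*015:02:01"),
    }
    expected_strings = {
        "B2": "2-2-2-2",
        "B4": "4-4-4-4",
        "B5": "5-5-5-5",
        "B6": "2-5-6-6",
        "B8": "2-8-5:02-5:02",
        "B12": "12-12-12-12",
        "B13": "4-4:02-4-4",
        "B14": "14-14-null-14",
        "B15": "15-15-4:02-15",
        "B19": "12-12:02-12:02-15:02",
    }
    expected_bfbl = {
        "B2": "2",
        "B4": "4",
        "B5": "5",
        "B6": "6",
        "B8": "5:02",
        "B12": "12",
        "B13": "4b",  # shares BF2*004 with the lower-numbered B4 on a distinct background
        "B14": "14",
        "B15": "15",
        "B19": "15:02",
    }
    return StandardFixture(records, evidence, null_slots, expected_names, expected_strings, expected_bfbl)
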