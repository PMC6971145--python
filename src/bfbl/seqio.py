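"""Sequence and metadata I/O for chicken MHC curation.

Observed sequences arrive as FASTA plus a tab-separated metadata sidecar
carrying the locus claim, haplotype label, provenance keys and an exon map.
Exon coordinates are 1-based inclusive on the provided nucleotide sequence,
matching the GenBank feature convention. Each exon may carry a frame offset
(default 0) because partial exon-2 amplicons in the literature can start
mid-codon.

Peptide-binding regions are extracted per locus class: the beta-1 domain
(exon 2) for class II B (BLB) genes, and the alpha-1 + alpha-2 domains
(exons 2 and 3, intron removed) for class I (BF) genes. Tree-mode trimming
removes the primer-affected termini: seven residues from each end of the BF
region and two residues from the start of the BLB region.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger("bfbl")

LOCUS_CLAIMS = frozenset(
    {"BLB1", "BLB2", "BF1", "BF2", "BLB_unassigned", "BF_unassigned", "unknown"}
)
BF_LOCI = ("BF1", "BF2")
BLB_LOCI = ("BLB1", "BLB2")
LOCI = BLB_LOCI + BF_LOCI

SIDECAR_COLUMNS = (
    "seq_id",
    "locus_claim",
    "haplotype",
    "line",
    "study_id",
    "pcr_id",
    "bird_id",
    "exon_map",
)

# residues removed in tree mode: (from start, from end), in amino acids
TREE_TRIM = {"BF": (7, 7), "BLB": (2, 0)}

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"
_NT = frozenset("ACGT")


class CurationError(Exception):
    """Base class for hard errors raised by the curation engine."""


class SidecarError(CurationError):
    """Metadata sidecar missing, malformed, or inconsistent with the FASTA."""


class RegionError(CurationError):
    """A requested region cannot be extracted from a record."""


class IncompleteBFError(RegionError):
    """BF record lacking one of exon 2 / exon 3 when both are required."""


@dataclass(frozen=True)
class Exon:
    """One exon segment: 1-based inclusive coordinates plus a frame offset."""

    name: str
    start: int
    end: int
    frame: int = 0

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise SidecarError(f"malformed coordinates for {self.name}: {self.start}-{self.end}")
        if self.frame not in (0, 1, 2):
            raise SidecarError(f"frame offset must be 0, 1 or 2 (exon {self.name})")


@dataclass
class SequenceRecord:
    """One observed sequence with its locus claim, haplotype label and provenance keys."""

    seq_id: str
    locus_claim: str = "unknown"
    haplotype: str | None = None
    line: str | None = None
    study_id: str | None = None
    pcr_id: str | None = None
    bird_id: str | None = None
    nt_seq: str = ""
    exons: tuple[Exon, ...] = ()
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.locus_claim not in LOCUS_CLAIMS:
            raise SidecarError(f"{self.seq_id}: unknown locus claim {self.locus_claim!r}")
        self.nt_seq = self.nt_seq.upper()
        n = len(self.nt_seq)
        seen: list[Exon] = []
        for ex in sorted(self.exons, key=lambda e: e.start):
            if ex.end > n:
                raise SidecarError(
                    f"{self.seq_id}: exon {ex.name} [{ex.start}-{ex.end}] exceeds sequence length {n}"
                )
            if seen and ex.start <= seen[-1].end:
                raise SidecarError(f"{self.seq_id}: exon {ex.name} overlaps {seen[-1].name}")
            seen.append(ex)
        self.exons = tuple(seen)

    @property
    def locus_class(self) -> str | None:
        """'BF', 'BLB', or None when the claim is 'unknown'."""
        if self.locus_claim.startswith("BF"):
            return "BF"
        if self.locus_claim.startswith("BLB"):
            return "BLB"
        return None

    def exon(self, name: str) -> Exon | None:
        for ex in self.exons:
            if ex.name == name:
                return ex
        return None

    def exon_nt(self, name: str) -> str:
        ex = self.exon(name)
        if ex is None:
            raise RegionError(f"{self.seq_id}: exon {name} not in exon map")
        return self.nt_seq[ex.start - 1 + ex.frame : ex.end]


@dataclass(frozen=True)
class RegionSpec:
    """Which region to extract, at which level, with which trimming preset."""

    locus_class: str  # BF | BLB
    region: str  # beta1 | alpha1 | alpha2 | alpha1_2 | CDS
    trim_policy: str = "none"  # none | tree_trim
    level: str = "aa"  # aa | nt

    def __post_init__(self) -> None:
        if self.locus_class not in ("BF", "BLB"):
            raise ValueError(f"locus_class must be BF or BLB, got {self.locus_class!r}")
        if self.region not in ("beta1", "alpha1", "alpha2", "alpha1_2", "CDS"):
            raise ValueError(f"unknown region {self.region!r}")
        if self.region == "beta1" and self.locus_class != "BLB":
            raise ValueError("beta1 is only valid for BLB")
        if self.region.startswith("alpha") and self.locus_class != "BF":
            raise ValueError(f"{self.region} is only valid for BF")
        if self.trim_policy not in ("none", "tree_trim"):
            raise ValueError(f"unknown trim policy {self.trim_policy!r}")
        if self.level not in ("aa", "nt"):
            raise ValueError(f"level must be aa or nt, got {self.level!r}")


_REGION_EXONS = {
    "beta1": ("exon2",),
    "alpha1": ("exon2",),
    "alpha2": ("exon3",),
    "alpha1_2": ("exon2", "exon3"),
}


def translate(nt: str, frame: int = 0, record: SequenceRecord | None = None) -> str:
    """Standard-code translation of ``nt`` from ``frame``.

    Codons containing any IUPAC ambiguity character translate to X; when a
    record is supplied it is flagged 'ambiguous-translation'. An internal stop
    codon flags the record 'putative-null-or-artefact' (the sequence is kept,
    not dropped: replication evidence, not translation, decides validity).
    """
    nt = nt.upper()
    if (len(nt) - frame) % 3 != 0:
        raise RegionError(f"length {len(nt)} minus frame {frame} is not a multiple of 3")
    out: list[str] = []
    for i in range(frame, len(nt), 3):
        codon = nt[i : i + 3]
        if set(codon) <= _NT:
            out.append(_CODON_TABLE[codon])
        else:
            out.append("X")
            if record is not None:
                record.flags.add("ambiguous-translation")
    aa = "".join(out)
    if "*" in aa[:-1] and record is not None:
        record.flags.add("putative-null-or-artefact")
    return aa


def extract_region(rec: SequenceRecord, spec: RegionSpec) -> str:
    """Extract the region defined by ``spec`` from ``rec``.

    For ``alpha1_2`` the exon 2 and exon 3 segments are concatenated with the
    intron removed. Tree trimming is applied after translation at aa level
    (and in codon units at nt level).
    """
    if rec.locus_class is not None and rec.locus_class != spec.locus_class:
        raise RegionError(
            f"{rec.seq_id}: record claims {rec.locus_claim}, spec is for {spec.locus_class}"
        )
    if spec.region == "CDS":
        if not rec.exons:
            raise RegionError(f"{rec.seq_id}: no exons in exon map")
        nt = "".join(rec.exon_nt(ex.name) for ex in rec.exons)
    else:
        wanted = _REGION_EXONS[spec.region]
        missing = [name for name in wanted if rec.exon(name) is None]
        if missing:
            if spec.region == "alpha1_2" and len(missing) == 1:
                rec.flags.add("incomplete-BF")
                raise IncompleteBFError(
                    f"incomplete-BF: {rec.seq_id} lacks {missing[0]} "
                    "(BF analyses require both exon 2 and exon 3)"
                )
            raise RegionError(f"{rec.seq_id}: exon(s) {', '.join(missing)} not in exon map")
        nt = "".join(rec.exon_nt(name) for name in wanted)

    lo, hi = TREE_TRIM[spec.locus_class] if spec.trim_policy == "tree_trim" else (0, 0)
    if spec.level == "nt":
        return nt[3 * lo : len(nt) - 3 * hi] if (lo or hi) else nt
    aa = translate(nt, 0, record=rec)
    return aa[lo : len(aa) - hi] if (lo or hi) else aa


def _parse_exon_map(text: str) -> tuple[Exon, ...]:
    """Parse 'exon2:1-270;exon3:271-546' (optional ':frame' third field)."""
    exons: list[Exon] = []
    if not text.strip():
        return ()
    for part in text.strip().split(";"):
        m = re.fullmatch(r"([\w.-]+):(\d+)-(\d+)(?::([012]))?", part.strip())
        if m is None:
            raise SidecarError(f"malformed exon map entry {part!r}")
        exons.append(Exon(m.group(1), int(m.group(2)), int(m.group(3)), int(m.group(4) or 0)))
    return tuple(exons)


def _format_exon_map(exons: Sequence[Exon]) -> str:
    parts = []
    for ex in exons:
        s = f"{ex.name}:{ex.start}-{ex.end}"
        if ex.frame:
            s += f":{ex.frame}"
        parts.append(s)
    return ";".join(parts)


def read_records(fasta_path: str | Path, sidecar_path: str | Path) -> list[SequenceRecord]:
    """Read FASTA + sidecar TSV into SequenceRecords.

    Every FASTA identifier must have a sidecar row; a missing row is a hard
    error naming the identifier. Sidecar rows without a FASTA sequence are
    reported to the log (not an error: curators often stage metadata first).
    """
    rows: dict[str, dict[str, str]] = {}
    with open(sidecar_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != SIDECAR_COLUMNS:
            raise SidecarError(
                f"sidecar header must be {list(SIDECAR_COLUMNS)}, got {reader.fieldnames}"
            )
        for row in reader:
            rows[row["seq_id"]] = row

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(fasta_path), "fasta"):
        row = rows.get(bio.id)
        if row is None:
            raise SidecarError(f"FASTA identifier {bio.id!r} has no sidecar row")
        seen.add(bio.id)
        records.append(
            SequenceRecord(
                seq_id=bio.id,
                locus_claim=row["locus_claim"] or "unknown",
                haplotype=row["haplotype"] or None,
                line=row["line"] or None,
                study_id=row["study_id"] or None,
                pcr_id=row["pcr_id"] or None,
                bird_id=row["bird_id"] or None,
                nt_seq=str(bio.seq),
                exons=_parse_exon_map(row["exon_map"]),
            )
        )
    unmatched = sorted(set(rows) - seen)
    if unmatched:
        logger.warning("sidecar rows without FASTA sequence: %s", ", ".join(unmatched))
    return records


def write_records(
    records: Iterable[SequenceRecord], fasta_path: str | Path, sidecar_path: str | Path
) -> None:
    """Write records back to FASTA + sidecar TSV (deterministic byte output)."""
    records = list(records)
    bio = [_BioRecord(Seq(r.nt_seq), id=r.seq_id, description="") for r in records]
    with open(fasta_path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")
    with open(sidecar_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SIDECAR_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.seq_id,
                    r.locus_claim,
                    r.haplotype or "",
                    r.line or "",
                    r.study_id or "",
                    r.pcr_id or "",
                    r.bird_id or "",
                    _format_exon_map(r.exons),
                ]
            )
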