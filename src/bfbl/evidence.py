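"""Replication evidence and validation of sequence identity classes.

A sequence is considered valid only when it has been seen in at least two
independent amplifications: independent PCRs from the same bird, different
birds or lines, or different studies/laboratories. Independence is judged by
distinct (source_kind, source_key) pairs, so two birds within one study count
as independent sources. A once-observed sequence within one or two
nucleotides of a validated one is flagged as a likely PCR
mis-incorporation; the flag is advisory and never renames anything.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .seqio import CurationError

SOURCE_KINDS = frozenset({"pcr_replicate", "bird", "line", "study"})

EVIDENCE_COLUMNS = ("seq_id", "source_kind", "source_key", "citation")

#: nucleotide window within which a singleton is presumed a PCR error
PCR_ERROR_MAX_NT = 2


@dataclass(frozen=True)
class EvidenceRecord:
    """One independent-isolation claim attached to an observed sequence."""

    seq_id: str
    source_kind: str
    source_key: str
    citation: str | None = None

    def __post_init__(self) -> None:
        if self.source_kind not in SOURCE_KINDS:
            raise CurationError(f"unknown evidence source kind {self.source_kind!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source_kind, self.source_key)


@dataclass(frozen=True)
class ValidationStatus:
    status: str  # valid | provisional | rejected
    reason: str = ""

    @property
    def is_valid(self) -> bool:
        return self.status == "valid"


def validate(
    identity_class: Iterable[str], evidence: Iterable[EvidenceRecord]
) -> ValidationStatus:
    """Decide valid/provisional for one identity class from its evidence.

    Valid requires at least two distinct (source_kind, source_key) pairs over
    the class members; duplicates of the same amplification do not count.
    Adding evidence can only promote, never demote (monotone).
    """
    members = set(identity_class)
    pairs = {e.pair for e in evidence if e.seq_id in members}
    if not pairs:
        return ValidationStatus("provisional", "no-evidence")
    if len(pairs) >= 2:
        return ValidationStatus("valid", f"replicated({len(pairs)} independent sources)")
    return ValidationStatus("provisional", "singleton")


def flag_suspect_singletons(
    statuses: Mapping[str, ValidationStatus],
    nt_distances: Mapping[tuple[str, str], int] | "object",
) -> dict[str, str]:
    """Flag provisional classes within 1-2 nt of a valid class.

    ``nt_distances`` is either a DistanceMatrix (nt level, labelled by class
    ids) or a mapping of unordered id pairs to nucleotide difference counts.
    Returns {class_id: flag}; flags are advisory and never alter the registry.
    """

    def dist(a: str, b: str) -> int | None:
        if hasattr(nt_distances, "get_pair"):
            try:
                return int(nt_distances.get_pair(a, b))  # type: ignore[union-attr]
            except KeyError:
                return None
        d = nt_distances.get((a, b))  # type: ignore[union-attr]
        if d is None:
            d = nt_distances.get((b, a))  # type: ignore[union-attr]
        return None if d is None else int(d)

    valid_ids = sorted(k for k, s in statuses.items() if s.is_valid)
    flags: dict[str, str] = {}
    for cid in sorted(statuses):
        if statuses[cid].is_valid:
            continue
        best: tuple[int, str] | None = None
        for vid in valid_ids:
            d = dist(cid, vid)
            if d is not None and (best is None or d < best[0]):
                best = (d, vid)
        if best is not None and best[0] <= PCR_ERROR_MAX_NT:
            flags[cid] = f"likely-PCR-error(nearest={best[1]})"
    return flags


def read_evidence(path: str | Path) -> list[EvidenceRecord]:
    out: list[EvidenceRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != EVIDENCE_COLUMNS:
            raise CurationError(
                f"evidence header must be {list(EVIDENCE_COLUMNS)}, got {reader.fieldnames}"
            )
        for row in reader:
            out.append(
                EvidenceRecord(
                    row["seq_id"], row["source_kind"], row["source_key"], row["citation"] or None
                )
            )
    return out


def write_evidence(records: Sequence[EvidenceRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(EVIDENCE_COLUMNS)
        for e in records:
            writer.writerow([e.seq_id, e.source_kind, e.source_key, e.citation or ""])


def write_flags(flags: Mapping[str, str], path: str | Path) -> None:
    """Emit the advisory flag report as TSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(("class_id", "flag"))
        for cid in sorted(flags):
            writer.writerow((cid, flags[cid]))
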