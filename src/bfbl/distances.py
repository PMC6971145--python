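"""Pairwise difference counting over peptide-binding regions.

Distances here are raw Hamming counts (no evolutionary-model correction),
at amino-acid or nucleotide level, because the grouping decisions rest on
counted differences. Positions where either sequence is masked (X at aa
level, any non-ACGT symbol at nt level) are excluded from the count and the
number of masked positions is reported alongside, so sequencing ambiguity
never inflates a difference count.

BF (class I) matrices additionally carry per-domain splits (alpha1 from
exon 2, alpha2 from exon 3) because the variant cutoff is applied per domain
as well as in total. Difference counts are binned for display the way the
curation matrices colour them: for BF, 0 (green), 1-4 (blue), 5-8 (yellow),
>8 (beyond); for BLB, 0, 1-2, 3-4, >4.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqio import CurationError, RegionSpec, SequenceRecord, extract_region

_AA_MASK = frozenset("X")
_NT_OK = frozenset("ACGT")


class IndelError(CurationError):
    """Region strings of unequal length (indel or truncation)."""


@dataclass(frozen=True)
class AlignedBlock:
    """Equal-length region strings for a set of sequences.

    ``domain_boundary`` is the index (in the block's coordinate system) where
    alpha2 starts, present only for BF alpha1_2 blocks.
    """

    region: RegionSpec
    labels: tuple[str, ...]
    strings: tuple[str, ...]
    domain_boundary: int | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.strings):
            raise ValueError("labels and strings must have equal length")
        lengths = {len(s) for s in self.strings}
        if len(lengths) > 1:
            raise IndelError(f"unequal string lengths {sorted(lengths)}")

    @property
    def ncols(self) -> int:
        return len(self.strings[0]) if self.strings else 0


def build_block(records: Sequence[SequenceRecord], spec: RegionSpec) -> AlignedBlock:
    """Extract ``spec`` from every record and assemble an aligned block.

    The peptide-binding exons carry no indels between classical alleles, so
    any length mismatch signals an indel or truncation: the offenders
    (sequences differing from the majority length) are named in a hard error
    and must be excluded pending curator review.
    """
    labels = []
    strings = []
    for rec in records:
        labels.append(rec.seq_id)
        strings.append(extract_region(rec, spec))
    lengths = [len(s) for s in strings]
    if len(set(lengths)) > 1:
        majority = max(set(lengths), key=lengths.count)
        offenders = sorted(l for l, n in zip(labels, lengths) if n != majority)
        raise IndelError("indel-or-truncation(" + ",".join(offenders) + ")")

    boundary = None
    if spec.locus_class == "BF" and spec.region == "alpha1_2" and records:
        ex2 = records[0].exon("exon2")
        if ex2 is not None:
            n2 = ex2.end - ex2.start + 1 - ex2.frame
            boundary = n2 if spec.level == "nt" else n2 // 3
            if spec.trim_policy == "tree_trim":
                boundary -= 7 if spec.level == "aa" else 21
    return AlignedBlock(spec, tuple(labels), tuple(strings), boundary)


def _masked(ch: str, level: str) -> bool:
    return ch in _AA_MASK if level == "aa" else ch not in _NT_OK


def count_diffs(a: str, b: str, level: str = "aa") -> tuple[int, int]:
    """Hamming count between two equal-length strings.

    Returns (differences, masked_positions); masked positions are skipped.
    """
    if len(a) != len(b):
        raise IndelError(f"unequal lengths {len(a)} vs {len(b)}")
    diff = 0
    masked = 0
    for x, y in zip(a, b):
        if _masked(x, level) or _masked(y, level):
            masked += 1
        elif x != y:
            diff += 1
    return diff, masked


@dataclass
class DistanceMatrix:
    """Symmetric pairwise difference counts over one region."""

    labels: tuple[str, ...]
    counts: np.ndarray  # (n, n) int
    level: str  # aa | nt
    ncols: int = 0
    masked: np.ndarray | None = None
    domains: dict[str, np.ndarray] | None = None  # alpha1 / alpha2 for BF

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts shape does not match labels")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if np.any(np.diag(self.counts) != 0):
            raise ValueError("diagonal must be zero")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(label) from None

    def get_pair(self, a: str, b: str) -> int:
        return int(self.counts[self.index(a), self.index(b)])

    def domain_pair(self, a: str, b: str) -> tuple[int, ...] | None:
        if not self.domains:
            return None
        i, j = self.index(a), self.index(b)
        return tuple(int(self.domains[k][i, j]) for k in sorted(self.domains))

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in labels]
        return DistanceMatrix(
            tuple(labels),
            self.counts[np.ix_(idx, idx)],
            self.level,
            self.ncols,
            None if self.masked is None else self.masked[np.ix_(idx, idx)],
            None
            if self.domains is None
            else {k: v[np.ix_(idx, idx)] for k, v in self.domains.items()},
        )


def _pair_counts(arr: np.ndarray, maskable: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = arr.shape[0]
    counts = np.zeros((n, n), dtype=int)
    masked = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            m = maskable[i] | maskable[j]
            d = int(np.sum((arr[i] != arr[j]) & ~m))
            counts[i, j] = counts[j, i] = d
            masked[i, j] = masked[j, i] = int(m.sum())
    return counts, masked


def matrix(block: AlignedBlock) -> DistanceMatrix:
    """All pairwise counts for a block; BF blocks carry per-domain splits."""
    arr = np.array([list(s) for s in block.strings], dtype="U1")
    if block.region.level == "aa":
        maskable = arr == "X"
    else:
        maskable = ~np.isin(arr, list(_NT_OK))
    counts, masked = _pair_counts(arr, maskable)
    domains = None
    b = block.domain_boundary
    if b is not None:
        c1, _ = _pair_counts(arr[:, :b], maskable[:, :b])
        c2, _ = _pair_counts(arr[:, b:], maskable[:, b:])
        domains = {"alpha1": c1, "alpha2": c2}
    return DistanceMatrix(block.labels, counts, block.region.level, block.ncols, masked, domains)


#: difference bins as used on the curation matrices
_BF_BINS = ((0, 0, "green"), (1, 4, "blue"), (5, 8, "yellow"))
_BLB_BINS = ((0, 0, "green"), (1, 2, "blue"), (3, 4, "yellow"))


def bin_count(count: int, locus_class: str) -> str:
    """Classify a difference count: green / blue / yellow / beyond."""
    if count < 0:
        raise ValueError("count must be non-negative")
    table = _BF_BINS if locus_class == "BF" else _BLB_BINS
    for lo, hi, name in table:
        if lo <= count <= hi:
            return name
    return "beyond"


def to_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(("",) + dm.labels)
        for label, row in zip(dm.labels, dm.counts):
            writer.writerow((label,) + tuple(int(x) for x in row))


def to_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """PHYLIP square distance matrix (relaxed label width)."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for label, row in zip(dm.labels, dm.counts):
            fh.write(label + "  " + "  ".join(str(int(x)) for x in row) + "\n")


def from_phylip(path: str | Path, level: str = "aa") -> DistanceMatrix:
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        labels = []
        rows = []
        for _ in range(n):
            parts = fh.readline().split()
            labels.append(parts[0])
            rows.append([int(float(x)) for x in parts[1:]])
    return DistanceMatrix(tuple(labels), np.array(rows, dtype=int), level)
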