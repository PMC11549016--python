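"""Sequence records, FASTA/TSV I/O, redundancy filtering and dataset partitioning.

The unit of data throughout the package is :class:`RnaRecord`: an identified
RNA sequence over ``{A, C, G, U}`` with an optional binary label (1 = the
central cytidine carries an N4-acetyl mark, 0 = it does not).  Site-prediction
windows are odd-length sequences with the candidate cytidine at the center;
:func:`validate_window` enforces that convention for whole datasets.

DNA-alphabet input is accepted everywhere: ``T`` is silently mapped to ``U``
on read, since public ac4C datasets are frequently distributed as DNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

RNA_ALPHABET = "ACGU"
_ALPHABET_SET = frozenset(RNA_ALPHABET)


class SequenceValidationError(ValueError):
    """A record violates the alphabet or window-geometry invariants."""


@dataclass(frozen=True)
class RnaRecord:
    """An identified RNA sequence with an optional binary ac4C label."""

    id: str
    seq: str
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - _ALPHABET_SET
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: residues outside {{A,C,G,U}}: {sorted(bad)}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise SequenceValidationError(
                f"record {self.id!r}: label must be 0 or 1, got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def normalize_sequence(raw: str, *, record_id: str = "?") -> str:
    """Uppercase and map ``T`` to ``U``; reject residues outside the alphabet."""
    seq = raw.upper().replace("T", "U")
    bad = set(seq) - _ALPHABET_SET
    if bad:
        raise SequenceValidationError(
            f"record {record_id!r}: residues outside {{A,C,G,U,T}}: {sorted(bad)}"
        )
    return seq


def validate_window(records: Sequence[RnaRecord], length: int | None = None) -> int:
    """Check the site-window invariant: equal odd length, central ``C``.

    Returns the common window length.
    """
    if not records:
        raise SequenceValidationError("empty dataset")
    if length is None:
        length = len(records[0])
    if length % 2 == 0:
        raise SequenceValidationError(f"window length must be odd, got {length}")
    center = (length - 1) // 2
    for r in records:
        if len(r) != length:
            raise SequenceValidationError(
                f"record {r.id!r}: length {len(r)} != declared window {length}"
            )
        if r.seq[center] != "C":
            raise SequenceValidationError(
                f"record {r.id!r}: central residue {r.seq[center]!r} is not C"
            )
    return length


# ---------------------------------------------------------------------------
# FASTA / TSV I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, label: int | None = None) -> list[RnaRecord]:
    """Read a FASTA file into records, normalizing case and mapping T->U.

    Entry ids are preserved verbatim; ``label``, if given, is attached to
    every record.
    """
    path = Path(path)
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(entry.seq), record_id=entry.id)
        records.append(RnaRecord(id=entry.id, seq=seq, label=label))
    if not records:
        raise SequenceValidationError(f"{path}: no FASTA entries found")
    return records


def write_fasta(records: Iterable[RnaRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.seq}\n")


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a ``id<TAB>label`` table (header required) into a dict."""
    labels: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.rstrip("\n").split("\t")[:2] == ["id", "label"]:
            raise ValueError(f"{path}: expected header 'id\\tlabel'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                rid, lab = line.split("\t")
                labels[rid] = int(lab)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed label line") from exc
    return labels


def write_labels(records: Iterable[RnaRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for r in records:
            fh.write(f"{r.id}\t{r.label}\n")


def attach_labels(records: Sequence[RnaRecord], labels: dict[str, int]) -> list[RnaRecord]:
    out = []
    for r in records:
        if r.id not in labels:
            raise KeyError(f"record {r.id!r} has no label in the table")
        out.append(RnaRecord(id=r.id, seq=r.seq, label=labels[r.id]))
    return out


# ---------------------------------------------------------------------------
# Synthetic benchmark generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic ac4C-window benchmark.

    The generator emulates the structure of curated ac4C datasets: fixed
    odd-length windows centred on a cytidine in *both* classes (the centre
    carries no class information, exactly as in peak-derived data), with
    positives enriched for C-initiated trinucleotides ("CXX" motifs) at rate
    ``motif_rate`` per eligible position.  ``motif_rate=0`` yields a
    label-free null dataset.
    """

    n_pos: int
    n_neg: int
    length: int = 201
    motif_rate: float = 0.1
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if self.length % 2 == 0:
            raise ValueError(f"window length must be odd, got {self.length}")
        if not 0.0 <= self.motif_rate <= 1.0:
            raise ValueError("motif_rate must be in [0, 1]")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")


def generate_synthetic(spec: SyntheticSpec) -> list[RnaRecord]:
    """Generate ``n_pos`` positive and ``n_neg`` negative labelled windows.

    All windows have C at the centre.  In positives, each position outside
    the centre (with room for a full trinucleotide that does not overlap the
    centre) independently seeds a C-starting trinucleotide with probability
    ``motif_rate``; the two trailing bases are drawn from the background, so
    the planted signal is purely the excess of C-initiated 3-mers.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list(RNA_ALPHABET))
    center = (spec.length - 1) // 2
    records: list[RnaRecord] = []

    def draw(label: int, index: int) -> RnaRecord:
        codes = rng.choice(4, size=spec.length, p=spec.background)
        if label == 1 and spec.motif_rate > 0:
            for pos in range(spec.length - 2):
                if pos <= center <= pos + 2:
                    continue
                if rng.random() < spec.motif_rate:
                    codes[pos] = 1  # C
        codes[center] = 1
        seq = "".join(bases[codes])
        return RnaRecord(id=f"{'pos' if label else 'neg'}_{index}", seq=seq, label=label)

    for i in range(spec.n_pos):
        records.append(draw(1, i))
    for i in range(spec.n_neg):
        records.append(draw(0, i))
    return records


# ---------------------------------------------------------------------------
# Redundancy filter (greedy positional identity)
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Fraction of positions at which two equal-length sequences agree."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def redundancy_filter(records: Sequence[RnaRecord], threshold: float = 0.8) -> list[RnaRecord]:
    """Greedy removal of near-duplicate sequences.

    Scans records in input order and keeps a record iff its ungapped
    positional identity to every already-kept record is strictly below
    ``threshold``.  This emulates the redundancy-removal step applied to
    curated ac4C datasets (identity cutoff 0.8) without clustering
    machinery; it is idempotent.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if records:
        L = len(records[0])
        for r in records:
            if len(r) != L:
                raise ValueError("redundancy_filter requires equal-length records")
    kept: list[RnaRecord] = []
    kept_arr: list[np.ndarray] = []
    limit = threshold * (len(records[0]) if records else 1)
    for r in records:
        arr = np.frombuffer(r.seq.encode(), dtype=np.uint8)
        if all((arr == k).sum() < limit for k in kept_arr):
            kept.append(r)
            kept_arr.append(arr)
    return kept


# ---------------------------------------------------------------------------
# Splitting and folding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetSplit:
    train: list[RnaRecord]
    test: list[RnaRecord]
    ratio: tuple[int, int]
    seed: int

    def __post_init__(self) -> None:
        overlap = {r.id for r in self.train} & {r.id for r in self.test}
        if overlap:
            raise ValueError(f"train/test overlap on ids: {sorted(overlap)[:5]}")


def _by_class(records: Sequence[RnaRecord]) -> dict[int, list[RnaRecord]]:
    groups: dict[int, list[RnaRecord]] = {}
    for r in records:
        if r.label is None:
            raise ValueError(f"record {r.id!r} is unlabelled")
        groups.setdefault(r.label, []).append(r)
    return groups


def split_dataset(
    records: Sequence[RnaRecord],
    ratio: tuple[int, int] = (4, 1),
    balanced: bool = True,
    seed: int = 0,
) -> DatasetSplit:
    """Random class-stratified train/test partition at ``ratio``.

    With the conventional 4:1 ratio on a balanced 2758+2758 dataset this
    yields 2206/552 records per class, the benchmark arrangement for
    ac4C-site training and independent testing.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    groups = _by_class(records)
    if balanced and len(groups) < 2:
        raise ValueError("balanced split requires both classes present")
    rng = np.random.default_rng(seed)
    frac_train = ratio[0] / (ratio[0] + ratio[1])
    train: list[RnaRecord] = []
    test: list[RnaRecord] = []
    for label in sorted(groups):
        members = groups[label]
        order = rng.permutation(len(members))
        n_train = round(frac_train * len(members))
        idx_train = set(order[:n_train].tolist())
        for i, r in enumerate(members):
            (train if i in idx_train else test).append(r)
    return DatasetSplit(train=train, test=test, ratio=tuple(ratio), seed=seed)


def make_folds(records: Sequence[RnaRecord], k: int = 10, seed: int = 0) -> list[set[str]]:
    """Label-stratified k-fold partition of record ids.

    Folds are pairwise disjoint, exhaustive, and differ in size by at most
    one.  Used for cross-validation where each fold serves once as the
    validation set.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(records):
        raise ValueError(f"k={k} exceeds number of records ({len(records)})")
    rng = np.random.default_rng(seed)
    folds: list[set[str]] = [set() for _ in range(k)]
    groups = _by_class(records)
    offset = 0
    for label in sorted(groups):
        members = groups[label]
        order = rng.permutation(len(members))
        for j, idx in enumerate(order):
            folds[(offset + j) % k].add(members[idx].id)
        offset += len(members)
    return folds


def write_split_manifest(split: DatasetSplit, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsubset\n")
        for r in split.train:
            fh.write(f"{r.id}\ttrain\n")
        for r in split.test:
            fh.write(f"{r.id}\ttest\n")
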