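"""Feature encodings for RNA site windows.

Three sequence representations feed the classifier:

* **integer encoding** — the fixed base map A->0, U->1, C->2, G->3
  (the alphabet enumerated as {A, U, C, G}), consumed by an embedding table;
  the classifier is invariant to which bijection is chosen, but this one is
  pinned so encodings are stable across versions;
* **PseKNC** — pseudo k-tuple nucleotide composition: overlapping k-mer
  counts, plus per-k-mer weights, plus a two-value correlation summary
  (mean and population standard deviation of the distinct nonzero counts);
* **one-hot** — the L x 4 indicator matrix, kept for ablation comparisons.

A sinusoidal positional-encoding matrix is also provided here; it is added
to embeddings so that base order survives order-agnostic attention layers.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Literal, Sequence

import numpy as np

from .dataio import RNA_ALPHABET, RnaRecord

BASE_TO_CODE = {"A": 0, "U": 1, "C": 2, "G": 3}
CODE_TO_BASE = {v: k for k, v in BASE_TO_CODE.items()}

EnumerationMode = Literal["observed-order", "full-lexicographic"]


# ---------------------------------------------------------------------------
# Integer and one-hot encodings
# ---------------------------------------------------------------------------

def integer_encode(record: RnaRecord | str) -> np.ndarray:
    """Map a sequence elementwise through A->0, U->1, C->2, G->3."""
    seq = record.seq if isinstance(record, RnaRecord) else record
    return np.array([BASE_TO_CODE[b] for b in seq], dtype=np.int64)


def integer_decode(codes: Sequence[int]) -> str:
    return "".join(CODE_TO_BASE[int(c)] for c in codes)


def one_hot_encode(record: RnaRecord | str) -> np.ndarray:
    """L x 4 indicator matrix; row i is the unit vector of ``seq[i]``'s code."""
    codes = integer_encode(record)
    out = np.zeros((len(codes), 4))
    out[np.arange(len(codes)), codes] = 1.0
    return out


# ---------------------------------------------------------------------------
# k-mer profile and PseKNC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KmerProfile:
    k: int
    order: tuple[str, ...]
    counts: np.ndarray  # aligned with `order`

    def as_dict(self) -> dict[str, int]:
        return {m: int(c) for m, c in zip(self.order, self.counts)}


def all_kmers(k: int) -> tuple[str, ...]:
    """All 4^k k-mers in lexicographic order over A < C < G < U."""
    return tuple("".join(p) for p in product(sorted(RNA_ALPHABET), repeat=k))


def kmer_profile(
    record: RnaRecord | str, k: int, mode: EnumerationMode = "full-lexicographic"
) -> KmerProfile:
    """Count overlapping k-mers (window step 1).

    ``observed-order`` lists k-mers by first occurrence, matching the way
    small worked examples are usually tabulated; ``full-lexicographic``
    enumerates all 4^k k-mers (zeros allowed) so the feature width is fixed
    across sequences, which the downstream CNN requires.
    """
    seq = record.seq if isinstance(record, RnaRecord) else record
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    tally: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        mer = seq[i : i + k]
        tally[mer] = tally.get(mer, 0) + 1
    if mode == "observed-order":
        order = tuple(tally)
    elif mode == "full-lexicographic":
        order = all_kmers(k)
    else:
        raise ValueError(f"unknown enumeration mode {mode!r}")
    counts = np.array([tally.get(m, 0) for m in order], dtype=np.int64)
    return KmerProfile(k=k, order=order, counts=counts)


@dataclass(frozen=True)
class PseKncVector:
    """Composite PseKNC feature: body = counts + weights, then (mean, std)."""

    body: np.ndarray
    corr: tuple[float, float]
    mode: EnumerationMode

    @property
    def F(self) -> np.ndarray:
        return np.concatenate([self.body, np.array(self.corr)])


def pseknc(
    record: RnaRecord | str,
    k: int = 2,
    weights: np.ndarray | float = 1.0,
    mode: EnumerationMode = "full-lexicographic",
) -> PseKncVector:
    """Pseudo k-tuple nucleotide composition of one sequence.

    The body adds a weight to each k-mer count elementwise; the appended
    correlation pair is the mean and *population* standard deviation of the
    set of distinct nonzero count values.  For ``AGCUUAG`` at k=2 with unit
    weights in observed order the result is ``[3,2,2,2,2, 1.5, 0.5]``.
    """
    profile = kmer_profile(record, k, mode)
    counts = profile.counts.astype(float)
    w = np.asarray(weights, dtype=float)
    if w.ndim == 0:
        w = np.full_like(counts, float(w))
    elif w.shape != counts.shape:
        raise ValueError(
            f"weights length {w.shape[0]} != number of k-mers {counts.shape[0]}"
        )
    distinct = np.unique(counts[counts > 0])
    if distinct.size == 0:
        corr = (0.0, 0.0)
    else:
        corr = (float(distinct.mean()), float(distinct.std()))  # population std
    return PseKncVector(body=counts + w, corr=corr, mode=mode)


def pseknc_matrix(records: Sequence[RnaRecord], k: int = 2) -> np.ndarray:
    """Stack fixed-width (4^k + 2) PseKNC vectors for a batch of records."""
    return np.stack([pseknc(r, k=k, mode="full-lexicographic").F for r in records])


# ---------------------------------------------------------------------------
# Sinusoidal positional encoding
# ---------------------------------------------------------------------------

def positional_encoding(L: int, d: int, a: float = 10000.0) -> np.ndarray:
    """Standard sinusoidal positional-encoding matrix (L x d).

    ``PE[pos, 2x] = sin(pos * a^(-2x/d))`` and ``PE[pos, 2x+1]`` is the
    matching cosine; row 0 is therefore ``(0, 1, 0, 1, ...)``.  The base
    ``a`` sets the geometric range of wavelengths.
    """
    if d % 2 != 0:
        raise ValueError(f"embedding width d must be even, got {d}")
    if L < 1:
        raise ValueError("L must be >= 1")
    if a < 2:
        raise ValueError("base a must be >= 2")
    pos = np.arange(L)[:, None]
    x = np.arange(d // 2)[None, :]
    angles = pos * np.power(float(a), -2.0 * x / d)
    pe = np.empty((L, d))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe
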