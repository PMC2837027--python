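"""Doublet/triplet motif classes under rotational identity.

A stack of ``k`` adjacent Watson-Crick base pairs read 5'->3' on one strand
is indistinguishable from the same stack read on the complementary strand,
i.e. the k-mer ``w`` and ``revcomp(w)`` denote the same physical motif.
Partitioning all 4**k k-mers by this equivalence yields 10 classes for
doublets (k=2) and 32 for triplets (k=3): the parameters of the
nearest-neighbour models.

A class is labelled ``TOP/BOTTOM`` where TOP is the lexicographically
smallest member and BOTTOM its base-wise complement, so ``GAC/CTG`` denotes
5'-GAC-3' paired with 3'-CTG-5'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "revcomp",
    "complement",
    "MotifClass",
    "canonical_class",
    "enumerate_classes",
    "class_labels",
    "count_motifs",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = "ACGT"


def _validate_seq(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(_BASES)
    if bad:
        raise ValueError(f"non-ACGT character(s) {sorted(bad)!r} in sequence {seq!r}")


def complement(seq: str) -> str:
    """Base-wise Watson-Crick complement (no reversal)."""
    _validate_seq(seq)
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string. Involutive: revcomp(revcomp(s)) == s."""
    _validate_seq(seq)
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifClass:
    """One rotational-identity equivalence class of k-mers (k = 2 or 3).

    ``members`` holds {w, revcomp(w)}: two k-mers, or one when w is its own
    reverse complement (possible only for even k, e.g. AT, GC).
    """

    label: str
    order: int
    members: frozenset[str] = field(compare=False)

    @property
    def top(self) -> str:
        return self.label.split("/")[0]


@lru_cache(maxsize=None)
def canonical_class(word: str) -> MotifClass:
    """Map a 2- or 3-mer to its rotational-identity class."""
    if len(word) not in (2, 3):
        raise ValueError(f"motif must have length 2 or 3, got {word!r}")
    _validate_seq(word)
    rc = revcomp(word)
    top = min(word, rc)
    return MotifClass(
        label=f"{top}/{complement(top)}",
        order=len(word),
        members=frozenset((word, rc)),
    )


@lru_cache(maxsize=None)
def enumerate_classes(order: int) -> tuple[MotifClass, ...]:
    """All motif classes of the given order, sorted by TOP member.

    Returns 10 classes for order 2 and 32 for order 3.
    """
    if order not in (2, 3):
        raise ValueError(f"order must be 2 or 3, got {order}")
    words = [""]
    for _ in range(order):
        words = [w + b for w in words for b in _BASES]
    classes = {canonical_class(w) for w in words}
    return tuple(sorted(classes, key=lambda c: c.top))


def class_labels(order: int) -> list[str]:
    """Canonical labels in enumeration order."""
    return [c.label for c in enumerate_classes(order)]


@lru_cache(maxsize=None)
def _class_index(order: int) -> dict[str, int]:
    # every k-mer -> column index of its class
    idx = {}
    for j, cls in enumerate(enumerate_classes(order)):
        for w in cls.members:
            idx[w] = j
    return idx


def count_motifs(seq: str, order: int) -> np.ndarray:
    """Count overlapping windows of ``seq`` per motif class.

    The sequence is scanned 5'->3' with a step-1 window of size ``order``;
    the complementary strand is implied by the class algebra and not scanned.
    The returned integer vector is in ``enumerate_classes(order)`` order and
    sums to ``len(seq) - order + 1``.
    """
    if order not in (2, 3):
        raise ValueError(f"order must be 2 or 3, got {order}")
    _validate_seq(seq)
    if len(seq) < order:
        raise ValueError(f"sequence {seq!r} shorter than motif order {order}")
    idx = _class_index(order)
    counts = np.zeros(len(enumerate_classes(order)), dtype=np.int64)
    for i in range(len(seq) - order + 1):
        counts[idx[seq[i : i + order]]] += 1
    return counts
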