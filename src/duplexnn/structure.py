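"""Secondary-structure comparison for DNA duplexes.

Structures are dot-parenthesis strings, one per strand, matched across the
concatenation struct1 + struct2 (nested matching; pseudoknots rejected).
Two families of measures:

* SSSI — the percentage of structure-string positions at which the
  experimental and computed annotations carry the same character,
  normalised by the summed sequence lengths. Because a base pair occupies
  two string positions, a prediction that gets only one end of a pair right
  still earns partial credit at that position.
* base-pair confusion — exact (i, j) pairs compared as sets, yielding
  sensitivity TP/(TP+FN), positive predictive value TP/(TP+FP) and their
  harmonic mean F.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datasets import gc_content

__all__ = [
    "DuplexStructure",
    "ConfusionCounts",
    "parse_duplex_structure",
    "sssi",
    "confusion",
    "sens_ppv_f",
    "stratified_metrics",
]


@dataclass(frozen=True)
class DuplexStructure:
    """A duplex structure and its base pairs.

    ``pairs`` are 0-based (i, j) positions, i < j, over the concatenation
    struct1 + struct2 (seq2 positions offset by len(struct1)).
    """

    struct1: str
    struct2: str
    pairs: frozenset[tuple[int, int]]

    @property
    def total_length(self) -> int:
        return len(self.struct1) + len(self.struct2)


def parse_duplex_structure(struct1: str, struct2: str) -> DuplexStructure:
    """Extract base pairs by nested parenthesis matching over both strands."""
    combined = struct1 + struct2
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(combined):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unmatched ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r} at position {pos}")
    if stack:
        raise ValueError(f"unmatched '(' at position {stack[-1]}")
    return DuplexStructure(struct1, struct2, frozenset(pairs))


def _require_same_lengths(exp: DuplexStructure, calc: DuplexStructure) -> None:
    if len(exp.struct1) != len(calc.struct1) or len(exp.struct2) != len(calc.struct2):
        raise ValueError(
            "experimental and calculated structures must have matching strand lengths"
        )


def sssi(exp: DuplexStructure, calc: DuplexStructure) -> float:
    """Secondary-structure similarity index, in percent.

    100 * (matching positions in strand 1 + matching positions in strand 2)
    / (len(strand 1) + len(strand 2)).
    """
    _require_same_lengths(exp, calc)
    same = sum(a == b for a, b in zip(exp.struct1, calc.struct1))
    same += sum(a == b for a, b in zip(exp.struct2, calc.struct2))
    return 100.0 * same / exp.total_length


@dataclass(frozen=True)
class ConfusionCounts:
    """Base-pair true positives, false positives and false negatives."""

    tp: int
    fp: int
    fn: int


def confusion(exp: DuplexStructure, calc: DuplexStructure) -> ConfusionCounts:
    """Set comparison of exact (i, j) base pairs."""
    _require_same_lengths(exp, calc)
    return ConfusionCounts(
        tp=len(exp.pairs & calc.pairs),
        fp=len(calc.pairs - exp.pairs),
        fn=len(exp.pairs - calc.pairs),
    )


def sens_ppv_f(c: ConfusionCounts) -> tuple[float, float, float]:
    """Sensitivity, positive predictive value and F-measure.

    Degenerate cases: with no experimental and no predicted pairs all three
    are 1 (vacuously perfect); a prediction with no pairs against a
    non-empty truth scores 0 on all three.
    """
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        return 1.0, 1.0, 1.0
    sens = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    ppv = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    f = 2 * sens * ppv / (sens + ppv) if sens + ppv else 0.0
    return sens, ppv, f


def stratified_metrics(records) -> pd.DataFrame:
    """Mean SENS/PPV/F per sequence-length bin and per 10-point GC bin.

    ``records``: iterable of (seq, exp_structure, calc_structure) triples,
    structures as :class:`DuplexStructure`. Returns a tidy table with
    columns (stratum, bin, n, sens, ppv, f) where stratum is "length" or
    "gc".
    """
    rows = []
    for seq, exp, calc in records:
        s, p, f = sens_ppv_f(confusion(exp, calc))
        gc = gc_content(seq)
        rows.append(
            {
                "length": len(seq),
                "gc_bin": f"{int(min(gc, 99.999) // 10) * 10}-{int(min(gc, 99.999) // 10) * 10 + 10}",
                "sens": s,
                "ppv": p,
                "f": f,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["stratum", "bin", "n", "sens", "ppv", "f"])
    df = pd.DataFrame(rows)
    out = []
    for stratum, key in (("length", "length"), ("gc", "gc_bin")):
        g = df.groupby(key, sort=True)[["sens", "ppv", "f"]].mean()
        g["n"] = df.groupby(key, sort=True).size()
        g = g.reset_index().rename(columns={key: "bin"})
        g.insert(0, "stratum", stratum)
        out.append(g[["stratum", "bin", "n", "sens", "ppv", "f"]])
    return pd.concat(out, ignore_index=True)
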