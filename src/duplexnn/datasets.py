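"""Experimental duplex datasets.

The on-disk format is a 15-column comma-separated table, one hybridization
experiment per row:

    1  seq1            first strand, 5'->3', A/C/G/T
    2  seq2            second strand, 5'->3'
    3  duplex_id       free-text identifier (typically source authors + index)
    4  struct1         dot-parenthesis structure of seq1
    5  struct2         dot-parenthesis structure of seq2
    6  dg_exp          experimental free energy dG37 [kcal/mol]
    7  dg_err          measurement error of dG [kcal/mol]
    8  ds_exp          experimental entropy [cal/(mol K)]
    9  ds_err          entropy error
    10 dh_exp          experimental enthalpy [kcal/mol]
    11 dh_err          enthalpy error
    12 temperature     hybridization temperature [deg C]
    13 conc_self       strand concentration, self-complementary case [mol/L]
    14 conc_nonself    strand concentration, non-self-complementary case [mol/L]
    15 na_conc         sodium concentration [mol/L]

Missing values are written as an empty field and accepted on input as
empty, ``n.r.`` or ``NA`` (the conventions found in published compilations);
they are represented in memory as ``None``, never as zero.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .motifs import revcomp

__all__ = [
    "DuplexRecord",
    "DuplexDataset",
    "read_dataset",
    "write_dataset",
    "load_exclusion_ids",
    "is_perfect_match",
    "filter_dataset",
    "gc_content",
    "dataset_summary",
]

_MISSING_TOKENS = {"", "n.r.", "nr", "na", "n/a"}
_STRUCT_CHARS = set(".()")

COLUMNS = (
    "seq1", "seq2", "duplex_id", "struct1", "struct2",
    "dg_exp", "dg_err", "ds_exp", "ds_err", "dh_exp", "dh_err",
    "temperature", "conc_self", "conc_nonself", "na_conc",
)
_NUMERIC = COLUMNS[5:]


@dataclass(frozen=True)
class DuplexRecord:
    """One experimental duplex measurement."""

    seq1: str
    seq2: str
    duplex_id: str
    struct1: str
    struct2: str
    dg_exp: float
    dg_err: float | None = None
    ds_exp: float | None = None
    ds_err: float | None = None
    dh_exp: float | None = None
    dh_err: float | None = None
    temperature: float = 37.0
    conc_self: float | None = None
    conc_nonself: float | None = None
    na_conc: float | None = None

    def __post_init__(self) -> None:
        for seq, struct, name in (
            (self.seq1, self.struct1, "seq1/struct1"),
            (self.seq2, self.struct2, "seq2/struct2"),
        ):
            if set(seq) - set("ACGT"):
                raise ValueError(f"{self.duplex_id}: non-ACGT base in {name}")
            if len(struct) != len(seq):
                raise ValueError(
                    f"{self.duplex_id}: {name} length mismatch "
                    f"({len(struct)} structure chars vs {len(seq)} bases)"
                )
            if set(struct) - _STRUCT_CHARS:
                raise ValueError(f"{self.duplex_id}: invalid structure character in {name}")
        both = self.struct1 + self.struct2
        if both.count("(") != both.count(")"):
            raise ValueError(f"{self.duplex_id}: unbalanced parentheses across the duplex")
        if not 4 <= len(self.seq1) <= 30:
            warnings.warn(
                f"{self.duplex_id}: sequence length {len(self.seq1)} outside the usual 4-30 nt range",
                stacklevel=2,
            )

    @property
    def source(self) -> str:
        """Source label inferred from the duplex id (leading non-digit prefix)."""
        m = re.match(r"[^\d]*", self.duplex_id)
        prefix = m.group(0).rstrip("-_. ") if m else ""
        return prefix or self.duplex_id


@dataclass
class DuplexDataset:
    """Ordered collection of duplex records.

    Duplex ids need not be unique: the same duplex is often measured at
    several temperatures.
    """

    records: list[DuplexRecord]
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[DuplexRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return DuplexDataset(self.records[i], self.source_label)
        return self.records[i]

    def subset(self, indices: Sequence[int], label: str | None = None) -> "DuplexDataset":
        return DuplexDataset(
            [self.records[i] for i in indices],
            self.source_label if label is None else label,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [{c: getattr(r, c) for c in COLUMNS} for r in self.records]
        return pd.DataFrame(rows, columns=list(COLUMNS))


def _parse_number(token: str, row: int, column: str) -> float | None:
    if token.strip().lower() in _MISSING_TOKENS:
        return None
    try:
        return float(token)
    except ValueError as exc:
        raise ValueError(f"row {row}: field {column!r} is not numeric: {token!r}") from exc


def _looks_like_header(fields: list[str]) -> bool:
    # require both signals (non-sequence first field AND non-numeric dG) so a
    # malformed data row is reported as an error instead of skipped as a header
    if not set(fields[0].strip().upper()) - set("ACGT"):
        return False
    try:
        float(fields[5])
    except ValueError:
        return fields[5].strip().lower() not in _MISSING_TOKENS
    return False


def read_dataset(
    path: str | Path,
    exclusion_ids: Iterable[str] | None = None,
    source_label: str | None = None,
) -> DuplexDataset:
    """Read a 15-column duplex file.

    ``exclusion_ids``: duplex ids to drop (curation lists, e.g. records an
    external evaluation step could not process). A header row is tolerated
    and auto-detected. Malformed rows raise ``ValueError`` naming the row
    number and offending field.
    """
    path = Path(path)
    excluded = set(exclusion_ids or ())
    records: list[DuplexRecord] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n\r")
            if not line.strip():
                continue
            fields = line.split(",")
            if len(fields) != 15:
                raise ValueError(
                    f"row {lineno}: expected 15 comma-separated fields, got {len(fields)}"
                )
            if lineno == 1 and _looks_like_header(fields):
                continue
            values = dict(zip(COLUMNS, (f.strip() for f in fields)))
            if values["duplex_id"] in excluded:
                continue
            numeric = {c: _parse_number(values[c], lineno, c) for c in _NUMERIC}
            if numeric["dg_exp"] is None:
                raise ValueError(f"row {lineno}: field 'dg_exp' is required")
            if numeric["temperature"] is None:
                raise ValueError(f"row {lineno}: field 'temperature' is required")
            try:
                rec = DuplexRecord(
                    seq1=values["seq1"].upper(),
                    seq2=values["seq2"].upper(),
                    duplex_id=values["duplex_id"],
                    struct1=values["struct1"],
                    struct2=values["struct2"],
                    **numeric,
                )
            except ValueError as exc:
                raise ValueError(f"row {lineno}: {exc}") from exc
            records.append(rec)
    return DuplexDataset(records, source_label if source_label is not None else path.stem)


def _fmt(value: float | None) -> str:
    if value is None:
        return ""
    return repr(value)


def write_dataset(dataset: DuplexDataset, path: str | Path, header: bool = True) -> None:
    """Write the 15-column format; round-trips through :func:`read_dataset`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header:
            fh.write(",".join(COLUMNS) + "\n")
        for r in dataset:
            fields = [r.seq1, r.seq2, r.duplex_id, r.struct1, r.struct2]
            fields += [_fmt(getattr(r, c)) for c in _NUMERIC]
            fh.write(",".join(fields) + "\n")


def load_exclusion_ids(path: str | Path) -> list[str]:
    """One duplex id per line; '#' comments and blank lines ignored."""
    ids = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.append(line)
    return ids


def is_perfect_match(record: DuplexRecord) -> bool:
    """True iff the strands are exact reverse complements and every base is paired.

    Both the sequence relation and the structure annotation are required, so
    a malformed structure cannot silently classify a mismatched duplex as
    perfect.
    """
    return (
        record.seq2 == revcomp(record.seq1)
        and set(record.struct1) == {"("}
        and set(record.struct2) == {")"}
        and len(record.struct1) == len(record.struct2)
    )


def filter_dataset(
    dataset: DuplexDataset,
    perfect_only: bool = False,
    temperature: float | None = None,
    na_conc: float | None = None,
) -> DuplexDataset:
    """Order-preserving subset; temperature matched within +/-0.01 deg C."""
    recs = list(dataset.records)
    if perfect_only:
        recs = [r for r in recs if is_perfect_match(r)]
    if temperature is not None:
        recs = [r for r in recs if abs(r.temperature - temperature) <= 0.01]
    if na_conc is not None:
        recs = [r for r in recs if r.na_conc is not None and r.na_conc == na_conc]
    return DuplexDataset(recs, dataset.source_label)


def gc_content(seq: str) -> float:
    """GC percentage of a sequence: 100 * (#G + #C) / length."""
    if not seq:
        raise ValueError("empty sequence")
    return 100.0 * sum(seq.count(b) for b in "GC") / len(seq)


def dataset_summary(dataset: DuplexDataset) -> dict[str, pd.DataFrame]:
    """Per-source feature table plus length and GC-content histograms.

    Returns ``{"sources": ..., "length_hist": ..., "gc_hist": ...}``.
    The source table gives, per source label: record count, sequence length
    range, the set of temperatures, the set of sodium concentrations and the
    strand-concentration range; a TOTAL row closes the table.
    """
    rows = []
    by_source: dict[str, list[DuplexRecord]] = {}
    for r in dataset:
        by_source.setdefault(r.source, []).append(r)

    def _span(values: list[float]) -> str:
        if not values:
            return "n.r."
        lo, hi = min(values), max(values)
        return f"{lo:g}" if lo == hi else f"{lo:g} - {hi:g}"

    for source in sorted(by_source):
        recs = by_source[source]
        lengths = [len(r.seq1) for r in recs]
        concs = [c for r in recs for c in (r.conc_self, r.conc_nonself) if c is not None]
        rows.append(
            {
                "source": source,
                "n_duplexes": len(recs),
                "seq_len": _span(lengths),
                "temperature_C": ", ".join(f"{t:g}" for t in sorted({r.temperature for r in recs})),
                "na_M": ", ".join(
                    f"{c:g}" for c in sorted({r.na_conc for r in recs if r.na_conc is not None})
                ) or "n.r.",
                "seq_conc_M": _span(concs),
            }
        )
    sources = pd.DataFrame(
        rows, columns=["source", "n_duplexes", "seq_len", "temperature_C", "na_M", "seq_conc_M"]
    )
    if len(sources):
        total = {"source": "TOTAL", "n_duplexes": int(sources["n_duplexes"].sum())}
        sources = pd.concat([sources, pd.DataFrame([total])], ignore_index=True)

    lengths = pd.Series([len(r.seq1) for r in dataset], dtype=int, name="count")
    length_hist = lengths.value_counts().sort_index().rename_axis("length").reset_index()

    gc = pd.Series([gc_content(r.seq1) for r in dataset], name="gc")
    # decile bins, right-closed, 100% folded into the top bin
    bins = pd.cut(gc, bins=range(0, 110, 10), right=False, include_lowest=True)
    gc_hist = (
        bins.cat.rename_categories(lambda c: f"{c.left:g}-{c.right:g}")
        .value_counts()
        .sort_index()
        .rename_axis("gc_bin")
        .rename("count")
        .reset_index()
    ) if len(gc) else pd.DataFrame(columns=["gc_bin", "count"])
    if len(gc):
        # pd.cut's right-open bins drop exactly-100% sequences; fold them into the top bin
        n100 = int((gc == 100.0).sum())
        if n100:
            gc_hist.loc[gc_hist["gc_bin"] == "90-100", "count"] += n100
    return {"sources": sources, "length_hist": length_hist, "gc_hist": gc_hist}
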