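"""Data model and interval arithmetic for deletions, genes, TADs and contacts.

Coordinate convention
---------------------
Positions are stored **1-based, exactly as printed** in clinical reports and
gene tables.  The length of an interval is ``end - start`` (this reproduces
every printed deletion size, e.g. 51,244,566 - 42,740,931 = 8,503,635 bp =
8.503635 Mb).  Consequently all set operations — overlap, containment,
distance — treat intervals as half-open ``[start, end)``: two intervals that
merely touch (``a.end == b.start``) do not overlap and have distance 0.

BED input (0-based half-open) is converted on read by adding 1 to both
coordinates, which preserves length under the convention above.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "GenomicInterval",
    "Deletion",
    "GeneAnnotation",
    "TADMap",
    "RegulatoryContact",
    "IntervalError",
    "ChromosomeMismatchError",
    "ConfigError",
    "DELETED",
    "PARTIALLY_DELETED",
    "WITHIN_WINDOW",
    "DISTAL",
    "STATUSES",
    "DEFAULT_WINDOW",
    "DEFAULT_SIZE_CUTOFFS",
    "interval_length",
    "overlaps",
    "contains",
    "distance",
    "point",
    "classify_gene_vs_deletion",
    "assign_size_class",
    "read_deletions",
    "read_genes",
    "read_tads",
    "read_contacts",
    "write_deletions",
    "write_genes",
    "write_tads",
    "write_contacts",
]

#: Default flanking-window size in bp on either side of a deletion breakpoint.
DEFAULT_WINDOW = 2_000_000

#: Default (lower, upper) bp cutoffs for the Small / Mid / Large deletion size
#: classes.  The grouping is an arbitrary stratification; these defaults
#: reproduce the printed labels of the five-patient validation panel
#: (8.50, 8.43 Large; 7.44 Mid; 3.46, 0.10 Small).
DEFAULT_SIZE_CUTOFFS = (5_000_000, 8_000_000)

DELETED = "deleted"
PARTIALLY_DELETED = "partially_deleted"
WITHIN_WINDOW = "within_window"
DISTAL = "distal"
STATUSES = (DELETED, PARTIALLY_DELETED, WITHIN_WINDOW, DISTAL)

_COORD_COMMENT = (
    "# coordinates: 1-based start/end as printed; length = end - start; "
    "set operations are half-open [start, end)"
)


class IntervalError(ValueError):
    """Malformed genomic interval (end < start, or start < 1)."""


class ChromosomeMismatchError(ValueError):
    """Comparison attempted between intervals on different chromosomes."""


class ConfigError(ValueError):
    """Invalid configuration value (e.g. non-increasing size cutoffs)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based genomic interval with half-open set semantics."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise IntervalError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise IntervalError(
                f"end ({self.end}) < start ({self.start}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        """Length in bp (``end - start``)."""
        return self.end - self.start

    @property
    def length_mb(self) -> float:
        return self.length / 1e6

    def format_mb(self) -> str:
        """Render the length in Mb with six decimals, as printed in reports."""
        return f"{self.length / 1e6:.6f}"

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset)


def point(chrom: str, pos: int) -> GenomicInterval:
    """Zero-length interval at ``pos`` (useful for breakpoint distances)."""
    return GenomicInterval(chrom, pos, pos)


@dataclass(frozen=True)
class Deletion:
    """A patient's deletion; ``terminal`` means no annotated genes lie distal
    of ``interval.end`` (22q13 terminal deletions reach the chromosome end)."""

    patient_id: str
    interval: GenomicInterval
    terminal: bool = True
    size_class: Optional[str] = None


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene with coordinates, haploinsufficiency percentage and phenotype terms.

    ``hi_score`` is a DECIPHER-style %HI percentile in [0, 100]; ``None`` means
    unknown and is never imputed (missing is distinct from 0).
    """

    symbol: str
    interval: GenomicInterval
    hi_score: Optional[float] = None
    phenotype_terms: frozenset = frozenset()
    expressed_in_blood: bool = True

    def __post_init__(self) -> None:
        if self.hi_score is not None and not (0.0 <= self.hi_score <= 100.0):
            raise ValueError(
                f"hi_score for {self.symbol} must be in [0, 100], got {self.hi_score}"
            )


@dataclass(frozen=True)
class TADMap:
    """Ordered, non-overlapping topologically associating domains."""

    tads: tuple

    def __init__(self, tads: Iterable[GenomicInterval]):
        tads = tuple(tads)
        for prev, cur in zip(tads, tads[1:]):
            if cur.start < prev.start:
                raise IntervalError("TADs must be sorted by start")
            if prev.chrom == cur.chrom and cur.start < prev.end:
                raise IntervalError(
                    f"TADs overlap: [{prev.start},{prev.end}) and "
                    f"[{cur.start},{cur.end}) on {cur.chrom}"
                )
        object.__setattr__(self, "tads", tads)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.tads)

    def __len__(self) -> int:
        return len(self.tads)


@dataclass(frozen=True)
class RegulatoryContact:
    """Known or predicted regulatory contact between a gene and an element."""

    gene_symbol: str
    element: GenomicInterval


# ---------------------------------------------------------------------------
# Interval arithmetic


def _require_same_chrom(a: GenomicInterval, b: GenomicInterval) -> None:
    if a.chrom != b.chrom:
        raise ChromosomeMismatchError(
            f"cannot compare intervals on {a.chrom!r} and {b.chrom!r}"
        )


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp; equals ``end - start`` under the printed convention."""
    return iv.length


def _bounds(iv: GenomicInterval) -> tuple:
    # A zero-length interval models a single position (a breakpoint): its
    # point set is {start}, i.e. the half-open span [start, start + 1).
    return iv.start, iv.end if iv.end > iv.start else iv.start + 1


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the half-open point sets [start, end) intersect.

    Zero-length intervals are treated as single positions.
    """
    _require_same_chrom(a, b)
    a0, a1 = _bounds(a)
    b0, b1 = _bounds(b)
    return a0 < b1 and b0 < a1


def contains(outer: GenomicInterval, inner: GenomicInterval) -> bool:
    """True iff ``inner``'s point set lies fully within ``outer``'s."""
    _require_same_chrom(outer, inner)
    o0, o1 = _bounds(outer)
    i0, i1 = _bounds(inner)
    return o0 <= i0 and i1 <= o1


def distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Gap in bp between nearest ends; 0 if the intervals overlap or touch."""
    _require_same_chrom(a, b)
    if overlaps(a, b):
        return 0
    if a.end <= b.start:
        return b.start - a.end
    if b.end <= a.start:
        return a.start - b.end
    return 0  # touching via a zero-length endpoint


def classify_gene_vs_deletion(
    gene: GeneAnnotation, deletion: Deletion, window: int = DEFAULT_WINDOW
) -> str:
    """Classify a gene relative to a deletion.

    Returns one of:

    * ``deleted`` — gene interval fully inside the deletion,
    * ``partially_deleted`` — gene overlaps a breakpoint (e.g. an intragenic
      deletion removing the major part of a gene),
    * ``within_window`` — disjoint but within ``window`` bp of a breakpoint,
    * ``distal`` — farther away.
    """
    g, d = gene.interval, deletion.interval
    _require_same_chrom(g, d)
    if contains(d, g):
        return DELETED
    if overlaps(g, d):
        return PARTIALLY_DELETED
    if distance(g, d) <= window:
        return WITHIN_WINDOW
    return DISTAL


def assign_size_class(
    deletion: Deletion, cutoffs: Sequence[int] = DEFAULT_SIZE_CUTOFFS
) -> Deletion:
    """Return a copy of ``deletion`` with its Small/Mid/Large size class set.

    ``Small`` if length < ``cutoffs[0]``, ``Large`` if length >= ``cutoffs[1]``
    (inclusive upper bound), else ``Mid``.  The stratification is deliberately
    configurable: it is a rough grouping, not a biological threshold.
    """
    lower, upper = cutoffs
    if not lower < upper:
        raise ConfigError(f"size cutoffs must be strictly increasing, got {cutoffs}")
    length = deletion.interval.length
    if length < lower:
        size_class = "Small"
    elif length >= upper:
        size_class = "Large"
    else:
        size_class = "Mid"
    return dataclasses.replace(deletion, size_class=size_class)


# ---------------------------------------------------------------------------
# Readers / writers
#
# Genes and TADs: 4+-column TSV (chrom, start, end, name, ...) or BED
# (0-based half-open, converted on read).  Deletions: TSV with patient_id,
# chrom, start, end, terminal.  Contacts: TSV with gene_symbol, chrom, start,
# end.  All writers emit TSV with a commented header naming the coordinate
# convention.

_TRUE_STRINGS = {"1", "true", "yes", "y", "t"}


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in _TRUE_STRINGS


def _read_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})


def read_deletions(path: Union[str, Path]) -> list:
    """Read deletions from TSV (patient_id, chrom, start, end, terminal[, size_class])."""
    df = _read_table(path)
    out = []
    for row in df.itertuples(index=False):
        size_class = getattr(row, "size_class", None)
        if size_class is not None and pd.isna(size_class):
            size_class = None
        out.append(
            Deletion(
                patient_id=str(row.patient_id),
                interval=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                terminal=_as_bool(row.terminal),
                size_class=size_class,
            )
        )
    return out


def _convert_bed(start: int, end: int, fmt: str) -> tuple:
    if fmt == "bed":
        return start + 1, end + 1
    return start, end


def read_genes(path: Union[str, Path], fmt: str = "tsv") -> list:
    """Read gene annotations.

    TSV columns: symbol, chrom, start, end [, hi_score, expressed_in_blood,
    phenotype_terms] — phenotype terms semicolon-separated.  ``fmt="bed"``
    reads chrom, start, end, name with 0-based half-open coordinates.
    """
    if fmt == "bed":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "symbol"], dtype={"chrom": str},
        )
    else:
        df = _read_table(path)
    genes = []
    seen = set()
    for row in df.itertuples(index=False):
        symbol = str(row.symbol)
        if symbol in seen:
            raise ValueError(f"duplicate gene symbol {symbol!r} in {path}")
        seen.add(symbol)
        start, end = _convert_bed(int(row.start), int(row.end), fmt)
        hi = getattr(row, "hi_score", None)
        hi = None if hi is None or pd.isna(hi) else float(hi)
        blood = getattr(row, "expressed_in_blood", True)
        blood = True if pd.isna(blood) else _as_bool(blood)
        terms = getattr(row, "phenotype_terms", None)
        if terms is None or pd.isna(terms) or not str(terms).strip():
            term_set = frozenset()
        else:
            term_set = frozenset(t for t in str(terms).split(";") if t)
        genes.append(
            GeneAnnotation(
                symbol=symbol,
                interval=GenomicInterval(str(row.chrom), start, end),
                hi_score=hi,
                phenotype_terms=term_set,
                expressed_in_blood=blood,
            )
        )
    return genes


def read_tads(path: Union[str, Path], fmt: str = "tsv") -> TADMap:
    """Read a TAD map from TSV (chrom, start, end[, name]) or BED."""
    if fmt == "bed":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "name"], dtype={"chrom": str},
        )
    else:
        df = _read_table(path)
    tads = []
    for row in df.itertuples(index=False):
        start, end = _convert_bed(int(row.start), int(row.end), fmt)
        tads.append(GenomicInterval(str(row.chrom), start, end))
    tads.sort(key=lambda iv: (iv.chrom, iv.start))
    return TADMap(tads)


def read_contacts(path: Union[str, Path]) -> list:
    """Read regulatory contacts from TSV (gene_symbol, chrom, start, end)."""
    df = _read_table(path)
    return [
        RegulatoryContact(
            gene_symbol=str(row.gene_symbol),
            element=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
        )
        for row in df.itertuples(index=False)
    ]


def _write_tsv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT + "\n")
        df.to_csv(fh, sep="\t", index=False)


def write_deletions(deletions: Iterable[Deletion], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [
            {
                "patient_id": d.patient_id,
                "chrom": d.interval.chrom,
                "start": d.interval.start,
                "end": d.interval.end,
                "terminal": int(d.terminal),
                "size_class": d.size_class or "",
            }
            for d in deletions
        ]
    )
    _write_tsv(df, path)


def write_genes(genes: Iterable[GeneAnnotation], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [
            {
                "symbol": g.symbol,
                "chrom": g.interval.chrom,
                "start": g.interval.start,
                "end": g.interval.end,
                "hi_score": "" if g.hi_score is None else g.hi_score,
                "expressed_in_blood": int(g.expressed_in_blood),
                "phenotype_terms": ";".join(sorted(g.phenotype_terms)),
            }
            for g in genes
        ]
    )
    _write_tsv(df, path)


def write_tads(tadmap: TADMap, path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [{"chrom": t.chrom, "start": t.start, "end": t.end} for t in tadmap]
    )
    _write_tsv(df, path)


def write_contacts(contacts: Iterable[RegulatoryContact], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [
            {
                "gene_symbol": c.gene_symbol,
                "chrom": c.element.chrom,
                "start": c.element.start,
                "end": c.element.end,
            }
            for c in contacts
        ]
    )
    _write_tsv(df, path)
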