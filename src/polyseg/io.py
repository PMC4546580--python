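"""Reading, writing and scoring of marker band-pattern tables.

A marker table is a rectangular delimited-text file: first column sample
ID, header row of marker IDs, each cell a band-pattern string. Patterns
follow gel-scoring conventions for codominant markers: ``"AA"``/``"Aa"``/
``"aa"`` at two-band markers, letter-set strings like ``"abc"`` or
``"abcd"`` at multi-band markers, and the single sentinel ``"M"`` for a
failed PCR or ambiguous lane. Empty cells are read as missing.
"""

from __future__ import annotations

import csv
import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ParseError, ValidationError
from .models import allele_sort_key

logger = logging.getLogger(__name__)

MISSING = "M"

__all__ = [
    "MISSING",
    "BandPattern",
    "MarkerTable",
    "LocusCounts",
    "score_band_pattern",
    "normalize_pattern",
    "parse_marker_table",
    "write_marker_table",
    "tabulate_locus",
]


@dataclass(frozen=True)
class BandPattern:
    """The observable phenotype of one sample at one marker: a set of
    distinct band labels, or missing (``bands is None``)."""

    bands: frozenset | None

    @property
    def is_missing(self) -> bool:
        return self.bands is None

    @classmethod
    def missing(cls) -> "BandPattern":
        return cls(None)

    @classmethod
    def from_string(cls, s: str) -> "BandPattern":
        s = s.strip()
        if s == "" or s == MISSING:
            return cls.missing()
        return cls(frozenset(s))

    def to_string(self, two_band: bool = False) -> str:
        if self.bands is None:
            return MISSING
        letters = sorted(self.bands, key=allele_sort_key)
        if two_band and len(letters) == 1:
            return letters[0] * 2
        return "".join(letters)


def normalize_pattern(s: str) -> str:
    """Canonicalize a raw cell string: strip whitespace, map empty to "M",
    sort letters of multi-band patterns. Idempotent on canonical strings."""
    s = s.strip()
    if s == "" or s == MISSING:
        return MISSING
    letters = frozenset(s)
    if len(letters) == 1 and len(s) == 2:
        return s[0] * 2  # doubled homozygote code, e.g. "AA"
    return "".join(sorted(letters, key=allele_sort_key))


def score_band_pattern(
    band_sizes: Sequence[float],
    parent_reference: Mapping[float, str],
    tolerance: float = 2.0,
) -> BandPattern:
    """Score raw band sizes against a parent's reference ladder.

    Each observed size is matched to the closest reference size within
    ``tolerance`` size units. Unmatched bands, empty input, or a single
    band at a ≥3-allele marker (dosage-ambiguous) score as missing, with a
    log record. At two-allele markers a single matched band is the
    homozygote for that allele.
    """
    if not parent_reference:
        raise ValidationError("parent_reference is empty")
    labels = set()
    for size in band_sizes:
        best = min(parent_reference, key=lambda ref: abs(ref - size))
        if abs(best - size) > tolerance:
            logger.warning("band size %s matches no reference within %s; scored missing",
                           size, tolerance)
            return BandPattern.missing()
        labels.add(parent_reference[best])
    if not labels:
        return BandPattern.missing()
    if len(parent_reference) > 2 and len(labels) == 1:
        logger.warning("single band %s at a %d-allele marker is ambiguous; scored missing",
                       next(iter(labels)), len(parent_reference))
        return BandPattern.missing()
    return BandPattern(frozenset(labels))


@dataclass
class MarkerTable:
    """Samples x markers grid of canonical band-pattern strings.

    Backed by a pandas DataFrame of strings (index: sample IDs, columns:
    marker IDs). Parent rows are flagged explicitly via ``parent_ids``,
    never inferred.
    """

    data: pd.DataFrame
    parent_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample IDs: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate marker IDs: {dups}")
        missing_parents = [p for p in self.parent_ids if p not in self.data.index]
        if missing_parents:
            raise ValidationError(f"parent IDs not in table: {missing_parents}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def markers(self) -> list[str]:
        return list(self.data.columns)

    @property
    def progeny_ids(self) -> list[str]:
        parents = set(self.parent_ids)
        return [s for s in self.samples if s not in parents]

    def cell(self, sample: str, marker: str) -> str:
        return self.data.at[sample, marker]

    def column(self, marker: str) -> pd.Series:
        if marker not in self.data.columns:
            raise KeyError(f"unknown marker {marker!r}")
        return self.data[marker]

    def row_patterns(self, sample: str) -> dict[str, str]:
        return dict(self.data.loc[sample])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MarkerTable)
            and self.parent_ids == other.parent_ids
            and self.data.equals(other.data)
        )


@dataclass(frozen=True)
class LocusCounts:
    """Observed class counts at one marker, with missing tallied separately."""

    marker: str
    classes: tuple[str, ...]
    observed: tuple[int, ...]
    missing: int = 0

    def __post_init__(self):
        if len(self.classes) != len(self.observed):
            raise ValidationError("classes and observed counts differ in length")
        if len(set(self.classes)) != len(self.classes):
            raise ValidationError("duplicate class labels")
        if any(c < 0 for c in self.observed) or self.missing < 0:
            raise ValidationError("negative count")

    @property
    def n(self) -> int:
        """Number of scored (non-missing) progeny."""
        return sum(self.observed)

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.classes, self.observed))


_DIALECTS = {"tsv": "\t", "csv": ","}


def _delimiter(dialect: str) -> str:
    try:
        return _DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")


def parse_marker_table(
    path, dialect: str = "tsv", parent_ids: Iterable[str] = ()
) -> MarkerTable:
    """Parse a delimited marker table; cells are normalized pattern strings.

    Raises :class:`ParseError` with a line number for ragged rows and
    :class:`ValidationError` for duplicate sample or marker IDs.
    """
    delim = _delimiter(dialect)
    text = Path(path).read_text(encoding="utf-8")
    return _parse_text(text, delim, tuple(parent_ids))


def _parse_text(text: str, delim: str, parent_ids: tuple[str, ...]) -> MarkerTable:
    reader = csv.reader(_io.StringIO(text), delimiter=delim)
    rows = [row for row in reader]
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if not rows:
        raise ParseError("empty marker table")
    header = rows[0]
    markers = [m.strip() for m in header[1:]]
    width = len(header)
    samples, cells = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ParseError(
                f"line {lineno}: expected {width} fields, found {len(row)}"
            )
        samples.append(row[0].strip())
        cells.append([normalize_pattern(c) for c in row[1:]])
    df = pd.DataFrame(cells, index=samples, columns=markers, dtype=object)
    return MarkerTable(data=df, parent_ids=parent_ids)


def write_marker_table(table: MarkerTable, path, dialect: str = "tsv") -> None:
    delim = _delimiter(dialect)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(["sample"] + table.markers)
        for s in table.samples:
            writer.writerow([s] + [table.cell(s, m) for m in table.markers])


def tabulate_locus(
    table: MarkerTable, marker: str, class_order: Sequence[str]
) -> LocusCounts:
    """Count progeny band-pattern classes at one marker.

    Missing cells are tallied separately and never enter the class counts.
    A pattern observed but absent from ``class_order`` raises, listing the
    offending samples — classes must be declared explicitly.
    """
    col = table.column(marker)
    counts = {c: 0 for c in class_order}
    missing = 0
    offenders: dict[str, list[str]] = {}
    for sample in table.progeny_ids:
        pat = col[sample]
        if pat == MISSING:
            missing += 1
        elif pat in counts:
            counts[pat] += 1
        else:
            offenders.setdefault(pat, []).append(sample)
    if offenders:
        detail = "; ".join(f"{p!r} in {s}" for p, s in offenders.items())
        raise ValidationError(
            f"marker {marker!r}: patterns outside declared classes: {detail}"
        )
    return LocusCounts(
        marker=marker,
        classes=tuple(class_order),
        observed=tuple(counts[c] for c in class_order),
        missing=missing,
    )
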