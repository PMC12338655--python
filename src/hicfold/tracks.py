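"""Fusing 1D genomic signals, annotations and bookmarks onto the bead model.

Tracks are per-bin scalar signals (ATAC-seq, ChIP-seq, arm coding, ...)
loaded from CSV and painted onto beads by the trivial bin->bead bijection.
Annotations are named genomic intervals (GFF3 or CSV) and bookmarks are
saved selections; both resolve to half-open bead ranges so downstream
reporting is agnostic to where a selection came from.

Coordinate conventions: internal intervals are 0-based half-open base-pair
ranges; GFF3 input (1-based, closed) is converted once at ingestion.  Strand
is kept as metadata only — a folded structure has no strand.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contactmap import GenomicBinning
from .polymer import BeadChain

__all__ = [
    "Track",
    "BeadTrack",
    "Interval",
    "Annotation",
    "Bookmark",
    "load_track_csv",
    "write_track_csv",
    "map_track_to_beads",
    "load_annotation",
    "interval_to_bead_range",
    "resolve_bookmark",
]


@dataclass
class Track:
    """Per-bin scalar values; missing bins are NaN."""

    name: str
    values: np.ndarray
    units: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("track values must be one-dimensional")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class BeadTrack:
    """A track painted onto beads (bin k -> bead k)."""

    name: str
    values: np.ndarray
    missing: np.ndarray
    unmappable: np.ndarray


@dataclass(frozen=True)
class Interval:
    """0-based half-open base-pair interval with a label."""

    start: int
    end: int
    label: str
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval {self.label!r}: start must be < end")
        if self.start < 0:
            raise ValueError(f"interval {self.label!r}: negative start")


@dataclass
class Annotation:
    name: str
    intervals: list[Interval] = field(default_factory=list)
    source_format: str = "csv"  # "gff3" | "csv"

    def find(self, label: str) -> Interval | None:
        for iv in self.intervals:
            if iv.label == label:
                return iv
        return None


@dataclass
class Bookmark:
    """A saved selection: either an explicit bin range or a feature label."""

    name: str
    bins: tuple[int, int] | None = None
    feature: str | None = None

    def __post_init__(self) -> None:
        if (self.bins is None) == (self.feature is None):
            raise ValueError("bookmark needs exactly one of bins or feature")


_AGGREGATORS = {"mean": np.mean, "sum": np.sum, "max": np.max}


def load_track_csv(
    path,
    binning: GenomicBinning,
    column_kind: str = "bin",
    header: str | bool = "auto",
    agg: str = "mean",
    name: str | None = None,
    units: str = "",
) -> Track:
    """Load a two-column CSV track and align it to bins.

    ``column_kind`` selects the key column: ``"bin"`` (bin index) or ``"bp"``
    (base-pair start position, mapped by ``floor(pos / resolution)``).  Rows
    finer than a bin are aggregated (mean by default; ``sum``/``max``
    available); bins with no rows are missing (NaN).
    """
    if column_kind not in ("bin", "bp"):
        raise ValueError("column_kind must be 'bin' or 'bp'")
    if agg not in _AGGREGATORS:
        raise ValueError(f"agg must be one of {sorted(_AGGREGATORS)}")
    path = Path(path)
    per_bin: dict[int, list[float]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        rows = [(lineno, row) for lineno, row in enumerate(reader, start=1)
                if row and any(cell.strip() for cell in row)]
    if not rows:
        raise ValueError(f"{path}: empty track file")

    def is_number(cell: str) -> bool:
        try:
            float(cell)
            return True
        except ValueError:
            return False

    start_at = 0
    if header is True or (header == "auto" and not is_number(rows[0][1][0])):
        start_at = 1
    for lineno, row in rows[start_at:]:
        if len(row) < 2:
            raise ValueError(f"{path} line {lineno}: expected two columns")
        key_cell, val_cell = row[0].strip(), row[1].strip()
        if not val_cell:  # explicit missing value
            continue
        try:
            key = float(key_cell)
            value = float(val_cell)
        except ValueError as exc:
            raise ValueError(f"{path} line {lineno}: unparseable value ({exc})") from exc
        if column_kind == "bp":
            if not (0 <= key < binning.extent_bp):
                raise ValueError(f"track out of range: {path} line {lineno} at {key} bp")
            b = int(key) // binning.resolution
        else:
            b = int(key)
            if b != key or not (0 <= b < binning.n_bins):
                raise ValueError(f"track out of range: {path} line {lineno} bin {key_cell}")
        per_bin.setdefault(b, []).append(value)

    values = np.full(binning.n_bins, np.nan)
    fn = _AGGREGATORS[agg]
    for b, vals in per_bin.items():
        values[b] = fn(vals)
    return Track(name or path.stem, values, units=units, source=str(path))


def write_track_csv(track: Track, path) -> Path:
    """Export as ``bin,value`` CSV; floats via repr so reloads are bit-exact."""
    path = Path(path)
    rows = ["bin,value"]
    for b, v in enumerate(track.values):
        rows.append(f"{b}," if math.isnan(v) else f"{b},{float(v)!r}")
    path.write_text("\n".join(rows) + "\n")
    return path


def map_track_to_beads(track: Track, chain: BeadChain) -> BeadTrack:
    """Paint a track onto the chain via the bin k -> bead k bijection.

    Missing values propagate; unmappable beads keep their value but are
    flagged so reports and renderers can grey them out.
    """
    if len(track.values) != chain.n_beads:
        raise ValueError(
            f"track/structure mismatch: {len(track.values)} bins vs {chain.n_beads} beads"
        )
    return BeadTrack(
        name=track.name,
        values=track.values.copy(),
        missing=track.missing.copy(),
        unmappable=chain.unmappable.copy(),
    )


def _parse_gff3_attributes(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attrs.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def load_annotation(
    path,
    binning: GenomicBinning | None = None,
    format: str | None = None,
    name: str | None = None,
) -> Annotation:
    """Load named intervals from GFF3 (1-based closed) or CSV (0-based half-open).

    GFF3 coordinates are converted to the internal 0-based half-open
    convention at ingestion (start - 1, end unchanged).  Labels come from the
    ``Name`` (else ``ID``, else type) attribute for GFF3 or the third CSV
    column.  If a binning is given, intervals must fall inside the chromosome
    extent.
    """
    path = Path(path)
    if format is None:
        format = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "csv"
    intervals: list[Interval] = []
    if format == "gff3":
        for raw in path.read_text().splitlines():
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {raw[:60]}")
            _, _, ftype, start, end, _, strand, _, attrs = fields
            a = _parse_gff3_attributes(attrs)
            label = a.get("Name") or a.get("ID") or ftype
            intervals.append(Interval(int(start) - 1, int(end), label, strand))
    elif format == "csv":
        with path.open(newline="") as fh:
            for lineno, row in enumerate(csv.reader(fh), start=1):
                if not row or not any(c.strip() for c in row):
                    continue
                if lineno == 1:
                    try:
                        int(row[0])
                    except ValueError:
                        continue  # header
                if len(row) < 3:
                    raise ValueError(f"{path} line {lineno}: expected start,end,label")
                intervals.append(Interval(int(row[0]), int(row[1]), row[2].strip()))
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if binning is not None:
        for iv in intervals:
            if iv.end > binning.extent_bp:
                raise ValueError(
                    f"interval {iv.label!r} extends past the chromosome extent"
                )
    return Annotation(name or path.stem, intervals, format)


def interval_to_bead_range(interval: Interval, binning: GenomicBinning) -> tuple[int, int]:
    """Half-open bead range covering a base-pair interval.

    ``[floor(start / res), ceil(end / res))``; a sub-resolution interval that
    would produce an empty range warns and returns its single containing bead.
    """
    res = binning.resolution
    b0 = interval.start // res
    b1 = -(-interval.end // res)  # ceil division
    b1 = min(b1, binning.n_bins)
    b0 = min(b0, binning.n_bins - 1)
    if b1 <= b0:
        warnings.warn(f"interval below resolution: {interval.label!r}", stacklevel=2)
        return b0, b0 + 1
    return int(b0), int(b1)


def resolve_bookmark(
    bookmark: Bookmark,
    binning: GenomicBinning,
    annotations: list[Annotation] | None = None,
) -> tuple[int, int]:
    """Resolve a bookmark to a half-open bead range.

    Explicit bin ranges are validated against the binning; feature references
    are searched across the given annotations by label.
    """
    if bookmark.bins is not None:
        b0, b1 = int(bookmark.bins[0]), int(bookmark.bins[1])
        if not (0 <= b0 < b1 <= binning.n_bins):
            raise ValueError(f"bookmark {bookmark.name!r}: bin range out of bounds")
        return b0, b1
    for ann in annotations or []:
        iv = ann.find(bookmark.feature)  # type: ignore[arg-type]
        if iv is not None:
            return interval_to_bead_range(iv, binning)
    raise KeyError(f"bookmark {bookmark.name!r}: feature {bookmark.feature!r} not found")
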