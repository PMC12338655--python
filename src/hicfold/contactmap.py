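"""Loading, balancing, filtering and binarization of Hi-C contact matrices.

A Hi-C experiment yields, for one chromosome at one resolution, a symmetric
matrix of contact counts between fixed-width genomic bins.  The modelling
pipeline consumes a *binary* version of that matrix: after coverage-bias
removal (matrix balancing) and deletion of the trivial self-contact diagonal,
every cell at or above a count threshold becomes a restrainable bin pair and
everything else is discarded.  Bins whose entire row is empty (centromeres and
other unmappable sequence) carry no information and are flagged so that no
restraint ever touches them.

All coordinates are 0-based, half-open: bin ``k`` covers
``[k * resolution, (k + 1) * resolution)`` base pairs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenomicBinning",
    "RawContactMatrix",
    "BinaryContactMap",
    "load_contacts",
    "kr_balance",
    "remove_diagonal",
    "detect_unmappable",
    "binarize",
    "preprocess",
    "write_binary_map",
    "read_binary_map",
]


@dataclass(frozen=True)
class GenomicBinning:
    """Fixed-width binning of one chromosome (0-based, half-open bins)."""

    chromosome: str
    resolution: int
    n_bins: int

    def __post_init__(self) -> None:
        if self.resolution < 1:
            raise ValueError("resolution must be a positive integer")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")

    @property
    def extent_bp(self) -> int:
        return self.n_bins * self.resolution

    def bin_of(self, position_bp: int) -> int:
        """Bin index containing a base-pair position."""
        return int(position_bp) // self.resolution


@dataclass
class RawContactMatrix:
    """Symmetric non-negative contact-count matrix for one binning.

    ``normalized`` records whether the values have been through matrix
    balancing (or arrived pre-normalized).
    """

    binning: GenomicBinning
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("malformed matrix: not square")
        if v.shape[0] != self.binning.n_bins:
            raise ValueError("malformed matrix: size does not match binning")
        if not np.all(np.isfinite(v)):
            raise ValueError("invalid contact value: non-finite entry")
        if np.any(v < 0):
            raise ValueError("invalid contact value: negative entry")
        if not np.allclose(v, v.T, rtol=1e-10, atol=1e-12):
            raise ValueError("malformed matrix: not symmetric")
        self.values = v


@dataclass
class BinaryContactMap:
    """Set of restrainable bin pairs after balance / diagonal / threshold.

    ``pairs`` holds unordered index pairs as ``(i, j)`` with ``i < j``; no
    pair touches the diagonal or an unmappable bin.
    """

    binning: GenomicBinning
    pairs: set[tuple[int, int]] = field(default_factory=set)
    unmappable: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.binning.n_bins
        if self.unmappable is None:
            self.unmappable = np.zeros(n, dtype=bool)
        self.unmappable = np.asarray(self.unmappable, dtype=bool)
        if self.unmappable.shape != (n,):
            raise ValueError("unmappable flags must have one entry per bin")
        clean: set[tuple[int, int]] = set()
        for i, j in self.pairs:
            i, j = int(i), int(j)
            if i == j:
                raise ValueError("self-pair on removed diagonal")
            if i > j:
                i, j = j, i
            if j >= n or i < 0:
                raise ValueError("pair index outside binning")
            if self.unmappable[i] or self.unmappable[j]:
                raise ValueError("pair touches an unmappable bin")
            clean.add((i, j))
        self.pairs = clean

    def pair_array(self) -> np.ndarray:
        """Pairs as a sorted ``(n_pairs, 2)`` integer array."""
        if not self.pairs:
            return np.empty((0, 2), dtype=int)
        return np.array(sorted(self.pairs), dtype=int)


def _read_text(path) -> str:
    return Path(path).read_text()


def _parse_declared_chromosome(text: str) -> str | None:
    # optional "# chrom: chr22" / "# chromosome=chr22" metadata comment
    for line in text.splitlines():
        line = line.strip()
        if not line.startswith("#"):
            continue
        body = line.lstrip("#").strip()
        for key in ("chromosome", "chrom", "chr"):
            if body.lower().startswith(key):
                rest = body[len(key):].lstrip(" :=")
                if rest:
                    return rest.split()[0]
    return None


def load_contacts(
    path,
    format: str = "coo-text",
    chromosome: str = "chr",
    resolution: int = 1,
    n_bins: int | None = None,
) -> RawContactMatrix:
    """Load a per-chromosome contact matrix from a text file.

    Parameters
    ----------
    path
        Input file.  ``coo-text`` is whitespace-separated ``bin_i bin_j count``
        with ``#`` comment lines; ``dense-csv`` is an ``n x n`` matrix with no
        header.
    format
        ``"coo-text"`` or ``"dense-csv"``.
    chromosome, resolution
        Metadata for the resulting :class:`GenomicBinning`.  If the file
        declares a chromosome in a comment (``# chrom: chrX``) it must match.
    n_bins
        Matrix size; for COO input defaults to ``max index + 1``.

    Entries given only as ``(i, j)`` are mirrored to ``(j, i)``; duplicate
    symmetric records must agree.
    """
    if format not in ("coo-text", "dense-csv"):
        raise ValueError(f"unknown contact format {format!r}")
    text = _read_text(path)
    declared = _parse_declared_chromosome(text)
    if declared is not None and declared != chromosome:
        raise ValueError(
            f"chromosome not found: requested {chromosome!r}, file declares {declared!r}"
        )

    if format == "coo-text":
        rows: list[tuple[int, int, float]] = []
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"malformed matrix: line {lineno} has {len(parts)} fields")
            try:
                i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed matrix: line {lineno}: {exc}") from exc
            if c < 0 or not np.isfinite(c):
                raise ValueError(f"invalid contact value: {c} at line {lineno}")
            if i < 0 or j < 0:
                raise ValueError(f"malformed matrix: negative bin index at line {lineno}")
            rows.append((i, j, c))
        max_idx = max((max(i, j) for i, j, _ in rows), default=-1)
        n = n_bins if n_bins is not None else max_idx + 1
        if max_idx >= n:
            raise ValueError("malformed matrix: bin index exceeds declared n_bins")
        if n < 2:
            raise ValueError("malformed matrix: fewer than two bins")
        values = np.zeros((n, n), dtype=float)
        for i, j, c in rows:
            values[i, j] = c
            values[j, i] = c
        binning = GenomicBinning(chromosome, resolution, n)
        return RawContactMatrix(binning, values)

    # dense-csv
    try:
        frame = pd.read_csv(io.StringIO(text), header=None, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed matrix: {exc}") from exc
    values = frame.to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("malformed matrix: not square")
    if n_bins is not None and values.shape[0] != n_bins:
        raise ValueError("malformed matrix: size does not match declared n_bins")
    binning = GenomicBinning(chromosome, resolution, values.shape[0])
    return RawContactMatrix(binning, values)


def kr_balance(
    matrix: RawContactMatrix,
    tol: float = 1e-6,
    max_iter: int = 5000,
    target_row_sum: float | None = None,
) -> RawContactMatrix:
    """Balance a symmetric contact matrix to a common row sum.

    Finds a positive diagonal scaling ``D`` such that every non-zero row of
    ``D A D`` sums to a common constant, removing per-bin coverage bias
    (the standardization normally done with the Knight-Ruiz algorithm).  The
    implementation is symmetric alternating (Sinkhorn-style) scaling, which
    converges to the same doubly-balanced fixed point.

    All-zero rows are skipped untouched.  ``target_row_sum`` defaults to the
    mean non-zero row sum of the input, which keeps balanced entries on the
    original count scale so that downstream count thresholds stay meaningful.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    A = matrix.values
    n = A.shape[0]
    row_sums = A.sum(axis=1)
    active = row_sums > 0
    if not np.any(active):
        return replace(matrix, values=A.copy(), normalized=True)
    if target_row_sum is None:
        target_row_sum = float(row_sums[active].mean())
    if target_row_sum <= 0:
        raise ValueError("target_row_sum must be positive")

    d = np.ones(n)
    for iteration in range(1, max_iter + 1):
        s = d * (A @ d)  # row sums of D A D
        err = np.max(np.abs(s[active] - target_row_sum))
        if err <= tol:
            out = (d[:, None] * A) * d[None, :]
            return replace(matrix, values=out, normalized=True)
        d[active] /= np.sqrt(s[active] / target_row_sum)
    raise RuntimeError(
        f"matrix balancing did not converge within {max_iter} iterations (tol={tol})"
    )


def remove_diagonal(matrix: RawContactMatrix) -> RawContactMatrix:
    """Zero the self-contact diagonal; off-diagonal entries untouched."""
    values = matrix.values.copy()
    np.fill_diagonal(values, 0.0)
    return replace(matrix, values=values)


def detect_unmappable(matrix: RawContactMatrix) -> np.ndarray:
    """Flag bins with no contact signal (entire row zero) as unmappable.

    Expects the diagonal to have been removed already, so a bin whose only
    signal was its self-contact is correctly flagged.
    """
    return ~np.any(matrix.values != 0, axis=1)


def binarize(matrix: RawContactMatrix, count_threshold: float = 2.0) -> BinaryContactMap:
    """Threshold a (balanced, diagonal-free) matrix into a binary contact map.

    Pair ``(i, j)``, ``i < j``, is kept iff ``values[i, j] >= count_threshold``
    and neither bin is unmappable.  The default threshold of 2.0 is the
    conventional count cutoff for balanced Hi-C counts.
    """
    if count_threshold <= 0:
        raise ValueError("invalid threshold: must be positive")
    if np.any(np.diagonal(matrix.values) != 0):
        raise ValueError("diagonal must be removed before binarization")
    unmappable = detect_unmappable(matrix)
    iu, ju = np.nonzero(np.triu(matrix.values >= count_threshold, k=1))
    keep = ~(unmappable[iu] | unmappable[ju])
    pairs = {(int(i), int(j)) for i, j in zip(iu[keep], ju[keep])}
    return BinaryContactMap(matrix.binning, pairs, unmappable)


def preprocess(
    matrix: RawContactMatrix,
    count_threshold: float = 2.0,
    balance: bool = True,
    tol: float = 1e-6,
    max_iter: int = 5000,
) -> BinaryContactMap:
    """Full preprocessing: balance (optional) -> remove diagonal -> binarize."""
    if balance and not matrix.normalized:
        matrix = kr_balance(matrix, tol=tol, max_iter=max_iter)
    return binarize(remove_diagonal(matrix), count_threshold)


def write_binary_map(bmap: BinaryContactMap, pairs_path, unmappable_path) -> None:
    """Serialize as sorted ``i,j`` CSV plus a one-index-per-line flag list."""
    lines = ["i,j"] + [f"{i},{j}" for i, j in sorted(bmap.pairs)]
    Path(pairs_path).write_text("\n".join(lines) + "\n")
    flagged = np.nonzero(bmap.unmappable)[0]
    Path(unmappable_path).write_text("".join(f"{k}\n" for k in flagged))


def read_binary_map(pairs_path, unmappable_path, binning: GenomicBinning) -> BinaryContactMap:
    """Inverse of :func:`write_binary_map`."""
    pairs: set[tuple[int, int]] = set()
    for line in Path(pairs_path).read_text().splitlines()[1:]:
        if line.strip():
            i, j = line.split(",")
            pairs.add((int(i), int(j)))
    unmappable = np.zeros(binning.n_bins, dtype=bool)
    for line in Path(unmappable_path).read_text().splitlines():
        if line.strip():
            unmappable[int(line)] = True
    return BinaryContactMap(binning, pairs, unmappable)
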