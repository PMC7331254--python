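"""Genome coordinate grid, intervals, interval pairs, and binned tracks.

All coordinates are 0-based half-open (BED convention). A :class:`GenomeGrid`
tiles each chromosome left to right into fixed-width bins (the last bin of a
chromosome may be short); global bin ids are dense and strictly increasing in
(chromosome order, start). Every matrix and track in the package shares one
grid, so bin arithmetic lives here and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeGrid",
    "Interval",
    "IntervalPair",
    "FeatureSet",
    "Track",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_intervals",
    "write_intervals",
    "read_interval_pairs",
    "write_interval_pairs",
    "track_from_bedgraph",
    "write_bedgraph",
    "mean_signal_over",
]


class ParseError(ValueError):
    """Malformed record in a text input file (carries the line number)."""


def _fmt(x: float) -> str:
    """Full-precision float formatting so write->read round-trips bit-exactly."""
    return repr(float(x))


@dataclass(frozen=True)
class GenomeGrid:
    """Fixed-bin coordinate system over an ordered set of chromosomes.

    Parameters
    ----------
    chrom_names
        Chromosome identifiers, in the order that defines global bin ids.
    chrom_lengths
        Length in bp of each chromosome, parallel to ``chrom_names``.
    bin_size
        Bin width in bp (> 0). Bins are half-open ``[k*bin_size, (k+1)*bin_size)``,
        the final bin clipped to the chromosome end.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be > 0, got {self.bin_size}")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    # -- derived geometry ---------------------------------------------------

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def n_bins(self, chrom: str) -> int:
        return -(-self.lengths[chrom] // self.bin_size)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_names)

    def chrom_offset(self, chrom: str) -> int:
        off = 0
        for c in self.chrom_names:
            if c == chrom:
                return off
            off += self.n_bins(c)
        raise KeyError(f"chromosome {chrom!r} not in grid")

    def chrom_slice(self, chrom: str) -> slice:
        """Slice of global bin ids covering ``chrom``."""
        off = self.chrom_offset(chrom)
        return slice(off, off + self.n_bins(chrom))

    def local_bin(self, chrom: str, pos: int) -> int:
        """Bin index within ``chrom`` of base-pair position ``pos``."""
        if not 0 <= pos < self.lengths[chrom]:
            raise ValueError(f"position {pos} outside {chrom} (length {self.lengths[chrom]})")
        return pos // self.bin_size

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin id of (chrom, pos)."""
        return self.chrom_offset(chrom) + self.local_bin(chrom, pos)

    def bin_bounds(self, chrom: str, local_bin: int) -> tuple[int, int]:
        """Half-open [start, end) of a local bin; last bin clipped."""
        n = self.n_bins(chrom)
        if not 0 <= local_bin < n:
            raise ValueError(f"bin {local_bin} outside {chrom} ({n} bins)")
        start = local_bin * self.bin_size
        return start, min(start + self.bin_size, self.lengths[chrom])

    def bins_dataframe(self):
        """All bins as a (chrom, start, end) pandas DataFrame in global-id order."""
        import pandas as pd

        rows = []
        for c in self.chrom_names:
            for k in range(self.n_bins(c)):
                s, e = self.bin_bounds(c, k)
                rows.append((c, s, e))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass(frozen=True, order=True)
class Interval:
    """Genomic interval, 0-based half-open, with optional score and label."""

    chrom: str
    start: int
    end: int
    score: float | None = field(default=None, compare=False)
    label: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def padded(self, slop_bp: int) -> "Interval":
        return replace(self, start=max(0, self.start - slop_bp), end=self.end + slop_bp)


@dataclass(frozen=True)
class IntervalPair:
    """Cis pair of anchors (a loop, a promoter pair), canonically ordered.

    After construction ``anchor_a.midpoint <= anchor_b.midpoint``; trans pairs
    are rejected here, callers that tolerate them must filter beforehand.
    """

    anchor_a: Interval
    anchor_b: Interval
    strength: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.anchor_a.chrom != self.anchor_b.chrom:
            raise ValueError("trans pair: anchors on different chromosomes")
        if self.anchor_a.midpoint > self.anchor_b.midpoint:
            a, b = self.anchor_b, self.anchor_a
            object.__setattr__(self, "anchor_a", a)
            object.__setattr__(self, "anchor_b", b)

    @property
    def chrom(self) -> str:
        return self.anchor_a.chrom

    @property
    def length(self) -> int:
        """Anchor midpoint separation in bp."""
        return self.anchor_b.midpoint - self.anchor_a.midpoint


class FeatureSet:
    """Ordered collection of :class:`Interval` or :class:`IntervalPair`.

    Intervals are kept sorted by (chrom, start, end); pairs by
    (chrom, anchor_a.start, anchor_b.start). Scores/labels ride along.
    """

    def __init__(self, items: Iterable[Interval | IntervalPair] = ()):  # noqa: D401
        items = list(items)
        if items and isinstance(items[0], IntervalPair):
            items.sort(key=lambda p: (p.chrom, p.anchor_a.start, p.anchor_b.start))
        else:
            items.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
        self._items: list = items

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self) -> Iterator:
        return iter(self._items)

    def __getitem__(self, i):
        return self._items[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureSet):
            return NotImplemented
        if len(self) != len(other):
            return False
        for a, b in zip(self._items, other._items):
            if a != b:
                return False
            sa = getattr(a, "score", getattr(a, "strength", None))
            sb = getattr(b, "score", getattr(b, "strength", None))
            if (sa is None) != (sb is None) or (sa is not None and sa != sb):
                return False
        return True

    def scores(self) -> np.ndarray:
        """Scores (intervals) or strengths (pairs) as a float array, NaN if absent."""
        out = np.full(len(self._items), np.nan)
        for i, it in enumerate(self._items):
            v = getattr(it, "score", None)
            if v is None:
                v = getattr(it, "strength", None)
            if v is not None:
                out[i] = v
        return out

    def by_chrom(self, chrom: str) -> list:
        return [it for it in self._items if getattr(it, "chrom", None) == chrom]


@dataclass
class Track:
    """One real value per grid bin, with a missing-data mask.

    ``values[i]`` is meaningful only where ``mask[i]`` is True; masked bins
    hold NaN. Length always equals ``grid.total_bins``.
    """

    grid: GenomeGrid
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).copy()
        self.mask = np.asarray(self.mask, dtype=bool).copy()
        if self.values.shape != (self.grid.total_bins,) or self.mask.shape != self.values.shape:
            raise ValueError("track length must equal total bin count")
        self.values[~self.mask] = np.nan

    @classmethod
    def from_values(cls, grid: GenomeGrid, values: np.ndarray) -> "Track":
        values = np.asarray(values, dtype=float)
        return cls(grid, values, np.isfinite(values))

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[self.grid.chrom_slice(chrom)]


# -- chrom.sizes ------------------------------------------------------------


def read_chrom_sizes(path: str | Path, bin_size: int) -> GenomeGrid:
    """Build a grid from a two-column ``chrom.sizes`` TSV.

    Chromosome naming is taken verbatim; no 'chr' normalization is attempted.
    """
    names, lengths = [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected two tab-separated columns")
        try:
            n = int(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
        names.append(parts[0])
        lengths.append(n)
    return GenomeGrid(tuple(names), tuple(lengths), bin_size)


def write_chrom_sizes(grid: GenomeGrid, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, l in zip(grid.chrom_names, grid.chrom_lengths):
            fh.write(f"{c}\t{l}\n")


# -- BED / BEDPE ------------------------------------------------------------


def read_intervals(
    path: str | Path,
    grid: GenomeGrid | None = None,
    drop_unknown_chroms: bool = True,
) -> FeatureSet:
    """Read BED3/BED6/broadPeak-like intervals, sorted by (chrom, start).

    Records on chromosomes absent from ``grid`` are dropped with a logged
    warning when ``drop_unknown_chroms`` is set, otherwise they raise.
    """
    items: list[Interval] = []
    dropped = 0
    known = set(grid.chrom_names) if grid is not None else None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
        chrom = parts[0]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start >= end or start < 0:
            raise ParseError(f"{path}:{lineno}: invalid interval {start}-{end}")
        if known is not None and chrom not in known:
            if drop_unknown_chroms:
                dropped += 1
                continue
            raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        label = parts[3] if len(parts) > 3 and parts[3] != "." else None
        score = None
        if len(parts) > 4 and parts[4] != ".":
            score = float(parts[4])
        items.append(Interval(chrom, start, end, score=score, label=label))
    if dropped:
        logger.warning("%s: dropped %d record(s) on chromosomes outside the grid", path, dropped)
    return FeatureSet(items)


def write_intervals(features: FeatureSet, path: str | Path) -> None:
    """Write sorted tab-separated BED6 (name/score as '.' when absent)."""
    with open(path, "w") as fh:
        for iv in features:
            name = iv.label if iv.label is not None else "."
            score = _fmt(iv.score) if iv.score is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\n")


def read_interval_pairs(path: str | Path, grid: GenomeGrid | None = None) -> FeatureSet:
    """Read BEDPE loops; anchors canonically ordered, trans pairs excluded.

    Trans pairs are counted and dropped with a logged warning. Anchors on a
    chromosome absent from the grid raise a validation error.
    """
    pairs: list[IntervalPair] = []
    n_trans = 0
    known = set(grid.chrom_names) if grid is not None else None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 6:
            raise ParseError(f"{path}:{lineno}: BEDPE needs >= 6 columns")
        c1, s1, e1, c2, s2, e2 = parts[:6]
        try:
            a = Interval(c1, int(s1), int(e1))
            b = Interval(c2, int(s2), int(e2))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if known is not None and (a.chrom not in known or b.chrom not in known):
            raise ParseError(f"{path}:{lineno}: anchor on unknown chromosome")
        if a.chrom != b.chrom:
            n_trans += 1
            continue
        strength = None
        if len(parts) > 7 and parts[7] not in (".", ""):
            strength = float(parts[7])
        label = parts[6] if len(parts) > 6 and parts[6] != "." else None
        pairs.append(IntervalPair(a, b, strength=strength, label=label))
    if n_trans:
        logger.warning("%s: excluded %d trans pair(s)", path, n_trans)
    return FeatureSet(pairs)


def write_interval_pairs(pairs: FeatureSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            a, b = p.anchor_a, p.anchor_b
            name = p.label if p.label is not None else "."
            strength = _fmt(p.strength) if p.strength is not None else "."
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
                f"\t{name}\t{strength}\n"
            )


# -- bedGraph tracks --------------------------------------------------------


def track_from_bedgraph(path: str | Path, grid: GenomeGrid, aggregation: str = "mean") -> Track:
    """Bin a bedGraph onto the grid.

    aggregation: 'mean' (bp-weighted), 'sum', or 'max'. Records may straddle
    bin edges; uncovered bins come out masked. Records on chromosomes absent
    from the grid are skipped with a warning.
    """
    if aggregation not in ("mean", "sum", "max"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    n = grid.total_bins
    wsum = np.zeros(n)       # value * overlap-bp, for the bp-weighted mean
    cov = np.zeros(n)        # overlap-bp
    rsum = np.zeros(n)       # plain per-record sum
    vmax = np.full(n, -np.inf)
    covered = np.zeros(n, dtype=bool)
    skipped = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
        chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        if chrom not in grid.lengths:
            skipped += 1
            continue
        if start >= end:
            raise ParseError(f"{path}:{lineno}: invalid interval {start}-{end}")
        end = min(end, grid.lengths[chrom])
        off = grid.chrom_offset(chrom)
        bs = grid.bin_size
        for k in range(start // bs, (end - 1) // bs + 1):
            lo, hi = grid.bin_bounds(chrom, k)
            overlap = min(end, hi) - max(start, lo)
            if overlap <= 0:
                continue
            g = off + k
            frac = overlap / (hi - lo)  # fraction of the bin, so a record
            wsum[g] += value * frac     # covering it fully round-trips exactly
            cov[g] += frac
            rsum[g] += value
            vmax[g] = max(vmax[g], value)
            covered[g] = True
    if skipped:
        logger.warning("%s: skipped %d record(s) on chromosomes outside the grid", path, skipped)
    values = np.full(n, np.nan)
    if aggregation == "mean":
        values[covered] = wsum[covered] / cov[covered]
    elif aggregation == "sum":
        values[covered] = rsum[covered]
    else:
        values[covered] = vmax[covered]
    return Track(grid, values, covered)


def write_bedgraph(track: Track, path: str | Path) -> None:
    """Write unmasked bins as sorted bedGraph records at full precision."""
    grid = track.grid
    with open(path, "w") as fh:
        for chrom in grid.chrom_names:
            off = grid.chrom_offset(chrom)
            for k in range(grid.n_bins(chrom)):
                g = off + k
                if not track.mask[g]:
                    continue
                s, e = grid.bin_bounds(chrom, k)
                fh.write(f"{chrom}\t{s}\t{e}\t{_fmt(track.values[g])}\n")


def mean_signal_over(track: Track, interval: Interval, flank_bp: int = 0) -> float:
    """Mean unmasked track value over [start - flank, end + flank), clipped.

    Returns NaN when every bin in the (clipped) window is masked.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    grid = track.grid
    length = grid.lengths[interval.chrom]
    start = max(0, interval.start - flank_bp)
    end = min(length, interval.end + flank_bp)
    off = grid.chrom_offset(interval.chrom)
    b0 = off + start // grid.bin_size
    b1 = off + (end - 1) // grid.bin_size + 1
    window = track.values[b0:b1]
    if not np.isfinite(window).any():
        return float("nan")
    return float(np.nanmean(window))
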