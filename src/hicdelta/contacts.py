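"""Contact matrices: pair filtering, binning, depth matching, balancing, O/E.

The numeric substrate for every figure-level analysis. Matrices are stored
per chromosome as dense symmetric arrays on a shared :class:`~hicdelta.grid.GenomeGrid`;
counts are integers, balanced and observed/expected values are floats with
NaN marking masked or undefined cells. On disk the canonical dialect is the
HiC-Pro sparse triplet (``.matrix`` + ``_abs.bed``), upper-triangular with
``i <= j``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .grid import GenomeGrid, ParseError, _fmt

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "ExpectedProfile",
    "FilterStats",
    "read_pairs",
    "filter_pairs",
    "bin_pairs",
    "downsample",
    "ice_balance",
    "expected_by_distance",
    "observed_over_expected",
    "read_matrix",
    "write_matrix",
    "write_weights",
    "read_weights",
]

PAIR_COLUMNS = ["chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]


class ContactMatrix:
    """Per-chromosome symmetric contact matrices on a fixed genome grid.

    Parameters
    ----------
    grid
        Shared coordinate system.
    data
        Mapping chromosome -> dense symmetric (n_bins x n_bins) array.
    value_kind
        'count' (integers), 'balanced', or 'oe'.
    bin_mask
        Optional mapping chromosome -> boolean valid-bin vector. For counts
        every bin is valid by default; balancing installs a mask.
    """

    def __init__(
        self,
        grid: GenomeGrid,
        data: Mapping[str, np.ndarray],
        value_kind: str = "count",
        bin_mask: Mapping[str, np.ndarray] | None = None,
        trans_count: int = 0,
    ):
        if value_kind not in ("count", "balanced", "oe"):
            raise ValueError(f"unknown value_kind {value_kind!r}")
        self.grid = grid
        self.value_kind = value_kind
        self.trans_count = int(trans_count)
        self._data: dict[str, np.ndarray] = {}
        self.bin_mask: dict[str, np.ndarray] = {}
        for chrom in grid.chrom_names:
            n = grid.n_bins(chrom)
            arr = np.asarray(data.get(chrom, np.zeros((n, n))), dtype=float)
            if arr.shape != (n, n):
                raise ValueError(f"{chrom}: matrix shape {arr.shape} != ({n}, {n})")
            if not np.allclose(arr, arr.T, equal_nan=True):
                raise ValueError(f"{chrom}: matrix not symmetric")
            if value_kind == "count":
                finite = arr[np.isfinite(arr)]
                if np.any(finite < 0) or not np.allclose(finite, np.round(finite)):
                    raise ValueError(f"{chrom}: count matrix must hold non-negative integers")
            self._data[chrom] = arr
            if bin_mask is not None and chrom in bin_mask:
                self.bin_mask[chrom] = np.asarray(bin_mask[chrom], dtype=bool).copy()
            else:
                self.bin_mask[chrom] = np.ones(n, dtype=bool)

    def dense(self, chrom: str) -> np.ndarray:
        """The symmetric dense matrix for one chromosome (a live view)."""
        return self._data[chrom]

    @property
    def chroms(self) -> tuple[str, ...]:
        return self.grid.chrom_names

    @property
    def total_count(self) -> float:
        """Sum of stored cis values, counting each off-diagonal cell once."""
        total = 0.0
        for chrom in self.chroms:
            a = self._data[chrom]
            with np.errstate(invalid="ignore"):
                total += (np.nansum(a) + np.nansum(np.diag(a))) / 2.0
        return float(total)

    def value(self, chrom: str, i: int, j: int) -> float:
        """Cell value; symmetric, so (j, i) returns (i, j)."""
        return float(self._data[chrom][i, j])

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.grid,
            {c: a.copy() for c, a in self._data.items()},
            self.value_kind,
            {c: m.copy() for c, m in self.bin_mask.items()},
            self.trans_count,
        )


@dataclass
class ExpectedProfile:
    """Per-chromosome mean contact value at each bin distance.

    ``values[chrom][d]`` is the average over valid (unmasked) bin pairs at
    distance d, NaN where no valid pair exists or d is below ``min_diag``.
    """

    grid: GenomeGrid
    values: dict[str, np.ndarray]
    n_valid: dict[str, np.ndarray]
    min_diag: int = 2

    def expected(self, chrom: str, d: int) -> float:
        return float(self.values[chrom][d])


@dataclass
class FilterStats:
    n_input: int = 0
    same_fragment: int = 0
    duplicate: int = 0
    retained: int = 0


# -- pairs ------------------------------------------------------------------


def read_pairs(path: str | Path) -> pd.DataFrame:
    """Read a 4DN-style ``.pairs`` text file (header lines start with '#').

    Columns used: readID chrom1 pos1 chrom2 pos2 strand1 strand2; extra
    columns are ignored. Records are canonically ordered so that side 1
    <= side 2 by (chrom, pos).
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 7:
            raise ParseError(f"{path}:{lineno}: .pairs needs >= 7 columns")
        rows.append(
            (parts[1], int(parts[2]), parts[3], int(parts[4]), parts[5], parts[6])
        )
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return canonicalize_pairs(df)


def canonicalize_pairs(df: pd.DataFrame) -> pd.DataFrame:
    """Order each record so (chrom1, pos1) <= (chrom2, pos2)."""
    df = df.reset_index(drop=True).copy()
    key1 = list(zip(df["chrom1"], df["pos1"]))
    key2 = list(zip(df["chrom2"], df["pos2"]))
    flip = np.array([k1 > k2 for k1, k2 in zip(key1, key2)])
    if flip.any():
        for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2")):
            df.loc[flip, [a, b]] = df.loc[flip, [b, a]].to_numpy()
    return df


def _assign_fragments(df: pd.DataFrame, fragments) -> tuple[np.ndarray, np.ndarray]:
    """Fragment id per pair end by position lookup in a fragment FeatureSet."""
    frag_starts: dict[str, np.ndarray] = {}
    frag_base: dict[str, int] = {}
    base = 0
    by_chrom: dict[str, list] = {}
    for iv in fragments:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        frag_starts[chrom] = np.array([iv.start for iv in ivs])
        frag_base[chrom] = base
        base += len(ivs)

    def lookup(chroms, poss):
        out = np.empty(len(chroms), dtype=int)
        for k, (c, p) in enumerate(zip(chroms, poss)):
            if c not in frag_starts:
                raise ValueError(f"no fragments for chromosome {c!r}")
            out[k] = frag_base[c] + int(np.searchsorted(frag_starts[c], p, side="right")) - 1
        return out

    return lookup(df["chrom1"], df["pos1"]), lookup(df["chrom2"], df["pos2"])


def filter_pairs(
    df: pd.DataFrame,
    fragments=None,
    drop_duplicates: bool = True,
) -> tuple[pd.DataFrame, FilterStats]:
    """Remove same-fragment pairs and exact PCR duplicates.

    Same-fragment pairs cover the dangling-end and self-circle ligation
    classes; an exact duplicate is positional + strand identity at both ends
    after canonical ordering. Fragment ids are taken from ``frag1``/``frag2``
    columns when present, otherwise computed from the ``fragments`` interval
    set (required in that case).
    """
    stats = FilterStats(n_input=len(df))
    df = canonicalize_pairs(df)
    if len(df) == 0:
        stats.retained = 0
        return df, stats
    if "frag1" in df.columns and "frag2" in df.columns:
        f1 = df["frag1"].to_numpy()
        f2 = df["frag2"].to_numpy()
    else:
        if fragments is None:
            raise ValueError("fragment ids absent and no fragment BED supplied")
        f1, f2 = _assign_fragments(df, fragments)
    same_chrom = (df["chrom1"] == df["chrom2"]).to_numpy()
    same_frag = same_chrom & (f1 == f2)
    stats.same_fragment = int(same_frag.sum())
    df = df.loc[~same_frag]
    if drop_duplicates:
        before = len(df)
        df = df.drop_duplicates(subset=PAIR_COLUMNS)
        stats.duplicate = before - len(df)
    stats.retained = len(df)
    return df.reset_index(drop=True), stats


def bin_pairs(df: pd.DataFrame, grid: GenomeGrid) -> ContactMatrix:
    """Bin filtered pairs into per-chromosome count matrices.

    Each cis pair increments one upper-triangular cell (mirrored into the
    symmetric store); trans pairs are kept only as a depth statistic on the
    returned matrix (``trans_count``).
    """
    data = {c: np.zeros((grid.n_bins(c),) * 2) for c in grid.chrom_names}
    trans = 0
    for c1, p1, c2, p2 in zip(df["chrom1"], df["pos1"], df["chrom2"], df["pos2"]):
        if c1 != c2:
            trans += 1
            continue
        i = grid.local_bin(c1, int(p1))
        j = grid.local_bin(c2, int(p2))
        i, j = min(i, j), max(i, j)
        data[c1][i, j] += 1
        if i != j:
            data[c1][j, i] += 1
    return ContactMatrix(grid, data, "count", trans_count=trans)


# -- depth matching ---------------------------------------------------------


def downsample(matrix: ContactMatrix, target_total: int, seed: int) -> ContactMatrix:
    """Sample ``target_total`` contacts without replacement across all cells.

    Multivariate hypergeometric over the multiset of cis contacts (every
    upper-triangular cell, all chromosomes jointly), so totals are conserved
    exactly and per-cell expectations are proportional to the originals.
    """
    if matrix.value_kind != "count":
        raise ValueError("downsample requires a count matrix")
    total = int(round(matrix.total_count))
    if not 0 <= target_total <= total:
        raise ValueError(f"target_total {target_total} outside [0, {total}]")
    counts = []
    shapes = {}
    for chrom in matrix.chroms:
        a = matrix.dense(chrom)
        iu = np.triu_indices(a.shape[0])
        counts.append(a[iu].astype(np.int64))
        shapes[chrom] = iu
    flat = np.concatenate(counts) if counts else np.array([], dtype=np.int64)
    rng = np.random.default_rng(seed)
    sampled = rng.multivariate_hypergeometric(flat, target_total, method="marginals")
    out = {}
    pos = 0
    for chrom in matrix.chroms:
        iu = shapes[chrom]
        k = len(iu[0])
        sub = sampled[pos : pos + k].astype(float)
        pos += k
        n = matrix.grid.n_bins(chrom)
        arr = np.zeros((n, n))
        arr[iu] = sub
        arr = arr + arr.T - np.diag(np.diag(arr))
        out[chrom] = arr
    return ContactMatrix(matrix.grid, out, "count", trans_count=matrix.trans_count)


# -- balancing --------------------------------------------------------------


def ice_balance(
    matrix: ContactMatrix,
    tol: float = 1e-6,
    max_iter: int = 400,
    min_coverage_frac: float = 0.02,
) -> tuple[ContactMatrix, dict[str, np.ndarray]]:
    """Iterative correction (ICE) per chromosome.

    Bins whose raw marginal falls below ``min_coverage_frac`` times the
    median nonzero marginal are masked before iterating. Iterations divide
    each cell by the product of its two bins' marginal sums (rescaled to
    mean 1 over unmasked bins) until the coefficient of variation of the
    unmasked marginals drops below ``tol``. Returns the balanced matrix
    (NaN at masked bins) and per-bin weights w with
    balanced(i, j) = count(i, j) * w_i * w_j.
    """
    if matrix.value_kind != "count":
        raise ValueError("ice_balance requires a count matrix")
    out = {}
    masks = {}
    weights: dict[str, np.ndarray] = {}
    any_valid = False
    for chrom in matrix.chroms:
        a = matrix.dense(chrom).astype(float).copy()
        n = a.shape[0]
        marg = a.sum(axis=1)
        nonzero = marg[marg > 0]
        cutoff = min_coverage_frac * (np.median(nonzero) if len(nonzero) else 0.0)
        valid = marg > max(cutoff, 0.0)
        if not valid.any():
            out[chrom] = np.full((n, n), np.nan)
            masks[chrom] = valid
            weights[chrom] = np.full(n, np.nan)
            continue
        any_valid = True
        a[~valid, :] = 0.0
        a[:, ~valid] = 0.0
        w = np.ones(n)
        converged = False
        for _ in range(max_iter):
            marg = a.sum(axis=1)
            mv = marg[valid]
            mean = mv.mean()
            if mean == 0:
                break
            cv = mv.std() / mean
            if cv < tol:
                converged = True
                break
            s = marg / mean
            s[~valid] = 1.0
            s[s == 0] = 1.0
            a /= np.outer(s, s)
            w /= s
        else:
            marg = a.sum(axis=1)
            mv = marg[valid]
            converged = mv.std() / mv.mean() < tol if mv.mean() else False
        if not converged:
            logger.warning("%s: ICE did not converge to tol=%g in %d iterations", chrom, tol, max_iter)
        a[~valid, :] = np.nan
        a[:, ~valid] = np.nan
        w[~valid] = np.nan
        out[chrom] = a
        masks[chrom] = valid
        weights[chrom] = w
    if not any_valid:
        raise ValueError("all bins masked on every chromosome; nothing to balance")
    balanced = ContactMatrix(matrix.grid, out, "balanced", bin_mask=masks,
                             trans_count=matrix.trans_count)
    return balanced, weights


# -- expected & O/E ---------------------------------------------------------


def expected_by_distance(matrix: ContactMatrix, min_diag: int = 2) -> ExpectedProfile:
    """Per-chromosome mean value at each bin distance over valid bin pairs.

    Distances below ``min_diag`` (default 2: the diagonal and the first
    off-diagonal, which are inflated by ligation artifacts) are reported as
    NaN; pass ``min_diag=0`` to keep them. Distances with zero valid pairs
    are NaN, never 0.
    """
    values: dict[str, np.ndarray] = {}
    n_valid: dict[str, np.ndarray] = {}
    for chrom in matrix.chroms:
        a = matrix.dense(chrom)
        mask = matrix.bin_mask[chrom]
        n = a.shape[0]
        e = np.full(n, np.nan)
        nv = np.zeros(n, dtype=int)
        for d in range(n):
            diag = np.diagonal(a, offset=d)
            pair_ok = mask[: n - d] & mask[d:] & np.isfinite(diag)
            nv[d] = int(pair_ok.sum())
            if d >= min_diag and nv[d] > 0:
                e[d] = diag[pair_ok].mean()
        values[chrom] = e
        n_valid[chrom] = nv
    return ExpectedProfile(matrix.grid, values, n_valid, min_diag=min_diag)


def observed_over_expected(matrix: ContactMatrix, profile: ExpectedProfile) -> ContactMatrix:
    """O/E transform: value(i, j) / e(|i - j|); undefined expected -> NaN."""
    if profile.grid is not matrix.grid and profile.grid != matrix.grid:
        raise ValueError("expected profile computed on a different grid")
    out = {}
    for chrom in matrix.chroms:
        a = matrix.dense(chrom).astype(float)
        n = a.shape[0]
        e = profile.values[chrom]
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        denom = e[d]
        with np.errstate(invalid="ignore", divide="ignore"):
            oe = np.where(np.isfinite(denom) & (denom > 0), a / denom, np.nan)
        mask = matrix.bin_mask[chrom]
        oe[~mask, :] = np.nan
        oe[:, ~mask] = np.nan
        out[chrom] = oe
    return ContactMatrix(matrix.grid, out, "oe", bin_mask=matrix.bin_mask,
                         trans_count=matrix.trans_count)


# -- HiC-Pro triplet I/O ----------------------------------------------------


def write_matrix(matrix: ContactMatrix, matrix_path: str | Path, bins_path: str | Path,
                 base: int = 1) -> None:
    """Write the HiC-Pro triplet dialect: ``.matrix`` + companion abs-bed.

    Upper-triangular nonzero cells only, bin ids ``base``-based (HiC-Pro
    convention is 1-based). NaN cells are omitted.
    """
    grid = matrix.grid
    with open(bins_path, "w") as fh:
        gid = base
        for chrom in grid.chrom_names:
            for k in range(grid.n_bins(chrom)):
                s, e = grid.bin_bounds(chrom, k)
                fh.write(f"{chrom}\t{s}\t{e}\t{gid}\n")
                gid += 1
    with open(matrix_path, "w") as fh:
        for chrom in grid.chrom_names:
            off = grid.chrom_offset(chrom) + base
            a = matrix.dense(chrom)
            iu = np.triu_indices(a.shape[0])
            vals = a[iu]
            keep = np.isfinite(vals) & (vals != 0)
            for i, j, v in zip(iu[0][keep], iu[1][keep], vals[keep]):
                if matrix.value_kind == "count":
                    fh.write(f"{off + i}\t{off + j}\t{int(round(v))}\n")
                else:
                    fh.write(f"{off + i}\t{off + j}\t{_fmt(v)}\n")


def read_matrix(matrix_path: str | Path, bins_path: str | Path, grid: GenomeGrid,
                value_kind: str = "count", base: int = 1) -> ContactMatrix:
    """Read a HiC-Pro triplet matrix; the abs-bed must match the grid."""
    bins = pd.read_csv(bins_path, sep="\t", header=None,
                       names=["chrom", "start", "end", "bin_id"])
    expected_bins = grid.bins_dataframe()
    if len(bins) != len(expected_bins):
        raise ValueError("abs-bed bin count does not match grid")
    if not (bins["chrom"].to_numpy() == expected_bins["chrom"].to_numpy()).all() or \
       not (bins["start"].to_numpy() == expected_bins["start"].to_numpy()).all() or \
       not (bins["end"].to_numpy() == expected_bins["end"].to_numpy()).all():
        raise ValueError("abs-bed bins do not match grid (bin width or chromosomes differ)")
    data = {c: np.zeros((grid.n_bins(c),) * 2) for c in grid.chrom_names}
    # map global id -> (chrom, local)
    bounds = []
    off = 0
    for c in grid.chrom_names:
        n = grid.n_bins(c)
        bounds.append((off, off + n, c))
        off += n
    total_bins = off
    tri = pd.read_csv(matrix_path, sep="\t", header=None, names=["a", "b", "v"])
    for a, b, v in zip(tri["a"], tri["b"], tri["v"]):
        ga, gb = int(a) - base, int(b) - base
        if not (0 <= ga < total_bins and 0 <= gb < total_bins):
            raise ValueError(f"bin id pair ({a}, {b}) outside grid")
        if ga > gb:
            ga, gb = gb, ga
        ca = next(c for lo, hi, c in bounds if lo <= ga < hi)
        cb = next(c for lo, hi, c in bounds if lo <= gb < hi)
        if ca != cb:
            continue  # trans cells are not stored
        lo = grid.chrom_offset(ca)
        i, j = ga - lo, gb - lo
        data[ca][i, j] += v
        if i != j:
            data[ca][j, i] += v
    return ContactMatrix(grid, data, value_kind)


def write_weights(weights: dict[str, np.ndarray], grid: GenomeGrid, path: str | Path) -> None:
    """ICE weight sidecar TSV: chrom, bin start, weight ('.' where masked)."""
    with open(path, "w") as fh:
        for chrom in grid.chrom_names:
            w = weights[chrom]
            for k in range(grid.n_bins(chrom)):
                s, _ = grid.bin_bounds(chrom, k)
                val = _fmt(w[k]) if np.isfinite(w[k]) else "."
                fh.write(f"{chrom}\t{s}\t{val}\n")


def read_weights(path: str | Path, grid: GenomeGrid) -> dict[str, np.ndarray]:
    out = {c: np.full(grid.n_bins(c), np.nan) for c in grid.chrom_names}
    for line in Path(path).read_text().splitlines():
        chrom, start, val = line.split("\t")
        if val != ".":
            out[chrom][int(start) // grid.bin_size] = float(val)
    return out
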