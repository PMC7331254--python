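"""A/B compartment eigenvector and saddle-plot compartmentalization strength.

The compartment signal is the leading eigenvector (PC1) of the per-chromosome
correlation matrix of observed/expected rows, sign-oriented against an
external track (GC content or any A-ness proxy). Compartmentalization
strength is read off a saddle plot: bins ranked by PC1 are cut into
quantile groups and the mean O/E between extreme groups is compared across
the corners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .contacts import ContactMatrix
from .grid import Track

logger = logging.getLogger(__name__)

__all__ = ["SaddleResult", "compartment_eigenvector", "saddle"]


@dataclass
class SaddleResult:
    """Mean O/E by PC1-quantile pair, plus the corner-ratio strength.

    ``matrix[q1, q2]`` is the mean cis O/E over bin pairs with one bin in
    quantile q1 and the other in q2 (quantiles ordered by increasing PC1,
    so index 0 is the strongest B group and index -1 the strongest A group).
    ``strength = (AA + BB) / (AB + BA)`` over the single extreme-quantile
    corner cells.
    """

    n_quantiles: int
    matrix: np.ndarray
    strength: float
    quantile_of_bin: np.ndarray  # global-bin -> quantile index, -1 = unassigned
    low_confidence: bool = False


def compartment_eigenvector(
    oe_matrix: ContactMatrix,
    orientation_track: Track,
    min_bins: int = 10,
) -> Track:
    """Leading eigenvector of the O/E row-correlation matrix, per chromosome.

    The eigenvector sign is chosen so PC1 correlates positively with
    ``orientation_track`` over each chromosome's valid bins. Chromosomes
    with fewer than ``min_bins`` unmasked bins are skipped with a warning.
    Undefined O/E cells inside the valid submatrix (excluded diagonals) are
    treated as the neutral value 1 before correlating.
    """
    grid = oe_matrix.grid
    values = np.full(grid.total_bins, np.nan)
    for chrom in oe_matrix.chroms:
        a = oe_matrix.dense(chrom)
        valid = oe_matrix.bin_mask[chrom] & np.isfinite(a).any(axis=1)
        if valid.sum() < min_bins:
            logger.warning("%s: only %d unmasked bins, PC1 skipped", chrom, valid.sum())
            continue
        sub = a[np.ix_(valid, valid)].copy()
        sub[~np.isfinite(sub)] = 1.0
        # rows with zero variance break the correlation; drop them too
        var = sub.std(axis=1)
        keep = var > 0
        if keep.sum() < min_bins:
            logger.warning("%s: O/E rows degenerate, PC1 skipped", chrom)
            continue
        idx = np.flatnonzero(valid)[keep]
        corr = np.corrcoef(sub[np.ix_(keep, keep)])
        evals, evecs = np.linalg.eigh(corr)
        pc1 = evecs[:, -1]
        if len(evals) > 1 and evals[-1] - evals[-2] < 1e-8 * max(abs(evals[-1]), 1.0):
            logger.warning("%s: leading eigenvalue nearly degenerate; PC1 low-confidence", chrom)
        sl = grid.chrom_slice(chrom)
        ref = orientation_track.values[sl][idx]
        ok = np.isfinite(ref)
        if ok.sum() >= 2 and np.corrcoef(pc1[ok], ref[ok])[0, 1] < 0:
            pc1 = -pc1
        values[idx + sl.start] = pc1
    return Track(grid, values, np.isfinite(values))


def saddle(
    oe_matrix: ContactMatrix,
    pc1: Track,
    n_quantiles: int = 5,
    min_dist_bins: int = 10,
) -> SaddleResult:
    """Saddle plot of mean cis O/E by PC1-quantile pair, and its strength.

    Bins with a defined PC1 are rank-ordered and split into ``n_quantiles``
    equal-size groups (remainder spread over the lowest groups). Cell
    (q1, q2) averages O/E over cis bin pairs at distance >= ``min_dist_bins``
    with one bin in each group. Strength is the ratio of the two same-label
    corners to the two cross-label corners.
    """
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    grid = oe_matrix.grid
    quant = np.full(grid.total_bins, -1, dtype=int)
    finite = np.isfinite(pc1.values)
    order = np.argsort(pc1.values[finite], kind="stable")
    g_ids = np.flatnonzero(finite)[order]
    n = len(g_ids)
    if n < n_quantiles:
        raise ValueError("fewer PC1 bins than quantiles")
    base, rem = divmod(n, n_quantiles)
    sizes = [base + (1 if k < rem else 0) for k in range(n_quantiles)]
    pos = 0
    for q, s in enumerate(sizes):
        if s == 0:
            raise ValueError("empty PC1 quantile")
        quant[g_ids[pos : pos + s]] = q
        pos += s

    sums = np.zeros((n_quantiles, n_quantiles))
    counts = np.zeros((n_quantiles, n_quantiles))
    for chrom in oe_matrix.chroms:
        sl = grid.chrom_slice(chrom)
        q = quant[sl]
        a = oe_matrix.dense(chrom)
        nb = a.shape[0]
        ii, jj = np.triu_indices(nb, k=max(min_dist_bins, 1))
        qi, qj = q[ii], q[jj]
        vals = a[ii, jj]
        ok = (qi >= 0) & (qj >= 0) & np.isfinite(vals)
        np.add.at(sums, (qi[ok], qj[ok]), vals[ok])
        np.add.at(counts, (qi[ok], qj[ok]), 1)
    sums = sums + sums.T
    counts = counts + counts.T
    with np.errstate(invalid="ignore"):
        mat = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    bb, aa = mat[0, 0], mat[-1, -1]
    ab, ba = mat[0, -1], mat[-1, 0]
    strength = float((aa + bb) / (ab + ba))
    return SaddleResult(n_quantiles, mat, strength, quant)
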