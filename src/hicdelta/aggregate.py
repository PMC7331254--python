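"""Pair-anchored pile-ups: PE-SCAn, loop APA, promoter-pair aggregates, stripes.

All operators extract fixed-size windows of a contact matrix centered on
feature-pair pixels and average them per pixel with missing cells excluded,
so every pile-up of a uniform matrix is uniform and the operators are
linear in the input matrix. Backgrounds, where used, repeat the procedure
on randomized anchors under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .contacts import ContactMatrix
from .grid import FeatureSet, Interval
from .insulation import AggregateResult

logger = logging.getLogger(__name__)

__all__ = [
    "pe_scan",
    "loop_apa",
    "promoter_pair_aggregate",
    "stripe_profile",
    "tertile_labels",
]


def _pileup_at_pairs(
    matrix: ContactMatrix,
    pair_bins: list[tuple[str, int, int]],
    half: int,
) -> tuple[np.ndarray, int, np.ndarray, np.ndarray]:
    """Mean (2*half+1)^2 window over pair pixels; pairs leaving the chromosome skipped.

    Returns (mean matrix, n pairs used, per-pair center pixels, per-pair
    center-3x3 means).
    """
    size = 2 * half + 1
    acc = np.zeros((size, size))
    cnt = np.zeros((size, size))
    centers = []
    centers3 = []
    used = 0
    for chrom, bi, bj in pair_bins:
        a = matrix.dense(chrom)
        n = a.shape[0]
        if bi - half < 0 or bj - half < 0 or bi + half + 1 > n or bj + half + 1 > n:
            continue
        win = a[bi - half : bi + half + 1, bj - half : bj + half + 1]
        finite = np.isfinite(win)
        acc[finite] += win[finite]
        cnt[finite] += 1
        centers.append(win[half, half])
        if half >= 1:
            block = win[half - 1 : half + 2, half - 1 : half + 2]
            centers3.append(float(np.nanmean(block)) if np.isfinite(block).any() else np.nan)
        else:
            centers3.append(win[half, half])
        used += 1
    with np.errstate(invalid="ignore"):
        mat = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return mat, used, np.asarray(centers), np.asarray(centers3)


def _frame_mean(mat: np.ndarray) -> float:
    """Mean over the outermost one-pixel ring."""
    frame = np.concatenate([mat[0, :], mat[-1, :], mat[1:-1, 0], mat[1:-1, -1]])
    return float(np.nanmean(frame))


def _center_stats(mat: np.ndarray) -> dict:
    half = mat.shape[0] // 2
    center = float(mat[half, half])
    c3 = float(np.nanmean(mat[half - 1 : half + 2, half - 1 : half + 2]))
    frame = _frame_mean(mat)
    return {
        "center": center,
        "center_3x3": c3,
        "frame_mean": frame,
        "center_enrichment": center / frame if frame else float("nan"),
        "center_3x3_enrichment": c3 / frame if frame else float("nan"),
    }


def pe_scan(
    matrix: ContactMatrix,
    anchors: FeatureSet,
    window_bp: int = 500_000,
    max_sep_bp: int = 10_000_000,
    background_mode: str = "permute",
    seed: int = 0,
    n_permutations: int = 1,
    min_sep_bp: int | None = None,
) -> AggregateResult:
    """Pile-up around all cis anchor pairs, with a permuted-anchor background.

    For every cis pair of point anchors separated by more than ``min_sep_bp``
    (default: twice the window, so the window frame stays clear of the
    strongly structured near-diagonal zone) and at most ``max_sep_bp``, the
    square window of +/- ``window_bp`` around the pair pixel is extracted
    and averaged. The background repeats the procedure with anchor positions
    redrawn uniformly per chromosome (same anchor count, fixed seed), and
    the result carries raw, background and ratio matrices plus
    center-vs-frame enrichments.
    """
    grid = matrix.grid
    half = window_bp // grid.bin_size
    if min_sep_bp is None:
        min_sep_bp = 2 * window_bp

    def pairs_from(bins_by_chrom: dict[str, np.ndarray]) -> list[tuple[str, int, int]]:
        out = []
        min_sep = max(min_sep_bp // grid.bin_size, half)
        max_sep = max_sep_bp // grid.bin_size
        for chrom, bins in bins_by_chrom.items():
            bins = np.sort(bins)
            if len(bins) < 2:
                logger.info("pe_scan: %s has < 2 anchors, no pairs", chrom)
                continue
            for x in range(len(bins)):
                for y in range(x + 1, len(bins)):
                    sep = bins[y] - bins[x]
                    if min_sep < sep <= max_sep:
                        out.append((chrom, int(bins[x]), int(bins[y])))
        return out

    anchor_bins: dict[str, np.ndarray] = {}
    for chrom in grid.chrom_names:
        pts = [grid.local_bin(chrom, iv.midpoint) for iv in anchors.by_chrom(chrom)]
        if pts:
            anchor_bins[chrom] = np.asarray(pts)

    raw, n_used, centers, centers3 = _pileup_at_pairs(matrix, pairs_from(anchor_bins), half)
    stats = {f"raw_{k}": v for k, v in _center_stats(raw).items()}

    background = None
    if background_mode == "permute":
        rng = np.random.default_rng(seed)
        size = raw.shape[0]
        bacc = np.zeros((size, size))
        bcnt = np.zeros((size, size))
        for _ in range(max(1, n_permutations)):
            permuted = {
                chrom: rng.integers(0, grid.n_bins(chrom), size=len(bins))
                for chrom, bins in anchor_bins.items()
            }
            bmat, bn, _, bcenters3 = _pileup_at_pairs(matrix, pairs_from(permuted), half)
            finite = np.isfinite(bmat)
            bacc[finite] += bmat[finite]
            bcnt[finite] += 1
        with np.errstate(invalid="ignore"):
            background = np.where(bcnt > 0, bacc / np.maximum(bcnt, 1), np.nan)
        stats.update({f"background_{k}": v for k, v in _center_stats(background).items()})
        with np.errstate(invalid="ignore"):
            ratio = raw / background
        stats.update({f"ratio_{k}": v for k, v in _center_stats(ratio).items()})
        stats["ratio_matrix"] = ratio
    elif background_mode not in ("none",):
        raise ValueError(f"unknown background_mode {background_mode!r}")

    stats["per_pair_center_3x3"] = centers3
    return AggregateResult(raw, n_used, background=background,
                           per_feature=centers, stats=stats)


def loop_apa(
    oe_matrix: ContactMatrix,
    loops: FeatureSet,
    half_window_bins: int = 5,
    corner_size: int = 3,
    mode: str = "center_pixel",
) -> AggregateResult:
    """Aggregate peak analysis at loop pixels.

    Loops with anchor-bin separation <= 2*half_window_bins are skipped (and
    counted in stats). The summary is the center pixel over the mean of the
    bottom-left (short-distance) corner block. Per-loop center values (or
    center-3x3 means when mode='center_3x3_mean') are retained.
    """
    grid = oe_matrix.grid
    pair_bins = []
    skipped = 0
    for p in loops:
        bi = grid.local_bin(p.chrom, p.anchor_a.midpoint)
        bj = grid.local_bin(p.chrom, p.anchor_b.midpoint)
        if abs(bj - bi) <= 2 * half_window_bins:
            skipped += 1
            continue
        pair_bins.append((p.chrom, min(bi, bj), max(bi, bj)))
    mat, n_used, centers, centers3 = _pileup_at_pairs(oe_matrix, pair_bins, half_window_bins)
    if n_used == 0:
        return AggregateResult(mat, 0, stats={"skipped_close": skipped})
    if mode == "center_3x3_mean":
        centers = centers3
    half = mat.shape[0] // 2
    center = float(mat[half, half])
    corner = float(np.nanmean(mat[-corner_size:, :corner_size]))
    stats = _center_stats(mat)
    stats.update({
        "corner_mean": corner,
        "apa_score": center / corner if corner else float("nan"),
        "skipped_close": skipped,
    })
    return AggregateResult(mat, n_used, per_feature=centers, stats=stats)


def tertile_labels(scores: np.ndarray, n_slices: int = 3) -> np.ndarray:
    """Rank-based equal slices, highest scores first; remainder to lower slices.

    Returns an integer label per element, 0 = top slice. Ties resolve by
    original order (stable sort), so e.g. 10 elements split 4/3/3.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    order = np.argsort(-scores, kind="stable")
    base, rem = divmod(n, n_slices)
    sizes = [base + (1 if k < rem else 0) for k in range(n_slices)]
    labels = np.empty(n, dtype=int)
    pos = 0
    for k, s in enumerate(sizes):
        labels[order[pos : pos + s]] = k
        pos += s
    return labels


def promoter_pair_aggregate(
    oe_matrix: ContactMatrix,
    promoters: FeatureSet,
    ctcf_peaks: FeatureSet | None = None,
    window_bp: int = 400_000,
    distance_classes: dict[str, tuple[int, int]] | None = None,
    activity_slices: int = 3,
    ctcf_slop_bp: int = 5_000,
) -> dict[str, AggregateResult]:
    """Promoter-pair pile-ups stratified by distance, activity, CTCF status.

    All cis promoter pairs within each distance class (defaults: intra-TAD
    200 kb - 2 Mb, long-range 2 - 10 Mb) are piled up in a square window of
    ``window_bp`` total width around the pair pixel. Promoters are split
    into ``activity_slices`` rank tertiles by score, and flagged CTCF-bound
    when any peak lies within ``ctcf_slop_bp`` of their midpoint. Group
    keys look like 'intra_tad', 'intra_tad|activity0', 'intra_tad|ctcf'.
    Groups with zero pairs are logged and omitted.
    """
    grid = oe_matrix.grid
    half = window_bp // 2 // grid.bin_size
    if distance_classes is None:
        distance_classes = {"intra_tad": (200_000, 2_000_000),
                            "long_range": (2_000_000, 10_000_000)}

    plist = list(promoters)
    scores = promoters.scores()
    act = tertile_labels(scores, activity_slices)

    ctcf_flags = np.zeros(len(plist), dtype=bool)
    if ctcf_peaks is not None:
        by_chrom: dict[str, list[Interval]] = {}
        for pk in ctcf_peaks:
            by_chrom.setdefault(pk.chrom, []).append(pk)
        for k, pr in enumerate(plist):
            mid = pr.midpoint
            for pk in by_chrom.get(pr.chrom, ()):  # peak lists are small
                if pk.start - ctcf_slop_bp <= mid < pk.end + ctcf_slop_bp:
                    ctcf_flags[k] = True
                    break

    # all cis pairs with their strata
    groups: dict[str, list[tuple[str, int, int]]] = {}
    idx_by_chrom: dict[str, list[int]] = {}
    for k, pr in enumerate(plist):
        idx_by_chrom.setdefault(pr.chrom, []).append(k)
    for chrom, idxs in idx_by_chrom.items():
        for x in range(len(idxs)):
            for y in range(x + 1, len(idxs)):
                a, b = plist[idxs[x]], plist[idxs[y]]
                sep = abs(b.midpoint - a.midpoint)
                for dname, (lo, hi) in distance_classes.items():
                    if not lo <= sep < hi:
                        continue
                    ba = grid.local_bin(chrom, a.midpoint)
                    bb = grid.local_bin(chrom, b.midpoint)
                    pair = (chrom, min(ba, bb), max(ba, bb))
                    groups.setdefault(dname, []).append(pair)
                    ta, tb = act[idxs[x]], act[idxs[y]]
                    if ta == tb:
                        groups.setdefault(f"{dname}|activity{ta}", []).append(pair)
                    both_ctcf = ctcf_flags[idxs[x]] and ctcf_flags[idxs[y]]
                    neither = not (ctcf_flags[idxs[x]] or ctcf_flags[idxs[y]])
                    if both_ctcf:
                        groups.setdefault(f"{dname}|ctcf", []).append(pair)
                    elif neither:
                        groups.setdefault(f"{dname}|noctcf", []).append(pair)

    out: dict[str, AggregateResult] = {}
    for name, pairs in groups.items():
        mat, n_used, centers, centers3 = _pileup_at_pairs(oe_matrix, pairs, half)
        if n_used == 0:
            logger.info("promoter_pair_aggregate: group %s has no usable pairs", name)
            continue
        out[name] = AggregateResult(mat, n_used, per_feature=centers,
                                    stats=_center_stats(mat))
    return out


def stripe_profile(
    matrix: ContactMatrix,
    targets: FeatureSet,
    max_dist_bp: int = 200_000,
    pileup: bool = True,
) -> tuple[np.ndarray, AggregateResult | None]:
    """Signal decay away from point targets, plus an optional diagonal pile-up.

    The curve's d-th entry (1 <= d <= max_dist/bin) is the mean matrix value
    connecting a target bin to bins d away, both directions averaged over
    all targets. Targets within ``max_dist_bp`` of a chromosome end
    contribute their surviving side only (flagged in the result stats).
    The returned aggregate carries one band-mean value per target (the mean
    over the target's whole distance range), the unit for between-condition
    statistics, and the diagonal pile-up matrix when ``pileup`` is set.
    """
    grid = matrix.grid
    dmax = max_dist_bp // grid.bin_size
    acc = np.zeros(dmax)
    cnt = np.zeros(dmax)
    truncated = 0
    target_bins = []
    per_target = []
    for iv in targets:
        b = grid.local_bin(iv.chrom, iv.midpoint)
        n = grid.n_bins(iv.chrom)
        a = matrix.dense(iv.chrom)
        if b - dmax < 0 or b + dmax + 1 > n:
            truncated += 1
        band = []
        for d in range(1, dmax + 1):
            vals = []
            if b - d >= 0:
                vals.append(a[b, b - d])
            if b + d < n:
                vals.append(a[b, b + d])
            vals = [v for v in vals if np.isfinite(v)]
            if vals:
                acc[d - 1] += float(np.mean(vals))
                cnt[d - 1] += 1
                band.extend(vals)
        per_target.append(float(np.mean(band)) if band else np.nan)
        target_bins.append((iv.chrom, b, b))
    with np.errstate(invalid="ignore"):
        curve = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    mat = None
    n_used = len(targets)
    if pileup:
        mat, n_used, _, _c3 = _pileup_at_pairs(matrix, target_bins, dmax)
    agg = AggregateResult(mat if mat is not None else np.empty((0, 0)),
                          n_used, per_feature=np.asarray(per_target),
                          stats={"truncated_targets": truncated})
    return curve, agg
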