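"""Loop- and hotspot-level feature engineering and perturbation statistics.

Classifies loops by ChIP-peak occupancy at their anchors, measures per-loop
contact strength, computes the percent-change statistic between conditions
(difference of means over the untreated mean) with its significance test,
relates change to loop length and to transcription, stitches binding peaks
into ranked hotspots with a tangent cutoff, and correlates contact changes
with signal tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .contacts import ContactMatrix
from .grid import FeatureSet, Interval, Track, mean_signal_over
from .aggregate import tertile_labels

logger = logging.getLogger(__name__)

__all__ = [
    "ChangeStat",
    "classify_loops",
    "loop_strength",
    "percent_change",
    "loop_length_trend",
    "rank_domains_by_transcription",
    "stitch_hotspots",
    "change_vs_signal_correlation",
]


# -- occupancy classification ----------------------------------------------


def _overlap_index(peaks: FeatureSet):
    """Per-chromosome (starts, cummax_ends) for O(log n) interval stabbing."""
    by_chrom: dict[str, list[Interval]] = {}
    for pk in peaks:
        by_chrom.setdefault(pk.chrom, []).append(pk)
    index = {}
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs, key=lambda x: x.start)
        starts = np.array([iv.start for iv in ivs])
        ends = np.maximum.accumulate(np.array([iv.end for iv in ivs]))
        index[chrom] = (starts, ends)
    return index


def _overlaps(index, chrom: str, start: int, end: int) -> bool:
    if chrom not in index:
        return False
    starts, cummax_ends = index[chrom]
    k = int(np.searchsorted(starts, end, side="left"))
    return k > 0 and cummax_ends[k - 1] > start


def classify_loops(
    loops: FeatureSet,
    peak_sets: dict[str, FeatureSet],
    slop_bp: int = 0,
) -> pd.DataFrame:
    """Anchor-occupancy call per loop and factor: 'both', 'single', or 'none'.

    'both' means each anchor overlaps >= 1 peak (>= 1 bp after padding
    anchors by ``slop_bp``); 'none' means neither anchor overlaps. The
    returned frame has one column per factor plus loop coordinates, so
    compound selections are plain pandas predicates.
    """
    indexes = {name: _overlap_index(pk) for name, pk in peak_sets.items()}
    rows = []
    for p in loops:
        row = {
            "chrom": p.chrom,
            "start_a": p.anchor_a.start, "end_a": p.anchor_a.end,
            "start_b": p.anchor_b.start, "end_b": p.anchor_b.end,
        }
        for name, idx in indexes.items():
            hits = sum(
                _overlaps(idx, p.chrom, max(0, anchor.start - slop_bp), anchor.end + slop_bp)
                for anchor in (p.anchor_a, p.anchor_b)
            )
            row[name] = {0: "none", 1: "single", 2: "both"}[hits]
        rows.append(row)
    return pd.DataFrame(rows)


# -- per-loop strength and change statistics --------------------------------


def loop_strength(
    matrix: ContactMatrix,
    loops: FeatureSet,
    mode: str = "center_pixel",
) -> np.ndarray:
    """One contact value per loop at its anchor-midpoint pixel.

    mode 'center_pixel' reads the single pixel; 'center_3x3_mean' averages
    the surrounding 3x3 block. Masked pixels give NaN.
    """
    if mode not in ("center_pixel", "center_3x3_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    grid = matrix.grid
    out = np.full(len(loops), np.nan)
    for k, p in enumerate(loops):
        a = matrix.dense(p.chrom)
        n = a.shape[0]
        bi = grid.local_bin(p.chrom, p.anchor_a.midpoint)
        bj = grid.local_bin(p.chrom, p.anchor_b.midpoint)
        if mode == "center_pixel":
            out[k] = a[bi, bj]
        else:
            i0, i1 = max(0, bi - 1), min(n, bi + 2)
            j0, j1 = max(0, bj - 1), min(n, bj + 2)
            block = a[i0:i1, j0:j1]
            out[k] = np.nanmean(block) if np.isfinite(block).any() else np.nan
    return out


@dataclass
class ChangeStat:
    """Percent change of the mean between conditions, with significance.

    percent_change = 100 * (mean_treated - mean_untreated) / mean_untreated.
    ``z`` is the mean difference over its standard error (Welch for
    unpaired sets, paired-difference otherwise).
    """

    n_untreated: int
    n_treated: int
    mean_untreated: float
    mean_treated: float
    percent_change: float
    se_diff: float
    z: float
    statistic: float
    pvalue: float
    test: str
    paired: bool


def percent_change(
    untreated: np.ndarray,
    treated: np.ndarray,
    test: str = "ttest",
    paired: bool = False,
) -> ChangeStat:
    """Difference of means over the untreated mean, as a percentage.

    NaNs are dropped (pairwise when ``paired``). ``test`` selects the
    accompanying two-sample test: 'ttest' (Student/Welch) or 'wilcoxon'
    (signed-rank when paired, rank-sum otherwise). Raises when the
    untreated mean is not positive.
    """
    u = np.asarray(untreated, dtype=float)
    t = np.asarray(treated, dtype=float)
    if paired:
        if len(u) != len(t):
            raise ValueError("paired sets must have equal length")
        ok = np.isfinite(u) & np.isfinite(t)
        u, t = u[ok], t[ok]
    else:
        u, t = u[np.isfinite(u)], t[np.isfinite(t)]
    mu, mt = float(np.mean(u)), float(np.mean(t))
    if not mu > 0:
        raise ValueError("percent change undefined: untreated mean <= 0")
    pct = 100.0 * (mt - mu) / mu
    if paired:
        diff = t - u
        se = float(diff.std(ddof=1) / np.sqrt(len(diff))) if len(diff) > 1 else float("nan")
    else:
        se = float(np.sqrt(u.var(ddof=1) / len(u) + t.var(ddof=1) / len(t))) \
            if min(len(u), len(t)) > 1 else float("nan")
    z = (mt - mu) / se if se and np.isfinite(se) and se > 0 else float("nan")
    if test == "ttest":
        if paired:
            res = sps.ttest_rel(t, u)
        else:
            res = sps.ttest_ind(t, u, equal_var=False)
    elif test == "wilcoxon":
        if paired:
            res = sps.wilcoxon(t, u) if np.any(t != u) else type("R", (), {"statistic": 0.0, "pvalue": 1.0})
        else:
            res = sps.mannwhitneyu(t, u, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return ChangeStat(
        n_untreated=len(u), n_treated=len(t),
        mean_untreated=mu, mean_treated=mt, percent_change=pct,
        se_diff=se, z=z,
        statistic=float(res.statistic), pvalue=float(res.pvalue),
        test=test, paired=paired,
    )


# -- loop-length trend ------------------------------------------------------


def loop_length_trend(
    loops: FeatureSet,
    values: np.ndarray,
    span: float = 0.3,
    n_grid: int = 50,
    n_bins: int = 10,
    length_split_bp: int = 250_000,
) -> dict:
    """Locally-weighted regression of loop strength on loop length.

    Returns the smoothed curve on a fixed grid of lengths (tricube weights,
    locally linear), binned means as a smoothing-free fallback, and a
    two-group summary at the <= / > ``length_split_bp`` dichotomy. With
    fewer than 10 loops only the binned means are computed.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    lengths = np.array([p.length for p in loops], dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(lengths) & np.isfinite(values)
    lengths, values = lengths[ok], values[ok]
    out: dict = {"n": len(lengths)}

    edges = np.linspace(lengths.min(), lengths.max(), n_bins + 1) if len(lengths) else None
    if edges is not None:
        which = np.clip(np.digitize(lengths, edges) - 1, 0, n_bins - 1)
        out["bin_centers"] = (edges[:-1] + edges[1:]) / 2.0
        out["bin_means"] = np.array([
            values[which == k].mean() if np.any(which == k) else np.nan
            for k in range(n_bins)
        ])

    short = lengths <= length_split_bp
    out["short_mean"] = float(values[short].mean()) if short.any() else float("nan")
    out["long_mean"] = float(values[~short].mean()) if (~short).any() else float("nan")
    out["n_short"] = int(short.sum())
    out["n_long"] = int((~short).sum())

    if len(lengths) < 10:
        logger.warning("loop_length_trend: < 10 loops, smoothed curve omitted")
        out["grid"] = out["curve"] = None
        return out

    from statsmodels.nonparametric.smoothers_lowess import lowess

    grid_x = np.linspace(lengths.min(), lengths.max(), n_grid)
    fitted = lowess(values, lengths, frac=span, xvals=grid_x)
    out["grid"] = grid_x
    out["curve"] = np.asarray(fitted, dtype=float)
    return out


# -- transcription ranking --------------------------------------------------


def rank_domains_by_transcription(
    domains: FeatureSet,
    track: Track,
    flank_bp: int = 100_000,
    n_groups: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Group domains by mean signal over the domain plus flanks, decreasing.

    Returns (group labels, scores); label 0 is the most-transcribed group.
    Equal-size groups with the remainder assigned to earlier groups; ties
    rank stably in coordinate order.
    """
    scores = np.array([mean_signal_over(track, d, flank_bp) for d in domains])
    return tertile_labels(scores, n_groups), scores


# -- hotspot stitching (ROSE-style) ----------------------------------------


def stitch_hotspots(
    peaks: FeatureSet,
    stitch_bp: int = 12_500,
) -> pd.DataFrame:
    """Stitch nearby peaks into clusters and call hotspots past a tangent cutoff.

    Peaks with gaps <= ``stitch_bp`` merge into clusters; clusters are
    ranked by total peak signal and, after min-max scaling both axes of the
    ranked signal curve to [0, 1], the cutoff sits where the curve's
    discrete tangent reaches slope 1 (the point maximizing y - x distance
    below the diagonal); clusters strictly above the cutoff signal are
    hotspots (ties resolve toward fewer hotspots). Each cluster's summit is
    the midpoint of its strongest constituent peak. Output is independent
    of input peak order (peaks are sorted internally).

    Returns a frame with one row per cluster: chrom, start, end, signal,
    rank (1 = strongest), summit, n_peaks, is_hotspot.
    """
    clusters: list[list[Interval]] = []
    for chrom in sorted({pk.chrom for pk in peaks}):
        ivs = sorted(peaks.by_chrom(chrom), key=lambda x: (x.start, x.end))
        current: list[Interval] = []
        for iv in ivs:
            if current and iv.start - current[-1].end <= stitch_bp:
                current.append(iv)
            else:
                if current:
                    clusters.append(current)
                current = [iv]
        if current:
            clusters.append(current)

    rows = []
    for cl in clusters:
        signal = float(sum(pk.score or 0.0 for pk in cl))
        strongest = max(cl, key=lambda pk: (pk.score or 0.0, -pk.start))
        rows.append({
            "chrom": cl[0].chrom,
            "start": min(pk.start for pk in cl),
            "end": max(pk.end for pk in cl),
            "signal": signal,
            "summit": strongest.midpoint,
            "n_peaks": len(cl),
        })
    df = pd.DataFrame(rows)
    if df.empty:
        df["rank"] = df["is_hotspot"] = []
        return df
    df = df.sort_values("signal", ascending=False, kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)

    s = np.sort(df["signal"].to_numpy())  # ascending ranked curve
    n = len(s)
    if n == 1:
        df["is_hotspot"] = True
        return df
    x = np.arange(n) / (n - 1)
    y = (s - s[0]) / (s[-1] - s[0]) if s[-1] > s[0] else np.zeros(n)
    cut_idx = int(np.argmin(y - x))  # deepest point below the unit diagonal
    cutoff_signal = s[cut_idx]
    df["is_hotspot"] = df["signal"] > cutoff_signal
    return df


def hotspot_summits(df: pd.DataFrame) -> FeatureSet:
    """Point intervals at the summits of called hotspots."""
    out = []
    for _, row in df[df["is_hotspot"]].iterrows():
        out.append(Interval(row["chrom"], int(row["summit"]), int(row["summit"]) + 1,
                            score=float(row["signal"])))
    return FeatureSet(out)


# -- change-vs-signal correlation -------------------------------------------


def change_vs_signal_correlation(
    delta_values: np.ndarray,
    signals: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Pearson and Spearman correlation of per-feature change with each signal.

    Missing features are dropped pairwise; tracks with fewer than 3 complete
    pairs report NaN coefficients.
    """
    delta = np.asarray(delta_values, dtype=float)
    rows = []
    for name, sig in signals.items():
        sig = np.asarray(sig, dtype=float)
        if len(sig) != len(delta):
            raise ValueError(f"signal {name!r} length mismatch")
        ok = np.isfinite(delta) & np.isfinite(sig)
        n = int(ok.sum())
        if n < 3:
            rows.append({"signal": name, "pearson": np.nan, "spearman": np.nan, "n": n})
            continue
        pear = float(sps.pearsonr(delta[ok], sig[ok]).statistic)
        spear = float(sps.spearmanr(delta[ok], sig[ok]).statistic)
        rows.append({"signal": name, "pearson": pear, "spearman": spear, "n": n})
    return pd.DataFrame(rows)
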