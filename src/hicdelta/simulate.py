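"""Synthetic Hi-C experiment generator with known ground truth.

Emulates the structures the analysis pipeline measures — power-law distance
decay, a two-compartment checkerboard, TAD blocks, focal loops of distinct
protein classes, anchor-tethered stripes, and clustered binding hotspots —
as a multiplicative intensity model, then draws Poisson counts at a chosen
sequencing depth. Every embedded feature carries its own perturbation
factor, so an in-silico depletion experiment is a pair of matrices sampled
from the same truth with factors switched on for the treated condition.

The default configuration is the package's in-silico analogue of an acute
RNA-polymerase-II depletion: polymerase-binding hotspot contacts and
Pol II-only loops and stripes weaken (factors < 1) while compartments,
domains, and CTCF/cohesin loops are untouched (factors = 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .contacts import ContactMatrix
from .grid import FeatureSet, GenomeGrid, Interval, IntervalPair, Track

__all__ = [
    "SimulationConfig",
    "LoopSpec",
    "StripeSpec",
    "SyntheticTruth",
    "SimulatedExperiment",
    "build_truth",
    "build_intensity",
    "sample_counts",
    "make_experiment",
]

LOOP_CLASSES = ("ctcf_cohesin", "pol2_only", "both")


@dataclass
class SimulationConfig:
    """All generator knobs, with documented defaults.

    Distances/sizes are in bp unless the name says bins. ``depth`` is the
    expected number of cis contacts per condition; conditions are matched by
    construction. ``f_*`` are multiplicative perturbation factors applied to
    the treated condition only (1 = unperturbed).
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 20_000_000, "chr2": 20_000_000}
    )
    bin_size: int = 25_000
    depth: int = 2_000_000
    seed: int = 0

    # decay and structure amplitudes (all boosts >= 1 pre-perturbation)
    gamma: float = 1.0            # cis power-law decay exponent
    alpha: float = 0.15           # compartment checkerboard amplitude
    beta: float = 1.6             # intra-domain boost
    lam: float = 2.5              # focal loop boost (3x3 kernel)
    sigma: float = 1.5            # stripe boost
    kappa: float = 1.4            # hotspot pairwise boost (3x3 kernel)
    rho: float = 1.0              # promoter-pair boost (active+CTCF stratum)

    # feature counts / geometry
    compartment_block_bins: tuple[int, int] = (20, 60)
    domain_size_bins: tuple[int, int] = (8, 32)
    frac_active_domains: float = 0.45
    loops_per_class: dict[str, int] = field(
        default_factory=lambda: {"ctcf_cohesin": 20, "pol2_only": 20, "both": 10}
    )
    n_hotspot_clusters: int = 15          # per chromosome
    peaks_per_cluster: tuple[int, int] = (3, 5)
    cluster_span_bp: int = 6_000          # peaks of one cluster fall in this span
    n_background_peaks: int = 40          # weak scattered peaks per chromosome
    n_stripes: int = 8                    # per chromosome
    stripe_extent_bp: int = 200_000
    n_inactive_promoters: int = 20        # per chromosome, beyond anchor promoters
    hotspot_max_sep_bp: int = 10_000_000

    # perturbation factors (treated condition)
    f_compartment: float = 1.0
    f_domain: float = 1.0
    f_loop: dict[str, float] = field(
        default_factory=lambda: {"ctcf_cohesin": 1.0, "pol2_only": 0.9, "both": 1.0}
    )
    f_stripe: float = 0.9
    f_hotspot: float = 0.874
    f_promoter_pair: float = 1.0

    overdispersion: float = 0.0   # 0 = Poisson; > 0 adds gamma mixing

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        for name in ("alpha",):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("beta", "lam", "sigma", "kappa", "rho"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1 (boosts pre-perturbation)")
        for cls in self.loops_per_class:
            if cls not in LOOP_CLASSES:
                raise ValueError(f"unknown loop class {cls!r}")

    def grid(self) -> GenomeGrid:
        names = tuple(self.chrom_lengths)
        return GenomeGrid(names, tuple(self.chrom_lengths[c] for c in names), self.bin_size)


@dataclass
class LoopSpec:
    chrom: str
    bin_a: int
    bin_b: int
    class_label: str
    boost: float
    factor: float = 1.0


@dataclass
class StripeSpec:
    chrom: str
    anchor_bin: int
    extent_bins: int
    boost: float
    factor: float = 1.0


@dataclass
class SyntheticTruth:
    """Catalog of embedded features and their perturbation factors."""

    grid: GenomeGrid
    gamma: float
    alpha: float
    beta: float
    kappa: float
    rho: float
    f_compartment: float
    f_domain: float
    f_hotspot: float
    f_promoter_pair: float
    compartments: dict[str, np.ndarray]      # +1 (A) / -1 (B) per bin
    domains: FeatureSet                      # label 'active'/'inactive'
    loops: list[LoopSpec]
    stripes: list[StripeSpec]
    hotspot_peaks: FeatureSet                # label = cluster id, score = signal
    hotspot_summits: FeatureSet              # point intervals, score = signal
    promoters: FeatureSet                    # score = activity, label 'ctcf'/'noctcf'
    boosted_promoter_bins: dict[str, list[int]] = field(default_factory=dict)

    @property
    def boundaries(self) -> FeatureSet:
        """One-bin boundary intervals between consecutive domains."""
        out = []
        by_chrom: dict[str, list[Interval]] = {}
        for d in self.domains:
            by_chrom.setdefault(d.chrom, []).append(d)
        bs = self.grid.bin_size
        for chrom, ds in by_chrom.items():
            ds = sorted(ds, key=lambda x: x.start)
            for prev, nxt in zip(ds, ds[1:]):
                if nxt.start > prev.end:
                    out.append(Interval(chrom, prev.end, nxt.start,
                                        label="boundary"))
                else:
                    b0 = (prev.end // bs) * bs
                    out.append(Interval(chrom, b0, b0 + bs, label="boundary"))
        return FeatureSet(out)

    def loop_pairs(self, classes: tuple[str, ...] | None = None) -> FeatureSet:
        """Loops as canonical interval pairs (anchors = one bin each)."""
        bs = self.grid.bin_size
        pairs = []
        for lp in self.loops:
            if classes is not None and lp.class_label not in classes:
                continue
            a = Interval(lp.chrom, lp.bin_a * bs, (lp.bin_a + 1) * bs)
            b = Interval(lp.chrom, lp.bin_b * bs, (lp.bin_b + 1) * bs)
            pairs.append(IntervalPair(a, b, label=lp.class_label))
        return FeatureSet(pairs)

    def to_dict(self) -> dict:
        return {
            "chrom_lengths": dict(zip(self.grid.chrom_names, self.grid.chrom_lengths)),
            "bin_size": self.grid.bin_size,
            "gamma": self.gamma,
            "alpha": self.alpha,
            "beta": self.beta,
            "kappa": self.kappa,
            "rho": self.rho,
            "f_compartment": self.f_compartment,
            "f_domain": self.f_domain,
            "f_hotspot": self.f_hotspot,
            "f_promoter_pair": self.f_promoter_pair,
            "compartments": {c: v.tolist() for c, v in self.compartments.items()},
            "domains": [[d.chrom, d.start, d.end, d.label] for d in self.domains],
            "loops": [asdict(lp) for lp in self.loops],
            "stripes": [asdict(sp) for sp in self.stripes],
            "hotspot_peaks": [[p.chrom, p.start, p.end, p.score, p.label]
                              for p in self.hotspot_peaks],
            "hotspot_summits": [[p.chrom, p.start, p.end, p.score]
                                for p in self.hotspot_summits],
            "promoters": [[p.chrom, p.start, p.end, p.score, p.label]
                          for p in self.promoters],
            "boosted_promoter_bins": self.boosted_promoter_bins,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        names = tuple(d["chrom_lengths"])
        grid = GenomeGrid(names, tuple(d["chrom_lengths"][c] for c in names),
                          d["bin_size"])
        return cls(
            grid=grid,
            gamma=d["gamma"], alpha=d["alpha"], beta=d["beta"], kappa=d["kappa"],
            rho=d["rho"], f_compartment=d["f_compartment"], f_domain=d["f_domain"],
            f_hotspot=d["f_hotspot"], f_promoter_pair=d["f_promoter_pair"],
            compartments={c: np.asarray(v, dtype=np.int8)
                          for c, v in d["compartments"].items()},
            domains=FeatureSet(Interval(c, s, e, label=l) for c, s, e, l in d["domains"]),
            loops=[LoopSpec(**lp) for lp in d["loops"]],
            stripes=[StripeSpec(**sp) for sp in d["stripes"]],
            hotspot_peaks=FeatureSet(Interval(c, s, e, score=sc, label=l)
                                     for c, s, e, sc, l in d["hotspot_peaks"]),
            hotspot_summits=FeatureSet(Interval(c, s, e, score=sc)
                                       for c, s, e, sc in d["hotspot_summits"]),
            promoters=FeatureSet(Interval(c, s, e, score=sc, label=l)
                                 for c, s, e, sc, l in d["promoters"]),
            boosted_promoter_bins={c: list(v)
                                   for c, v in d["boosted_promoter_bins"].items()},
        )

    @classmethod
    def read_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    truth: SyntheticTruth
    untreated: ContactMatrix
    treated: ContactMatrix
    tracks: dict[str, Track]
    peak_sets: dict[str, FeatureSet]


# -- truth construction -----------------------------------------------------


def build_truth(config: SimulationConfig, rng: np.random.Generator) -> SyntheticTruth:
    """Lay out compartments, domains, loops, stripes, hotspots, promoters."""
    grid = config.grid()
    bs = grid.bin_size
    compartments: dict[str, np.ndarray] = {}
    domains: list[Interval] = []
    loops: list[LoopSpec] = []
    stripes: list[StripeSpec] = []
    hotspot_peaks: list[Interval] = []
    hotspot_summits: list[Interval] = []
    promoters: list[Interval] = []
    boosted_bins: dict[str, list[int]] = {}

    per_class = dict(config.loops_per_class)
    for chrom in grid.chrom_names:
        n = grid.n_bins(chrom)
        # compartment checkerboard: alternating A/B blocks of random size
        labels = np.empty(n, dtype=np.int8)
        pos, lab = 0, 1 if rng.random() < 0.5 else -1
        while pos < n:
            blk = int(rng.integers(*config.compartment_block_bins, endpoint=True))
            labels[pos : pos + blk] = lab
            pos += blk
            lab = -lab
        compartments[chrom] = labels

        # domains tile the chromosome with one-bin boundary gaps
        chrom_domains: list[Interval] = []
        pos = 2
        while pos + config.domain_size_bins[0] + 2 < n:
            size = int(rng.integers(*config.domain_size_bins, endpoint=True))
            end = min(pos + size, n - 2)
            if end - pos >= config.domain_size_bins[0]:
                active = rng.random() < config.frac_active_domains
                chrom_domains.append(
                    Interval(chrom, pos * bs, end * bs,
                             label="active" if active else "inactive")
                )
            pos = end + 1
        domains.extend(chrom_domains)

        # corner loops on domains; pol2-type classes prefer active domains
        active_doms = [d for d in chrom_domains if d.label == "active"]
        other_doms = [d for d in chrom_domains if d.label == "inactive"]
        rng.shuffle(active_doms)
        rng.shuffle(other_doms)
        n_chroms = len(grid.chrom_names)
        for cls in LOOP_CLASSES:
            want = per_class.get(cls, 0) // n_chroms
            pool = active_doms if cls in ("pol2_only", "both") else other_doms
            for _ in range(want):
                if not pool:
                    break
                d = pool.pop()
                ba, bb = d.start // bs, d.end // bs - 1
                loops.append(LoopSpec(chrom, ba, bb, cls, config.lam,
                                      config.f_loop.get(cls, 1.0)))

        # stripes anchored inside active domains (super-enhancer-like)
        extent_bins = config.stripe_extent_bp // bs
        stripe_doms = [d for d in chrom_domains if d.label == "active"]
        rng.shuffle(stripe_doms)
        for d in stripe_doms[: config.n_stripes]:
            anchor = int(rng.integers(d.start // bs + 1, max(d.start // bs + 2, d.end // bs - 1)))
            if extent_bins < anchor < n - extent_bins:
                stripes.append(StripeSpec(chrom, anchor, extent_bins,
                                          config.sigma, config.f_stripe))

        # clustered binding hotspots: tight, well-separated clusters of strong
        # peaks (the boosted structures) over a sea of weak scattered peaks
        margin = 21  # keep the 500-kb pile-up window inside the chromosome
        if config.n_hotspot_clusters > 0:
            centers = np.sort(
                rng.choice(np.arange(margin, n - margin),
                           size=config.n_hotspot_clusters, replace=False)
            )
            # enforce >= 6 bins between cluster centers
            keep = [centers[0]]
            for c in centers[1:]:
                if c - keep[-1] >= 6:
                    keep.append(c)
            for ci, center in enumerate(keep):
                npk = int(rng.integers(*config.peaks_per_cluster, endpoint=True))
                base_bp = int(center) * bs
                best: Interval | None = None
                for _ in range(npk):
                    offset = int(rng.integers(0, max(1, config.cluster_span_bp - 500)))
                    start = base_bp + offset
                    signal = float(rng.lognormal(mean=3.5, sigma=0.4))
                    pk = Interval(chrom, start, start + 500, score=signal,
                                  label=f"{chrom}_cluster{ci}")
                    hotspot_peaks.append(pk)
                    if best is None or pk.score > best.score:
                        best = pk
                hotspot_summits.append(
                    Interval(chrom, best.midpoint, best.midpoint + 1, score=best.score)
                )
        for _ in range(config.n_background_peaks):
            start = int(rng.integers(0, (n - 1) * bs))
            hotspot_peaks.append(
                Interval(chrom, start, start + 500,
                         score=float(rng.lognormal(mean=0.5, sigma=0.5)),
                         label="background")
            )

        # promoters: one at each pol2-type loop anchor (active), plus silent ones
        chrom_boosted: list[int] = []
        for lp in loops:
            if lp.chrom != chrom or lp.class_label not in ("pol2_only", "both"):
                continue
            for b in (lp.bin_a, lp.bin_b):
                has_ctcf = lp.class_label == "both"
                promoters.append(
                    Interval(chrom, b * bs + bs // 2, b * bs + bs // 2 + 1000,
                             score=float(rng.lognormal(2.0, 0.5)),
                             label="ctcf" if has_ctcf else "noctcf")
                )
                if has_ctcf:
                    chrom_boosted.append(b)
        for _ in range(config.n_inactive_promoters):
            b = int(rng.integers(2, n - 2))
            promoters.append(
                Interval(chrom, b * bs + bs // 2, b * bs + bs // 2 + 1000,
                         score=float(rng.lognormal(-1.0, 0.5)), label="noctcf")
            )
        if config.rho > 1.0 or config.f_promoter_pair != 1.0:
            boosted_bins[chrom] = sorted(set(chrom_boosted))

    return SyntheticTruth(
        grid=grid,
        gamma=config.gamma, alpha=config.alpha, beta=config.beta,
        kappa=config.kappa, rho=config.rho,
        f_compartment=config.f_compartment, f_domain=config.f_domain,
        f_hotspot=config.f_hotspot, f_promoter_pair=config.f_promoter_pair,
        compartments=compartments,
        domains=FeatureSet(domains),
        loops=loops,
        stripes=stripes,
        hotspot_peaks=FeatureSet(hotspot_peaks),
        hotspot_summits=FeatureSet(hotspot_summits),
        promoters=FeatureSet(promoters),
        boosted_promoter_bins=boosted_bins,
    )


# -- forward model ----------------------------------------------------------


def _apply_kernel(mu: np.ndarray, i: int, j: int, factor: float, half: int = 1) -> None:
    """Multiply a (2*half+1)^2 block at (i, j) and its mirror by ``factor``."""
    n = mu.shape[0]
    i0, i1 = max(0, i - half), min(n, i + half + 1)
    j0, j1 = max(0, j - half), min(n, j + half + 1)
    mu[i0:i1, j0:j1] *= factor
    if i != j:
        mu[j0:j1, i0:i1] *= factor


def build_intensity(truth: SyntheticTruth, chrom: str, perturbed: bool = False,
                    base: float = 1.0) -> np.ndarray:
    """Dense intensity mu(i, j) for one chromosome.

    mu = base * max(d, 1)^(-gamma) * compartment * domain * loop * stripe *
    hotspot (* promoter-pair), all multiplicative; the compartment
    checkerboard is renormalized per diagonal so it preserves the mean
    intensity at every distance exactly. ``perturbed`` switches each
    feature's factor on (treated condition).
    """
    grid = truth.grid
    n = grid.n_bins(chrom)
    bs = grid.bin_size
    idx = np.arange(n)
    d = np.abs(np.subtract.outer(idx, idx))
    mu = base * np.maximum(d, 1).astype(float) ** (-truth.gamma)

    # compartments: same-label boost, different-label depletion, mean-preserving
    alpha = truth.alpha * (truth.f_compartment if perturbed else 1.0)
    if alpha > 0:
        labels = truth.compartments[chrom].astype(float)
        same = np.outer(labels, labels) > 0
        c = np.where(same, 1.0 + alpha, 1.0 - alpha)
        for off in range(n):
            diag = np.diagonal(c, offset=off)  # live view: copy before writing
            m = diag.mean()
            if m > 0:
                nd = diag / m
                sl = (idx[: n - off], idx[: n - off] + off)
                c[sl] = nd
                if off:
                    c[(sl[1], sl[0])] = nd
        mu *= c

    # domains: block boost on both-bins-inside cells
    f_dom = truth.f_domain if perturbed else 1.0
    for dom in truth.domains.by_chrom(chrom):
        b0, b1 = dom.start // bs, dom.end // bs
        mu[b0:b1, b0:b1] *= truth.beta * f_dom

    # loops: 3x3 kernel at anchor-bin intersections
    for lp in truth.loops:
        if lp.chrom != chrom:
            continue
        f = lp.factor if perturbed else 1.0
        _apply_kernel(mu, lp.bin_a, lp.bin_b, lp.boost * f)

    # stripes: band from the anchor out to the extent, both orientations
    for sp in truth.stripes:
        if sp.chrom != chrom:
            continue
        f = sp.factor if perturbed else 1.0
        a = sp.anchor_bin
        j0, j1 = max(0, a - sp.extent_bins), min(n, a + sp.extent_bins + 1)
        row = np.ones(n)
        row[j0:j1] = sp.boost * f
        row[a] = 1.0
        mu[a, :] *= row
        mu[:, a] *= row

    # hotspot pairs: 3x3 kernel at summit-bin intersections within max sep
    f_hot = truth.f_hotspot if perturbed else 1.0
    summits = [s.midpoint // bs for s in truth.hotspot_summits.by_chrom(chrom)]
    max_sep = 10_000_000 // bs
    for ai in range(len(summits)):
        for bi in range(ai + 1, len(summits)):
            sa, sb = summits[ai], summits[bi]
            if 3 < abs(sb - sa) <= max_sep:
                _apply_kernel(mu, min(sa, sb), max(sa, sb), truth.kappa * f_hot)

    # promoter pairs (optional stratum-specific boost)
    if truth.rho > 1.0 and chrom in truth.boosted_promoter_bins:
        f_pp = truth.f_promoter_pair if perturbed else 1.0
        bins = truth.boosted_promoter_bins[chrom]
        for ai in range(len(bins)):
            for bi in range(ai + 1, len(bins)):
                if abs(bins[bi] - bins[ai]) > 3:
                    _apply_kernel(mu, min(bins[ai], bins[bi]),
                                  max(bins[ai], bins[bi]), truth.rho * f_pp)

    return (mu + mu.T) / 2.0


def sample_counts(
    grid: GenomeGrid,
    intensity: Mapping[str, np.ndarray],
    depth: int,
    seed: int,
    overdispersion: float = 0.0,
) -> ContactMatrix:
    """Poisson counts per upper-triangular cell, expected total = ``depth``.

    Rates are the intensities rescaled so the genome-wide upper-triangular
    sum equals ``depth``. ``overdispersion`` > 0 mixes the rates with a
    gamma variate of that squared coefficient of variation (negative
    binomial counts). Fixed seed reproduces exactly.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    chroms = list(grid.chrom_names)
    total = sum(np.triu(intensity[c]).sum() for c in chroms)
    rng = np.random.default_rng(seed)
    data = {}
    for chrom in chroms:
        mu = np.triu(np.asarray(intensity[chrom], dtype=float)) * (depth / total)
        if overdispersion > 0:
            shape = 1.0 / overdispersion
            mu = mu * rng.gamma(shape, 1.0 / shape, size=mu.shape)
        counts = rng.poisson(mu).astype(float)
        data[chrom] = counts + np.triu(counts, 1).T
    return ContactMatrix(grid, data, "count")


def make_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Run the full in-silico depletion experiment.

    Returns matched-depth untreated/treated count matrices (the treated one
    sampled from the perturbed intensity), the ground-truth catalog, signal
    tracks (nascent-transcription-like, polymerase ChIP-like, and a
    compartment orientation proxy), and the ChIP peak sets used for loop
    classification.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    rng_truth = np.random.default_rng(seeds[0])
    truth = build_truth(config, rng_truth)
    grid = truth.grid

    mu_u = {c: build_intensity(truth, c, perturbed=False) for c in grid.chrom_names}
    mu_t = {c: build_intensity(truth, c, perturbed=True) for c in grid.chrom_names}
    untreated = sample_counts(grid, mu_u, config.depth, seeds[1], config.overdispersion)
    treated = sample_counts(grid, mu_t, config.depth, seeds[2], config.overdispersion)

    rng_tracks = np.random.default_rng(seeds[3])
    n = grid.total_bins
    bs = grid.bin_size

    # nascent-transcription-like signal: high over active domains
    gro = rng_tracks.lognormal(-1.5, 0.4, size=n)
    for dom in truth.domains:
        if dom.label != "active":
            continue
        sl = grid.chrom_slice(dom.chrom)
        b0, b1 = dom.start // bs, dom.end // bs
        gro[sl.start + b0 : sl.start + b1] += rng_tracks.lognormal(1.5, 0.3, size=b1 - b0)
    groseq = Track(grid, gro, np.ones(n, dtype=bool))

    # polymerase-ChIP-like signal: peak signal summed into bins
    chip = np.zeros(n)
    for pk in truth.hotspot_peaks:
        chip[grid.bin_index(pk.chrom, pk.midpoint)] += pk.score
    chip += rng_tracks.lognormal(-2.0, 0.3, size=n)
    chip_track = Track(grid, chip, np.ones(n, dtype=bool))

    # compartment orientation proxy (GC-like): noisy A-ness
    orient = np.concatenate([truth.compartments[c].astype(float)
                             for c in grid.chrom_names])
    orient = orient + rng_tracks.normal(0.0, 0.3, size=n)
    orientation = Track(grid, orient, np.ones(n, dtype=bool))

    # ChIP peak sets for loop classification
    def anchors_of(classes: tuple[str, ...]) -> FeatureSet:
        out = []
        for lp in truth.loops:
            if lp.class_label in classes:
                for b in (lp.bin_a, lp.bin_b):
                    mid = b * bs + bs // 2
                    out.append(Interval(lp.chrom, mid - 250, mid + 250, score=1.0))
        return FeatureSet(out)

    pol2_peaks = list(anchors_of(("pol2_only", "both")))
    for pk in truth.hotspot_peaks:
        pol2_peaks.append(pk)
    peak_sets = {
        "pol2": FeatureSet(pol2_peaks),
        "ctcf": anchors_of(("ctcf_cohesin", "both")),
        "cohesin": anchors_of(("ctcf_cohesin", "both")),
    }

    return SimulatedExperiment(
        config=config,
        truth=truth,
        untreated=untreated,
        treated=treated,
        tracks={"groseq": groseq, "chip": chip_track, "orientation": orientation},
        peak_sets=peak_sets,
    )
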