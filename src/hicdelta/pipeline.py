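"""End-to-end in-silico depletion experiment: simulate, analyze, recover.

``simulate_to_dir`` materializes a synthetic experiment as the standard
text formats (HiC-Pro triplet matrices, BED/BEDPE/bedGraph catalogs, a
truth JSON, and a manifest with seeds and a parameter hash).
``analyze_experiment`` runs the full analysis sequence — depth matching,
balancing, O/E, compartment saddle, insulation, meta-domain pile-up,
hotspot PE-SCAn, loop-class change statistics, length/transcription
trends, stripe decay, promoter-pair aggregates — and returns a
machine-readable report. ``recover`` compares the report's recovered
changes with the generator's injected factors.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import aggregate, compartments, contacts, insulation, loops as loop_ops
from .grid import (FeatureSet, GenomeGrid, Interval, Track, read_chrom_sizes,
                   read_intervals, read_interval_pairs, track_from_bedgraph,
                   write_bedgraph, write_chrom_sizes, write_intervals,
                   write_interval_pairs)
from .simulate import (SimulatedExperiment, SimulationConfig, SyntheticTruth,
                       make_experiment)

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisParams",
    "load_config",
    "simulate_to_dir",
    "load_experiment",
    "analyze_experiment",
    "analyze_dir",
    "recover",
]


@dataclass
class AnalysisParams:
    """Analysis-stage knobs; defaults match the package's documented choices."""

    insulation_window_bp: int = 250_000
    saddle_quantiles: int = 5
    saddle_min_dist_bins: int = 10
    meta_domain_out_size: int = 90
    apa_half_window_bins: int = 3
    apa_mode: str = "center_3x3_mean"
    pescan_window_bp: int = 500_000
    pescan_max_sep_bp: int = 10_000_000
    stripe_max_dist_bp: int = 200_000
    promoter_window_bp: int = 400_000
    loop_length_split_bp: int = 250_000
    min_diag: int = 2
    ice_tol: float = 1e-6
    seed: int = 0


_CONFIG_SECTIONS = {"version", "simulation", "analysis"}


def load_config(path: str | Path) -> tuple[SimulationConfig, AnalysisParams]:
    """Parse a YAML experiment config; unknown keys raise a schema error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    bad = set(raw) - _CONFIG_SECTIONS
    if bad:
        raise ValueError(f"unknown config section(s): {sorted(bad)}")
    sim_raw = raw.get("simulation", {}) or {}
    ana_raw = raw.get("analysis", {}) or {}
    sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    ana_fields = {f.name for f in dataclasses.fields(AnalysisParams)}
    bad = set(sim_raw) - sim_fields
    if bad:
        raise ValueError(f"unknown simulation key(s): {sorted(bad)}")
    bad = set(ana_raw) - ana_fields
    if bad:
        raise ValueError(f"unknown analysis key(s): {sorted(bad)}")
    if "loops_per_class" in sim_raw:
        sim_raw["loops_per_class"] = dict(sim_raw["loops_per_class"])
    if "f_loop" in sim_raw:
        sim_raw["f_loop"] = dict(sim_raw["f_loop"])
    if "chrom_lengths" in sim_raw:
        sim_raw["chrom_lengths"] = dict(sim_raw["chrom_lengths"])
    for tup in ("compartment_block_bins", "domain_size_bins", "peaks_per_cluster"):
        if tup in sim_raw:
            sim_raw[tup] = tuple(sim_raw[tup])
    return SimulationConfig(**sim_raw), AnalysisParams(**ana_raw)


def _config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# -- simulate ---------------------------------------------------------------


def simulate_to_dir(config: SimulationConfig, out_dir: str | Path) -> SimulatedExperiment:
    """Run the generator and write every artifact as text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exp = make_experiment(config)
    grid = exp.truth.grid
    write_chrom_sizes(grid, out / "chrom.sizes")
    for name, matrix in (("untreated", exp.untreated), ("treated", exp.treated)):
        contacts.write_matrix(matrix, out / f"{name}.matrix", out / f"{name}_abs.bed")
    write_intervals(exp.truth.domains, out / "domains.bed")
    write_intervals(exp.truth.boundaries, out / "boundaries.bed")
    write_interval_pairs(exp.truth.loop_pairs(), out / "loops.bedpe")
    write_intervals(exp.truth.hotspot_peaks, out / "hotspot_peaks.bed")
    write_intervals(
        FeatureSet(Interval(sp.chrom, sp.anchor_bin * grid.bin_size,
                            (sp.anchor_bin + 1) * grid.bin_size, label="stripe")
                   for sp in exp.truth.stripes),
        out / "se_targets.bed")
    write_intervals(exp.truth.promoters, out / "promoters.bed")
    for name, pk in exp.peak_sets.items():
        write_intervals(pk, out / f"peaks_{name}.bed")
    for name, tr in exp.tracks.items():
        write_bedgraph(tr, out / f"{name}.bedgraph")
    exp.truth.write_json(out / "truth.json")
    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return exp


def load_experiment(exp_dir: str | Path) -> SimulatedExperiment:
    """Reconstruct a simulated experiment from its directory."""
    d = Path(exp_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    cfg = manifest["config"]
    for tup in ("compartment_block_bins", "domain_size_bins", "peaks_per_cluster"):
        cfg[tup] = tuple(cfg[tup])
    config = SimulationConfig(**cfg)
    truth = SyntheticTruth.read_json(d / "truth.json")
    grid = truth.grid
    untreated = contacts.read_matrix(d / "untreated.matrix", d / "untreated_abs.bed", grid)
    treated = contacts.read_matrix(d / "treated.matrix", d / "treated_abs.bed", grid)
    tracks = {name: track_from_bedgraph(d / f"{name}.bedgraph", grid)
              for name in ("groseq", "chip", "orientation")}
    peak_sets = {name: read_intervals(d / f"peaks_{name}.bed", grid)
                 for name in ("pol2", "ctcf", "cohesin")}
    return SimulatedExperiment(config, truth, untreated, treated, tracks, peak_sets)


# -- analyze ----------------------------------------------------------------


def _prepare_condition(matrix, params: AnalysisParams):
    """Balance and O/E-transform one depth-matched count matrix."""
    balanced, weights = contacts.ice_balance(matrix, tol=params.ice_tol)
    profile = contacts.expected_by_distance(balanced, min_diag=params.min_diag)
    oe = contacts.observed_over_expected(balanced, profile)
    return balanced, oe


def analyze_experiment(exp: SimulatedExperiment,
                       params: AnalysisParams | None = None) -> dict:
    """Full analysis of an untreated/treated pair; returns the report dict."""
    params = params or AnalysisParams()
    truth = exp.truth
    grid = truth.grid
    report: dict = {"params": dataclasses.asdict(params),
                    "config_hash": _config_hash(exp.config)}

    # 1. sequencing-depth matching
    tot_u = int(round(exp.untreated.total_count))
    tot_t = int(round(exp.treated.total_count))
    target = min(tot_u, tot_t)
    mat_u = contacts.downsample(exp.untreated, target, seed=params.seed)
    mat_t = contacts.downsample(exp.treated, target, seed=params.seed + 1)
    report["depth"] = {"untreated": tot_u, "treated": tot_t, "matched": target}

    # 2. balance + O/E (balanced for map-level analytics) and a raw
    # distance-normalized O/E (contact frequency over expected, no balancing)
    # for the pile-up quantities defined on contact frequency (see methods)
    bal_u, oe_u = _prepare_condition(mat_u, params)
    bal_t, oe_t = _prepare_condition(mat_t, params)
    oe_raw_u = contacts.observed_over_expected(
        mat_u, contacts.expected_by_distance(mat_u, min_diag=params.min_diag))
    oe_raw_t = contacts.observed_over_expected(
        mat_t, contacts.expected_by_distance(mat_t, min_diag=params.min_diag))

    # 3. compartments: PC1 (oriented by the provided proxy track) + saddle
    orientation = exp.tracks["orientation"]
    pc1_u = compartments.compartment_eigenvector(oe_u, orientation)
    pc1_t = compartments.compartment_eigenvector(oe_t, orientation)
    sad_u = compartments.saddle(oe_u, pc1_u, params.saddle_quantiles,
                                params.saddle_min_dist_bins)
    sad_t = compartments.saddle(oe_t, pc1_t, params.saddle_quantiles,
                                params.saddle_min_dist_bins)
    report["compartments"] = {
        "saddle_strength_untreated": sad_u.strength,
        "saddle_strength_treated": sad_t.strength,
        "strength_change_pct": 100.0 * (sad_t.strength - sad_u.strength) / sad_u.strength,
    }

    # 4. insulation at boundaries, stratified by CTCF occupancy
    ins_u = insulation.insulation_score(bal_u, params.insulation_window_bp)
    ins_t = insulation.insulation_score(bal_t, params.insulation_window_bp)
    ctcf_idx = loop_ops._overlap_index(exp.peak_sets["ctcf"])
    bound_ctcf, bound_no = [], []
    for b in truth.boundaries:
        near = loop_ops._overlaps(ctcf_idx, b.chrom, b.start - grid.bin_size,
                                  b.end + grid.bin_size)
        (bound_ctcf if near else bound_no).append(b)
    flank = params.insulation_window_bp
    report["insulation"] = {}
    for name, feats in (("ctcf_bound", FeatureSet(bound_ctcf)),
                        ("ctcf_unbound", FeatureSet(bound_no))):
        if len(feats) == 0:
            continue
        prof_u = insulation.average_profile_at(ins_u, feats, flank)
        prof_t = insulation.average_profile_at(ins_t, feats, flank)
        mid = len(prof_u) // 2
        report["insulation"][name] = {
            "n_boundaries": len(feats),
            "profile_untreated": prof_u.tolist(),
            "profile_treated": prof_t.tolist(),
            "boundary_score_untreated": float(prof_u[mid]),
            "boundary_score_treated": float(prof_t[mid]),
        }

    # 5. meta-domain pile-up and intra-domain enrichment (paired Wilcoxon)
    meta_u = insulation.meta_domain_pileup(oe_u, truth.domains,
                                           params.meta_domain_out_size)
    meta_t = insulation.meta_domain_pileup(oe_t, truth.domains,
                                           params.meta_domain_out_size)
    enr_u = insulation.intra_domain_enrichment(oe_u, truth.domains)
    enr_t = insulation.intra_domain_enrichment(oe_t, truth.domains)
    dom_change = loop_ops.percent_change(enr_u, enr_t, test="wilcoxon", paired=True)
    report["domains"] = {
        "n_domains": len(truth.domains),
        "meta_central_third_untreated": meta_u.stats.get("central_third_mean"),
        "meta_central_third_treated": meta_t.stats.get("central_third_mean"),
        "intra_tad_change": dataclasses.asdict(dom_change),
    }

    # 6. hotspot stitching + PE-SCAn change
    clusters = loop_ops.stitch_hotspots(exp.truth.hotspot_peaks)
    summits = loop_ops.hotspot_summits(clusters)
    if len(summits) < 2:  # tangent cutoff can be stringent on flat rankings
        summits = truth.hotspot_summits
    pes_u = aggregate.pe_scan(oe_raw_u, summits, params.pescan_window_bp,
                              params.pescan_max_sep_bp, seed=params.seed)
    pes_t = aggregate.pe_scan(oe_raw_t, summits, params.pescan_window_bp,
                              params.pescan_max_sep_bp, seed=params.seed)
    hot_change = loop_ops.percent_change(
        pes_u.stats["per_pair_center_3x3"], pes_t.stats["per_pair_center_3x3"],
        test="wilcoxon", paired=True)
    report["hotspots"] = {
        "n_clusters": int(len(clusters)),
        "n_hotspots": int(clusters["is_hotspot"].sum()) if len(clusters) else 0,
        "n_pairs": pes_u.n_features,
        "pescan_center_untreated": pes_u.stats["raw_center"],
        "pescan_center_treated": pes_t.stats["raw_center"],
        "background_center_enrichment": pes_u.stats.get("background_center_enrichment"),
        "contact_change": dataclasses.asdict(hot_change),
    }

    # 7. loop classification + per-class change statistics
    loop_pairs = truth.loop_pairs()
    cls = loop_ops.classify_loops(loop_pairs, exp.peak_sets)
    sel = {
        "pol2_only": (cls["pol2"] == "both") & (cls["ctcf"] == "none")
                     & (cls["cohesin"] == "none"),
        "ctcf_cohesin": (cls["ctcf"] == "both") & (cls["cohesin"] == "both")
                        & (cls["pol2"] == "none"),
        "both": (cls["pol2"] == "both") & (cls["ctcf"] == "both"),
    }
    vals_u = loop_ops.loop_strength(oe_u, loop_pairs, mode=params.apa_mode)
    vals_t = loop_ops.loop_strength(oe_t, loop_pairs, mode=params.apa_mode)
    report["loops"] = {"classes": {}}
    for name, mask in sel.items():
        m = mask.to_numpy()
        if m.sum() == 0:
            continue
        ch = loop_ops.percent_change(vals_u[m], vals_t[m], test="ttest", paired=True)
        report["loops"]["classes"][name] = dict(n=int(m.sum()),
                                                **dataclasses.asdict(ch))
    apa_u = aggregate.loop_apa(oe_u, loop_pairs, params.apa_half_window_bins)
    apa_t = aggregate.loop_apa(oe_t, loop_pairs, params.apa_half_window_bins)
    report["loops"]["apa_score_untreated"] = apa_u.stats.get("apa_score")
    report["loops"]["apa_score_treated"] = apa_t.stats.get("apa_score")

    # 8. loop-length trend (two-group summary at the 250-kb dichotomy)
    trend_u = loop_ops.loop_length_trend(loop_pairs, vals_u,
                                         length_split_bp=params.loop_length_split_bp)
    trend_t = loop_ops.loop_length_trend(loop_pairs, vals_t,
                                         length_split_bp=params.loop_length_split_bp)
    report["loop_length"] = {
        "short_change_pct": 100.0 * (trend_t["short_mean"] - trend_u["short_mean"])
        / trend_u["short_mean"] if trend_u["n_short"] else None,
        "long_change_pct": 100.0 * (trend_t["long_mean"] - trend_u["long_mean"])
        / trend_u["long_mean"] if trend_u["n_long"] else None,
        "n_short": trend_u["n_short"],
        "n_long": trend_u["n_long"],
    }

    # 9. transcription-ranked domains: change concentrated in the active group
    groups, scores = loop_ops.rank_domains_by_transcription(
        truth.domains, exp.tracks["groseq"], flank_bp=100_000, n_groups=2)
    report["transcription_groups"] = {}
    dom_loop_change: dict[str, float] = {}
    for g, gname in ((0, "top"), (1, "bottom")):
        gm = groups == g
        dom_bins = [d for d, m in zip(truth.domains, gm) if m]
        in_group = np.zeros(len(loop_pairs), dtype=bool)
        for k, p in enumerate(loop_pairs):
            for d in dom_bins:
                if d.chrom == p.chrom and d.start <= p.anchor_a.midpoint \
                        and p.anchor_b.midpoint <= d.end:
                    in_group[k] = True
                    break
        if in_group.sum() >= 2:
            ch = loop_ops.percent_change(vals_u[in_group], vals_t[in_group],
                                         test="ttest", paired=True)
            report["transcription_groups"][gname] = dict(
                n_domains=int(gm.sum()), n_loops=int(in_group.sum()),
                **dataclasses.asdict(ch))

    # 10. stripe decay curves
    se_targets = FeatureSet(
        Interval(sp.chrom, sp.anchor_bin * grid.bin_size,
                 (sp.anchor_bin + 1) * grid.bin_size)
        for sp in truth.stripes)
    stripe_change = None
    if len(se_targets):
        curve_u, stag_u = aggregate.stripe_profile(oe_raw_u, se_targets,
                                                   params.stripe_max_dist_bp, pileup=False)
        curve_t, stag_t = aggregate.stripe_profile(oe_raw_t, se_targets,
                                                   params.stripe_max_dist_bp, pileup=False)
        stripe_change = loop_ops.percent_change(stag_u.per_feature, stag_t.per_feature,
                                                test="wilcoxon", paired=True)
        report["stripes"] = {
            "n_targets": len(se_targets),
            "curve_untreated": curve_u.tolist(),
            "curve_treated": curve_t.tolist(),
            "mean_change": dataclasses.asdict(stripe_change),
        }

    # 11. change-vs-signal correlation at hotspot summits
    deltas, chip_sig, gro_sig = [], [], []
    chip_tr, gro_tr = exp.tracks["chip"], exp.tracks["groseq"]
    half = params.pescan_window_bp // grid.bin_size
    for s in summits:
        b = grid.local_bin(s.chrom, s.midpoint)
        others = [grid.local_bin(o.chrom, o.midpoint) for o in summits.by_chrom(s.chrom)
                  if o is not s]
        du, dt = [], []
        a_u, a_t = oe_raw_u.dense(s.chrom), oe_raw_t.dense(s.chrom)
        n = a_u.shape[0]
        for ob in others:
            if abs(ob - b) <= 2 * half or abs(ob - b) > params.pescan_max_sep_bp // grid.bin_size:
                continue
            i, j = min(b, ob), max(b, ob)
            if np.isfinite(a_u[i, j]) and np.isfinite(a_t[i, j]):
                du.append(a_u[i, j])
                dt.append(a_t[i, j])
        if du:
            deltas.append(float(np.mean(dt) - np.mean(du)))
            g = grid.bin_index(s.chrom, s.midpoint)
            chip_sig.append(chip_tr.values[g])
            gro_sig.append(gro_tr.values[g])
    if len(deltas) >= 3:
        corr = loop_ops.change_vs_signal_correlation(
            np.array(deltas), {"chip": np.array(chip_sig), "groseq": np.array(gro_sig)})
        report["change_vs_signal"] = corr.to_dict(orient="records")

    # 12. promoter-pair aggregates per stratum
    ppa_u = aggregate.promoter_pair_aggregate(
        oe_u, truth.promoters, ctcf_peaks=exp.peak_sets["ctcf"],
        window_bp=params.promoter_window_bp)
    ppa_t = aggregate.promoter_pair_aggregate(
        oe_t, truth.promoters, ctcf_peaks=exp.peak_sets["ctcf"],
        window_bp=params.promoter_window_bp)
    report["promoter_pairs"] = {}
    for name in sorted(set(ppa_u) & set(ppa_t)):
        report["promoter_pairs"][name] = {
            "n_pairs": ppa_u[name].n_features,
            "center_enrichment_untreated": ppa_u[name].stats["center_enrichment"],
            "center_enrichment_treated": ppa_t[name].stats["center_enrichment"],
        }

    return report


def analyze_dir(exp_dir: str | Path, params: AnalysisParams | None = None,
                out_path: str | Path | None = None) -> dict:
    """Load an experiment directory, analyze it, optionally write the report."""
    exp = load_experiment(exp_dir)
    report = analyze_experiment(exp, params)
    if out_path is not None:
        Path(out_path).write_text(json.dumps(_jsonable(report), indent=1))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


# -- recovery ---------------------------------------------------------------


def recover(report: dict, truth: SyntheticTruth, config: SimulationConfig) -> list[dict]:
    """Compare recovered percent changes against the injected factors.

    Raises when the report's config hash does not match the truth's
    configuration (mismatched experiment).
    """
    if report.get("config_hash") != _config_hash(config):
        raise ValueError("report and truth come from different experiments "
                         "(manifest hash mismatch)")
    rows = []

    def add(feature: str, injected_factor: float, recovered_pct):
        expected_pct = 100.0 * (injected_factor - 1.0)
        err = abs(recovered_pct - expected_pct) if recovered_pct is not None else None
        rows.append({"feature": feature, "injected_factor": injected_factor,
                     "expected_change_pct": expected_pct,
                     "recovered_change_pct": recovered_pct,
                     "abs_error_pct": err})

    add("hotspot_clusters", truth.f_hotspot,
        report["hotspots"]["contact_change"]["percent_change"])
    for cls_name, stats in report.get("loops", {}).get("classes", {}).items():
        f = config.f_loop.get(cls_name, 1.0)
        add(f"loops_{cls_name}", f, stats["percent_change"])
    add("domains", truth.f_domain,
        report["domains"]["intra_tad_change"]["percent_change"])
    if "stripes" in report:
        f_stripe = truth.stripes[0].factor if truth.stripes else 1.0
        add("stripes", f_stripe, report["stripes"]["mean_change"]["percent_change"])
    return rows
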