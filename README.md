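# hicdelta

Differential Hi-C contact-map analytics: quantify how an acute protein
depletion (an auxin-degron experiment) reshapes chromatin architecture at
every scale, from megabase A/B compartments down to single chromatin loops —
with a synthetic contact-map generator that provides ground truth for
calibrating and validating every statistic.

The package is aimed at chromatin-biology analysts who have binned Hi-C
contact matrices (HiC-Pro text triplets or 4DN `.pairs`) for an untreated and
a treated condition, plus the usual interval annotations (peaks as BED, loops
as BEDPE, binned signal as bedGraph), and want the standard battery of
perturbation readouts:

- **Matrix substrate** — pair-level filtering (same-fragment, PCR
  duplicates), binning, sequencing-depth matching by exact multivariate
  hypergeometric downsampling, ICE balancing, and distance-expected /
  observed-over-expected (O/E) transforms.
- **Compartments** — PC1 of the O/E row-correlation matrix per chromosome;
  saddle plots of mean O/E by PC1 quantile; compartmentalization strength
  `(AA + BB) / (AB + BA)` over the extreme-quantile corners.
- **Domains** — diamond-window insulation score
  `log2(diamond sum / chromosome mean)`, prominence-based boundary calling,
  rescaled meta-domain (meta-TAD) pile-ups, and per-domain intra-TAD O/E
  enrichment compared between conditions with a paired Wilcoxon test.
- **Pair-anchored pile-ups** — PE-SCAn around all cis pairs of binding-hotspot
  summits with a permuted-anchor background; loop APA with a
  center-over-corner score; promoter-pair aggregates stratified by distance
  class, activity tertile, and CTCF occupancy; stripe decay curves around
  super-enhancer-like targets.
- **Feature-level change statistics** — loop classification by ChIP-peak
  anchor occupancy (both / single / none per factor), the percent-change
  statistic `100·(mean_treated − mean_untreated) / mean_untreated` with t or
  Wilcoxon tests, loess loop-length trends, transcription-ranked domain
  groups, ROSE-style peak stitching with a tangent cutoff, and
  change-vs-signal correlations.
- **Synthetic generator** — a multiplicative intensity model
  `μ(i,j) = base·max(d,1)^(−γ) · compartment · domain · loop · stripe ·
  hotspot` with Poisson counts at a set sequencing depth, and a perturbation
  factor per feature so an entire degron experiment can be simulated with
  known truth and recovered end to end.

## Worked example

The default configuration is an in-silico Pol II depletion: binding-hotspot
contacts carry a 0.874 factor (a 12.6 % decrease), Pol II-only loops 0.9, and
super-enhancer stripes 0.9, while compartments, domains, and CTCF/cohesin
loops are untouched.

```python
from hicdelta import SimulationConfig, make_experiment, analyze_experiment

config = SimulationConfig(seed=0)          # two 20-Mb chromosomes, 25-kb bins,
experiment = make_experiment(config)       # 2e6 contacts per condition
report = analyze_experiment(experiment)

hot = report["hotspots"]["contact_change"]
loops = report["loops"]["classes"]
comp = report["compartments"]
dom = report["domains"]["intra_tad_change"]
print(f"hotspot-pair contact change: {hot['percent_change']:.1f}% "
      f"(n={report['hotspots']['n_pairs']} pairs, Wilcoxon p={hot['pvalue']:.2g})")
print(f"Pol II-only loop change:     {loops['pol2_only']['percent_change']:.1f}% "
      f"(t-test p={loops['pol2_only']['pvalue']:.2g})")
print(f"CTCF/cohesin loop change:    {loops['ctcf_cohesin']['percent_change']:.1f}% "
      f"(t-test p={loops['ctcf_cohesin']['pvalue']:.2g})")
print(f"saddle strength:             {comp['saddle_strength_untreated']:.2f} -> "
      f"{comp['saddle_strength_treated']:.2f}")
print(f"intra-TAD enrichment change: {dom['percent_change']:.2f}% "
      f"(Wilcoxon p={dom['pvalue']:.2g})")
```

prints, for seed 0:

```
hotspot-pair contact change: -11.4% (n=123 pairs, Wilcoxon p=0.017)
Pol II-only loop change:     -7.4% (t-test p=0.0012)
CTCF/cohesin loop change:    2.0% (t-test p=0.29)
saddle strength:             1.63 -> 1.62
intra-TAD enrichment change: -0.07% (Wilcoxon p=0.91)
```

Read: the injected hotspot depletion (−12.6 %) and Pol II-loop depletion
(−10 %) come back out at a single 2-million-contact sequencing depth within
sampling error, the untouched CTCF/cohesin loops test null, and the
large-scale readouts (compartment saddle strength, intra-TAD enrichment) are
statistically unchanged — the loop-level perturbation stays invisible at
domain and compartment scale.

The same pipeline runs from the shell:

```bash
hicdelta simulate --out exp/                 # write matrices + annotations
hicdelta analyze --experiment exp/ --out report.json
hicdelta recover --report report.json --experiment exp/
```

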