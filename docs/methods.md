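# Methods

## The problem

Acute degradation of an abundant chromatin protein (an auxin-degron
experiment) asks a scale question of Hi-C data: does the perturbation move
megabase-scale architecture (A/B compartments, TADs), or only local,
gene-scale structure (loops, binding-cluster contacts, stripes)? Answering it
requires a matched battery of statistics whose null behaviour is understood,
because the conclusion "compartments did not change" is only as strong as the
calibration of the test that failed to fire. hicdelta implements that battery
together with a generative model of the data it consumes, so every statistic
can be exercised against known truth.

## Contact-matrix model and normalization

Contacts live on a fixed genome grid (chromosome sizes plus one bin width;
0-based half-open coordinates everywhere, matching BED). Matrices are
per-chromosome, symmetric, cis-only; trans pairs are counted but not stored.
On disk the canonical dialect is the HiC-Pro sparse triplet (`.matrix` +
`_abs.bed`, 1-based upper-triangular ids); in memory the package keeps dense
symmetric arrays, which every downstream operator (diamond sums, quantile
blocks, window extraction) consumes directly.

*Depth matching.* Comparing conditions at different sequencing depths biases
every count-derived statistic, so the deeper matrix is downsampled to the
shallower total by a single multivariate-hypergeometric draw across all cells
jointly: totals are conserved exactly and cell expectations stay proportional.

*Balancing.* ICE iterative correction per chromosome: bins with a marginal
below 2 % of the median nonzero marginal are masked, then cells are repeatedly
divided by the product of their bins' mean-1-rescaled marginals until the
coefficient of variation of unmasked marginals falls below `tol` (default
1e-6, max 400 iterations; non-convergence warns). Weights `w` satisfy
`balanced(i,j) = count(i,j)·w_i·w_j`.

*Expected and O/E.* The expected profile is the per-chromosome mean value at
each bin distance over valid bin pairs; distances 0 and 1 are excluded by
default (ligation-artifact inflation) and distances with no valid pair are
missing, never zero. O/E divides each cell by the expected at its distance,
which makes per-distance means exactly 1 — the invariant the tests assert.

Two O/E flavours are used deliberately. Map-level analytics (compartments,
insulation, meta-domain pile-ups, intra-TAD enrichment, loop APA) run on
balanced O/E. Pile-ups that quantify *row-level* depletions — stripe decay
and hotspot PE-SCAn — run on depth-matched **count** O/E without balancing:
ICE equalizes marginals, so it partially re-inflates a depleted anchor row
and systematically attenuates exactly the effect those statistics measure
(in simulation, an injected −10 % stripe change reads as −3.9 % after
balancing but −9.3 % without it). Contact *frequency* normalized only to
distance is also what those quantities mean operationally.

## Compartments

PC1 is the leading eigenvector of the correlation matrix of O/E rows per
chromosome (undefined near-diagonal cells are treated as the neutral value 1;
constant rows are dropped; chromosomes with fewer than 10 usable bins are
skipped). The eigenvector sign is arbitrary, so it is oriented to correlate
positively with a caller-supplied track (GC content or any A-ness proxy).
The saddle ranks PC1 bins into `n` equal-size quantile groups (default 5,
remainder to the lowest groups) and averages cis O/E over bin pairs at
distance ≥ 10 bins for each group pair; strength is the ratio of the two
same-label extreme-corner cells to the two cross-label corners. Single corner
cells (not corner blocks) are used and reported as such.

## Domains and insulation

The insulation score of bin `b` is `log2` of the diamond sum
`Σ {(i,j): b−w ≤ i < b < j ≤ b+w}` over the chromosome-mean diamond sum
(window default 250 kb = 10 bins; bins within `w` of a chromosome end are
masked). Boundaries are prominent local minima: the mean of the flanking-
window maxima must exceed the minimum by `min_depth`; plateaus report their
leftmost bin. Boundary calling exists so synthetic runs are self-contained —
real analyses are expected to supply externally defined boundaries as BED.

Meta-domain pile-ups extend each domain window to three domain lengths
(centered), rescale it to a common square (default 90×90, central third = the
domain) by exact area-weighted resampling (the global mean is preserved;
missing cells are excluded with their weight), and average per pixel.
Intra-TAD enrichment is the per-domain mean O/E over in-domain cell pairs at
distance ≥ 2 bins; between conditions the per-domain values are compared with
a paired two-sided Wilcoxon test, mirroring how domain-level change is
conventionally reported.

## Pair-anchored pile-ups

All pile-up operators extract fixed windows centered on feature-pair pixels
and average per pixel with missing-cell exclusion; they are linear in the
matrix, and a uniform matrix yields a uniform pile-up — both are tested.

*PE-SCAn.* All cis pairs of point anchors (hotspot summits) separated by at
most 10 Mb form the pair set; the window is ±500 kb. Pairs closer than twice
the window are excluded so the window frame stays clear of the strongly
structured near-diagonal zone — without this the permuted background's
center-vs-frame enrichment is biased below 1 and the permutation null is
miscalibrated. The background redraws anchor positions uniformly per
chromosome (anchor count preserved, seed-controlled). Center enrichment is
the center pixel over the outermost one-pixel ring; the center-3×3 mean is
carried alongside and is the unit for between-condition change statistics,
because a single pixel of a 2-million-contact matrix is Poisson-noisy enough
to swamp a ten-percent effect.

*Loop APA.* O/E windows centered on loop pixels (anchor midpoints); loops
with anchor separation ≤ 2 half-windows are skipped and counted. The summary
is center pixel over the mean of the bottom-left (short-distance) 3×3 corner
block.

*Promoter pairs.* Cis promoter pairs are grouped by distance class (intra-TAD
200 kb–2 Mb, long-range 2–10 Mb), by activity tertile (rank tertiles over
the supplied activity score, remainder to the top slices: 10 promoters split
4/3/3), and by CTCF status (any peak within ±5 kb of the promoter midpoint);
each group gets a 400-kb-wide pile-up.

*Stripes.* For each point target the decay curve at distance `d` averages the
two cells connecting the target bin to bins `d` away, for `d` up to 200 kb;
targets near a chromosome end contribute their surviving side and are
flagged. The per-target band mean (one number per target) is the paired unit
for condition comparisons — curve points share targets and are strongly
correlated, so treating them as units makes the test anti-conservative.

## Feature-level statistics

Loop classification calls each factor `both`/`single`/`none` by ≥ 1 bp
anchor-peak overlap (anchors optionally padded); compound classes are pandas
predicates over the per-factor columns. Percent change is
`100·(mean_t − mean_u)/mean_u` with a paired or Welch standard error and
either Student's t (loop sets) or Wilcoxon (domain enrichments) — both
mirror the conventional reporting for those feature types. The loop-length
trend uses statsmodels lowess (tricube, locally linear, default span 0.3)
evaluated on a fixed length grid, with binned means as a smoothing-free
fallback and a ≤/> 250 kb two-group summary. ROSE-style stitching merges
peaks with gaps ≤ 12.5 kb, ranks clusters by total signal, min-max scales
both axes of the ranked curve and cuts where the curve is deepest below the
unit diagonal (the discrete slope-1 tangent point); ties resolve toward
fewer hotspots, and each cluster's summit is its strongest peak.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes — it
is not a polymer model and makes no claim about any real genome. Intensity
is multiplicative on a power-law background `max(d,1)^(−γ)`:

| parameter | meaning | default |
|---|---|---|
| γ | cis decay exponent | 1.0 |
| α | compartment checkerboard amplitude | 0.15 |
| β | intra-domain boost | 1.6 |
| λ | focal loop boost (3×3 kernel) | 2.5 |
| σ | stripe boost | 1.5 |
| κ | hotspot pairwise boost (3×3 kernel) | 1.4 |
| depth | expected cis contacts per condition | 2 × 10⁶ |
| bins | two 20-Mb chromosomes at 25 kb | 1600 bins |

The checkerboard factor (1+α same-label / 1−α cross-label) is renormalized
per diagonal so it preserves the mean intensity at every distance exactly —
O/E saddle corners then sit symmetrically around 1. Domains tile each
chromosome (8–32 bins) with one-bin boundary gaps; ~45 % are "active" and
carry the nascent-transcription-like track signal, the Pol II-type corner
loops, and the stripe anchors. Loops render as 3×3 kernels at domain-corner
anchor bins (single pixels would not survive downsampling); hotspot clusters
are tight groups of 3–5 strong peaks (span ≤ 6 kb so a 12.5-kb stitch keeps
them whole) over a sea of weak scattered peaks, which makes the ranked-signal
curve realistic for the tangent cutoff; hotspot summit pairs within 10 Mb get
the κ kernel. Counts are independent Poisson per upper-triangular cell with
rates scaled to the target depth (optional gamma overdispersion); treated
matrices use the same truth with each feature's factor applied. The defaults
are the package's Pol II depletion scenario: hotspot factor 0.874 (−12.6 %),
Pol II-only loop factor 0.9, stripe factor 0.9, everything else 1.

What passing tests on this generator show: the estimators are unbiased in
the noiseless limit, their nulls are calibrated at the stated depth, and
injected multiplicative effects of ~10 % are recovered within sampling error.
What they do not show: robustness to real-data pathologies the model lacks —
mappability and copy-number structure, restriction-fragment bias,
translocations, overdispersion beyond Poisson (available but off by
default), nested/hierarchical domains, or trans contacts.

## Numerical choices and degenerate inputs

Missing data is NaN throughout and excluded per pixel/per pair, never
zero-filled; uncovered track bins are missing, not zero. Distances 0–1 are
excluded from expected profiles and all pile-ups by default. The d = 0
singularity of the power law is handled as `max(d,1)^(−γ)`. Percent change
requires a positive untreated mean and raises otherwise. Boundary-call ties
report the leftmost bin; tertile remainders go to the top slices; the ROSE
cutoff resolves ties toward fewer hotspots. All randomness (sampling,
downsampling, permutation backgrounds) flows from explicit integer seeds,
and identical config + seed reproduces outputs bit-identically.

## Problem sizes

Simulated studies use two 20-Mb chromosomes at 25-kb bins and 2 × 10⁶
contacts per condition — large enough that every statistic has its intended
sampling behaviour, small enough that a 20-seed calibration sweep runs in
about a minute on one CPU. Multi-seed averages (6–8 seeds) are used for
recovery quantities whose single-seed sampling error (~3 percentage points
for the hotspot change) exceeds the effect resolution of interest.

## Known limitations

- Corner loops are part of their domain, so a loop-only perturbation leaks
  weakly into intra-TAD enrichment (≈ −0.3 % for the default scenario); with
  many perturbed loops per domain a paired Wilcoxon across domains can detect
  it. This is a real property of the statistic, not an artifact.
- ICE balancing attenuates row-level depletions (see above); choose the
  count-O/E route for stripe- and hotspot-type quantities.
- The saddle strength is a single scalar per condition; its between-condition
  comparison relies on across-seed (or across-replicate) dispersion, not a
  per-feature test.
- TAD and loop *discovery* are out of scope: boundaries may be called from
  insulation minima for self-contained runs, but domains and loops are
  expected as caller-supplied annotations.
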