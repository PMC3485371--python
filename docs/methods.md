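# Methods

## Analysis model

The pipeline treats a study as a fully crossed design: every subject
contributes one multi-minute recording per condition (block), each recording
being a nodes × samples array of source-level ("virtual electrode") time
series at a common sampling rate. Blocks whose label starts with `test` are
task blocks by default; the canonical design is rest1, test1, test2, rest2.
Only the first `analysis_duration` seconds of each block enter the analysis,
so blocks of unequal raw length contribute equal data.

### Spectral estimation

Coherence and power use the overlapping-segment (Welch) scheme: 256-sample
segments advanced by 150 samples, each segment de-meaned, Hanning-tapered,
and transformed with a 256-point FFT. At fs = 300 Hz a segment is 0.853 s.
The segment length is fixed at 256 samples rather than one full second
because a 256-point transform is the only choice consistent with both a
256-bin spectrum and exactly 51 analysis bins between 4 and 64 Hz
(51 = #{k : 4 ≤ k·300/256 ≤ 64}); the hop stays at 0.5 s.

Numerical conventions, fixed and documented because they would otherwise be
implicit:

* The analysis range `[f_min, f_max]` is inclusive on both ends. On the
  default grid the boundary frequencies are not bin centers, so inclusivity
  does not change the 51-bin count.
* Segments are de-meaned before tapering to suppress DC leakage.
* No FFT scaling is applied to power: coherence is scale-free and power
  enters PLS mean-centered, so only within-run relative scale matters.
* Bins at which either signal has zero total power yield NaN coherence
  (flagged missing) instead of raising; the PLS stage refuses tensors
  containing missing values, so degenerate inputs fail loudly but locally.
* The cross-spectrum accumulates in explicitly symmetric real arithmetic,
  making `coherence(x, y)` and `coherence(y, x)` bitwise equal.
* Node-pairs are enumerated lexicographically (i < j) over the atlas's node
  order, and the pair axis carries explicit (i, j) labels.

### Mean-centered task PLS

Observations are (block, subject) rows of the flattened tensor. Condition
means are computed over subjects, the grand mean of the condition means is
subtracted, and the conditions × features deviation matrix is decomposed by
SVD. With C conditions at most C − 1 latent variables carry signal.

* **Permutation test** (default 512 draws): block labels are reshuffled
  *within each subject*, preserving one observation per block per subject,
  because the design is fully within-subject; a pooled whole-row shuffle is
  available (`permute="pooled"`) as a sensitivity variant. Each LV's p-value
  is add-one corrected, `p = (1 + #{s_perm ≥ s_obs}) / (1 + n_perm)`, so the
  smallest attainable p with 512 permutations is 1/513 ≈ 0.00195. Sampled
  group permutations with the add-one rule are exact-to-conservative; at the
  null the empirical size at α = 0.05 measures ≈ 0.04.
* **Bootstrap ratios** (default 512 iterations): subjects are resampled with
  replacement, the same resample applied across all blocks (blocks are
  repeated measures of the same subjects). Bootstrap saliences are aligned
  to the original before their standard deviation is taken — by per-LV sign
  flip on the dot product by default, with full orthogonal Procrustes
  rotation as an option — because SVD signs are otherwise arbitrary and
  would corrupt the variance. BSR = original salience / bootstrap SD.
  Unweighted saliences are the default; singular-value-weighted saliences
  are a switch (`weighted_saliences=True`), since both conventions exist in
  the PLS literature. Saliences at machine zero (a feature constant across
  the whole design) report BSR 0 rather than a ratio of rounding noise;
  zero bootstrap variance at a non-zero salience reports a signed infinity
  (flagged, not dropped). Bootstrap samples with an exactly zero deviation
  matrix are skipped and counted, with a warning if more than 1% are.
* One seed drives both resampling schemes through independently spawned
  streams, so changing `n_perm` never alters the bootstrap draws; all
  results are bit-reproducible given (data, seed).
* LV orientation: SVD signs are arbitrary, so reports orient each LV such
  that task blocks load positive (`PLSResult.oriented`), making positive
  BSRs mean "greater during task".

**Small-sample BSR calibration.** With 8 subjects the bootstrap SD estimate
has roughly 7 effective degrees of freedom, which makes the null BSR
distribution t-like: the pooled null SD measures ≈ 1.24 rather than 1. At 16
subjects it is ≈ 1.16 and the standard-normal approximation is serviceable.
The test suite checks approximate normality on a 16-subject null design and
this inflation at the study's n = 8 should be kept in mind when reading BSR
magnitudes as pseudo-z values.

### Band networks

The BSR map of a significant LV is thresholded at a percentile of the |BSR|
distribution — 99.9 for coherence, 99 for power — applied symmetrically
(±T). The percentile-of-absolute convention treats task-positive and
task-negative effects symmetrically; a signed-percentile mode exists for
sensitivity analyses. The percentile rule is linear interpolation between
order statistics, and ties at exactly T count as supra-threshold. Note the
threshold is *relative*: roughly a fixed fraction of bin × feature
combinations survives, so the supra-threshold count scales with the feature
count, not with effect strength.

Bands partition the analysis range as theta 4–8, alpha 8–16, beta 16–32,
gamma 32–64 Hz; assignment is half-open [f_lo, f_hi) with the top band
closed, so each of the 51 bins belongs to exactly one band. Per band and
node-pair, the largest supra-threshold positive and the most negative
supra-threshold BSR are kept, with the bin frequency of each extremum. Node
degree counts *distinct neighbour nodes* across the union of all bands'
edges of one signed network (a pair connected in beta and gamma counts
once); the high-degree table lists nodes with degree ≥ 3 with the min-to-max
frequency span of their contributing bands — when the contributing bands are
non-adjacent the span bridges the gap, which is flagged here as a
formatting convention rather than a claim of mid-band involvement. Degrees
are computed for the positive and negative networks separately; the
positive network is the headline summary.

## Synthetic data generator

Each node carries unit-variance 1/f ("pink") background noise (spectral
exponent 1.0 by default), independent across nodes, subjects and blocks,
with log-normal inter-subject amplitude jitter (σ = 0.1) constant across
blocks. Two kinds of task-state effect can be injected:

* **Coupling edges** (common-source model): in task blocks only, a shared
  band-limited component is added to both endpoint nodes. The amplitude is
  calibrated from the analytically expected in-band pink-noise power so the
  in-band shared-variance fraction equals √c for requested coupling c,
  giving band-aggregate coherence ≈ c; √c is clamped at 0.999 so c = 1
  stays finite. Attained coherence is monotone in c by construction. A
  shared additive component was chosen over phase-lagged coupling because
  magnitude-squared coherence is insensitive to which mechanism produces
  the synchrony, and the common source guarantees band-specific coherence.
* **Power effects**: listed nodes carry an independent band-limited
  oscillation in *every* block, with in-band power 8× the expected in-band
  background power (a strong narrow-band rhythm dominating the local 1/f
  floor). In task blocks the component amplitude is rescaled; the rescaling
  is compensated for the unscaled background so that the *measured* total
  in-band power changes by exactly the requested factor in expectation
  (scaling only the component would undershoot). With the 8:1 dominance the
  per-bin power ratio stays within about ±1 percentage point of the
  band-aggregate target across the band.

Band-limited components have a flat random-phase spectrum strictly inside
the band, so essentially all their power is in-band. Everything derives from
one root seed through keyed independent RNG streams (per subject, block,
effect and node), making the full dataset bit-reproducible.

What the generator does **not** emulate: source-leakage ("cross-talk")
mixing between node estimates, inter-subject latency or spectral-shape
differences, within-block non-stationarity, physiological artefacts, and
1/f-exponent heterogeneity across nodes. Passing recovery tests therefore
demonstrates correctness of the estimators and inference machinery under a
clean generative model, not robustness to those real-data complications. In
particular, absolute-coherence inflation by leakage — one motivation for
analysing state *differences* — is not reproduced.

## Study-condition scales

The generator's defaults mirror the emulated design: 8 subjects, four 360-s
blocks at 300 Hz, up to 80 nodes (default 20). The packaged experiments run
at desk scale as the package's own choice of problem size:

* Significance checks (coherence and power tracks): 12 nodes, 60-s blocks,
  five coupling edges at c = 0.6 or alpha 0.7× / gamma 1.187× power effects.
* Effect-size recovery: gamma 1.187× only, 12 nodes, full 360-s blocks,
  20 seeded replicates. The full block length matters here: the
  99th-percentile threshold keeps only a handful of bins, and at 60 s the
  per-bin estimates are noisy enough that selecting bins by BSR rank
  inflates the recovered percent change (winner's-curse selection bias,
  ≈ +6 pp at 60 s, negligible at 360 s).
* Edge recovery: 20 nodes, 60-s blocks, five disjoint beta edges at c = 0.9;
  sensitivity and false-discovery proportion are scored against ground truth.
* Null calibration: 4–8 subjects, 6–8 nodes, 30-s blocks, ≥100 replicates.

## Known limitations

* The in-memory dataset container holds the full subjects × blocks × nodes ×
  samples array; at the full 80-node, 360-s scale that is ~22 GB in float64,
  so full-scale runs need a chunked/streaming adaptation of `build_tensors`
  (the per-subject-block loop is already stream-shaped).
* The PLS stage requires a complete crossing (every subject observed in
  every block); unbalanced designs are not supported.
* Network summaries stop at node degree — no clustering, path length or
  modularity — and no brain rendering; edge lists and Talairach coordinates
  are exported for downstream tools.
* The packaged 80-node atlas carries real coordinates only for the eight
  cerebellar nodes; the 72 cortical entries are synthetic placeholders and
  any anatomical reading requires a user-supplied atlas.
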