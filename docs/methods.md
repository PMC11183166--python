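# Methods

## The analysis in one paragraph

`morphnet` implements individual-level morphological brain-network
analysis. For each subject, every parcellation region contributes a sample
of voxel-level gray-matter (GM) values; the region's value distribution is
estimated by Gaussian-kernel KDE and every region pair is scored by a
divergence-based similarity — `KLDs = exp(−[KL(P‖Q) + KL(Q‖P)])` (natural
log) or `JSDs = 1 − JSD(P,Q)` (base-2 Jensen–Shannon, so both measures lie
in [0, 1]). The resulting N×N similarity matrix is one subject's
morphological network. Networks are binarized over a sparsity grid
(fraction of strongest edges retained, 0.05–0.40 in steps of 0.01, 36
thresholds), global and nodal graph metrics are computed at every
threshold and summarized by the trapezoidal area under the curve (AUC),
and groups are compared by label-permutation tests with BH-FDR control of
nodal discoveries, the network-based statistic (NBS) for edge-level
localization, and Pearson partial correlation against clinical scores.
Because no imaging data ship with the package, a synthetic cohort
generator reproduces the statistical structure the analysis assumes, and
every stage is validated against it.

## Similarity construction

- **KDE.** Gaussian kernel with Silverman's rule-of-thumb bandwidth
  `h = 0.9·min(sd, IQR/1.34)·n^(−1/5)` per region sample; the bandwidth
  rule is a pluggable argument.
- **Pair-specific common grid.** Divergences require a shared support:
  each unordered pair's distributions are discretized on a 256-point grid
  spanning the pooled sample range plus 3 bandwidths of padding, floored
  at 1e−10 and renormalized (the floor keeps KL finite when one region's
  support does not cover the other's). The floor, grid size and padding
  are recorded in the matrix metadata.
- **Fast path.** Evaluating both KDEs per pair exactly is O(n·m) per
  evaluation and prohibitive at cohort scale (~6700 pairs × 76 subjects ×
  up to 2000 voxels). By default each region's KDE is evaluated once on a
  fine 512-point grid covering its range ± max(padding, 8) bandwidths and
  linearly interpolated onto pair grids (zero outside, then floored). The
  wide cache matters: truncating at 3 bandwidths distorts log-ratios in
  the low-density gap between separated regions. Against the exact mode
  (`method="exact"`, also provided) the fast path agrees to ~1e−4 in
  similarity units; tests assert the agreement.
- The diagonal is fixed at 1 and never enters thresholding.

## Graph topology

- **Thresholding.** `floor(S·N(N−1)/2)` strongest off-diagonal edges,
  ties broken by ascending (row, column) pair so equal matrices always
  threshold identically. `floor` guarantees the realized sparsity never
  exceeds S.
- **Path length convention.** Sparse binarized graphs can disconnect, so
  `Lp = 1/Eg` (harmonic mean over pairs; unreachable pairs contribute zero
  efficiency). This keeps `Lp` and `λ` finite at every threshold and is
  applied identically to real and null graphs.
- **Clustering.** `Cp` is the mean over nodes of `2tᵢ/(kᵢ(kᵢ−1))` with
  `Cᵢ = 0` for degree < 2; local efficiency is the mean over nodes of the
  global efficiency of each node's neighbor-induced subgraph.
- **Normalization.** `γ = Cp/⟨Cp_null⟩`, `λ = Lp/⟨Lp_null⟩`,
  `σ = γ/λ`, with degree-preserving double-edge-swap null graphs
  (10×|E| attempted swaps; 100 nulls by default, 20 in the headline
  screening where the group mean over 38 subjects suppresses null noise).
  Complete graphs admit no legal swap and are returned unchanged (γ = λ
  = 1 exactly).
- **Implementation notes.** All-pairs shortest paths use dense
  boolean-matrix BFS (exact for unweighted graphs, fast at parcellation
  scale); the swap kernel is numba-compiled; betweenness (unnormalized,
  each unordered pair once, fractional credit across equal-length paths)
  comes from igraph's Brandes implementation. Every metric is
  cross-checked against an independent Floyd–Warshall-based brute-force
  oracle, and betweenness additionally against networkx, in the tests.

## Group inference

- **Permutation AUC tests.** Group labels are reshuffled without
  replacement; two-tailed p = proportion of permuted |mean differences| at
  least the observed one (raw proportion, no +1 smoothing); the 95th
  percentile of the null |difference| is reported as the significance
  threshold. 10,000 permutations by default; an exhaustive enumeration
  mode is automatic for ≤ 10 subjects.
- **BH-FDR** (q = 0.05) is applied within each nodal metric family across
  regions (the family choice is recorded in the run manifest); the
  step-up procedure is delegated to statsmodels and pinned by a
  hand-executed example in the tests.
- **NBS.** Edge-wise pooled-variance t statistics on raw (unthresholded)
  similarities within a node mask; one-sided retention at the primary
  threshold t = 3.2 separately for hyper- and hypo-connectivity;
  connected components of suprathreshold edges; component size = edge
  count; corrected p = #(permutation max component size ≥ k)/5000 with
  the full edge-test/threshold/component procedure re-run per
  permutation. No suprathreshold edges is an empty (not erroneous)
  result. In the orchestrated pipeline the node mask is the set of
  BH-FDR-significant nodes from any nodal metric.
- **Demographics.** Two-sample pooled t for age, chi-square (no Yates
  correction) for sex; Shapiro–Wilk normality p-values are reported
  descriptively and never gate the test choice.

## Clinical association

Pearson partial correlation: x and y are each residualized on the
covariates (with intercept) and the residuals correlated; two-tailed p
from the t transform at df = n − 2 − #covariates. Sex enters as a binary
indicator; missing values are dropped listwise per target; p-values are
reported uncorrected and flagged as such. The residual formulation is
cross-checked against the inverse-correlation-matrix identity and against
pingouin in the tests.

## The synthetic cohort generator

The generator emulates a 38-vs-38 pediatric case-control morphometry
study over a 116-region (alternatively 83-region) parcellation.

**Value distributions.** Each region's voxel values follow a Gaussian
mixture of K = 8 components at a shared layout (component centers evenly
spaced over 0.20–0.95 of the GM-fraction scale, base width 0.05). The
first component is a *dominant shared background peak* (relative weight 5,
i.e. ~42% of mass) whose location barely varies across regions (SD 0.005)
or subjects; regional identity lives in the remaining components' means
(SD 0.022), log-widths (0.15) and log-weights (0.30). Two design
iterations matter here:

1. *Dimensionality.* A two-component mixture was tried first and
   rejected: its shape space has so few effective dimensions (overlapping
   components can even compensate each other's shifts) that
   divergence-based networks degenerate into low-dimensional proximity
   graphs — near-disjoint cliques at sparse thresholds with path-length
   ratios λ ≈ 2–3, nothing like real morphological networks. With K = 8
   semi-resolved components every parameter is independently visible in
   the density, the shape space has ~24 comparable dimensions, and the
   networks sit in the empirical small-world regime (γ ≈ 3–5 at the
   sparsest threshold decaying to ~1.2 at the densest; λ ≤ ~1.17
   throughout).
2. *The background peak.* Making the dominant component common to all
   regions serves the effect model: a disease shift of that component is
   then a monotone similarity loss against every neighbor. When the
   dominant component's location varied across regions at the same scale
   as the shift, a shifted region could move *toward* neighbors sitting
   below it, silencing or even reversing its degree change for some
   realized geometries.

**Communities.** Regions scatter (relative spread 0.3) around latent
community centroids on a hypersphere in the 24-dimensional parameter
space; 26 communities by default at 116 regions (≈ 4–5 regions each,
emulating small families of morphologically alike regions such as
homotopic pairs and gyral subdivisions). Random centroids are
near-equidistant in high dimension, so communities have no metric
ordering among themselves: within-community similarity is elevated
(clustering, γ > 1) while cross-community edges at the threshold margin
are effectively random (shortcuts, λ ≈ 1).

**Subject variability.** Total between-subject location variability
`subject_sd = 0.04` is split evenly across components (damped ×0.5 on the
background peak), plus log-width jitter 0.03 and log-weight jitter 0.06
per component, plus multinomial sampling of 400–2000 voxels per region
(region-specific, fixed across subjects).

**Group effect.** Each patient draws a severity exposure
`e ~ effect_size·(1 + 0.3·z)` (clipped at 0.2·effect_size); in every
effect node the background peak shifts down by `e·subject_sd·m_j` with
fixed per-node multipliers `m_j` spanning 0.7–1.3. Controls receive no
shift. `population_similarity_change` computes the resulting noise-free
similarity difference from the exact mixture densities — the ground truth
that defines the planted component in recovery experiments.

**Clinical covariates** match the emulated cohort's printed ranges
(patients aged 5–17, mean 10.37 ± 3.81; controls 6–20, 10.30 ± 3.54;
24:14 male:female in both groups of 38; onset 2.55 ± 2.59; duration
7.78 ± 3.61; motor score 0–66 from 33 items scored 0–2). The motor score
is `round(66·logistic(slope·(effect_size − e) + ε))`, ε ~ N(0, 0.5), so
it *decreases* with exposure; duration is drawn with correlation 0.6 to
exposure, so it *increases* with severity. Designed association signs for
the effect-node degree signature are therefore positive (score) and
negative (duration); link strengths were calibrated at design time so the
associations are recoverable at n = 38, as the design requires.

**What the generator does not emulate:** spatial voxel grids, smoothing,
anatomy, site or scanner effects, age-dependent morphology, or any
coupling between clinical covariates and brain structure beyond the
planted exposure pathway. Passing tests demonstrate that the pipeline
recovers structure *of the kind it assumes*, not that the assumptions
hold in real MRI data.

## Study conditions for validation

- **Small-world screening** (headline condition): the default cohort,
  KLDs networks, group-mean γ and λ at all 36 thresholds, 20 rewired
  nulls per graph. γ > 1 and λ ∈ [0.8, 1.2] at every threshold for both
  groups.
- **Calibration**: type-I error of the permutation AUC test over 1000
  null replicates at 1000 permutations (binomial 95% envelope around
  0.05); NBS familywise error over 50 null replicates at 500
  permutations; both scaled down from the defaults to keep the suite
  affordable while leaving the procedures unchanged.
- **Effect recovery**: 20 replicates of a 38-vs-38, 50-region design
  with five effect nodes at effect size 1.5. Effect nodes are the five
  regions with the highest population-level similarity degree, one per
  community, chosen from the noise-free model before any data are drawn —
  pathology planted in connected structures; a peripheral region has no
  connectivity to lose, which would make the recovery question
  degenerate. Success criteria: all effect nodes FDR-significant in
  nodal-degree AUC, effect nodes in the top decile of |AUC difference|,
  ≥ 80% of planted (ground-truth) edges covered by NBS components at
  corrected p ≤ 0.05, and the designed association signs.

## Numerical choices and degenerate inputs

- Constant or short (< 10 values) region samples are rejected with the
  region named; matrix construction reports *all* failing regions.
- Divergences use `scipy.special.rel_entr`, so zero-mass bins follow the
  correct limits (0·log 0 = 0; mass against zero gives +inf, mapped to
  similarity 0).
- Similarities are clipped to [0, 1] against floating-point overshoot;
  matrices are exactly symmetric by construction.
- Thresholding a matrix whose sparsity would retain zero edges is an
  error; sparsity 1 yields the complete graph.
- Graphs with fewer than 3 nodes are rejected by the metric routines;
  degenerate null means (all-zero clustering) abort normalization.
- All randomness flows from one root seed through named, CRC-derived
  substreams (`stage_seed`), so partial re-runs are reproducible and any
  derived seed fits in 31 bits.

## Known limitations

- The exact per-pair KDE mode is quadratic and only practical for small
  parcellations; the default interpolating mode is an approximation
  (~1e−4 absolute in similarity).
- λ at the sparsest threshold (mean degree ≈ 5.7) sits near the top of
  the plausible band (~1.17): clustered proximity graphs cannot reach
  λ = 1 exactly, since clustering spends edges locally
  (λ ≳ ln k / ln(k(1−C))).
- The NBS node-selection rule (FDR-significant nodes) and the FDR family
  (within metric, across regions) are analysis conventions recorded in
  the manifest, not facts about the data; alternative choices change
  which edges the NBS can see.
- Betweenness p-values are typically far from significance in the
  synthetic designs (as in the emulated study); the pipeline reports them
  without further interpretation.
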