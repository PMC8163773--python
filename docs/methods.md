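# Methods

## Colony growth model

Colony area over time is described by the Gompertz law

    f(t) = A_min + A_Δ · exp(−exp(k (t_m − t)))

with baseline area `A_min` (area units), total area gain `A_Δ > 0`,
maximum relative growth rate `k > 0` (1/h) and inflection time `t_m`
(h).  Two quantities derive in closed form:

- **Maximum growth rate** `μ_max = f′(t_m) = A_Δ k / e` (area/h).
- **Lag time**: the intersection of the tangent at the inflection point
  with a baseline area level,
  `T_lag = t_m + (baseline − A_min − A_Δ/e) · e / (A_Δ k)`.
  For `baseline = A_min` (the default) this is `t_m − 1/k`; for
  `baseline = 0` (colony size at inoculation taken as zero) it is
  `t_m − 1/k − A_min e/(A_Δ k)`.  An alternative printed sign
  convention, `(A_min + (A_Δ/e)(1 − k t_m)) / ((A_Δ/e) k)`, equals the
  *negative* of the zero-baseline intersection; it is exposed via
  `convention="printed"` for comparison but the tangent intersection —
  which increases with `t_m`, as a lag should — is the default.  Both
  closed forms are tested against finite-difference and root-finding
  oracles to 1e−8/1e−10.

Fitting uses trust-region-reflective least squares with positivity
bounds on `A_Δ` and `k`, restarted from 50 deterministic data-driven
start points (a grid of `t_m` spanning the observed window crossed with
log-spaced `k` around 4/duration; `A_min` from the first area, `A_Δ`
from the observed range).  The grid is fixed, so fits are exactly
reproducible.  Degenerate (constant) series return `converged=False`
rather than raising; callers decide exclusion.  Times are hours
internally; minute inputs are converted at the model boundary.

## Respiratory rate

The formazan accumulation of a respiring colony is summarized by the
steepest linear segment of its mean red-channel trace: over every
contiguous window of ≥ 10 points, `intensity = α t + β` is fitted by
OLS (prefix-sum implementation, all windows exact) and the window with
maximal `α` (AU/h) is returned; ties resolve to the earliest, then
shortest, window.  `α` is invariant to intensity offsets and scales
linearly with intensity rescaling.  On noisy traces the max-window
estimator is upward biased (it prefers windows that noise tilts
upward); rank-based downstream use is unaffected, which is how the
analyses here consume it.

## Batch OD600 kinetics

The exponential rate of a batch culture is the maximum slope of
`ln OD` over all contiguous windows spanning ≥ 100 min; the lag is
where the fitted exponential extension meets the inoculum OD,
`lag = (ln OD₀ − intercept)/rate`, clipped at zero.

## Image analysis

1. **Temporal-SD projection.**  Frames are converted to grayscale
   (mean of RGB — redness is reserved for respiration) and the
   per-pixel population SD across frames is computed; growing colonies
   leave a high-variance footprint, static agar does not.
2. **Thresholding.**  Otsu's threshold is computed from in-plate
   pixels only, which makes the cut robust to illumination differences
   between plates.  Constant rasters raise a degenerate-threshold
   error.
3. **Segmentation.**  Touching colonies are split by a watershed on
   the (Gaussian-smoothed, σ=1 px) SD projection, seeded at its
   h-maxima (default h = 5% of the in-mask dynamic range); flat
   regions without a maximum fall back to distance-transform peaks.
4. **Per-frame extents.**  The watershed footprint under-covers pixels
   colonized only near the end of the movie, so labels are expanded by
   8 px and each frame's Otsu foreground (threshold from the final
   frame, where both classes exist) is split along those basins, then
   relabeled independently per frame.
5. **Tracking.**  Per-frame labels are linked by a gated Hungarian
   nearest-centroid assignment; the gate defaults to 1.5× the median
   equivalent colony radius (floor 5 px), so would-be identity swaps
   beyond the gate terminate tracks instead of exchanging them.
   Colonies absent before detection carry zero area; frames lost
   mid-track are linearly interpolated for area and flagged.
6. **Artifact filter.**  Tracks are dropped when detected in fewer
   than 5 frames, with final area outside configured bounds, with a
   final centroid within 10 px of the plate rim, or with a relative
   frame-to-frame area drop above 30%.  Every rule can be disabled.
   The specific thresholds are this package's declared defaults — the
   assay literature states only that outliers are filtered.

Plate geometry is detected by a Hough circle transform on the first
frame (fallback: largest inscribed circle) and can be overridden.
Coordinates are (row, col), 0-based, origin top-left.

## Expression noise

Noise is the squared coefficient of variation `η_p = σ_p²/μ_p²`.  The
expected noise at a protein's abundance, `η̄_p`, is the mean `η` over
the `⌈0.05 N⌉` proteins nearest in **log10 abundance** (the protein
itself included).  Abundance spans several decades, so log distance is
the natural metric; the k-NN window realizes the abundance-window
average of the smoothing construction, and a brute-force O(N²) oracle
checks it exactly in the tests.  Deviating noise is `ε_p = η_p/η̄_p`,
reported both as the raw ratio and as `log2 ε` (0 = exactly as noisy
as expected).

## Enrichment statistics

Set-level scores (gene-ontology terms, TF regulons, metabolic
pathways) use a permutation test: the observed set statistic (mean, or
median for TF regulons) against `n_permutations` independent same-size
draws without replacement, with add-one p-values
`p = (1 + #{null ≥ obs})/(1 + n_permutations)` — never 0, never > 1.
Each set gets its own null draws; sharing one draw matrix across sets
would correlate their p-values and inflate calibration tests.  An
exact-tie tolerance (1e−9 relative) keeps degenerate cases (e.g. the
all-members set) at p = 1 despite floating-point summation order.
TF-regulon results also report the Bonferroni-corrected threshold
(1e−4 / number of TFs) used to call significant regulators.

Multiple testing uses Storey q-values: `π̂₀(λ) = #{p > λ}/(m(1 − λ))`
on λ = 0.05…0.95 (step 0.05), a cubic smoother evaluated at λ = 0.95,
clipped to (0, 1]; with fewer than 100 tests π̂₀ is pinned at 1 (the
smoother is unstable there).  `q_i = min_{p_j ≥ p_i} π̂₀ m p_j /
rank(p_j)`, monotone in p and never below `π̂₀ p`.

## Pareto analysis

Colonies compete on two objectives: maximize growth rate, minimize
lag.  The non-dominated set is computed by an O(n log n) sweep and
verified against the O(n²) dominance oracle; identical phenotypes are
mutually non-dominated.  Fitness is approximated as the ratio of
min-max-normalized growth rate to normalized lag (isoclines = rays in
the normalized plane, as plotted); the raw ratio is available by flag.
The colony at the minimum lag has infinite normalized fitness and is
treated as above every finite quantile when bands are formed.  Band
membership uses linear-interpolation quantiles of the finite scores.
The "random choice" baseline is the fitness histogram of 10,000 points
uniform over the bounding rectangle of the normalized cloud, scaled to
the population size.

The equal-fitness exponential model: cells reaching the same number of
divisions D in a fixed period T satisfy `λ(T − T_lag) = c` with
`c = D ln 2`, i.e. `T_lag = T − c/λ`, an inverse relation between
growth rate and lag feasible for `λ ≥ c/T`.

The CV bootstrap draws `n_reps = 1000` subsamples of `n_draw = 400`
colonies without replacement within a draw and reports the CV
(sd/mean) distribution; two populations are compared by a two-sided
t-test on their CV distributions.  Draws with non-positive mean are
flagged NaN rather than crashing.

The lowess trend is a tricube-weighted local linear regression over
the `⌈span·n⌉` nearest points, evaluated on a grid — exact on linear
data by construction.

## Metabolome statistics

Ions are annotated by matching measured m/z to expected adduct masses
of a user-supplied metabolite list within a ppm tolerance (default
10 ppm, single default adduct [M−H]⁻ at −1.007276 Da; both are
configuration, as the upstream acquisition details vary).  Multiple
matches are retained and flagged ambiguous; when several ions map to
one metabolite, the ion with the highest median intensity represents
it.  Differential abundance between two groups: log2 fold change of
group means and a Welch two-tailed t-test on `log2(intensity + 1)`
(the +1 stabilizes zeros; raw intensities are non-negative), with
Storey q-values across metabolites.  Zero-variance metabolites are
flagged `degenerate` with p = 1 instead of crashing.  Pathway
enrichment feeds |log2 FC| (signed by flag) into the permutation
machinery above.  Starvation time courses return per-(strain,
timepoint) mean ± sd trajectories plus per-timepoint differential
tests when both strains have ≥ 2 replicates.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (configuration, seed) and return
ground truth for every entity, making parameter recovery measurable.

- **Plate time-lapse**: colonies are disks on a 512 px plate (60
  frames, 10 min apart) whose areas follow per-colony Gompertz curves
  and whose red channel rises linearly at rate α once the colony
  passes its lag (red accumulation is tied to active metabolism); a
  smooth radial illumination gradient (10%) and i.i.d. pixel noise
  (sd 0.02) are added.  Colony placement is rejection sampling with a
  10,000-attempt cap.  Not emulated: 3D colony morphology, nutrient
  diffusion, lid condensation, reflections — segmentation results here
  bound what the algorithm can do on clean geometry, not on every real
  plate.
- **Colony traces**: 24 h, 10-min sampling; per-colony parameters
  drawn with colony-to-colony dispersions matching the observed
  populations (growth-rate CV 0.4, lag CV ≈ 0.15 via t_m sd 1.5 h,
  respiratory-rate CV 0.25); area noise 5% of each colony's `A_Δ`.
  The red trace is a mean over the colony mask, so per-pixel sensor
  noise averages down by √(mask size); its absolute noise default is
  0.005 AU, a conservative multiple of that limit.
- **Proteome table**: 1018 proteins, log10 abundance ~ N(1.2, 0.9);
  noise `η = (a/μ + b)·ε*` with intrinsic coefficient a = 1
  (Poisson-like 1/μ term dominating at low copy number), extrinsic
  floor b = 0.1, and per-protein log-normal deviation ε* (log-sd
  0.5).  Essential flags are biased toward high abundance and low
  deviation.  Annotation sets can be tilted toward high-ε proteins by
  a configurable weight.
- **Flux panel**: 40 enzymes × 7 conditions (the carbon-source panel
  width); `flux = s·protein + noise`, with 25% of enzymes given
  s = 0.
- **Metabolome**: 955 ions, log2 baseline ~ N(10, 2), replicate sd
  0.5; a planted pathway shifted by the configured log2 effect in one
  group; default two groups × 3 replicates (the exponential-phase
  design; the starvation design uses 6).  Each ion carries a
  deprotonated m/z with 2 ppm jitter plus the matching neutral-mass
  list.

Passing recovery tests on these inputs demonstrates the estimators are
correct and well calibrated under the stated noise models; they do not
certify performance on real scanner images or spectra, whose artifacts
are deliberately out of scope.

## Problem sizes and reproducibility

The shipped acceptance checks use 200 colonies for kinetic recovery,
one 50-colony plate for segmentation, 1000 proteins for noise
recovery, 200 random sets × 2000 permutations for calibration, 5000
p-values for π̂₀, n = 2000 for the Pareto oracle and 1000×400 for the
CV bootstrap — sizes chosen so the whole suite reruns in about two
minutes while keeping Monte-Carlo error well inside the asserted
margins.  All randomness flows through explicit integer seeds;
`scripts/acceptance.py` derives per-stage seeds from a single `--seed`
via `numpy.random.SeedSequence`.

## Known limitations

- The deposited colony-phenotype table of the original assay has no
  public accession, so population summaries (colony counts, CVs per
  condition) are exercised on synthetic stand-in populations at the
  same scale; `pareto.colony_population_summary` accepts any such
  table when one is available.
- The max-slope respiratory estimator is upward biased under noise
  (see above); treat α comparisons as ordinal.
- The enrichment test is a permutation test throughout; the iterative
  hypergeometric variant sometimes used for ontology enrichment is not
  reimplemented.
- Tracking assumes colonies are sessile; the gate guards against
  label swaps but large frame-to-frame plate shifts require upstream
  registration, which is out of scope.
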