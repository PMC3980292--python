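# Methods

## Model

A calcium-imaging movie is a matrix `A` with `m` time points (rows, flattened
frames) and `n` pixels (columns, time series).  Pixels of one functional unit
(a glomerulus, or a receptor-neuron patch on the antenna) report correlated
signals, so `A` is well approximated by a low-rank product

    A  ≈  T S,      T: m x c time series,   S: c x n coefficient images,

and, more specifically, by a non-negative mixture `A = T S⁰⁺ + N`: each pixel
is either a *pure* copy of one unit's signal (centre of the unit) or a
non-negative blend of several units (light scatter at the fringes), plus
noise.  Under this model the pure-pixel time series are the extreme rays of
the convex cone spanned by the columns of `A`, which is what makes them
identifiable without any anatomical information.

## Streaming estimation

Each incoming frame is processed in O(n·k):

1. **Running z-score.**  Per-pixel mean and variance are maintained with
   Welford's one-pass recurrence (population 1/N variance, so the final
   running statistics equal batch statistics to machine precision; a sigma
   floor of 1e-6 guards dead pixels).  The frame is normalised with the
   statistics *including* itself; early frames are therefore normalised
   against immature estimates — an inherent property of the online setting,
   quantified rather than hidden.  An optional spatial Gaussian pre-filter
   (odd width `w`, sigma `w/4`, kernel truncated to `w` pixels, reflect
   boundary; default width 9) precedes normalisation for camera data.

2. **Incremental PCA (candid covariance-free).**  The component matrix `V`
   (k rows, unnormalised) is updated per frame:

       V_r ← ((i−1)/i)·V_r + (1/i)·x·(xᵀV_r/‖V_r‖),
       x   ← x − (xᵀv̂_r)·v̂_r         (r = 1..k in order),

   where `x` is a working copy of the normalised frame and `v̂_r` the unit
   vector of the freshly updated row.  Row `r` is seeded with the residual of
   the r-th incoming frame after downdating against rows `< r` (deterministic
   Gram-Schmidt-style, data-driven initialisation; canonical basis vectors as
   a degenerate-frame fallback; dead rows re-seed from the current residual).
   Rows converge to eigenvalue-scaled principal components; this scale is
   load-bearing for the selection step below.  An amnesic weight (mass on
   recent frames) is exposed but off by default: on these movies it slows
   early map formation because recent-frame emphasis amplifies noise.

3. **Convex-cone selection.**  On the current `V`, greedily pick the column
   (pixel) of largest residual norm (ties → lowest index), orthonormalise its
   residual direction into a basis (two Gram-Schmidt passes), project that
   direction out of every column by downdating the cached squared norms, and
   repeat `c` times.  Columns whose residual norm falls below 1e-9 of the
   initial maximum are ineligible; running out of eligible columns returns a
   shorter selection with a warning (or an error, configurable).  Selection
   is a pure function of `V`: re-running it on the same state is
   bit-identical, so a model snapshot cadence (`select_every`) is purely a
   throughput choice.

   The eigenvalue scale of the rows matters: on orthonormalised components,
   a unit's column norm is diluted by its footprint size while the aggregate
   leverage of noise directions grows with `k`, and noise pixels start
   winning selections.  For the same reason the offline reference runs the
   cone on the singular-value-weighted components `σ_r·v_r`, whose column
   geometry equals that of the rank-k movie.

4. **Coefficients and reconstruction.**  `S = QᵀV` for the orthonormal cone
   basis `Q`; negative entries are clipped by default (streaming-safe), with
   per-pixel non-negative least squares as an offline option.  The per-frame
   low-rank approximation projects the normalised frame onto the row space
   of `S` through a rank-guarded pseudoinverse (singular values below 1e-10
   of the maximum are discarded), making the operation idempotent and
   non-expansive regardless of row degeneracy.  The first two frames bypass
   factorisation (warm-up).

The `T` matrix reported at the end of a run contains the selected pixels'
series z-scored with the *final* running statistics: per-frame online
z-scores are scaled by immature statistics early on and are not comparable
across the recording, which visibly corrupts downstream per-window features.

## Offline reference and comparison

The batch path z-scores the full movie with final statistics and computes
exact top-k right singular directions (ARPACK with a fixed start vector for
k ≪ min(m, n), full SVD otherwise; the sign of each component is fixed so
its largest-magnitude entry is positive).  `compare_models` greedily matches
selected-pixel positions within a radius (default 5 px); when ground truth
is available, the reference model's selections are first restricted to those
inside true footprints — surplus selections chase movie-specific noise modes
and carry no information about unit recovery.

## Functional maps

Rows of `S` carry arbitrary scale, so `build_map` first normalises each row
to unit L2 norm, then assigns every pixel to the arg-max row (ties → lowest
row index) provided the winning coefficient clears a threshold: default
`relative` mode keeps pixels above 0.5 of the row maximum (the FWHM cut of
the winning source's coefficient profile); `quantile` and `absolute` modes
are available.  Labelling is invariant to positive rescaling of any row.
Map snapshots over the stream report completeness: the fraction of true
units with at least one selected pixel inside their footprint.

## Display transforms

Real-time display uses a causal first-order high-pass per pixel
(`y = x − EMA(x)`, `alpha = 1 − exp(−2π·f_c/f_s)`, default cutoff 0.025 Hz)
whose discrete pole matches the analogue time constant `1/(2π·f_c)` exactly,
and a false-colour scale driven by cumulative minimum/maximum (blue → white
→ red fixed 256-entry table).  Both are O(1) memory per pixel.  The
incremental scale is deliberately not the final scale: a value seen early is
coloured with the narrower range known at that moment.

## Chemosensing analysis

Per stimulation, the feature of a response unit is the maximum of its time
series from the onset to the next onset (the last window runs to the end).
Optional baseline subtraction removes the mean of the 5 pre-onset frames —
recommended whenever slow drift (bleaching, illumination) is present,
because drift shifts whole-window maxima.  Stimulus-by-stimulus Euclidean
distance matrices are clustered with Ward's minimum-variance linkage
(scipy's implementation behind the module surface) and compared across
individuals with a Mantel permutation test: Pearson correlation of the
upper triangles, joint row/column permutations of the second matrix,
two-tailed on |r|, `p = (#{|r*| ≥ |r|} + 1)/(n_perm + 1)` so p = 0 is
impossible; deterministic per seed.

## Synthetic movies

The generator emulates the statistical structure the method assumes:

- **Footprints**: truncated Gaussian discs (sigma = radius/2, cut at
  2 sigma), weight 1 at the centre; centres are separated by at least
  0.8·(r_i + r_j) and by max(r_i, r_j) + 1, which keeps every centre pixel
  pure while letting fringes overlap (scatter mixing).  The FWHM region
  (weight ≥ 0.5) serves as the evaluation core.
- **Sources**: per unit, a stimulus-response table (each odour elicits a
  response with probability 0.5, amplitude uniform in [0.5, 1.5]) convolved
  with a difference-of-exponentials transient (0.5 s rise, 3 s decay), plus
  smoothed Gaussian spontaneous activity (sd 0.2 of the mean amplitude, 2 s
  correlation).
- **Nuisance structure**: white sensor noise (SNR is defined as mean
  response amplitude / noise sd); optionally multiplicative bleaching
  `exp(−t/τ)` on a baseline; and by default 8 structured background
  components — smooth spatial fields with slow temporal drift (60 s
  timescale), standing in for the staining and illumination artifacts of
  real recordings.  Exact-identifiability tests switch background off.
- All randomness flows through seeded generators; ground truth renders
  bit-identically for a fixed seed.

What the generator does *not* emulate: photon (Poisson) statistics, optics
beyond footprint fringes, movement artifacts, or receptor adaptation.
Passing tests therefore show that the estimator recovers the mixture
structure it assumes under calibrated noise — not that it is robust to
motion or nonstationary optics.

## Benchmark experiments and problem sizes

The standard benchmark movie is 120 x 160 px, 20 units, 3000 frames at 5 Hz
(34 stimulations, 84-frame intervals) with k = c = 50, the standard
configuration for antennal-lobe recordings; chemosensing uses a
32-stimulation protocol (22 odours + 2 references applied 5x each) and two
individuals sharing the tuning table.  The spatial pre-filter stays off in
benchmarks: synthetic noise is white, top-k truncation already denoises it,
and a width-9 kernel (sigma ≈ 2.25 px) would blur footprints whose own
sigma is 2-3.5 px, degrading the comparison against true cores.  CCIPCA
convergence is measured against the batch PCA of the same frames (sampling
error cancels), on 16-pixel streams with covariance diag(9, 4, 1, 0.1 ...).
Map-completion sweeps use 20 seeds at SNR 10 with snapshots every 100
frames.

Two known limitations the benchmarks expose honestly: late incremental
components are still mixtures after 3000 frames, so maps built from the
*streaming* S are blurrier than maps from the exact factorisation (median
core Jaccard ≈ 0.6 vs 0.8); and early-stream map completeness is bounded by
information, not by the estimator — an exact batch factorisation of only
the first 600 frames recovers 55-75% of units, because most stimuli simply
have not happened yet and spontaneous activity is deliberately
low-amplitude.

## Other numerical choices

- Population (1/N) standard deviations throughout, so streaming and batch
  moments agree exactly.
- Tie-breaks: arg-max ties always resolve to the lowest index (cone columns,
  map rows) for determinism.
- Ratio preprocessing for dual-excitation data: consecutive (340, 380 nm)
  frames collapse to one time point at half the raw rate, with an epsilon
  guard in the denominator.
- Filtering order: spatial filter → z-score (configurable).
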