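# Methods

This note records the models, conventions and numerical choices behind
`perfilt`, in the order the method runs.

## Data model and preprocessing

The central object is the taxa table: a samples × taxa matrix of
non-negative integer read counts with unique string identifiers and
optional per-sample metadata (`lab`, `dilution`, `dna_conc`, `group`).
Canonical orientation is samples-in-rows everywhere; transposed
delimited files and dense BIOM 1.0 JSON (whose own convention is
taxa-in-rows) are transposed at read time.  Samples with zero library
size are retained but flagged; each downstream statistic decides its
own policy (Shannon assigns H = 0, Bray–Curtis errors only if a
*pair* of all-zero samples makes a dissimilarity undefined, contaminant
scoring excludes them from the regression).

Preprocessing mirrors common mock-community practice: species-level
name collapsing sums columns that map to the same label under a
user-supplied key (name normalisation is dataset-specific, so the key
is an argument, not a built-in), and the prevalence filter removes taxa
present in strictly fewer than a given fraction of samples — a taxon
sitting exactly on the boundary is kept.

## Filtering loss

FL(J) = 1 − ‖X₋ᴊᵀX₋ᴊ‖²\_F / ‖XᵀX‖²\_F is computed on raw counts by
default (a proportion option exists); the ratio form makes it
scale-free either way.  The DFL sequence along an ordering is obtained
incrementally: removing column c from the kept set K adds
2·Σ\_{l∈K, l≠c} G²\[c,l\] + G²\[c,c\] to the removed squared-Frobenius
mass, where G = XᵀX.  This is a factor p cheaper than p independent
evaluations and bitwise-deterministic (sequential, no chunking).
Accumulation is double precision with Kahan compensation; the
conservation identities (fl\[0\] = 0, fl\[p\] = 1, Σ DFL = 1) are tested
at 1e−10 against a naive per-set oracle.  Importance ordering is by
number of samples present (ties: total count ascending, then taxon id),
stored ascending so that removal consumes the head of the permutation.

## Filtering tests

Both tests ask, position by position, whether the observed DFL is too
large to be noise, and remove everything before the first significant
position (cutoff j\*; removal set = positions 1..j\*−1).  Default
α = 0.1.

**Null family.** Log-DFL values are right-skewed, so nulls are fitted
with a three-parameter skew-normal.  Parameters come from moment
matching (sample skewness clipped to 99.5% of the family's attainable
skewness, then the standard delta inversion) rather than maximum
likelihood: the permutation filter performs thousands of fits per run
and moment matching is orders of magnitude faster and never fails to
converge.  Degenerate inputs (fewer than 3 values, zero variance) fall
back to an empirical tail, and an all-equal DFL spectrum is a hard
error for the simultaneous test.

**Bulk-anchored fits.** When the spectrum of log-DFL values contains a
clean break — a gap of at least 5 log units (an e⁵ ≈ 150-fold jump)
above the median; count discreteness produces gaps of 1–3, genuine
noise/signal separation typically > 8 — the values above the break are
treated as the strong-signal mode and excluded from the null fit, and
the fitted tail is trusted only for observations above the break.
Observations below the break are floored by the empirical tail of the
full sample.  Rationale: a single skew-normal stretched over a strongly
bimodal spectrum places the first signal taxon's p-value just above any
reasonable α (the boundary is exactly where the fit compromises), while
a null trimmed by spread alone becomes so tight that mid-noise
positions turn spuriously significant.  The gap rule makes the null
describe the low-signal bulk — which is the test's own modeling
assumption — and reduces to the plain fitted tail on continuous
spectra, where no break exists.

**Simultaneous test.** One fit to the log-DFL values of all positions;
p\_j is the fitted upper tail at log DFL(j) (DFL = 0 gives p = 1).

**Permutation test.** For each position j, the null is the DFL at
position j of k (default 1000) uniformly random taxa orderings of the
same table — the table is preserved, only the order is randomised; this
convention is logged because the randomisation scheme is a design
choice, not a given.  Draws for position j come from the dedicated
substream `default_rng([seed, j])`, so any evaluation order — and in
particular the full and fast variants — sees identical draws.  The
empirical tail ((1 + #{null ≥ obs}) / (k + 1)) is available as an
option.

**Smoothing and cutoff.** Per-position p-values are noisy; under the
single-changepoint assumption they are smoothed with a centered running
*median* of window 3 before thresholding.  A running mean was rejected
because it provably shifts the detected crossing one position into the
signal block: at an abrupt changepoint the window at the first
significant position always averages in one large pre-boundary value.
The median is the standard edge-preserving smoother and leaves the
crossing in place.  The stored p-value sequence is additionally
monotonized (running minimum) for reporting; the first crossing is
unchanged by monotonization.

**Fast search.** The fast permutation variant evaluates the smoothed
p-value only at probed positions: galloping (1, 2, 4, 8, …) until a
significant probe, then binary search in the bracketing interval, then
verification of the two boundary positions.  Probe count is bounded by
2·⌈log₂ p⌉ + 4.  Under a monotone significance indicator with a single
crossing this returns exactly the full method's cutoff; a detected
violation at the final interval triggers a linear-scan fallback with a
warning.  Parallel workers are unnecessary at desk scale; because
position-keyed substreams fix every null draw in advance, results could
not depend on a worker count in any case.

## Diversity evaluation

Shannon index H = −Σ pᵢ ln pᵢ (natural log) per sample over positive
proportions.  Bray–Curtis dissimilarity on raw counts by default
(proportions as a sensitivity option).  PCoA uses Gower double
centering and an `eigh` decomposition; per-axis variance fractions
divide each eigenvalue by the sum of **all** eigenvalues, negative ones
included — Bray–Curtis matrices are generally non-Euclidean and zeroing
the negative part overstates the explained variance.  Coordinates are
emitted for positive eigenvalues only.  Dunn's pairwise rank test uses
mid-ranks, the Σ(t³−t) tie correction and two-sided normal p-values,
with Benjamini–Hochberg step-up over all group pairs; a fully tied
sample yields z = 0, p = 1 rather than a division error.  The
combined-matrix ordination stacks one row per (sample, filtering
method) over the union of taxa (zeros where a method removed a taxon)
and runs Bray–Curtis + PCoA on the stack, so the distance between a
sample and its own filtered replicate measures directly how much a
filter moved it.

## Contaminant scoring

For each taxon present in at least `min_positive` (default 3) samples,
two least-squares models are compared on (log₁₀ concentration, log₁₀
frequency) over its positive samples: slope −1 with free intercept
(contaminant: frequency inversely proportional to total DNA) versus
slope 0 (frequency independent of DNA).  The score is the
F(n−1, n−1) CDF at SSR₁/SSR₀ — near 0 when the contaminant model fits
far better — and a taxon is called a contaminant at score ≤ 0.1.  The
statistic is a deliberate, documented choice that preserves the
orientation and threshold idiom of frequency-based contaminant
identification; matching any particular external tool bit-for-bit is
not a goal.  Scores are invariant to rescaling all concentrations
(intercepts absorb the scale).  Taxa below `min_positive` score NA:
their regression would be driven by one or two points.

## Synthetic mock communities

The generator emulates the two laboratory designs on which filtering
methods are classically judged, with Poisson counts around per-sample
expectations (a gamma-mixing knob adds overdispersion; Poisson is the
default for the analytic tractability of the Monte-Carlo checks):

* **multi-lab design** (default): 22 signal taxa with geometric
  proportions (ratio 0.85, ≈30-fold spread), 3 labs × 20 samples,
  expected signal library 50 000 reads; each lab contributes 20 private
  noise taxa appearing with probability 0.1 per sample at Poisson mean
  5 counts.  Scales chosen to mirror a multi-lab oral mock community at
  desk size.
* **dilution design**: 3 signal taxa (0.7/0.2/0.1), 3 institutes × 6
  ten-fold dilution levels × 1 sample, base signal library 10⁶;
  15 contaminant taxa with dilution-independent expected counts
  (mean 20, lognormal heterogeneity) and 10 private noise taxa per
  institute.  Recorded DNA concentration is base/10^dilution exactly.
  The base library keeps signal dominant through the middle dilutions,
  the regime in which contaminant frequency is genuinely proportional
  to 1/concentration; at the deepest dilutions the relation flattens as
  contaminants take over the library, which the frequency score
  tolerates.

What the generator does **not** emulate: read-level error, chimeras,
taxonomy assignment noise, compositional count correlation (counts are
independent Poisson given expectations), or batch effects beyond
lab-private noise taxa.  Passing the recovery checks therefore shows
that the tests find a clean noise/signal changepoint under the designed
sparsity structure — not that any particular real dataset splits as
cleanly; real DFL spectra are more continuous, in which case the
filters reduce to their plain fitted-tail behavior and the cutoff is a
genuine statistical estimate rather than a boundary detection.

## Problem sizes and determinism

Default evaluation sizes are desk-scale by design: 60 × 82 tables for
the multi-lab checks (20 seeds), 20 × 40 tables for the fast/full
equivalence sweep (30 seeds, k = 500), 18 × 58 for the dilution-series
checks.  All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); the same seed reproduces every table,
filter result and report byte-for-byte.  The evaluation pipeline writes
plain TSV/JSON only, records seed/parameters/versions in a manifest,
and records per-method failures (e.g. a degenerate fit) without
aborting the bundle.

## Known limitations

* The permutation null randomises taxa order only; alternative nulls
  (e.g. resampling counts) would answer slightly different questions.
* The fast search guarantees the full method's cutoff only under a
  single significance crossing; with wide, heterogeneous noise blocks
  the indicator can be non-monotone, in which case the two methods may
  disagree and the full method is authoritative.
* The contaminant score is a two-model F-ratio heuristic, not a
  calibrated p-value; its threshold (0.1) is an operating convention.
* FDR-controlling filter variants, covariate-adjusted filtering,
  UniFrac/phylogenetic diversity and sparse BIOM storage are out of
  scope.
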