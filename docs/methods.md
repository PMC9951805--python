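# Methods

## Scope and data model

The package quantifies niche partitioning between two sympatric species on
three axes — space, time, diet — from two kinds of field records:

* **Detection events** (site, species, timestamp at minute precision) from a
  fixed grid of camera traps, assumed equal-effort per site (15-day
  deployments in the motivating study). An optional per-site effort column
  divides counts before normalisation when deployments were unequal.
* **Scat records** (scat id, species, set of food-item categories present).
  A category is counted once per scat (frequency of occurrence), so
  abundance within a scat is deliberately not modelled; biomass consumed is
  out of scope.

## Detection independence

Camera bursts are thinned by a greedy single-pass filter per (site, species)
group: events sorted by time; the first is kept; each later event is kept
iff it is **≥ window** minutes (default 30) after the last *kept* event.
The boundary case — exactly `window` minutes — is kept, reading "within
30 min" strictly. This greedy rule is the only order-independent single-pass
interpretation and is idempotent, which the tests enforce. Timestamps are
naive local clock times; intervals spanning midnight are handled by true
datetime differencing, with no time-zone or DST logic.

## Spatial overlap

Pianka's index on the two species' per-site detection-share vectors.
Deployed sites with no detections of either species stay in the matrix: they
contribute nothing to the index (both shares are 0) but are reported for
occupancy summaries. The index is invariant to rescaling either species'
counts and to site permutation; the test suite pins it to direct formula
evaluation at 1e-12 on random matrices.

## Temporal overlap

Times of day are angles, 2π·minutes/1440. Activity is estimated by a von
Mises kernel density estimate:

* κ̂ from the sample by maximum likelihood — Brent root of A(κ) = R̄ with
  A = I₁/I₀ evaluated via exponentially scaled Bessel functions, to
  |A(κ̂) − R̄| < 1e-9. A sample with R̄ ≈ 1 (all angles identical) has no
  finite MLE and is rejected with a suggestion to jitter; an optional
  seed-controlled ±30 s jitter is *not* applied by default since
  minute-precision ties are harmless at field sample sizes.
* Kernel concentration from Taylor's (2008) plug-in rule
  κ_bw = [3 n κ̂² I₂(2κ̂) / (4 √π I₀(κ̂)²)]^{2/5}, divided by an `adjust`
  multiplier (larger = smoother). Defaults follow the convention of the
  widely used diel-overlap software: adjust 0.8 for Δ̂1 and 1.0 for Δ̂4.
  Exact numeric parity with that software is not claimed; instead the
  estimators are validated against the package's own quadrature oracle
  (below), which is the stronger property.

Δ̂1 integrates min(f̂, ĝ) by trapezoid rule on 512 equally spaced grid
points (periodically closed); quadrature error at this resolution is far
below the 2-decimal reporting precision. Δ̂4 averages the bounded density
ratios min(ĝ/f̂, 1) and min(f̂/ĝ, 1) at the observed angles of each sample,
which makes Δ̂4(s, s) = 1 exactly; ratios are floored at densities of 1e-12
to avoid underflow blow-ups at outlying observations, and a warning is
issued when either sample has ≤ 75 points (the conventional threshold below
which Δ̂1 is preferred).

Classification uses the 0–1 scale: low Δ ≤ 0.50 < moderate ≤ 0.75 < high.
Diel periods are half-open intervals [04:00, 06:00) dawn, [06:00, 18:30)
day, [18:30, 20:30) dusk, [20:30, 04:00) night (wrapping midnight), so the
four periods partition the 1440-minute day exactly — the published period
boundaries share endpoints, and half-openness is the design choice that
makes them a partition.

## Dietary metrics

All proportions come from occurrence totals (p_i = FO_i / Σ FO), as the RFO
definition requires — not from scat counts. Natural logarithms throughout.
The item universe for H′, E, S and for n in Lst is the set of categories the
species actually used (FO > 0), *including* the non-food residues grit and
artificial matter; this convention exactly reproduces the published
richness (29, 19), diversity (2.78, 2.53) and evenness (0.86; the other
species' 0.825 prints as 0.82) values, whereas excluding them does not. A
`--exclude-nonfood` flag (off by default) drops the 'other' group first for
users who want food-only metrics. Pairwise dietary overlap is computed on
the union of the two species' categories with absent items as zero. Group
subtotals are always derived by summing item rows.

Three cells of the source composition table do not recompute from its own
rows and are treated as errata rather than targets: the species-A
domestic-animal subtotal (prints 8, rows sum to 21 — and 21/193 matches the
printed 10.9%), one species-B subtotal percentage (prints 30.7, rows give
30.645 → 30.6), one per-item RFO (prints 4.2, FO 8/193 gives 4.1), and the
Levins pairs (printed L = 9.69/Lst = 0.31 and L = 10/Lst = 0.52 versus
recomputed 9.30/0.30 and 8.86/0.44; the second pair is also internally
inconsistent with Lst = (L−1)/(n−1) at n = 19). The Levins implementation is
therefore validated by direct formula evaluation at 1e-12, and the
recomputed table values are pinned in the tests for the record.

## Synthetic data and oracles

Generators are pure functions of (parameters, seed); the documented fixture
seed is 20230221.

* **Detections**: sites multinomial from per-site intensities, times from a
  von Mises mixture per species, dates uniform. Defaults mirror the
  motivating study's magnitudes: 30 sites, 7 vs 11 occupied, 98 vs 1,321
  detections. Occupied-site intensities are log-normal(0, 1), a standard
  right-skewed model for camera-trap count heterogeneity.
* **True overlap oracle**: ∫ min(f, g) of two activity models by dense
  trapezoid quadrature at 2¹⁷ points. The integrand has kinks at density
  crossings, where adaptive quadrature needlessly subdivides; at this
  resolution the absolute error is ~1e-8, inside the 1e-6 contract. Every
  estimator test consumes this oracle rather than hard-coded constants.
* **Calibration**: two unimodal models with fixed κ whose mean separation is
  solved (Brent) so the oracle overlap hits a requested Δ within 1e-3;
  overlap is monotone decreasing in separation, which a test sweeps. At
  κ = 2 the reachable range is ≈ [0.15, 1).
* **Scats**: item count per scat uniform on a range (1–5 and 1–3 by default
  for the two civets; the uniform-within-range choice is an assumption, as
  only the ranges are reported), items sampled without replacement
  proportional to the supplied probabilities. The exact-replay mode deals
  each item's FO occurrences round-robin into the scats with most remaining
  capacity, so tabulating the result returns the input FO column exactly —
  the round-trip identity used to validate the tabulation path.

What the generator does **not** emulate: site-dependent activity curves
(spatio-temporal interaction), imperfect/variable detectability, seasonal
diet shifts, or overdispersed items-per-scat counts. Passing tests on
synthetic data therefore demonstrate estimator correctness under the stated
sampling model, not robustness to these real-data features.

## Validation problem sizes

Estimator-recovery checks run at the study's own scale or modestly above:
bias of Δ̂1/Δ̂4 is checked with 200 replicates of n = 200 per species at
true Δ ∈ {0.2, 0.39, 0.6, 0.9} (tolerance ±0.03 on the mean), KDE
convergence and concentration recovery at n = 10⁴, and law-of-large-numbers
checks at n = 10⁴ with 3σ multinomial bounds. These sizes keep the full
suite under a minute while leaving the stochastic tolerances comfortably
non-trivial.

## Known limitations

* No detection-probability correction or occupancy modelling; spatial
  shares are raw (effort-normalised at most).
* No bootstrap confidence intervals for Δ (point estimation only), and no
  Δ̂5 estimator.
* Spatial and temporal axes are treated independently.
* The published per-site count data needed to reproduce the study's spatial
  overlap value (0.32) are distributed only as that paper's supplementary
  file and are not packaged; the spatial path is validated by oracle
  equivalence instead.
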