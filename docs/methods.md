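# Methods

This note documents the models, definitions, and numerical choices behind
`opendog`, in the order the pipeline runs.

## Track processing

Raw input is 1 Hz GPS fixes (GPX 1.1 or `timestamp,lat,lon` CSV, WGS-84)
for a dog and a handler sharing one run. Quality control removes fixes
implying instantaneous speeds above a plausibility ceiling (defaults
15 m/s for dogs, 4 m/s for handlers — generous for a galloping dog and a
jogging human), collapses duplicate timestamps to the first occurrence,
and linearly interpolates gaps of up to 5 s onto the 1 Hz grid; longer
gaps are left as breaks. A track losing more than half its fixes is
rejected. All thresholds are configuration options.

Both tracks are resampled by linear interpolation onto the 1 Hz grid of
their overlapping span (minimum 30 s) and projected into a single local
equirectangular frame, x = R·Δλ·cos φ₀, y = R·Δφ (R = 6,371 km), anchored
at the handler-track centroid so both actors share one metric frame. A
chain of pairwise great-circle distances would preserve step lengths but
not the global geometry that the overlap grid and the divider walk need;
within the ≤ 10 km domain enforced by the projection, step lengths agree
with haversine distances to well under 0.1 % (validated by tests).
Headings use the navigation convention (0° = north, clockwise).

## The 18 features

Definitions needing comment:

* **OC (orientation consistency)** is the mean resultant length of the
  *turning angles* (successive heading differences), not of the raw
  headings. In a bounded field every 10-minute run covers all compass
  directions almost uniformly, so a resultant of raw headings is ≈ 0 for
  every dog and carries no signal; the turn-angle resultant measures how
  consistently the dog keeps its current direction, and is the natural
  companion of DAD (the first cosine moment of the same turn
  distribution) — the two are strongly coupled for real and simulated
  dogs alike.
* **Headings** are computed only for steps ≥ 0.2 m so that stationary GPS
  jitter does not flood the circular statistics.
* **FractalD** uses the divider (ruler) method: walk the path with rulers
  of 2–64 m, counting strides N(s) with the fractional end piece
  included; FractalD is minus the slope of the least-squares fit of
  log N(s) on log s, clipped to [1, 2] with a warning. The walk is done
  from both ends and averaged, which removes the slight direction
  dependence of a single pass and makes the estimate exactly invariant
  under time reversal. Crossings landing exactly on a polyline vertex are
  accepted with a 1e-9 parameter tolerance — without it, a ruler exactly
  equal to a segment chord (as on a Koch test curve) falls to rounding.
* **PO (path overlap)** discretizes fixes to a 5 m grid, collapses
  consecutive same-cell fixes, and reports 1 − unique/entries. Because
  the grid is axis-aligned, PO is exactly invariant only under 90°
  rotations; oblique rotations can re-bin boundary fixes (tests allow
  0.05 there).
* **ST (stamina)** is mean speed over the last third of the run divided
  by the first third; **QT (quartering)** counts sign changes of the
  dog's lateral offset from the handler's travel axis (1 m dead-band) per
  100 m of handler travel.
* A feature whose preconditions fail (e.g. sinuosity of a closed loop,
  quartering under a stationary handler) is an explicit missing value,
  never a silent zero; a run missing more than 4 features is rejected.

## Statistics

* **Standardization**: natural log then per-column z-score. Features
  bounded in [−1, 1] or [0, 1] (DAD, RAD, PTA, OC, ROC, PO) are shifted
  by 1 + 1e-6 before the log; QT (a rate that can be exactly 0) by 1.
* **Correlation screen**: pairwise-complete Pearson ρ with exact-t
  two-sided p-values and an optional Benjamini–Hochberg matrix.
* **Estimation**: two-independent-sample BCa bootstrap for median
  differences (default 5,000 resamples). The bias term comes from the
  bootstrap distribution's position relative to the observed difference,
  the acceleration from a grouped delete-one jackknife; zeroing both
  recovers the percentile interval exactly (asserted in tests), and a
  coverage simulation (N(0,1) vs N(1,1), n = 24 + 24) confirms ≥ 90 %
  coverage of the 95 % interval.
* **Discriminant analysis**: canonical axes solve the symmetric
  generalized eigenproblem B v = λ W v (between/within scatter) via
  `scipy.linalg.eigh`; when W is near-singular (condition > 1e10) a ridge
  λ·tr(W)/p with λ = 1e-3 is added and recorded. Wilks' Λ = Π 1/(1+λᵢ)
  with Bartlett's χ² approximation, df = p(g−1). With 18 features and few
  dogs the analysis can also run in PCA-score space (`dfa_space: pca`),
  which is the default for cohorts with fewer rows than features.
* **PCA + rotation**: eigendecomposition of the feature correlation
  matrix (features are already z-scored, so correlation ≡ covariance);
  4 components retained by default; varimax rotation (SVD iteration, no
  Kaiser row normalization); signs fixed so each component's largest
  loading is positive. Rotated-axis *scores* use the factor-analysis
  regression estimator F = Z C⁻¹ L (rescaled to unit sd) — the
  convention of behavioral factor software — rather than an exact
  orthogonal rotation of the PC scores.
* **Two-way Ward clustering**: dogs are clustered on their per-dog mean
  rotated scores with each axis kept at its natural scale (sd = √ of its
  variance share), so dog–dog distances reflect the data metric rather
  than whitened axes; the cut is fixed at k = 4. The axes themselves are
  clustered on the correlation distance 1 − |r| between their *loading
  profiles*: a loading column describes what an axis measures and is far
  more stable than a handful of per-dog score means (with 16 dogs the
  sampling noise of a score correlation is ±0.25, while rotated scores
  are near-orthogonal by construction — axis similarity measured there
  is mostly noise). |r| is used because the sign of a rotated axis is
  arbitrary. Dendrograms are exported as Newick strings.

## The synthetic cohort

The generator emulates the study design the analysis assumes: a handler
pacing an approximately square path (150 m side, 1.4 m/s, 3° heading
jitter, direction randomized per run) around a fixed field anchor, and
dogs simulated at 1 Hz as correlated random walks. Each second the dog's
heading is a von Mises draw (concentration κ) around a blend of its
previous heading and the bearing to a moving target — the handler offset
laterally by a sinusoid (quartering); speed is a truncated Gaussian with
exponential fatigue decay; independent Gaussian noise (sd 1.5 m) models
GPS error on the emitted fixes only. Runs last the full 600 s.

Four archetypes span the energetic-exploration and handler-focus axes:
`rover_social` (fast, moderately attracted, wide quartering),
`heeler` (slow, strongly attracted), `liner` (high persistence, weak
attraction), `independent` (fastest, near-zero attraction, strongest
fatigue). The parameter table is a declared fixture, not a fit to real
dogs, but its structure is mechanistic rather than arbitrary:

* a heeling dog carries a speed surplus over the handler's 1.4 m/s —
  without it, it cannot close distance and trails tens of meters behind;
* a fast *strongly* attracted dog would perpetually orbit the handler,
  which inflates its divider fractal dimension above every other type;
  the fast social archetype therefore gets moderate attraction and
  ranges in excursion-and-return loops;
* per-second persistence κ is lowest for the slow social type, because
  wiggle amplitude at the divider scales grows with speed.

Two modest random-effect layers add realism: per-dog individuality (one
latent quality factor moving speed and attraction together, sd 5 %) and
per-run arousal (an excited run is faster but checks in with the handler
less, sd 10 %). The arousal layer is what lets the energy and social
latent axes covary across dogs at all: principal-component scores are
exactly uncorrelated over runs, so any between-dog correlation must be
balanced by within-dog (run-to-run) anticorrelation.

What the generator does **not** model: early run termination (real runs
ended when the dog found a planted bird), autocorrelated GPS multipath
error, terrain or scent gradients, or any fitted resemblance to real
animals. Passing tests therefore demonstrate that the pipeline measures
what the generative model encodes — monotone responses to attraction,
recovery of planted cluster structure, the expected correlation signs —
not that real dogs behave like the simulator.

## Problem sizes

The default cohort is 4 archetypes × 4 dogs × 3 runs of 600 s (48 dyads,
~29,000 simulated fixes per actor set), chosen to match the emulated
study design. The bootstrap coverage check uses 200 replicates of 5,000
resamples; discriminant null behavior uses 100 label permutations at
n = 48. The full simulate → extract → analyze chain runs in well under a
minute on one CPU.

## Known limitations

* The divider estimator is biased toward 1 on paths much smoother than
  the smallest ruler and is sensitive to GPS noise at the 2–4 m scales;
  comparisons are only meaningful at a fixed scale set.
* Wilks' Λ p-values treat runs as independent, ignoring the repeated-
  measures structure of 3 runs per dog (matching the descriptive use of
  repeated runs in this workflow).
* With 16 dogs, which axes co-cluster in the two-way heatmap is fragile
  under score-based axis distances; the loading-profile distance used
  here is stable but answers a slightly different question ("do these
  axes measure overlapping feature sets") than dog-profile similarity.
* The local equirectangular frame is adequate for field-scale (< 10 km)
  work only.
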