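# Methods

This note documents the models and procedures implemented in `eegselect`,
the parameter choices that matter, and what the synthetic experiments do
and do not demonstrate.

## Signal containers and preprocessing

Recordings are channels × samples matrices with an ordered electrode
list (default: the 16-site 10–20 montage FP1…T6). Analysis spans are
explicit parameters (`start_s`, `duration_s`) rather than hard-coded, with
the convention that a recording is cut into `floor(duration/epoch_seconds)`
non-overlapping epochs of `round(epoch_seconds × fs)` samples and the
trailing remainder is discarded. Every epoch is normalized per channel to
zero mean and unit variance before feature extraction, using the
population (1/N) standard deviation; a channel that is constant (up to a
relative tolerance of 1e-12) is a hard error, because complexity features
are undefined on flat signals. Artifact rejection, surface-Laplacian
filtering and band-pass emulation are out of scope; the CSV matrix
(header = channel labels, rows = channels) is the canonical interchange
format and EDF import is an optional feature delegated to `mne`.

## SODP geometry and entropies

The second-order difference plot of a series s is the cloud of points
(x(n), y(n)) = (s(n+1) − s(n), s(n+2) − s(n+1)), length N − 2. Descriptors:

* **STD1/STD2/STD** — population standard deviations of the projections
  onto the anti-identity and identity axes, STD1 = √Var((x − y)/√2),
  STD2 = √Var((x + y)/√2), and the ellipse area STD = π·STD1·STD2. The
  projection convention is the standard Poincaré-plot one.
* **SAV** — summed angle terms over consecutive point-to-point vectors.
  Two modes are shipped because the defining formula is ambiguous in the
  literature this follows: the default "printed" mode accumulates
  (a·b)/(‖a‖² + ‖b‖²) — the *sum of squared norms* in the denominator,
  implemented verbatim — while "angle" mode accumulates
  arccos(a·b/(‖a‖‖b‖)) with the cosine clipped to [−1, 1]. Zero-length
  vectors contribute 0 (printed) or are skipped (angle). The mode is
  recorded in the feature table's config sidecar.
* **SDC / SSHD / SSVL** — summed distances of points from the origin,
  summed perpendicular distances from the 45° line (|x − y|/√2), and the
  total path length through the cloud in plotting order.
* **STA / SCC** — summed areas of sliding-triplet triangles, and summed
  distances between centroids of consecutive sliding triangles.
* **CTM(r)** — the fraction of SODP points within the radius-r disk at
  the origin; the denominator is the SODP point count, so CTM ∈ [0, 1]
  and is non-decreasing in r. Default radii {0.2, 0.5, 0.8} are absolute
  and meaningful because epochs are z-scored first.
* **SampEn(m, r)** — template matching under the Chebyshev distance with
  self-matches excluded; both embedding dimensions m and m + 1 use the
  same N − m templates so the match fractions are comparable
  (Richman–Moorman pairing). Default m = 2, r = 0.15 × SD. A series with
  no (m+1)-matches returns an `inf` sentinel rather than raising, so
  batch extraction survives pathological epochs.
* **FuzzyEn(m, τ, n, r)** — the hard threshold replaced by the membership
  μ(d) = exp(−(d/r)^n) on Chebyshev distances between delay-embedded
  vectors, no vector-baseline removal; FuzzyEn = ln φ^m − ln φ^{m+1}.
  Both φ's average over the same N − mτ templates, so the normalizing
  constants cancel in the difference of logs. Defaults m = 2, τ = 1,
  n = 2, r = 0.15 × SD.

The default per-channel roster is 12-dimensional: the seven geometric
descriptors (STD, SAV, SDC, STA, SSHD, SCC, SSVL), CTM at three radii, and
the two entropies — 192 columns for a 16-channel montage. The roster is
config-driven; STD1/STD2 are available but not in the default grid.

## Screening and fusion

The **maximum cross-correlation** matrix is computed on per-epoch feature
series averaged over channels, as the maximum over lags in
[−max_lag, max_lag] of the absolute Pearson correlation; the default
max_lag = 0 reduces to |Pearson|, since no lag window is canonical for
epoch-indexed series. A greedy pass then picks k features minimizing the
maximum correlation to the already-selected set (deterministic,
lexicographic tie-breaks). Discriminability is screened by per-(channel,
feature) one-way ANOVA at α = 0.05 and 0.01 — no multiple-testing
correction, matching the screening's exploratory role — and features are
ranked by **retention count**, the number of channels on which they are
significant. Coefficient-of-variation profiles (within-subject CVs
averaged over subjects, within-group CVs averaged over groups, and a
pooled between-group CV; sd/|mean|, flagged NaN when |mean| < 1e-12)
quantify stability. The defaults keep the top 8 low-correlation features
and fuse the top 3 by retention.

**ReliefF** is the deterministic full-pass variant: every row is an
instance, the k = 5 nearest hits and misses are found by Euclidean
distance on internally z-scored features, and weights accumulate
range-normalized differences, w_f += Σ_miss diff/(mk) − Σ_hit diff/(mk).
Fusion is channel-local — each channel's selected features are z-scored,
weighted by that channel's own ReliefF weights clipped at zero (negative
weights mark anti-informative features, which are dropped rather than
subtracted), and averaged with the weights normalized to sum 1. A channel
with no positive weight falls back to the unweighted mean of z-scores and
logs a warning.

## Optimizers

All three algorithms minimize over a box; accuracy-type objectives are
negated internally. Standalone **WOA** implements shrinking encircling
(X′ = X\* − A·|C·X\* − X|), random-whale search, and the logarithmic
spiral (X′ = |X\* − X|·e^{bl}cos(2πl) + X\*) with scalar A = 2ar₁ − a,
C = 2r₂ per whale and linear a = 2(1 − t/T). Standalone **GWO** generates
three candidates from the α/β/δ leaders with per-dimension coefficient
vectors and averages them.

The **WOA-GWO hybrid** adds, on top of the two parent mechanisms:

* *Chaotic initialization.* One logistic chain c ← 4c(1 − c) per
  dimension, seeded away from the map's fixed/periodic points
  {0.25, 0.5, 0.75} and affinely mapped into the box (tent map behind a
  flag).
* *Subpopulations.* The whale fraction interpolates linearly from 0.7 to
  0.3 across iterations (exploration-first, exploitation-later); whales
  dispatch per draw: p < 0.5 and |A| < 1 → weighted hierarchical
  (three-leader) update; p < 0.5 and |A| ≥ 1 → random search; p ≥ 0.5 →
  the hybrid spiral X(t+1) = (X\*+X_α)/2 + |C∘X\* − X|·e^{bl}cos(2πl),
  which anchors the spiral at the midpoint of the global best and the
  wolf pack's α. Wolves always take the weighted hierarchical step with
  leader weights w_i = (f_worst − f_i)/(f_worst − f_best), normalized;
  equal weights 1/3 when the population is fitness-degenerate.
* *Nonlinear convergence factor.* The default mode is
  a(t) = 2 − 2(t/T)(1 − t/T), which stays in [1.5, 2] — it never decays,
  keeping exploration pressure high for the whole run. Convergence is
  nevertheless achieved because the hybrid uses greedy (improve-only)
  acceptance: a proposal replaces an individual only if its fitness
  improves, which ratchets the population downhill (10-D Sphere reaches
  machine zero well within 300 iterations). A classic linear decay is
  available as `convergence_mode="linear"`.
* *Elite exchange.* After each generation the best whale is copied into
  the worst wolf slot and the α wolf into the worst whale slot.
* *Periodic perturbation.* Every 25 iterations (configurable) the worst
  10% of individuals are redrawn uniformly; the best individual is never
  perturbed.
* *Boundary reflection.* Out-of-bounds coordinates are folded back by
  triangle-wave reflection (clipping behind a flag).

Population diversity is tracked per iteration as the mean pairwise
Euclidean distance normalized by the box diagonal, which makes curves
comparable across problems. Binary masks come from thresholding positions
at t = 0 with a strict inequality (an exactly-zero coordinate excludes
the channel). Same seed ⇒ bit-identical results.

### Benchmarks

The registry holds 12 classic functions at a default 10 dimensions.
Three have no universally printed form and use documented recipes:
"Quadric" is the rotated hyper-ellipsoid (Schwefel 1.2); "Schaffer" is
the Schaffer-N.2 term summed over consecutive coordinate pairs;
the constrained sphere adds an exterior quadratic penalty outside half
the box range; the hybrid splits dimensions 3/3/4 across
Sphere/Rastrigin/Griewank with per-part rescaling; the composite is the
minimum over shifted, height-biased primitives with its global optimum
(value 0) at the origin sheet; Kursawe's two objectives are summed into
one (flagged as an interpretation — no analytic optimum is claimed).
No claim of bit-exact equivalence with any competition suite is made.

## Wrapper channel selection

Fitness of a mask is the mean subject-stratified 5-fold CV accuracy
(LOSO available) of a classifier trained on the fused features of the
masked channels; folds are built on subjects, so all epochs of a subject
travel together. The default classifier is gradient-boosted trees with
1000 rounds, learning rate 0.02 and depth 6; a logistic fallback keeps
desk-scale experiments fast. The all-zero mask receives the defined
penalty fitness 0 so the optimizer can recover from infeasible positions.
Cardinality-constrained searches (e.g. "best 4 channels") repair each
position by keeping the k largest coordinates — the continuous position
still carries the ranking information. Fitness values are memoized by
mask: a 16-bit space is revisited heavily across hundreds of iterations,
so distinct-mask evaluations, not objective calls, dominate the cost.
"Fitness" (mean CV accuracy) and "optimal accuracy" (best single fold)
are reported separately. Accuracy is epoch-level; subject-level majority
voting is not applied.

Classification metrics derive exactly from confusion counts
(precision, sensitivity, specificity, F1, accuracy) with zero-denominator
cases flagged NaN; AUC is the rank (Mann–Whitney) statistic with half
credit for ties.

## Synthetic cohorts

Each channel is unit-variance 1/f-shaped noise (amplitude 1.0) plus a
random-phase sinusoid drawn from the alpha band 8–12 Hz (amplitude 0.8,
RMS-normalized) plus a unit-variance broadband component (amplitude 1.0).
In AD-group recordings the planted channels (default T5, FP1, T4, F4)
become more regular: the broadband component turns into an AR(1) process
with coefficient 0.95·min(1, effect) (variance-normalized, so no
amplitude cue) and the oscillation frequency interpolates toward a draw
from the theta band 4–8 Hz. The same random draws are made regardless of
group, so at effect_size = 0 the groups are exchangeable in distribution.
A per-subject gain ~N(1, 0.05²) adds benign subject-level amplitude
variation that z-scoring removes before features are computed. Channels
are independent — no volume-conduction model — and no artifacts (blinks,
EMG) are simulated.

The default effect_size = 0.45 was calibrated once against the wrapper's
operating regime: at 1.0 a single planted channel separates the groups
perfectly, the fitness landscape plateaus at accuracy 1.0 and mask
recovery degenerates into arbitrary completions; at 0.45 one planted
channel yields roughly 0.68 epoch-level CV accuracy and the full planted
quadruple roughly 0.97, a gradient the search can climb, while the
planted-channel entropy contrast remains far below p = 0.01. The
generator defaults (15 subjects per group, 16 channels, 120 s at 256 Hz,
twelve 10-s epochs per subject) mirror a small resting-state study;
256 Hz rather than a kHz-range clinical rate keeps full-pipeline runs at
desk scale and is a config choice, not a constraint of the method.

**What passing tests show — and don't.** The synthetic cohorts plant a
complexity/regularity contrast exactly of the kind the features target,
with independent channels and stationary signals. Recovery of the planted
subset therefore validates the machinery (features measure what they
claim, fusion preserves it, the search finds it, CV has no subject
leakage), not clinical performance: real EEG has volume conduction,
artifacts, non-stationarity, and subject-level heterogeneity far beyond a
5% gain factor, and no claim about clinical accuracy follows from these
experiments.

## Numerical choices and degenerate inputs

* Population (1/N) variance throughout (z-scoring, STD descriptors, CV).
* SampEn returns `inf` (not an exception) when no higher-dimensional
  template matches; constant series with relative tolerance are an error
  (r = 0.15 × SD is undefined at SD = 0).
* MCC entries for constant series are NaN (flagged undefined); greedy
  selection treats NaN as worst-case correlation 1.
* Ties everywhere (greedy selection, retention ranking, neighbor search,
  top-k repair) break deterministically — lexicographically for names,
  by stable sort order for indices.
* The wrapper's end-to-end chance-level check uses *nested* CV (selection
  re-run inside each outer training fold): the unnested optimized fitness
  is biased upward by the maximum over explored masks even without any
  leakage, so it cannot serve as a leakage guard.
* Desk-scale problem sizes used by the test suite and the acceptance
  script: pop 30 × 300 iterations for benchmark runs; pop 20 × 60
  iterations (with memoization) for cohort channel selection; pop 12 × 25
  inside nested folds. These sizes were chosen so the distinct-mask space
  is well covered; enlarging them does not change the reported behavior.

## Known limitations

* The hybrid's subpopulation sizing, perturbation schedule and elite
  exchange protocol are reasonable choices among several consistent with
  their verbal descriptions; alternatives are exposed as configuration.
* The "printed" SAV mode is not scale-free in the way the angle mode is;
  comparisons across preprocessing variants should fix the mode.
* EDF import does not resample; recordings must already be at the target
  sampling rate.
* Epoch-level accuracy overstates subject-level screening performance
  when epochs within a subject are correlated; subject-stratified folds
  prevent leakage but the unit of inference remains the epoch.
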