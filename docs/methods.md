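# Methods

## Travel-time model

A trail is an ordered sequence of monotone-slope route segments. A
segment of distance `Td` km on a surface with horizontal average speed
`Has` contributes `Td/Has` **minutes**; if it slopes, it additionally
contributes `Td/Us` (uphill) or `Td/Ds` (downhill) **seconds**, with
`Us = 0.2` and `Ds = 0.3` km/h. The asymmetric unit convention —
horizontal term in minutes, slope term in seconds — is deliberately
preserved from the NBR 15505-2 / MIDE trail-rating tradition this
package implements: treating both terms in the same unit does not
reproduce the published per-route times, while this convention
reproduces them to the second. Internally every duration is an exact
`Fraction` of seconds; rounding happens only at rendering.

Surface difficulty maps to `Has` as very easy 5, easy 4, moderate 3,
hard 2 km/h (configurable per segment). Uphill stretches are slower
than downhill ones of equal length because `Us < Ds`.

The total time maps to the effort index: little (≤ 1 h), moderate
(1–3 h], significant (3–6 h], intense (6–10 h], extraordinary (> 10 h),
scored 1–5. Bands are half-open on the right: an exactly 3-hour trail
is *moderate*, because the bands are phrased inclusively ("up to …").

Known data caveat: in the Missão Velha worked table two printed rows
are internally inconsistent with the formula on their own printed
inputs (one matches a 0.45 km distance rather than the printed 0.5 km;
one applies the downhill constant to an uphill stretch). The engine
reproduces the formula, yielding 1 h 37 min 5 s against the printed
1 h 35 min 30 s; both classify as moderate.

## Rubric engines

Every rubric total is the plain sum or count of its components, and a
prevalence is `100·total/reference`. Full precision is stored; the
per-site rounding (integers vs 1–2 decimals) is applied only when
rendering.

* **Severity**: 26 boolean hazard items (geo/biodiversity a–i, aquatic
  j–m, climate n–v, infrastructure w–z). Bands: ≤3 slightly severe, 4–5
  moderately severe, 6–8 severe, 9–12 quite severe, ≥13 very severe.
  The bands partition the non-negative integers; checking one more item
  raises the score by exactly one.
* **Orientation and surface**: ordinal 1–5 scales with canonical
  labels. The surface class suggests a `Has` via {1: 5, 2: 4, 3: 3,
  4: 2, 5: 2} km/h, but an explicitly supplied per-trail speed always
  wins — the worked trails themselves deviate from the suggestion
  (a class-2 trail walked at 3 km/h, a class-3 trail at 2 km/h).
* **Aquatic diversity**: five components scored 0–3 against a reference
  of 15. The component legends start at 1, but 0 is admitted for absent
  features because the worked tables use it.
* **Climate exposure**: a 6-indicator × 4-seasonal-cycle grid of {1,2,3}
  cells against a reference of 72, with per-cycle column subtotals.
* **Wellness**: per-category item counts (visions, sounds, odors,
  interaction) against a reference of 60 (the national inventory of
  listed adventure-activity offers).
* **Geodiversity**: scientific, degradation-risk, educational and
  touristic values against a reference of 1600.
* **Shannon–Weaver**: `H = −Σ pᵢ ln pᵢ` over normalized proportions
  (natural log by default, configurable base), compared to the 5.5
  tropical-forest reference. H is order-invariant and maximized at
  `ln k` by the uniform distribution. Published prevalence figures for
  this indicator are rounded approximations of `100·H/5.5`; the engine
  reports the computed ratio.

## Biomechanical knee overload

Gradient walking raises maximum plantar pressure and knee load. A
linear regression of representative load against gradient (percent),
fitted by ordinary least squares and rescaled by its own zero-gradient
prediction so that `multiplier(0) = 1`, converts each segment into an
equivalent flat distance: `Σ distance · multiplier(gradient)`. Fits
with R² < 0.8 are rejected outright — below that the gradient explains
too little of the load variance to support an equivalence claim. The
default treats the gradient's magnitude as the loading variable (both
ascent and descent overload the knee); a signed variant is available.

The regression coefficients are measured in laboratory gait studies and
are supplied as configuration, not estimated from trail data; published
equivalent distances can be given directly, bypassing the model. The
accumulated-load reference is 5000 flat steps (≈ 5 km).

Derived quantities: overload percent `100·(equivalent/measured − 1)`;
additional travel time `(equivalent − measured)/Has` hours, clamped at
zero; and the effort reclassification of base + additional time. The
published additional-time values do not match this formula exactly
(differences of ~1 min; the underlying computation was not recoverable),
so the pipeline accepts externally supplied additional times and uses
the formula otherwise. The identity model (slope 0) leaves distance,
time and classification unchanged for every profile.

## Network stage

Indicator prevalences (severity, orientation, surface as percents of
their maxima 26/5/6; distance and time fixed at 100; overload and
additional time as percent increases) form the observations ×
7-variable matrix. The dependence structure is modelled as a pairwise
Markov random field for continuous data: the precision matrix Θ of a
Gaussian model, estimated by maximizing

```
log det Θ − tr(SΘ) − λ·Σ_{i≠j} |θ_ij|
```

over positive-definite matrices (S the sample correlation matrix;
penalty on off-diagonal entries only, so a diagonal S yields exactly
the identity precision and an empty network). The solver is a
block-coordinate-descent graphical lasso written in-house: each column
update is a coordinate-descent lasso regression on the current
covariance estimate; solutions along the λ path are warm-started. It is
verified in the test suite against a brute-force penalized-likelihood
optimizer on 3×3 instances (1e-4 agreement) and against an independent
library implementation.

λ is selected on a log-spaced path of 100 values from λ_max (the
largest absolute off-diagonal of S, where the network is empty) down to
0.01·λ_max, minimizing

```
EBIC = −n·(log det Θ − tr(SΘ)) + E·log n + 4·E·γ·log p
```

with E the number of edges and γ = 0.5 (γ = 0 recovers BIC). Edges are
partial correlations `w_ij = −θ_ij/√(θ_ii θ_jj)`. Strength centrality
is `s_i = Σ_j |w_ij|`, standardized to z-scores (sample SD); layouts
use Fruchterman–Reingold on absolute weights with a fixed seed.

With n < p — the worked example has only 3 trails for 7 indicators —
the sample correlation matrix is singular. The pipeline mimics the
original workflow rather than refusing: constant columns are dropped
with a warning, a ridge repair (+1e-3·I) restores positive
definiteness, and a loud small-sample warning is emitted. Per-trail
networks of the original study are **not** reproducible (the
observations feeding each per-trail correlation matrix are
unspecified); the stage is therefore validated by oracle equivalence
and synthetic recovery, not by published edge weights.

## Synthetic generators

The generators emulate the study's input shapes so every stage is
testable: trails of ~10 routes of 0.05–0.4 km with elevation changes of
a few to ~20 m (alternating or random signs) on a hard 2 km/h surface,
matching the worked route tables; GPX tracks laid east along a parallel
with 10–50 m steps and a recorded exact arc length; Bernoulli(0.35)
severity checklists (expected score 9.1, in the observed 7–11 range);
and multivariate-normal indicator data from a known sparse precision
matrix, by default a 7-node chain with partial correlations 0.3. One
global seed fans out to fixed per-generator streams
(`numpy.random.SeedSequence` spawn keys), so generators are pure
functions of (config, seed) and adding one never perturbs existing
fixtures.

What the generators do *not* emulate: GPS measurement noise and device
smoothing, fractal terrain, correlated rubric responses, non-Gaussian
indicator marginals. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated models, not robustness
to field-data artifacts.

Problem sizes used in the shipped tests were chosen to keep the whole
suite desk-scale: edge recovery uses p = 7, n = 200 over 20 replicate
seeds (≈ 3 s); distributional checks use 1000–10000 draws.

## Numerical choices

* Durations: exact rational seconds; rounding only at rendering.
* Flat detection: exact equality by default (tolerance configurable);
  the worked tables contain no flat routes.
* GPX segmentation: runs of equal elevation-change sign; runs with
  total change below `min_elev_change_m` (default 1 m) merge into their
  left neighbour (first run merges right) — deterministic and
  explainable, in place of filtering. Segment distances always sum to
  the track length.
* Glasso: convergence when the mean absolute change of the working
  covariance falls below `tol` × mean |off-diagonal of S|; max 500
  outer iterations, with the duality gap reported on failure. Exact
  zeros come from the soft-threshold, so edge counts need no epsilon.
* Ties in effort/severity bands: upper endpoint belongs to the lower
  class.
* Route tables chain altitudes row to row from an explicit start row;
  direction labels are validated against the altitude change.

## Known limitations

* The travel-time model is a rating convention, not a physiological
  model; it ignores load carriage, fitness, rests and weather, and its
  slope correction is linear in distance, not in gradient.
* The knee-overload channel is a single scalar multiplier; multi-zone
  plantar maps, joint kinetics and gait adaptation are out of scope.
* With n ≪ p the selected network says little beyond the ridge-repaired
  correlation structure; treat the worked example's network as
  illustrative, not inferential.
* Energy-expenditure models (Naismith/Tobler style), heart-rate based
  effort, map rendering and geodesic datum handling are deliberately
  not implemented.
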