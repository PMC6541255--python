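# Methods

This note documents the models implemented in `carcassdrift`, the
numerical and design choices behind them, and what the synthetic-data
tests do and do not demonstrate about real data.

## Coordinate frame and winds

All geometry lives in a planar local-tangent frame in km centred on the
primary island (an equirectangular projection with cos-latitude scaling
when converting from geographic coordinates). The domain of interest is
≲ 200 km across, where the distortion of a tangent plane is negligible,
and planar geometry keeps the integrator and the coastline-intersection
tests simple and exact.

Winds are a regular (time, y, x) grid of u/v components in m/s with a
uniform 3-h step (`WindGrid`). Sampling is bilinear over the four
surrounding nodes and linear in time between bracketing fields. Time
points beyond the series are clamped to the nearest field with a logged
warning. Positions outside the spatial hull raise an error through the
public `wind_at`; inside the advection loop a particle that leaves the
hull is instead retired at sea, since it can no longer reach the islands
of interest and the wind there is undefined.

NetCDF reanalysis input is supported opportunistically through
`xarray.open_dataset`, but the canonical interchange formats are
long-format CSV and in-memory arrays; no part of the test path depends
on NetCDF libraries.

## Drift model

Carcasses are modelled as surface-trapped particles moving at a fixed
**windage** of 2.5 % of the 10-m wind. Each particle is integrated with
4th-order Runge–Kutta at the 3-h wind step; on a constant field this
reproduces straight-line drift to machine precision (verified in tests).
Surface currents are deliberately excluded: no current product resolves
the nearshore, 3-hourly dynamics relevant at this scale, and wind drift
dominates surface-trapped carcass motion.

**Beaching** is detected by intersecting each step's chord with island
coastline polygons, not by testing endpoint containment — at 3-h steps a
particle can move several km and would otherwise tunnel through a narrow
island. The first intersection along the chord wins (across islands,
the smallest intersection parameter); the float duration `f` is the
fractional step time at the crossing, and the landing point is the
intersection itself. After beaching a trajectory does not continue.

**Releases** are uniform per unit area over the region within `d_max` km
of the island *coastline* (excluding the interior), drawn by rejection
from the enclosing centroid disc with the `r = R√u` area-uniform rule.
Defining the offshore distance `d₀` relative to the coastline (rather
than the centroid) is what makes the published nearshore-compression
scenario `d_max` = 2 km meaningful for an island whose own radius
exceeds 2 km. Subsets for smaller `d_max` are nested by construction.
Releases occur at 00:00 of each release day; whether birds in the lee of
the island should be screened from release is unknown and no screening
is applied.

Defaults: 10,000 particles per daily release in full runs (tests and the
acceptance script use 500/day, which leaves the Monte Carlo error of the
deposition series well below the detection/persistence uncertainty), a
14-day (336 h) drift cap, and a single integer seed governing release
sampling; advection itself is deterministic.

## Float function

The proportion of carcasses still afloat after `f` hours is

    p(f) = η₁ − η₁ / (1 + exp(−η₂ (f − η₃))),   p(f ≥ 336 h) = 0.

The shape parameters are not observable directly; they are derived from
two constraints: the midpoint η₃ equals the target median float duration
(7 × 24 or 9 × 24 h, the two field-supported scenarios for cold Alaskan
waters), and the function must have decayed to a small tail by the
14-day cap, operationalised as `p(336 h) = tail_prob · η₁` with
`tail_prob` = 0.01 ("nearly all sunk by 14 days"). This gives
`η₂ = ln((1 − tail_prob)/tail_prob) / (336 − η₃)`; η₁ defaults to 1.
All three parameters are overridable. The 9-day function dominates the
7-day one pointwise, so the 9-day scenario always beaches at least as
much of each release.

## Catchment analysis

A beached particle contributes its float weight `p(f)` to summaries:

* **Deposition grids** sum `p(f)` into 5 × 5 km cells indexed by each
  particle's *start* location for a given deposition-day window, mapping
  where the beached carcasses plausibly originated. Windows require
  releases from at least 3 days before they open, since carcasses
  beaching early in a window may have drifted for days.
* The **`d_max` ratio scan** compares windowed deposition on a
  neighbouring island against the primary island as the assumed maximum
  offshore distance grows, using only particles with `d₀ ≤ d_max`. If
  carcasses appear on one island and not its neighbour, the scan bounds
  how far offshore the source population can have extended. The full
  curve is returned; a crossing helper reports where the ratio reaches
  any chosen threshold (the narrative thresholds 10/20/50 % are not
  fixed by the method).
* The **daily deposition series** `P_j(i)` is the summed `p(f)` of
  particles released on day *j* that beach on day *i*, divided by the
  number of *released* particles — so `P_j(i)` is a per-carcass beaching
  probability and the mortality `M_j` it multiplies is an at-sea death
  count. Beaching days are calendar days (floor of release time plus
  float duration).

**Half-island accounting.** Because deposition on opposite shores is
driven by opposite wind regimes, the island is split into northern and
southern halves (boundary segments are labelled, by default by the sign
of their midpoint's y relative to the centroid). For the per-half
series the normalising denominator is the released particles starting in
that half's half-plane. This choice makes the estimator's sum over
halves exactly consistent with a single uniform at-sea population: each
half's effective mortality then refers to deaths in that half's waters
(≈ half the disc each), and their sum is the total without double
counting. A whole-disc denominator for both halves would double-count.

## Mortality estimation

The expected count on beach `b` at survey day `d`, given the previous
survey of that half on day `d′`, is

    C_{b,d} = (1 − φ) ρ(d − d′) C_{b,d′}
              + φ L_b Σ_{i=d′+1..d} ρ(d − i) D_i

with detection probability φ, surveyed frontage `L_b` (km), per-km daily
deposition `D_i = (M/L) Σ_{j=i−14..i} P_j(i)`, island frontage
`L` = 21.8 km (the island's maximum linear dimension, the frontage each
half presents to the wind), and two-stage persistence

    ρ(τ) = 1 (τ = 0);   ρ₀ ρ₁^{τ−1} (τ > 0),

where ρ₀ is first-day persistence (removal is fastest in the first 24 h)
and ρ₁ the subsequent daily rate. Solving for `M` under the assumption
that the effective daily mortality is constant across the releases
feeding a count gives the closed-form inversion implemented in
`effective_mortality`; the forward and inverse forms are exact algebraic
inverses (property-tested to 1e-9 over random parameter sets).

The carryover term uses `ρ(d − d′)` applied to the *observed* previous
count as printed in the source formulation. Note this is exactly
consistent in expectation with a detect-and-remove observation process
in which undetected carcasses remain (E[C_{d′}] = φ · stock implies
φ(1−φ)ρ·stock = (1−φ)ρ·E[C_{d′}]); the residual approximation is that
an undetected old carcass's true survival over the next interval is
ρ₁^{Δ} rather than ρ₀ρ₁^{Δ−1}. At the default parameters this biases
the estimate upward by a few percent on synthetic events — far inside
the detection/persistence uncertainty band.

**Monte Carlo propagation.** Detection and persistence are uncertain;
each of `n_perm` permutations (5,000 by default) draws (φ, ρ₀, ρ₁) from
normal priors φ ~ N(0.53, 0.13), ρ₀ ~ N(0.755, 0.035),
ρ₁ ~ N(0.895, 0.045), truncated to (0.01, 1] by redrawing (untruncated
draws can leave the probability range). Per permutation, every per-half
survey count is inverted to `M̃`, the per-half values are averaged
(unweighted by default, effort-weighted optionally), multiplied by the
43-day event duration, and the halves summed into one total-mortality
draw. The reported estimate is the median with 50 % and 95 % percentile
intervals; everything is bit-reproducible under a fixed seed, and
medians agree across seeds to well under 2 % at the default permutation
count.

Bookkeeping conventions: the event opens one day before the first
possible deposition day (conservatively, one day before the first
carcass report), so the first survey of each half anchors at day 0 with
a zero previous count; negative inversion numerators (counts below the
modelled carryover) are floored at zero with a warning; a positive count
with zero modelled deposition and no carryover raises an inconsistency
error. Survey counts spanning both halves are split by the recorded
north:south percentage when present, otherwise in proportion to the
per-beach frontage; the default beach-to-half map assigns North Beach to
the northern half and Benson/Lukanin/Polovina to the southern, with
individual beach frontages (10, 6.5, 3.1, 1.9 km) recovered from the
combined lengths printed in the survey table. A cross-check on the
parameter centres: persistence at a 12–13-day residence times φ = 0.53
gives a 10.6–11.9 % expected refind rate, bracketing the 12 % observed
when marked carcasses were resighted at that survey interval.

**Scenario sweep.** One estimate per (`d_max`, float-median) pair, with
common random draws across scenarios so differences reflect the
drift/float inputs rather than Monte Carlo noise. Species-scaled totals
use the in-window species fraction computed from the survey records, not
a hard-coded constant.

## Synthetic events

The generator realises the study conditions end to end so that every
stage is testable without external data:

* **Winds**: 3-hourly u/v on a 32-km grid over a ±288 km domain,
  specified as contiguous stanzas of mean direction/speed with Gaussian
  perturbations (default 8 ± 2 m/s, 20° angular sd). The default regime
  alternates northerly and southerly stanzas every 4 days — both island
  halves receive deposition over the event, as in the real meteorology.
  This matters: with a single onshore regime the far half's waters would
  be unobservable and no count-based estimator could see deaths there.
* **Event**: a true daily mortality series (default 120 deaths/day over
  43 days, within `d_max_true` = 10 km of a 5-km-radius island) is
  realised as particle releases; each beached particle is retained as a
  deposited carcass with probability `p(f)` (Bernoulli).
* **Observation**: each deposited carcass lands at a uniform position
  along its half's 21.8-km frontage and persists day to day as a
  Bernoulli chain with hazards ρ₀ then ρ₁, so its marginal presence is
  exactly the estimator's ρ(τ). Surveys cover a fixed stretch of the
  frontage, detect with probability φ, and *remove* what they find;
  undetected carcasses remain by default (matching the count model), or
  the surveyed stretch can be cleared entirely to probe the alternative
  reading of the carryover term. The default schedule alternates halves
  every 3 days (each half every 6 days, 10 km per survey), straddling
  the wind stanzas so every survey interval has modelled deposition.

Full-loop recovery on this generator (drift ensemble of 500
particles/day feeding the estimator, 1,000 permutations, priors centred
on the generating values) returns the true total within the 95 %
interval in ≥ 90 % of replicates and a median within 25 % of truth; the
acceptance suite runs 20 replicates.

What the synthetic tests do **not** show: real winds are not stanza-wise
Gaussian; real at-sea distributions are not uniform discs and need not
be stationary; real persistence varies with weather, scavenger activity
and carcass condition rather than following a time-homogeneous two-stage
chain; species composition, intactness and molt dynamics are not
simulated; and the real coastline is not a convex polygon. Passing
recovery tests demonstrates the internal consistency of the
estimator/generator pair under the stated assumptions, not the realism
of those assumptions.

## Numerical and degenerate-input choices

* RK4 with the 3-h wind step; no substepping (drift speeds of
  ≤ 0.5 km/h make the chord a good path approximation; beaching times
  are resolved within the step by the chord-intersection parameter).
* Ties between islands within one step resolve to the smallest chord
  parameter.
* `P_j(i)` denominators are per release day; ratio scans return 0 when
  the near island receives weight and the far one none, and flag the
  ratio undefined when both receive none.
* Priors are redrawn (not clipped) on truncation violations, preserving
  the shape of the admissible region.
* The permutation seed, release seed, wind-realisation seed and
  observation seed are all derived from one global seed by hashing the
  stage name (`derive_seed`), so stages are independently reproducible.

## Known limitations

* The published encounter rates (3.27, 4.11 carcasses km⁻¹) and their
  fold-changes over baseline (65×, 74×) are not exactly derivable from
  the printed survey table under either the pooled or mean-of-surveys
  formula (the pooled period-1 rate is 247/86.1 ≈ 2.87); the averaging
  scheme behind the published values is unspecified, so both variants
  are exposed and neither is asserted against those two numbers.
* The published "median persistence at day 13 = 0.23" is inconsistent
  with the persistence function at its median parameters
  (0.755 × 0.895¹² ≈ 0.200, a τ−1 vs τ exponent ambiguity); the function
  is implemented as printed and the refind cross-check uses the
  resulting 10.6–11.9 % band.
* Reproducing the published total-mortality medians (3,150–8,800)
  requires the real regional reanalysis winds for 1 Oct–24 Nov 2016,
  which are external inputs; with synthetic winds the pipeline
  reproduces the *structure* of those results (median growth with
  `d_max`, slightly higher totals under the 7-day float scenario).
* Surface currents, Stokes drift, and leeway-angle effects are excluded
  from the drift model.
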