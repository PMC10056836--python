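# Methods

This note documents the models, parameter choices and known limitations of
`spinedyn` — what each stage assumes, which knobs matter, and what the
synthetic validation does and does not demonstrate about real data.
The package is organised as a library plus numbered drivers under
`analysis/`; the workflow is a staged analysis rather than an interactive
tool, so no shell CLI is shipped — the drivers and functions are the
interface, configured through the validated JSON run configuration.

## Data model

A session is a two-channel 3-D stack: red = cytosolic morphology marker,
green = surface-receptor tag (pH-sensitive GFP variant, dark in
endosomes). Default calibration is 0.125 µm/px laterally — chosen so that
the field's "0.5 µm = four pixels" spine criterion holds exactly — and
1 µm axial section spacing. The six-session schedule T0 < 2h < 18h < 42h
< D6 < D10 (hours/days after the first training session) is a fixed
vocabulary; extra labels are rejected rather than silently ordered.
Dendrite segments carry a polyline centerline in µm; analysis segments are
30–80 µm. Spine ROIs are planar polygons in pixel coordinates whose raster
footprint is the set of pixels whose centres fall inside (half-open
semantics for integer rectangles), with a 4-pixel minimum footprint.

## Pre-processing

*Background*: the per-channel histogram mode, subtracted and floored at 0.
The mode is a deliberate choice for sparse neuropil images where most
voxels are background plateau; ties break toward the lower intensity.
Degenerate constant images come back all zero with a warning.

*Bleed-through*: estimated once per cohort from a red-only control animal
as the Theil–Sen slope of green vs red over voxels at or above the 90th
percentile of positive red signal (brightest 1,000 voxels; pairwise-median
slopes are exact on noiseless data and robust otherwise), clipped at 0,
then `green − f·red` applied globally. At realistic photon counts a true
fraction of 3×10⁻⁴ is below the shot-noise floor and estimates as 0; the
residual error inside a spine ROI is a fraction of a count and is ignored.

Both corrections are monotone — no voxel value ever increases.

## Spine detection and tracking

Detection operates on the corrected red channel: Gaussian smoothing
(σ = 1 px laterally), Otsu threshold restricted to a 3 µm tube around the
centerline, then connected components of above-threshold voxels beyond a
geometric shaft mask (0.7 µm radius — wide enough to swallow the shaft's
intensity shoulder at any plausible threshold). A component attached to
the masked shaft becomes a spine when its peak-intensity voxel lies more
than 0.5 µm beyond the shaft surface (shaft radius 0.25 µm). Measuring the
extent at the peak voxel rather than the component's outermost voxel makes
the accept/reject decision independent of the exact threshold; exactly
0.5 µm is rejected (the criterion is a strict inequality). The ROI is the
component's bounding rectangle on its peak section. On the noiseless
calibration fixture the decision is exact by construction; on rendered
cohorts with default noise, recall and precision are ≥ 0.9 (they are 1.0
at the shipped settings).

Across sessions, consecutive-session detections are matched one-to-one by
arc position along the centerline (padded linear-sum assignment:
maximal number of matches with a hard 2 µm cap, then minimal total
distance). Intensity is deliberately not used — synthetic spines are ≥1 µm
apart and real re-localized dendrites drift by less than the cap. A track
that goes unmatched closes permanently; a detection re-appearing at the
same arc opens a new track. Fate labels per session: *stable* (present now
and at the previous session), *eliminated* (present before, absent now;
counted against the previous census), *new* (first appearance after
baseline). Formation percent uses the current census as denominator and
elimination the previous one — the conventional asymmetric bookkeeping.
Dendrite-level rates are averaged per mouse, then per condition.

## Receptor quantification

Per spine and session: integrate each channel inside the ROI footprint per
section and keep the sum of the three brightest sections, selected
independently per channel by default (a config switch shares the
morphology channel's sections instead, since the convention is ambiguous
in practice). The normalization reference is the shaft itself: two
4×4-pixel boxes centred on the centerline at ±1.5 µm arc from the spine
(stepping outward to ±3 µm if a box would overlap any spine ROI or leave
the volume), each reduced to the mean of its single brightest section on
the red channel, averaged. One brightest section per box is the documented
reading of "brightest frames"; the reference is computed per spine. Spines
whose boxes cannot be placed are flagged and excluded.

Folds are `norm(t)/norm(T0)`; baseline folds are exactly 1. Fold changes
are floored at 10⁻³ so geometric means stay defined (observed real-data
minima are ~7×10⁻³); the floor is logged whenever applied. "Persistent
spine" analyses use tracks present at all six sessions — the stricter of
the two possible readings, chosen so every fold in a series refers to the
same physical spine.

Group summaries are hierarchical geometric means (spine → dendrite →
mouse → condition, equal weight per child at each level) with SEM across
the children at each level. Up/Same/Down uses strict ±30% inequalities;
percent changes within 10⁻⁹ of the threshold count as boundary (Same) so
that a fold of 1.3 computed in floating point does not flip to Up.
Baseline-percentile groups use mid-rank percentiles `100·(rank−0.5)/n`
with right-closed 25-point bins (`group = ceil(pct/25)`), so a dendrite of
all-equal baselines (rank 50) lands in group 2; dendrites with fewer than
4 baseline spines are excluded. The late-session distribution comparison
is a two-sample Kolmogorov–Smirnov test on per-spine means of the D6 and
D10 folds (exact p for groups under 5, with a warning).

## Behaviour and correlations

Performance is the success rate (% of reach attempts retrieving the
pellet), normalized to training day 1; day 1 of the normalized series is
identically 1, so day-1 correlation cells are flagged as constant.
The paired regression matches each imaging session to the closest previous
training day (2h, 18h → day 1; 42h → day 2; D6 → day 5; D10 has no
subsequent training day and is excluded), fitting OLS per mouse and on the
across-mouse averages per timepoint. The Spearman matrix correlates, across
mice, the imaging quantity at each of the five post-baseline sessions with
performance on each of the five training days; normalized rate is the
default x-variable (switchable to raw). P-values are unadjusted; the
report carries a multiple-testing notice.

## Nested statistics

Observations nest as spine ⊂ dendrite ⊂ mouse ⊂ condition. Summaries
aggregate bottom-up with equal weight per child, so a 50-spine dendrite
cannot dominate a 5-spine one. Group differences are tested by permuting
condition labels across mouse-level summaries — the exchangeable unit —
with |Δmean| as statistic: full enumeration (exact p) when the number of
distinct assignments is at most `n_perm`, otherwise Monte-Carlo with the
add-one estimator `(b+1)/(n_perm+1)`. This deliberately replaces nested
random-effects mixed models: those are off-the-shelf machinery, and a
mouse-level permutation test gives calibrated error control (verified at
α = 0.05 over null simulations) without variance-component assumptions.
The cost is power — spine-level information enters only through the mouse
summary.

## Synthetic cohort generator

The generator is the package's validation instrument. Its layers:

* **Census** — per-interval elimination hazards ε and formation hazards φ
  derived from a programmed per-condition density multiplier, so the
  expected census follows e.g. (1, 1.07, 1.15, 1.10, 1.03, 1.00) for the
  contralateral WT preset (+15% peak at 18 h); KO contralateral peaks at
  +8%; ipsilateral drifts slightly negative. Eliminated spines never
  reappear. Spines sit ≥1 µm apart in arc; positions are rejection-sampled
  with an error after 100 attempts, and segment lengths (30–80 µm) are
  sized with headroom below the sequential-packing limit.
* **Trajectories** — baseline receptor level is log-normal (log-SD 0.6),
  with KO medians 25% below WT. Session t's observable level is
  `base · g_m(t) · exp(σ_day·Z)`, size is `size0 · exp(σ_size·V)`, Z and V
  iid standard normal per spine per session (median-one noise, so
  geometric means are unbiased for the trend). The condition trend g(t)
  (e.g. (1, 1, 1.02, 1.08, 1.2, 1.2) contralateral WT) is scaled per mouse
  by a latent log-normal factor that also scales behavioural improvement —
  the coupling that makes imaging–behaviour correlations non-trivial.
* **Rendering** — the dendrite is a flat-core/Gaussian-shoulder tube
  (radius 0.25 µm, shoulder σ 0.15 µm); each spine adds a neck tube plus a
  Gaussian head whose centre sits exactly `shaft radius + protrusion
  length` from the centerline. Red amplitude encodes size, green encodes
  size × receptor level (so the green ROI integral measures total surface
  receptor content, the quantity the normalization chain is built for).
  A per-stack log-normal gain (σ 0.05) emulates day-to-day imaging
  conditions — the thing shaft normalization exists to cancel — followed
  by red→green bleed-through (3×10⁻⁴), constant background (50 counts),
  Poisson shot noise and Gaussian read noise (σ 2), quantized to uint16.
* **Behaviour** — 100 reach attempts/day; success probability follows a
  rising curve for WT (roughly doubling by day 5) and stays flat for KO,
  with binomial sampling (a deterministic switch exists for invariance
  tests).

Noise presets: σ_day = 0.091 and σ_size = 0.05 were set — once, as part of
the study conditions — so that 2 SD of trend-free consecutive-session
percent changes lands near the 30% threshold regime (closed form:
2·100·√(e^{s²}(e^{s²}−1)) with s² = 2(σ_day²+σ_size²), ≈ 29.8%). The
threshold re-derivation is validated on the flat preset because the closed
form assumes no trend between the two sessions.

**What passing does and does not show.** The generator has no optical PSF,
no motion or registration error, no depth-dependent attenuation, no
filopodia or spine-subtype morphology, and its day noise is independent
across sessions and spines. Recovery of programmed trends therefore
validates the bookkeeping and estimators — normalization really cancels
gain, the detector really applies the 0.5 µm criterion, geometric means
really recover multiplicative trends — not robustness to optical
confounds a real microscope would add. Census-scale checks (the 20,000
spine turnover run) bypass rendering entirely and exercise the
track/fate/rate code paths on ground-truth presence tables; rendering
4,800 full stacks would add nothing to that particular check.

## Numerical choices

* Matching pads the assignment matrix with unmatched costs of 10⁶ so match
  count dominates total distance; equal-cost ties resolve deterministically.
* Detection extent comparisons are exact on the raster because all
  calibration geometry snaps to pixel multiples.
* Classification treats |pct − threshold| < 10⁻⁹ as the boundary (Same).
* Permutation p-values: exact proportion when enumerating, add-one
  estimator when sampling; degenerate all-equal data returns p = 1.
* Problem sizes in the shipped tests and drivers (2 mice × 4 dendrites ×
  25 spines rendered; 20,000 spines census-level; 5,000 transitions for the
  threshold; 200 null simulations) were chosen as the smallest cohorts at
  which the stochastic checks have comfortable margins under the presets'
  closed-form sampling variance.

## Known limitations

* ROIs are bounding rectangles of the detected component, not traced spine
  boundaries; adjacent-shaft flux inside the ROI biases folds slightly
  toward 1 (visible as ~1–2% shrinkage of programmed 20% trends).
* Re-appearing spines always start new tracks; transient detection misses
  therefore inflate turnover on noisy data (persistent-spine analyses are
  unaffected since they require presence everywhere).
* The bleed-through estimator cannot resolve fractions below the shot-noise
  floor; it returns 0 there, which is harmless at those magnitudes.
* No image registration across sessions: stacks are assumed coarsely
  re-localized, as with stage-coordinate repositioning.
* Mixed-model variance decomposition is out of scope; the permutation test
  trades power for assumption-free calibration.
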