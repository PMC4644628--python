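# Methods

## Problem and scope

`icefox` implements the analysis chain used to locate spatio-temporal
hotspots of satellite-tracked territorial predators on sea ice — the
setting is a winter tracking study of arctic foxes (*Vulpes lagopus*)
holding tundra territories along a coastline, occasionally travelling onto
the land-fast ice to scavenge. The chain is: Argos location filtering →
dynamic Brownian bridge movement models (dBBMM) per animal → population
utilization distributions over sliding 30-day time slices → hotspot
extraction with attendance chronologies → mixed-model inference on hotspot
joining and length of stay. Because the original raw tracking data were
never deposited, the package ships a synthetic scenario generator with a
complete truth ledger, so each stage can be validated by recovery tests.

All coordinates are planar meters in one shared projection. The package
never transforms geographic coordinates: projection handling is orthogonal
to the analysis and error-prone, and telemetry workflows project once,
up-front. Calendar days are UTC dates throughout (collars transmit in a
fixed UTC window, which removes timezone ambiguity).

## Argos filtering

Two stages. First, only fixes of Argos location class 3, 2 or 1 are kept
(nominal error radii < 250 m, 250–500 m, 500–1500 m; the class upper bound
substitutes for a missing per-fix radius). Second, an iterative forward
speed filter: scanning each animal's track in time order, a fix is dropped
when the straight-line speed from the last *retained* fix exceeds a
threshold; the threshold is `v_burst` = 10 km/h when the elapsed time is at
most `t_burst` = 12 min (a short acceleration bout) and `v_max` = 7 km/h
otherwise. The anchor persists after a drop, so the filter output is a
fixed point (re-filtering changes nothing) and always contains the first
fix.

Two subtleties are worth recording. The burst rule is interpreted as an
elapsed-time-conditional threshold — the simplest reading consistent with
"12-min bouts of 10 km/h". And the filter is *not* monotone in `v_max`:
raising the threshold can retain an early fast fix which then becomes the
anchor and rejects later fixes. The tests therefore assert exact
equivalence with an exhaustive-enumeration oracle on short tracks, plus the
true weaker property that a track passing clean at one threshold is
untouched at a looser one.

Animals that disperse or die are censored: all fixes on or after the
censor date are removed before analysis.

## Dynamic Brownian bridge movement model

Between consecutive fixes p1 (time t1, error SD d1) and p2 (t2, d2), the
bridge density at relative time a in [0, 1] is an isotropic bivariate
normal with mean the time-interpolated point and variance

    var(a) = T a (1 - a) sigma2m + (1 - a)^2 d1^2 + a^2 d2^2,   T = t2 - t1,

where sigma2m (m^2/s) is the Brownian motion variance. Argos error radii
are converted to Gaussian SDs as d = radius / 2 (the radius is treated as
roughly a 2-SD circular error); the factor is configurable and the
synthetic generator uses the same convention, so generator and estimator
agree by construction.

**Variance estimation.** sigma2m is estimated by leave-one-out: each fix at
an odd index within a window is predicted from its two neighbours; its
sampling distribution is the bridge density *plus its own observation error
variance* (the observed fix = true bridge position + error), i.e.
`var = T a(1-a) sigma2m + (1-a)^2 d_left^2 + a^2 d_right^2 + d_mid^2`.
Omitting the `d_mid^2` term inflates sigma2m several-fold at Argos-scale
errors; the term is part of the construction this estimator follows.

**Changepoints.** A sliding window of `w` = 9 fixes (about 2 days at the
collar duty cycle) moves one fix at a time. Each window is fit with one
sigma2m, and with two for every breakpoint at least `margin` = 3 fixes from
either end (a leave-one-out term belongs to the left part when its center
index is at or below the breakpoint). Models are scored by
BIC = 2·nll + k·ln(m) with k = 1 or 2 and m the number of leave-one-out
terms in the window; the breakpoint index itself is not counted. Ties keep
the simpler model; among equal-BIC breakpoints the earliest wins. The
chosen estimates are assigned to every segment their part spans, and each
segment's final value is the arithmetic mean over all windows covering it.
Tracks shorter than the window fall back to a single static sigma2m with a
warning; fewer than 2·margin+1 fixes is an error.

The 1-D likelihood optimizations run on log10(sigma2m) in [-8, 6] m^2/s
(a strictly positive scale parameter spanning many orders) by staged grid
refinement — three stages of 25 points, vectorized across all windows of a
trajectory, reaching ~0.008 in log10 (under 2% in sigma2m), which is far
below the sampling noise of a 4-term window fit.

**UD computation.** Each segment contributes the average of bridge
densities over 30 equally spaced alpha values (trapezoid weights), weighted
by segment duration, accumulated on a north-up raster (default cell 500 m,
commensurate with LC-1 error) and normalized to unit mass. Densities are
evaluated on a local sub-grid out to 4.5 SD (at least one cell), exploiting
the separability of the isotropic Gaussian; a variance floor of
(cell/10)^2 regularizes near-degenerate bridges. Long transmission gaps
(the ~21 h daily silence of duty-cycled collars) are bridged like any other
segment — nothing in the method caps gap length — but a max-gap option
exists. A cumulative probability contour at level p is the smallest set of
cells, in descending density order with (row, col) tie-breaks, reaching
mass p; contours therefore nest by construction. The home range is the 50%
contour of the UD fitted to the animal's on-land fixes only.

**Calibration conditions.** The estimator checks simulate pure Brownian
tracks of 200 fixes at 30-min intervals. Variance recovery uses
sigma2m = 100 m^2/s — an actively moving fox (~420 m net displacement per
half hour) — with LC3-grade error (radius 250 m, SD 125 m); the median
relative error of the mean profile stays below 15%. The per-window
estimates themselves are strongly right-skewed whenever observation error
dominates the bridge signal (error variance contributes ~3 d^2 per term
against ~T/2·sigma2m of signal), so recovery of *resting-scale* variances
(< 1 m^2/s) under Argos noise is not claimed — a limitation shared by any
windowed estimator with ~4 likelihood terms per window. Changepoint
sensitivity uses the 100-fold step 0.05 → 5 m^2/s with 10 m error SD so
that the low-variance half is identifiable at all.

## Population surfaces, time slices and hotspots

Time slices are half-open 30-day windows stepped by 14 days from the
season start (25 October by default), so consecutive slices overlap by 16
days. Within a slice, every animal with at least 2·margin+1 = 7 retained
fixes gets a dBBMM UD on a shared grid. The population UD is the cellwise
sum of the individual UDs, renormalized; land-cell mass is then zeroed and
the remainder rescaled to 1 (carrion at sea is the target signal; there
are no large herbivores to scavenge on land in this system).

Hotspot candidates come from an overlap count: per cell, how many
individual 75% contours (the moderate-to-high-use area) cover it. The
contours are taken on the *unmasked* individual UDs. This is a deliberate
design choice: with sea-masked individual UDs, an animal that never left
land still shows a sliver of offshore bridge/noise mass which rescaling
inflates into a spurious coastal 75% band, and adjacent territories then
chain into one long false coastal hotspot. With unmasked contours a
territorial animal's 75% region is simply its home range (on land), so it
contributes nothing at sea, while a visiting animal's sea-ice stay — a few
days of concentrated use — reliably enters its contour.

Sea cells with count >= 3 are grouped into 8-connected components (queen
connectivity: 500-m cells are smaller than the Argos error that smears use
across diagonals). Each per-slice candidate is then screened with the
attendance rules — at least 3 distinct animals with presence days and at
least one animal present on 2+ consecutive days (synchronous multi-day use
is what distinguishes a carcass from crossing traffic) — *before* any
cross-slice merging. The early screen matters: residual offshore smear
from several adjacent coastal home ranges can reach the count threshold,
and although such bands have essentially no attending animals and die
under the screen, merging them first would chain genuine hotspots into one
coastal region. Surviving candidates from different slices whose
footprints share or touch cells are unioned with transitive closure —
overlapping slices necessarily re-detect the same event, so some such
deduplication is implied by any per-slice analysis — and the screen is
re-applied to each merged draft.

The hotspot center is the cell with the highest population-UD value
(averaged over the contributing slices), ties broken by (row, col). On
synthetic data the argmax of the rather flat carcass-scale peak jitters by
about one cell; a UD-weighted centroid of the hotspot cells would roughly
halve that error, but the highest-value cell is the convention this
pipeline reproduces, so the centroid is not used.

## Attendance and seasonal summaries

A fix is *sea-classified* when it lies off the land mask and farther from
the home-range polygon than its own error radius; a day is a sea day when
any of its fixes is sea-classified, and days without fixes drop out of all
denominators. Presence at a hotspot on a day requires a sea-classified fix
within its own error radius of the hotspot polygon — hotspot areas at the
count threshold are often narrower than the Argos error, so strict
point-in-polygon would systematically undercount short visits; treating
the fix as an error disk mirrors how the sea/land rule already uses the
radius. A visit is a maximal run of consecutive presence days. The joining distance of a visit is measured from the
animal's chronologically last fix on the calendar day before the visit
began to the hotspot center (missing prior-day fixes are recorded as
missing, not imputed); non-joiners get their closest approach to the
center during the hotspot's active dates. Coast distance is from the
UD-mass-weighted centroid of the 50% home-range cells to the coastline.
Percentages in seasonal summaries are reported to 1 decimal with half-up
rounding, matching how such tables are printed.

## Mixed models

Joining: logistic regression of joined/not on one distance predictor with
crossed random intercepts for animal and hotspot, fit by maximum
likelihood under the Laplace approximation (the glmer default). The inner
random-effect mode is found by damped Newton (the joint objective is
strictly concave, so backtracking guarantees ascent); the outer
optimization runs Nelder-Mead on (beta, log sd_animal, log sd_hotspot)
with one restart. The implementation reproduces lme4::glmer coefficients,
log-likelihoods and standard errors to ~1e-4 on test data; the reported SE
is the fixed-effect block of the inverse full-parameter Hessian (glmer's
convention), falling back to the conditional Schur-complement SE at
boundary fits. Stay: linear mixed model of days at the hotspot on one
predictor with a hotspot random intercept, ML fit via statsmodels MixedLM;
the response is log-transformed for the travel-distance analysis only
(mirroring the asymmetric convention of the original analysis without
rationalizing it). Every fit is compared to its null by a likelihood-ratio
test on 1 df; ML (not REML) is used throughout since the comparison is on
fixed effects. A constant response short-circuits to a zero-effect flagged
fit rather than a degenerate likelihood.

Validation is simulation-based (the published coefficients cannot be
reproduced without the raw data and are treated as format references
only): at the study's design size (5 hotspots × ~21 animals, ~105 pairs;
35 stay records), the joining LRT's type-I error at nominal 5% stays
within [1%, 15%], planted strong effects have their sign recovered in
>= 90% of runs, and zero-effect Wald intervals cover 0 in >= 85%.

## Synthetic scenario generator

The generator emulates the study conditions, not fox cognition. Landscape:
a straight east-west coastline with a land strip 60 km long and 15 km
deep; 24 territory centers stratified along the coast (one per equal
interval, jittered, pairwise spacing >= 1.5 km), depths uniform in
(0, 15 km). Movement: a stationary Ornstein-Uhlenbeck walk per fox at
1-min resolution (SD 2 km, relaxation time 6 h — displacement statistics
of a patrolling territorial fox; the depth coordinate reflects at the
shoreline so non-excursing foxes never cross the coast). Carcass events: 5
planted sites 3–10 km offshore, active 8–17 days each between December and
February, with 3–12 scheduled visitors staying 1–8 days (35% repeat-visit
chance), plus 2 distractor sites with at most 2 visitors; excursions
splice directed travel at 5 km/h (below the filter ceiling) and a local OU
wander (SD 1 km) around the site into the territorial walk, continuously.

Observation model: per fox-day a usable-fix count drawn as round(N(5.3,
2.1)) clipped to [0, 9]; fix times stratified within the 14:00–17:00 UTC
duty window (one fix per equal sub-bin, jittered to the central 70%, so
successive fixes stay minutes apart and Argos-noise speed artifacts remain
rare — the realized speed-filter casualty rate is under 5% of fixes);
location classes drawn with probabilities (0.35, 0.40, 0.25) for (3, 2, 1)
— the study reports no class mix, so this is a configurable default —
position noise isotropic Gaussian with SD = radius/2.

What the generator does *not* emulate: curved coastlines, sea-ice drift,
prey-driven movement, dispersal (covered instead by the censor-table
hook), class-dependent fix availability, or any behavioral response to
carcass depletion. Passing recovery tests therefore show that the pipeline
detects synchronized multi-animal offshore use under realistic sampling
and error — not that real fox data would yield the same hotspot count.

## Numerical choices and degenerate inputs

- UD mass tolerance 1e-9; contour requires a normalized grid (1e-8).
- ESRI ASCII rasters are written with full repr precision; round-trips are
  exact to 1e-12 relative.
- Variance floor in likelihood terms: 1e-12 m^2 (guards the zero-error,
  zero-variance limit); in UD evaluation: (cell/10)^2.
- Ties: contour cells and hotspot centers break by (row, col); equal-BIC
  models prefer fewer parameters, then the earlier breakpoint.
- Zero sea mass in masking, empty trajectories, too-few on-land fixes, and
  unknown location classes raise errors naming the offender rather than
  degrading silently.

## Problem sizes used in the shipped checks

Estimator calibration runs 20 tracks × 200 fixes; hotspot recovery runs 20
full synthetic winters (24 foxes, 219 days, ~28k fixes each) end-to-end;
mixed-model error rates use 50 simulated datasets per scenario. These
sizes give binomial standard errors of a few percent on the reported
rates while keeping a full validation run in the minutes range.
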