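# Methods

This note documents the models and procedures phenotrack implements, the
defaults and why, what the synthetic generators do and do not emulate, and
the design choices made where more than one reasonable convention exists.

## Video tracker

The tracker assumes one bright animal on a darker, static arena viewed from
a fixed overhead camera. The background model is the pixel-wise mean of a
mouse-free segment (185 frames at 50 frames/s by default, i.e. ~4 s of
empty-apparatus video), Gaussian-filtered with sigma = 2 px. Per frame the
absolute difference between the Gaussian-filtered frame and the background
is thresholded at a user-set intensity value (default 25 on an 8-bit
scale); contours of the binary image are extracted by marching squares
(`skimage.measure.find_contours`), which performs boundary detection and
contour following of the binary mask in a single established step. Contour
area is computed by the shoelace formula and the animal position is the
polygon centroid of the largest-area acceptable contour. "Center" of a
contour is taken as the centroid rather than the bounding-box center; for
near-elliptical mouse blobs the two differ negligibly, and the centroid is
the stabler estimator.

Candidate rejection: a contour is discarded when its centroid is more than
`jump_limit` = 100 px from the previous position (suspended before the
first detection, when no previous position exists), outside the arena
bounds, or inside an exclusion area. On rejection, or with no contour at
all, the position is inferred to be the most recent detected location and
flagged `inferred`; before any detection it is `undefined` (NaN). A tie
between equal-area contours goes to the one nearest the previous position.
The output trajectory always has one record per input frame.

Zone occupancy converts frame counts to seconds at the frame rate; an
entrance is a change of the per-frame zone label into a zone (the session's
first in-zone frame counts as an entrance); distance is the summed
Euclidean step length of finite positions divided by the pixel scale.

Plus-maze arm entries are split into full vs jittery by penetration depth:
an excursion whose maximum distance from the central-zone polygon reaches
`full_depth` (default 4 cm) is a full entry, otherwise jittery. The depth
criterion operationalizes "stretching across the border without a full
entrance" for a centroid-only tracker, which cannot see torso posture; 4 cm
is roughly half a body length.

## Behavioral metrics

All metrics are pure functions of their event/occupancy inputs. Ratio
metrics (preferences, commitment) lie in [0, 1]; novelty-seeking and the
grooming ratio are relative differences, unbounded below and at most 1.
Zero denominators produce NaN and propagate as missing. Grooming events
shorter than 1 s are excluded before any summary (the cutoff is strict:
an exactly 1-s bout is kept). Y-maze multisession metrics are ordinary
least-squares slopes of percent-correct against session number over
sessions 1–3; with equally spaced sessions this equals (s3 − s1)/2.

The novelty-seeking formula — (baseline entrances − test entrances) over
baseline entrances — is implemented with this printed sign even though a
*drop* in entrances then yields a *positive* score; callers who prefer the
intuitive direction can negate the column.

## Eyeblink scoring

Each trial's baseline is the mean of the 200 ms preceding CS onset (trial
start for US-only trials); the full UR range is the mean, over the 10
US-only trials, of the peak deflection above baseline (mean rather than max
across trials, as the stabler estimator of full closure). Traces are
rescaled so baseline → 0 and full closure → 1. The CR criterion is a
threshold crossing of 0.15 within the window (CS+100 ms, CS+280 ms],
treated as half-open; the boundary convention matters only for samples
landing exactly on an endpoint. Trials are not auto-rejected for movement
artifacts; a threshold argument exists for sensitivity analyses.

CV2 uses the standard local definition over adjacent inter-spike intervals,
bounded in [0, 2) and invariant under uniform time rescaling; firing
frequency is (N−1) spikes over the spanned time.

## Gait

Stance is computed as the mean left–right placement separation within a
girdle, projected perpendicular to the locomotion axis (the principal axis
of all placements), matching the conventional stance-width reading of a
left-vs-right paw distance. An alternative reading — separation measured
*along* the direction of locomotion — appears in some descriptions of the
same measurement; the perpendicular projection is adopted because stance
width is a lateral quantity and forward stagger between paired steps would
otherwise dominate. Left/right placements are paired by step index after
trimming to the common length.

## Eigenbehavior statistics

Controls are z-scored by their own mean and SD (sample SD, ddof = 1); the
PCA is the SVD of the z-scored control matrix, whose column means are
exactly zero, so covariance-PCA and correlation-PCA coincide. Loadings are
unit-norm, ordered by descending control variance, with each loading's
largest-magnitude entry made positive for reproducible reporting. Groups
are projected after z-scoring with the *control* mean/SD, making projection
an isometry on z-scored data: the full component set preserves any group's
total variance.

High-contribution components must pass all three criteria: |mean score
difference from controls| ≥ 0.01 (in component-score units — the data's
natural units after control normalization), ≥ 10% of the group's projected
variance, and two-sample t-test p < 0.05. Fitting requires at least one
more control than metrics; mice missing any metric of a task's subset
should be dropped before fitting, while the correlation network uses
pairwise-complete observations.

Spearman correlation p-values are exact permutation probabilities: for
n ≤ 9 the null is the exhaustive set of n! rank permutations; above that,
10⁵ seeded Monte-Carlo draws with the add-one estimator
p = (1 + hits)/(1 + draws). Permuting whole rank vectors preserves tie
structure. The large-sample t-approximation is available as an alternative
(`method="t"`). The variance-ratio test doubles the smaller F tail;
Cohen's d uses the pooled SD with n₁+n₂−2 degrees of freedom.

## Dosage models

Volumes arrive on a common isotropic grid, axis order (anterior–posterior,
dorsoventral, mediolateral); registration is upstream of this package.
Lobule expression is |label ∧ mask| / |mask| per lobule — monotone in the
label set and bounded in [0, 1]. Mediolateral profiles are max-projections
along the AP axis averaged over the DV axis. One OLS model is fitted per
continuous behavioral metric on injected mice only (controls carry no
expression and hence no dosage information), with the three discrete
Y-maze metrics (final learning, initial/final reversal 2) excluded;
standard errors come from the usual OLS covariance with n − 5 residual
degrees of freedom, and cohorts (juvenile- vs adult-perturbed) are fitted
separately. Relative neocortical tracing expression divides each region's
positive-section count by the motor-cortex count, so the reference entry is
identically 1.

## Synthetic generators

The generators define the study conditions for all tests. Everything is
deterministic given the seed; independent `SeedSequence` streams keep the
generators decoupled.

*Video*: an anisotropic Gaussian intensity blob (sigma 10 × 6 px, amplitude
170) oriented along the direction of travel, on a gently graded static
background, with additive Gaussian pixel noise (SD 2 intensity units);
sessions open with 185 mouse-free frames. Distractor blobs (larger than the
mouse, placed > 130 px from the true position) and dropped-blob frames are
inserted at configurable rates, default 0. The generator does not emulate
photorealistic appearance, shadows, reflections, occlusion or multi-animal
scenes, so passing tests demonstrate the algorithmic correctness of the
pipeline, not robustness to those nuisances.

*Eyeblink*: trial composition is exactly 200 paired / 20 CS-only /
10 US-only in randomized order (the itemized counts, not an expected-value
90/10 split); CS 500 ms, US 30 ms co-terminating, so the US starts 470 ms
after CS onset. Eyelid transients are alpha-function bumps; CR amplitudes
default to U(0.35, 0.85) of the UR range with peak latencies U(140, 240) ms
after the CS, non-CR trials to U(0, 0.05), and trace noise SD 0.01 — planted
labels are therefore separated from the 0.15 threshold by many noise SDs,
which is what makes exact label recovery a meaningful detector test.

*Metric cohorts*: controls are multivariate normal with unit variances and
a block covariance in which distance/velocity measures correlate at 0.7
(movement dominates the leading control component) over a 0.1 background;
experimental groups add a planted per-metric mean shift and variance
inflation. No real-data features such as floor/ceiling effects, skew or
outliers are emulated.

*Expression cohorts*: injections rotate over the four lobules; the targeted
lobule's labeled fraction is drawn from N(0.21, 0.12) and spillover into an
adjacent lobule from N(0.11, 0.11) (clipped), with trace label elsewhere;
labeled voxels are placed uniformly within each lobule mask at exactly the
drawn count, so planted fractions are recovered exactly. Behavioral metrics
follow the planted linear model with Gaussian noise.

## Problem sizes and numerical choices

Calibration tests use sizes chosen to keep the whole suite fast while
retaining power: tracker accuracy on ten 1000-frame videos at 240 × 320 px;
eigenbehavior recovery over 200 seeds with 36 controls and 12 mice per
group across 10 metrics (the planted shift is 3 component-score SDs along
the dominant control eigenbehavior); p-value uniformity over 1000 seeds,
with coprime KS sample sizes (31, 37) so the discrete two-sample KS
statistic yields a near-continuous p distribution; dosage calibration over
500 seeds at n = 20 with noise SD equal to the planted-signal SD
(population R² = 0.5). For a planted-zero coefficient at n = 20 the
normalized weight is exactly t-distributed with 15 degrees of freedom, so
the expected |w| < 2 rate is P(|t₁₅| < 2) = 0.936, and the calibration test
checks agreement with that value rather than with the large-sample 0.95.

Known limitations: the tracker holds the last position indefinitely during
long detection gaps (no interpolation or re-acquisition search); EPM entry
classification depends on the configured full-entry depth; the eigenbehavior
selection criteria inherit the t-test's Gaussian assumptions; and the dosage
models are linear in lobule fractions, so conflicting or nonlinear regional
effects are out of reach by design.
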