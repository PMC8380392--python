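# Methods

This note documents the models, conventions and parameter choices behind
`vestcomp`: what each metric computes, what the synthetic-cohort generator
emulates (and does not), and the numerical decisions made where the
acquisition protocols leave the definition open.

## Coordinate and unit conventions

One frame is used everywhere: x = antero-posterior axis (cm, positive
toward the head; statokinesigram abscissa), y = lateral axis (cm, positive
toward the animal's **right**). A positive lateral barycenter position or
laterality index therefore means a rightward weight shift; after a left
vestibular lesion the expected signs are negative (leftward). Forces are in
grams, times in seconds, angles in degrees. Body torsion is the signed
angle between the tail→center and center→nose vectors, counter-clockwise
positive as seen from above, which with these axes is a bend toward the
animal's left.

## Posturography

**Stance epochs.** The barycenter is only meaningful when the animal is
static on four paws. An epoch is a maximal frame run where (i) all four paw
forces ≥ `min_paw_force` and (ii) the frame-to-frame barycenter speed ≤
`max_barycenter_speed`; runs shorter than `min_stance_duration` are
discarded. The protocol states the *concept* ("static and on its four
paws") but no thresholds, so the defaults — 5 g, 0.2 s, 2 cm/s — are
package conventions, config-overridable, chosen at the scale of a 250–350 g
rat (5 g rejects sensor noise, 2 cm/s is well below locomotion speed). The
epoch's representative frame is the arithmetic time-average of its member
frames (uniform sampling assumed; also a convention).

**Dispersion.** "Barycenter inertia" is implemented as the
duration-weighted mean squared Euclidean distance of the per-epoch
barycenter points from their duration-weighted mean — the trace of the
weighted covariance. This is the simplest rotation-invariant dispersion
summary consistent with the verbal definition; it scales as distance² and
is translation-invariant (both property-tested). Maximum lateral deviation
is By_max − By_min over epochs. Normalization follows the acquisition
protocol exactly: subtraction of the preop value for mean lateral position
and abdomen load, ratio to the preop value for inertia and maximum lateral
deviation. A missing preop baseline yields a missing value with a warning,
never an imputation; a degenerate (zero) preop baseline for the
ratio-normalized metrics is an error.

**Time averages** (laterality index, rearing fraction, abdomen load) weight
each sample by its forward time difference, with the last sample carrying
the median step, so irregular sampling does not bias the average.

**Circling.** A lap is one completed 360° of cumulative unwrapped heading
(from center-point displacements) in the requested direction, inside a run
where the instantaneous speed stays at or above `circling_min_speed`;
progress is measured from the running extremum, so back-and-forth wiggling
never accumulates laps, and partial laps are not counted. "Fast laps" is
not quantified in the protocol; the default gate of 18 cm/s sits above
normal exploratory gait (~12 cm/s in the generator, and of that order in
rats) and below the tight fast rotations characteristic of the lesioned
acute phase. Left laps on a trajectory equal right laps on its mirror image
(tested). Whether circling is computed from DWB or open-field tracking is
unspecified in the source protocol; the implementation accepts any
trajectory.

## Open-field kinematics

Distance is the summed step length of the smoothed center path; mean
velocity is distance over elapsed time; mean acceleration is the
time-averaged *magnitude* of the second finite difference (the protocol
says only "mean acceleration"; the magnitude is the only choice that is
non-zero for curved steady motion and matches v²/r on a circle, which is
tested). Positions are boxcar-smoothed over 0.5 s before differentiation —
raw second differences on 25–30 Hz tracker output amplify pixel jitter into
the acceleration estimate; the window is configurable and 0 disables it.
Torsion uses the tail→center→nose bend angle; "the angle between the nose
and the tail" is not self-contained, and the bend angle is the standard
tracker definition that is translation/rotation-invariant and
mirror-antisymmetric. Locomotor parameters are normalized as post/preop
ratios, torsion as post − preop difference, per the protocol. Masked
(missing) tracker samples are excluded from differentiation, not
interpolated.

## Image quantification

**Support surface** is the shoelace area of the paw quadrilateral in
perimeter order FL→FR→RR→RL; collinear/duplicate configurations give area 0
with a warning. Sessions are the mean of the (nominally 10) landing trials
and are expressed relative to the animal's preop session (preop ≡ 1). Paw
centroids come from annotation tables; a simple blob detector is available
but the annotation path is primary, since the original "image analysis
system" is unspecified.

**Membrane fluorescence.** Threshold T = mean + 3·SD of a user-outlined
background region (≥ 50 px) devoid of stained structures; T is subtracted
image-wide and negative values discarded; within each membrane ROI the
reported value is the mean of retained pixels ≥ 80 % of the ROI maximum.
The phrase "20 % above the maximum values" in the source protocol cannot be
read literally (no pixel exceeds the maximum); the top-20 %-of-maximum band
is the interpretation implemented, chosen because it matches the stated
intent of restricting the average to membrane pixels. It is a documented
interpretation, not an assertion of the original authors' code. Note the
reported value is on the *threshold-subtracted* scale: a ring of true
intensity I over a background N(μ, σ) reports ≈ I − (μ + 3σ).

**Cell counts** use background subtraction (median + 3 robust SD by
default), connected components and a minimum area, with only centroids
inside the square counting frame counted. The frame area is taken verbatim
from the protocol text (425.10 mm²; the unit is odd for a confocal
counting chamber — almost certainly µm²-scale in reality — so the number is
config-parameterized and never hard-codes behavior). The detector is a
stand-in for manual counting and is validated **only** against planted
blobs in synthetic images, where it is exact for well-separated cells.
Per-animal values average the 10 ± 2 assessed sections; counts outside that
range warn.

**Colocalization** matches marker to nuclear centroids greedily by
increasing distance, one-to-one, within a 3 µm radius (config-overridable;
the original counting was visual overlap). **Survival** is
100 × mean(d30)/mean(d3) of the proliferation-marker counts; because
different cohorts are sacrificed at each terminal day it is computed on
group means, not per animal.

## Syndrome scale

Fixed integer weights — tumbling 5, retropulsion 4, circling 3, bobbing 2,
head tilt 1 — summed over the symptoms present (0–15). No fractional
scores; group curves are plain means over animals.

## Statistics

Normality screening uses the D'Agostino–Pearson omnibus K² (scipy), n ≥ 8
enforced, with Q–Q coordinates returned for plotting. The independent
two-way ANOVA is statsmodels OLS + type-II `anova_lm`; the split-plot
(1-between/1-within) ANOVA is computed from sums of squares in-package —
group tested against subjects-within-groups, time and interaction against
the within-subject residual — and is cross-checked against
`pingouin.mixed_anova` in the tests. No sphericity correction is applied by
default (none is reported in the source analyses); incomplete
within-subject series are dropped with a warning.

Tukey contrasts use `se_diff = √(MSE·(1/n₁ + 1/n₂))` (Tukey–Kramer;
√(2·MSE/n) when balanced) and `q = √2·|Δmean|/se_diff`, with the adjusted p
from the studentized range (scipy's numerically integrated tail) at the
family size k. Recomputation of the thirteen parseable published worked
rows fixes both conventions: the q identity reproduces every printed q
within its printed rounding, and **k = the number of groups compared within
a delay (3)** reproduces every printed p to ~3 decimals, whereas a family
of all group × time cells does not — the large error df in those tables
comes from the ANOVA error term, not from a larger family. The family size
remains configurable. The whole chain is Monte-Carlo calibrated: under a
complete null (3 × 2 cells, n = 8) the family-wise error over all cell-mean
contrasts sits at the nominal 5 % (2000 replicates), and the integrated
studentized-range tail agrees with an independent million-draw simulation
of ranges over a χ scale.

## Synthetic cohort generator

A latent syndrome intensity drives everything:

    s(t) = s∞ + (s0 − s∞)·e^(−λt)   (t = post-operative day; s(preop) = 0)

with per-group (s0, λ/day, s∞): sham (0, –, 0), placebo (0.75, 0.12, 0.10),
treated (0.85, 0.05, 0.22) — the treated group peaks higher, recovers more
slowly and plateaus higher, the qualitative pattern of the modeled
experiment. A per-animal random effect (SD 0.06) is added and the sum
truncated to [0, 1]. The exponential family is a generator convention (the
source experiment fits no curve); all magnitudes are emulation targets
chosen once to land in the published ranges, not estimates of the real
data.

Per modality (all monotone in s, which is property-tested):

* **DWB streams** alternate stance / rearing / locomotion episodes with
  exponential durations; the *time share* of rearing is 0.5·(1 − s) (sham
  ≈ 50 %, the published sham mean); the left-paw weight fraction is
  0.5 + 0.20·s (leftward bias); abdomen contact occurs in stance episodes
  with probability 0.8·s carrying ~15 % of body weight; stance-to-stance
  paw-placement jitter grows with s (inflating barycenter dispersion);
  locomotion episodes move the paw set at 6 cm/s so stance detection
  excludes them. Body weight ~N(300, 15) g, 10 Hz sampling, 3 g frame
  noise.
* **Trajectories** are heading random walks at 25 Hz with wall reflection
  in an 80 × 80 cm arena; base speed 12 cm/s, suppressed by (1 − 0.6·s)
  acutely, with lesion-linked late hyperactivity (+50 % saturating after
  the acute phase); torsion offset 15°·s (per-acquisition SD 3°, per-sample
  tracker jitter 5°); left-circling bouts (fast 22 cm/s laps of radius
  8 cm) arrive Poisson with mean 9·s per acquisition during the acute phase
  and 0.5·s after.
* **Landing quads** scale a base 8 × 6 cm rectangle so the expected area
  ratio is 1 + 0.8·s (per-trial SD 0.08), 10 trials/session, sessions at
  preop and d3 onward as in the protocol.
* **Micrographs**: punctate markers are Gaussian spots planted
  Poisson-around the group × day targets (taken from the published group
  means for the lesioned groups, conventional sham baselines) inside the
  counting frame, ≥ 10 px apart so detection is exact; the membrane marker
  draws annular rings whose intensity follows its group × day target on an
  N(10, 2) background; nuclear centroids colocalize with the target
  percentage of marker cells. Only the sacrifice subset (4 animals/group at
  d3 and at d30, 10 ± 2 sections) carries images.
* **Checklists** threshold s + N(0, 0.08) at (0.14, 0.30, 0.46, 0.62,
  0.78) for head tilt → tumbling.

Determinism: every animal × timepoint × modality has its own
`SeedSequence(master_seed, spawn_key=…)`, so cohorts are bit-reproducible
and modality subsets can be generated independently.

**What the generator does not emulate:** biomechanically realistic force
waveforms or gait, video appearance, tissue morphology beyond blobs and
rings, inter-metric correlations beyond the shared latent s, attrition, or
the fact that sacrificed animals leave the behavioral study. Passing tests
therefore certify the *quantification chain* — that each metric recovers
what was planted and the statistics are calibrated — not that the generator
reproduces real rats.

## Parameter recovery

Per lesioned group, the post-operative group-mean time courses of the
normalized body torsion and support-surface ratio are jointly fit with
`a_m + b_m·e^(−λt)` sharing one λ (scipy `least_squares`, residuals
inverse-SEM weighted so precise metrics dominate, multi-start over λ₀ ∈
{0.03, 0.1, 0.3}). Bounding the plateau within one span of the data and the
amplitude at ten spans blocks the λ→0 near-linear degeneracy that an
unconstrained 3-parameter exponential exhibits on slow-recovery curves.
On noiseless curves the fit is exact; with a fully zeroed noise
configuration the cohort-level estimates are within 1 %; at default noise
with 20 animals/group the relative RMSE over replicate cohorts is ~7 %
(placebo) and ~15 % (treated, whose slower λ is intrinsically less
identified inside a 30-day window).

## Problem sizes

Simulation studies and the analysis drivers use 60 s acquisitions
(protocol lengths are 5 min DWB / 10 min open field; the full lengths
remain the config defaults) and 50 replicate cohorts for the recovery
study — sizes at which every Monte-Carlo band in the tests is several
standard errors wide.

## Known limitations

* The abdomen parameter is described in the source protocol as an "average
  time … on the ground sensors" yet expressed in grams; the grams (weight)
  reading is implemented, as reflected in the metric name.
* The published figure-level group statistics cannot be re-derived (no raw
  data are deposited); only the printed worked table rows are used as
  numeric anchors.
* The split-plot sums of squares use the classical unweighted formulas;
  for strongly unbalanced group sizes a likelihood-based mixed model would
  be preferable (out of scope).
* The cell detector is not a segmentation method; overlapping or dim cells
  in real micrographs would require a dedicated tool.
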