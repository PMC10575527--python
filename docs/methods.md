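# Methods

## The model

The virtual pivot point (VPP) hypothesis states that during single
support the ground reaction force (GRF) lines, expressed in a sagittal
frame centred on the whole-body centre of mass (CoM) with a vertical
axis parallel to gravity, converge toward a point above the CoM. The
package operationalises this with two quantities.

**Position.** Each instant $j$ of trial $i$ contributes a line with
origin $p_{ij} = (\mathrm{CoP}_x - \mathrm{CoM}_x,\; -\mathrm{CoM}_z)$
(the CoP lies on the ground, so its CoM-relative height is minus the CoM
height) and unit direction $d_{ij} = (F_x, F_z)/\lVert F \rVert$. The
VPP is the minimiser of $\sum_{ij} \lVert (I - d_{ij}d_{ij}^\top)(v -
p_{ij}) \rVert^2$, i.e. the solution of the normal equations $A v = b$
with $A = \sum (I - dd^\top)$, $b = \sum (I - dd^\top) p$. The sum is
unweighted over instants and trials; a force-magnitude-weighted variant
exists behind a flag for sensitivity analysis. $A$ is singular iff all
lines are parallel, which is reported as a degeneracy rather than a
position.

**Existence.** $R^2 = 1 - \sum (\theta_{\mathrm{Exp}} -
\theta_{\mathrm{VPP}})^2 / \sum (\theta_{\mathrm{Exp}} -
\bar\theta_{\mathrm{Exp}})^2$, where $\theta_{\mathrm{Exp}}$ is the
angle between the ground and the GRF, $\theta_{\mathrm{VPP}}$ the angle
of the CoP-to-VPP connection, and $\bar\theta_{\mathrm{Exp}}$ the grand
mean over all trials and instants of one participant-condition. Angles
are measured counterclockwise from the +x (travel-direction) ground
axis, so an upward force has $\theta \in (0, \pi)$; the statistic is
invariant under rigid rotation of the whole line set. $R^2$ is
undefined when all experimental angles coincide (zero denominator) and
can be arbitrarily negative. The VPP is classified as a point iff
$R^2 > 0.6$, strictly: a value of exactly 0.6 is not a point.

**Two granularities.** The VPP position is fitted per trial; $R^2$
pools all trials of one participant-condition, each trial predicted by
its own fitted VPP, with the grand mean taken over the pooled set. A
pooled-position mode (one fit to all lines) exists for condition-level
fan plots. Downstream, VPP coordinates are only reported when the
participant-condition is classified as having a point.

## Pipeline and parameter defaults

| parameter | default | meaning |
|---|---|---|
| `filter_cutoff_hz` | 50 Hz | kinematic low-pass cutoff (zero-phase 4th-order Butterworth) |
| `filter_forces` | off | forces are analysed unfiltered; filtering is a config option |
| `event_threshold_bw` | 0.05 BW | vertical-GRF threshold for touchdown/take-off |
| `min_contact_s` | 0.05 s | supra-threshold runs shorter than this are plate noise |
| `r2_threshold` | 0.6 | strict existence threshold on $R^2$ |
| `pooled_position` | off | per-trial VPP fits (pooled $R^2$) by default |
| `cop_trim` | 0.05 | fraction of contact trimmed per edge when *reporting* CoP curves |
| `gravity` | 9.81 m/s² | BW normalisation constant |

Notes on choices that were genuinely open:

* The forward-backward Butterworth pass squares the magnitude response,
  so the gain at the nominal cutoff is 1/2, verified against the
  frequency-response oracle in the tests.
* Touchdown is the first sample strictly above threshold of the longest
  debounced supra-threshold run; take-off is the first sample at/below
  threshold after it. The 50 ms debounce is ours: thresholds alone are
  ambiguous on noisy plates.
* The analysis timeline is the marker timeline (240 Hz by default);
  forces and CoP are linearly interpolated down to it, while event
  timestamps keep force-rate (960 Hz) resolution. The CoM is
  marker-derived, so interpolating it *up* to the force rate would
  fabricate resolution.
* Instants whose GRF magnitude is below the event threshold are excluded
  from the line set so near-zero forces cannot contribute ill-defined
  directions.
* Walking direction is normalised by mirroring x (positions and force
  components) so +x is always the direction of travel; the map is an
  involution and leaves the fitted VPP of a mirrored trial identical to
  machine precision.

## Body model

The whole-body CoM is the mass-fraction-weighted sum of segment CoMs;
each segment is a two-point rod between a proximal and a distal marker
with its CoM at a fixed fraction of the axis. The shipped default table
(head+trunk pooled into one C7–L5 segment, bilateral arm/leg segments)
uses conventional values adapted from the classical cadaver-based
body-segment-parameter literature; all correctness tests use synthetic
tables so no conclusion depends on those constants. The hand and foot
are two-point rods over the available markers (no dedicated foot-CoM
markers exist in the marker set).

Sagittal angular momentum about the CoM sums orbital terms $m_s (r_s -
r_{\mathrm{CoM}}) \times (v_s - v_{\mathrm{CoM}})$ and spin terms $I_s
\omega_s$ with rod inertia $I_s = m_s (\kappa_s \ell_s)^2$
($\kappa_s$ = radius-of-gyration fraction). Velocities are central
finite differences of the filtered positions. Counterclockwise (seen
from the subject's left, x forward, z up) is positive, so clockwise
rotation is negative. The dimensionless momentum divides by body mass ×
condition-mean speed × mean CoM height.

Ankle (or, for hand-walking, wrist) torque is quasi-static:
$\tau = [(\mathrm{CoP} - \mathrm{ankle}) \times F]/m$, neglecting foot
inertia — a standard stance-phase approximation; swing samples have no
CoP and come out masked. Joint angles are interior angles in degrees
(180° = fully extended); the trunk angle is the signed angle between the
vertical and the line from L5 to the acromion midpoint (forward lean
positive).

## Statistics

Per participant and condition, trial values are averaged. Across
participants, VPP variables ($R^2$, VPPx, VPPz) are summarised as median
± median absolute deviation (unscaled MAD — robust to the occasional
non-VPP outlier); spatio-temporal variables as mean ± s.d. The one-way
repeated-measures ANOVA uses the classical sums-of-squares
decomposition, $F = MS_{\mathrm{cond}}/MS_{\mathrm{error}}$ on
$(k-1, (n-1)(k-1))$ degrees of freedom, with classical (not partial)
$\eta^2 = SS_{\mathrm{cond}}/SS_{\mathrm{total}}$; no sphericity
correction is applied by default (an explicit choice — the design
targets the conventional uncorrected report; pingouin serves as an
independent oracle in the tests). Post-hoc pairwise paired t-tests and
the one-sample t-tests of VPPx/VPPz against zero use the Šidák level
$\alpha' = 1 - (1-\alpha)^{1/m}$. Incomplete participants are dropped
listwise from the ANOVA; a missing participant-condition is recorded as
missing, never as zero. Spatio-temporal definitions: speed = mean CoM
forward velocity over the contact; DSP time = mean of the two
double-support intervals of the measured contact; step length/width =
anterior-posterior / mediolateral distance between the two lateral
malleoli at the second touchdown; cadence = 60/(step time).

## The synthetic generator

No public dataset accompanies the VPP protocol this package implements,
so the generator is the test bed. It emulates, per trial: a three-plate
walkway with one full contact on the middle plate bracketed by the
contralateral take-off (plate 1) and touchdown (plate 3); a
double-humped vertical GRF built from two raised cosines (flat trapezoid
for the handstand-like condition, which has no braking/propulsion
humps); an anteriorly progressing CoP; a CoM advancing at the prescribed
speed with a small (1.5 cm) vertical oscillation; and GRF directions
that pass exactly through a planted VPP in the CoM frame, optionally
rotated by zero-mean Gaussian angular noise. Timing follows a periodic
gait with step time 60/cadence, contact = step time/0.76 (single support
52 % and each double support 24 % of contact — typical slow-walking duty
factors). Markers describe a planar multi-segment body; after
construction, all markers are shifted per instant so the
segment-weighted CoM equals the prescribed trajectory exactly
(reconstruction is translation-equivariant), which makes the planted CoM
an exact ground truth. Cohort defaults mirror a metronome-paced
walkway study: 11 participants × 6 conditions × 10 trials, mass
57.7 ± 6.1 kg, height 1.65 ± 0.09 m, ~80–90 steps/min, slow speeds
(0.43–0.62 m/s by condition), per-condition planted VPP heights of
0.13–0.49 m with 0.05 m between-participant spread, and alternating
walking direction. The default angular noise of 0.5° s.d. is calibrated
so the pooled $R^2$ of a participant-condition falls in the 0.93–0.99
range reported for real walking.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: physiological waveform detail (the
mid-stance valley is deeper than in human GRFs), marker soft-tissue
artefact and dropouts, frontal-plane dynamics (the mediolateral
coordinate exists only so step width is computable), genuinely inverted
handstand kinematics (that condition differs only in its force profile),
and any within-trial correlation structure in the angular noise (which
is white).

## Numerical behaviour and known limitations

* **VPPz is weakly identified.** A single-support fan spans only a few
  degrees of line directions (a 0.2 m CoP sweep at 1 m CoM height is
  ±5.7°), so the vertical coordinate of the intersection is poorly
  conditioned: at 2° angular noise the median VPPz error of a 50-line
  fan is ~0.45 m while VPPx stays within ±0.01 m. This is a property of
  the estimation problem, not the solver — the brute-force grid search
  lands on the same minimiser.
* **Downward attenuation.** Angular noise systematically pulls the
  least-squares intersection down toward the CoP origins (the median
  *signed* VPPz error is negative at every noise level). At the 0.5°
  default the bias reaches ~0.1 m for the highest plants; condition
  ordering and VPPx are preserved. Interpret absolute VPP heights from
  noisy data accordingly.
* Grid-search comparisons must respect anisotropy: the exhaustive grid
  argmin can sit several cells from the continuous minimiser along the
  flat valley; the exact equivalence bound used in the tests is
  $\lVert \hat v - g \rVert \le \sqrt{\operatorname{cond}(A)}$ × cell
  half-diagonal.
* Degenerate inputs are errors, not numbers: all-parallel lines
  (singular $A$), all-equal experimental angles (zero $R^2$
  denominator), zero-variance one-sample t-tests, sub-threshold force
  plates ("no contact"), and event orderings violating
  TD₂ < TO₁ < TD₃ < TO₂ each raise a specific exception.
* Quasi-static torque neglects foot inertia; CoM velocities are central
  differences; marker gap-filling beyond short linear interpolation and
  full inverse dynamics are out of scope.
* Test and acceptance problem sizes are deliberately desk-scale: fans of
  50–200 lines, cohorts of 1–4 participants × 2 conditions × 2 trials
  for end-to-end checks, 100-replicate power studies at the
  value-matrix level, and 1000-cohort type-I calibration of the ANOVA
  stage. The full 660-trial design is exercised at the
  specification level (deterministic trial specs) and is available from
  the CLI.
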