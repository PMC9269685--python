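# Methods notes

## Coordinate conventions and units

All positions are joint centers in millimetres in a camera-style frame:
y vertical up, x horizontal along the transfer direction, z depth.
Recordings in other frames must be pre-rotated before entering the
pipeline. Internally everything stays in mm; the only unit conversion is
DSWP's mm → cm at feature output. Angles are unsigned, in [0, 180]°,
computed as `arccos` of the clamped normalized dot product — no signed
plane-of-elevation convention is attempted, since the reliability analysis
operates on magnitudes.

The *leading* side is the side toward which the person transfers (left by
default). With `side="right"` the shoulder/elbow joint mappings mirror;
the canonical slot names keep their left-based spelling and should be read
as "leading"/"trailing".

## Recording I/O

The canonical on-disk layout is long-format CSV (`timestamp,joint,x,y,z,
valid`), chosen because it is robust to vocabulary differences between
sensors; wide layout is auto-detected on read, gzip is transparent.
Malformed numeric fields flag the sample missing rather than dropping the
frame — downstream stages decide whether to interpolate or abort, I/O never
does. Floats are written at full precision and parsed with round-trip
precision so write∘read is the identity bit for bit.

Paired recordings are aligned by mutual nearest-neighbour timestamp
matching within a tolerance (default: half the coarser sensor's frame
period). Mutual matching makes the pair count symmetric in argument order.
Whether the two capture laptops' clocks were offset-corrected is not
knowable from a recording, so a constant `offset_b` is exposed rather than
estimated.

## Harmonization

Five canonical joints feed all four features: pelvis, upper spine, both
shoulders, leading elbow. Kinect V2 supplies all five directly (SpineBase,
SpineShoulder, shoulders, elbow). The Azure lacks an upper-spine joint; it
is derived as the midpoint of ClavicleLeft/ClavicleRight. The
RealSense/Nuitrack vocabulary likewise carries left/right collar joints,
and the same midpoint rule is applied there for symmetry — whether the
original processing used a single collar point or a midpoint is not
determinable, and this choice is flagged as an assumption. A derived joint
is valid only when every source joint is tracked. Harmonization is
per-frame and stateless.

## Lift-phase segmentation

The pelvis x-trajectory of a transfer is plateau – rise – plateau. The
series is low-pass filtered with a 4th-order Butterworth applied
forward–backward (zero phase), cutoff 15 Hz by default. Two numerical
notes:

- At the nominal 30 Hz sensor rate a 15 Hz cutoff sits exactly at Nyquist,
  where a digital Butterworth is undefined; the cutoff is clamped to
  0.99 × Nyquist with a warning, making the default filter nearly
  transparent. This is consistent with the filter's role here: it exists
  only to stabilize phase detection, never to smooth the feature data.
- Zero-phase filtering is the default because a causal pass would lag the
  detected indices by the group delay; a single-pass mode is available for
  sensitivity checks (`zero_phase=False`).

The lift window is "end of first plateau" to "start of landing plateau",
operationalized as a plateau-band rule with two combined candidates:

1. *tight*: on the filtered series, the last sample before the half-rise
   point within `max(0.5·σ̂, 0.2% of displacement)` of the first-plateau
   level (and symmetrically the first sample after half-rise within the
   band below the landing level). On noiseless data this degenerates to the
   exact last-minimum / first-maximum sample.
2. *smoothed*: the same rule on a 5-sample moving-average copy with band
   `3·σ̂/√5`, which a single noise excursion cannot fool.

Lift start is the **later** of the two start candidates and lift end the
**earlier** of the two end candidates, so whichever rule is sharper for the
data at hand governs. σ̂ is a robust noise SD from the median absolute
first difference of the filtered series; plateau *levels* are medians of
the pre-10%-rise and post-90%-rise segments, and rise landmarks are read
off the smoothed copy so they cannot be triggered by one outlier. Measured
behaviour on simulated transfers: exact indices on noiseless trajectories,
95th-percentile index error ≤ 3 frames at 5 mm jitter. A single adaptive
band was rejected because on eased (C¹) ramps a wide band biases the
boundary several frames inward, clipping up to 4% of the pelvis travel out
of DSWP.

Degenerate inputs fail loudly: net displacement below 100 mm raises
"no transfer"; a monotone ramp with no dwell (≥ 0.2 s within the plateau
band) at either end raises "no plateau"; a missing-pelvis run longer than
0.5 s aborts the trial (short gaps are linearly interpolated first).
Transfers toward −x are detected from the sign of the net displacement and
analysed on the negated series; DSWP keeps its positive sign convention.

## Features

Angle features are arithmetic means of per-frame angles over the lift
window, both endpoints included, computed on **raw unfiltered**
coordinates. Frames with an untracked or geometrically degenerate joint
are excluded per feature; the excluded fraction is reported and > 25%
flags the trial low-quality. DSWP uses the raw pelvis x at the window
endpoints (falling back to the nearest tracked sample inside the window if
an endpoint is missing).

The LPOE transverse plane is body-referenced — the plane orthogonal to the
trunk vector — because the chest normal is constructed from the same trunk
basis; `transverse="lab"` switches to the lab horizontal for sensitivity
analysis. The upper arm's distal end is the elbow throughout. When the
upper arm is (near) parallel to the plane normal its projection collapses
and the frame is dropped for LPOE (or an error raised in the single-frame
API).

Invariances, asserted in tests: all angle features are invariant to global
translation and uniform scaling; LE and LPOE to every global rotation; TF
only to rotations about the lab vertical, because it references gravity.

## Reliability statistics

Both ICC forms are single-measure ICCs from the two-way ANOVA mean squares
(targets × raters, complete-case):

- inter-sensor, ICC(2,1): two-way random effects, **absolute agreement**
  (McGraw–Wong ICC(A,1)) — a systematic offset between sensors lowers it;
- intra-sensor, ICC(3,1): two-way mixed effects, **consistency**
  (McGraw–Wong ICC(C,1)) — insensitive to a fixed rater offset, hence
  ICC(3,1) ≥ ICC(2,1) on offset data, which the tests verify empirically.

SPSS-style reports often label the absolute-agreement single-measure ICC
as "two-way mixed"; the convention here follows the McGraw–Wong
definitions, and cross-checks against pingouin's `intraclass_corr` to
1e-9 (point estimates) in tests. 95% CIs use the exact F method
(Satterthwaite degrees of freedom for ICC(A,1)); CI bounds are clipped to
bracket the estimate and never exceed 1. Degenerate matrices (zero total
variance) raise rather than returning a conventional value. Sample SDs use
n−1 throughout.

Category bands: excellent (> 0.8, strict), good [0.6, 0.8], moderate
[0.4, 0.6), fair [0.2, 0.4), poor (< 0.2). The bands are half-open with
inclusive lower bounds so they partition the line; only the excellent
bound is strict.

Bland–Altman: differences d = a − b, limits m ± 1.96 s, interchangeable
when at least 95% of differences fall inside the limits. With small n the
empirical within-fraction is granular (one outlier in 70 pairs is 98.6%,
two in 30 is 93%), so "interchangeable" should be read alongside n.

Report designs: intra-sensor matrices are subjects × trial repetitions,
truncated to the common minimum repetition count (subjects with fewer
trials are truncated with a logged warning, < 2 repetitions omits the
section); inter-sensor matrices are pooled trials × sensors with
complete-case pairing. The flat CSV column set
(`feature … interchangeable`) is emitted as-is for the inter design; the
intra design writes the same columns per sensor with the pair-wise columns
empty, since one flat row cannot carry two sensors' intra ICCs.

## Score agreement

Eleven TAI items are modeled (1, 2, 7–15). Ground-truth tables derive from
a transfer-type plan: `good` trials score 1 everywhere; `feet` zeroes
item 7, `trunk` item 13, `arm` items 9 and 12 (leading-arm position before
and after the transfer), `fist` item 11. The mapping is overridable in one
dict — e.g. whether a fist grip should also zero the push-off-hand item 10
is arguable; the default zeroes only the leading-hand item. Percent
agreement is per-item exact-match counting (symmetric by construction);
accuracy vs truth is stratified by transfer type with full 2×2 confusion
counts retained. Percentages are reported at full precision; round to one
decimal for display.

## Synthetic transfer simulator

The generator is a minimal rigid-segment upper body — pelvis, trunk
(500 mm), shoulder girdle (half-width 180 mm, clavicle half-width 60 mm),
leading upper arm (300 mm) — **not** a biomechanically validated human
model. It exists to give every pipeline stage inputs with exact closed-form
ground truth:

- pelvis x: plateau, C¹ smoothstep rise of `pelvis_travel` mm over
  `lift_s`, plateau (defaults 2 s / 1 s / 2 s at 30 Hz);
- trunk flexion, elevation and plane-of-elevation profiles ramp smoothly
  during the pre/post phases but hold their prescribed values over a
  window slightly wider than the lift, so the analytic lift-phase means
  equal the profile parameters exactly and are insensitive to a few frames
  of segmentation error;
- the trunk leans toward the camera; the arm direction is built in the
  trunk frame so that the elevation and plane-of-elevation angles are the
  prescribed ones by construction.

Default magnitudes (travel 477.5 mm, TF 30.58°, LE 44.83°, LPOE 84.38°)
are typical able-bodied transfer values, so synthetic output is on the
scale of real recordings. Session simulation draws subject means from
between-subject SDs (travel 40 mm, angles 4–5°) and trial values from
within-subject SDs (20 mm, 2.5–3°), which produce realistic intra-sensor
ICCs in the 0.4–0.9 range at study-size designs.

The sensor noise model covers the failure modes seen in practice with
these devices: isotropic Gaussian jitter per joint, a pelvis-only
reporting lag (the pelvis estimate trailing the body), per-frame per-joint
dropout, and constant per-joint bias. It does **not** model correlated
occlusion (whole-limb loss for contiguous intervals tied to body pose),
skeleton mis-assignment to furniture, depth-dependent noise, or soft-tissue
artefact — so passing recovery tests demonstrates correctness of the
*analysis*, not field robustness of any sensor. Improper-technique trials
modify the motion where the 5-joint model can express it (trunk: TF capped
at 35% of nominal; arm: LPOE widened 30%); feet and fist conditions are
kinematically invisible to these five joints and only affect the score
tables. "Predicted" score tables are synthetic stand-ins for classifier
output: ground truth flipped at a per-sensor error rate.

Random streams are split per (subject, trial) for motion and per
(subject, trial, sensor) for noise with fixed per-sensor stream keys, so
adding a sensor to a design never perturbs existing trials, and equal
seeds give bit-identical output.

## Problem sizes and numerical tolerances

Test and acceptance runs use sizes chosen to make the statistics
informative while keeping the suite quick: ICC-oracle agreement on 50
random small matrices at 1e-10; ICC parameter recovery at 500 subjects ×
2 repetitions against the analytic variance ratio σ²_b/(σ²_b+σ²_w) within
0.03; noiseless end-to-end recovery over 100 random profiles within 1° /
0.5 cm; Bland–Altman Gaussian coverage at n = 1000 within 0.02 of 0.95;
segmentation at 5 mm jitter over 100 seeds, 95th-percentile error ≤ 3
frames. Angle computations clamp cosines to [−1, 1]; vectors below 1e-9 mm
are degenerate; projection degeneracy uses a relative 1e-6 threshold.

## Known limitations

- Reliability values from real recordings depend on sensor idiosyncrasies
  the simulator does not emulate (see above); the package validates the
  statistical machinery, not any particular sensor.
- Intra-sensor matrices assume repetitions are exchangeable within subject
  (no learning/fatigue ordering effect is modeled or corrected).
- One recording is assumed to contain exactly one transfer; multi-transfer
  parsing of continuous captures is out of scope.
- Only the five canonical upper-body joints are harmonized; lower-limb or
  hand analyses would need vocabulary and mapping extensions.
- Published intra/inter-sensor ICC tables from real cohorts occasionally
  disagree with their accompanying text (e.g. a DSWP inter-sensor ICC
  printed as 0.25 in a table vs 0.13 in prose); such source discrepancies
  cannot be resolved computationally and no attempt is made here.
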