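# Methods

This note documents the model, the geometric data generator, the
numerical choices and the analysis battery implemented by `reachdepth`,
together with the assumptions behind them and their known limits.

## The transformation problem

Planning a reach requires converting eye-centred visual information
about the hand and the target — each seen as a retinal direction plus a
binocular disparity — into a movement vector expressed relative to the
arm.  Direction (azimuth/elevation) and depth must both be transformed:
retinal disparity only specifies distance *relative to the fixation
point*, so the brain must combine it with vergence, eye-in-head and
head-on-body signals to recover the metric movement in shoulder-centred
coordinates.  The package implements a feed-forward network that learns
exactly this mapping from geometrically exact examples and then asks
what response properties its units develop.

## Coordinate conventions and kinematics

All frames are right-handed with `+X` rightward, `+Y` anterior and
`+Z` upward; the body frame has its origin at the cyclopean eye.
Rotations are angular vectors in degrees (unit axis x angle); the
eye-in-head rotation composes onto the head-on-body rotation.

Binocular eye orientations fixating a point are constructed as the
minimal rotation from each eye's *primary direction* to its
eye-to-fixation direction.  The minimal rotation's axis is orthogonal
to the primary direction, which is precisely Listing's law.  Three
oculomotor refinements modulate the primary direction (gains are
configuration parameters of `GeometryParams`):

* binocular extension (L2): each eye's Listing plane rotates temporally
  about the vertical axis by `l2_gain * vergence / 2` (default gain 1);
* static torsional VOR: ocular counter-roll of `-counter_roll_gain`
  times the head roll about the gaze line (default 0.1);
* Listing-plane pitch tilt of `pitch_tilt_gain` times head pitch
  (default 0.5).

These gains are literature-typical values, not fitted quantities.  The
interocular distance is 6.5 cm (standard adult); the right shoulder
sits 15 cm right and 30 cm below the cyclopean eye; head rotations are
centred on the cyclopean midpoint, so head orientation affects the eye
positions only through the interocular baseline.  Any fixed linkage
choice is admissible here because the network learns whatever geometry
the generator defines; the linkage is frozen in configuration.

Projections are exact ray geometry, not small-angle approximations:
azimuth `atan2(x, y)` and elevation against the gaze plane, per eye.
Disparity is signed as left-minus-right projection angles, which makes
objects nearer than fixation positive and farther negative.  Vertical
disparity is the elevation difference in the two eyes' rotated frames
(not epipolar-rectified), so cyclotorsion produces the vertical
disparity patterns that make eye/head context recoverable from vision.

## Training-set generator

Each sample draws

* a head angular vector: uniform random axis, magnitude uniform in
  [0, 65 deg];
* a cyclopean gaze direction: eccentricity uniform in [0, 45 deg];
* a vergence angle: **exactly uniform** between the vergences of a 5 m
  and a 25 cm midline fixation (about 0.74-14.8 deg).  The fixation
  point is placed on the cyclopean gaze ray at the distance where the
  exact two-eye vergence equals the drawn angle (bisection); if that
  distance leaves [25 cm, 5 m] — which happens for eccentric gaze at
  extreme vergence — the *gaze direction* is redrawn, never the
  vergence, keeping the vergence marginal uniform by construction;
* hand and target positions: uniform in the 85 cm ball around the right
  shoulder, rejection-sampled for frontal placement in both eyes,
  cyclopean eccentricity <= 70 deg and disparities within the
  (25 deg, 10 deg) data range.

The ideal movement vector is `target - hand` in shoulder coordinates
(never exceeding 175 cm by construction of the reach ball).  The
generator emulates the statistics of the study conditions, not natural
reaching: positions are uniform rather than task-structured, there is
no visual noise, no temporal dynamics and no proprioceptive hand
signal.  Tests passing on these data show that the *transformation* is
learned and analysed correctly; they do not certify behaviour on
naturalistic input distributions.

## Input population codes (653 inputs)

* **Retinal position maps** (hand and target, 253 units each):
  Gaussian receptive fields, width sigma = 20 deg, preferred directions
  on a 10 deg grid within 90 deg eccentricity (the 19 x 19 grid clipped
  to the disk has exactly 253 nodes).  The field extends to 90 deg
  although data stay within 70 deg, avoiding edge effects.
* **Retinal disparity maps** (hand and target, 67 units each):
  separable Gaussians over (horizontal, vertical) disparity with
  per-axis width `max(10 arcmin, 1 + 0.35 |preferred component|)` deg.
  Preferred disparities live inside a (45 deg, 30 deg) ellipse on a
  graded lattice: 1 deg spacing below 2 deg, 5 deg spacing up to
  10 deg, 10 deg spacing beyond — concretely a 10 deg grid clipped to
  the ellipse (43 nodes) refined by a 5 deg grid on [-10, 10]^2 (16 new
  nodes) and a 1 deg grid on [-1, 1]^2 (8 new nodes), 67 total.  The
  exact functional form of the disparity tuning curve is a documented
  assumption (Gaussian); every property used downstream — peak at the
  preferred value, width growing with preferred magnitude, asymmetric
  population tuning — holds for it.
* **Eye and head orientation** (6 push-pull units each): each
  angular-vector component drives an antagonistic pair at
  `0.5 +- r_k / (2 r0)` with r0 = 50 deg (eye) and 70 deg (head).  The
  eye frame's (torsion, vertical) axes are rotated 45 deg about the
  vertical axis before encoding, mimicking the mixed vertical-torsional
  coordinates of the brainstem integrator; a 25 deg horizontal eye
  orientation yields the horizontal pair at 0.75/0.25 and all other
  units at 0.5.
* **Vergence** (1 unit): linear, 0 at zero vergence and 1 at the
  vergence of a 25 cm fixation (~14.8 deg).  Only the zero point and
  linearity are constrained by the modelled physiology; the slope
  normalisation is a frozen configuration choice.

## Network and read-out

Inputs feed a fully connected sigmoid hidden layer (HLUs, default
200, matching the published width), which feeds a fully connected
sigmoid population output layer (125 POUs).  POU preferred directions
are drawn uniformly on the sphere (Marsaglia construction) and define a
fixed linear read-out: assuming cosine tuning
`a_i = 0.5 + |M| cos(angle(M, p_i)) / (2 A_max)` with A_max = 2 m, the
optimal linear estimator weights solve `Q w = L` with
`L = E[a M^T]` and `Q = E[a a^T] + sigma_k^2 I`, sigma_k = 0.01.  The
moment matrices are evaluated by Monte-Carlo integration (10^6
movements, uniform direction, amplitude uniform in [0, 175 cm]) — the
closed forms for isotropic cosine populations are equivalent, and the
contract is behavioural: decoding ideal cosine responses of 1,000
random movements errs by well under 2 cm on average.  The read-out is
computed once and never updated by training; POU activations are not
constrained toward the cosine ideal in any way.

## Training

Only `w_in`, `w_out` and the two bias vectors are trained, by batch
minimisation of the mean squared read-out error with L-BFGS and
analytic backpropagation gradients.  Batch second-order optimisation is
one of the admissible choices here; network conclusions are known to be
robust to the training method.  Numerical choices:

* loss/gradient evaluation in single precision (the heavy dense matrix
  products), parameters and optimiser state in double precision;
* inputs standardised (frozen mean/scale of the training batch) during
  optimisation only; the affine transform is folded back into `w_in`
  and the hidden biases afterwards, so the served network operates on
  raw inputs — the reparameterisation is exact and purely a
  conditioning device;
* initial weights uniform in `+-1/sqrt(fan_in)`, seed-controlled (the
  small `smoke` profile instead uses raw inputs at scale 0.1, which
  optimises better for few hidden units);
* run to a fixed iteration budget (`TrainConfig.max_iter`) rather than
  a tolerance, mirroring the fixed-iteration protocol of the original
  study.

The default desk profile (200 HLUs, 20,000 scenes, 1,000 L-BFGS
iterations) is sized for a single CPU at roughly ten minutes of
training and fits its training set to a few centimetres; the `full`
profile reproduces the published problem size (200 HLUs, 250,000
scenes, 10,000 iterations) and is cluster-class.  Held-out error at
desk scale is limited by the training-set size, not by the network:
the transformation generalises at the published precision only from
hundreds of thousands of scenes.  The emergent unit properties (wide
population-output vs narrow hidden-layer shift distributions,
correlated eye/head depth modulation) appear only once training is
near convergence, which is why the desk profile favours a converged
network on fewer scenes over a partially converged one on more.

## Evaluation and the compensation index

Held-out evaluation reports the mean/SD Euclidean movement error, the
depth-component error (anterior-posterior axis of the default pose;
configurable to radial-from-shoulder), and compensation indices.  The
*no-compensation vector* of a sample reinterprets both retinal
observations under the default context (primary eye/head position,
50 cm fixation): the object direction is the cyclopean ray, and the
distance along it is solved from horizontal disparity by bisection.
Disparities more negative than the default context's point-at-infinity
limit (about -7.4 deg) have no geometric preimage; the inversion
therefore saturates at a plausible-workspace bound of 300 cm.  This
bound is part of the index definition: without it the diverging
reconstructions dominate the regression and the index of *any* network
tends to 1.  The compensation index is the pooled OLS slope of observed
compensation (decoded minus no-compensation vector) on predicted
compensation (ideal minus no-compensation vector); 1 means full use of
the extra-retinal signals, 0 means the network behaves as if frozen at
the default context.

## Analysis battery

All probes clamp every input to a fully specified context (default:
zero eye/head rotation, fixation 50 cm, hand and target foveal at
50 cm) and vary one or two quantities; object disparities default to
the true midline geometry of the clamped distances.  Modulators for
the shift analyses are *input-referred*: a vergence sweep moves only
the vergence unit — the probe analogue of recording experiments in
which stimulus disparity is controlled retinally, independent of
fixation distance.  (A physically coupled `fixation_distance_cm`
modulator, which also recomputes every object disparity as a real
fixation change would, is available; coupling the vergence sweep to
the disparity inputs drives hidden units through the disparity maps
and masks the gain-vs-shift distinction the analysis is designed to
expose.)  The gain-index cube and the reach-protocol simulation, whose
experimental referents place objects at physical distances, keep the
coupled geometry.

* **Response fields**: unit activation over a retinal-position grid
  (+-45 deg, 5 deg steps) or disparity grid (+-15 x +-7.5 deg, 1.5 deg
  steps).  Statistics: activation-weighted centre of mass on raw
  activations (no baseline subtraction; an above-baseline variant is a
  flag), argmax/argmin with lowest-index tie-break.
* **Shift indices**: OLS slope of the field centre of mass against a
  modulator (vergence, hand/target depth or disparity, eye/head
  rotation components), per grid axis, with R^2 and p.  Degenerate
  all-zero fields are flagged with zero slope.
* **Gain indices**: `(a_max - a_min)/(a_max + a_min)` across 4 vergence
  angles or 5 hand/target depths, computed for every combination of the
  two unrelated depth parameters and averaged; threshold 0.2 classifies
  a unit as gain-modulated.  The exact index formula follows the
  max-min contrast convention of the electrophysiological literature
  it mirrors, which also bounds it in [0, 1].
* **Separability angles**: central-difference gradients of a unit's
  activity over a 2-D grid of two depth variables; gradient directions
  are doubled, averaged circularly with magnitude weights (weighting
  suppresses flat-region noise; unweighted averaging is noisier but
  qualitatively identical), and reported in (-180, 180].  Pure
  first-axis modulation gives 0 deg, pure second-axis 180 deg,
  difference coding -90 deg (subtractive), sum coding +90 deg.
* **Sensitivity vectors**: for an HLU, the `w_in` slice of an input
  group; for a POU, that slice contracted with the unit's `w_out` row —
  the linearisation of the input-to-POU path with unit sigmoid gains.
* **Protocol simulation**: activations over 5 target x 3 initial-hand
  x 3 fixation midline distances (defaults 30-70 / 35-65 / 30-80 cm;
  the original distances are not published, so these are configurable),
  exported as a tidy table of tuning curves.
* **Distribution comparisons**: one-sided variance-ratio (F) tests for
  wider POU than HLU shift-index distributions; no multiple-testing
  correction is applied, matching the source analyses.

## Degenerate inputs and tie-breaks

All-zero response fields raise a dedicated error (COM undefined); flat
2-D fields raise for separability; constant modulators or constant COM
series regress to slope 0 and are flagged; extremum ties break at the
lowest flat index deterministically.  All analyses are deterministic
functions of a frozen network and probe configuration.

## Known limitations

* The position-code centre of mass is biased inward for stimuli beyond
  ~45 deg eccentricity (Gaussian mass truncated by the 90 deg field
  edge); COM-based decoding claims hold only in the unbiased regime.
* The no-compensation inversion ignores vertical disparity (it is
  redundant given the direction and horizontal disparity) and saturates
  outside the workspace bound.
* Eye-only rotations change binocular disparity geometry slightly
  (baseline foreshortening), so the "rotate the reconstruction by the
  gaze angle" intuition is exact for head rotations but only
  approximate for eye rotations.
* Desk-scale training does not reach the error floor of the published
  cluster-scale configuration; the acceptance analyses treat the
  published error figures as upper bounds and the distributional
  results directionally, at reduced scale.
* The model is static and rate-based, with no proprioceptive input, no
  multisensory integration and no inverse arm model.
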