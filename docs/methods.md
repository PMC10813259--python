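# Methods

This note documents the models implemented in `capsulereg`, the parameter
choices that matter, what the synthetic data emulate (and do not), and the
numerical decisions a user auditing results should know about.

## Reduced-order capsule mechanics

The capsule is a sleeve of longitudinal path-springs between two attachment
loops: each of `n_lines` (default 36, i.e. 10° circumferential spacing)
lines connects index-corresponded nodes of the acetabular and femoral loops
and follows the shortest path around the femoral-head sphere — straight when
the segment clears the sphere, otherwise tangent segment → great-circle arc →
tangent segment. The head sphere defaults to radius 22 mm at the hip center
(dual-mobility liner scale) and is configurable via `MeshConfig`.

Lines are grouped into six equal circumferential sectors numbered from the
most superior line. A sector's stiffness (N/mm) is the total for the sector,
divided evenly across its parallel lines; series subdivision along a line is
collapsed into a single path-spring, which is mechanically equivalent for
uniform properties in a quasi-static setting.

**Spring law.** Tension only. For elongation `d` beyond the slack length, the
force is a quadratic toe `k d² / (4 d_t)` up to `d = 2 d_t` and linear
`k (d − d_t)` beyond, with toe elongation `d_t` equal to 3% of slack length
(a typical ligament toe strain). Force and stiffness are continuous at the
transition, and the implemented strain energy is its exact antiderivative —
the restoring torque therefore equals the energy gradient to round-off, which
the tests verify.

**Pre-strain.** Pre-strain `p` sets tautness through the slack length
`L0 = L_ref · p^(−α)` with slack-attenuation exponent α = 0.2, where `L_ref`
is the as-meshed wrapped length at the neutral pose. `p = 1` means exactly
taut at neutral; `p < 1` means slack; larger `p` always means a tauter sector
and less laxity. The exponent is a deliberate attenuation of the raw
stretch-ratio reading `L0 = L_ref / p`: with population pre-strains down to
0.48, the raw mapping hands some sectors 45–75 mm of slack — more than
sphere-wrap geometry can take up at any physiologic rotation — leaving them
permanently unrecruited and the 5 Nm laxity undefined in most of the
population. With α = 0.2 the slack deficits span ~0.1–10 mm, every sector is
recruited somewhere in the tested rotation envelope (matching the recruitment
behavior expected of the capsule, where all six sectors engage during I-E or
Ad-Ab rotation between 0° and 90° flexion), and the mapping agrees with the
stretch-ratio form to first order near `p = 1`.

**Kinematics and laxity.** The femur rotates rigidly about the hip center
with an intrinsic flexion → ab/adduction → internal/external sequence
(three-cylindric open chain); the non-loaded rotation DOF is held neutral.
Laxity reproduces a quasi-static torque ramp: the joint first settles at its
passive equilibrium (the nearest stable zero of the restoring torque reached
from neutral), then follows the stable branch of the torque–rotation curve to
the first up-crossing of 1 Nm and then 5 Nm, each crossing bisected to an
interval below 1e-3°. The ramp formulation matters: the torque curve is only
locally monotone — at extreme rotations the wrap geometry "collapses" (path
lengths peak), and at deep flexion the curve can dip — so naive root-finding
could land on unstable or non-physical equilibria. Rotations are signed,
positive in the loaded direction; a negative laxity means the passive
equilibrium plus ramp ends short of the neutral rotation, which legitimately
happens for a tightly wound capsule in deep flexion. If the target torque is
unreachable within ±175° the solver raises rather than clipping; trial
generation records such trials as failed instead of dropping them.

The 40-metric profile evaluates 4 directions × 5 flexion angles
(0/30/45/60/90°), reading both torque levels off each of the 20 ramps.

## Attachment shape model

Attachment loops are resampled to equal arc-length spacing (numeric
arc-length parameterization of the fitted ellipse, dense trapezoidal grid),
starting at the most superior point and traversing counter-clockwise as seen
from lateral, so node indices correspond anatomically across subjects and
across the two loops. Ellipse fitting is least-squares in two stages: the
plane from the smallest singular vector of the centered points, then a direct
least-squares conic fit of the projected points.

The shape model is a plain mean-centered PCA of the concatenated
`3·(n_ace + n_fem)` coordinates; no Procrustes step is applied because inputs
are already expressed in anatomic frames with origins at the joint centers.
Scores are standardized to unit per-mode SD, so "±2" bounds in the sampling
registry mean ±2 population SDs; reconstruction is
`mean + Σ score_i · sd_i · pc_i`. Four modes are retained by default.

## Probabilistic sampling

The 16 inputs are six sector stiffnesses, six pre-strains, and four shape
scores. Defaults (means and SDs) are the package's population registry:
stiffness means 61.0/62.3/58.5/53.9/70.5/50.4 N/mm with SD 15.0, pre-strain
means 0.99/0.71/0.62/0.57/0.48/0.57 with SD 0.05, and standard-normal shape
scores. Latin hypercube sampling stratifies each marginal into `n`
equal-probability bins of the truncated normal (±1.96 SD for mechanical
parameters, covering 95% of the population; ±2 SD for shape scores), places
one uniform draw per bin, and permutes the pairing between columns; all
randomness flows through one seed, and a dataset is bit-reproducible from it.

## Surrogate and validation

Each of the 12 capsule parameters gets an independent stepwise linear model
with intercept. Selection uses 1-df partial F-tests: enter the best candidate
while its p-value is below 0.05, then drop the worst included term while its
removal p-value exceeds 0.10, iterating to a fixed point (a visited-state
guard breaks add/remove cycles; a numerically perfect fit neither attracts
nor retains noise terms). Laxity predictors are used in raw degrees and shape
scores in SD units — mixed scaling is harmless for ordinary least squares.
The intercept is retained even though the surrogate's canonical form omits
one, since the capsule parameters have nonzero means that pure linear terms
cannot anchor. Linear terms only; no interactions.

Closed-loop validation re-simulates each held-out trial with its predicted
parameters (clipped to the sampled population support — the surrogate is an
interpolator and extrapolated parameters can be unphysical) and the true
shape scores, then reports per-trial RMSE over all 40 metrics regardless of
which subset trained the model, per-metric RMSE across trials, and the
composite mean ± SD. The convergence study trains on nested subsets
(100…450 by default) against a fixed holdout and flags convergence when the
last relative change in composite RMSE is below 5%. Between-set comparisons
use two-sided Student's t-tests with equal-variance pooling on the per-trial
RMSE samples (a paired option exists, since set variants share the same
holdout).

## Synthetic data: what it emulates, what it does not

`synthetic_attachment_population` stands in for a CT-derived anatomical
database: a base pair of ellipses (acetabular ring hugging the head, femoral
ring at the lateral neck base with slight anteversion, so the sleeve is
roughly coaxial with the femoral neck) perturbed along four exactly
orthogonal displacement modes with SDs 4/3/2/1 mm — qualitatively capsule
length, a version-like A-P shift, an inclination-like lateral shift, and
acetabular depth — plus 0.1 mm isotropic node noise. The neck-coaxial sleeve
is a deliberate choice: it tolerates the full 0–90° flexion arc the way a
real capsule does (flexion partly twists rather than purely bends it), which
keeps the deep-flexion torque curves single-welled.

`synthetic_specimen` stands in for a cadaveric laxity experiment: true
parameters drawn from the population registry, laxity simulated, and only the
experimentally measurable subset exposed (I-E at 0/30/60/90° flexion, both
torque levels — 16 values) plus the true shape scores, with additive Gaussian
measurement noise (default 1.0°, a plausible motion-capture repeatability).

What passing tests on these data do **not** show: agreement with any real
anatomical database (mode shapes and variance fractions are constructed, not
measured), absolute laxity magnitudes of a physical hip (no membrane
stresses, no bone/implant contact away from the head sphere, no friction),
or accuracy against real cadaveric measurements. The closed loop is
internally consistent by design — the same engine generates and re-simulates
laxity — so its RMSE measures surrogate fidelity, not model validity.

## Numerical choices and degenerate inputs

- Ellipse resampling uses a 40 000-point trapezoidal arc-length grid; for a
  circle the inversion is exact to round-off, and segment arc lengths agree
  with adaptive quadrature to ~1e-8 relative.
- Most-superior start-node ties are broken by the anterior (A-P) component,
  then S-I; loop direction ties (normal perpendicular to M-L) fall back to
  A-P, then S-I.
- Sphere-wrap geometry treats endpoints on the sphere surface as valid;
  endpoints strictly inside raise `InvalidGeometryError`. Antipodal endpoint
  configurations pick an arbitrary but deterministic wrap plane.
- The ramp solver marches in 5° steps before bisecting; torque dips narrower
  than one step could in principle be stepped over, which matches the
  quasi-static intent (such dips are snap-through events).
- Zero-variance shape populations yield a degenerate model (zero mode SDs)
  whose reconstructions all equal the mean; projections of such modes are 0.
- Stepwise fitting rejects constant candidate columns and reports
  rank-deficient selections; trials whose simulation fails are kept in the
  dataset with a failure flag and excluded (with a logged count) from
  validation aggregates.
- Mesh resolution: halving the 10° line spacing changes solved laxity by
  under 0.5° on the default geometry, so 36 lines is treated as converged.

## Problem sizes

The shipped study sizes are 150 synthetic subjects for the shape model, 500
probabilistic trials (450 train / 50 holdout) at 36 capsule lines for the
headline closed-loop result, and coarser 60-node / 12-line configurations
with ~120–160 trials for the fast property suites in the tests. These
defaults are the package's own study conditions; all of them are arguments.

## Known limitations

- The torque ramp models the capsule as the only restraint; impingement,
  labrum, and musculature are absent, so extreme-rotation behavior is
  capsule-limited by construction.
- Pre-strain's slack-attenuation exponent is a modeling convention; other
  conventions (raw stretch ratio, engineering strain) change the absolute
  laxity scale substantially.
- Stepwise selection inherits the usual caveats (greedy, post-selection
  inference invalid); it is used here as a calibration device, not for
  hypothesis testing on coefficients.
- The six-sector division and single-sphere wrapping are simplifications; a
  capsule with focal defects or repairs is outside this parameterization.
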