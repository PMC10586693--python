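# Methods

`markerless` estimates human movement dynamics from multi-camera 2D keypoint
time series: synchronization and confidence-weighted triangulation of the
20-keypoint canon, regression of a 43-marker anatomical set, inverse
kinematics on an articulated model, and muscle-driven tracking simulation
yielding ground reaction forces, joint moments, and muscle activations,
followed by a clinical analysis battery (symmetry indices, ROC
classification, paired statistics). This note records the models, the
numerical choices, and what the synthetic validation does and does not show.

## Camera model and calibration

Cameras follow the fifteen-parameter pinhole convention: 3 + 3 extrinsic
(axis-angle rotation and translation, world-to-camera), 2 focal lengths, 2
principal-point coordinates, and 5 distortion coefficients (radial k1, k2,
k3; tangential p1, p2). Intrinsics are inputs (smartphone intrinsics are
device properties); extrinsics are estimated from a single checkerboard
image: undistortion of the corners, a normalized-DLT homography from the
planar board, orthonormalization of the decomposed rotation, and
Levenberg-Marquardt refinement of the pixel reprojection error. The planar
two-fold ambiguity is resolved by requiring positive board depth.
Undistortion inverts the distortion map by a 2D Newton iteration;
non-converged points are flagged rather than silently accepted. Corner
*detection* is out of scope; the module consumes corner coordinates.

## Synchronization and triangulation

Smartphone cameras lack hardware synchronization, so inter-camera offsets
are recovered from the motion itself. The synchronization signal is the
confidence-weighted mean keypoint speed per frame (central differences;
weights renormalized per frame), chosen for robustness against
single-keypoint dropouts. Lags are the argmax of the normalized
cross-correlation of the mean-removed signals over integer lags (ties
toward zero); at 60 Hz the sub-frame residual is at most ~8 ms. Strictly
periodic motion makes this correlation ambiguous at multiples of the
period; the rig's gait generator therefore includes slow stride-to-stride
amplitude modulation, which real gait also exhibits. Very slow, smooth
tasks (a single 2-s squat) carry little velocity structure, so their
estimated lags can be off by several frames; this matters little in
practice because the same smoothness makes the downstream stages
insensitive to small misalignments.

Triangulation is homogeneous DLT on undistorted (normalized) observations:
each camera contributes two rows scaled by its keypoint confidence (not
squared), and the point is the smallest right singular vector. Scaling all
confidences by a common factor provably leaves the solution unchanged; a
camera below the confidence threshold (default 0.3) is excluded, and a
point seen by fewer than two cameras is marked invalid. Short
low-confidence runs (<= 0.5 s below confidence 0.4) are bridged beforehand
by cubic-spline interpolation, with interpolated confidence set to the mean
of the flanking values; longer occlusions stay invalid.

## Marker augmentation

Two submodels map root-centered, height-normalized keypoints plus height
and mass to anatomical markers: *body* (15 lower-limb/torso keypoints ->
35 markers) and *arm* (7 arm/torso keypoints -> 8 markers). The root is the
midpoint of the hip keypoints; inputs are split into non-overlapping 0.5-s
windows at 60 Hz (30 frames; a trailing partial window is edge-padded).
Gaussian noise with 3D magnitude 18 mm at the corpus mean height is added
to every keypoint time step during training.

The regressor is a *windowed spectral ridge* model: each channel's window
is projected onto its leading 10 orthonormal DCT components, a
ridge-regularized linear map (closed form) predicts the output channels'
DCT components, and markers are reconstructed by the inverse transform,
un-normalized by height, and re-anchored to the per-frame root. The
truncated temporal basis provides the temporal consistency and noise
suppression that recurrent networks are used for in this role, while
training deterministically (bit-identical under a fixed seed) in well under
a second. Root-centering makes the predictor exactly translation
equivariant by construction.

Two corpus details matter. First, trials are duplicated left-right
mirrored, which makes the learned map unbiased between limbs by
construction. Second, squat-like corpus trials carry random between-limb
knee offsets; without them the left and right channels of a symmetric-only
corpus are collinear, ridge splits weight across the two sides, and genuine
asymmetries in new inputs are partially averaged away at prediction time.

## Skeletal models, scaling, inverse kinematics

Models are trees of rigid segments; each joint is a fixed translation plus
an ordered sequence of single-axis rotations/translations (no quaternion
coordinates), matching the generalized-coordinate convention of the optimal
control stage. Two fixtures ship: `demo2d` (sagittal; pelvis 3-DOF + hips,
knees, ankles; 9 DOF; 8 Hill muscles, 6 torque motors, 2 contact spheres
per foot) and `demo3d` (6-DOF pelvis, 3-DOF hips, knees, 2-DOF ankles,
3-DOF lumbar; 21 DOF). Both carry the full 43-marker and 20-keypoint
attachment sets (arm markers ride on the torso; fixture arms are rigid).
The YAML model format admits richer models with more segments, muscles, and
spheres.

Scaling uses per-segment marker pairs: the segment factor is the ratio of
measured to default inter-pair distance, time-averaged over a neutral
trial; attachments, muscle paths, and child-joint locations scale with the
segment; masses are rescaled to total body mass preserving fractions.
Scaling is idempotent.

IK is per-frame weighted nonlinear least squares over all coordinates with
analytic marker Jacobians, warm-started from the previous frame, with a
tiny (1e-6, switchable) pull toward the previous frame to resolve
redundancy; uniform marker weights by default. Coordinates are low-pass
filtered with fourth-order zero-lag Butterworth filters (defaults 12 Hz for
gait, 30 Hz for non-gait; the synthetic squat studies use 4 Hz) and
differentiated by central differences. Under 18-mm marker noise some
coordinates (subtalar, hip rotation) are weakly observable and dominate the
raw error; the filtered trajectories are the pipeline's product.

## Muscle, contact, and skeletal dynamics

Excitation-activation coupling is first order with separate activation
(15 ms) and deactivation (60 ms) time constants, blended by a tanh switch
(width 0.1) for differentiability. The Hill model combines a Gaussian
active force-length curve (width 0.45), an asinh-shaped force-velocity
curve normalized to f(0)=1 and f(-1)=0, an exponential passive curve
(kpe=4, e0=0.6), and a constant-thickness pennation model; the tendon is
rigid by default (fixture tendons are set so fibers sit at optimal length
in the neutral pose). Muscle-tendon lengths and moment arms are polynomial
surrogates fit to postures sampled uniformly within the coordinate bounds
(5000 postures, total degree <= 9, order selected per muscle by held-out
error; moment arms are the analytic derivatives -dL/dq of the fitted
length). Foot-ground contact is a smooth compliant law: normal force
k * d^1.5 * (1 + c * d_dot), square-root-smoothed so force and derivatives
vanish as penetration goes to zero, with regularized Coulomb friction
(saturation velocity 1 cm/s). The default plane-strain stiffness 2.5e5
N/m^1.5 gives ~15 mm standing penetration; a compliant (rather than very
stiff) default deliberately de-sensitizes the load distribution to
millimeter-scale kinematic error, which video-based estimates always carry.

Inverse dynamics is a recursive Newton-Euler evaluation over the tree in
world coordinates, vectorized over frames, returning per-coordinate net
generalized forces including the six pelvis residuals; it is exact to
machine precision on the pendulum closed form and satisfies power balance.

## Tracking simulation (direct collocation)

The optimal control problem minimizes the time integral of
`w1*|a|^2 + w2*|e_tm|^2 + w3*|q_ref-q|^2 + w4*|qd_ref-qd|^2 +
w5*|qdd_ref-qdd|^2` plus penalties on the remaining controls (muscle
excitations, reserve torques), subject to activation dynamics, implicit
skeleton dynamics (inverse-dynamics residuals must vanish at every
collocation point), torque-motor first-order lag, and contact. When the
model has ground contact the pelvis carries no actuator, so converged
solutions are dynamically consistent by construction: the whole-body
equations are balanced by the contact forces alone.

Transcription is trapezoidal collocation on a fixed mesh (default 50
intervals/s; the fixture studies use 12-20/s). States are q, qd,
activations, and motor states; controls are qdd (implicit dynamics),
excitations, and heavily penalized reserve torques. The transcription is a
second-order scheme — chosen over a third-order one because the mesh
refinement study (halving the interval changes pendulum moments by <1%)
shows the discretization error is already below the quantities of
interest at these mesh densities.

The solve has two stages. Stage one is a sparse trust-region least-squares
pass on the tracking cost plus weighted constraint residuals; the Jacobian
exploits the structure (cost and integration-defect rows analytic;
dynamics rows by central finite differences batched over all nodes in a
single vectorized physics evaluation). A per-node bounded ridge least
squares distributes the inverse-dynamics torques of the reference over
muscles, motors, and reserves as a warm start. Stage two is a feasibility
polish: column-scaled Gauss-Newton steps (sparse LSMR with backtracking) on
the constraints alone, which drives the dynamics residuals to ~1e-4 N*m —
far below the 1e-4 (scaled) convergence tolerance — while staying at the
stage-one optimum. Solutions report per-term cost breakdown, residuals,
GRF, centers of pressure, and joint moments; `static_optimization`
(per-frame min sum(a^2) under moment equality) provides an independent
cross-check of activation estimates.

Default weights (w1=1, w2=1, w3=1000, w4=10, w5=1e-3, wp=1e-2,
w_reserve=400) are configuration tuned on the fixture models, not
constants; video-derived references are tracked with softer w3=150, w4=5.

### Video-derived references

Video kinematics carry centimeter-level absolute error, which a compliant
contact model turns into grossly wrong implied forces. Before tracking, the
pipeline therefore (i) shifts the trajectory vertically so the feet load
the ground, (ii) projects out per-leg floor penetration with smooth knee
corrections (floating feet are left alone, so genuine unloading survives),
(iii) removes common-mode horizontal foot travel (millimeter sliding
saturates the regularized friction), (iv) registers the pelvis height per
frame so the implied total vertical contact force matches m*(g+a_com), and
(v) drops 0.25 s at each boundary where zero-lag filtering and one-sided
differentiation are unreliable. These are estimation-side corrections of
the reference; the simulation itself remains fully dynamics-consistent.

## Synthetic rig and study conditions

The rig emulates the acquisition geometry of a two-smartphone capture:
cameras 1.5 m high, 3 m from the volume at +/-45 degrees (a five-camera
+/-70/+/-45/0 preset exists), 60 Hz, 720x1280, smartphone-like intrinsics
with mild distortion; 3D Gaussian keypoint noise (default SD 18 mm)
injected before projection; per-camera integer frame offsets; confidence
dropouts and exponential-duration occlusion intervals. Motions (walk,
squat, sit-to-stand, static) are smooth coordinate patterns with seeded
subject-to-subject variation; squat-like tasks keep the feet flat and
anchored and the center of mass over the feet (a Newton pass on hip
flexion), without which no actuator set can realize the motion. Subjects
are uniformly scaled fixtures (height 1.50-1.95 m, mass 50-100 kg) with
small symmetric per-segment-type proportion jitter.

The squat-symmetry cohort pairs a natural squat with an "asymmetric" squat
per subject. The effect parameter f scales imposed extra involved-side
(left) knee flexion, (1-f)*1.1 rad; this scale is defined so f=0.6
produces near-complete unloading of the involved limb at the squat bottom,
the synthetic analogue of instructed reduced-force squats, while f=1 is
the exact null (identical kinematics in both conditions). Classification
uses the peak knee-extension-moment symmetry index
`1 - (peak_involved - peak_uninvolved)/peak_uninvolved`, peaks taken over
the movement proper (frames with knee flexion above 30% of its excursion);
the clinical deficit threshold 1.15 ships as a named constant.

## Statistics

Paired comparisons gate on Shapiro-Wilk normality of the differences
(p > .05 -> two-sided paired t, else Wilcoxon signed rank; all-zero
differences are a flagged degenerate case with p = 1), report Cohen's d_z
or rank-biserial r, Benjamini-Hochberg adjust p-values across each family,
and compute post-hoc power (paired t exactly via the noncentral t;
Wilcoxon approximately via the asymptotic relative efficiency 3/pi). ROC
analysis uses the tie-corrected rank statistic for the AUC and sweeps
observed scores for the threshold maximizing TPR - FPR.

## What the synthetic validation shows — and does not

Every stage is validated against generator ground truth or independent
oracles: exact lag recovery, sub-micrometer noiseless triangulation and
calibration recovery, IK/FK round trips, filter transfer-function checks,
augmenter noise suppression (13-20 mm marker RMSE under 18-mm keypoint
noise), tracking solutions that are dynamically consistent to ~1e-3 N*m,
and end-to-end cohort classification. The rig does not emulate pose-network
error structure (its noise is white and Gaussian, real keypoint error is
correlated and occasionally grossly wrong), soft-tissue artifact,
photometric effects, or model mismatch between the subject and the fitted
skeleton (cohort analyses reuse the generating model for IK). Passing these
tests therefore demonstrates the correctness and internal consistency of
the algorithms at desk scale, not field accuracy on real video, and the
fixture models are far smaller than full musculoskeletal models (the
format supports the latter; the shipped studies do not exercise them).

## Problem sizes

Default test/validation sizes: 50-subject augmenter corpus (3 s trials,
four tasks, mirrored); 5000-posture surrogate fits; 100-pose calibration
and IK recovery studies; 2-2.4 s squats at 12-20 collocation intervals/s;
12-20 subject cohorts. These sizes are the package's validation design
choices; all are parameters.
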