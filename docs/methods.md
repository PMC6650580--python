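# Methods

This note documents the models, numerical choices and design decisions behind
the package, and what the synthetic test bed does and does not demonstrate.

## Musculoskeletal model

The model is a tree of rigid segments connected by single-axis rotational
joints; each non-root segment carries at most one generalized coordinate
(radians internally, degrees at file boundaries; meters and N·m throughout).
Multi-DOF joints are composed from chained single-hinge segments (the toy
model's hip is a flexion hinge followed by a long-axis rotation hinge on a
massless carrier). Each segment may additionally carry a fixed
`joint_offset` rotation of its joint platform in the parent frame; osteotomy
operators update it so that reorienting a distal bone fragment propagates to
the entire distal chain even at zero joint angle.

Muscle paths are polylines of points fixed in segment frames (one origin, one
insertion, any number of via points; no wrapping surfaces or moving via
points). Musculotendon length is the summed Euclidean length after forward
kinematics; moment arms use the tendon-excursion definition
`r_jm = −∂l_mt/∂q_j`, evaluated by central differences with a step of 1e-6
rad. Finite differences were chosen over symbolic differentiation because
they are simple and directly checkable against an independent oracle; the
test suite verifies agreement to 1e-8 m.

### Hill mechanics

The tendon is rigid: `l = (l_mt − l_ts)/cos α`, `l̃ = l/l_mo`, with constant
pennation `α` (default 0 in the fixtures; pennation has limited effect on
simulated forces at these operating ranges). Tuned-subset ("M") muscles
produce `F = F_max (a·f_L(l̃) + f_P(l̃))`; the remaining ("N") muscles are
activation-proportional, `F = F_max·a`. There is deliberately no
force–velocity relation and no activation/contraction dynamics: all analyses
are static optimizations at measured kinematics.

The normalized curves are:

- active: `f_L(l̃) = exp(−((l̃ − 1)/w)²)`, width `w = 0.45` — a smooth
  unimodal bump peaking at 1 with value 1;
- passive: `f_P(l̃) = expm1(k (l̃ − 1)/ε) / expm1(k)` for `l̃ > 1`, else 0,
  with `k = 4`, `ε = 0.6`.

The passive parameters are calibrated to the single anchor the method relies
on: a muscle stretched to 1.5 optimal fiber lengths exerts ≈0.5 F_max
passively (the defaults give 0.504; the half-force length solved by bisection
is 1.499). The exact curve family is a package design choice — any smooth
family satisfying the anchor and monotonicity would serve — and the
parameters are user-configurable per model file.

## Parameter tuning

Variables: per-frame activations `a_mi ∈ [0,1]` and reserve moments
`τ^R_ji`, the parameters `(l_mo, l_ts)` of every tuned muscle (bounded to
[0.5, 1.5]× their initial values), and one EMG scale factor `σ_m ∈
[0.05, 20]` per EMG-mapped muscle (channels mapping to several muscles share
the envelope but keep independent σ). The cost and constraints are given in
the README; strict inequalities ("crosses 1", "ROM above 1") are implemented
with a margin δ = 1e-3.

Two structural reductions make the problem tractable with a dense SQP:

1. **Reserve elimination.** The equilibrium constraint uniquely defines the
   reserves, so they are substituted into the cost; equilibrium then holds
   identically and the reserve penalty becomes a weighted moment-tracking
   residual.
2. **Bilevel split.** For fixed parameters and σ the problem separates into
   per-frame convex box-constrained least squares in the activations, solved
   exactly by a vectorized active-set method (`capgap.qp`), with
   `scipy.optimize.lsq_linear` as a per-frame fallback and as the independent
   oracle in tests. The outer problem over `(l_mo, l_ts, σ)` — a few dozen
   variables — minimizes this value function with SLSQP. Because the inner
   problems are strictly convex, a KKT point of the reduced problem together
   with the exact inner minimizers is a KKT point of the full coupled
   program. The extreme-frame constraints use the per-muscle argmin/argmax of
   `l_mt`, precomputed once: for fixed kinematics `l̃` is increasing in
   `l_mt`, so those frames carry the binding bounds for any parameter value.

The outer problem is nonconvex; a seeded multi-start (default 3 perturbed
starts) is used and the best feasible objective kept. Defaults: `w1 = 0.2`,
`w2 = 10` (N·m)⁻², `w3 = 20`, `w4 = 10`, 150 SLSQP iterations, ftol 1e-10.
The weight balance matters: because σ is free, the EMG term constrains only
the *shape* of each activation; if the effort term dominates (`w1 ≳ w3/10`)
the optimizer drifts parameters toward length configurations where less
activation is needed, and the calibration becomes weakly identified. With
the shipped defaults the generative-recovery harness (±20% perturbed starts,
noise-free EMG, seeds 0–4) recovers parameters with ~3–8% median relative
error and reserves below 0.1% of the peak moment. An idealized
"already-optimal" start does not sit exactly at the cost minimum (the effort
term and the ROM pull trade against the moment fit), so parameters may move
by more than a few percent for weakly-observed muscles even from truth; the
recovery criterion is therefore stated on the median.

## Motor control

NNMF uses the classic multiplicative updates with seeded uniform(0,1]
initialization, best of 10 restarts, convergence at relative objective change
< 1e-6 or 2000 iterations; the Frobenius objective is non-increasing along
the updates by construction (asserted per iteration in tests, and
cross-checked against scikit-learn's MU solver). VAF is global:
`1 − ‖E − WH‖²_F/‖E‖²_F`.

The bootstrap resamples time instants (columns) with replacement, applying
the same indices to the EMG and to H; the weights W are extracted once from
the original signal and never re-fit per resample. `N_s` is the smallest
rank with coverage ≥ 95% at VAF > 90% over 500 resamples. If no rank
qualifies the result is an explicit "insufficient VAF" value, not an
exception.

The EMG-informed static optimization resolves the bilinear σ·a coupling by
alternating exact steps: batched box-constrained least squares in the
activations, then the closed-form update `σ_m = Σ_i a_mi ε_mi / Σ_i a²_mi`
clipped to bounds. The alternation converges linearly and slowly near the
scale-degenerate direction, so the iteration cap is 2000 (still ~1 s on the
fixtures) with the σ-change tolerance at 1e-4.

`build_motor_control` factorizes the all-muscle activation matrix with
`N_s + 1` synergies — the extra synergy absorbs muscles without surface
EMG — and rescales W columns to max 1 with H rescaled inversely (the product
is unchanged to 1e-12).

## Virtual surgery

All operators return a new model (inputs are never mutated) with `lineage`
pointing at the parent and the operation recorded verbatim in `provenance`;
a plan is the sequential fold of its operations.

- **Derotation osteotomy**: rotation about the cutting-plane normal through
  the plane point, plus an in-plane translation, applied to every path
  point, landmark, mesh vertex and child joint frame on the distal side. The
  distal side defaults to the half-space not containing the segment's own
  joint center, overridable per operation.
- **Extension + derotation osteotomy**: the two plane normals must point into
  the wedge. Distal content is mapped by the rigid map joining plane b onto
  plane a — a rotation by the dihedral angle about the plane-intersection
  line for a triangular wedge, the inter-plane translation for a trapezoidal
  (parallel-plane) wedge — composed with the user derotation about the
  joined-plane normal and an in-plane translation. A muscle attachment
  inside the wedge is a hard error (silent deletion would shorten the muscle
  unnoticed); mesh vertices in the wedge are removed, landmarks are treated
  as distal.
- **Muscle transfer**: path-point edits (add/remove/move), with
  `l_ts' = l_ts + Δl_mt(q_ref)` so normalized fiber length at the reference
  posture is preserved exactly; fiber architecture is untouched. `q_ref`
  defaults to the anatomical zero posture. An explicit `delta_l_ts` supports
  pure tendon lengthening/shortening. The canned rectus-transfer recipe pins
  a via point (fixed in the femur frame) at the path midpoint and moves the
  insertion to the semitendinosus-analog insertion.
- **Patella advancement**: reduced to the plane perpendicular to the knee
  axis with a 2D femoral profile polyline. Per knee angle, a 3-parameter
  pose (rotation + 2 translations) minimizes the squared difference of the
  two point-to-profile distances subject to the ligament length held at its
  new value. As stated, that problem is under-determined (3 parameters, 1
  constraint, scalar objective), so a light regularizer (weight 0.05) keeps
  the mean clearance near its pre-operative value; poses are warm-started
  along the angle grid. Osteotomies do not transform the patella construct
  (limitation).
- **Strength change**: `F_max' = s·F_max`, `s ∈ [0,1]`; `s = 0` is a release.

Morphometrics: anteversion is the signed angle from the condylar axis to the
neck axis, both projected on the plane normal to the shaft axis; neck-shaft
is the angle between the neck axis and the distal shaft direction (collinear
neck and shaft → 180°).

## Capability gap

The desired motion comes from a reference gait template (cycle-normalized
angles, moments per kg, marker trajectories): moments scale linearly with
body mass; kinematics are either imposed directly or retargeted by per-frame
nonlinear least squares on virtual marker positions (bounded by coordinate
ranges, warm-started frame to frame). Retargeting is what keeps the foot
pointing forward on a femur with torsional deformity. Ground-reaction-force
handling collapses to this mass scaling because moments are inputs in this
architecture; center-of-pressure height scaling is absorbed into the
template's marker scaling by the height ratio.

Stage 1 fixes ΔW = 0 and solves per-frame convex problems in `(H_i ≥ 0)`
with `a_i = W_pre H_i` (muscle force linear in `a` at fixed kinematics, with
or without the force–length relation). Stage 2 alternates two exact
least-squares steps — ΔW with H fixed (elementwise box |ΔW| ≤ 0.05 after
max-normalization, `W_pre + ΔW ≥ 0`, one shared ΔW across frames) and H with
ΔW fixed — so the objective is non-increasing; it stops at relative change
< 1e-6 or 20 alternations. Activations are clamped to [0,1] when evaluated
(the clamp fraction is reported; it is ~0 on the fixtures). Without synergy
constraints, activations are optimized freely per frame, which is classic
static optimization (verified against an independent per-frame QP oracle to
1e-6).

Reserves are the equilibrium residual by construction, so equilibrium holds
to machine precision. The reserve weight is `w2 = 1000` per (N·m)²
(`w1 = 1` on activations): at `w2 = 10` the effort/reserve trade leaves a few
percent of spurious reserve on perfectly achievable motions, contaminating
the gap of healthy configurations; at 1000 the self-consistency gap is
< 0.002 per joint while deficit cases are unaffected. `CG_j` divides by
`Σ_i |τ^ID_ji|` floored at 1 N·m·frames: joints with near-zero reference
moments (the toy hip rotation) otherwise produce unbounded ratios; their CG
values should be read qualitatively. `CG_mean` is the unweighted mean over
joints.

The muscle operating report flags frames with passive force > 0.5 F_max
("stretched") and frames with activation > 0.25 at `l̃ < 0.6`
("short-active"), as maximal runs of flagged frames. Gait-profile RMSE is the
per-joint root-mean-square angle deviation over the cycle (reported in
degrees) with the aggregate as the RMS of per-joint values.

## Synthetic test bed

Because no clinical data ships with the package, every pipeline stage is
exercised on seeded generative fixtures (`capgap.fixtures`):

- A planar 4-link lower-limb analog (pelvis / femur with hip flexion +
  long-axis rotation / shank / foot) with 8 muscles including biarticular
  rectus-femoris, hamstrings and gastrocnemius analogs, femoral landmarks
  built from prescribed anteversion (20°) and neck-shaft (130°) angles, and
  a planar patella construct with a circular condyle profile.
- Gait kinematics are band-limited Fourier series (two harmonics per joint,
  one cycle exactly periodic); trials default to 3 cycles × 51 points.
  Activations are `clip(W*H*, 0, 1)` from 3 (configurable 2–4) von-Mises
  synergy bumps with near-disjoint muscle groups; EMG envelopes are the
  measured activations plus optional Gaussian noise, clipped at 0 and
  peak-normalized. Joint moments are *defined* as the resulting muscle-moment
  sums, so a zero-reserve solution exists by construction and recovery tests
  have exact ground truth. Skeletal dynamical consistency is unnecessary and
  omitted: every consumer uses only (τ^ID, r, l_mt, ε).
- Fiber parameters are calibrated from the nominal cycle so that, under the
  truth, `l̃` crosses 1 during gait, stays within [0.4, 1.5], and reaches
  ≈1.48 in the range-of-motion postures — i.e., the clinical end range
  reaches the considerable-passive-force region near 1.5, which is the
  operating assumption of the tuning stage. `F_max` is drawn uniformly from
  600–1500 N per seed.
- The reference gait template is generated from the undeformed chain and is
  a synthetic stand-in for an averaged typically-developing dataset; the
  deformity generator (femoral derotation + hamstring shortening) carries
  the exact corrective plan for end-to-end inversion tests.

What passing tests show: the estimation machinery recovers known parameters
and synergy structure under the generator's assumptions (noise-free or
low-noise EMG, perfectly consistent moments, no model mismatch), surgery
operators are exact rigid maps, and the capability gap responds in the right
direction to capacity removal and bony deformity. What they do not show:
robustness to real EMG artifacts and crosstalk, soft-tissue wrapping,
marker noise, model-form error in the force–length curves, or the clinical
validity of the gap as an outcome predictor.

## Problem sizes and runtimes

Defaults were chosen so the full pipeline runs in seconds-to-minutes on one
CPU: trials of 153 frames, 8 muscles, 4 joints; tuning ≈ 2 s per start
(3 starts); bootstrap 500 resamples × k ≤ 6 ≈ 1 s; capability gap ≈ 0.2 s.
The acceptance script completes in well under a minute; the full test suite
in a few minutes.

## Known limitations

- No wrapping geometry, conditional via points, compliant tendon, muscle
  dynamics, force–velocity relation, or spasticity model.
- Inverse kinematics/dynamics of real recordings are out of scope: joint
  moments, lengths and moment arms are consumed as (or generated into) trial
  bundles.
- The two-stage (W+ΔW)·H alternation is a local scheme; with the seeded
  deterministic initialization it is reproducible but not guaranteed
  globally optimal. The same holds for the multi-start tuning NLP.
- Per-joint CG is unstable when reference moments are near zero; the floored
  denominator bounds but does not normalize those values.
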