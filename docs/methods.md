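# Methods

This note documents the statistical model behind `handsyn`, the defaults and
why they are set where they are, what the synthetic cohorts do and do not
emulate, and the numerical choices that matter when reproducing results.

## Signal model

A recording is a frames × 16 matrix of anatomical joint angles in degrees,
relative to a flat-hand reference posture, sampled at 100 Hz. The analysis
assumes hand motion during everyday tasks is generated by a small number of
latent *synergies*: smooth scalar activation signals mapped onto the joints
through fixed loading vectors, plus joints that move independently, plus
measurement noise. Nothing in the pipeline requires that model to be exactly
true — it extracts whatever low-dimensional linear structure the data has —
but the sensor-reduction logic (record a few angles, estimate the rest
linearly) only pays off when the structure is strong.

## Preprocessing

* **Low-pass filter**: 2nd-order Butterworth, 5 Hz cut-off, applied forward
  and backward (zero phase; effective magnitude is the squared response).
  Voluntary hand motion lives below ~5 Hz; the filter removes sensor noise
  without phase distortion. Edges are padded by odd reflection over five
  cut-off periods (100 samples at 100 Hz): shorter padding leaves edge
  transients of order 0.05°, which would break the chain's idempotence and
  bleed into the static-trim step.
* **Static trimming**: recordings begin and end with the hand at rest. A
  frame is static when every DoF's |angular velocity| (central differences)
  is below 2 °/s; maximal leading/trailing static runs lasting at least
  0.2 s are removed. The threshold is conservative — it only removes truly
  idle posture holds — and both values are configurable because resting
  tremor and sensor noise floors differ between set-ups.
* **Time normalisation**: each task is linearly interpolated onto 1000
  equally spaced frames so that long and short tasks contribute equally to
  the subject-level ensemble. Linear interpolation suffices because the
  signal is already band-limited to 5 Hz. Evaluation of fitted estimators
  deliberately uses native frame counts: there, frames are the unit of
  error, not tasks.
* **Standardisation**: per subject, tasks are concatenated (16 × 1000·T) and
  each DoF row is z-scored. Without this, joints with large ranges (MCP
  flexions, ~90°) dominate the PCA and small-range joints (abductions,
  palmar arch, ~15–20°) are ignored. A zero-variance DoF raises an error
  rather than being dropped: every matrix in the package carries the fixed
  16-label contract, and silently losing a channel would corrupt everything
  downstream.

## Synergy extraction

PCA is computed from the correlation structure (eigendecomposition of
`X Xᵀ / N` for the z-scored ensemble). The retained count k is the smallest
number of leading components whose cumulative variance reaches the threshold
(default 0.95); k is fixed *before* rotation, which cannot change the
retained subspace or its total variance. An optional `fixed_k` override
exists for reproducing analyses that pinned the component count.

The retained loadings (eigenvectors scaled by √eigenvalue — correlation
coefficients, since the rows are standardised) are Varimax-rotated to
sparsify them. The implementation is Kaiser's pairwise algorithm: rows are
normalised to unit communality, then column pairs are repeatedly rotated by
the closed-form optimal angle `φ = atan2(D − 2AB/p, C − (A² − B²)/p) / 4`
until the criterion stops improving (tolerance 1e-8, max 1000 sweeps). The
pairwise form is used instead of the SVD fixed-point update because the
latter stalls in a two-cycle on symmetric block structures that are common
in clean kinematic data. One caveat inherent to the whole algorithm family:
a loading configuration mixed at exactly 45° is a saddle of the varimax
criterion (zero gradient), and no rotation is performed there; any
asymmetry, including sampling noise, breaks the tie.

Component signs are arbitrary; reported loadings fix each column's
largest-magnitude entry positive, and all downstream consumers are
sign-invariant.

## Cross-subject clustering

All subjects' rotated components are pooled and clustered with
complete-linkage (farthest-neighbour) agglomeration on the inter-component
angle `arccos(|u·v| / ‖u‖‖v‖)` in degrees. The absolute cosine makes the
distance sign-invariant; it is a semimetric bounded by 90°. Angles are
computed on the CC loading vectors (the only loading form the pipeline
defines); distances on unscaled eigenvectors would differ slightly, which
matters if comparing against analyses that clustered raw eigenvectors.

The flat partition is *not* chosen by eyeballing a dendrogram height: it is
the minimum number of clusters such that no cluster holds two components
from one subject — a subject cannot exhibit the same synergy twice, so a
cluster with a duplicated subject has merged two distinct synergies. The
reported cut distance is the height of the first merge the cut undoes,
rounded to 1°, which is how a dendrogram cut-off is conventionally quoted.
Two identical loadings from one subject make the rule unsatisfiable and
raise an explicit error.

Each cluster is summarised by its averaged loading (members sign-aligned to
the highest-variance member before the element-wise mean), the fraction of
subjects contributing, and the mean variance explained.

## Classification and candidate enumeration

Reading the averaged loading of each cluster (absolute CC values, strict
inequalities):

* subject fraction < 0.10 → **discarded** as idiosyncratic. The 10% floor
  keeps any synergy carried by more than a couple of subjects in a
  twenty-subject cohort while dropping pair-specific quirks; it is
  configurable.
* exactly one |CC| > 0.8 and all others < 0.3 → nominally **independent**.
* otherwise a **coordination**; all DoF with |CC| > 0.4 are candidates.

A nominally independent cluster whose DoF also appears among some
coordination's candidates is demoted to candidate status (iterated to a
fixpoint): its motion is evidently not independent of the rest of the hand.
Coordination clusters whose candidate sets overlap are pooled into one
group — they are the same coordination carried with different weights by
different subjects. This overlap rule is one formalisation of a judgement
call; other groupings are defensible, which is why the thresholds and the
resulting classification table are exported rather than buried.

Representative sets are all combinations of one candidate per group plus
every independent DoF, in deterministic order (groups by discovery,
candidates canonically). With groups of 3 and 7 candidates that is 21
combinations; the synthetic default (4 and 3) gives 12.

## Estimation and selection

For each representative set, every remaining DoF is fitted as an affine
function of the representative angles by ordinary least squares over all
pooled training frames, *in raw degrees* — intercepts are then physical
angles and coefficients are interpretable gain ratios between joints. The
generic iterative least-squares formulation reduces exactly to OLS because
the model is affine; the solver is SVD-based (`lstsq`), and a design
condition number above 1e10 raises a degenerate-design error instead of
returning meaningless coefficients. One global model is fitted across
subjects and tasks; per-subject estimators are out of scope.

Combinations are scored by mean training RMSE across their estimated DoF;
ties break by enumeration order.

## Evaluation

The selected bank is applied frame-wise to a held-out dataset (filtered and
trimmed, native frame counts). Errors are RMSE in degrees: *global* pools
all frames of all subjects (one value per joint — so global RMSE² is exactly
the frame-count-weighted mean of per-activity RMSE², a decomposition the
tests assert), and *per activity* pools all subjects' frames of one
activity. Both are also expressed as a percentage of each joint's range of
motion, pooled max − min over training and evaluation data together (a
single-dataset fallback exists for synthetic runs). %RoM makes errors
comparable between large-range flexions and small-range abductions.

## Synthetic cohorts

`SynthConfig` defaults encode the reference study conditions used throughout
the tests and the acceptance script: 8 subjects × 6 tasks × 600 motion
frames at 100 Hz, two planted coordination blocks — MCP flexions with
weights (0.60, 0.55, 0.45, 0.37) and PIP flexions (index excluded) with
(0.65, 0.55, 0.52), unit-normalised — nine independent channels for the
remaining DoF, 5° per-subject angular jitter on the block loadings, 1°
Gaussian measurement noise, and 0.5 s exact static pads at both ends.
Activations are 5 Hz-low-passed white noise, unit SD, scaled by per-task
amplitudes U(0.7, 1.3) and gains chosen to give realistic excursions
(~10–16° SD for flexions, less for abductions and palm arch); offsets are
kind-dependent resting angles. Planted directions are mutually orthogonal,
comfortably beyond the 60° separation the generator enforces so the planted
partition is recoverable.

What the generator emulates: low-dimensional linear coordination, subject
variability in loadings, task-to-task amplitude variation, band-limited
smooth motion, static lead-ins, sensor noise. What it does not: joint
limits, tendon-coupling nonlinearity, grasp-type structure across tasks,
drift or calibration error. Passing tests therefore demonstrate that the
*pipeline* recovers linear structure it is pointed at — not that real hands
are this linear.

Two properties of the defaults worth knowing:

* With band-limited activations over finite tasks, sample cross-correlations
  between the 11 latent sources are non-negligible (effective sample count
  ≈ 2·bandwidth·duration), so the 95% retention rule typically keeps 10
  components per subject, one short of the planted 11. The cross-subject
  partition still recovers all 11 clusters because different subjects drop
  different directions. Exact-recovery tests on noiseless cohorts extract at
  a 100% threshold instead — a noiseless ensemble has nothing to discard,
  and any lower threshold deliberately drops planted signal.
* Estimator coefficients fitted on the jittered default cohort land within
  0.05 of the planted loading ratios; the bias grows with jitter as the
  pooled fit averages over subject-specific loadings.

## Problem sizes

The test suite and acceptance script run cohorts of 2–8 subjects, 2–6 tasks
and 150–1000 frames per task (tens of thousands of pooled frames), sizes at
which every stage's behaviour — retention counts, cluster recovery,
coefficient recovery, error decompositions — is already stable across seeds
while the full suite completes in well under a minute. The same code paths
scale linearly in frames to full-size glove datasets.

## Known limitations

* The subject-uniqueness cut rule can be sensitive to the Varimax flavour
  and trimming thresholds near cluster-count boundaries; counts on real data
  should be read together with the exported dendrogram merge list.
* The classification thresholds (0.8 / 0.3 / 0.4) are inherited conventions
  with strict inequalities; loadings sitting exactly on a threshold flip
  class with measurement noise.
* OLS estimation is unregularised by design; highly collinear representative
  sets are rejected rather than shrunk.
* `pc_angle` has an absolute precision floor of ~1e-5 degrees near
  collinearity (arccos conditioning); distances that small are ties for
  every practical purpose.
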