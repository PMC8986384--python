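# Methods

This note documents the models and procedures habitatkit implements, the
choices made where the design was genuinely open, and what the synthetic
phantoms do and do not establish about behaviour on real MRI.

## Pipeline model and assumptions

A study is six scalar 3-D volumes plus a binary tumor ROI mask. The analysis
assumes the sequences are acquired in one session and are spatially
consistent up to their stored origin/spacing metadata, so registration is
purely metadata-driven nearest-neighbour resampling onto the reference (DWI)
grid — no intensity-based registration, no bias-field correction. Nearest-
neighbour interpolation breaks exact half-voxel ties toward the lower index,
a convention chosen so the operation is deterministic and order-free.

Intensities are z-scored per sequence over ROI voxels (population
denominator N), which removes scanner- and sequence-specific scale and
offset; each sequence then contributes with equal weight to the voxel's 6-D
coordinate. Noise is suppressed by replacing each voxel with the mean of its
3×3×3 neighbourhood (in-bounds neighbours only at borders). The order
standardize→smooth is the default; smooth→standardize is available by flag
(`order="smooth-first"`), and smoothing can be disabled entirely. With
z-scoring first, the smoothed columns no longer have exactly unit variance;
that is harmless because k-means and all five statistics are computed on the
same matrix for every study.

Habitat segmentation is Lloyd's k-means with Euclidean distance, K = 3 by
default: assignment to the nearest centroid (ties to the lowest centroid
index), centroid update as the assigned mean, convergence when the maximum
centroid displacement falls below 1e-6 or after 300 iterations, with
k-means++ seeding and the best of 10 restarts by final within-cluster SSE.
An empty cluster is repaired by reseeding its centre on the point farthest
from its current centroid, which strictly decreases the SSE and keeps the
recorded inertia trace monotone. The returned labelling is re-derived from
the final centroids so it is a fixed point of the assignment step. An
optional expectation-maximization diagnostic fits a spherical Gaussian
mixture initialized at the k-means solution and reports its log-likelihood;
it never changes labels.

## Validity statistics

The five per-tumor features are defined in the README. Numerical
conventions:

* inertia uses squared Euclidean distance (the quantity k-means minimizes);
* Calinski-Harabasz uses the standard degrees-of-freedom normalization
  [B/(k−1)]/[W/(N−k)]; when W is zero — or below 1e-12·B, i.e. pure float
  rounding of a perfectly tight clustering — CH is reported as the +inf
  sentinel and the study is flagged `degenerate`; modelling drops flagged
  studies;
* silhouette follows Rousseeuw's formula; singleton clusters and the 0/0
  case of coincident points contribute 0;
* separation averages over the k(k−1)/2 unordered centroid pairs (summing
  instead would differ by the constant 3 at fixed k = 3 and would not change
  any ROC ranking);
* Davies-Bouldin uses mean member-to-centroid distance as the scatter; a
  pair with zero centroid distance and zero scatter contributes 0.

Under a feature-space rescaling by c > 0, separation scales by c, inertia by
c², and CH, silhouette and DB are invariant; all five are invariant to
cluster relabeling and row order. These laws, exactness against brute-force
O(N²) reference implementations, and the hand-computable cases (CH = 50,
SP = 4.0, DB = 0.2) are pinned in the test suite.

## Prediction model

Single features are evaluated by ROC: AUC is the normalized Mann-Whitney U
(ties count ½), the 95 % CI is a stratified percentile bootstrap (2000
resamples, seeded; the method is a package choice — nothing in the problem
fixes it), and the score direction is auto-oriented so a biomarker's AUC is
reported ≥ 0.5 with the flip recorded. Model probabilities are *not*
auto-oriented: a fitted classifier's direction is part of its contract.

The joint model is two-class discrete AdaBoost (SAMME) on the
Calinski-Harabasz and inertia features, standardized with train-set
mean/sd that are frozen for test data. The weak classifier is a Gaussian-
process classifier with a fixed unit-length-scale RBF kernel on the
standardized features. Two choices deserve justification:

* **Weight handling.** GP classifiers do not accept sample weights, so each
  round fits on a weight-proportional bootstrap resample — the standard
  recipe for unweightable weak learners. A decision-stump weak learner
  (exhaustive weighted threshold search, deterministic tie-breaks) is
  available by flag; because stumps consume the weights directly, the
  boosting arithmetic (round errors ε, vote weights α = ½ln((1−ε)/ε),
  weight updates) is exactly traceable and is tested against a hand-worked
  8-point problem.
* **Fixed kernel.** Optimizing the RBF length scale per round by marginal
  likelihood on the weight-biased resample drives the scale toward zero: the
  GP then memorizes its resample, every round looks near-perfect in
  training, and the ensemble generalizes far worse than a plain logistic
  fit on the same two features. Freezing the length scale at 1.0 on
  standardized inputs keeps the learner smooth and genuinely "weak", which
  is what boosting assumes.

Rounds with weighted error ≥ 0.5 are rejected and stop the boosting; a
perfect round (ε = 0) is kept with a capped α and also stops. The ensemble
score is the weighted vote margin F(x) = Σ α<sub>t</sub>h<sub>t</sub>(x),
mapped to a probability by the logistic link p = 1/(1+e^{−2F}). Operating
metrics are reported at the probability threshold 0.5 and at the
Youden-optimal point (the problem fixes neither; both are exposed).
Evaluation uses a single stratified split, 0.8 by default (mirroring a
100:25 train/test design); no cross-validation is claimed. The calibration
curve uses 10 equal-width bins, reports per-bin mean prediction, observed
fraction and count, and omits empty bins.

## Synthetic phantoms: what they emulate, and what they do not

Each phantom is a spherical tumor (default: radius 8 mm on a 24³ grid at
1 mm isotropic spacing, ≈2100 ROI voxels) whose ROI is carved into K = 3
spatially contiguous habitats by k-means on voxel *coordinates* — a Voronoi
partition, matching the expectation that habitats are compact, connected
subregions. Habitat h in sequence s has intensity
`habitat_means[h,s] · centroid_scale + N(0, noise_sd · dispersion_scale)`,
with a fixed default 3×6 mean matrix (pairwise 6-D gaps ≈69–107 a.u.) and
noise_sd = 10 a.u. — clear but not trivial habitat contrast. The binary
group acts multiplicatively: mutants get centroid_scale 1.5 (habitat-mean
spread, driving separation and CH) and dispersion_scale 1.3 (within-habitat
noise, driving inertia, silhouette and DB). On top of the group effect every
phantom draws lognormal between-subject jitter (sd 0.05 on the log scale) on
both multipliers, so the groups overlap rather than separate trivially; the
direction of each feature's shift is an empirical outcome, not an assertion.
An IHC staining percentage is drawn consistently with the group (mutants
U(5,100), wild-type U(0,5)), so the −/+/++/+++ scoring rule (boundaries:
"−" < 5; "+" on [5,25]; "++" on (25,50], closing the gap the integer
phrasing leaves between 25 and 26; "+++" above 50) reproduces the label.

Cohorts derive per-phantom seeds and jitters deterministically from one
master seed; identical configuration yields byte-identical outputs.

The phantoms deliberately omit MR physics (no Rician noise, bias fields,
partial-volume or motion effects), irregular tumor shapes, necrotic cores,
and any correlation structure between sequences beyond the shared habitat
geometry. Passing tests therefore establish the *algorithmic* correctness of
the pipeline and its ability to recover a known multiplicative group effect
at realistic noise — not clinical performance on patient MRI, which must be
assessed on real cohorts.

One interaction worth knowing: the 3×3×3 mean filter blends voxels across
habitat boundaries, so exact recovery of the latent partition (ARI = 1 at
zero noise) is only defined without smoothing; the recovery tests cluster
standardized, unsmoothed features, while the default pipeline keeps
smoothing on as a noise-suppression step.

## Problem sizes and numerical settings

Default study conditions: cohorts of n = 200 (prevalence 0.5) for effect
and null analyses; 24³ phantoms for the main pipeline and 16³ (radius 6 mm,
≈900 voxels) for the recovery sweeps; k-means tol 1e-6, max_iter 300,
n_init 10; AdaBoost 10 rounds; bootstrap 2000 resamples. Brute-force oracle
comparisons use N ≤ 200 and k ∈ {2,3,4} at tolerance 1e-9.

## Known limitations

* Metadata-only registration assumes honest headers; misregistered inputs
  pass silently if their metadata claim alignment.
* The Markov-random-field flavour of spatial regularization is represented
  by its mean-filter restatement; a Potts/graph-cut model is out of scope.
* K is fixed (default 3); no automatic model selection across K.
* The GP weak learner's fixed kernel trades adaptivity for robustness; on
  problems with very different feature geometry the stump learner or a
  rescaled kernel may be preferable.
* Manual ROI drawing and DICOM writing are out of scope; an optional DICOM
  series can be converted externally to NIfTI before use.
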