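# Methods note

This note records the mathematical model, the numerical choices and the
synthetic-data design behind `gaitnet`, including every place where a design
decision was required and why it was resolved the way it was.

## 1. Kinematic preprocessing

Input: per subject, a labelled set of 3D position series (metres) for up to 23
canonical body segments at a common sampling rate `fs`.

* **Filtering.** Each Cartesian axis is low-pass filtered with a 4th-order
  Butterworth at 10 Hz, applied forward and backward (`scipy.signal.filtfilt`)
  so the magnitude response is squared and the phase cancels. Edge handling
  uses filtfilt's odd-extension padding with the default
  `padlen = 3·max(len(a), len(b)) = 15` samples, i.e. proportional to the
  filter order. Signals must exceed the pad length and `fs > 2 × cutoff`.
* **Magnitude and speed.** The position magnitude is
  `m(t) = ‖(x, y, z)‖₂` of the filtered axes. Speed is the norm of per-axis
  `np.gradient` derivatives (central differences inside, one-sided at the
  ends); differentiating before taking the norm makes speed invariant to
  rotations and translations of the coordinate frame (property-tested).
* **Dispersion features.** Each signal is summarised by its interquartile
  range (Q3 − Q1, linear-interpolation quantiles): `pos_<Segment>` and
  `vel_<Segment>`.

## 2. Similarity networks

* **Density estimation.** For every segment pair the two magnitude sample
  sets are placed on a *shared* 512-point uniform grid spanning the pooled
  minimum − 3h to the pooled maximum + 3h, where `h` is the larger of the two
  Silverman bandwidths `0.9 · min(sd, IQR/1.349) · n^(−1/5)`. Each set keeps
  its own bandwidth. The Gaussian KDE is evaluated by linear binning followed
  by convolution with the kernel tabulated out to ±8h; this reproduces the
  direct kernel sum to O((Δx/h)²) relative error (≈1e−5 here, asserted
  against the direct sum in the tests) and reduces the per-pair cost from
  O(n·512) kernel evaluations to one FFT-free convolution. Densities are
  renormalized to unit trapezoid integral. Zero-variance signals raise a
  dedicated error and are flagged as missing nodes (NaN rows in the
  adjacency).
* **Divergence.** The base-2 Jensen–Shannon divergence
  `JS = ½ KL(p‖M) + ½ KL(q‖M)`, `M = ½(p+q)`, is computed by trapezoid
  quadrature with the `0·log 0 = 0` convention and a 1e−12 floor inside the
  logarithm; base 2 bounds it in [0, 1]. Edge weight: `A_ij = 1 − JS`.
  Acceptance tests compare against a dense-quadrature oracle (16 385 points)
  on random Gaussian mixtures (tolerance 1e−3) and assert symmetry, range and
  `A = 1` for identical signals.
* **Thresholding.** Edges with `A_ij ≥ τ` are retained for
  τ ∈ {0.20, 0.25, …, 0.60}. Graphs are weighted by default (`binary`
  available). Path-based metrics use an explicit per-edge `length` attribute;
  the default treats the weight itself as the distance (`identity`), with
  `1 − w` and `1/w` available.
* **Metrics.** Local (per node): degree, strength, weighted clustering,
  normalized betweenness, closeness (Wasserman–Faust component correction),
  eigenvector centrality (power iteration, tol 1e−6, NaN on
  non-convergence), PageRank (damping 0.85). Global: density, average
  clustering, global efficiency, characteristic path length on the largest
  connected component, greedy-modularity community modularity, degree
  assortativity (NaN when undefined), transitivity, average strength, number
  of components. Metrics are computed at each threshold and averaged across
  the thresholds at which they are defined (NaN-aware mean); a metric
  undefined everywhere stays NaN. All of betweenness, closeness, clustering,
  transitivity, density and components are verified exactly against
  brute-force enumeration oracles on all 52 non-isomorphic graphs with ≤ 5
  nodes.

## 3. Feature table, confounds, cleaning

With S segments the table has `2S + S(S−1)/2 + 7S + 9` columns (469 at
S = 23): kinematic IQRs, raw upper-triangle adjacency weights in canonical
segment order, threshold-averaged local metrics, threshold-averaged global
metrics.

* **Residualization.** Every feature is replaced by its OLS residual on
  intercept + age + sex, fit per feature on the rows where it is observed;
  missing entries stay missing.
* **Cleaning.** Columns with > 80 % missing are dropped, the rest
  median-imputed, zero-variance columns dropped, and all columns z-scored.
  Every statistic is computed on a designated fit subset (the outer-training
  rows inside cross-validation), so held-out subjects never influence the
  transform — asserted by a mutation test (perturbing a held-out row must not
  change the fit statistics or the transformed training rows).

## 4. Voting feature selection (VFS)

Four rankers score every feature: one-way ANOVA F; |coefficients| of an
L1-penalized logistic regression (liblinear, `C = vfs_lr_c`); gain importances
of an XGBoost ensemble (300 trees, depth 3, learning rate 0.1); and MultiSURF.
Each ranker votes for its top `vfs_k` features; the final order is (votes
descending, summed min-max-normalized scores descending, name ascending) and
the first `vfs_k` are retained, with a full audit record.

MultiSURF is implemented in-package from its published definition: instances
are range-normalized, distances are Manhattan, the neighborhood of instance
*i* is everything closer than `μ_i − σ_i/2` (mean/SD of *i*'s distances to
all others); same-class neighbors subtract the mean normalized feature
difference, different-class neighbors add the class-prior-weighted
(`P(c)/(1 − P(class_i))`) mean difference, and scores are averaged over
instances. It is verified *exactly* (1e−12) against an independent
double-loop oracle, and the vote ordering against an exhaustive re-sort
oracle over 100 randomized fixtures.

## 5. Nested cross-validation

Outer: stratified k-fold (default 10) repeated (default 3). Inner: per outer
training split, a randomized search (default 20 candidates) over
`vfs_k ∈ [25, 100]`, `vfs_lr_c` log-uniform in [1e−3, 1e3], and XGBoost
`n_estimators ∈ [100, 500]`, `max_depth ∈ [2, 6]`, learning rate log-uniform
[0.01, 0.3], subsample/colsample ∈ [0.6, 1], L1/L2 regularization log-uniform
[1e−3, 10], scored by stratified inner k-fold (default 4) mean AUC; the best
configuration is refit on the whole outer-training split and evaluated once
on the untouched outer test subjects. Cleaning statistics and feature
selection run strictly on the training side. Per-fold seeds are derived
deterministically from (global seed, repeat, fold). AUC is the exact
rank-sum statistic with half credit for ties; accuracy/sensitivity/
specificity threshold the predicted probability at 0.5.

## 6. Explainability

Per outer fold, exact TreeSHAP attributions of the refit model are computed
on the fold's held-out subjects through XGBoost's native per-feature
prediction contributions (`pred_contribs=True`). The external `shap` package
is not required: for tree ensembles those contributions *are* exact TreeSHAP
values, and the local-accuracy axiom (contributions + base value = margin) is
asserted in the tests to 1e−4. Features outside the fold's selection get
attribution exactly 0.

Fold-level mean |SHAP| vectors are averaged into a global vector `s̄` (sorted
descending, name tie-break). The cumulative share `C(k)` defines the top-95 %
set (smallest prefix with `C(k) ≥ 0.95`; hand-checked fixtures:
`s̄ = (0.5, 0.3, 0.15, 0.05) → k = 3`, uniform 100 features → k = 95).
Stability of feature *j* is the percentage of folds whose selected list
contains *j*; the stable set intersects {stab ≥ 95 %} with the top-95 % set.
A body-network JSON maps per-segment features to stickman nodes and adjacency
features to edges, each with summed importance and the sign of the
case-conditional mean signed SHAP.

## 7. Statistics and power

Welch t-tests per feature with Benjamini–Hochberg FDR (validated against a
brute-force step-up oracle); Fisher exact (sex) and Kruskal–Wallis (age) for
demographics; Spearman correlations between stable features and clinical
scores with |ρ| ≥ 0.30 and p < 0.05 flagged as relevant. Effect sizes:
Cohen's d with (n−1)-weighted pooled SD, Cohen's w = √(χ²/N) without
continuity correction. Achieved power at α = 0.05: noncentral-t route for
two-sample means (noncentrality `d·√(n₁n₂/(n₁+n₂))`), noncentral-χ² route for
contingency tables (noncentrality `w²N`). With the reference demographic
numbers (d = 1.36 at 51/53; w = 0.45 at N = 104) the computed powers exceed
0.99 and 0.95 respectively; the t-power route is additionally checked against
a 4 000-replication simulation.

## 8. Synthetic cohort generator

Each segment's position is an anatomical offset plus a gait oscillator plus
shared latent oscillators plus sensor noise (SD 4 mm/axis), with optional
random-walk drift:

* **Cadence and harmonics.** Subject cadence `f₀ ~ U(0.9, 1.1)` Hz; each
  segment oscillates at `f₀` with harmonic weights (1, 0.35, 0.15),
  segment-specific amplitude (trunk ≈ 2.5 cm up to toes 14 cm), left/right
  anti-phase, fixed forward/lateral/vertical mixing.
* **Offsets.** Offset *directions* follow rough anatomy but the *norms* are
  closely spaced (1.000–1.088 m in 4 mm steps). With literal anatomical norms
  (1.0 vs 1.7 m) the magnitude distributions of different segments are
  disjoint, every Jensen–Shannon divergence saturates and all similarity
  weights collapse to ≈ 0, emptying the 0.20–0.60 threshold window — the
  spacing was chosen so the weights span the window, *before* any acceptance
  assertion was frozen.
* **Latent coupling.** A trunk latent (proximal segments) and an interlimb
  latent (arms + legs) sit at non-harmonic cadence multiples (1.37 f₀,
  0.63 f₀) so their variance adds incoherently; at harmonic frequencies they
  add coherently with random phase and coupling effects would have no
  monotone direction.
* **Effects** (per affected subject, scaled by a latent severity
  `clip(N(1, 0.35), 0.2, 2)`):
  * `distal_speed_scale < 1` — bradykinesia-like distal slowing, implemented
    as *temporal* (frequency) scaling
    `f_seg = f₀ · scale^(0.5 + 0.5·severity)` of feet/toes/hands. Frequency
    scaling lowers speed dispersion by the same factor while leaving the
    position-amplitude distribution — the network substrate — untouched, so
    the mechanism is recoverable in the `vel_*` family rather than leaking
    into every within-limb adjacency (an amplitude implementation was tried
    and rejected for exactly that reason; the defining behavioural contract —
    lower foot-speed IQR in the affected group — holds either way and is
    tested).
  * `positional_drift_sd` — whole-body random walk (step SD
    `drift·severity/√fs` per axis), inflating position IQRs.
  * `proximal_coupling_gain` — multiplies the trunk-latent weight for
    proximal segments by `1 + gain·severity`, raising trunk/head adjacency.
  * `interlimb_decoupling` — suppresses the interlimb latent on the *arm*
    side only (reduced arm swing), `w = max(0, 1 − dec·severity)`; symmetric
    suppression would shrink arm and leg amplitude distributions equally and
    leave their similarity unchanged.
* **Recoverability and null.** Property tests demand the correct direction of
  each mechanism in ≥ 18/20 (kinematic effects) or ≥ 9/10 (network effects)
  seeds, and statistical indistinguishability plus coin-flip direction under
  the null. With all effects zero the two groups' signals are exchangeable in
  distribution by construction.
* **Demographics and clinical scores.** Ages `N(69.6, 8.67)` (cases) vs
  `N(51.3, 17.03)` (controls) clipped to [18, 95]; male fractions 37/51 and
  19/53. Clinical scores are monotone affine in severity (anchors at
  severity 1: total motor score ≈ 29.9, part-III ≈ 17.0, staging ≈ 1.54,
  disease duration ≈ 7.6 y, onset age ≈ 62) with independent Gaussian noise
  (SD 0.25 by default) and plausibility clipping; controls carry no scores.
  `EffectSpec.reference()` (scale 0.6, drift 0.01, gain 0.5) is the moderate
  disease-like condition used by the acceptance run.

## 9. Problem sizes (package choices)

The acceptance-scale conditions are package choices sized for a single-CPU
budget, fixed before their assertions were frozen:

* *Effect recovery*: 25+25 subjects, all 23 segments, 15 s at 100 Hz,
  reference effect, outer 10-fold × 1 repeat, 10-candidate search
  (≈ 1.5 min). Result at seed 7: mean outer AUC 0.90; stable core
  {trunk adjacencies, `vel_Left Foot`}; distal `vel_*` and proximal
  adjacency/centrality features in the top-95 % set with positive
  case-conditional SHAP.
* *Null calibration*: 10 seeds × (16+16 subjects, 12 segments, 8 s at 60 Hz),
  outer 4-fold × 2 repeats, 2-candidate search (≈ 2 min); mean AUC ≈ 0.52,
  no seed with > 10 % of features at q < 0.05 (observed 0 %). Smaller
  per-seed cohorts were rejected: with ≤ 12 subjects per group the nested-CV
  null AUC is pessimistically biased (selection anti-learning) below 0.4.

## 10. Limitations

* The generator is a stylised oscillator model — it makes no claim of
  biomechanical realism beyond the feature families it is designed to move;
  absolute metric values do not transfer to real motion-capture cohorts.
* Clinical scores are affine severity read-outs, not validated instruments.
* Eigenvector centrality may fail to converge on near-disconnected weighted
  graphs; such values are NaN and excluded from threshold averaging rather
  than imputed.
* The threshold sweep treats edge weight itself as path length by default;
  alternative distances (`1 − w`, `1/w`) are provided but not swept jointly.
* MVNX/live-sensor ingestion, multi-center harmonisation and longitudinal
  modelling are out of scope.
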