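# gaitnet

Subject-specific kinematic similarity networks for explainable classification
of Parkinsonian gait.

Each subject's full-body motion capture (23 labelled body segments, 3D
positions) is turned into a **personal body network**: the amplitude
distribution of every segment's position magnitude is estimated by kernel
density estimation, every pair of segments is compared with the base-2
Jensen–Shannon divergence, and the similarity `A_ij = 1 − JS_ij` becomes the
edge weight between segments *i* and *j*. Graph-theoretic descriptors of this
network — swept over a range of edge-retention thresholds and averaged — are
combined with simple speed/position dispersion features, screened by a
four-method voting feature selection, and classified with a gradient-boosted
tree ensemble inside a leakage-safe nested cross-validation. Exact TreeSHAP
attributions aggregated across folds give a global importance ranking, a
compact "top-95 %" feature set, a cross-fold stability profile, and a
stickman-renderable body map of where in the body the discriminative signal
lives.

Because no subject-level clinical dataset ships with this package, it includes
a fully controllable **synthetic gait cohort generator** whose
disease-mimicking mechanisms (distal slowing, postural drift, proximal
coupling, interlimb decoupling) move exactly the feature families the pipeline
claims to measure. The generator doubles as the test bed: effects must be
recovered where they were injected, and null cohorts must calibrate to chance.

## Pipeline

1. **kinematics** — zero-phase Butterworth low-pass (4th order, 10 Hz) per
   axis; magnitude and speed signals; interquartile-range features; tidy CSV
   cohort I/O.
2. **simnet** — Gaussian KDE (Silverman bandwidth, shared 512-point grid),
   base-2 Jensen–Shannon divergence, similarity adjacency; threshold sweep
   0.20–0.60 (step 0.05); 7 local and 9 global weighted graph metrics averaged
   across thresholds.
3. **features** — one table per cohort (2 S kinematic + S(S−1)/2 adjacency +
   7 S local + 9 global columns; 469 for S = 23 segments); OLS residualization
   on age and sex; missingness screen, median imputation, zero-variance drop,
   z-scoring — all statistics from the training rows only.
4. **vfs** — feature votes from ANOVA F, L1-logistic weights, gradient-boosted
   gain importances and MultiSURF relevance; ties resolved by summed min-max
   normalized scores, then name.
5. **evaluate** — stratified nested cross-validation (10-fold outer × 3
   repeats, 4-fold inner, randomized search over the selector and XGBoost
   hyperparameters, AUC-selected refit).
6. **explain** — exact TreeSHAP per outer fold, global importance with the
   cumulative-share top-95 % set, ≥95 % cross-fold stability set, body-network
   JSON export.
7. **stats** — Welch t-tests with Benjamini–Hochberg FDR, Fisher/Kruskal–Wallis
   demographics, Spearman clinical-correlation screen (|ρ| ≥ 0.30, p < 0.05),
   sensitivity power analysis from Cohen's d and w.
8. **cli** — `gaitnet {simulate,network,features,train,explain,stats,all}`
   with a strict YAML config, per-stage artifacts and manifests.

## Tests

```bash
pytest -q
```

The suite contains unit, property and oracle tests plus seven end-to-end
acceptance tests (`tests/test_acceptance.py`); the two pipeline-level
acceptance tests dominate the runtime (the full suite takes roughly 6–8
minutes on one CPU).

## Quickstart (CLI)

```bash
gaitnet all --seed 5 --outdir run1 --config config.yaml
```

with a config such as

```yaml
simulate:
  n_group_a: 15
  n_group_b: 15
  n_segments: 19
  duration: 10.0
  effect:
    distal_speed_scale: 0.6
    positional_drift_sd: 0.01
    proximal_coupling_gain: 0.5
cv:
  outer_folds: 5
  outer_repeats: 1
  inner_folds: 3
  search_iterations: 4
```

Artifacts land under `run1/`: the simulated cohort (`kinematics.csv`,
`metadata.csv`), per-subject adjacency matrices (`networks/`), the feature
table, fold metrics, the SHAP summary, the body-network JSON, univariate
statistics and a manifest tying everything to the config hash and seed.
Unknown config keys are rejected; every stage names the producing stage when
an upstream artifact is missing.

## Worked example (library API)

```python
from gaitnet.synthetic import CohortSpec, EffectSpec, generate_cohort
from gaitnet.features import compute_cohort_features, residualize
from gaitnet.evaluate import CVConfig, nested_cv
from gaitnet.explain import aggregate_global, stability

spec = CohortSpec(n_group_a=15, n_group_b=15, n_segments=19, fs=60.0,
                  duration=10.0, effect=EffectSpec.reference(), seed=42)
recordings, metadata = generate_cohort(spec)
table, nets = compute_cohort_features(recordings)
print(table.values.shape)                                  # (30, 351)
print(nets["PD001"].edge_weight("Pelvis", "L5"))           # 0.986

meta = metadata.set_index("subject")
table = residualize(table, meta["age"], meta["sex"])
cv = CVConfig(outer_folds=5, outer_repeats=1, inner_folds=3,
              search_iterations=4, seed=0)
results, summary = nested_cv(table, meta["group"], cv)
print(summary["auc"]["mean"])                              # 0.744

shap = aggregate_global([r.shap_mean_abs for r in results])
stab, stable = stability([r.selected_features for r in results],
                         shap.top95_set, cutoff=80.0)
print(len(shap.top95_set))                                 # 33
print(list(shap.s_bar.index[:2]))   # ['vel_Right Toe', 'betweenness_Right Hand']
```

This takes about a minute on one CPU. The moderate disease-like condition
(`EffectSpec.reference()`: 40 % distal slowing, mild postural drift, moderate
proximal coupling) is already recovered at this small scale — the most
important feature is a distal speed dispersion (`vel_Right Toe`) and the
stable set mixes speed and network-centrality features. The acceptance-scale
condition (25+25 subjects, all 23 segments, 15 s recordings) reaches a mean
outer-fold AUC of 0.90 with a stable core of proximal trunk adjacencies plus
distal speed features.

## Layout

```
src/gaitnet/
  kinematics.py   filtering, magnitudes, IQR features, cohort CSV I/O
  synthetic.py    synthetic cohort generator + clinical scores
  simnet.py       KDE, Jensen–Shannon divergence, networks, graph metrics
  features.py     table assembly, residualization, cleaning
  vfs.py          four rankers + voting feature selection
  evaluate.py     nested cross-validation, binary metrics
  explain.py      TreeSHAP aggregation, stability, body-network export
  stats.py        group tests, correlations, power analysis
  cli.py          stage orchestration
docs/methods.md   modelling and numerical choices in detail
scripts/acceptance.py  headline-quantity run
```

All shipped data are synthetic; see `docs/methods.md` for the generator's
mechanism and its limitations.
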