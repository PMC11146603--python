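# morphostrat

Unsupervised whole-slide-image (WSI) morphology clustering for prognostic
stratification of glioblastoma (GBM, IDH-wildtype, CNS WHO grade 4).

Glioblastoma tissue is histologically heterogeneous: a single H&E-stained
section mixes necrosis, dense cellular tumor, vascular proliferation, tissue
edges, and more. `morphostrat` implements a label-free pipeline that turns
that heterogeneity into a prognostic signal:

1. **Tiling** — segment tissue from slide background by thresholding the HSV
   saturation channel of a low-resolution thumbnail, then cut the slide into
   non-overlapping 256×256 patches at 10X working magnification, dropping
   tiles with more than 60% background.
2. **Curation** — discard artifact patches in three colorspace-rule steps:
   (i) >60% white/black pixels in RGB (blank background, black lines),
   (ii) >90% low-saturation high-value pixels in HSV (glass reflections,
   debris), (iii) >90% high-eosin pixels after Ruifrok H/E/DAB stain
   deconvolution (pen markings).
3. **Encoding** — each curated patch passes through a VGG16-style
   convolutional stack truncated after its final conv block; global average
   pooling yields a 512-dimensional feature vector. Weights are pluggable
   (user-supplied `.npz`, seeded random, or a deterministic filter bank).
4. **Reduction** — z-score the features and project onto principal
   components, chosen directly or by a retained-variance target.
5. **Cluster-count selection** — sweep K-means over K = 2…10; judge
   *reproducibility* by the mean Rand index between independently seeded
   permutations, and *separability* by the mean silhouette coefficient
   s = (b − a)/max(a, b); pick K where the silhouette drops suddenly
   (elbow rule).
6. **Profiles and classification** — summarize each slide as its
   cluster-proportion vector p (p_k = patches in cluster k / total patches)
   and train a grid-searched decision tree to separate short (OS ≤ 9 months)
   from long (OS ≥ 13 months) survivors under an 80/20 hold-out with 10-fold
   cross-validation (80/10/10 train/val/test per fold). The positive class is
   the long survivor throughout.

Real inputs are H&E FFPE slides scanned at 20X/40X plus a clinical table of
overall survival in days. Because such data cannot ship with a package, a
first-class synthetic generator (`morphostrat.synthetic`) produces H&E-like
slides with planted artifacts and truth masks, Gaussian-mixture feature
cohorts with a controllable separation, class-conditional Dirichlet profile
cohorts, and clinical tables — so every stage is testable end to end with
known ground truth.

## Worked example

Train and evaluate the prognostic classifier on a planted-signal cohort of
200 patients whose cluster-proportion profiles are drawn from
class-conditional Dirichlet distributions (short ~ Dir(5,1,…,1), long ~
Dir(1,5,1,…,1), K = 7):

```python
from morphostrat import ProfileCohortSpec, make_profile_cohort, \
    train_classifier, evaluate

profiles, labels = make_profile_cohort(ProfileCohortSpec(n_patients=200, seed=3))
model, params, cv = train_classifier(profiles.iloc[:160], labels.iloc[:160],
                                     n_folds=10, seed=0)
result = evaluate(model, profiles.iloc[160:], labels.iloc[160:])
print("chosen hyperparameters:", params)
print(result.to_dict())
```

prints

```
chosen hyperparameters: {'max_depth': 2, 'min_samples_leaf': 2, 'min_samples_split': 2, 'criterion': 'gini'}
{'positive_class': 'long', 'TP': 23, 'FP': 0, 'TN': 16, 'FN': 1, 'accuracy': 0.975, 'sensitivity': 0.9583333333333334, 'specificity': 1.0}
```

i.e. on the 40-patient hold-out the tree recovers the planted signal almost
perfectly: 23 of 24 long survivors identified (sensitivity 0.96) and no
short survivor mislabeled (specificity 1.0).

The full slide-level pipeline runs from a YAML config or the CLI:

```bash
morphostrat simulate cohort/ --n-patients 24 --seed 0   # synthetic slides + clinical CSV
morphostrat run --config pipeline.yaml                  # cohort → … → evaluate
morphostrat select-k --config pipeline.yaml             # re-run one stage in isolation
```

`run` writes every stage artifact (cohort labels, split manifest, curation
reports, feature matrices, PCA model, silhouette curve, profiles, the fitted
tree as a readable rule list, and the hold-out confusion metrics) plus a JSON
run manifest with per-stage hashes, counts and seeds. Note that on synthetic
cohorts whose survival times are independent of slide content, hold-out
accuracy is expected to sit at chance — the slides carry no prognostic
signal to find.

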