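# charmkit

Segmentation-free whole-image classification for biological microscopy.

Many bioimage classification problems — phenotype scoring in
high-content screens, tissue-compartment annotation — are bottlenecked
by object segmentation. `charmkit` avoids segmentation entirely: it
computes a large, multi-group, multi-level descriptor on the *whole
image* and classifies in that feature space. It is aimed at
screening/imaging groups who have labeled example images per condition
and want a classifier plus an honest, batch-aware estimate of its
accuracy.

## Method

**Features.** Each channel of each image yields a 953-element
CHARM-style vector ("Compound Hierarchy of Algorithms Representing
Morphology"). Nine feature groups — pixel statistics, the first four
moments, multiscale histograms (3/5/7/9 bins), Gabor responses at four
orientations, 13 Haralick co-occurrence statistics at 4 directions × 2
distances, Tamura contrast/coarseness/directionality, edge statistics,
and histograms of the discrete Chebyshev and Chebyshev–Fourier
decompositions — are computed both on the image and on *transform
levels*: the Haar wavelet transform W, the Chebyshev transform C, the
Fourier modulus F, and the compound transforms WF and CF. Starred
groups contribute on all six levels (146 × 6), base groups on the
original image only (77): 953 in total.

**Classification.** Features are z-scored and projected onto the
minimal set of principal components explaining ≥ 98 % of variance
(tunable); a linear discriminant,
δ_c(x) = xᵀΣ⁻¹μ_c − ½μ_cᵀΣ⁻¹μ_c + log π_c, classifies the scores. The
historical baseline is also provided: per-feature Fisher scores
w_f = Var_c(μ_fc)/mean_c(σ²_fc), retention of the top 15 % of features,
and a weighted-neighbor-distance (WND) classifier scoring each class by
the mean of D(x,t)⁻⁵ over its training samples, with
D = Σ w_f²(x_f − t_f)².

**Validation.** Unstratified 10-fold cross-validation, repeated 100
times with fresh splits; accuracy is reported as the median ± standard
deviation over runs. Folds can be grouped by acquisition *batch*, so
that image-wide artifacts shared within a batch (illumination drift,
plate effects) can never leak from training into test. A
label-permutation null calibrates chance performance and yields an
empirical p-value.

See `docs/methods.md` for every convention and the design rationale.

## Worked example

`charmkit` ships a synthetic-data generator so the whole pipeline runs
without downloads. Generate a 32-image two-class set (16 stripes, 16
checkerboard textures, 64×64, with pixel noise), extract features, and
validate:

```bash
charmkit synth demo/images --preset separable --seed 0
charmkit extract demo/images/manifest.csv demo/features.csv
charmkit validate demo/features.csv --out demo/cv.json \
    --n-runs 100 --seed 0 --shuffle-null
```

which prints

```
INFO charmkit: wrote 32 images and demo/images/manifest.csv
INFO charmkit: wrote 32 samples x 953 features to demo/features.csv
INFO charmkit: accuracy median 1.000 std 0.000 over 100 runs
INFO charmkit: null median 0.469 std 0.116 p=0.009901
```

Reading: over 100 repetitions of 10-fold cross-validation the PCA-LDA
pipeline separates the two textures perfectly (median accuracy 1.000,
std 0.000), while the same pipeline on label-shuffled data sits at
chance for a balanced two-class problem (median 0.469 ≈ 0.5, std
0.116); the empirical p-value 0.0099 = 1/101 says no shuffled run
matched the observed accuracy. Per-sample feature tables are plain CSV
(`sample_id, class, batch`, then 953 named columns per channel), so
extraction — the expensive step — runs once and is reused.

Train/predict round trips work on the same CSVs:

```bash
charmkit train demo/features.csv demo/model.json          # PCA-LDA
charmkit predict demo/features.csv demo/model.json --out demo/pred.csv
```

The library mirrors the CLI one-to-one
(`charmkit.assemble_feature_vector`, `fit_pca`, `fit_lda`, `wnd_fit`,
`repeat_validation`, `permutation_null`, ...), and the batch-leakage
safeguard is testable in a few lines: on a fixture whose only class
signal is a per-batch brightness offset, naive folds score near-perfect
accuracy while batch-grouped folds fall to chance
(`tests/test_validation.py::TestBatchLeakage`).

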