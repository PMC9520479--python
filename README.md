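# ramanbiopsy

Analysis pipeline for Raman-spectroscopy optical biopsy of brain tissue.
Given raw Raman spectra of tissue samples from three classes — normal white
matter, tumor edge (infiltration area) and tumor center — the package
preprocesses the spectra, selects the wavenumbers that discriminate the
classes, maps them onto biochemical bands, and compares three routes to a
tissue classifier:

* **pca_only** — PCA to two components over the whole 900–1800 cm⁻¹ range,
  then an RBF-kernel SVM;
* **filtered_svm** — per-wavenumber Fisher-criterion (one-way ANOVA F)
  filtering, retained intensities straight into the SVM;
* **combined** — Fisher filtering first, PCA on the retained wavenumbers,
  then the SVM.

It is written for spectroscopists and methodologists who want a tested,
reproducible reference implementation of this chemometric workflow, plus a
synthetic-data generator with known ground truth for validating each stage.

## The method

Preprocessing follows the standard acquisition chain. Replicates whose raw
signal exceeds 90% of the spectrometer dynamic range are excluded. The
per-sample ambient background (averaged over 5 frames) is subtracted, the
spectrum is smoothed with a Savitzky–Golay filter (15 points, 3rd order),
and the intense fluorescence continuum is modeled as a sum of K real-valued
Morlet wavelets

    B(ν) = Σₖ aₖ · exp(−((ν−cₖ)/sₖ)²/2) · cos(ω₀ (ν−cₖ)/sₖ),   ω₀ = 5, K = 4,

fitted by bounded nonlinear least squares with an asymmetric loss that
penalizes overshoot above the signal (baseline must stay under the peaks).
After subtracting B, spectra are cropped to the diagnostic window
900–1800 cm⁻¹ and normalized by their integral intensity.

Feature filtering computes, per wavenumber, the one-way ANOVA F statistic
across the three classes, F = MS_between / MS_within with df (k−1, n−k),
and keeps wavenumbers with F above the F-distribution critical value at
α = 0.05. Retained intensities are summed within biochemical bands
(cholesterol, carotenoids, hemoglobin, water, amide groups, …) and each
band sum is re-tested for class differences (`*` p<0.05, `**` p<0.001).

Classification uses a 30% training split with at least 5 spectra per class
(for sizes 14/15/19 this gives 5/5/6), an RBF-SVM (one-vs-one), and
malignant-vs-normal metrics after collapsing edge ∪ center into "malignant":
accuracy (TP+TN)/N, sensitivity TP/(TP+FN), specificity TN/(TN+FP).
Because a single split of ~50 spectra is high-variance, reporting uses 50
seeded splits shared across variants (paired design).

## Worked example

```python
from ramanbiopsy import (GroupedMatrix, VariantConfig, build_mask,
                         generate_dataset, paper_like_config,
                         preprocess_pipeline, repeated_evaluation)

measurements, backgrounds, truth = generate_dataset(paper_like_config(seed=1))
processed = preprocess_pipeline(measurements, backgrounds)
matrix = GroupedMatrix.from_spectrum_set(processed)

mask = build_mask(matrix, alpha=0.05)
print(f"{matrix.X.shape[0]} spectra, kept {mask.n_kept}/{mask.keep.size} wavenumbers")

for variant in ("pca_only", "filtered_svm", "combined"):
    s = repeated_evaluation(matrix, variant, VariantConfig(),
                            n_repeats=50, base_seed=1)
    print(f"{variant}: accuracy {s.mean('accuracy'):.3f} "
          f"sensitivity {s.mean('sensitivity'):.3f} "
          f"specificity {s.mean('specificity'):.3f}")
```

Output:

```
48 spectra, kept 223/683 wavenumbers
pca_only: accuracy 0.878 sensitivity 0.910 specificity 0.793
filtered_svm: accuracy 0.991 sensitivity 0.993 specificity 0.984
combined: accuracy 0.969 sensitivity 0.980 specificity 0.940
```

The generator emulates the study design: 3/3/4 samples × 5 replicates with
two saturated replicates, leaving 14/15/19 usable measurements. On these
synthetic data, filtering before PCA recovers specificity that plain PCA
loses to dense spot-to-spot nuisance variance (0.940 vs 0.793 above), at
comparable accuracy — the qualitative signature this pipeline exists to
demonstrate. The same pipeline runs from the shell:

```
ramanbiopsy run --repeats 50 --seed 1 --out report.json
```

## Layout

```
src/ramanbiopsy/
  spectra_io.py     CSV/JSON readers and writers, axis/band domain types
  synthetic.py      ground-truth synthetic spectrum generator
  preprocess.py     background, Savitzky-Golay, Morlet baseline, normalize
  feature_filter.py Fisher-criterion mask and biochemical band summaries
  classify.py       PCA, train/test splitting, RBF-SVM, metrics
  pipeline.py       variant orchestration and repeated evaluation
  cli.py            command-line entry points
docs/methods.md     model, parameters, and design notes
```
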