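# lipidlda

Classification of ambient mass-spectrometry lipid fingerprints with PCA-LDA
and Mahalanobis-distance class calls.

A *sampling event* (one ~10-second acquisition) yields a centroided peak
list. Peaks are summed into fixed 0.1-Da bins over [100, 1000) Da, rows are
TIC-normalized, and a PCA-LDA model is fitted: mean-centring, principal-axis
reduction, then Fisher discriminant axes with equal class priors. Query
events are called by cluster overlap — nearest class by squared Mahalanobis
distance, gated by a chi-square quantile ellipsoid (default 3 SD) — with an
equal-prior Gaussian posterior compared against a strict > 0.95 probability
threshold. Events with signal duration ≤ 3 s are "bad" and excluded from
every model and metric; events outside all gates are "outliers".

The package covers the full analysis workflow:

- **spectra_io** — peak-list/metadata I/O (CSV/TSV, optional mzML via
  `pyteomics`), half-open 0.1-Da binning with midpoint labels, TIC
  normalization, duration QC.
- **synthetic** — hierarchical cohort generator (specimen and event
  log-normal effects, m/z jitter, TIC scaling, bad and outlier events)
  anchored on the 41-lipid marker array in `lipidlda.markers`, so every
  downstream stage is testable without patient data.
- **model** — PCA-LDA fit/projection, loading-based marker ranking,
  specimen-level label permutation, learning curves, sparse feature
  restriction (e.g. the 41-bin marker array).
- **classify** — per-event Mahalanobis distances, posteriors, gate calls,
  cohort reports with total/bad/outlier/classifiable accounting.
- **validate** — event-level stratified k-fold and leave-one-specimen-out
  cross-validation, confusion matrices, one-vs-rest sensitivity/specificity
  (thresholded and unthresholded), averaged metrics (mean ± population SD,
  rounded to integer percent), spatial concordance.

## CLI

```sh
lipidlda simulate --seed 1 --out-dir sim            # synthetic cohort
lipidlda bin --peaks sim/peaks.tsv --meta sim/meta.tsv --out matrix.tsv
lipidlda fit --matrix matrix.tsv --meta sim/meta.tsv --out model.json
lipidlda crossval --matrix matrix.tsv --meta sim/meta.tsv --scheme fullgroup --out cv.json
lipidlda rank --model model.json --top-n 100 --out rank.tsv
lipidlda predict --model model.json --peaks sim/peaks.tsv --meta sim/meta.tsv --out preds.tsv
lipidlda metrics --predictions preds.tsv --out report.json
lipidlda permute --meta sim/meta.tsv --seed 2 --out permuted_meta.tsv
lipidlda learncurve --matrix matrix.tsv --meta sim/meta.tsv --out curve.tsv
```

Sparse (41-feature) analysis: pass `--features markers` to `fit`/`crossval`;
`predict` restricts columns automatically from the model's stored feature
subset. Every artifact gets a `<name>.manifest.json` recording inputs,
parameters, seed, and version; identical manifests reproduce identical
artifacts.

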