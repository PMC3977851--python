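# wbdwi — whole-body DWI tumor burden and ADC-histogram response metrics

`wbdwi` implements a semi-automatic pipeline for segmenting metastatic
bone disease on whole-body diffusion-weighted MRI (WBDWI) and deriving
two quantitative treatment-response biomarkers per study:

* **tDV** (total diffusion volume) — the segmented disease volume in
  milliliters, and
* **gADC** (global apparent diffusion coefficient) — the pooled ADC
  distribution over all segmented disease voxels, summarized by its
  median, variance, skewness and excess kurtosis.

It is aimed at imaging scientists who want a reproducible, scriptable
implementation of this workflow, complete with a synthetic phantom
generator so every stage can be exercised and validated without
clinical data.

## Method

WBDWI is acquired as sequential axial stations at two b-values
(typically b = 50 and 900 s/mm²). The pipeline chains four steps:

1. **Station fusion.** Per-station receiver gain is corrected by
   matching the cumulative intensity histograms of the abutting
   boundary slabs (a quantile–quantile fit through the origin yields
   the gain `g` minimizing `Σ(q_a − g·q_b)²`), then the integer
   displacement along the phase-encode axis minimizing the mean-square
   boundary difference is applied. Stations are processed in turn,
   superior → inferior. Corrections estimated on the low-b volume are
   applied to both b-values so the ADC map is invariant to the joint
   scaling.
2. **Computed DWI.** With a monoexponential model
   `S(b) = S(0)·exp(−b·ADC)`, the two-point estimator
   `ADC = ln(S(b_low)/S(b_high)) / (b_high − b_low)` is exact, and a
   computed image at any virtual b-value `b_c` is
   `S(b_c) = S(0)·exp(−b_c·ADC)`. High computed b-values suppress
   normal tissue and maximize lesion-to-background contrast.
3. **Segmentation.** A manually chosen global threshold on the
   computed-DWI image, followed by (a) optional seeded 3-D GrowCut
   editing — a cellular automaton in which labeled cells conquer
   neighbors with force `g(|C_p − C_q|)·θ_q`, `g(x) = 1 − x/max‖C‖` —
   to remove bright normal structures such as the spleen, and (b) a
   two-class Markov-random-field smoothing (Gaussian likelihood +
   Potts prior, optimized by iterated conditional modes) that removes
   noise speckle and artifact voxels. Connected components become
   volumes of interest (VOIs); everything superior to a chosen
   cervical cutoff slice is discarded and individual VOIs can be
   excluded.
4. **Metrics.** tDV = voxel census × voxel volume; gADC statistics are
   computed on the ADC values pooled over *all* included VOIs.
   Group-level response comparisons use exact Mann-Whitney U tests
   (one-sided for Δ median gADC, where successful treatment is
   expected to raise ADC; two-sided otherwise) and exact Wilcoxon
   signed-rank tests for paired pre/post change.

## Worked example

Simulate a default phantom study (three 21.4 ml lesions with ADC
0.82×10⁻³ mm²/s in a suppressed body background, four stations, Rician
noise at SNR 22/15) and run the full pipeline:

```bash
wbdwi simulate --seed 0 --out-dir study/
cat > pipeline.yaml <<EOF
study_config: study/study.yaml
threshold: 25.0
output_dir: study/out
EOF
wbdwi run --config pipeline.yaml
```

which prints

```
tDV = 64.9 ml, median gADC = 0.82 x10^-3 mm^2/s; artifacts in study/out
```

— the recovered tumor burden (truth: 64.3 ml analytic, 64.8 ml at the
voxel grid) and the planted lesion ADC. `study/out/` contains the
fused volumes, the ADC and computed-DWI maps, the disease mask and VOI
label map (NIfTI), `metrics.json` with all histogram descriptors, and
a provenance record with input hashes.

The same stages are available individually (`wbdwi fuse`, `wbdwi
cdwi`, `wbdwi segment`, `wbdwi growcut-remove`, `wbdwi edit`, `wbdwi
metrics`, `wbdwi respond`, `wbdwi simulate-cohort`), and as library
functions (`wbdwi.run_study_pipeline` and the per-module API).

## Conventions

* In-memory axis order is `(slice, row, column)`, slice 0 most
  superior; indexing is 0-based.
* ADC is carried in mm²/s internally; displays use ×10⁻³ mm²/s.
* NIfTI is the only volumetric format (DICOM ingestion is out of
  scope); study layout is declared in a small YAML config.
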