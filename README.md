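# sddmark

Automated discovery of lipid markers of **subretinal drusenoid deposits
(SDD)** in MALDI imaging mass spectrometry (IMS) data.

SDD are extracellular lesions that form between the photoreceptors and the
retinal pigment epithelium (RPE) in age-related macular degeneration. MALDI
IMS measures one centroided mass spectrum per ~10 µm tissue pixel, so an SDD
section becomes an image in which every pixel carries hundreds of lipid ion
intensities. `sddmark` implements the full computational workflow that turns
such data into a ranked shortlist of candidate SDD markers:

1. **Spectral preprocessing** — internal-peak m/z alignment (one scalar ppm
   shift per pixel, references = 6 peaks present in ≥ 50 % of pixels),
   ≥ 4-calibrant ppm recalibration (error model linear in m/z), resampling
   onto a common geometric mass axis (1.5 ppm bins), mean-spectrum peak
   picking, ± 7 ppm feature extraction, and robust **5–95th percentile TIC**
   normalization (per pixel, only intensities between that pixel's own 5th
   and 95th intensity percentiles enter the TIC, making single outlier
   spikes nearly invisible to the correction).
2. **Pixel labeling** — non-negative matrix factorization of the feature
   matrix; the most lesion-like spatial component is thresholded into an
   SDD-positive mask (with a file-based manual-correction hook), and the
   background class is sampled from non-SDD pixels to equal size.
3. **Classification** — an XGBoost model predicts SDD vs background per
   pixel from its spectrum (67 %/33 % stratified train/test split; balanced
   accuracy, precision, recall, F1 on held-out pixels).
4. **Interpretation** — exact TreeSHAP values per pixel and feature.
   A feature's global score is its mean |SHAP| over all pixels; its
   direction is the sign of the correlation between intensity and SHAP
   (positive = more ion ⇒ more likely SDD). The top-20 shortlist and
   per-feature spatial SHAP maps are the primary outputs.
5. **Annotation** — theoretical m/z from glycerophospholipid/sphingomyelin
   composition rules, monoisotopic masses, the five common adducts
   ([M+H]⁺, [M+Na]⁺, [M+K]⁺, [M−H]⁻, [M+Cl]⁻) and ¹³C isotopologues
   (Δm = 1.0033548), matched to picked peaks at ≤ 10 ppm.

Because donor-eye raw data are not publicly deposited, the package ships a
first-class **synthetic phantom generator** (`sddmark.synthetic_msi`): a 2-D
retina section with horizontal tissue strata, dome-shaped deposits on the
RPE boundary, per-stratum lipid panels with deposit-exclusive lysolipids
(LPC/LPE/LPA), shared species, a deposit-excluded sphingomyelin, isotope
envelopes, smooth per-pixel mass drift (tens of ppm), per-pixel intensity
scaling, outlier spikes and a noise floor — with full ground truth, so every
pipeline stage is testable against a known answer key.

## Worked example

Run the end-to-end pipeline on a small seeded phantom:

```bash
cat > example.yaml <<'YAML'
seed: 1
phantom:
  grid_width: 100
  grid_height: 60
  n_deposits: 6
  deposit_size_px: [5, 8]
YAML
sddmark run-all --config example.yaml --out run/
```

prints the held-out classifier metrics

```
{
  "balanced_accuracy": 1.0,
  "precision": 1.0,
  "recall": 1.0,
  "f1": 1.0,
  "n_test": 614
}
```

and writes `run/shortlist.csv`, whose top rows are

```
rank  mz        direction  annotation
1     519.3278  positive   LPC(18:3) [M+H]+ (+1 13C)
2     410.2396  positive   LPA(16:0) [M-H]- (+1 13C)
3     815.7003  negative   SM(42:1) [M+H]+
4     481.3126  positive   LPE(18:0) [M-H]- (+1 13C)
5     480.3093  positive   LPE(18:0) [M-H]-
6     518.3239  positive   LPC(18:3) [M+H]+
7     409.2360  positive   LPA(16:0) [M-H]-
```

Reading: all six planted deposit-exclusive lysolipid ions (three species ×
two isotopologues, cross-referenced in the `isotope_of_mz` column) are
recovered with positive direction — a higher intensity raises the SDD
probability — while the deposit-excluded sphingomyelin appears with
negative direction, because its intensity drops to zero inside lesions.
Note the top-ranked feature is the ¹³C isotopologue of LysoPC(18:3): since
isotope peaks are deliberately not removed, one lipid species can occupy
several shortlist rows, and the isotope cross-reference makes that visible.

The run directory also contains the phantom as processed-mode imzML, label
masks (PNG + CSV), the serialized model with its feature manifest, a SHAP
map of the top feature, and `report.json` with per-stage timings, the
picked-peak count, calibration residual and class sizes.

Library use mirrors the CLI: see `sddmark.pipeline.run_pipeline` and the
per-stage modules (`preprocess`, `labeling`, `classify`, `interpret`,
`annotate`), which operate on explicit in-memory objects
(`IMSDataset`, `FeatureMatrix`, `LabelMask`, `ShapResult`).

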