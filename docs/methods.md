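# Methods

This note documents the models, defaults and numerical choices behind
`sddmark`, and what the synthetic phantom does and does not establish about
real tissue data.

## Signal model and preprocessing

**Centroid data model.** Every pixel is a centroided peak list (m/z,
intensity), m/z strictly increasing. Profile spectra, ion mobility and
vendor raw formats are out of scope; imzML (processed mode) is the exchange
format.

**Per-pixel alignment.** Mass drift across a section is modeled as one
scalar ppm shift per pixel, applied multiplicatively
(`mz_obs = mz_true · (1 + d·1e−6)`). A scalar shift is the minimal model
able to explain smooth drift along the m/z axis, and it is what the phantom
injects; no warping is attempted. Reference peaks are chosen from the
un-aligned mean spectrum: the `n_peaks = 6` most pixel-occupied candidates
with occupancy ≥ 0.5, greedily thinned to a mutual spacing of ≥ 50 Th so
the set spans the mass range. A pixel's shift is the median ppm deviation
of its matched references (window ± 30 ppm); with fewer than two matches the
pixel is left untouched and a warning is logged. The median is exact when
drift is truly scalar and degrades gracefully when an interloping peak
falls into one reference window.

**Calibration.** The residual systematic error is modeled as
`err_ppm(mz) = a + b·mz`, fitted by least squares on ≥ 4 calibrant species
and inverted on every spectrum. Observed calibrant positions are medians of
per-pixel nearest-centroid matches (± 30 ppm window, required in ≥ 10 % of
pixels), which gives sub-bin accuracy and robustness to interlopers;
fitting against binned mean-spectrum apexes would quantize positions at the
1.5 ppm bin width. Calibrants found in fewer pixels are silently dropped;
fewer than four matches is an error. Residuals above 5 ppm trigger a
warning in the model record.

**Common axis and resampling.** The shared mass axis is geometric with
relative spacing 1.5 ppm (edges `e_{i+1} = e_i (1 + 1.5·10⁻⁶)`), ~1.26
million bins over m/z 300–2000. Resampling adds each centroid's intensity
to the bin containing its m/z, conserving in-range intensity exactly;
out-of-range peaks are dropped and counted.

**Peak picking.** Local maxima of the binned mean spectrum above
`3 × 1.4826 × MAD` (plus an optional absolute prominence floor). On sparse
centroid-derived spectra the MAD is zero and every isolated local maximum
survives, which is what makes the exact-count property on noiseless
phantoms hold. Apex m/z is the intensity-weighted centroid over apex ± 1
bin, i.e. finer than the bin width. Isotope peaks are kept as separate
features throughout.

**Feature extraction and occupancy filter.** Feature windows are
± 7 ppm around each picked apex, clipped at midpoints between adjacent
features so no centroid is counted twice. The pipeline then drops features
with nonzero intensity in < 2 % of pixels: single-pixel outlier spikes
survive peak picking as near-empty features and, left in, dominate
variance-based factorizations. The filter is a pipeline step, not part of
`pick_peaks`, and is exposed in config (`min_feature_occupancy`).

**Robust TIC normalization.** Per pixel, the TIC sums only intensities
between that pixel's own 5th and 95th intensity percentiles (computed over
its positive values). The normalization factor is
`median_pixels(TIC₅₋₉₅) / TIC₅₋₉₅(pixel)`, and *all* of the pixel's
intensities — including those outside the percentile window — are scaled by
it. The alternative reading (leaving excluded intensities unscaled) would
break cross-pixel comparability of individual features and is not used; the
choice matters only for pixels containing extreme outliers. The procedure
is idempotent (second-pass factors equal 1 to 1e−6) because percentile
selection is scale-invariant. All-zero pixels get factor 1 with a warning.

## Labeling

NMF (rank 8, multiplicative-update solver, seeded random non-negative
initialization, Frobenius loss, ≤ 400 iterations) factorizes the normalized
feature matrix into spatial score images and spectral loadings. The
SDD-positive mask comes from one component:

* **Component auto-selection.** Candidates must be high-contrast: the
  Otsu-active region of the score image has to capture ≥ 80 % of the
  component's score mass (this screens out diffuse noise components). Among
  candidates, the winner maximizes the coefficient of variation of the
  active region's per-column pixel count: tissue strata are horizontal
  bands, nearly translation-invariant along the section (CV ≈ 0), whereas
  dome lesions — isolated or confluent — produce a strongly oscillating
  column profile. This is a heuristic stand-in for the human choice of the
  lesion pattern; an explicit `component` override exists at every call
  site.
* **Thresholding.** Default is Otsu's threshold on the component scores
  (data-driven lesion/background split). A fixed `threshold_quantile` is
  available instead; a fixed quantile hard-codes an assumed lesion area
  fraction, which is why it is not the default.
* **Correction hook.** A correction mask (PNG/CSV) can veto or add pixels,
  standing in for histology-guided manual correction.

Negatives are drawn uniformly without replacement from non-positive pixels,
one per positive (all of them, with a warning, if fewer exist), so the
classes are balanced and SDD pixels can never enter the background class.

## Classification

XGBoost binary classifier, one model per dataset/polarity. Defaults: 200
trees, depth 4, learning rate 0.1, logistic objective, histogram tree
method, single thread, seeded — deterministic end to end. Split is
stratified 67 %/33 %; metrics are balanced accuracy (mean of per-class
recalls) plus precision/recall/F1 of the SDD class at threshold 0.5,
computed only on held-out pixels (an explicit guard rejects train/test
overlap).

`colsample_bynode = 0.2` is on by default for interpretability rather than
accuracy: isotopologue features of one species are nearly collinear, and a
deterministic tree ensemble will otherwise concentrate the whole species'
attribution on whichever feature it happens to split on first. Per-node
column subsampling gives every correlated feature split opportunities, so
SHAP spreads attribution across a species' isotope envelope — the behavior
the shortlist's isotope cross-referencing is designed to surface.

## Interpretation

Local values are exact path-dependent TreeSHAP values on the margin
(log-odds) scale, computed by the booster itself; additivity
(base + Σ contributions = margin) therefore holds at float precision. The
margin is emitted in float32, so the additivity check is applied at 1e−6
*relative* to the margin scale. The independent cross-check in the test
suite is a brute-force Shapley enumerator over all feature coalitions that
walks the dumped trees with cover-weighted expectations; it agrees with the
fast path to < 1e−4 on stump and depth-2 ensembles.

Global score = mean |SHAP| over all pixels (all pixels, not only test
pixels, matching whole-tissue SHAP maps). Direction = sign of the Pearson
correlation between a feature's intensity and its SHAP column; features the
model never uses have zero columns, direction "none", and sort last (ties
break toward lower m/z). SHAP maps are rendered with a symmetric diverging
scale (red positive, blue negative, white zero). The shortlist takes the
top 20 features, joins annotations, and flags rows sitting k × 1.0033548
above another shortlisted feature as ¹³C isotopologues.

## Mass chemistry

Monoisotopic masses use H 1.0078250319, C 12 (exact), N 14.0030740,
O 15.9949146, P 30.9737615, Na 22.9897693, K 38.9637065, Cl 34.9688527;
proton 1.00727646, electron 0.00054858, ¹³C−¹²C 1.0033548. Adduct ions
account for the electron (e.g. [M+Na]⁺ adds the sodium *cation* mass).
Composition rules cover PC, LPC, PE, LPE, PE-NMe2, PA, LPA, cPA, PI and SM,
parameterized by total acyl carbons and double bonds (SM uses the
base + acyl total, matching names like "SM(42:1)"). Only ¹³C isotopologues
are modeled; ²H/¹⁵N/¹⁸O envelopes are irrelevant at the ± 7–10 ppm windows
used. Annotation is nearest-match within tolerance, lower m/z winning ties;
unmatched features are carried as "unknown".

## The phantom: what it emulates, and what it does not

The generator emulates: a four-stratum retina section (inner retina,
bacillary/photoreceptor layer, RPE, choroid) on a default 200 × 120 grid;
dome-shaped deposits centered on the RPE upper boundary, placed in jittered
slots across the section so all requested lesions fit — neighboring domes
may partially merge, as confluent late-stage deposits do; a ~90-species
panel (~290 peaks with isotopes) containing three deposit-exclusive
lysolipids, three deposit/photoreceptor-shared phospholipids, one
deposit-excluded sphingomyelin present in all strata but displaced by
lesions, eight ubiquitous species that double as alignment references and
calibrants, and deterministic per-stratum filler species (panel members
whose isotope envelopes would come within 30 ppm of an existing peak are
dropped, so every peak is resolvable on the 1.5 ppm axis). Intensities are
`base × isotope ratio × pixel scale × lognormal(σ = 0.25)` plus a Gaussian
noise floor (σ = 1, truncated at zero); isotope ratios are binomial in the
carbon count (p(¹³C) = 0.0107). Mass drift is low-pass-filtered white noise
scaled to ± 15 ppm; the per-pixel intensity scale spans 0.5–2×. Each pixel
carries one huge spike at a uniform random m/z with probability 0.02.

The deposit-exclusive species emit two isotopologues (M, M+1): for C16–C26
lysolipids at the panel's base intensities the M+2 peak (2–3 % relative
abundance) sits below the noise floor, and a "true marker" that is planted
below the detection limit is not a meaningful recovery target. Larger
shared/ubiquitous species emit three.

Compartment rule: a deposit pixel emits exactly the species whose
compartment set includes "deposit"; every other pixel emits its stratum's
species. Consequently exclusive species are *identically zero* outside
lesions (not merely small), and the excluded species is zero inside them.

What passing tests on phantoms therefore shows: the pipeline's machinery —
alignment and calibration arithmetic, conservation and robustness
invariants, label construction, model fitting, exact SHAP attribution and
ranking logic — behaves correctly under realistic geometry, drift, scaling
and outliers. What it does not show: performance on real tissue, where
marker species are enriched rather than binary present/absent, peak shapes
and isotope patterns deviate from the ideal, m/z centroids carry
measurement noise beyond a smooth drift field, and labels are imperfect.
The near-perfect phantom classifier metrics are a property of the planted
separability, not a performance claim about donor data.

## Problem sizes and determinism

Unit tests run on 100 × 60-pixel phantoms (6 deposits, radius 5–8 px);
the acceptance properties use ten seeded end-to-end runs at the default
200 × 120 scale (12 deposits, radius 8–12 px, ~3,300–3,500 positive pixels
per class) — sizes chosen so a full validation cycle completes in minutes
on one core while the labeled-class sizes match the hundreds-of-thousands-
of-pixels regime only in class balance, not in total pixel count. All
randomness flows from explicit integer seeds through `numpy` Generators
(the drift field, intensity jitter, deposit placement, negative sampling,
NMF init, the train/test split and the booster each draw from seeded,
separated streams), so identical configs reproduce byte-identical datasets,
models, metrics and shortlists in single-threaded mode.

## Known limitations

* The drift magnitude of real instruments is not characterized here; the
  ± 15 ppm default is a config-exposed stand-in.
* The component auto-selection heuristic assumes lesions are laterally
  localized blobs on a stratified background; unusual geometries need the
  manual `component` override.
* Scalar-shift alignment cannot correct m/z-dependent *per-pixel* error
  (only the global component is removed by calibration).
* Per-feature windows (± 7 ppm) assume post-calibration residuals ≪ 7 ppm;
  uncalibrated data with large drift will lose intensity at window edges.
* No deisotoping by design: rankings deliberately contain isotopologues,
  which the shortlist cross-references rather than collapses.
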