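# Methods

## The model system and what the pipeline measures

Human stem-cell-derived midbrain dopaminergic neurons (mDANs) exposed for
72 h to bisphenols (BPA, BPS) or perfluoroalkyls (PFOS, PFOA) at 0.01, 0.1,
1 and 2 µM show a Parkinson's-disease-like phenotypic shift: elevated
α-synuclein and tyrosine-hydroxylase (TH) staining — the latter both in the
cytoplasm and around the cell membrane — and a shorter, less branched MAP2
neurite network, with no loss of viability. The effects are small at the
single-feature level; they become reliably detectable when a broad
phenotypic profile (126 features over four subcellular compartments) is
fed to a classifier. This package implements that measurement chain and a
synthetic data generator that emulates its statistical structure, so each
stage can be validated against known ground truth.

## Synthetic plate generator

One field is a 4-channel (DNA/Hoechst, TH, αSyn, MAP2) 16-bit image.
Defaults (all in `RenderParams`, intensities in camera units, lengths in
pixels at 0.1628 µm/px):

* **Field geometry**: 256×256 px, ~7 cells/field (Poisson), minimum
  soma-centre separation 66 px. The study acquired larger fields with more
  cells; the scaled-down field keeps segmentation non-trivial (touching
  MAP2 areas, neurite crossings) while a full plate stays tractable on one
  CPU.
* **Nuclei**: rotated ellipses, semi-axes 27–32 px (area 2200–3100 px —
  always above the 2000-px living-cell bound), DNA intensity 900–1250
  (below the 1500 apoptotic bound). Apoptotic nuclei: semi-axes 12–16 px,
  intensity 2600–3600, violating the living rule on both sides by
  construction. The apoptotic fraction (default 0.08) is shared by every
  condition including vehicle, making the living-cell count a true null
  readout.
* **Intensity scale**: background ~200 with a smooth per-field gradient
  (amplitude 40) to exercise illumination correction; soma signal
  2400–5400 per channel. The scale is calibrated so the printed nuclear
  viability threshold of 1500 is meaningful; the camera bit depth of the
  real instrument is not stated anywhere, so 16-bit was fixed here.
* **Neurites**: 2–4 walks per cell, unit steps with Gaussian angular
  jitter (σ = 0.18 rad), length ~N(110, 25) px, branch probability
  0.025/step (a branch forks at ±0.95 rad with 60% of the remaining
  length). The ground-truth length is the Euclidean length of the chain of
  *newly visited* centreline pixels outside every soma: self-overlaps,
  branch overlaps and segments hidden under a neighbouring soma are not
  counted, because no image-based skeleton can recover them. The branch
  rate is set high enough that genuine branches dominate the
  junction-detection floor created by chance neurite crossings; with it,
  injected length and branch multipliers are recovered within ±15%
  through the full segmentation pipeline.
* **TH structure**: TH fills the soma of TH-positive cells (85%); a 4-px
  rim at the soma edge carries a separate, brighter membrane pool
  (5400 vs 2800) that *replaces* the cytoplasmic fill under the rim, so
  the membrane-TH readout responds ~linearly to its effect multiplier.
* **Effects and variability**: a condition's `ConditionEffect` multiplies
  αSyn intensity, cytoplasmic TH, membrane TH (up with dose) and neurite
  length / branch probability (down with dose). Default ladders are
  monotone over 0.01→2 µM with class-shared directions — bisphenols weigh
  more on αSyn and neurite loss, perfluoroalkyls more on TH — giving the
  two compound classes distinct but overlapping signatures. On top of the
  condition effect sit lognormal per-cell (CV 10%), per-well (CV 4%) and
  per-biological-replicate (CV 3%) factors; the two replicates emulate
  separate thawings as plate-level offsets.
* **Noise**: Poisson shot noise (gain 0.5 photons/unit) plus Gaussian read
  noise (σ 25), clipped to uint16.
* **Determinism**: per-(well, field) `SeedSequence` spawning; identical
  inputs give byte-identical TIFFs regardless of iteration order.

What the generator does **not** emulate: optics (PSF, defocus, chromatic
shifts), 3-D structure (the real acquisition took 3 z-slices; fields here
are born 2-D), staining chemistry and its artefacts, cell-cycle and
morphological subpopulations beyond the living/apoptotic dichotomy, and
spatial plate effects other than a per-replicate offset. Passing tests
therefore certify the *analysis chain* — that known injected effects are
recovered and known nulls stay null — not performance on real microscope
images.

## Segmentation

All steps run on illumination-corrected images. The background estimate is
a wide Gaussian (σ 64 px) of the image clipped at its 25th percentile and
8× downsampled — clipping keeps bright somata from inflating the estimate
(which would otherwise carve intensity out of nearby neurites), and the
minimum is retained so flat images pass through unchanged.

* **Nuclei**: threshold (per-field Otsu by default, fixed value via
  config), objects < 120 px removed, touching nuclei split by
  distance-transform watershed (peak separation 12 px).
* **Viability**: living ⇔ area > 2000 px AND mean DNA < 1500, both strict,
  per the printed rule; everything else is apoptotic.
* **Cells**: MAP2-positive area (Otsu), partitioned among *living* nuclei
  by watershed on distance-to-nucleus; MAP2 components containing no
  living nucleus stay background, pixels beyond 400 px of every nucleus
  are dropped, and no nucleus pixel is ever assigned to another cell.
* **Compartments**: cytoplasm(L) = cell(L) − nucleus(L);
  membrane(L) = cell(L) − erosion(cell(L), 3×3 cross × 5 iterations),
  computed per label so rims also exist along shared watershed boundaries.
  The printed "0.81 µm²" for the 5-px window is dimensionally a linear
  width (5 × 0.1628 µm = 0.81 µm) and is treated as such.
* **Neurites**: soma = isotropic opening of the cell mask (radius 8 px);
  the remainder (fragments < 8 px discarded) is skeletonized. Length sums
  inter-pixel steps (1 for 4-neighbours, √2 for diagonals) × pixel pitch
  on the unpruned skeleton; branch points are junction clusters (≥ 3
  skeleton neighbours) counted after 5 rounds of endpoint pruning, which
  suppresses noise spurs at the cost of branches shorter than ~5 px.
  Per-cell attribution follows the cell-label partition.

Segmentation is fully deterministic. Cells whose bounding box touches the
field border keep intensity features but report NaN shape features.

## Feature catalogue

The 126-feature registry (`catalogue.py`) is data, not code — name, class,
compartment, channel per feature, hashed into every output table:

| block | count | contents |
|---|---|---|
| intensity | 48 | {cell, cytoplasm, membrane, nucleus} × {TH, αSyn, MAP2} × {mean, median, std, integrated} |
| shape | 20 | 4 compartments × {area µm², perimeter µm, eccentricity, solidity, form factor 4πA/P²} |
| texture | 24 | {cell, cytoplasm} × {αSyn, TH, MAP2} × {ASM, contrast, correlation, homogeneity} |
| context | 34 | 6 channel-pair Pearson r × {cell, cytoplasm, nucleus}; counts, apoptotic fraction, density, TH⁺ fraction, nearest-neighbour distances; neurite length and branch points per cell; MAP2 surface per nucleus; αSyn in TH⁺ cells; TH/αSyn double-positive surface intensity and area fraction; nuclear DNA content |

GLCM texture uses 16 gray levels quantized over the compartment's 1st–99th
intensity percentiles, distance 1, four directions averaged, symmetric,
with a sentinel level excluding pixel pairs that cross the compartment
boundary. Constant regions report ASM = 1, contrast = 0 and correlation 0
(undefined). TH-positivity and double-positivity gates default to
per-field Otsu thresholds on the respective channel; per-plate Otsu on
cell means was rejected because ~6 cells per field make a cell-level Otsu
unstable.

Per-cell features are averaged over all living cells pooled across a
well's fields; field-level features are averaged over fields. A well with
zero living cells yields a NaN row that is dropped (profiling) or
median-imputed per feature (classification) downstream.

## Profiling, classification, statistics

* **Scaling**: x′ = (x − median)/IQR per feature (IQR = Q3 − Q1, linear
  interpolation), population = all wells jointly; IQR = 0 → centred only,
  flagged. Condition profiles are per-feature medians of scaled well rows.
* **Clustering**: cosine distance between profiles, average linkage (the
  linkage is configurable; the source analysis does not state one);
  exported as a distance matrix and a Newick tree.
* **Embedding**: UMAP (2-D, fixed seed) with the treated-vs-control
  silhouette reported as a diagnostic. UMAP is the supported method; the
  method argument is open for other embeddings.
* **Classification**: control = vehicle wells, treated = any compound at
  any dose. Stratified 90/10 split by well row; 5-fold grid search
  (LDA: solver/shrinkage; LightGBM: n_estimators × learning rate ×
  num_leaves; XGBoost: n_estimators × learning rate × max_depth — grids
  are config, none were stated in the source); refit on the full training
  set; 10-fold CV spread; confusion matrix, accuracy = trace/total and
  P(control) per test well; importances = |standardized coefficients|
  (LDA) or gain (trees), normalized to fractions, top-10 reported. By
  default the scaler is fit inside the pipeline on training folds only,
  which avoids information leakage; `scale_before_split=True` scales the
  whole table first, replicating the original processing order. Splitting
  is by well row, as in the original analysis; replicate-grouped splits
  were considered and left out of the default.
* **Dose–response**: per feature and compound, well values are divided by
  the vehicle mean of their biological replicate (the per-plate
  normalization unit here); one-way ANOVA across the five dose groups;
  if p < 0.05, Tukey HSD with only dose-vs-vehicle contrasts reported;
  tiers ns/*/**/*** at 0.05/0.01/0.001; 95% t-interval of the mean.
  Normality is assumed (a Shapiro diagnostic is available but never
  gates). Degenerate all-equal groups report an undefined F flagged "ns".

## Problem sizes

The default configuration — 84 wells (36 vehicle + 4 compounds × 4 doses ×
3 technical replicates over 2 biological replicates), 4 fields/well,
256² px, ~7 cells/field — is the package's scaled-down standard
experiment: large enough that the 10% test split (9 wells) can express
accuracies at the granularity the classification claims require, small
enough that a full simulate→classify run takes ~1–2 minutes. The
control-majority design mirrors the original screen, whose test split
held 15 control against 11 treated wells. The study-scale acquisition
(16 fields/well, 384-well coordinates, edge wells excluded) is available
through the same config.

## Known limitations

* Skeleton-based neurite length is biased ~8% low (threshold erosion at
  neurite tips, soma-adjacent pixels); the bias is shared by treated and
  vehicle wells and cancels in ratios, which is what the dose–response
  and classification stages consume.
* Branch-point detection has a floor from chance neurite crossings; at
  the default density it contributes ~0.5 junctions/cell.
* LDA coefficients on 126 correlated features with ~75 training wells are
  unstable; its importance ranking is reported but should be read with
  less confidence than the trees' gain importances.
* The membrane compartment of a cell includes its neurites (the cell mask
  is the whole MAP2-positive area, and thin neurites erode away
  entirely), so membrane intensity readouts mix the soma rim with the
  neurite arbor. This mirrors the compartment definition rather than an
  idealized "soma membrane".
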