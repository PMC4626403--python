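# Methods

Mathematical conventions implemented by `histotex`, stated precisely so that
results are reproducible from this note alone. Degenerate-input behaviour is
part of the contract because synthetic and mask-like tiles routinely produce
constant planes.

## 1. Colour models (`histotex.colour`)

Input is 8-bit RGB. Conversions keep native units; `rescale8` maps each
channel's *nominal* range linearly onto [0, 255]:

| model | channels (native range) |
|---|---|
| `rgb` | R, G, B ∈ [0, 255] |
| `cmyk` | C, M, Y, K ∈ [0, 1]; K = 1 − max(R′,G′,B′), C = (1−R′−K)/(1−K) etc. with R′ = R/255; C = M = Y = 0 for black |
| `hsv` | H ∈ [0, 360), S, V ∈ [0, 1] |
| `lab` | CIELAB under D65, L ∈ [0, 100], a, b ∈ [−128, 127] |
| `luv` | CIELUV under D65, L ∈ [0, 100], u, v ∈ [−134, 220] / [−140, 122] |
| `sct` | M = √(R²+G²+B²) ∈ [0, 255√3]; φ = arccos(B/M), θ = arctan(G/R), both in degrees ∈ [0, 90] |
| `lbb` | (L, b, b) from CIELAB |
| `hbb` | (H, b, b): HSV hue plus CIELAB b twice |

SCT degenerate cases: M = 0 ⇒ φ = 0; R = 0 ⇒ θ = 90° if G > 0 else 0.

`channel_plane(img, model)` = convert → rescale8 → mean over channels; this
single scalar plane is what all texture descriptors consume.

## 2. Statistics bank (`histotex.statsbank`)

Planes are rounded and clipped to integer grey levels g ∈ {0, …, 255};
h(g) is the normalised histogram. All entropies use the natural logarithm
with the convention −Σ p log p and 0·log 0 = 0.

**First order (13):** mean, mode (ties → smaller grey), variance, the three
quartiles (smallest g whose cumulative histogram ≥ 1/4, 1/2, 3/4), IQR, min,
max, range, entropy, skewness and kurtosis (raw moment ratios; 0 when
σ = 0).

**Second order (19):** the GLCM p(i, j) is computed globally at 256 levels,
symmetrised (each pair counted both ways) and normalised to sum 1, for every
(distance, angle) ∈ {1, 3, 5} × {0°, 45°, 90°, 135°}; 0° pairs each pixel
with its east neighbour, 90° with its north neighbour. With marginals
p_x, p_y, means μ_x, μ_y, deviations σ_x, σ_y, and the diagonal sums
p_{x+y}(k) = Σ_{i+j=k} p, p_{x−y}(k) = Σ_{|i−j|=k} p:

- energy Σp², contrast Σ k² p_{x−y}, max probability, dissimilarity
  Σ|i−j| p, homogeneity₁ Σ p/(1+(i−j)²), homogeneity₂ Σ p/(1+|i−j|);
- correlation (Σ i j p − μ_x μ_y)/(σ_x σ_y), defined as **0** when a σ
  vanishes; autocorrelation Σ i j p;
- variance Σ (i−μ)² p with μ = (μ_x+μ_y)/2; cluster shade/prominence
  Σ (i+j−μ_x−μ_y)^{3,4} p;
- sum average Σ k p_{x+y}; sum entropy SE = −Σ p_{x+y} log p_{x+y};
  **sum variance Σ (k − SE)² p_{x+y}** (the classical formula, which centres
  on the sum entropy rather than the sum average);
- **difference variance Σ k² p_{x−y}**, i.e. numerically equal to contrast
  (the uncentred second moment of p_{x−y});
- entropy HXY = −Σ p log p; difference entropy; information correlations
  IC1 = (HXY − HXY1)/max(HX, HY) and IC2 = √(1 − e^{−2(HXY2 − HXY)}) with
  HXY1 = −Σ p log(p_x p_y), HXY2 = −Σ p_x p_y log(p_x p_y). Because p is
  symmetric and normalised, HXY1 = HXY2 = HX + HY exactly; the code uses this
  identity, and the test suite verifies it against the literal double sums.

Bank layout: 13 first-order values, then 19 second-order values per offset in
distance-major order — 241 features per image.

## 3. Space-frequency descriptors (`histotex.spacefreq`)

**Fourier bands.** The centred 2-D spectrum is partitioned into four
equal-width annuli of radius [0, r_max] (DC in band 1; masks disjoint and
exhaustive, so the four inverse-transformed band images sum to the input).
Each band image is the real part of the inverse FFT.

**Wavelet details.** Four-level undecimated (stationary) transform with
Daubechies-5. Tiles are symmetrically padded to a multiple of 2⁴ and cropped
back. Per level the three detail images are summed (H+V+D); labels run
finest (lvl1) to coarsest (lvl4); the approximation is discarded.

**Gabor energies.** Complex kernels
G(x, y) = (f²/πγη)·exp(−(f²/γ² x′² + f²/η² y′²))·exp(j2πf x′), x′ along the
orientation, with γ = η = 1, four octave-spaced central frequencies
f ∈ {0.25, 0.125, 0.0625, 0.03125} cycles/pixel and four orientations
{0°, 45°, 90°, 135°}. The kernel mean is subtracted (zero DC response), the
tile is convolved (FFT convolution, `same` size), and per scale the four
orientation magnitudes |G∗I| are summed into one energy image.

## 4. Transformed-image descriptors (`histotex.transformed`)

**M-LBP.** For each pixel, the 8 neighbours at radius 1 (edge-replicated)
are thresholded at the **mean of those 8 neighbours** (centre excluded),
with H(0) = 1 (ties count as 1). Bit p = 0 is the east neighbour, proceeding
clockwise. Codes lie in [0, 255]; the map is invariant to affine grey
changes a·I + b, a > 0.

**Spatial textons.** All overlapping 3×3 patches (as 9-vectors) of the
training tiles of each class are clustered with k-means (k-means++, 10
restarts, seeded) into 60 words per class; the concatenated 240-word
vocabulary labels each test-tile patch with its nearest (Euclidean) word,
lowest index winning ties. The index map is rescaled by 255/(K−1) to an
8-bit plane before the statistics bank.

## 5. Feature naming and counts (`histotex.features`)

Feature names are `model:descriptor:band:stat`. Descriptor order is fixed:
intensity, fourier, wavelet, gabor, mlbp, stextons. Counts per colour model:
241 (single-image descriptors), 964 (four-image descriptors), 3615 for all
six. Multi-model tables concatenate per-model blocks; e.g. eight models ×
intensity = 1928, eight × one quad descriptor = 7712, and six models ×
Intensity&M-LBP&Gabor&S-Textons = 10 122.

## 6. Correlation filter (`histotex.reduce`)

Columns are visited in table order. Zero-variance columns are dropped first.
A column is dropped iff its absolute Pearson correlation with **any
already-kept** column reaches the threshold (greedy keep-first); each drop
records the kept partner. The fitted filter is a plain column selection and
can be applied to new tables.

## 7. Classifiers and cross-validation (`histotex.learn`)

**Bagging:** L = 50 bootstrap resamples (size N, with replacement), one
unpruned CART each, majority vote; per-class support = vote fraction.

**AdaBoost (M1 by resampling):** weights start 1/N. Each round draws a
weighted resample, fits a depth-3 tree, computes the weighted error ε on the
full training set. ε = 0 or ε ≥ 0.5 ⇒ the round is discarded and weights
reset. Otherwise β = ε/(1−ε), weights update w ∝ w·β^(1−ℓ) (ℓ = 1 iff
misclassified), and the member votes with weight ln(1/β); class support is
Σ ln(1/β) over members voting for it. Total rounds are capped at 5L; if no
member is ever retained, a single unweighted tree is fitted as a fallback.

Baselines: one-vs-rest least-squares Fisher discriminant (ridge 10⁻⁶,
z-scored), linear SVM (z-scored), 50-tree random forest.

**Cross-validation:** stratified k-fold (default 10), shuffled with the run
seed; every sample is predicted exactly once. With a correlation threshold,
the filter is refit on each training fold (default) or once globally
(`paper_mode`). Texton vocabularies follow the same rule in the pipeline
driver.

## 8. Evaluation (`histotex.evaluate`)

The confusion matrix is oriented rows = predicted, columns = true. Per class
(one-vs-rest): TP = diagonal, FP = row − TP, FN = column − TP,
TN = total − row − column + TP, and

PPV = TP/(TP+FP), NPV = TN/(TN+FN), sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), ACC = (TP+TN)/total,

reported in percent, rounded half-up to two decimals (exact decimal
arithmetic, not float rounding). Macro averages are the exact decimal mean
of the rounded per-class cells, rounded half-up. Empty denominators are
reported as 100 and flagged, never as NaN. ROC curves sweep the per-class
support scores; AUC is trapezoidal and the Youden point maximises
TPR − FPR.

## 9. Synthetic fixtures (`histotex.fixtures`)

Four seeded texture recipes emulate the class structure of HE-stained breast
tissue at the level a texture pipeline sees: (1) stroma — smooth pink field
with sparse blue nuclei; (2) adipose — packed pale discs with thin pink
rims; (3) ducts — dark ring structures with pale lumina; (4) carcinoma —
dense dark-blue speckle. Additive Gaussian noise (σ = 12) is applied before
rounding to 8-bit. Default cohort: 170/103/163/192 tiles of 200×200 px.
Generation is byte-reproducible from (seed, spec). These fixtures exercise
the pipeline end-to-end; they make no claim of histological realism.
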