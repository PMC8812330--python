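# Methods

## Scope and model

`ldcontacts` quantifies linear contact sites between lipid droplets (LDs) and
mitochondria in single confocal sections with three channels (nucleus, LD,
mitochondria; 8/12/16-bit TIFF). A *contact* is operationally defined as one
8-connected component of the skeleton of the per-droplet colocalization mask
— a one-pixel curve running along the apposed membranes, with a calibrated
length. This is a light-microscopy proxy: at ~93 nm pixels and a confocal
PSF, co-occurrence of the two stains indicates proximity, not molecular
tethering, and a 2-D section both truncates and (relative to thin-section
EM) over-collects membrane. All quantities are reported per cell.

Conventions used throughout: 0-based `(row, col)` pixel-centre coordinates;
areas `= pixel count × s²` and lengths in µm with `s` the pixel edge
(default 0.093 µm when no TIFF calibration is present — always logged);
binary masks are boolean arrays; label maps are integer arrays with a
contiguous 1..n range; foreground for every threshold is **strictly
greater** than the level.

## Pipeline stages and parameters

**Cell individualization** (no membrane marker). Composite landscape
`0.2·LD₈ + 0.2·mito₈ + 255·nucleus_mask`, clipped to [0, 255]; the
compensation factors (default 0.2 each) exist to keep the cytoplasmic
channels from rivalling the binary nucleus term and are exposed in the
config. Maxima of the composite with prominence (noise tolerance) > 100
seed a marker watershed (8-connected peak detection, 4-connected flooding,
one-pixel limit lines encoded as label 0). Cell foreground is a Huang
threshold of the median-filtered (circular kernel, radius 2, i.e. offsets
with d² ≤ r²+1; nearest-edge policy) flattened image, where flattening is
the per-pixel mean of the three 8-bit-converted channels. Foreground minus
limit pixels is labelled 4-connected; components ≥ `min_cell_area_um2`
(default 50 µm²) that contain at least one nucleus pixel are kept, numbered
in raster order of first occurrence; border-touching cells are kept but
flagged so users can filter them downstream.

**Thresholds.** Otsu (maximum between-class variance), Yen (maximum
correlation criterion) and Huang (minimum fuzzy Shannon entropy of
membership, class means rounded to integers, membership
`1/(1+|g−m|/C)` with `C` the populated histogram range) all operate on the
256-bin histogram of the 8-bit-converted plane and break ties toward the
smallest optimizing level. Huang accumulates its score with
correctly-rounded summation (`math.fsum`) so near-ties resolve
independently of accumulation order. Degenerate (single-bin) histograms
raise, or at pipeline level produce an empty mask with a warning.

**LD segmentation.** A per-pixel random forest (default 200 trees,
√n_features per split, seeded and bit-reproducible) over a feature bank:
raw intensity; Gaussian blurs at σ ∈ {1, 2, 4, 8, 16} px; all pairwise
differences of those Gaussians; Sobel gradient magnitude of each smoothed
plane; largest/smallest eigenvalue of the finite-difference Hessian of each
smoothed plane; and six projections (sum, mean, std, median, max, min) over
six 30°-rotations of a 19×19 line kernel of thickness 3. Training
subsamples at most 4000 labelled pixels per class per image (seeded).
Models persist as a directory: `model.json` (feature configuration,
metadata) plus a joblib payload for the fitted forest; loading reproduces
predictions exactly. Without a model the pipeline falls back to a Yen
threshold of the LD channel with components < 9 px removed as
sub-resolution speckle.

**Colocalization and contacts.** Pixel colocalized iff LD intensity
strictly above the LD channel's Yen level, mitochondria intensity strictly
above the mitochondria channel's Otsu level, and
`100·min/max > ratio_percent` (default 50). The min/max ratio is symmetric
in the two channels, so the rule is order-independent. Individual droplets
come from a watershed of the Euclidean distance transform of the LD mask
(prominence 0.5 px — any two lobes separated by more than half a pixel of
depth split); the colocalization mask minus the droplet limit lines is
skeletonized by thinning (Zhang–Suen family); each 8-connected skeleton
component is one contact. Length counts traced steps — orthogonal `s`,
diagonal `s√2`, with a diagonal not counted where the two endpoints already
share a 4-connected skeleton member — and an isolated pixel counts `s`.
Skeleton spurs are *not* pruned; branched skeletons contribute the sum of
their branch steps. Contacts are assigned to the droplet and cell with
majority pixel overlap under the skeleton, ties to the lower label.

**Measurements.** Perimeters use the corner-weighted boundary estimator of
`skimage.measure.regionprops` (locked by a golden test: a 10×10 px square
has perimeter 36 at s = 1). LD area SD uses the n−1 denominator, 0 for a
single droplet, NaN for none; contact efficiency
(= total contact length / total LD perimeter) is NaN when the droplet
perimeter is zero — undefined ratios never masquerade as 0. Mitochondria
per cell are 4-connected components of the Otsu mask clipped to the cell.
Organelles overlapping no cell are excluded from per-cell statistics and
counted in a log line.

## Synthetic scenes

The generator emulates the targeted data: adherent cells (disks, radius
70 px ≈ 6.5 µm) with an elliptical nucleus; droplets as bright disks
(radius 6–10 px) in the cytoplasmic ring; mitochondria as dilated
random-walk filaments; planted contacts as annular bands on droplet rims
whose centreline arc length is the analytic ground truth. Channels get a
Gaussian PSF (σ 1.5 px ≈ 140 nm) then Poisson photon noise plus Gaussian
read noise (sd 3), giving the principal signals an SNR near 14 and the
cytoplasmic haze an SNR near 5; output is quantized to the acquisition bit
depth.

Construction choices that make the analytic length oracle valid:

* the band spans `[r − 2h, r]` with halfwidth h = 1.25 px and saturated
  intensity (255), and truth is measured on its centreline radius `r − h`,
  where the skeleton of the recovered band runs;
* the angular span is extended by 0.75 px of arc per end, compensating the
  endpoint erosion of thinning (calibrated once against the pipeline on
  held-out seeds; validated afterwards: over 60 two-cell scenes the
  recovered total per scene has mean error −0.7 %, sd 5.1 %, max 12.2 %,
  with contact counts exact in all 60);
* cytoplasmic haze is channel-asymmetric — low in the LD channel (droplet
  dyes are specific), moderate in the mitochondria channel (immunostain
  background), faint in the nucleus channel — and falls off radially toward
  the cell rim. The asymmetry is also what keeps the 50 % ratio criterion
  from firing on bare filaments, and filament walks keep an 8 px margin
  from droplet rims so blur tails cannot jointly clear both thresholds;
* droplets never touch each other (≥ 6 px gaps) and at most one arc is
  planted per droplet.

What the generator does **not** emulate: z-structure and out-of-focus haze
beyond a single Gaussian PSF, chromatic shift, uneven illumination, varying
droplet brightness, genuinely touching droplet clusters, and mitochondrial
network morphology beyond dilated walks. Passing recovery tests therefore
demonstrates correctness of the algorithmic chain under controlled imaging
physics, not robustness to every real-world artifact.

## Numerical and degenerate-input choices

* Prominence is computed by persistence pairing (descending flood with
  union-find): each non-global maximum dies at its highest saddle toward
  higher ground; a maximum survives a tolerance `p` iff its persistence
  strictly exceeds `p`. Plateaus yield one representative, the
  lexicographically smallest pixel; equal-height merges retain the summit
  with the smaller raster index. Peak sets are therefore exactly nested as
  prominence grows, and adding a constant changes nothing.
* A constant image has exactly one peak (the global plateau); a blank
  nucleus channel gives an empty mask and a warning; an empty
  colocalization mask gives zero contacts; empty folders are errors while
  unreadable single images are logged skips.
* All batch outputs are byte-reproducible given the same inputs and
  configuration; the run log records every parameter verbatim.

## Known limitations

* The Huang cell-foreground threshold is bistable when cells fill roughly
  half the frame or more: its fuzzy-entropy curve has competing minima at
  the background/cytoplasm and cytoplasm/organelle splits. Fields should be
  acquired with adequate background around the cells.
* The 50 % intensity-ratio contour can, rarely, isolate a single
  colocalized pixel on a band's inner flank under noise, which then counts
  as a one-pixel contact (~1 per several hundred contacts under the
  default scene conditions). This is a property of the colocalization rule,
  not of the skeletonization.
* Watershed ridge placement inside flat, quantization-limited valleys
  (e.g., between two touching cells with symmetric haze) carries several
  pixels of slack; cell identity and nucleus ownership are stable, the
  exact ridge position is not.
* Chain-code lengths overestimate smooth curves by up to ~8 % depending on
  orientation; at 93 nm pixels this, together with endpoint erosion of
  thinning, dominates the per-contact length uncertainty for arcs under
  ~0.7 µm.
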