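# ldcontacts

Detection and quantification of **lipid droplet–mitochondria membrane contact
sites** in multi-channel fluorescence microscopy images.

Lipid droplets (LDs) and mitochondria exchange lipids and metabolites through
membrane contact sites ("metabolic synapses"). Electron microscopy resolves
these contacts directly but does not scale to hundreds of cells; confocal
fluorescence microscopy does scale, if the image analysis can turn the fuzzy
overlap of two stains into a measurable, per-cell contact line. `ldcontacts`
implements that workflow as a scriptable Python library and CLI for
single-section, three-channel images (nucleus / LD / mitochondria), producing
per-cell linear contact measurements together with full organelle
morphometry.

## Method

For each image the pipeline:

1. **Individualizes cells without a membrane marker.** The cytoplasmic
   channels, intensity-compensated (`0.2·I_LD + 0.2·I_mito`), are added to a
   binary Otsu nucleus mask (×255). Local maxima of this composite with
   prominence > 100 (one per nucleus) seed a watershed whose one-pixel
   *limit* lines split touching cells; the cell foreground itself is a Huang
   threshold of the median-filtered (r = 2) flattened image. Components
   ≥ 50 µm² containing a nucleus become cells.
2. **Segments organelles.** LDs via a trainable per-pixel random-forest
   classifier over a Weka-style feature bank (Gaussian blur, difference of
   Gaussians, Sobel, Hessian eigenvalues, membrane projections at
   σ ∈ {1,2,4,8,16} px), with a Yen-threshold fallback when no model is
   supplied; mitochondria via Otsu.
3. **Extracts contact sites.** A pixel is *colocalized* iff
   `I_LD > T_Yen(LD)` and `I_mito > T_Otsu(mito)` and
   `100·min(I_LD,I_mito)/max(I_LD,I_mito) > 50`. The colocalization mask is
   cut along the limit lines of a per-droplet watershed (on the distance
   transform of the LD mask), so a blob shared by two droplets splits. Each
   piece is thinned to a one-pixel skeleton; every 8-connected skeleton
   component is one contact, with calibrated length
   `N_orth·s + N_diag·s·√2` (s = pixel size, default 0.093 µm).
4. **Tabulates per cell:** area; LD and mitochondria counts, areas,
   perimeters; contact count, total and mean length; and the **contact
   efficiency** = total contact length / total LD perimeter, a normalized
   measure of how much droplet surface communicates with mitochondria.

A synthetic-scene generator (`ldcontacts.synthetic`) renders calibrated
three-channel scenes with known cells, droplets, filamentous mitochondria and
planted contact arcs of analytically known length, so every stage is testable
against ground truth without any image download.

## Worked example

```python
from ldcontacts import analyze_stack, generate_scene, random_scene

stack, truth = generate_scene(random_scene(seed=7))   # one synthetic cell
result = analyze_stack(stack)

print("cells:", result.cells.n_cells,
      "droplets:", int(result.ld_labels.max()),
      "contacts:", len(result.contact_sites))
rec = result.records[0]
print(f"total contact length: {rec.contact_total_length_um:.3f} um "
      f"(planted: {truth.total_contact_length_um:.3f} um)")
print(f"contact efficiency:   {rec.contact_efficiency:.3f}")
```

prints

```
cells: 1 droplets: 9 contacts: 8
total contact length: 9.401 um (planted: 10.135 um)
contact efficiency:   0.180
```

The scene planted 8 contact arcs totalling 10.135 µm on 9 droplets; the
pipeline recovers all 8 contacts and 93 % of the planted length (the residual
is skeleton discretization at 93 nm pixels). The efficiency says 18 % of the
total droplet perimeter in this cell is engaged in contacts.

From a shell, the same pipeline runs over a folder of TIFFs:

```bash
ldcontacts simulate -o scenes --n-scenes 3 --seed 1     # demo data
ldcontacts analyze scenes -o results                    # batch analysis
ldcontacts train --image ld.tif --labels labels.tif -o Model   # LD classifier
```

`analyze` writes one tab-separated `results.txt` (one row per cell per
image), per-image label maps (cells, droplets, mitochondria, contacts), a
per-contact CSV and a `run_log.json` recording every parameter, so each
number in the table is traceable to its inputs.

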