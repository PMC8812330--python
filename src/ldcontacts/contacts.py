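"""Linear LD-mitochondria contact sites.

A contact site is derived in three steps: (1) a colocalization mask marks
pixels where the LD and mitochondria signals jointly exceed their per-channel
auto-thresholds and an intensity-ratio criterion; (2) the mask is cut along
the limit lines of a per-LD segmented-particles partition so a colocalized
blob shared by two droplets splits into one piece per droplet; (3) each piece
is thinned to a one-pixel-wide skeleton, and every 8-connected skeleton
component becomes one contact with a calibrated length.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .io import to_8bit
from .maxima import MaximaResult, segmented_particles
from .thresholds import DegenerateHistogramError, histogram256, threshold_by_name

logger = logging.getLogger("ldcontacts")

_STRUCT8 = np.ones((3, 3), dtype=bool)
_SQRT2 = math.sqrt(2.0)

#: prominence (in pixels of distance) used on the distance transform when
#: splitting touching droplets; anything above half a pixel separates lobes.
LD_SPLIT_PROMINENCE = 0.5


@dataclasses.dataclass
class ColocalizationParams:
    """Thresholding methods and intensity-ratio cut-off of the colocalization rule."""

    ld_threshold_method: str = "yen"
    mito_threshold_method: str = "otsu"
    ratio_percent: float = 50.0

    def __post_init__(self) -> None:
        if not 0 <= self.ratio_percent <= 100:
            raise ValueError(f"ratio_percent must be in [0, 100], got {self.ratio_percent}")


@dataclasses.dataclass
class ContactSite:
    """One skeletonized contact line with its calibrated length and owners."""

    pixels: np.ndarray      # (n, 2) array of (row, col) skeleton pixels
    length_um: float
    ld_label: int
    cell_label: int


def colocalization_mask(
    ld_plane: np.ndarray,
    mito_plane: np.ndarray,
    params: ColocalizationParams | None = None,
    bit_depth: int = 8,
) -> np.ndarray:
    """Pixels where LD and mitochondria signals colocalize.

    Both planes are 8-bit converted; a pixel is colocalized iff its LD
    intensity is strictly above the Yen threshold of the LD plane, its
    mitochondria intensity strictly above the Otsu threshold of the
    mitochondria plane, and ``100 * min(I_ld, I_mito) / max(I_ld, I_mito)``
    is strictly above ``ratio_percent``. A degenerate histogram in either
    channel yields an empty mask with a warning.
    """
    params = params or ColocalizationParams()
    ld8 = to_8bit(ld_plane, bit_depth).astype(np.float64)
    mito8 = to_8bit(mito_plane, bit_depth).astype(np.float64)
    if ld8.shape != mito8.shape:
        raise ValueError("LD and mitochondria planes differ in shape")
    try:
        t_ld = threshold_by_name(histogram256(ld8.astype(np.uint8)), params.ld_threshold_method)
        t_mito = threshold_by_name(
            histogram256(mito8.astype(np.uint8)), params.mito_threshold_method
        )
    except DegenerateHistogramError:
        logger.warning("degenerate histogram in colocalization input; empty mask")
        return np.zeros(ld8.shape, dtype=bool)
    hi = np.maximum(ld8, mito8)
    lo = np.minimum(ld8, mito8)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(hi > 0, 100.0 * lo / np.maximum(hi, 1e-12), 0.0)
    return (ld8 > t_ld) & (mito8 > t_mito) & (ratio > params.ratio_percent)


def ld_particles(ld_mask: np.ndarray) -> MaximaResult:
    """Individualize droplets by segmented particles on the distance transform.

    The Euclidean distance transform of the droplet mask is the landscape;
    its prominent maxima (one per droplet lobe) seed a watershed whose limit
    lines split touching droplets. Regions are restricted to the mask and
    relabelled 1..n.
    """
    ld_mask = np.asarray(ld_mask, dtype=bool)
    if not ld_mask.any():
        empty = np.zeros(ld_mask.shape, dtype=np.int32)
        return MaximaResult([], empty, np.zeros(ld_mask.shape, dtype=bool))
    edt = ndimage.distance_transform_edt(ld_mask)
    res = segmented_particles(edt, LD_SPLIT_PROMINENCE)
    restricted = np.where(ld_mask, res.particles, 0).astype(np.int32)
    old_labels = np.unique(restricted)
    old_labels = old_labels[old_labels > 0]
    remap = np.zeros(int(res.particles.max()) + 1, dtype=np.int32)
    remap[old_labels] = np.arange(1, len(old_labels) + 1)
    relabelled = remap[restricted]
    peaks = [p for p in res.peaks if relabelled[p] > 0 or restricted[p] > 0]
    return MaximaResult(peaks, relabelled, res.limits)


def skeleton_length_px(component: np.ndarray) -> float:
    """Traced length of one skeleton component, in pixel units.

    Orthogonal steps count 1, diagonal steps sqrt(2); a diagonal step is not
    counted when its two endpoints already share a 4-connected skeleton
    neighbour (the path goes around the corner instead). An isolated pixel
    has length 1.
    """
    comp = np.asarray(component, dtype=bool)
    n_pix = int(comp.sum())
    if n_pix == 0:
        return 0.0
    if n_pix == 1:
        return 1.0
    p = np.pad(comp, 1)
    east = p[1:-1, 1:-1] & p[1:-1, 2:]
    south = p[1:-1, 1:-1] & p[2:, 1:-1]
    se = p[1:-1, 1:-1] & p[2:, 2:] & ~(p[1:-1, 2:] | p[2:, 1:-1])
    sw = p[1:-1, 1:-1] & p[2:, :-2] & ~(p[1:-1, :-2] | p[2:, 1:-1])
    n_orth = int(east.sum() + south.sum())
    n_diag = int(se.sum() + sw.sum())
    return n_orth + n_diag * _SQRT2


def _majority_label(label_map: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> int:
    """Most frequent positive label under the given pixels; ties to the lower
    label; 0 if no positive label is present."""
    vals = label_map[rows, cols]
    vals = vals[vals > 0]
    if vals.size == 0:
        return 0
    counts = np.bincount(vals)
    return int(np.argmax(counts))  # argmax ties break to the lower label


def extract_contacts(
    coloc: np.ndarray,
    ld_result: MaximaResult,
    cells: np.ndarray,
    pixel_size_um: float,
) -> list:
    """Skeletonized per-LD contact sites from a colocalization mask.

    The colocalization mask is first cut by the droplet limits
    (minimum-image semantics: limit pixels removed), then thinned; each
    8-connected skeleton component yields one :class:`ContactSite` whose
    droplet and cell owners are assigned by majority overlap with the
    droplet particles and cell label maps (ties to the lower label).
    """
    coloc = np.asarray(coloc, dtype=bool)
    regions = coloc & ~ld_result.limits
    if not regions.any():
        return []
    skeleton = skeletonize(regions)
    labelled, n = ndimage.label(skeleton, structure=_STRUCT8)
    sites = []
    objects = ndimage.find_objects(labelled)
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        comp = labelled[sl] == lab
        rows, cols = np.nonzero(comp)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        length = skeleton_length_px(comp) * pixel_size_um
        sites.append(
            ContactSite(
                pixels=np.column_stack([rows, cols]),
                length_um=float(length),
                ld_label=_majority_label(ld_result.particles, rows, cols),
                cell_label=_majority_label(cells, rows, cols),
            )
        )
    return sites
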