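"""Cell individualization without a membrane marker.

The dataset this workflow targets has no cell-mask stain, so cells are
delineated from what is available: the two cytoplasmic channels (LD and
mitochondria), intensity-compensated so they do not drown the nuclei, are
added to a binary nucleus mask. The nuclei then dominate the resulting
landscape and seed a prominence-based segmented-particles partition whose
limit lines split touching cells; the cell foreground itself comes from a
Huang threshold of the median-filtered flattened image.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage

from .io import ChannelStack, flatten_to_8bit, median_filter, to_8bit
from .maxima import segmented_particles
from .thresholds import auto_mask

logger = logging.getLogger("ldcontacts")

DEFAULT_COMPENSATION = {"ld": 0.2, "mito": 0.2}
DEFAULT_PROMINENCE = 100.0
DEFAULT_MIN_CELL_AREA_UM2 = 50.0

_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclasses.dataclass
class CellPartition:
    """Individualized cells: label map, the nucleus mask that seeded them,
    the compensation factors used, and the labels of cells touching the
    image border."""

    cells: np.ndarray
    nucleus_mask: np.ndarray
    compensation: dict
    border_labels: frozenset = frozenset()

    @property
    def n_cells(self) -> int:
        return int(self.cells.max())


def nucleus_mask(nucleus_plane: np.ndarray, bit_depth: int = 8) -> np.ndarray:
    """Otsu-thresholded, hole-filled binary nucleus mask."""
    mask, _ = auto_mask(nucleus_plane, "otsu", bit_depth)
    if not mask.any():
        logger.warning("nucleus channel produced an empty mask")
        return mask
    return ndimage.binary_fill_holes(mask, structure=_STRUCT4)


def composite_image(
    stack: ChannelStack,
    compensation: dict | None = None,
    nuc_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Seeding landscape: compensated cytoplasmic channels plus the nucleus mask.

    ``ld*f_ld + mito*f_mito + 255*nucleus_mask`` on the 8-bit converted
    planes, clipped to [0, 255]; float output.
    """
    comp = dict(DEFAULT_COMPENSATION, **(compensation or {}))
    for k, f in comp.items():
        if not 0 < f <= 1:
            raise ValueError(f"compensation factor {k}={f} outside (0, 1]")
    if nuc_mask is None:
        nuc_mask = nucleus_mask(stack.planes["nucleus"], stack.bit_depth)
    ld8 = to_8bit(stack.planes["ld"], stack.bit_depth).astype(np.float64)
    mito8 = to_8bit(stack.planes["mito"], stack.bit_depth).astype(np.float64)
    out = ld8 * comp["ld"] + mito8 * comp["mito"] + 255.0 * nuc_mask
    return np.clip(out, 0.0, 255.0)


def individualize_cells(
    stack: ChannelStack,
    prominence: float = DEFAULT_PROMINENCE,
    compensation: dict | None = None,
    min_cell_area_um2: float = DEFAULT_MIN_CELL_AREA_UM2,
    require_nucleus: bool = True,
) -> CellPartition:
    """Segment and label the individual cells of a stack.

    Pipeline: (1) segmented-particles partition of the composite landscape;
    (2) Huang threshold of the median-filtered (radius 2) flattened image as
    cell foreground; (3) minimum of foreground and the limits-complement so
    the ridge lines cut touching cells apart; (4) particle analysis keeping
    4-connected components of at least ``min_cell_area_um2`` that contain at
    least one nucleus pixel, relabelled 1..n in raster order of first
    occurrence. Cells touching the image border are kept but flagged.
    """
    comp = dict(DEFAULT_COMPENSATION, **(compensation or {}))
    nuc = nucleus_mask(stack.planes["nucleus"], stack.bit_depth)
    landscape = composite_image(stack, comp, nuc_mask=nuc)
    particles = segmented_particles(landscape, prominence)

    flat = flatten_to_8bit(stack)
    filtered = median_filter(flat, radius=2)
    foreground, _ = auto_mask(filtered, "huang", bit_depth=8)

    split = foreground & ~particles.limits
    labels, n = ndimage.label(split, structure=_STRUCT4)

    min_px = min_cell_area_um2 / (stack.pixel_size_um**2)
    h, w = labels.shape
    cells = np.zeros_like(labels, dtype=np.int32)
    border_labels = []
    next_label = 0
    for lab in range(1, n + 1):  # scipy labels are already in raster order
        region = labels == lab
        if region.sum() < min_px:
            continue
        if require_nucleus and not (region & nuc).any():
            continue
        next_label += 1
        cells[region] = next_label
        if (
            region[0, :].any()
            or region[-1, :].any()
            or region[:, 0].any()
            or region[:, -1].any()
        ):
            border_labels.append(next_label)

    if next_label == 0:
        logger.warning("no cells found in %s", stack.source_path or "image")
    return CellPartition(
        cells=cells,
        nucleus_mask=nuc,
        compensation=comp,
        border_labels=frozenset(border_labels),
    )
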