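"""Per-cell morphometry and contact statistics.

One :class:`CellRecord` per cell per image: cell area, organelle counts,
areas and perimeters, and the contact statistics (total/mean length, count)
plus the contact efficiency — total contact length divided by total LD
perimeter, a normalized measure of how much droplet surface is engaged in
communication with mitochondria.

Areas are ``pixel count * s^2`` (s = pixel size in um); perimeters use the
corner-weighted boundary estimator of ``skimage.measure.regionprops``
(orthogonal steps weighted 1, corner configurations corrected), locked by a
golden test. Undefined ratios (no droplets, zero droplet perimeter) carry a
NaN sentinel, never 0.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy import ndimage
from skimage import measure

logger = logging.getLogger("ldcontacts")

_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclasses.dataclass
class CellRecord:
    """One row of the results table."""

    image_id: str
    cell_label: int
    border_cell: bool
    cell_area_um2: float
    n_ld: int
    n_mito: int
    ld_total_area_um2: float
    mito_total_area_um2: float
    ld_mean_area_um2: float
    ld_area_sd_um2: float
    ld_mean_perimeter_um: float
    ld_total_perimeter_um: float
    mito_total_perimeter_um: float
    n_contacts: int
    contact_total_length_um: float
    contact_mean_length_um: float
    contact_efficiency: float


CELL_RECORD_FIELDS = [f.name for f in dataclasses.fields(CellRecord)]


def region_morphometry(labels: np.ndarray, pixel_size_um: float) -> dict:
    """``{label: (area_um2, perimeter_um)}`` for every positive label."""
    labels = np.asarray(labels)
    out = {}
    for rp in measure.regionprops(labels):
        out[int(rp.label)] = (
            float(rp.area) * pixel_size_um**2,
            float(rp.perimeter) * pixel_size_um,
        )
    return out


def _majority_assignment(organelles: np.ndarray, cells: np.ndarray) -> dict:
    """Assign each organelle label to the cell covering most of its pixels.

    Organelles whose pixels overlap no cell map to 0 (unassigned). Ties go
    to the lower cell label.
    """
    assign = {}
    for rp in measure.regionprops(np.asarray(organelles)):
        rows, cols = rp.coords[:, 0], rp.coords[:, 1]
        under = cells[rows, cols]
        under = under[under > 0]
        assign[int(rp.label)] = int(np.argmax(np.bincount(under))) if under.size else 0
    return assign


def assemble_records(
    cells,
    ld_labels: np.ndarray,
    mito_mask: np.ndarray,
    contact_sites,
    image_id: str,
    pixel_size_um: float,
) -> list:
    """Build one :class:`CellRecord` per cell.

    ``cells`` is a :class:`~ldcontacts.cell_segmentation.CellPartition` (or a
    bare label map). Droplets are assigned to cells by majority overlap;
    mitochondria are counted as 4-connected components of the mitochondria
    mask clipped to each cell; contacts carry their own cell assignment.
    Organelles overlapping no cell are excluded and logged.
    """
    from .cell_segmentation import CellPartition

    if isinstance(cells, CellPartition):
        cell_map = cells.cells
        border = cells.border_labels
    else:
        cell_map = np.asarray(cells)
        border = frozenset()

    n_cells = int(cell_map.max())
    cell_morpho = region_morphometry(cell_map, pixel_size_um)
    ld_morpho = region_morphometry(ld_labels, pixel_size_um)
    ld_to_cell = _majority_assignment(ld_labels, cell_map)

    unassigned = sum(1 for c in ld_to_cell.values() if c == 0)
    if unassigned:
        logger.info("%s: %d LD(s) overlap no cell and are unassigned", image_id, unassigned)

    records = []
    px2 = pixel_size_um**2
    mito_mask = np.asarray(mito_mask, dtype=bool)
    for lab in range(1, n_cells + 1):
        area, _ = cell_morpho.get(lab, (0.0, 0.0))
        my_lds = [ld for ld, c in ld_to_cell.items() if c == lab]
        ld_areas = np.array([ld_morpho[ld][0] for ld in my_lds])
        ld_perims = np.array([ld_morpho[ld][1] for ld in my_lds])

        in_cell = mito_mask & (cell_map == lab)
        mito_lab, n_mito = ndimage.label(in_cell, structure=_STRUCT4)
        mito_area = float(in_cell.sum()) * px2
        mito_perim = sum(p for _, p in region_morphometry(mito_lab, pixel_size_um).values())

        my_contacts = [s for s in contact_sites if s.cell_label == lab]
        n_contacts = len(my_contacts)
        total_len = float(sum(s.length_um for s in my_contacts))
        ld_total_perim = float(ld_perims.sum())

        n_ld = len(my_lds)
        records.append(
            CellRecord(
                image_id=str(image_id),
                cell_label=lab,
                border_cell=lab in border,
                cell_area_um2=area,
                n_ld=n_ld,
                n_mito=int(n_mito),
                ld_total_area_um2=float(ld_areas.sum()),
                mito_total_area_um2=mito_area,
                ld_mean_area_um2=float(ld_areas.mean()) if n_ld else math.nan,
                ld_area_sd_um2=float(ld_areas.std(ddof=1)) if n_ld > 1 else (0.0 if n_ld == 1 else math.nan),
                ld_mean_perimeter_um=float(ld_perims.mean()) if n_ld else math.nan,
                ld_total_perimeter_um=ld_total_perim,
                mito_total_perimeter_um=float(mito_perim),
                n_contacts=n_contacts,
                contact_total_length_um=total_len,
                contact_mean_length_um=total_len / n_contacts if n_contacts else 0.0,
                contact_efficiency=total_len / ld_total_perim if ld_total_perim > 0 else math.nan,
            )
        )
    return records
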