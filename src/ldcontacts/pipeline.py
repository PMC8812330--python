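"""End-to-end analysis of one stack and batch processing of a folder."""

from __future__ import annotations

import dataclasses
import glob
import logging
import os

import numpy as np

from . import io as ldio
from .cell_segmentation import (
    DEFAULT_MIN_CELL_AREA_UM2,
    DEFAULT_PROMINENCE,
    CellPartition,
    individualize_cells,
)
from .contacts import (
    ColocalizationParams,
    colocalization_mask,
    extract_contacts,
    ld_particles,
)
from .measurements import assemble_records
from .pixel_classifier import LDPixelClassifier, fallback_ld_mask
from .thresholds import auto_mask

logger = logging.getLogger("ldcontacts")


@dataclasses.dataclass
class PipelineConfig:
    """Every tunable of the analysis; recorded verbatim in the run log."""

    compensation_ld: float = 0.2
    compensation_mito: float = 0.2
    prominence: float = DEFAULT_PROMINENCE
    min_cell_area_um2: float = DEFAULT_MIN_CELL_AREA_UM2
    ld_threshold_method: str = "yen"
    mito_threshold_method: str = "otsu"
    ratio_percent: float = 50.0
    pixel_size_um: float | None = None    # override; None = from metadata
    channel_order: tuple = ldio.CHANNEL_ROLES
    model_path: str | None = None
    seed: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class AnalysisResult:
    """All artifacts of one image analysis."""

    records: list
    cells: CellPartition
    ld_mask: np.ndarray
    ld_labels: np.ndarray
    mito_mask: np.ndarray
    coloc_mask: np.ndarray
    contact_sites: list
    contact_map: np.ndarray


def analyze_stack(
    stack: ldio.ChannelStack,
    config: PipelineConfig | None = None,
    classifier: LDPixelClassifier | None = None,
    image_id: str | None = None,
) -> AnalysisResult:
    """Run the full pipeline on one stack.

    Cells are individualized from the composite landscape; the droplet mask
    comes from the trained pixel classifier when one is supplied, else from
    the Yen-threshold fallback; mitochondria are Otsu-thresholded; contacts
    are extracted from the colocalization mask cut per droplet and
    skeletonized; finally one record per cell is assembled.
    """
    config = config or PipelineConfig()
    if image_id is None:
        image_id = os.path.basename(stack.source_path) or "image"
    if config.pixel_size_um is not None:
        stack = dataclasses.replace(stack, pixel_size_um=config.pixel_size_um)

    cells = individualize_cells(
        stack,
        prominence=config.prominence,
        compensation={"ld": config.compensation_ld, "mito": config.compensation_mito},
        min_cell_area_um2=config.min_cell_area_um2,
    )

    if classifier is not None:
        ld_mask = classifier.predict_mask(ldio.to_8bit(stack.planes["ld"], stack.bit_depth))
    else:
        ld_mask = fallback_ld_mask(stack.planes["ld"], stack.bit_depth)
    mito_mask, _ = auto_mask(stack.planes["mito"], config.mito_threshold_method, stack.bit_depth)

    coloc = colocalization_mask(
        stack.planes["ld"],
        stack.planes["mito"],
        ColocalizationParams(
            ld_threshold_method=config.ld_threshold_method,
            mito_threshold_method=config.mito_threshold_method,
            ratio_percent=config.ratio_percent,
        ),
        stack.bit_depth,
    )
    ld_result = ld_particles(ld_mask)
    sites = extract_contacts(coloc, ld_result, cells.cells, stack.pixel_size_um)

    contact_map = np.zeros(stack.shape, dtype=np.int32)
    for i, site in enumerate(sites, start=1):
        contact_map[site.pixels[:, 0], site.pixels[:, 1]] = i

    records = assemble_records(
        cells, ld_result.particles, mito_mask, sites, image_id, stack.pixel_size_um
    )
    return AnalysisResult(
        records=records,
        cells=cells,
        ld_mask=ld_mask,
        ld_labels=ld_result.particles,
        mito_mask=mito_mask,
        coloc_mask=coloc,
        contact_sites=sites,
        contact_map=contact_map,
    )


def _contacts_csv(sites, image_id, path):
    import csv

    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["image_id", "cell_label", "ld_label", "length_um"])
        for s in sites:
            wr.writerow([image_id, s.cell_label, s.ld_label, f"{s.length_um:.6f}"])


def run_batch(
    input_dir: str | os.PathLike,
    output_dir: str | os.PathLike,
    config: PipelineConfig | None = None,
) -> str:
    """Analyse every TIFF in ``input_dir``; write a Results-style folder.

    Per image: label maps for cells, droplets, mitochondria and contacts
    plus a per-contact CSV; cumulatively: one tab-separated results table
    and a JSON run log of all parameters. Unreadable images are logged and
    skipped; an empty folder is an error. Returns the results-table path.
    """
    config = config or PipelineConfig()
    paths = sorted(
        p
        for pattern in ("*.tif", "*.tiff")
        for p in glob.glob(os.path.join(str(input_dir), pattern))
    )
    if not paths:
        raise FileNotFoundError(f"no TIFF images found in {input_dir}")

    classifier = (
        LDPixelClassifier.load(config.model_path) if config.model_path else None
    )

    all_records = []
    label_maps = {}
    processed, skipped = [], []
    os.makedirs(output_dir, exist_ok=True)
    for path in paths:
        image_id = os.path.splitext(os.path.basename(path))[0]
        try:
            stack = ldio.read_stack(
                path, config.channel_order, pixel_size_um=config.pixel_size_um
            )
            result = analyze_stack(stack, config, classifier, image_id=image_id)
        except Exception as exc:  # per-image failure: log and continue
            logger.error("skipping %s: %s", path, exc)
            skipped.append(path)
            continue
        all_records.extend(result.records)
        label_maps[image_id] = {
            "cells": result.cells.cells,
            "ld_labels": result.ld_labels,
            "mito_mask": result.mito_mask,
            "contacts": result.contact_map,
        }
        _contacts_csv(
            result.contact_sites,
            image_id,
            os.path.join(output_dir, f"{image_id}_contacts.csv"),
        )
        processed.append(path)

    if not processed:
        raise RuntimeError(f"all {len(paths)} image(s) in {input_dir} failed")

    params = dict(
        config.as_dict(), input_dir=str(input_dir), processed=processed, skipped=skipped
    )
    return ldio.write_results(all_records, output_dir, label_maps, params)
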