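"""Image and results I/O, calibration, and the intensity primitives of the pipeline.

Conventions used throughout the package:

* images are 2-D numpy arrays indexed ``(row, col)``, 0-based, pixel centres;
* binary masks are boolean arrays of the same shape as their source plane;
* label maps are non-negative integer arrays, 0 = background, labels 1..n;
* areas are ``pixel count * pixel_size_um**2`` (um^2), lengths in um.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("ldcontacts")

#: Calibration assumed when a TIFF carries no resolution metadata (um per pixel edge).
DEFAULT_PIXEL_SIZE_UM = 0.093

CHANNEL_ROLES = ("nucleus", "ld", "mito")


class FormatError(ValueError):
    """Raised when an input image does not match the expected layout."""


@dataclasses.dataclass
class ChannelStack:
    """A calibrated single-section multi-channel fluorescence image.

    Parameters
    ----------
    planes
        Mapping of channel role (``nucleus``, ``ld``, ``mito``) to a 2-D
        intensity array. All planes must share one shape.
    bit_depth
        Acquisition bit depth (8, 12 or 16). Intensities must lie in
        ``[0, 2**bit_depth - 1]``.
    pixel_size_um
        Physical edge length of one pixel in micrometres.
    source_path
        Provenance string (file the stack was read from, or a synthetic tag).
    """

    planes: dict
    bit_depth: int
    pixel_size_um: float
    source_path: str = ""

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 12, 16):
            raise ValueError(f"bit_depth must be 8, 12 or 16, got {self.bit_depth}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {p.shape for p in self.planes.values()}
        if len(shapes) != 1:
            raise FormatError(f"planes disagree in shape: {shapes}")
        vmax = 2 ** self.bit_depth - 1
        for role, plane in self.planes.items():
            if plane.ndim != 2:
                raise FormatError(f"plane {role!r} is not 2-D (3D/time not supported)")
            if np.min(plane) < 0 or np.max(plane) > vmax:
                raise ValueError(
                    f"plane {role!r} intensities outside [0, {vmax}] for "
                    f"bit depth {self.bit_depth}"
                )

    @property
    def shape(self) -> tuple:
        return next(iter(self.planes.values())).shape

    def plane(self, role: str) -> np.ndarray:
        return self.planes[role]


def _pixel_size_from_tags(page) -> float | None:
    """Pixel size (um) from TIFF XResolution/ResolutionUnit tags, if present."""
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0 or den == 0:
        return None
    xres = num / den  # pixels per resolution unit
    if xres == 1.0:   # (1, 1) is the conventional "uncalibrated" placeholder
        return None
    unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 2
    unit = int(unit)
    if unit == 3:  # centimetre
        return 1e4 / xres
    if unit == 2:  # inch
        return 25400.0 / xres
    # ResolutionUnit NONE: ImageJ-style convention, pixels per micron
    return 1.0 / xres


def read_stack(
    path: str | os.PathLike,
    channel_order: Sequence[str] = CHANNEL_ROLES,
    pixel_size_um: float | None = None,
    bit_depth: int | None = None,
) -> ChannelStack:
    """Read a single-section multi-channel TIFF into a :class:`ChannelStack`.

    ``channel_order`` maps plane index (or RGB channel index) to role. Pixel
    size is taken from the argument if given, else from the TIFF resolution
    metadata, else :data:`DEFAULT_PIXEL_SIZE_UM` with a logged warning.

    Raises
    ------
    FormatError
        If the file holds fewer planes than roles requested or planes are
        not 2-D.
    """
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta_px = _pixel_size_from_tags(tf.pages[0])

    if arr.ndim == 2:
        raise FormatError(f"{path}: single plane, need {len(channel_order)} channels")
    if arr.ndim != 3:
        raise FormatError(f"{path}: {arr.ndim}-D data not supported (3D/time unsupported)")

    # channels may be the first axis (planes) or the last (RGB-interleaved)
    if arr.shape[0] <= 4 and arr.shape[0] < arr.shape[-1]:
        planes_arr = arr
    elif arr.shape[-1] <= 4:
        planes_arr = np.moveaxis(arr, -1, 0)
    else:
        planes_arr = arr
    if planes_arr.shape[0] < len(channel_order):
        raise FormatError(
            f"{path}: {planes_arr.shape[0]} planes, need {len(channel_order)}"
        )

    if pixel_size_um is None:
        pixel_size_um = meta_px
    if pixel_size_um is None:
        pixel_size_um = DEFAULT_PIXEL_SIZE_UM
        logger.warning(
            "%s: no pixel-size metadata; assuming %.3f um/px", path, pixel_size_um
        )

    if bit_depth is None:
        bit_depth = 8 if planes_arr.dtype == np.uint8 else 16

    planes = {
        role: np.asarray(planes_arr[i]) for i, role in enumerate(channel_order)
    }
    return ChannelStack(
        planes=planes,
        bit_depth=bit_depth,
        pixel_size_um=float(pixel_size_um),
        source_path=str(path),
    )


def write_stack(stack: ChannelStack, path: str | os.PathLike) -> None:
    """Write a stack as a multi-plane TIFF with pixel-size metadata (px/cm)."""
    arr = np.stack([stack.planes[r] for r in CHANNEL_ROLES])
    res = 1e4 / stack.pixel_size_um  # pixels per centimetre
    tifffile.imwrite(
        path,
        arr,
        photometric="minisblack",
        resolution=(res, res),
        resolutionunit="CENTIMETER",
    )


def to_8bit(plane: np.ndarray, bit_depth: int = 16) -> np.ndarray:
    """Linear display-range conversion of a plane to 8 bit.

    An 8-bit plane is returned unchanged. Otherwise the plane's ``[min, max]``
    is mapped linearly onto ``[0, 255]`` with round-half-up; a constant plane
    maps to all zeros.
    """
    plane = np.asarray(plane)
    if bit_depth == 8 or plane.dtype == np.uint8:
        return plane.astype(np.uint8, copy=False)
    lo = float(plane.min())
    hi = float(plane.max())
    if hi == lo:
        return np.zeros(plane.shape, dtype=np.uint8)
    scaled = (plane.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return np.floor(scaled + 0.5).astype(np.uint8)


def disk_footprint(radius: int) -> np.ndarray:
    """Rank-filter disk: offsets with squared distance <= radius**2 + 1."""
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r + 1


def median_filter(plane: np.ndarray, radius: int = 2) -> np.ndarray:
    """Median filter with a circular (rank-filter) kernel, nearest-edge policy."""
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    from scipy import ndimage

    return ndimage.median_filter(
        plane, footprint=disk_footprint(radius), mode="nearest"
    )


def flatten_to_8bit(stack: ChannelStack) -> np.ndarray:
    """Flatten the three channels to one 8-bit plane.

    Each channel is 8-bit-converted independently, then the per-pixel
    unweighted mean of the three 8-bit planes is taken (the (R+G+B)/3 rule of
    an RGB-to-8-bit conversion), rounded half-up.
    """
    planes8 = [
        to_8bit(stack.planes[r], stack.bit_depth).astype(np.float64)
        for r in CHANNEL_ROLES
    ]
    mean = sum(planes8) / 3.0
    return np.floor(mean + 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# results output

RESULTS_TABLE = "results.txt"
RUN_LOG = "run_log.json"


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Cell records (dataclasses) as a DataFrame with a stable column order."""
    from .measurements import CELL_RECORD_FIELDS

    rows = [dataclasses.asdict(r) for r in records]
    return pd.DataFrame(rows, columns=CELL_RECORD_FIELDS)


def write_results(
    records: Sequence,
    out_dir: str | os.PathLike,
    label_maps: Mapping[str, Mapping[str, np.ndarray]] | None = None,
    params: Mapping | None = None,
) -> str:
    """Write the per-cell results table, label-map TIFFs and a run log.

    ``label_maps`` maps image id -> {artifact name -> 2-D integer array};
    each array is written as ``<image>_<name>.tif``. ``params`` is dumped
    verbatim to ``run_log.json`` so every number in the table is traceable
    to the parameters that produced it. Returns the path of the table.
    """
    os.makedirs(out_dir, exist_ok=True)
    table_path = os.path.join(out_dir, RESULTS_TABLE)
    frame = records_to_frame(records)
    frame.to_csv(table_path, sep="\t", index=False, na_rep="NaN")

    for image_id, maps in (label_maps or {}).items():
        safe = str(image_id).replace(os.sep, "_")
        for name, arr in maps.items():
            arr = np.asarray(arr)
            if arr.dtype == bool:
                arr = arr.astype(np.uint8) * 255
            dtype = np.uint16 if arr.max() < 2**16 else np.int32
            tifffile.imwrite(
                os.path.join(out_dir, f"{safe}_{name}.tif"), arr.astype(dtype)
            )

    if params is not None:
        with open(os.path.join(out_dir, RUN_LOG), "w") as fh:
            json.dump(params, fh, indent=2, sort_keys=True, default=str)
    return table_path


def read_results(table_path: str | os.PathLike) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`."""
    return pd.read_csv(table_path, sep="\t")
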