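"""Prominence-based local maxima and segmented-particles partitioning.

A local maximum counts as a peak when its height above the highest saddle
connecting it to higher ground exceeds the prominence (noise tolerance);
plateau maxima yield one representative pixel, the lexicographically smallest
``(row, col)`` of the plateau. The "segmented particles" output partitions the
whole image into one region per surviving peak, separated by one-pixel ridge
("limits") lines encoded as label 0.

Peak detection uses 8-connectivity; the flooding that builds the regions uses
4-connectivity so every non-limit pixel is assigned to a 4-connected region.
"""

from __future__ import annotations

import dataclasses

import numba
import numpy as np
from skimage.segmentation import watershed


@dataclasses.dataclass
class MaximaResult:
    """Peaks, their regions, and the ridge lines separating them."""

    peaks: list            # [(row, col), ...] sorted by (row, col)
    particles: np.ndarray  # int label map, 0 on limits
    limits: np.ndarray     # bool mask of ridge pixels

    @property
    def n_labels(self) -> int:
        return len(self.peaks)


@numba.njit(cache=False)
def _flood(flat: np.ndarray, order: np.ndarray, h: int, w: int):
    """Descending union-find flood; persistence (prominence) of each summit.

    Pixels are processed from high to low (raster order within ties). A pixel
    with no higher processed 8-neighbour founds a summit; when components
    meet, every lower summit dies at the meeting level and its prominence is
    recorded. Surviving summits (the global maximum) get +inf.

    Returns ``(prom, is_summit)`` flat arrays; ``prom`` is only meaningful
    where ``is_summit`` is set.
    """
    n = h * w
    dr = np.array((-1, -1, -1, 0, 0, 1, 1, 1), dtype=np.int64)
    dc = np.array((-1, 0, 1, -1, 1, -1, 0, 1), dtype=np.int64)
    parent = np.full(n, -1, dtype=np.int64)
    comp_summit = np.zeros(n, dtype=np.int64)
    comp_value = np.zeros(n, dtype=np.float64)
    prom = np.full(n, -1.0)
    is_summit = np.zeros(n, dtype=numba.boolean)
    roots_buf = np.zeros(8, dtype=np.int64)

    for k in range(n):
        idx = order[k]
        r = idx // w
        c = idx % w
        v = flat[idx]
        nroots = 0
        for t in range(8):
            rr = r + dr[t]
            cc = c + dc[t]
            if 0 <= rr < h and 0 <= cc < w:
                j = rr * w + cc
                if parent[j] != -1:
                    root = j
                    while parent[root] != root:
                        root = parent[root]
                    jj = j
                    while parent[jj] != root:
                        nxt = parent[jj]
                        parent[jj] = root
                        jj = nxt
                    dup = False
                    for q in range(nroots):
                        if roots_buf[q] == root:
                            dup = True
                            break
                    if not dup:
                        roots_buf[nroots] = root
                        nroots += 1
        if nroots == 0:
            parent[idx] = idx
            comp_summit[idx] = idx
            comp_value[idx] = v
            is_summit[idx] = True
            continue
        target = roots_buf[0]
        for q in range(1, nroots):
            rt = roots_buf[q]
            if comp_value[rt] > comp_value[target] or (
                comp_value[rt] == comp_value[target]
                and comp_summit[rt] < comp_summit[target]
            ):
                target = rt
        parent[idx] = target
        for q in range(nroots):
            rt = roots_buf[q]
            if rt != target:
                prom[comp_summit[rt]] = comp_value[rt] - v
                parent[rt] = target

    for i in range(n):
        if is_summit[i] and prom[i] < 0.0:
            prom[i] = np.inf
    return prom, is_summit


def peak_prominences(plane: np.ndarray) -> dict:
    """``{(row, col) of summit representative: prominence}`` for all candidate maxima."""
    plane = np.asarray(plane, dtype=np.float64)
    h, w = plane.shape
    flat = np.ascontiguousarray(plane.ravel())
    order = np.lexsort((np.arange(h * w), -flat))
    prom, is_summit = _flood(flat, order.astype(np.int64), h, w)
    idx = np.nonzero(is_summit)[0]
    return {(int(i) // w, int(i) % w): float(prom[i]) for i in idx}


def find_maxima(plane: np.ndarray, prominence: float) -> list:
    """Representative pixels of maxima with prominence strictly above the tolerance.

    A constant image yields exactly one peak (the global plateau's
    representative). Peaks are returned sorted by ``(row, col)``.
    """
    if not prominence > 0:
        raise ValueError(f"prominence must be > 0, got {prominence}")
    proms = peak_prominences(plane)
    return sorted(p for p, value in proms.items() if value > prominence)


def segmented_particles(plane: np.ndarray, prominence: float) -> MaximaResult:
    """Partition the intensity landscape into one region per prominent peak.

    Marker-based watershed flooding of the inverted landscape from each peak;
    adjacent regions are separated by one-pixel-wide limit lines (label 0).
    """
    plane = np.asarray(plane, dtype=np.float64)
    peaks = find_maxima(plane, prominence)
    if len(peaks) <= 1:
        particles = np.full(plane.shape, len(peaks), dtype=np.int32)
        return MaximaResult(peaks, particles, np.zeros(plane.shape, dtype=bool))
    markers = np.zeros(plane.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    particles = watershed(-plane, markers=markers, connectivity=1, watershed_line=True)
    return MaximaResult(peaks, particles.astype(np.int32), particles == 0)
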