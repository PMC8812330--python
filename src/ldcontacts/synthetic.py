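"""Synthetic three-channel scenes with known cells, organelles and contacts.

The generator emulates the kind of data the pipeline targets: one confocal
section of adherent cells with a DAPI-like nucleus channel, a BODIPY-like
lipid-droplet channel (bright disks over a dim cytoplasmic haze) and an
immunostained mitochondria channel (dilated filament walks). Planted
contacts are thin annular bands just inside a droplet's rim where the
mitochondria signal is raised to droplet-level intensity, so both channels
jointly clear their auto-thresholds there; the band's skeleton length then
approximates the planted arc length. Each plane is blurred with a Gaussian
PSF and degraded with Poisson (photon) plus Gaussian (read) noise.

Every scene is fully determined by its :class:`SceneSpec` (including the
seed).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .io import DEFAULT_PIXEL_SIZE_UM, ChannelStack


class SceneError(ValueError):
    """Scene geometry out of bounds or otherwise invalid."""


@dataclasses.dataclass
class ContactArc:
    """A planted contact: an arc on the rim of one droplet."""

    ld_index: int       # index into the owning cell's ld list
    theta0: float       # radians, arc start
    theta1: float       # radians, arc end (theta1 > theta0)


@dataclasses.dataclass
class CellSpec:
    center: tuple       # (row, col)
    radius_px: float
    nucleus_axes: tuple = (15.0, 11.0)   # ellipse semi-axes (row, col), px
    nucleus_angle: float = 0.0
    lds: list = dataclasses.field(default_factory=list)      # [((row, col), radius_px)]
    mito_paths: list = dataclasses.field(default_factory=list)  # [[(row, col), ...]]
    contacts: list = dataclasses.field(default_factory=list)    # [ContactArc]


@dataclasses.dataclass
class SceneSpec:
    """Full description of one synthetic scene.

    Intensity levels are on the 8-bit scale; defaults give the principal
    signals a photon-noise SNR well above 5 (sqrt(200) ~ 14) and the
    cytoplasmic haze an SNR near 5.
    """

    shape: tuple = (256, 256)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    cells: list = dataclasses.field(default_factory=list)
    psf_sigma_px: float = 1.5
    photon_scale: float = 1.0    # Poisson gain: counts = photon_scale * intensity
    gaussian_sd: float = 3.0     # read noise, 8-bit units
    bit_depth: int = 8
    seed: int = 0
    nucleus_intensity: float = 220.0
    ld_intensity: float = 200.0
    mito_intensity: float = 180.0
    contact_intensity: float = 255.0
    # diffuse cytoplasmic haze: low in the droplet channel (BODIPY-class dyes
    # are droplet-specific), moderate in the immunostained mitochondria
    # channel; the asymmetry keeps the colocalization ratio criterion from
    # firing on bare filaments, while the mito haze stays far enough below
    # the filament level that Otsu splits filaments from cytoplasm
    cytoplasm_ld: float = 12.0
    cytoplasm_mito: float = 30.0
    # faint nucleic-acid counterstain background outside the nucleus; gives
    # the flattened image a distinct cytoplasm mode for the Huang cell mask
    cytoplasm_nucleus: float = 10.0
    mito_width_px: int = 1       # dilation radius of filament walks
    band_halfwidth_px: float = 1.25
    # angular end-cap extension of the rendered band (px of arc at the band
    # centreline); compensates the endpoint erosion of thinning so the
    # skeleton length tracks the planted arc length
    band_end_ext_px: float = 0.75


@dataclasses.dataclass
class ContactTruth:
    cell_label: int
    ld_label: int
    arc_length_um: float


@dataclasses.dataclass
class GroundTruth:
    """Noise-free geometry of a scene, for oracle comparisons."""

    cells: np.ndarray        # cell label map
    ld_labels: np.ndarray    # droplet label map (global labels)
    mito_mask: np.ndarray    # filaments + contact bands
    contacts: list           # [ContactTruth]

    @property
    def total_contact_length_um(self) -> float:
        return float(sum(c.arc_length_um for c in self.contacts))


def _disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _ellipse_mask(shape, center, axes, angle):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _draw_path(mask: np.ndarray, points, width: int) -> None:
    from skimage.draw import line

    for (r0, c0), (r1, c1) in zip(points[:-1], points[1:]):
        rr, cc = line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
        mask[rr, cc] = True
    if width > 0:
        mask |= ndimage.binary_dilation(
            mask, structure=ndimage.generate_binary_structure(2, 2), iterations=width
        )


def _band_mask(shape, center, radius, theta0, theta1, halfwidth, ext_px):
    """Annular band inside the droplet rim spanning [theta0, theta1].

    The angular span is extended by ``ext_px`` (arc pixels at the band
    centreline) at each end, compensating the endpoint erosion of thinning
    so the skeleton length recovers the nominal centreline arc length.
    """
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    d = np.sqrt(dr**2 + dc**2)
    radial = (d >= radius - 2 * halfwidth) & (d <= radius)
    ext = ext_px / (radius - halfwidth)
    ang = np.arctan2(dc, dr)  # angle convention: 0 along +row axis
    lo, hi = theta0 - ext, theta1 + ext
    # compare on the circle: normalize offsets into [0, 2pi)
    span = (hi - lo) % (2 * math.pi) if (hi - lo) < 2 * math.pi else 2 * math.pi
    off = (ang - lo) % (2 * math.pi)
    return radial & (off <= span)


def generate_scene(spec: SceneSpec) -> tuple:
    """Render a scene; returns ``(ChannelStack, GroundTruth)``."""
    h, w = spec.shape
    nucleus = np.zeros((h, w))
    ld = np.zeros((h, w))
    mito = np.zeros((h, w))
    cell_labels = np.zeros((h, w), dtype=np.int32)
    ld_labels = np.zeros((h, w), dtype=np.int32)
    mito_truth = np.zeros((h, w), dtype=bool)
    contacts_truth = []
    next_ld = 0

    for ci, cell in enumerate(spec.cells, start=1):
        r0, c0 = cell.center
        if (
            r0 - cell.radius_px < 0
            or c0 - cell.radius_px < 0
            or r0 + cell.radius_px >= h
            or c0 + cell.radius_px >= w
        ):
            raise SceneError(f"cell {ci} extends beyond image bounds")
        cell_mask = _disk_mask((h, w), cell.center, cell.radius_px)
        cell_labels[cell_mask] = ci
        # cytoplasmic haze falls off toward the cell edge (the cell thins
        # out), so the seeding landscape has a true valley where two cells
        # touch instead of a flat plateau
        rr_g, cc_g = np.mgrid[:h, :w]
        dist = np.sqrt((rr_g - r0) ** 2 + (cc_g - c0) ** 2)
        profile = np.where(
            cell_mask, 0.5 + 0.5 * (1.0 - (dist / cell.radius_px) ** 2), 0.0
        )
        ld += spec.cytoplasm_ld * profile
        mito += spec.cytoplasm_mito * profile
        nucleus += spec.cytoplasm_nucleus * profile

        nuc = _ellipse_mask((h, w), cell.center, cell.nucleus_axes, cell.nucleus_angle)
        nucleus[nuc] = spec.nucleus_intensity

        ld_index_to_label = {}
        for li, (lcenter, lradius) in enumerate(cell.lds):
            d = math.hypot(lcenter[0] - r0, lcenter[1] - c0)
            if d + lradius > cell.radius_px:
                raise SceneError(f"LD {li} of cell {ci} extends beyond its cell")
            next_ld += 1
            ld_index_to_label[li] = next_ld
            dmask = _disk_mask((h, w), lcenter, lradius)
            ld[dmask] = spec.ld_intensity
            ld_labels[dmask] = next_ld

        fil = np.zeros((h, w), dtype=bool)
        for path in cell.mito_paths:
            _draw_path(fil, path, spec.mito_width_px)
        fil &= cell_mask
        mito[fil] = spec.mito_intensity
        mito_truth |= fil

        for arc in cell.contacts:
            lcenter, lradius = cell.lds[arc.ld_index]
            if not arc.theta1 > arc.theta0:
                raise SceneError("contact arc must have theta1 > theta0")
            band = _band_mask(
                (h, w), lcenter, lradius, arc.theta0, arc.theta1,
                spec.band_halfwidth_px, spec.band_end_ext_px,
            )
            mito[band] = spec.contact_intensity
            mito_truth |= band
            # the planted band spans [r - 2h, r]; its centreline, where the
            # skeleton of the recovered apposition band runs, has radius r - h
            r_mid = lradius - spec.band_halfwidth_px
            contacts_truth.append(
                ContactTruth(
                    cell_label=ci,
                    ld_label=ld_index_to_label[arc.ld_index],
                    arc_length_um=r_mid * (arc.theta1 - arc.theta0) * spec.pixel_size_um,
                )
            )

    rng = np.random.default_rng(spec.seed)
    vmax = 2**spec.bit_depth - 1
    scale = vmax / 255.0
    planes = {}
    for role, plane in (("nucleus", nucleus), ("ld", ld), ("mito", mito)):
        blurred = ndimage.gaussian_filter(plane, spec.psf_sigma_px)
        counts = rng.poisson(np.maximum(blurred, 0.0) * spec.photon_scale)
        noisy = counts / spec.photon_scale + rng.normal(0.0, spec.gaussian_sd, plane.shape)
        out = np.clip(np.round(noisy * scale), 0, vmax)
        planes[role] = out.astype(np.uint8 if spec.bit_depth == 8 else np.uint16)

    stack = ChannelStack(
        planes=planes,
        bit_depth=spec.bit_depth,
        pixel_size_um=spec.pixel_size_um,
        source_path=f"synthetic(seed={spec.seed})",
    )
    truth = GroundTruth(
        cells=cell_labels, ld_labels=ld_labels, mito_mask=mito_truth, contacts=contacts_truth
    )
    return stack, truth


# ---------------------------------------------------------------------------
# randomized but reproducible scene construction


def _segment_clears_disks(p0, p1, disks, margin) -> bool:
    """True if segment p0-p1 stays at least ``margin`` from every disk rim."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    v = p1 - p0
    vv = float(v @ v)
    for (center, radius) in disks:
        c = np.asarray(center, dtype=float)
        t = 0.0 if vv == 0 else float(np.clip((c - p0) @ v / vv, 0.0, 1.0))
        closest = p0 + t * v
        if np.linalg.norm(closest - c) < radius + margin:
            return False
    return True


def random_scene(
    seed: int,
    n_cells: int = 1,
    n_lds: tuple = (8, 12),
    n_contacts: tuple = (5, 8),
    arc_length_um: tuple = (0.4, 2.0),
    cell_radius_px: float = 70.0,
    ld_radius_px: tuple = (6.0, 10.0),
    n_mito_paths: int = 3,
    **spec_overrides,
) -> SceneSpec:
    """Build a valid random :class:`SceneSpec`, deterministic in ``seed``.

    Cells sit on a jittered grid with generous spacing; droplets occupy the
    cytoplasmic ring between nucleus and cell rim without touching each
    other; filament walks avoid droplet rims by a safety margin so no
    spurious colocalization arises; at most one contact arc is planted per
    droplet, with the angular span required by the requested arc length.
    """
    rng = np.random.default_rng(seed)
    ncols = math.ceil(math.sqrt(n_cells))
    nrows = math.ceil(n_cells / ncols)
    spacing = 2 * cell_radius_px + 40
    margin = cell_radius_px + 12
    shape = (
        int(margin * 2 + spacing * (nrows - 1)),
        int(margin * 2 + spacing * (ncols - 1)),
    )
    shape = (max(shape[0], 256), max(shape[1], 256))

    cells = []
    for i in range(n_cells):
        gr, gc = divmod(i, ncols)
        center = (
            margin + gr * spacing + rng.uniform(-6, 6),
            margin + gc * spacing + rng.uniform(-6, 6),
        )
        nuc_axes = (rng.uniform(13, 16), rng.uniform(10, 13))
        nuc_angle = rng.uniform(0, math.pi)

        # droplets in the cytoplasmic ring, pairwise non-touching
        lds = []
        want_ld = int(rng.integers(n_lds[0], n_lds[1] + 1))
        tries = 0
        while len(lds) < want_ld and tries < 400:
            tries += 1
            lr = rng.uniform(*ld_radius_px)
            rad = rng.uniform(max(nuc_axes) + lr + 6, cell_radius_px - lr - 4)
            ang = rng.uniform(0, 2 * math.pi)
            pos = (center[0] + rad * math.cos(ang), center[1] + rad * math.sin(ang))
            if all(
                math.hypot(pos[0] - p[0], pos[1] - p[1]) > lr + pr + 6
                for (p, pr) in lds
            ):
                lds.append((pos, lr))

        # contact arcs: one per droplet at most, span set by arc length
        contacts = []
        want_contacts = int(rng.integers(n_contacts[0], n_contacts[1] + 1))
        ld_order = rng.permutation(len(lds))
        for li in ld_order:
            if len(contacts) >= want_contacts:
                break
            _, lr = lds[li]
            length_um = rng.uniform(*arc_length_um)
            span = length_um / spec_overrides.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM) / lr
            if span > 1.6 * math.pi:
                continue
            theta0 = rng.uniform(0, 2 * math.pi)
            contacts.append(ContactArc(ld_index=int(li), theta0=theta0, theta1=theta0 + span))

        # filament walks that keep clear of droplet rims; the margin must
        # exceed the reach of both blur tails (LD disk + filament) jointly
        # clearing their thresholds, else spurious colocalization appears
        paths = []
        safety = 8.0
        for _ in range(n_mito_paths):
            pts = []
            tries = 0
            while len(pts) < 4 and tries < 600:
                tries += 1
                rad = rng.uniform(max(nuc_axes) + 4, cell_radius_px - 4)
                ang = rng.uniform(0, 2 * math.pi)
                cand = (center[0] + rad * math.cos(ang), center[1] + rad * math.sin(ang))
                if any(
                    math.hypot(cand[0] - p[0], cand[1] - p[1]) < pr + safety
                    for (p, pr) in lds
                ):
                    continue
                if pts and not _segment_clears_disks(pts[-1], cand, lds, safety):
                    continue
                pts.append(cand)
            if len(pts) >= 2:
                paths.append(pts)

        cells.append(
            CellSpec(
                center=center,
                radius_px=cell_radius_px,
                nucleus_axes=nuc_axes,
                nucleus_angle=nuc_angle,
                lds=lds,
                mito_paths=paths,
                contacts=contacts,
            )
        )

    return SceneSpec(shape=shape, cells=cells, seed=seed, **spec_overrides)
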