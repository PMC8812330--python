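"""Cell individualization from composite landscape + nucleus seeds."""

import numpy as np
import pytest
from scipy import ndimage

from ldcontacts.cell_segmentation import (
    composite_image,
    individualize_cells,
    nucleus_mask,
)
from ldcontacts.io import ChannelStack
from ldcontacts.synthetic import CellSpec, SceneSpec, generate_scene, random_scene


def _ellipse(shape, center, axes):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - center[0]) / axes[0]) ** 2 + ((xx - center[1]) / axes[1]) ** 2 <= 1


class TestNucleusMask:
    def test_recovers_synthetic_ellipses_with_noise(self, rng):
        truth = _ellipse((96, 96), (48, 48), (16, 11))
        plane = np.where(truth, 200.0, 20.0)
        plane = ndimage.gaussian_filter(plane, 1.5)
        noisy = np.clip(plane + rng.normal(0, 20, plane.shape), 0, 255).astype(np.uint8)
        mask = nucleus_mask(noisy)
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.9

    def test_blank_plane_gives_empty_mask_and_warning(self, caplog):
        with caplog.at_level("WARNING", logger="ldcontacts"):
            mask = nucleus_mask(np.zeros((32, 32), dtype=np.uint8))
        assert not mask.any()

    def test_two_ellipses_two_components(self, rng):
        truth = _ellipse((96, 96), (30, 30), (12, 9)) | _ellipse((96, 96), (66, 66), (12, 9))
        plane = np.where(truth, 220, 10).astype(np.uint8)
        mask = nucleus_mask(plane)
        _, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(2, 1))
        assert n == 2

    def test_holes_are_filled(self):
        plane = np.zeros((40, 40), dtype=np.uint8)
        plane[10:30, 10:30] = 200
        plane[18:22, 18:22] = 0  # dark interior (nucleolus-like)
        assert nucleus_mask(plane)[18:22, 18:22].all()


class TestCompositeImage:
    @staticmethod
    def _stack(ld, mito, nucleus):
        return ChannelStack(
            planes={"nucleus": nucleus, "ld": ld, "mito": mito},
            bit_depth=8,
            pixel_size_um=0.093,
        )

    def test_zero_cytoplasm_composite_is_nucleus_mask(self):
        nucleus = np.zeros((32, 32), dtype=np.uint8)
        nucleus[10:20, 10:20] = 200
        stack = self._stack(
            np.zeros((32, 32), np.uint8), np.zeros((32, 32), np.uint8), nucleus
        )
        comp = composite_image(stack)
        assert (comp[10:20, 10:20] == 255).all()
        comp[10:20, 10:20] = 0
        assert not comp.any()

    def test_matches_hand_arithmetic(self, rng):
        ld = rng.integers(0, 200, (16, 16)).astype(np.uint8)
        mito = rng.integers(0, 200, (16, 16)).astype(np.uint8)
        nucleus = np.zeros((16, 16), dtype=np.uint8)
        stack = self._stack(ld, mito, nucleus)
        comp = composite_image(stack, {"ld": 0.2, "mito": 0.2})
        expected = np.clip(ld * 0.2 + mito * 0.2, 0, 255)
        np.testing.assert_allclose(comp, expected)

    def test_larger_factors_never_decrease_composite(self, rng):
        ld = rng.integers(0, 200, (16, 16)).astype(np.uint8)
        mito = rng.integers(0, 200, (16, 16)).astype(np.uint8)
        nucleus = np.zeros((16, 16), dtype=np.uint8)
        stack = self._stack(ld, mito, nucleus)
        low = composite_image(stack, {"ld": 0.2, "mito": 0.2})
        high = composite_image(stack, {"ld": 1.0, "mito": 1.0})
        assert (high >= low).all()

    def test_factor_outside_range_rejected(self, rng):
        stack = self._stack(
            np.zeros((8, 8), np.uint8), np.zeros((8, 8), np.uint8),
            np.zeros((8, 8), np.uint8),
        )
        with pytest.raises(ValueError):
            composite_image(stack, {"ld": 0.0, "mito": 0.2})


class TestIndividualizeCells:
    def test_separated_cells_one_label_each_with_own_nucleus(self):
        stack, truth = generate_scene(random_scene(seed=301, n_cells=3))
        part = individualize_cells(stack)
        assert part.n_cells == 3
        for ci in range(1, 4):
            r, c = np.argwhere(truth.cells == ci).mean(axis=0).astype(int)
            assert part.cells[r, c] == ci or part.cells[r, c] > 0
        # each recovered cell holds exactly one ground-truth nucleus centroid
        hits = [
            part.cells[tuple(np.argwhere(truth.cells == ci).mean(axis=0).astype(int))]
            for ci in range(1, 4)
        ]
        assert sorted(hits) == [1, 2, 3]

    def test_touching_cells_split_into_two_labels(self):
        # two cells whose disks overlap; nuclei are distinct -> 2 labels
        cells = [
            CellSpec(center=(100.0, 80.0), radius_px=60.0),
            CellSpec(center=(100.0, 185.0), radius_px=60.0),
        ]
        stack, _ = generate_scene(SceneSpec(shape=(200, 266), cells=cells, seed=5))
        assert individualize_cells(stack).n_cells == 2

    def test_touching_cells_ridge_near_symmetric_midline(self):
        # checked at high SNR; the valley floor between the cells is flat at
        # 8-bit quantization, leaving the ridge several pixels of slack even
        # without noise
        cells = [
            CellSpec(center=(100.0, 80.0), radius_px=60.0),
            CellSpec(center=(100.0, 185.0), radius_px=60.0),
        ]
        spec = SceneSpec(
            shape=(200, 266), cells=cells, seed=5,
            photon_scale=50.0, gaussian_sd=0.5,
        )
        stack, _ = generate_scene(spec)
        part = individualize_cells(stack)
        assert part.n_cells == 2
        # look only where the two labels actually abut
        near1 = ndimage.binary_dilation(part.cells == 1, iterations=2)
        near2 = ndimage.binary_dilation(part.cells == 2, iterations=2)
        ridge = near1 & near2
        assert ridge.any()
        cols = np.nonzero(ridge)[1]
        assert abs(np.median(cols) - 132.5) <= 10

    def test_blank_image_empty_partition_with_warning(self, caplog):
        blank = ChannelStack(
            planes={k: np.zeros((64, 64), np.uint8) for k in ("nucleus", "ld", "mito")},
            bit_depth=8,
            pixel_size_um=0.093,
        )
        with caplog.at_level("WARNING", logger="ldcontacts"):
            part = individualize_cells(blank)
        assert part.n_cells == 0

    def test_labels_respect_limits_and_nucleus_requirement(self, scene):
        stack, truth = scene
        part = individualize_cells(stack)
        for lab in range(1, part.n_cells + 1):
            assert (part.nucleus_mask & (part.cells == lab)).any()
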