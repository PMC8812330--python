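"""Colocalization rule, droplet splitting and skeletonized contact extraction."""

import math

import numpy as np
import pytest
from scipy import ndimage

from ldcontacts.contacts import (
    ColocalizationParams,
    colocalization_mask,
    extract_contacts,
    ld_particles,
    skeleton_length_px,
)
from ldcontacts.thresholds import histogram256, otsu_threshold, yen_threshold

S = 0.093  # um per pixel


def coloc_bruteforce(ld8, mito8, ratio_percent):
    """Triple-condition pixel loop with its own threshold computation."""
    t_ld = yen_threshold(histogram256(ld8))
    t_mito = otsu_threshold(histogram256(mito8))
    out = np.zeros(ld8.shape, dtype=bool)
    for r in range(ld8.shape[0]):
        for c in range(ld8.shape[1]):
            a, b = int(ld8[r, c]), int(mito8[r, c])
            if a <= t_ld or b <= t_mito:
                continue
            hi, lo = max(a, b), min(a, b)
            if hi > 0 and 100.0 * lo / hi > ratio_percent:
                out[r, c] = True
    return out


class TestColocalizationMask:
    def test_matches_bruteforce_pixel_loop(self, rng):
        for _ in range(3):
            ld8 = rng.integers(0, 256, (64, 64)).astype(np.uint8)
            mito8 = rng.integers(0, 256, (64, 64)).astype(np.uint8)
            got = colocalization_mask(ld8, mito8)
            np.testing.assert_array_equal(got, coloc_bruteforce(ld8, mito8, 50.0))

    def test_ratio_rule_excludes_unbalanced_intensities(self):
        # two-block planes pin the auto-thresholds between the blocks, then a
        # probe pixel pair (200, 90) has ratio 45 <= 50 -> excluded, while
        # (200, 150) has ratio 75 > 50 -> colocalized
        ld8 = np.zeros((20, 20), dtype=np.uint8)
        mito8 = np.zeros((20, 20), dtype=np.uint8)
        ld8[:10] = 200
        mito8[:10] = 150
        t_ld = yen_threshold(histogram256(ld8))
        t_mito = otsu_threshold(histogram256(mito8))
        assert t_ld < 200 and t_mito < 90
        mito8[0, 0] = 90
        mask = colocalization_mask(ld8, mito8)
        assert not mask[0, 0]        # 100*90/200 = 45, fails the ratio
        assert mask[1:10].all()      # 100*150/200 = 75, passes

    def test_raising_ratio_shrinks_mask(self, rng):
        ld8 = rng.integers(0, 256, (48, 48)).astype(np.uint8)
        mito8 = rng.integers(0, 256, (48, 48)).astype(np.uint8)
        prev = None
        for ratio in (0.0, 30.0, 60.0, 90.0):
            mask = colocalization_mask(
                ld8, mito8, ColocalizationParams(ratio_percent=ratio)
            )
            if prev is not None:
                assert not (mask & ~prev).any()
            prev = mask

    def test_degenerate_channel_yields_empty_mask(self, caplog):
        flat = np.zeros((16, 16), dtype=np.uint8)
        other = np.tile(np.arange(16, dtype=np.uint8) * 16, (16, 1))
        with caplog.at_level("WARNING", logger="ldcontacts"):
            mask = colocalization_mask(flat, other)
        assert not mask.any()


class TestLdParticles:
    @staticmethod
    def _disk(shape, center, r):
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r * r

    def test_single_disk_single_label(self):
        mask = self._disk((40, 40), (20, 20), 10)
        res = ld_particles(mask)
        assert res.particles.max() == 1
        assert (res.particles[mask] > 0).sum() >= mask.sum() - res.limits.sum()

    def test_overlapping_disks_split_near_bisector(self):
        r = 10
        c1, c2 = (24, 17), (24, 32)  # centers 1.5 r apart
        mask = self._disk((48, 48), c1, r) | self._disk((48, 48), c2, r)
        res = ld_particles(mask)
        assert res.particles.max() == 2
        cut = res.limits & mask
        assert cut.any()
        rows, cols = np.nonzero(cut)
        assert np.all(np.abs(cols - 24.5) <= 2)  # perpendicular bisector col

    def test_empty_mask_empty_result(self):
        res = ld_particles(np.zeros((16, 16), dtype=bool))
        assert res.particles.max() == 0 and res.peaks == []


class TestSkeletonLength:
    @pytest.mark.parametrize(
        "pixels,expected",
        [
            ([(0, 0)], 1.0),                                  # isolated pixel
            ([(0, c) for c in range(10)], 9.0),               # straight line
            ([(i, i) for i in range(5)], 4 * math.sqrt(2)),   # diagonal
            ([(0, 0), (0, 1), (1, 1)], 2.0),                  # corner, no shortcut
        ],
    )
    def test_traced_step_lengths(self, pixels, expected):
        comp = np.zeros((12, 12), dtype=bool)
        for r, c in pixels:
            comp[r, c] = True
        assert skeleton_length_px(comp) == pytest.approx(expected)


def _maxima_result_for(mask):
    return ld_particles(mask)


class TestExtractContacts:
    def test_empty_colocalization_no_contacts(self):
        empty = np.zeros((20, 20), dtype=bool)
        ld_res = _maxima_result_for(np.zeros((20, 20), dtype=bool))
        assert extract_contacts(empty, ld_res, np.zeros((20, 20), int), S) == []

    def test_horizontal_band_length(self):
        # 10x2 band: skeleton is the 10-pixel midline, 9 orthogonal steps
        coloc = np.zeros((20, 30), dtype=bool)
        coloc[10:12, 5:15] = True
        ld_mask = np.zeros((20, 30), dtype=bool)
        ld_mask[8:16, 3:17] = True
        cells = np.ones((20, 30), dtype=np.int32)
        sites = extract_contacts(coloc, _maxima_result_for(ld_mask), cells, S)
        assert len(sites) == 1
        assert sites[0].length_um == pytest.approx(9 * S, abs=2 * S)
        assert sites[0].cell_label == 1

    def test_blob_straddling_droplet_limit_splits(self):
        yy, xx = np.ogrid[:48, :48]
        r = 10
        ld_mask = ((yy - 24) ** 2 + (xx - 17) ** 2 <= r * r) | (
            (yy - 24) ** 2 + (xx - 32) ** 2 <= r * r
        )
        ld_res = _maxima_result_for(ld_mask)
        coloc = np.zeros((48, 48), dtype=bool)
        coloc[22:27, 20:30] = True  # spans the bisector between the droplets
        cells = np.ones((48, 48), dtype=np.int32)
        sites = extract_contacts(coloc, ld_res, cells, S)
        assert len(sites) == 2
        assert {s.ld_label for s in sites} == {1, 2}

    def test_skeleton_pixels_stay_inside_mask(self, rng):
        coloc = ndimage.binary_dilation(rng.random((40, 40)) > 0.92, iterations=2)
        ld_res = _maxima_result_for(np.ones((40, 40), dtype=bool))
        for site in extract_contacts(coloc, ld_res, np.ones((40, 40), int), S):
            assert coloc[site.pixels[:, 0], site.pixels[:, 1]].all()

    def test_total_length_invariant_under_flip_and_rotation(self):
        coloc = np.zeros((30, 30), dtype=bool)
        coloc[5:7, 4:16] = True
        coloc[20:26, 22:24] = True
        ld_res = _maxima_result_for(np.ones((30, 30), dtype=bool))
        cells = np.ones((30, 30), dtype=np.int32)

        def total(mask):
            return sum(
                s.length_um
                for s in extract_contacts(mask, _maxima_result_for(np.ones_like(mask)), cells, S)
            )

        base = total(coloc)
        assert total(np.rot90(coloc).copy()) == pytest.approx(base)
        assert total(coloc[::-1].copy()) == pytest.approx(base)

    def test_contact_count_equals_skeleton_components(self, scene):
        from ldcontacts.pipeline import analyze_stack
        from skimage.morphology import skeletonize

        stack, _ = scene
        res = analyze_stack(stack)
        regions = res.coloc_mask & ~ld_particles(res.ld_mask).limits
        skel = skeletonize(regions)
        _, n = ndimage.label(skel, structure=np.ones((3, 3)))
        assert len(res.contact_sites) == n
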