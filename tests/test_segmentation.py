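"""Soma segmentation: grey-scale filters against brute-force oracles,
particle metrology on analytic shapes, gates and tissue boundary."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.draw import disk, ellipse

from gliaspat.segmentation import (
    RasterImage,
    SegmentationParams,
    attribute_open,
    extract_particles,
    max_entropy_threshold,
    morphological_open,
    nnd_gate,
    retina_area_and_boundary,
    segment_image,
)


def brute_force_area_opening(img: np.ndarray, area_min: int) -> np.ndarray:
    """Threshold-decomposition oracle: out(p) = max{t : p lies in a
    connected component of {img ≥ t} with ≥ area_min pixels} (8-conn)."""
    out = np.zeros_like(img, dtype=np.int32)
    structure = np.ones((3, 3), dtype=int)
    for t in np.unique(img):
        if t == 0:
            continue
        lab, _ = ndimage.label(img >= t, structure=structure)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        out[sizes[lab] >= area_min] = t
    return out.astype(img.dtype)


def brute_force_max_entropy(img: np.ndarray) -> int:
    """Exhaustive Kapur objective over all candidate thresholds."""
    hist = np.bincount(img.ravel(), minlength=256).astype(float)
    p = hist / hist.sum()
    best_t, best = -1, -np.inf
    for t in range(256):
        lo, hi = p[: t + 1], p[t + 1 :]
        w0, w1 = lo.sum(), hi.sum()
        if w0 <= 0 or w1 <= 0:
            continue
        h0 = -sum(q / w0 * np.log(q / w0) for q in lo if q > 0)
        h1 = -sum(q / w1 * np.log(q / w1) for q in hi if q > 0)
        if h0 + h1 > best + 1e-12:
            best, best_t = h0 + h1, t
    return best_t


class TestAttributeOpen:
    def test_small_blob_removed_large_kept(self):
        img = np.zeros((40, 80), np.uint8)
        img[5:7, 5:10] = 200  # 10 px blob
        img[20:26, 40:45] = 200  # 30 px blob
        out = attribute_open(RasterImage(img, 1.0), area_min=25).intensities
        assert out[5:7, 5:10].max() == 0
        assert np.all(out[20:26, 40:45] == 200)

    def test_blank_image_identity(self):
        img = np.zeros((16, 16), np.uint8)
        out = attribute_open(RasterImage(img, 1.0)).intensities
        np.testing.assert_array_equal(out, img)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_component_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (24, 24)).astype(np.uint8)
        out = attribute_open(RasterImage(img, 1.0), area_min=12,
                             connectivity=8).intensities
        np.testing.assert_array_equal(out, brute_force_area_opening(img, 12))

    def test_anti_extensive_and_idempotent(self, rng):
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        once = attribute_open(RasterImage(img, 1.0))
        assert np.all(once.intensities <= img)
        twice = attribute_open(once)
        np.testing.assert_array_equal(twice.intensities, once.intensities)


class TestMorphologicalOpen:
    def test_thin_line_removed(self):
        img = np.zeros((32, 32), np.uint8)
        img[16, 4:28] = 220  # 1-px-wide line
        out = morphological_open(RasterImage(img, 1.0)).intensities
        assert out.max() == 0

    def test_disc_preserved(self):
        img = np.zeros((32, 32), np.uint8)
        rr, cc = disk((16, 16), 5)
        img[rr, cc] = 200
        out = morphological_open(RasterImage(img, 1.0)).intensities
        kept = (out == 200).sum()
        assert kept >= 0.85 * len(rr)  # boundary discretization only

    def test_idempotent_and_anti_extensive(self, rng):
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        once = morphological_open(RasterImage(img, 1.0))
        assert np.all(once.intensities <= img)
        twice = morphological_open(once)
        np.testing.assert_array_equal(twice.intensities, once.intensities)


class TestMaxEntropyThreshold:
    def test_separates_bimodal_levels(self):
        img = np.r_[np.full(600, 20), np.full(400, 200)].astype(np.uint8)
        t = max_entropy_threshold(img.reshape(20, 50))
        assert 20 <= t < 200

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            max_entropy_threshold(np.full((10, 10), 7, np.uint8))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(100 + seed)
        img = np.clip(
            np.r_[rng.normal(60, 15, 2000), rng.normal(180, 25, 1000)],
            0, 255).astype(np.uint8).reshape(50, 60)
        assert max_entropy_threshold(img) == brute_force_max_entropy(img)


class TestExtractParticles:
    def test_disc_area_and_roundness(self):
        mask = np.zeros((64, 64), bool)
        rr, cc = disk((32, 32), 10)
        mask[rr, cc] = True
        (p,) = extract_particles(mask, 1.0)
        assert abs(p.area_um2 - np.pi * 100) / (np.pi * 100) < 0.03
        assert abs(p.roundness - 1.0) < 0.05
        assert abs(p.x_um - 32) < 0.5 and abs(p.y_um - 32) < 0.5

    def test_two_to_one_ellipse_roundness_half(self):
        mask = np.zeros((128, 128), bool)
        rr, cc = ellipse(64, 64, 10, 20)
        mask[rr, cc] = True
        (p,) = extract_particles(mask, 1.0)
        assert abs(p.roundness - 0.5) < 0.05

    def test_pixel_size_scales_area(self):
        mask = np.zeros((64, 64), bool)
        rr, cc = disk((32, 32), 10)
        mask[rr, cc] = True
        p1 = extract_particles(mask, 1.0)[0]
        p2 = extract_particles(mask, 1.24)[0]
        assert p2.area_um2 == pytest.approx(p1.area_um2 * 1.24**2)
        assert p2.roundness == pytest.approx(p1.roundness)

    def test_nine_pixel_component_excluded_at_threshold_ten(self):
        mask = np.zeros((16, 16), bool)
        mask[2:5, 2:5] = True  # 9 px
        assert extract_particles(mask, 1.0, particle_area_min=10) == []
        assert len(extract_particles(mask, 1.0, particle_area_min=9)) == 1

    def test_empty_mask_empty_list(self):
        assert extract_particles(np.zeros((8, 8), bool), 1.0) == []


class TestNndGate:
    def _particles(self, xs):
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        (proto,) = extract_particles(mask, 1.0, 4)
        out = []
        for x in xs:
            from dataclasses import replace

            out.append(replace(proto, x_um=float(x), y_um=0.0))
        return out

    def test_printed_rule_keeps_close_pair(self):
        parts = self._particles([0, 10, 100])
        kept = nnd_gate(parts, gate_um=14 * 1.24, keep_below=True)
        assert [p.x_um for p in kept] == [0, 10]

    def test_all_far_apart_keep_below_empty(self):
        parts = self._particles([0, 100, 200])
        assert nnd_gate(parts, gate_um=17.36, keep_below=True) == []

    def test_direction_flag_inverts(self):
        parts = self._particles([0, 10, 100])
        kept = nnd_gate(parts, gate_um=17.36, keep_below=False)
        assert [p.x_um for p in kept] == [100]

    def test_single_particle_unfiltered_with_warning(self):
        parts = self._particles([0])
        with pytest.warns(UserWarning, match="NND undefined"):
            kept = nnd_gate(parts, gate_um=17.36)
        assert kept == parts


class TestRetinaAreaAndBoundary:
    def test_full_tissue_unit_conversion(self):
        img = np.full((1000, 1000), 100, np.uint8)
        area, poly = retina_area_and_boundary(RasterImage(img, 1.0))
        assert area == pytest.approx(1.0)

    def test_blank_image_rejected(self):
        with pytest.raises(ValueError, match="empty tissue"):
            retina_area_and_boundary(
                RasterImage(np.zeros((64, 64), np.uint8), 1.0))

    def test_disc_tissue_area_and_circumference(self):
        img = np.zeros((1100, 1100), np.uint8)
        rr, cc = disk((550, 550), 500)
        img[rr, cc] = 128
        area, poly = retina_area_and_boundary(RasterImage(img, 1.0))
        assert abs(area - 0.785) / 0.785 < 0.02
        assert abs(poly.exterior.length - 2 * np.pi * 500) < 0.05 * 2 * np.pi * 500


class TestPipelineOrder:
    def test_end_to_end_recovery_on_rendered_fixture(self):
        """Full segmentation pipeline on a rendered pattern with process
        fragments recovers essentially all ground-truth somata."""
        from .fixtures import rendered_fixture

        img, truth, pat = rendered_fixture(n=40, seed=2, noise_sd=5,
                                           n_fragments=30)
        params = SegmentationParams(particle_area_min=30,
                                    nnd_keep_below=False)
        parts = segment_image(RasterImage(img, 1.24), params)
        from scipy.spatial import cKDTree

        xy = np.array([[p.x_um, p.y_um] for p in parts])
        d, _ = cKDTree(xy).query(np.column_stack([truth["x_um"],
                                                  truth["y_um"]]))
        recovered = np.sum(d < 2 * 1.24)
        assert recovered >= 0.95 * pat.n
        assert len(parts) <= 1.05 * pat.n  # few spurious detections
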