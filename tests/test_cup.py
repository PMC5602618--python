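"""Cup cascade: brightest-spot selection, gap healing, Hough fitting and the
four-loop error-detection contract."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

import fundus_cdr.cup as cup_mod
from fundus_cdr.core import LabelImage, ValidationError
from fundus_cdr.cup import (
    CUP_LOOPS,
    CupConfig,
    brightest_region,
    filled_circle,
    hough_circle_fit,
    refine_cup,
    segment_cup,
    touches_disc_boundary,
)


def _disk_mask(shape, center, radius):
    m = np.zeros(shape, bool)
    rr, cc = draw_disk(center, radius, shape=shape)
    m[rr, cc] = True
    return m


def _labels_with_spots(spots, shape=(128, 128), k=3):
    grid = np.zeros(shape, np.int16)
    for center, radius_or_px in spots:
        if isinstance(radius_or_px, tuple):  # explicit rectangle (h, w)
            h, w = radius_or_px
            grid[center[0] : center[0] + h, center[1] : center[1] + w] = k
        else:
            rr, cc = draw_disk(center, radius_or_px, shape=shape)
            grid[rr, cc] = k
    return LabelImage(grid, k)


class TestBrightestRegion:
    def test_small_spot_eliminated(self):
        # 49-px and 300-px bright components: only the larger survives
        labels = _labels_with_spots([((20, 20), (7, 7)), ((80, 80), 10)])
        mask = brightest_region(labels, min_spot=50)
        assert mask[80, 80] and not mask[20, 20]

    def test_exactly_min_spot_survives(self):
        labels = _labels_with_spots([((20, 20), (5, 10))])  # exactly 50 px
        mask = brightest_region(labels, min_spot=50)
        assert mask.sum() == 50

    def test_empty_top_class_gives_empty_mask(self):
        labels = LabelImage(np.zeros((64, 64), np.int16), k=3)
        assert not brightest_region(labels).any()

    def test_tie_broken_toward_center(self):
        labels = _labels_with_spots([((10, 10), (8, 8)), ((60, 60), (8, 8))], shape=(128, 128))
        mask = brightest_region(labels, min_spot=10)
        assert mask[62, 62] and not mask[12, 12]


class TestRefineCup:
    def test_vessel_gap_bridged_into_one_component(self):
        from skimage.measure import label

        mask = np.zeros((96, 96), bool)
        mask[30:60, 20:45] = True
        mask[30:60, 48:70] = True  # 3-px vertical gap
        vessels = np.zeros((96, 96), bool)
        vessels[:, 45:48] = True
        out = refine_cup(mask, vessels, closing_radius=0, bridge_radius=4)
        assert label(out, connectivity=2).max() == 1
        assert out[40, 46]

    def test_no_vessels_zero_closing_returns_largest_component(self):
        mask = np.zeros((64, 64), bool)
        mask[5:10, 5:10] = True
        mask[30:50, 30:50] = True
        out = refine_cup(mask, np.zeros((64, 64), bool), closing_radius=0, bridge_radius=0)
        assert out.sum() == 400 and out[40, 40]

    def test_extensive_on_single_component(self):
        mask = _disk_mask((96, 96), (48, 48), 20)
        rng = np.random.default_rng(0)
        vessels = rng.random((96, 96)) < 0.05
        out = refine_cup(mask, vessels)
        assert out.sum() >= mask.sum()
        assert (out & mask).sum() == mask.sum()

    def test_empty_input_empty_output(self):
        assert not refine_cup(np.zeros((32, 32), bool), np.ones((32, 32), bool)).any()


class TestHoughFit:
    def test_filled_disk_recovered_within_one_pixel(self):
        mask = _disk_mask((128, 128), (64, 64), 40)
        row, col, r = hough_circle_fit(mask, 10, 60)
        assert abs(r - 40) <= 1 and abs(row - 64) <= 1 and abs(col - 64) <= 1

    def _brute_force(self, mask, radii):
        # independent exhaustive accumulator on the full grid
        from skimage.morphology import disk, erosion

        boundary = mask & ~erosion(mask, disk(1))
        pts = np.argwhere(boundary)
        best = (-1, None)
        for r0 in range(mask.shape[0]):
            for c0 in range(mask.shape[1]):
                d = np.hypot(pts[:, 0] - r0, pts[:, 1] - c0)
                for rad in radii:
                    votes = int((np.abs(d - rad) <= 0.5).sum())
                    if votes > best[0]:
                        best = (votes, (r0, c0, rad))
        return best[1]

    def test_half_moon_center_matches_exhaustive_accumulator(self):
        mask = _disk_mask((64, 64), (32, 32), 20)
        mask[:, :32] = False
        row, col, r = hough_circle_fit(mask, 15, 25)
        oracle = self._brute_force(mask, range(15, 26))
        assert np.hypot(row - oracle[0], col - oracle[1]) <= 3
        assert abs(row - 32) <= 3 and abs(col - 32) <= 3

    def test_jittered_boundary_radius_within_two_pixels(self):
        rng = np.random.default_rng(1)
        mask = np.zeros((64, 64), bool)
        theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        rr = (32 + (20 + rng.integers(-1, 2, theta.size)) * np.sin(theta)).astype(int)
        cc = (32 + (20 + rng.integers(-1, 2, theta.size)) * np.cos(theta)).astype(int)
        mask[rr, cc] = True
        from scipy.ndimage import binary_fill_holes

        mask = binary_fill_holes(mask)
        _, _, r = hough_circle_fit(mask, 15, 25)
        assert abs(r - 20) <= 2

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            hough_circle_fit(np.zeros((32, 32), bool), 5, 10)


class TestCascadeContract:
    """Loop order and error conditions with scripted candidates."""

    disc = _disk_mask((128, 128), (64, 64), 55)

    def _script(self, monkeypatch, outcomes):
        seen = []

        def fake_run_loop(loop, k, enhance, roi_gray, vessels, disc, cfg):
            seen.append((loop, k, enhance))
            out = outcomes[loop - 1]
            if out is None:
                return None, None, None
            cand = _disk_mask((128, 128), (64, 64), out["radius"])
            circle = (64.0, 64.0, float(out["radius"]))
            return filled_circle(circle, (128, 128)), circle, cand

        monkeypatch.setattr(cup_mod, "_run_loop", fake_run_loop)
        return seen

    def test_loop_configuration_is_fixed(self):
        assert CUP_LOOPS == ((1, 3, True), (2, 2, True), (3, 4, False), (4, 3, False))

    def test_small_area_triggers_exactly_next_loop(self, monkeypatch):
        # loop 1 yields 2500 px (radius 28) <= 3000 floor in unscaled mode
        outcomes = [{"radius": 28}, {"radius": 35}, None, None]
        seen = self._script(monkeypatch, outcomes)
        cfg = CupConfig(scale_area_floor=False)
        res = segment_cup(np.zeros((128, 128), np.uint8), self.disc, np.zeros((128, 128), bool), cfg)
        assert res.success and res.loop_used == 2
        assert [s[0] for s in seen] == [1, 2]

    def test_disc_contact_triggers_next_loop(self, monkeypatch):
        outcomes = [{"radius": 55}, {"radius": 56}, {"radius": 35}, None]
        seen = self._script(monkeypatch, outcomes)
        cfg = CupConfig(scale_area_floor=False)
        res = segment_cup(np.zeros((128, 128), np.uint8), self.disc, np.zeros((128, 128), bool), cfg)
        assert res.success and res.loop_used == 3
        assert [s[0] for s in seen] == [1, 2, 3]

    def test_accept_first_loop_when_clean(self, monkeypatch):
        seen = self._script(monkeypatch, [{"radius": 32}, None, None, None])
        cfg = CupConfig(scale_area_floor=False)  # area ~3200 > 3000, no contact
        res = segment_cup(np.zeros((128, 128), np.uint8), self.disc, np.zeros((128, 128), bool), cfg)
        assert res.success and res.loop_used == 1 and seen == [(1, 3, True)]

    def test_exhaustion_is_failure_without_revisit(self, monkeypatch):
        seen = self._script(monkeypatch, [{"radius": 55}] * 4)
        res = segment_cup(np.zeros((128, 128), np.uint8), self.disc, np.zeros((128, 128), bool),
                          CupConfig(scale_area_floor=False))
        assert not res.success and res.loop_used is None
        assert [s[0] for s in seen] == [1, 2, 3, 4]
        assert [s[1] for s in seen] == [3, 2, 4, 3]
        assert [s[2] for s in seen] == [True, True, False, False]


class TestSegmentCupEndToEnd:
    def test_phantom_cup_accepted_and_clear_of_disc(self, noisy_phantom):
        from fundus_cdr.disc import segment_disc
        from fundus_cdr.vessels import extract_vessels, inpaint

        image, disc, cup, vessels, truth = noisy_phantom
        vm = extract_vessels(image)
        inpainted = inpaint(image, vm)
        res = segment_disc(image, vessels=vm, inpainted=inpainted, seed=0)
        roi = res.roi
        out = segment_cup(roi.extract(inpainted.green), roi.extract(res.mask), roi.extract(vm),
                          CupConfig(seed=0), image_width=image.width)
        assert out.success
        assert not touches_disc_boundary(out.mask, roi.extract(res.mask))

    def test_suite_success_and_error_criteria(self, suite_results):
        ok = suite_results["status"] == "ok"
        assert ok.mean() >= 0.9
        assert suite_results.loc[ok, "hcdr_err"].abs().median() <= 0.10
        assert suite_results.loc[ok, "vcdr_err"].abs().median() <= 0.10
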