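"""Process area, motility classification, bounds detection, Sholl profiles."""

import numpy as np
import pytest

from caltrack.motility import (Exclusion, MotilityEvent, ProcessAreaSeries,
                               classify_motility, detect_motility_bounds,
                               process_area_series, sholl_profile,
                               total_process_area, two_color_overlay)
from caltrack.rois import Roi
from caltrack.simulate import MotilitySpec, SimulationConfig, simulate
from caltrack.stack import ImageStack, average_intensity_projection

PX = 1.0  # 1 um/px in the constructed-geometry tests below


def area_projection(area_um2, shape=(64, 64), offset=(10, 10), value=100.0):
    """A bright patch of the requested area (1 um/px) on a dark field."""

    proj = np.zeros(shape)
    n = int(area_um2)
    cols = 8
    r0, c0 = offset
    full, rem = divmod(n, cols)
    proj[r0 : r0 + full, c0 : c0 + cols] = value
    if rem:
        proj[r0 + full, c0 : c0 + rem] = value
    return proj


def big_roi(shape=(64, 64)):
    return Roi("p", "process", np.ones(shape, bool), pixel_size_um=PX)


class TestClassification:
    @pytest.mark.parametrize(
        "first,last,expected",
        [(10, 15, "extension"), (10, 5, "retraction"), (10, 12, "stable"),
         (10, 15.0, "extension")],
    )
    def test_worked_boundaries(self, first, last, expected):
        """10->15 um^2 is an extension, 10->5 a retraction, 10->12 stable."""

        got = classify_motility(big_roi(), area_projection(first),
                                area_projection(last), threshold=50.0,
                                pixel_size_um=PX)
        assert isinstance(got, MotilityEvent)
        assert got.klass == expected
        assert got.area_first_um2 == first

    def test_exact_50_percent_counts_as_motile(self):
        got = classify_motility(big_roi(), area_projection(10),
                                area_projection(15), 50.0, PX)
        assert got.klass == "extension"
        assert got.fractional_change == pytest.approx(0.5)

    def test_small_process_excluded(self):
        """First area of 8 um^2 fails the >9 um^2 inclusion rule."""

        got = classify_motility(big_roi(), area_projection(8),
                                area_projection(16), 50.0, PX)
        assert isinstance(got, Exclusion)
        assert "minimum size" in got.reason

    def test_boundary_9_um2_excluded(self):
        got = classify_motility(big_roi(), area_projection(9),
                                area_projection(18), 50.0, PX)
        assert isinstance(got, Exclusion)

    def test_zero_first_area_excluded(self):
        got = classify_motility(big_roi(), np.zeros((64, 64)),
                                area_projection(20), 50.0, PX)
        assert isinstance(got, Exclusion)
        assert "zero" in got.reason

    def test_trichotomy(self, rng):
        """Every included ROI receives exactly one of the three classes."""

        for _ in range(20):
            first = float(rng.uniform(10, 40))
            last = float(rng.uniform(1, 80))
            got = classify_motility(big_roi(), area_projection(first),
                                    area_projection(last), 50.0, PX)
            assert got.klass in ("extension", "retraction", "stable")

    def test_antisymmetry_under_projection_swap(self):
        """Swapping first/last projections turns a +100% extension into a
        -50% retraction (the matched boundary pair)."""

        fwd = classify_motility(big_roi(), area_projection(10),
                                area_projection(20), 50.0, PX)
        rev = classify_motility(big_roi(), area_projection(20),
                                area_projection(10), 50.0, PX)
        assert fwd.klass == "extension" and rev.klass == "retraction"


class TestOverlay:
    def test_static_stack_channels_identical(self):
        data = np.tile(area_projection(30)[None], (220, 1, 1))
        ov = two_color_overlay(ImageStack(data, 1.0, PX))
        assert np.array_equal(ov.first, ov.last)
        assert np.array_equal(ov.rgb[..., 0], ov.rgb[..., 1])

    def test_new_structure_is_green_only(self):
        data = np.zeros((220, 32, 32))
        data[120:, 5:10, 5:10] = 100.0       # appears in the last 100 frames
        ov = two_color_overlay(ImageStack(data, 1.0, PX))
        assert ov.first[7, 7] == 0.0 and ov.last[7, 7] == 100.0
        assert ov.rgb[7, 7, 0] == 0.0 and ov.rgb[7, 7, 1] > 0

    def test_channels_match_projection_oracle(self, rng):
        data = rng.random((250, 16, 16))
        s = ImageStack(data, 1.0, PX)
        ov = two_color_overlay(s)
        assert np.allclose(ov.first, average_intensity_projection(s, np.arange(100)))
        assert np.allclose(ov.last, average_intensity_projection(s, np.arange(150, 250)))

    def test_short_stack_rejected(self):
        with pytest.raises(ValueError):
            two_color_overlay(ImageStack(np.zeros((150, 8, 8)), 1.0, PX))


class TestTotalProcessArea:
    def test_background_only_is_zero(self):
        data = np.zeros((40, 32, 32))
        with pytest.warns(UserWarning, match="baseline"):
            areas, _ = total_process_area(
                ImageStack(data, 1.0, PX), [], [(0, 20), (20, 40)],
                threshold_method="fixed", fixed_threshold=10.0,
            )
        assert areas == [0.0, 0.0]

    def test_binary_morphology_area_scaling(self):
        """1,000 process px at 300/512 um/px give 1000 x (300/512)^2 um^2."""

        px = 300.0 / 512.0
        data = np.zeros((10, 64, 64))
        data[:, 10:30, 10:60] = 100.0        # 1000 px
        areas, _ = total_process_area(
            ImageStack(data, 1.0, px), [], [(0, 10)],
            threshold_method="fixed", fixed_threshold=50.0,
        )
        assert areas[0] == pytest.approx(1000 * px**2)
        assert areas[0] == pytest.approx(343.3, abs=0.5)

    def test_area_monotone_under_mask_growth(self):
        base = np.zeros((10, 64, 64))
        base[:, 20:30, 20:30] = 100.0
        grown = base.copy()
        grown[:, 18:32, 18:32] = 100.0
        kw = dict(threshold_method="fixed", fixed_threshold=50.0)
        a1, _ = total_process_area(ImageStack(base, 1.0, PX), [], [(0, 10)], **kw)
        a2, _ = total_process_area(ImageStack(grown, 1.0, PX), [], [(0, 10)], **kw)
        assert a2[0] >= a1[0]

    def test_uniform_threshold_from_baseline_period(self):
        """The threshold computed in the baseline period is reused in later
        periods even if their intensity distribution differs."""

        data = np.zeros((20, 32, 32))
        data[:10, 5:15, 5:15] = 100.0
        data[10:, 5:15, 5:15] = 100.0
        data[10:, 20:30, 20:30] = 60.0       # second structure, dimmer
        areas, thr = total_process_area(
            ImageStack(data, 1.0, PX), [], [(0, 10), (10, 20)],
        )
        assert areas[1] > areas[0]           # both structures beat the Otsu cut
        assert 0 < thr < 60

    def test_empty_baseline_warns(self):
        data = np.zeros((10, 16, 16))
        with pytest.warns(UserWarning, match="baseline"):
            areas, _ = total_process_area(
                ImageStack(data, 1.0, PX), [], [(0, 10)],
                threshold_method="fixed", fixed_threshold=10.0,
            )
        assert areas == [0.0]


class TestBounds:
    def series(self, values, window_s=15.0):
        v = np.asarray(values, float)
        return ProcessAreaSeries("p", window_s,
                                 np.arange(len(v)) * int(window_s), v)

    def test_constant_series_none(self):
        assert detect_motility_bounds(self.series([10, 10, 10])) is None

    def test_worked_example(self):
        """10,10,12,14,16,16,16 with tolerance 1: start window 2, end window 5."""

        b = detect_motility_bounds(self.series([10, 10, 12, 14, 16, 16, 16]),
                                   tolerance=1.0)
        assert b.start_frame == 2 * 15 and b.end_frame == 5 * 15
        assert b.direction == "extension"

    def test_retraction_mirrored(self):
        b = detect_motility_bounds(self.series([16, 16, 14, 12, 10, 10, 10]),
                                   tolerance=1.0)
        assert b.direction == "retraction"
        assert b.start_frame == 2 * 15 and b.end_frame == 5 * 15

    def test_noise_below_tolerance_ignored(self):
        b = detect_motility_bounds(self.series([10, 10.4, 9.8, 10.2, 10.1, 9.9]),
                                   tolerance=1.0)
        assert b is None

    def test_simulated_ramp_recovered_within_one_window(self):
        cfg = SimulationConfig(
            image_shape=(160, 160), n_frames=300, n_cells=1, seed=5,
            event_rate_soma_hz=0.0, event_rate_process_hz=0.0,
            motility_spec=[MotilitySpec("cell0_proc0", 100, 60, 0.6)],
        )
        stack, gt, morph = simulate(cfg)
        from skimage.morphology import dilation, disk

        soma = np.zeros(stack.data.shape[1:], bool)
        for m in gt.soma_masks.values():
            soma |= m
        roi = Roi("cell0_proc0", "process",
                  dilation(morph.process_masks["cell0_proc0"], disk(6)),
                  pixel_size_um=cfg.pixel_size_um)
        thr = cfg.background_intensity + 0.5 * cfg.baseline_intensity * cfg.process_intensity_frac
        series = process_area_series(stack, roi, thr, window_s=15.0,
                                     soma_mask=dilation(soma, disk(2)))
        b = detect_motility_bounds(series)
        assert b is not None and b.direction == "extension"
        assert abs(b.start_frame - 100) <= 15
        assert abs(b.end_frame - 160) <= 15


class TestSholl:
    @staticmethod
    def star_mask(shape=(201, 201), n_rays=4, ray_len_px=80, soma_r_px=10):
        """Analytic star cell: a disk with straight rays along the axes."""

        c = shape[0] // 2
        mask = np.zeros(shape, bool)
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        mask[(yy - c) ** 2 + (xx - c) ** 2 <= soma_r_px**2] = True
        for k in range(n_rays):
            ang = 2 * np.pi * k / n_rays
            for t in range(ray_len_px):
                y = int(round(c + t * np.sin(ang)))
                x = int(round(c + t * np.cos(ang)))
                mask[max(y - 1, 0) : y + 2, max(x - 1, 0) : x + 2] = True
        return mask, (float(c), float(c))

    def test_star_has_four_intersections(self):
        """A 4-ray star crosses every circle between soma edge and ray tip
        exactly 4 times."""

        mask, center = self.star_mask()
        prof = sholl_profile(mask, center, r_max_um=70, step_um=5,
                             pixel_size_um=1.0, cell_id="star")
        sel = (prof.radii_um > 12) & (prof.radii_um < 78)
        assert np.all(prof.intersections[sel & (prof.radii_um < 78)] == 4)

    def test_beyond_rays_zero(self):
        mask, center = self.star_mask(ray_len_px=40)
        prof = sholl_profile(mask, center, r_max_um=95, step_um=5, pixel_size_um=1.0)
        assert prof.intersections[prof.radii_um > 60].sum() == 0

    def test_inside_soma_single_region(self):
        mask, center = self.star_mask()
        prof = sholl_profile(mask, center, r_max_um=8, step_um=4, pixel_size_um=1.0)
        assert np.all(prof.intersections == 1)

    def test_center_outside_rejected(self):
        mask, _ = self.star_mask()
        with pytest.raises(ValueError):
            sholl_profile(mask, (500.0, 500.0), 10)

    def test_matches_circle_walk_oracle(self):
        """Counts agree with a brute-force oracle that groups the perimeter
        pixels of each circle into 8-connected angular runs."""

        from skimage.draw import circle_perimeter

        cfg = SimulationConfig(image_shape=(200, 200), n_frames=2, n_cells=1,
                               seed=21, event_rate_soma_hz=0.0,
                               event_rate_process_hz=0.0, noise_sigma_frac=0.0)
        _, gt, morph = simulate(cfg)
        mask = np.zeros(cfg.image_shape, bool)
        for m in list(gt.soma_masks.values()) + list(gt.process_masks.values()):
            mask |= m
        ys, xs = np.nonzero(gt.soma_masks["cell0_soma"])
        center = (float(ys.mean()), float(xs.mean()))
        prof = sholl_profile(mask, center, r_max_um=30, step_um=3, pixel_size_um=1.0)
        for r_um, got in zip(prof.radii_um, prof.intersections):
            rr, cc = circle_perimeter(int(round(center[0])), int(round(center[1])),
                                      int(round(r_um)), shape=mask.shape)
            ang = np.arctan2(rr - center[0], cc - center[1])
            order = np.argsort(ang)
            vals = mask[rr[order], cc[order]]
            if not vals.any():
                oracle = 0
            elif vals.all():
                oracle = 1
            else:
                oracle = int(np.sum(vals & ~np.roll(vals, 1)))
            assert abs(int(got) - oracle) <= 1
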