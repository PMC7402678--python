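"""Calcium-motility association, latency analysis, and cohort reporting."""

import json

import numpy as np
import pytest

from caltrack.association import (activity_by_motility_class,
                                  bin_latency_fractions, nearest_event_latency)
from caltrack.motility import MotilityEvent
from caltrack.traces import CalciumEvent, MicrodomainStats


def event(peak_frame, peak_dff=1.0, roi="p"):
    return CalciumEvent(roi_id=roi, onset_frame=max(peak_frame - 2, 0),
                        offset_frame=peak_frame + 5, peak_frame=peak_frame,
                        peak_dff=peak_dff, area=peak_dff * 5)


def motility(roi="p", klass="extension", start=100):
    return MotilityEvent(roi_id=roi, klass=klass, area_first_um2=12.0,
                         area_last_um2=20.0, fractional_change=0.66,
                         start_frame=start, end_frame=start + 50)


def stats(roi, area):
    return MicrodomainStats(roi_id=roi, kind="process", signal_area=area,
                            max_amplitude=1.0, active=area >= 5, n_events=1)


class TestNearestEventLatency:
    def test_before_and_after_latencies(self):
        """Start at 100 s with peaks at 80 s and 150 s: before 20 s, after
        50 s, nearest 20 s, in every bin."""

        rec = nearest_event_latency([event(80), event(150)], motility(start=100),
                                    frame_rate_hz=1.0)
        assert rec.nearest_before_s == 20.0
        assert rec.nearest_after_s == 50.0
        assert rec.nearest_abs_s == 20.0
        assert rec.bins == {"<30s": True, "<60s": True, "<120s": True}

    def test_only_late_event_outside_all_bins(self):
        rec = nearest_event_latency([event(130)], motility(start=0), 1.0)
        assert rec.nearest_before_s is None
        assert rec.nearest_abs_s == 130.0
        assert rec.bins == {"<30s": False, "<60s": False, "<120s": False}

    def test_sub_half_dff_events_do_not_qualify(self):
        """Events must reach peak dF/F 0.5 to count."""

        rec = nearest_event_latency([event(95, peak_dff=0.4)], motility(start=100), 1.0)
        assert rec.nearest_abs_s is None
        assert not any(rec.bins.values())
        rec2 = nearest_event_latency([event(95, peak_dff=0.5)], motility(start=100), 1.0)
        assert rec2.nearest_abs_s == 5.0

    def test_tie_resolves_to_preceding_event(self):
        rec = nearest_event_latency([event(90), event(110)], motility(start=100), 1.0)
        assert rec.nearest_abs_s == rec.nearest_before_s == 10.0

    def test_bin_nesting_invariant(self, rng):
        for _ in range(50):
            peaks = sorted(rng.integers(0, 500, size=3))
            rec = nearest_event_latency([event(int(p)) for p in peaks],
                                        motility(start=int(rng.integers(0, 500))), 1.0)
            b = rec.bins
            assert (not b["<30s"] or b["<60s"]) and (not b["<60s"] or b["<120s"])

    def test_missing_start_frame_rejected(self):
        m = motility()
        m.start_frame = None
        with pytest.raises(ValueError):
            nearest_event_latency([], m, 1.0)


class TestBinFractions:
    def test_counting_example(self):
        """Latencies 25, 45, 100, 130 s give fractions 1/4, 2/4, 3/4."""

        recs = [
            nearest_event_latency([event(int(100 - lat))], motility(start=100), 1.0)
            for lat in (25, 45, 100)
        ] + [nearest_event_latency([event(230)], motility(start=100), 1.0)]
        df = bin_latency_fractions(recs)
        ext = df[df["class"] == "extension"].set_index("bin")
        assert ext.loc["<30s", "fraction"] == 0.25
        assert ext.loc["<60s", "fraction"] == 0.5
        assert ext.loc["<120s", "fraction"] == 0.75

    def test_empty_class_null_fraction(self):
        df = bin_latency_fractions([])
        assert df["fraction"].isna().all()

    def test_fractions_non_decreasing_with_bin_width(self, rng):
        recs = []
        for i in range(30):
            start = int(rng.integers(100, 500))
            peaks = rng.integers(0, 600, size=2)
            recs.append(
                nearest_event_latency([event(int(p)) for p in peaks],
                                      motility(roi=f"p{i}", start=start), 1.0)
            )
        df = bin_latency_fractions(recs)
        fr = df[df["class"] == "extension"]["fraction"].to_numpy()
        assert fr[0] <= fr[1] <= fr[2]

    def test_no_event_processes_stay_in_denominator(self):
        recs = [
            nearest_event_latency([event(90)], motility(roi="a", start=100), 1.0),
            nearest_event_latency([], motility(roi="b", start=100), 1.0),
        ]
        df = bin_latency_fractions(recs)
        ext = df[df["class"] == "extension"].set_index("bin")
        assert ext.loc["<30s", "n"] == 2
        assert ext.loc["<30s", "fraction"] == 0.5


class TestActivityByClass:
    def test_arithmetic_example(self):
        """Three extending processes with areas 6, 7, 0: 2/3 active, mean 13/3."""

        mots = [motility(roi=r) for r in ("a", "b", "c")]
        sts = [stats("a", 6.0), stats("b", 7.0), stats("c", 0.0)]
        summ = activity_by_motility_class(mots, sts, activity_threshold=5.0)
        ext = summ.by_class["extension"]
        assert ext.n_processes == 3 and ext.n_with_calcium == 2
        assert ext.fraction_active == pytest.approx(2 / 3)
        assert ext.mean_signal_area == pytest.approx(13 / 3)

    def test_all_inactive(self):
        mots = [motility(roi=r, klass=k) for r, k in
                (("a", "extension"), ("b", "retraction"), ("c", "stable"))]
        sts = [stats(r, 0.1) for r in ("a", "b", "c")]
        summ = activity_by_motility_class(mots, sts)
        assert all(v.fraction_active == 0.0 for v in summ.by_class.values())

    def test_empty_class_reports_null_not_zero(self):
        summ = activity_by_motility_class([motility(roi="a")], [stats("a", 6.0)])
        ret = summ.by_class["retraction"]
        assert ret.n_processes == 0
        assert ret.fraction_active is None and ret.mean_signal_area is None

    def test_coupled_simulation_recovers_association(self):
        """When extensions are programmed to coincide with injected calcium
        events and stable processes stay silent, the extension class is the
        active one."""

        from caltrack.pipeline import AnalysisConfig, analyze_stack
        from caltrack.rois import Roi
        from caltrack.simulate import (MotilitySpec, SimulationConfig,
                                       generate_morphology, render_stack,
                                       calcium_kernel, SENSOR_PRESETS)

        cfg = SimulationConfig(image_shape=(256, 256), n_frames=300, n_cells=3,
                               seed=31, event_rate_soma_hz=0.0,
                               event_rate_process_hz=0.0)
        rng = np.random.default_rng(cfg.seed)
        morph = generate_morphology(cfg, rng)
        proc_ids = sorted(morph.process_masks)
        extending = proc_ids[::2]            # half extend, half stay stable
        cfg.motility_spec = [MotilitySpec(p, 120, 45, 0.7) for p in extending]
        # couple a large transient to each extension start
        dff = {p: np.zeros(cfg.n_frames) for p in proc_ids}
        kern = calcium_kernel(1.5, SENSOR_PRESETS["cytosolic_slow"], 1.0)
        for p in extending:
            dff[p][110 : 110 + len(kern)] += kern[: cfg.n_frames - 110]
        stack, gt = render_stack(cfg, morph, ([], dff), rng)

        analysis = AnalysisConfig()
        somas = [Roi(id=k, kind="soma", mask=m, pixel_size_um=cfg.pixel_size_um)
                 for k, m in gt.soma_masks.items()]
        proc_rois = [Roi(id=p, kind="process", mask=gt.process_masks[p],
                         pixel_size_um=cfg.pixel_size_um) for p in proc_ids]
        res = analyze_stack(stack, somas, analysis, extra_rois=proc_rois)
        mots = [motility(roi=p, klass="extension") for p in extending] + [
            motility(roi=p, klass="stable") for p in proc_ids if p not in extending
        ]
        summ = activity_by_motility_class(mots, res.stats)
        assert summ.by_class["extension"].fraction_active >= 0.9
        assert summ.by_class["stable"].fraction_active <= 0.1


class TestCohortReport:
    def _make_results(self):
        from caltrack.pipeline import AnalysisConfig, run_simulated_recording
        from caltrack.simulate import SimulationConfig

        cfg = SimulationConfig(image_shape=(192, 192), n_frames=120, n_cells=2,
                               seed=41, event_rate_process_hz=0.02,
                               event_rate_soma_hz=0.01)
        res, _, _ = run_simulated_recording(cfg, AnalysisConfig(), "rec0")
        return [res]

    def test_report_deterministic(self, tmp_path):
        results = self._make_results()
        from caltrack.pipeline import cohort_report

        cohort_report(results, tmp_path / "a", seeds=[41])
        cohort_report(results, tmp_path / "b", seeds=[41])
        for name in ("microdomain_summary.csv", "association_summary.csv",
                     "latency_bins.csv", "manifest.json", "per_minute_signal.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_per_minute_binning(self, tmp_path):
        import pandas as pd

        results = self._make_results()
        from caltrack.pipeline import cohort_report

        cohort_report(results, tmp_path)
        df = pd.read_csv(tmp_path / "per_minute_signal.csv")
        # 120 frames at 1 Hz -> 2 one-minute bins per territory
        assert set(df["minute"]) == {0, 1}

    def test_percent_active_recountable_from_csv(self, tmp_path):
        import pandas as pd

        results = self._make_results()
        from caltrack.pipeline import cohort_report

        cohort_report(results, tmp_path)
        df = pd.read_csv(tmp_path / "microdomain_summary.csv")
        recount = (df["signal_area"] >= 5.0).mean()
        assert recount == pytest.approx(df["active"].mean())

    def test_missing_stage_raises_dependency_error(self, tmp_path):
        from caltrack.pipeline import DependencyError, RecordingResult, cohort_report

        empty = RecordingResult(recording_id="r", frame_rate_hz=1.0,
                                somas=[], territories=[])
        with pytest.raises(DependencyError, match="summary"):
            cohort_report([empty], tmp_path)
        with pytest.raises(DependencyError):
            cohort_report([], tmp_path)

    def test_manifest_contents(self, tmp_path):
        from caltrack.pipeline import cohort_report

        results = self._make_results()
        cohort_report(results, tmp_path, seeds=[41])
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["seeds"] == [41]
        assert manifest["recordings"] == ["rec0"]
        assert manifest["n_microdomains"] == len(results[0].stats)
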