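"""Per-filter aggregation and folder summaries."""

import math

import numpy as np
import pytest

from voidspot.calibration import CalibrationCurve
from voidspot.detectors import SpotInstance, SpotSet
from voidspot.raster_io import GrayImage, SpotAreaRecord, write_spot_csv
from voidspot.synth_scenes import SceneConfig, generate_scene
from voidspot.void_summary import (SUMMARY_HEADER, FilterSummary,
                                   filter_offpaper_spots, segregate_background,
                                   summarize, summarize_folder)

IDENTITY_CURVE = CalibrationCurve(slope=0.01, intercept=0.0, r_squared=1.0,
                                  n_points=16)


def _records(areas):
    return [SpotAreaRecord(i, a) for i, a in enumerate(areas, start=1)]


class TestSummarize:
    @pytest.mark.parametrize("areas,expected", [
        # (total, count, primary, primary mean, micro)
        ((10000, 9270, 8550), (278.2, 3, 3, 92.7, 0)),
        ((12810, 470, 470, 470, 470, 470), (151.6, 6, 1, 128.1, 5)),
        ((6510,) * 11 + (425,) * 10, (758.6, 21, 11, 65.1, 10)),
    ])
    def test_summary_rows(self, areas, expected):
        s = summarize("row", _records(areas), IDENTITY_CURVE)
        assert (s.total_volume_ul, s.total_spot_count, s.primary_count,
                s.primary_mean_volume_ul, s.micro_count) == expected

    def test_empty_spot_list(self):
        s = summarize("none", [], IDENTITY_CURVE)
        assert (s.total_volume_ul, s.total_spot_count, s.primary_count,
                s.primary_mean_volume_ul, s.micro_count) == (0.0, 0, 0, 0.0, 0)

    def test_bin_boundaries(self):
        # exactly 20 uL is micro; exactly 1 uL is micro; below 1 uL excluded
        s = summarize("edges", _records((2000, 100, 99)), IDENTITY_CURVE)
        assert (s.primary_count, s.micro_count, s.total_spot_count) == (0, 2, 2)
        assert s.total_volume_ul == 21.0

    def test_permutation_invariant(self):
        areas = (12810, 470, 6510, 99, 2000)
        a = summarize("p", _records(areas), IDENTITY_CURVE)
        b = summarize("p", _records(areas[::-1]), IDENTITY_CURVE)
        assert a == b

    def test_counts_always_reconcile(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            areas = rng.integers(10, 30000, size=rng.integers(1, 30))
            s = summarize("r", _records(areas), IDENTITY_CURVE)
            assert s.total_spot_count == s.primary_count + s.micro_count

    def test_inconsistent_row_rejected(self):
        with pytest.raises(ValueError, match="primary"):
            FilterSummary("bad", 10.0, 3, 1, 5.0, 1)


class TestSummarizeFolder:
    def test_rows_ordered_and_header_verbatim(self, tmp_path):
        write_spot_csv(_records((10000, 9270, 8550)), tmp_path / "b_areas.csv")
        write_spot_csv(_records((12810, 470, 470, 470, 470, 470)),
                       tmp_path / "a_areas.csv")
        out, n_errors = summarize_folder(tmp_path, IDENTITY_CURVE)
        assert n_errors == 0
        lines = out.read_text(encoding="utf-8").splitlines()
        assert lines[0] == ",".join(SUMMARY_HEADER)
        assert lines[1].startswith("a_areas.csv,151.6,6,1,128.1,5")
        assert lines[2].startswith("b_areas.csv,278.2,3,3,92.7,0")

    def test_unreadable_csv_skipped_with_error_count(self, tmp_path):
        write_spot_csv(_records((10000,)), tmp_path / "good_areas.csv")
        (tmp_path / "bad_areas.csv").write_text("id,area\n1,oops\n")
        out, n_errors = summarize_folder(tmp_path, IDENTITY_CURVE)
        assert n_errors == 1
        assert len(out.read_text().splitlines()) == 2

    def test_empty_folder_header_only(self, tmp_path):
        out, _ = summarize_folder(tmp_path, IDENTITY_CURVE)
        assert out.read_text(encoding="utf-8").splitlines() == \
               [",".join(SUMMARY_HEADER)]

    def test_rerun_overwrites_deterministically(self, tmp_path):
        write_spot_csv(_records((10000,)), tmp_path / "x_areas.csv")
        out1, _ = summarize_folder(tmp_path, IDENTITY_CURVE)
        first = out1.read_text()
        out2, _ = summarize_folder(tmp_path, IDENTITY_CURVE)
        assert out2.read_text() == first


class TestSegregateBackground:
    def test_circular_filter_disk_area(self):
        img, _ = generate_scene(SceneConfig(seed=7, filter_shape="circular",
                                            n_spots=4, spot_radius_range=(5, 20)))
        mask, area = segregate_background(img)
        r = 0.5 * 512 - 4
        assert area == pytest.approx(math.pi * r * r, rel=0.02)

    def test_rectangular_scene_full_frame(self):
        img, _ = generate_scene(SceneConfig(seed=8))
        mask, area = segregate_background(img)
        assert area == img.pixels.size
        assert mask.all()

    def test_offpaper_detections_dropped(self):
        paper = np.zeros((40, 40), dtype=bool)
        paper[:, :20] = True
        on = SpotInstance(1, np.arange(5) + 5, np.full(5, 10))
        off = SpotInstance(2, np.arange(5) + 5, np.full(5, 30))
        spots = SpotSet("x", [on, off], "baseline")
        kept = filter_offpaper_spots(spots, paper)
        assert len(kept) == 1
        assert kept.instances[0].spot_id == 1
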