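"""Raster and areas-CSV I/O contracts."""

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image

from voidspot.detectors import SpotInstance, SpotSet
from voidspot.raster_io import (FormatError, GrayImage, SpotAreaRecord, read_image,
                                read_spot_csv, write_image, write_overlay,
                                write_spot_csv)


class TestGrayImage:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GrayImage(pixels=np.zeros((0, 5), dtype=np.uint8))
        with pytest.raises(ValueError):
            GrayImage(pixels=np.array([[300, 0]]))

    def test_dimensions(self):
        img = GrayImage(pixels=np.zeros((712, 1068), dtype=np.uint8))
        assert (img.width, img.height) == (1068, 712)


class TestReadImage:
    def test_full_size_8bit_tiff(self, tmp_path):
        arr = np.random.default_rng(0).integers(0, 256, (1424, 2136), dtype=np.uint8)
        tifffile.imwrite(tmp_path / "frame.tif", arr)
        img = read_image(tmp_path / "frame.tif")
        assert (img.width, img.height) == (2136, 1424)
        assert np.array_equal(img.pixels, arr)

    def test_16bit_rescaled_over_dtype_range(self, tmp_path):
        # blank stays blank; full-scale maps to 255; midtone maps linearly
        arr = np.zeros((4, 4), dtype=np.uint16)
        arr[0, 0] = 65535
        arr[1, 1] = 32768
        tifffile.imwrite(tmp_path / "deep.tif", arr)
        img = read_image(tmp_path / "deep.tif")
        assert img.pixels[2, 2] == 0
        assert img.pixels[0, 0] == 255
        assert img.pixels[1, 1] == 128

    def test_rgb_png_luminance(self, tmp_path):
        rgb = np.zeros((3, 3, 3), dtype=np.uint8)
        rgb[0, 0] = (255, 255, 255)
        Image.fromarray(rgb).save(tmp_path / "c.png")
        img = read_image(tmp_path / "c.png")
        assert img.pixels[0, 0] == 255
        assert img.pixels[1, 1] == 0

    def test_missing_and_malformed(self, tmp_path):
        with pytest.raises(FormatError, match="nowhere"):
            read_image(tmp_path / "nowhere.tif")
        (tmp_path / "junk.tif").write_bytes(b"not a tiff")
        with pytest.raises(FormatError, match="junk.tif"):
            read_image(tmp_path / "junk.tif")

    def test_write_read_identity(self, tmp_path):
        arr = np.random.default_rng(1).integers(0, 256, (37, 53), dtype=np.uint8)
        for name in ("a.tif", "a.png"):
            write_image(GrayImage(pixels=arr), tmp_path / name)
            assert np.array_equal(read_image(tmp_path / name).pixels, arr)


class TestSpotCsv:
    def test_worked_roundtrip(self, tmp_path):
        path = tmp_path / "x_areas.csv"
        write_spot_csv([SpotAreaRecord(1, 9270)], path)
        assert read_spot_csv(path) == [SpotAreaRecord(1, 9270)]

    def test_empty_list(self, tmp_path):
        path = tmp_path / "e_areas.csv"
        write_spot_csv([], path)
        assert path.read_text() == "id,area\n"
        assert read_spot_csv(path) == []

    def test_rows_sorted_by_id(self, tmp_path):
        path = tmp_path / "s_areas.csv"
        write_spot_csv([SpotAreaRecord(3, 30), SpotAreaRecord(1, 10),
                        SpotAreaRecord(2, 20)], path)
        ids = [int(line.split(",")[0]) for line in
               path.read_text().splitlines()[1:]]
        assert ids == sorted(ids) == [1, 2, 3]

    @pytest.mark.parametrize("body,lineno", [
        ("id,area\n1,ten\n", 2),
        ("id,area\n1,5\n7\n", 3),
    ])
    def test_malformed_row_names_line(self, tmp_path, body, lineno):
        path = tmp_path / "bad.csv"
        path.write_text(body)
        with pytest.raises(FormatError, match=f"line {lineno}"):
            read_spot_csv(path)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(1, 10**6), st.integers(1, 10**8)),
                    unique_by=lambda t: t[0], max_size=40))
    def test_roundtrip_identity_property(self, rows):
        import tempfile
        from pathlib import Path

        records = [SpotAreaRecord(i, a) for i, a in rows]
        with tempfile.TemporaryDirectory() as tmp:
            path = Path(tmp) / "r_areas.csv"
            write_spot_csv(records, path)
            assert read_spot_csv(path) == sorted(records, key=lambda r: r.spot_id)


class TestOverlay:
    @staticmethod
    def _image(seed=0):
        arr = np.full((60, 80), 100, dtype=np.uint8)
        return GrayImage(pixels=arr, label="ov")

    def test_no_spots_same_size(self, tmp_path):
        img = self._image()
        write_overlay(img, SpotSet("ov", [], "baseline"), tmp_path / "o.png")
        with Image.open(tmp_path / "o.png") as im:
            assert im.size == (80, 60)

    def test_one_spot_visibly_differs(self, tmp_path):
        img = self._image()
        rows, cols = np.nonzero(np.ones((10, 10), dtype=bool))
        spot = SpotInstance(1, rows + 20, cols + 30)
        write_overlay(img, SpotSet("ov", [spot], "baseline"), tmp_path / "o.png")
        with Image.open(tmp_path / "o.png") as im:
            out = np.asarray(im.convert("L"))
        assert out.shape == (60, 80)
        assert np.any(out != img.pixels)

    def test_out_of_bounds_mask_rejected(self, tmp_path):
        img = self._image()
        spot = SpotInstance(1, np.array([59, 60]), np.array([0, 0]))
        with pytest.raises(ValueError, match="outside"):
            write_overlay(img, SpotSet("ov", [spot], "baseline"), tmp_path / "o.png")
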