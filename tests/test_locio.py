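"""Localization I/O: dialect parsing, intensity filter, binning, masks."""

import numpy as np
import pytest
import tifffile
from hypothesis import given, strategies as st

from aznano.locio import (
    EpiImage,
    FormatError,
    LocalizationTable,
    read_localizations,
    read_mask_image,
    render_density_matrix,
    write_localizations,
    write_mask_image,
)

TOY = """x y frame intensity
100.0 200.0 1 15000
150.0 250.0 2 11999
300.5 120.25 3 13000
400.0 410.0 4 11999
500.0 0.5 5 20000
"""


def _write(tmp_path, text, name="locs.txt"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadLocalizations:
    def test_intensity_filter_drops_dim_spots(self, tmp_path):
        """Only spots with A/D count over the threshold are analyzed."""
        t = read_localizations(_write(tmp_path, TOY), intensity_min=12000)
        assert len(t) == 3
        assert t.intensity.min() > 12000
        # row order preserved
        assert list(t.x) == [100.0, 300.5, 500.0]

    def test_zero_threshold_keeps_everything(self, tmp_path):
        t = read_localizations(_write(tmp_path, TOY), intensity_min=0)
        assert len(t) == 5

    def test_rapidstorm_attribute_header(self, tmp_path):
        text = (
            '# <field identifier="Position-0-0" unit="nanometer" />'
            '<field identifier="Position-1-0" unit="nanometer" />'
            '<field identifier="ImageNumber-0-0" />'
            '<field identifier="Amplitude-0-0" />\n'
            "10.5 20.5 3 15000\n"
            "11.5 21.5 4 16000\n"
        )
        t = read_localizations(_write(tmp_path, text))
        assert len(t) == 2
        assert t.x[0] == 10.5 and t.y[1] == 21.5 and t.frame[1] == 4

    def test_missing_column_named_in_error(self, tmp_path):
        with pytest.raises(FormatError, match="y"):
            read_localizations(_write(tmp_path, "x intensity\n1 13000\n"))

    def test_empty_file_is_empty_table(self, tmp_path):
        t = read_localizations(_write(tmp_path, ""))
        assert len(t) == 0

    def test_header_only_is_empty_table(self, tmp_path):
        t = read_localizations(_write(tmp_path, "x y frame intensity\n"))
        assert len(t) == 0

    def test_missing_intensity_passes_any_filter(self, tmp_path):
        t = read_localizations(_write(tmp_path, "x y\n1 2\n3 4\n"), intensity_min=1e9)
        assert len(t) == 2

    @given(
        st.integers(0, 60).flatmap(
            lambda n: st.tuples(
                st.lists(st.floats(0, 1e5), min_size=n, max_size=n),
                st.lists(st.floats(0, 1e5), min_size=n, max_size=n),
                st.lists(st.integers(0, 15000), min_size=n, max_size=n),
                st.lists(st.floats(12001, 1e6), min_size=n, max_size=n),
            )
        )
    )
    def test_roundtrip_identity(self, tmp_path_factory, cols):
        """write -> read recovers every value to 1e-6 nm."""
        x, y, frame, inten = (np.asarray(c) for c in cols)
        table = LocalizationTable(x, y, frame, inten)
        path = tmp_path_factory.mktemp("rt") / "t.txt"
        write_localizations(table, path)
        back = read_localizations(path, intensity_min=0)
        assert len(back) == len(table)
        np.testing.assert_allclose(back.x, table.x, atol=1e-6)
        np.testing.assert_allclose(back.y, table.y, atol=1e-6)
        np.testing.assert_array_equal(back.frame, table.frame)


class TestDensityMatrix:
    def test_single_point_single_bin(self):
        t = LocalizationTable(np.array([5.0]), np.array([5.0]), None, None)
        dm = render_density_matrix(t, 10.0)
        assert dm.counts.shape == (1, 1) and dm.counts[0, 0] == 1

    def test_count_conservation(self, rng):
        xy = rng.uniform(0, 100, (100, 2))
        t = LocalizationTable(xy[:, 0], xy[:, 1], None, None)
        for b in (3.0, 7.0, 10.0, 50.0):
            assert render_density_matrix(t, b).counts.sum() == 100

    def test_half_open_convention_vs_bruteforce(self):
        """Points on bin corners follow the [lo, hi) rule exactly."""
        g = np.arange(0.0, 50.0, 10.0)
        xx, yy = np.meshgrid(g, g)
        t = LocalizationTable(xx.ravel(), yy.ravel(), None, None)
        dm = render_density_matrix(t, 10.0)
        x0, y0 = dm.origin
        b = dm.bin_size
        expect = np.zeros_like(dm.counts)
        for x, y in zip(t.x, t.y):  # brute-force binning oracle
            j = int(np.floor((x - x0) / b))
            i = int(np.floor((y - y0) / b))
            expect[i, j] += 1
        np.testing.assert_array_equal(dm.counts, expect)
        assert dm.counts.sum() == len(t)

    def test_empty_table(self):
        dm = render_density_matrix(LocalizationTable.empty(), 10.0)
        assert dm.counts.shape == (0, 0)

    def test_bad_bin_size(self):
        with pytest.raises(ValueError):
            render_density_matrix(LocalizationTable.empty(), 0.0)


class TestMaskIO:
    def test_roundtrip(self, tmp_path, rng):
        img = EpiImage(rng.integers(0, 256, (10, 12)).astype(np.uint8))
        write_mask_image(img, tmp_path / "m.tif")
        back = read_mask_image(tmp_path / "m.tif")
        np.testing.assert_array_equal(back.pixels, img.pixels)
        assert back.pixel_size == 126.0

    def test_all_zero(self, tmp_path):
        write_mask_image(EpiImage(np.zeros((10, 10), np.uint8)), tmp_path / "z.tif")
        assert read_mask_image(tmp_path / "z.tif").pixels.sum() == 0

    def test_16bit_rejected(self, tmp_path):
        tifffile.imwrite(tmp_path / "deep.tif", np.zeros((5, 5), np.uint16))
        with pytest.raises(FormatError, match="8-bit"):
            read_mask_image(tmp_path / "deep.tif")

    def test_multichannel_rejected(self, tmp_path):
        tifffile.imwrite(tmp_path / "rgb.tif", np.zeros((5, 5, 3), np.uint8))
        with pytest.raises(FormatError):
            read_mask_image(tmp_path / "rgb.tif")
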