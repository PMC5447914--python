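"""Spectra container, I/O round trips, replicate averaging and splitting."""

import numpy as np
import pytest

from conftest import make_set
from nirmc.exceptions import (
    ArgumentError,
    ConsistencyError,
    CoverageError,
    FormatError,
    GridError,
    LookupError_,
)
from nirmc.spectra import (
    WavelengthGrid,
    average_replicates,
    read_spectra,
    split_by_origin,
    subset_wavelengths,
    write_spectra,
)


class TestWavelengthGrid:
    def test_default_grid_has_1557_points_spanning_1000_2500(self):
        g = WavelengthGrid.default()
        assert len(g) == 1557
        assert g.values[0] == pytest.approx(1000.0)
        assert g.values[-1] == pytest.approx(2500.0)
        assert np.all(np.diff(g.values) > 0)

    @pytest.mark.parametrize("vals", [[1000.0], [1500.0, 1400.0],
                                      [1000.0, 1000.0, 1100.0]])
    def test_rejects_short_or_non_increasing(self, vals):
        with pytest.raises(GridError):
            WavelengthGrid(np.array(vals))

    def test_nearest_tie_breaks_toward_lower_wavelength(self):
        g = WavelengthGrid(np.array([1154.0, 1156.0]))
        assert g.nearest(1155.0, tolerance=2.0) == 0

    def test_nearest_out_of_tolerance_raises(self):
        g = WavelengthGrid.default()
        with pytest.raises(LookupError_):
            g.nearest(900.0, tolerance=2.0)


class TestWideCsvIO:
    def test_parse_small_wide_csv(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text(
            "sample_id,species,origin,replicate,role,mc,1100,1200,1300,1400,1500\n"
            "A,Arabica,Aceh,1,calibration,10.5,0.1,0.2,0.3,0.4,0.5\n"
            "B,Robusta,Bali,1,validation,,0.2,0.3,0.4,0.5,0.6\n"
            "C,Arabica,Aceh,2,unassigned,12,0.0,0.1,0.0,0.1,0.0\n")
        s = read_spectra(p)
        assert len(s) == 3
        assert s.n_wavelengths == 5
        assert s.grid.values.tolist() == [1100, 1200, 1300, 1400, 1500]
        assert s.reference_mc[0] == 10.5 and np.isnan(s.reference_mc[1])

    def test_round_trip_is_value_identical(self, tmp_path, rng):
        s = make_set(rng.normal(size=(4, 7)),
                     mc=np.array([8.0, 9.123456789012345, np.nan, 11.0]))
        p = tmp_path / "rt.csv"
        write_spectra(s, p)
        s2 = read_spectra(p)
        assert s.values_equal(s2)

    def test_ragged_row_error_names_the_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "sample_id,species,origin,replicate,role,mc,1100,1200,1300,1400,1500\n"
            "A,Arabica,Aceh,1,calibration,10,0.1,0.2,0.3,0.4\n")
        with pytest.raises(FormatError, match="row 2"):
            read_spectra(p)

    def test_non_numeric_absorbance_raises(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "sample_id,species,origin,replicate,role,mc,1100,1200\n"
            "A,Arabica,Aceh,1,calibration,10,0.1,oops\n")
        with pytest.raises(FormatError, match="non-numeric"):
            read_spectra(p)

    def test_non_monotonic_header_raises_grid_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "sample_id,species,origin,replicate,role,mc,1200,1100\n"
            "A,Arabica,Aceh,1,calibration,10,0.1,0.2\n")
        with pytest.raises(GridError):
            read_spectra(p)


class TestJcamp:
    def test_reads_xy_pairs(self, tmp_path):
        p = tmp_path / "one.jdx"
        p.write_text("##TITLE=bean\n##XUNITS=NANOMETERS\n##XYDATA=(XY..XY)\n"
                     "1100, 0.10\n1102, 0.20\n1104, 0.30\n##END=\n")
        s = read_spectra(p, dialect="jcampdx_like")
        assert len(s) == 1
        assert s.grid.values.tolist() == [1100, 1102, 1104]
        assert s.X[0].tolist() == [0.10, 0.20, 0.30]

    def test_wrong_xunits_rejected(self, tmp_path):
        p = tmp_path / "one.jdx"
        p.write_text("##XUNITS=WAVENUMBERS\n##XYDATA=(XY..XY)\n"
                     "1100 0.1\n1102 0.2\n##END=\n")
        with pytest.raises(FormatError, match="NANOMETERS"):
            read_spectra(p, dialect="jcampdx_like")


class TestAverageReplicates:
    def test_mean_of_replicate_vectors(self):
        s = make_set([[0.0, 0.0], [2.0, 2.0], [4.0, 4.0]],
                     sample_ids=["A", "A", "A"], replicates=[1, 2, 3],
                     grid=WavelengthGrid(np.array([1100.0, 1200.0])))
        out = average_replicates(s)
        assert len(out) == 1
        assert out.X[0].tolist() == [2.0, 2.0]

    def test_identical_replicates_collapse_unchanged(self):
        s = make_set([[0.3, 0.5]] * 3, sample_ids=["A"] * 3,
                     replicates=[1, 2, 3],
                     grid=WavelengthGrid(np.array([1100.0, 1200.0])))
        out = average_replicates(s)
        assert out.X.tolist() == [[0.3, 0.5]]
        assert out.meta["sample_id"].tolist() == ["A"]

    def test_conflicting_species_raises(self):
        s = make_set([[0.1, 0.2], [0.1, 0.2]], sample_ids=["A", "A"],
                     species=["Arabica", "Robusta"], replicates=[1, 2],
                     grid=WavelengthGrid(np.array([1100.0, 1200.0])))
        with pytest.raises(ConsistencyError, match="species"):
            average_replicates(s)


class TestSplitByOrigin:
    def test_overlapping_lists_rejected(self):
        s = make_set(np.zeros((2, 3)), origins=["Bali", "Aceh"])
        with pytest.raises(ArgumentError, match="Bali"):
            split_by_origin(s, ["Bali", "Aceh"], ["Bali"])

    def test_uncovered_origin_rejected(self):
        s = make_set(np.zeros((2, 3)), origins=["Bali", "Flores"])
        with pytest.raises(CoverageError, match="Flores"):
            split_by_origin(s, ["Bali"], ["Aceh"])

    def test_empty_validation_list_puts_all_in_calibration(self):
        s = make_set(np.zeros((3, 3)), origins=["Bali", "Bali", "Aceh"])
        cal, val = split_by_origin(s, ["Bali", "Aceh"], [])
        assert len(cal) == 3 and len(val) == 0

    def test_default_synthetic_set_splits_into_7_and_5_origins(
            self, default_dataset):
        spectra, _, _ = default_dataset
        from nirmc.simulate import DEFAULT_CAL_ORIGINS, DEFAULT_VAL_ORIGINS
        cal, val = split_by_origin(spectra,
                                   [o for o, _, _ in DEFAULT_CAL_ORIGINS],
                                   [o for o, _, _ in DEFAULT_VAL_ORIGINS])
        assert cal.meta["origin"].nunique() == 7
        assert val.meta["origin"].nunique() == 5
        assert len(cal) + len(val) == len(spectra)

    def test_averaging_commutes_with_splitting(self, default_dataset):
        spectra, _, _ = default_dataset
        from nirmc.simulate import DEFAULT_CAL_ORIGINS, DEFAULT_VAL_ORIGINS
        cal_o = [o for o, _, _ in DEFAULT_CAL_ORIGINS]
        val_o = [o for o, _, _ in DEFAULT_VAL_ORIGINS]
        a_then_s = split_by_origin(average_replicates(spectra), cal_o, val_o)
        s_then_a = split_by_origin(spectra, cal_o, val_o)
        assert a_then_s[0].values_equal(average_replicates(s_then_a[0]))
        assert a_then_s[1].values_equal(average_replicates(s_then_a[1]))


class TestSubsetWavelengths:
    def test_published_wavelengths_in_listed_order(self):
        from nirmc.wavelengths import PUBLISHED_WAVELENGTHS
        grid = WavelengthGrid(np.array(sorted(list(PUBLISHED_WAVELENGTHS)
                                              + [1000.0, 2500.0])))
        X = np.arange(len(grid), dtype=float)[None, :]
        s = make_set(X, grid=grid)
        out = subset_wavelengths(s, PUBLISHED_WAVELENGTHS, tolerance=0.5)
        assert out.n_wavelengths == 7
        assert out.grid.values.tolist() == list(PUBLISHED_WAVELENGTHS)
        # columns are copies of the originals, no interpolation
        for j, w in enumerate(PUBLISHED_WAVELENGTHS):
            src = int(np.where(grid.values == w)[0][0])
            assert out.X[0, j] == X[0, src]

    def test_out_of_range_target_raises(self, default_dataset):
        spectra, _, _ = default_dataset
        with pytest.raises(LookupError_, match="900"):
            subset_wavelengths(spectra, [900.0], tolerance=2.0)
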