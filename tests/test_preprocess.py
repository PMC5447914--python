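"""Pre-treatment correctness: filters, normalisations, scatter correction,
orthogonal signal correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import make_set
from nirmc.exceptions import (
    ArgumentError,
    DegenerateSpectrumError,
    RankError,
)
from nirmc.preprocess import (
    OrthogonalSignalCorrection,
    Preprocessor,
    ScatterCorrection,
    baseline_correct,
    compare_preprocessing,
    fit_osc,
    fit_scatter,
    normalize,
    preprocessing_catalogue,
    sg_derivative,
    smooth,
    snv,
)
from nirmc.spectra import WavelengthGrid

finite_spectra = arrays(np.float64, 25,
                        elements=st.floats(0.01, 10.0, allow_nan=False))


class TestSmoothing:
    @pytest.mark.parametrize("method", ["moving_average", "gaussian", "median"])
    @pytest.mark.parametrize("window", [3, 7, 11, 15, 19])
    def test_constant_spectrum_unchanged(self, method, window):
        x = np.full(40, 0.7)
        assert smooth(x, method, window) == pytest.approx(x)

    def test_moving_average_hand_value(self):
        x = np.array([0.0, 0.0, 3.0, 0.0, 0.0])
        assert smooth(x, "moving_average", 3)[2] == pytest.approx(1.0)

    def test_even_window_rejected(self):
        with pytest.raises(ArgumentError):
            smooth(np.ones(10), "moving_average", 4)

    def test_window_exceeding_length_rejected(self):
        with pytest.raises(ArgumentError):
            smooth(np.ones(5), "median", 7)


class TestSgDerivative:
    def test_first_derivative_of_line_is_slope(self):
        idx = np.arange(30, dtype=float)
        x = 2.0 + 0.5 * idx
        d = sg_derivative(x, deriv=1, poly=2, window=7)
        assert d[5:-5] == pytest.approx(np.full(20, 0.5), abs=1e-10)

    def test_second_derivative_of_quadratic(self):
        idx = np.arange(30, dtype=float)
        d = sg_derivative(idx ** 2, deriv=2, poly=2, window=7)
        assert d[5:-5] == pytest.approx(np.full(20, 2.0), abs=1e-9)

    def test_deriv_above_poly_rejected(self):
        with pytest.raises(ArgumentError):
            sg_derivative(np.ones(20), deriv=3, poly=2, window=7)

    @pytest.mark.parametrize("deriv,poly", [(1, 2), (2, 2), (3, 3)])
    def test_supported_study_configs_run(self, deriv, poly):
        x = np.sin(np.linspace(0, 3, 50))
        out = sg_derivative(x, deriv, poly, 11)
        assert out.shape == x.shape


class TestNormalize:
    @given(x=finite_spectra)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mean_mode_gives_unit_mean(self, x):
        assert normalize(x, "mean").mean() == pytest.approx(1.0, rel=1e-9)

    @given(x=finite_spectra)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_area_mode_gives_unit_absolute_area(self, x):
        assert np.abs(normalize(x, "area")).sum() == pytest.approx(1.0, rel=1e-9)

    def test_hand_value(self):
        assert normalize(np.array([1.0, 3.0]), "area").tolist() == [0.25, 0.75]

    def test_zero_spectrum_degenerate(self):
        with pytest.raises(DegenerateSpectrumError):
            normalize(np.zeros(5), "area")


class TestBaseline:
    def test_offset_mode_fixed_point(self):
        x = np.array([0.0, 1.0, 2.0])
        assert baseline_correct(x, "offset") == pytest.approx(x)

    def test_linear_spectrum_maps_to_zero(self):
        x = 3.0 + 0.2 * np.arange(20)
        assert baseline_correct(x, "linear") == pytest.approx(
            np.zeros(20), abs=1e-10)

    def test_single_point_linear_rejected(self):
        with pytest.raises(ArgumentError):
            baseline_correct(np.array([1.0]), "linear")


class TestSnv:
    def test_hand_value(self):
        assert snv(np.array([1.0, 2.0, 3.0])) == pytest.approx([-1.0, 0.0, 1.0])

    @given(x=finite_spectra)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_output_mean_zero_sd_one_and_idempotent(self, x):
        x = x + np.arange(25) * 0.1  # guarantee non-constant
        z = snv(x)
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-9)
        assert snv(z) == pytest.approx(z, abs=1e-9)

    def test_constant_spectrum_degenerate(self):
        with pytest.raises(DegenerateSpectrumError):
            snv(np.full(10, 2.0))


class TestScatterCorrection:
    @pytest.fixture
    def cal(self, rng):
        grid = WavelengthGrid(np.linspace(1000, 2500, 60))
        base = np.exp(-0.5 * ((grid.values - 1900) / 120) ** 2)
        X = np.array([(0.8 + 0.1 * i) * base + 0.02 * i for i in range(6)])
        return make_set(X, grid=grid)

    def test_reference_spectrum_is_fixed_point_of_msc(self, cal):
        corr = fit_scatter(cal, "msc")
        m = corr.reference_
        assert corr.transform(m[None, :])[0] == pytest.approx(m, abs=1e-10)

    def test_msc_inverts_affine_distortion(self, cal):
        corr = fit_scatter(cal, "msc")
        m = corr.reference_
        x = 2.0 * m + 1.0
        assert corr.transform(x[None, :])[0] == pytest.approx(m, abs=1e-8)

    def test_emsc_inverts_polynomial_distortion(self, cal):
        corr = fit_scatter(cal, "emsc", poly_order=2)
        m = corr.reference_
        t = cal.grid.scaled()
        x = m + 0.3 * t + 0.1 * t ** 2
        assert corr.transform(x[None, :])[0] == pytest.approx(m, abs=1e-8)

    def test_transform_of_calibration_matches_fit_time(self, cal):
        corr = fit_scatter(cal, "emsc")
        z1 = corr.transform(cal.X)
        z2 = corr.transform(cal.X)
        assert z1 == pytest.approx(z2)  # deterministic given fitted state


class TestOsc:
    def test_zero_components_is_identity(self, rng):
        X = rng.normal(size=(8, 6))
        y = rng.normal(size=8)
        grid = WavelengthGrid(np.linspace(1000, 2500, 6))
        proc = OrthogonalSignalCorrection(0).fit(X, y, grid)
        assert proc.transform(X) == pytest.approx(X)

    def test_removed_training_score_is_orthogonal_to_y(self, rng):
        X = rng.normal(size=(10, 8))
        y = rng.normal(size=10)
        proc = OrthogonalSignalCorrection(1).fit(X, y)
        t = proc.train_scores_[0]
        yc = y - y.mean()
        assert abs(t @ yc) <= 1e-8 * np.linalg.norm(t) * np.linalg.norm(yc)

    def test_matches_independent_step_by_step_iteration(self, rng):
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        proc = OrthogonalSignalCorrection(1, tol=1e-10).fit(X, y)

        # independent re-implementation of the same NIPALS-style loop
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        t = u[:, 0] * s[0]
        for _ in range(500):
            t_orth = t - yc * (yc @ t) / (yc @ yc)
            w = Xc.T @ t_orth
            w = w / np.linalg.norm(w)
            t_new = Xc @ w
            if np.linalg.norm(t_new - t) <= 1e-10 * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        t_orth = t - yc * (yc @ t) / (yc @ yc)
        p = Xc.T @ t_orth / (t_orth @ t_orth)
        expected = Xc - np.outer(t_orth, p) + X.mean(axis=0)

        # fit-time deflation stored by the transformer
        fitted_deflation = (X - proc.x_mean_
                            - np.outer(proc.train_scores_[0], proc.loadings_[0])
                            + proc.x_mean_)
        assert fitted_deflation == pytest.approx(expected, abs=1e-8)

    def test_too_many_components_rejected(self, rng):
        X = rng.normal(size=(4, 3))
        with pytest.raises(RankError):
            OrthogonalSignalCorrection(3).fit(X, rng.normal(size=4))


class TestCatalogue:
    def test_catalogue_covers_the_study_grid(self):
        names = [f().name for f in preprocessing_catalogue()]
        assert sum(n.startswith("smooth_") for n in names) == 15
        # window 3 is admissible for poly 2 but not poly 3: 5 + 5 + 4
        assert sum(n.startswith("sg_") for n in names) == 14
        for expected in ("normalize_area", "normalize_mean", "baseline_offset",
                         "baseline_linear", "snv", "msc", "emsc2", "osc1"):
            assert expected in names

    def test_comparison_ranks_by_rmsecv(self, rng):
        # small synthetic problem where smoothing should not hurt
        grid = WavelengthGrid(np.linspace(1000, 2500, 30))
        y = rng.uniform(6, 22, size=12)
        base = np.exp(-0.5 * ((grid.values - 1900) / 150) ** 2)
        X = y[:, None] * 0.01 * base + rng.normal(0, 0.001, (12, 30)) + 0.3
        cal = make_set(X, grid=grid)
        few = [lambda: Preprocessor(),
               lambda: ScatterCorrection(poly_order=0)]
        out = compare_preprocessing(cal, y, max_lv=3, factories=few,
                                    include_raw=False)
        assert list(out.columns) == ["name", "best_n_lv", "rmsecv", "r2_cv"]
        assert out["rmsecv"].is_monotonic_increasing
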