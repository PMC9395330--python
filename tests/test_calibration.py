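import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import reeftrack as rt
from reeftrack.exceptions import CalibrationError

from _oracles import ols_line


def fixes_with_hpe(values):
    return pd.DataFrame({"hpe": np.asarray(values, dtype=float)})


class TestExtremeHpeExclusion:
    def test_95th_percentile_of_1_to_100(self):
        kept, cutoff = rt.exclude_extreme_hpe(fixes_with_hpe(np.arange(1, 101)))
        # linear-interpolation quantile of 1..100 at 0.95
        assert cutoff == pytest.approx(95.05)
        assert len(kept) == 95

    def test_degenerate_distribution_removes_nothing(self):
        kept, cutoff = rt.exclude_extreme_hpe(fixes_with_hpe([3.0] * 50))
        assert len(kept) == 50
        assert cutoff == 3.0

    def test_small_sample_warns_and_skips(self):
        with pytest.warns(UserWarning, match="skipping"):
            kept, cutoff = rt.exclude_extreme_hpe(fixes_with_hpe([1, 2, 3]))
        assert len(kept) == 3
        assert np.isnan(cutoff)

    def test_empty_input_errors(self):
        with pytest.raises(CalibrationError):
            rt.exclude_extreme_hpe(fixes_with_hpe([]))


class Test2drmsBins:
    def test_unit_cross_deviations(self):
        # MSE_x = MSE_y = 0.5 -> 2DRMS = 2 * sqrt(1.0) = 2.0
        df = pd.DataFrame(
            {"hpe": [0.2, 0.4, 0.6, 0.8],
             "dx": [1.0, -1.0, 0.0, 0.0],
             "dy": [0.0, 0.0, 1.0, -1.0]}
        )
        bins = rt.compute_2drms_bins(df)
        assert len(bins) == 1
        assert bins.loc[0, "twodrms"] == pytest.approx(2.0)
        assert bins.loc[0, "bin_mid"] == 0.5

    def test_zero_deviations_zero_2drms(self):
        df = pd.DataFrame({"hpe": [0.5, 1.5, 2.5], "dx": 0.0, "dy": 0.0})
        bins = rt.compute_2drms_bins(df)
        assert (bins["twodrms"] == 0.0).all()
        assert len(bins) == 3

    def test_single_fix_closed_form(self):
        df = pd.DataFrame({"hpe": [1.2], "dx": [1.0], "dy": [1.0]})
        bins = rt.compute_2drms_bins(df)
        assert bins.loc[0, "twodrms"] == pytest.approx(2.0 * np.sqrt(2.0))

    def test_half_metre_bin_width(self):
        df = pd.DataFrame({"hpe": [0.2, 0.7], "dx": [1.0, 2.0], "dy": [0.0, 0.0]})
        bins = rt.compute_2drms_bins(df, bin_width=0.5)
        assert bins["bin_mid"].tolist() == [0.25, 0.75]

    def test_no_receiver_fixes_errors(self):
        with pytest.raises(CalibrationError, match="impossible"):
            rt.compute_2drms_bins(pd.DataFrame({"hpe": [], "dx": [], "dy": []}))


class TestRegression:
    def test_two_point_line(self):
        bins = pd.DataFrame({"bin_mid": [0.5, 1.5], "twodrms": [1.0, 2.0], "n": 1})
        model = rt.fit_hpe_regression(bins)
        assert model.slope == pytest.approx(1.0)
        assert model.intercept == pytest.approx(0.5)

    def test_collinear_bins_zero_residuals(self):
        bins = pd.DataFrame(
            {"bin_mid": [0.5, 1.5, 2.5], "twodrms": [1.0, 3.0, 5.0], "n": 1}
        )
        model = rt.fit_hpe_regression(bins)
        assert model.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        x = [0.5, 1.5, 2.5]
        y = [1.0, 1.8, 3.2]
        bins = pd.DataFrame({"bin_mid": x, "twodrms": y, "n": 1})
        model = rt.fit_hpe_regression(bins)
        slope, intercept = ols_line(x, y)
        assert model.slope == pytest.approx(slope, abs=1e-10)
        assert model.intercept == pytest.approx(intercept, abs=1e-10)

    def test_single_bin_errors(self):
        with pytest.raises(CalibrationError, match=">= 2"):
            rt.fit_hpe_regression(
                pd.DataFrame({"bin_mid": [0.5], "twodrms": [1.0], "n": 1})
            )

    def test_json_round_trip(self, tmp_path):
        bins = pd.DataFrame({"bin_mid": [0.5, 1.5], "twodrms": [1.0, 2.0], "n": 1})
        model = rt.fit_hpe_regression(bins, hpe_cutoff=9.9)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = rt.HpeCalibrationResults.from_json(path)
        assert back.slope == model.slope
        assert back.hpe_cutoff == 9.9
        assert back.summary()  # renders


class TestApplyAndFilter:
    @pytest.mark.parametrize(
        "slope,intercept,hpe,expected",
        [(1.0, 0.5, 0.0, 0.5), (1.0, 0.0, 7.0, 7.0)],
    )
    def test_linear_map(self, slope, intercept, hpe, expected):
        model = rt.HpeCalibrationResults(
            slope=slope, intercept=intercept, hpe_cutoff=np.nan,
            bin_table=pd.DataFrame(),
        )
        out = rt.apply_calibration(fixes_with_hpe([hpe]), model)
        assert out.loc[0, "hpe_m"] == pytest.approx(expected)

    def test_negative_prediction_clamped_with_warning(self):
        model = rt.HpeCalibrationResults(
            slope=1.0, intercept=-5.0, hpe_cutoff=np.nan, bin_table=pd.DataFrame()
        )
        with pytest.warns(UserWarning, match="clamped"):
            out = rt.apply_calibration(fixes_with_hpe([1.0]), model)
        assert out.loc[0, "hpe_m"] == 0.0

    def test_retention_count(self):
        fixes = pd.DataFrame({"hpe_m": 0.2 * np.arange(1, 101)})
        kept, report = rt.filter_positions(fixes, 10.0)
        assert report.n_out == 50
        assert report.retention == pytest.approx(0.5)

    def test_infinite_threshold_keeps_all(self):
        fixes = pd.DataFrame({"hpe_m": [1.0, 5.0, 100.0]})
        _, report = rt.filter_positions(fixes, np.inf)
        assert report.retention == 1.0

    def test_all_filtered_warns(self):
        fixes = pd.DataFrame({"hpe_m": [20.0, 30.0]})
        with pytest.warns(UserWarning, match="no fixes"):
            kept, report = rt.filter_positions(fixes, 5.0)
        assert len(kept) == 0
        assert report.retention == 0.0

    def test_nonpositive_threshold_errors(self):
        with pytest.raises(CalibrationError):
            rt.filter_positions(pd.DataFrame({"hpe_m": [1.0]}), 0.0)

    @given(
        st.lists(st.floats(0.0, 50.0), min_size=1, max_size=200),
        st.floats(0.1, 20.0),
        st.floats(0.0, 20.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_retention_monotone_in_threshold(self, hpe_m, t1, extra):
        """Raising the error threshold can only retain more fixes."""
        fixes = pd.DataFrame({"hpe_m": hpe_m})
        _, r1 = rt.filter_positions(fixes, t1)
        _, r2 = rt.filter_positions(fixes, t1 + extra)
        assert r1.n_out <= r2.n_out


class TestDriftTest:
    def _gps(self):
        return pd.DataFrame(
            {
                "t": pd.to_datetime(["2018-07-01 00:00:00", "2018-07-01 00:00:10"],
                                    utc=True),
                "x": [0.0, 10.0],
                "y": [0.0, 0.0],
            }
        )

    def test_exact_position_zero_error(self):
        vps = pd.DataFrame(
            {"t": pd.to_datetime(["2018-07-01 00:00:00"], utc=True),
             "x": [0.0], "y": [0.0]}
        )
        out, _ = rt.drift_test_error(vps, self._gps())
        assert out.loc[0, "error_m"] == 0.0

    def test_interpolated_error(self):
        vps = pd.DataFrame(
            {"t": pd.to_datetime(["2018-07-01 00:00:05"], utc=True),
             "x": [5.0], "y": [1.0]}
        )
        out, _ = rt.drift_test_error(vps, self._gps())
        assert out.loc[0, "error_m"] == pytest.approx(1.0)

    def test_fix_outside_span_excluded(self):
        vps = pd.DataFrame(
            {
                "t": pd.to_datetime(
                    ["2018-07-01 00:00:05", "2018-07-01 00:01:00"], utc=True
                ),
                "x": [5.0, 99.0],
                "y": [0.0, 99.0],
            }
        )
        out, _ = rt.drift_test_error(vps, self._gps())
        assert len(out) == 1

    def test_no_overlap_errors(self):
        vps = pd.DataFrame(
            {"t": pd.to_datetime(["2018-07-02 00:00:00"], utc=True),
             "x": [0.0], "y": [0.0]}
        )
        with pytest.raises(CalibrationError, match="overlap"):
            rt.drift_test_error(vps, self._gps())

    def test_region_means(self):
        vps = pd.DataFrame(
            {
                "t": pd.to_datetime(
                    ["2018-07-01 00:00:02", "2018-07-01 00:00:08"], utc=True
                ),
                "x": [2.0, 8.0],
                "y": [0.5, 2.0],
            }
        )
        out, means = rt.drift_test_error(
            vps, self._gps(), region_of=lambda x, y: "centre" if x < 5 else "edge"
        )
        assert means["centre"] == pytest.approx(0.5)
        assert means["edge"] == pytest.approx(2.0)
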