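import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import reeftrack as rt

from _oracles import km_by_ecdf


def ts(day):
    return pd.Timestamp("2016-05-01", tz="UTC") + pd.Timedelta(days=day)


class TestResidencyRecords:
    def _inputs(self, visits_rows, fate, fate_day, last_day=100.0):
        visits = pd.DataFrame(
            visits_rows,
            columns=["fish_id", "reef_id", "t_start", "t_end", "n_fixes"],
        )
        fates = pd.DataFrame(
            {"fish_id": ["f1"], "fate": [fate], "t": [ts(fate_day)]}
        )
        return visits, fates, {"f1": "R0"}, {"f1": ts(0)}, {"f1": ts(last_day)}

    def test_stayer_censored_at_last_observation(self):
        args = self._inputs([("f1", "R0", ts(1), ts(99), 10)], "at_large", 100)
        rec = rt.build_residency_records(*args)
        assert rec.loc[0, "event"] == False  # noqa: E712
        assert rec.loc[0, "duration"] == pytest.approx(100.0)

    def test_departure_scored_at_first_other_reef_visit(self):
        args = self._inputs(
            [("f1", "R0", ts(1), ts(40), 10), ("f1", "P", ts(43), ts(50), 5)],
            "at_large", 100,
        )
        rec = rt.build_residency_records(*args)
        assert rec.loc[0, "event"] == True  # noqa: E712
        assert rec.loc[0, "duration"] == pytest.approx(43.0)

    def test_predation_censors_if_never_left(self):
        args = self._inputs([("f1", "R0", ts(1), ts(9), 10)], "predation", 10,
                            last_day=10.0)
        rec = rt.build_residency_records(*args)
        assert rec.loc[0, "event"] == False  # noqa: E712
        assert rec.loc[0, "duration"] == pytest.approx(10.0)

    def test_emigration_fate_is_an_event(self):
        args = self._inputs([("f1", "R0", ts(1), ts(20), 10)], "emigration", 21,
                            last_day=21.0)
        rec = rt.build_residency_records(*args)
        assert rec.loc[0, "event"] == True  # noqa: E712
        assert rec.loc[0, "duration"] == pytest.approx(21.0)

    def test_short_presence_excluded(self):
        args = self._inputs([], "unknown", 2, last_day=2.0)
        rec = rt.build_residency_records(*args)
        assert len(rec) == 0

    def test_missing_release_reef_errors(self):
        visits = pd.DataFrame(
            columns=["fish_id", "reef_id", "t_start", "t_end", "n_fixes"]
        )
        fates = pd.DataFrame({"fish_id": ["f1"], "fate": ["at_large"], "t": [ts(50)]})
        with pytest.raises(ValueError, match="release reef"):
            rt.build_residency_records(
                visits, fates, {}, {"f1": ts(0)}, {"f1": ts(50)}
            )


class TestKaplanMeier:
    def test_hand_worked_all_events(self):
        res = rt.KaplanMeier([2, 4, 4, 7], [True] * 4).fit()
        s = dict(zip(res.table["t"], res.table["survival"]))
        assert s[2.0] == pytest.approx(0.75)
        assert s[4.0] == pytest.approx(0.25)
        assert s[7.0] == pytest.approx(0.0)

    def test_hand_worked_with_censoring(self):
        # {2 event, 3 censored, 4 event}: S(2)=2/3, S(4)=2/3*(1-1/1)=0
        res = rt.KaplanMeier([2, 3, 4], [True, False, True]).fit()
        s = dict(zip(res.table["t"], res.table["survival"]))
        assert s[2.0] == pytest.approx(2.0 / 3.0)
        assert s[4.0] == pytest.approx(0.0)

    def test_no_events_survival_stays_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = rt.KaplanMeier([5, 6, 7], [False] * 3).fit()
        assert (res.table["survival"] == 1.0).all()
        assert not res.median_.reached

    def test_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(1234)
        durations = rng.exponential(10.0, size=200).round(3) + 0.001
        res = rt.KaplanMeier(durations, np.ones(200, dtype=bool)).fit()
        times, surv = km_by_ecdf(durations)
        np.testing.assert_allclose(res.table["survival"].to_numpy(), surv,
                                   atol=1e-12)
        np.testing.assert_allclose(res.table["t"].to_numpy(), times)

    def test_matches_lifelines_on_censored_data(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(99)
        durations = rng.exponential(30.0, size=150) + 0.01
        events = rng.random(150) > 0.3
        res = rt.KaplanMeier(durations, events).fit()
        kmf = lifelines.KaplanMeierFitter()
        kmf.fit(durations, events)
        ours = res.survival_at(res.table["t"].to_numpy())
        theirs = (
            kmf.survival_function_at_times(res.table["t"].to_numpy()).to_numpy()
        )
        np.testing.assert_allclose(ours, theirs, atol=1e-10)
        assert res.median_.t50 == pytest.approx(
            float(kmf.median_survival_time_), abs=1e-9
        )

    def test_curve_is_monotone_and_bounded(self):
        rng = np.random.default_rng(5)
        res = rt.KaplanMeier(
            rng.exponential(20, 100) + 0.01, rng.random(100) > 0.4
        ).fit()
        s = res.table["survival"].to_numpy()
        assert (np.diff(s) <= 1e-12).all()
        assert ((s >= 0) & (s <= 1)).all()
        assert (res.table["ci_lower"] <= s + 1e-12).all()
        assert (s <= res.table["ci_upper"] + 1e-12).all()


class TestMedian:
    def test_median_of_hand_example(self):
        res = rt.KaplanMeier([2, 4, 4, 7], [True] * 4).fit()
        assert res.median_.t50 == 4.0

    def test_exactly_half_counts(self):
        # S(2) = 0.5 exactly -> median is 2 under the <= rule
        res = rt.KaplanMeier([2, 9], [True, False]).fit()
        assert res.median_.t50 == 2.0

    def test_median_ci_brackets_point(self):
        rng = np.random.default_rng(8)
        res = rt.KaplanMeier(
            rng.exponential(43.0, 300) + 0.01, np.ones(300, bool)
        ).fit()
        m = res.median_
        assert m.ci_lower <= m.t50 <= m.ci_upper


class TestParameterRecovery:
    def test_median_ci_coverage_under_censoring(self):
        """With 30% independent censoring the Greenwood-based CI for the
        median should cover the true value in >= 90% of replicates."""
        rng = np.random.default_rng(31)
        true_median = 43.0
        rate = np.log(2) / true_median
        hits = 0
        for _ in range(100):
            t_event = rng.exponential(1.0 / rate, size=1000)
            # censoring rate chosen so ~30% of records are censored
            t_cens = rng.exponential(1.0 / rate / 0.42, size=1000)
            durations = np.minimum(t_event, t_cens) + 1e-9
            events = t_event <= t_cens
            res = rt.KaplanMeier(durations, events).fit()
            m = res.median_
            if m.reached and m.ci_lower <= true_median <= m.ci_upper:
                hits += 1
        assert hits >= 90


class TestFidelityAlgebra:
    def test_definition_cases(self):
        assert rt.convert_fidelity(sf=0.5, t_sf=100.0).t50 == pytest.approx(100.0)
        assert rt.convert_fidelity(sf=0.25, t_sf=365.0).t50 == pytest.approx(182.5)

    def test_printed_precision_case(self):
        p = rt.convert_fidelity(sf=0.8, t_sf=365.0)
        assert p.t50 == pytest.approx(365.0 * np.log(0.5) / np.log(0.8), abs=1e-9)
        assert p.t50 == pytest.approx(1133.79, abs=0.01)

    def test_round_trip_is_exact(self):
        p = rt.convert_fidelity(sf=0.8, t_sf=365.0)
        back = rt.convert_fidelity(t50=p.t50, t_sf=365.0)
        assert back.sf == pytest.approx(0.8, abs=1e-12)
        assert back.r_e == pytest.approx(p.r_e, abs=1e-15)

    @given(st.floats(0.01, 0.99), st.floats(1.0, 1000.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_property(self, sf, t_sf):
        p = rt.convert_fidelity(sf=sf, t_sf=t_sf)
        back = rt.convert_fidelity(t50=p.t50, t_sf=t_sf)
        assert back.sf == pytest.approx(sf, rel=1e-9, abs=1e-12)
        # internal consistency of the completed set
        assert np.exp(-p.t_sf * p.r_e) == pytest.approx(p.sf, abs=1e-12)
        assert np.log(2) / p.r_e == pytest.approx(p.t50, rel=1e-12)

    def test_annual_special_case(self):
        p = rt.convert_fidelity(r_e=np.log(2) / 43.0)
        assert p.af == pytest.approx(np.exp(-365.0 * np.log(2) / 43.0))
        assert p.t50 == pytest.approx(43.0)

    def test_sf_one_signals_infinite_median(self):
        with pytest.warns(UserWarning, match="infinite"):
            p = rt.convert_fidelity(sf=1.0, t_sf=365.0)
        assert np.isinf(p.t50)
        assert p.r_e == 0.0

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_invalid_sf_errors(self, bad):
        with pytest.raises(ValueError):
            rt.convert_fidelity(sf=bad, t_sf=365.0)
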