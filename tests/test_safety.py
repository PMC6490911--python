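import numpy as np
import pandas as pd
import pytest

from lznpk import (PopulationModel, SafetyDataset, ToxicityModel, event_rate,
                   exposure_by_event_group, format_rate, generate_safety,
                   km_estimate, logrank_test, rmst_compare, time_to_event)
from oracles import km_by_hand, logrank_by_hand, rmst_rectangles


class TestEventRate:
    @pytest.mark.parametrize("n,py,printed", [
        (12, 21.0, 57.1), (1, 21.0, 4.8), (2, 21.0, 9.5), (0, 13.7, 0.0)])
    def test_per_100_person_years(self, n, py, printed):
        assert format_rate(event_rate(n, py)) == printed

    def test_rounding_is_half_up(self):
        assert format_rate(9.45) == 9.5
        assert format_rate(9.4499) == 9.4

    def test_nonpositive_person_time_rejected(self):
        with pytest.raises(ValueError):
            event_rate(3, 0.0)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        steps = [(t, s) for t, s in zip(curve.times, curve.survival)]
        assert steps == [(1.0, pytest.approx(2 / 3)),
                         (2.0, pytest.approx(1 / 3)),
                         (3.0, pytest.approx(0.0))]

    def test_all_censored_survival_stays_one(self):
        curve = km_estimate([5.0, 9.0, 12.0], [0, 0, 0])
        assert np.all(curve.survival == 1.0)

    def test_interleaved_censoring_matches_hand_product_limit(self):
        """Classic 6-subject example with censoring between events."""
        times = [6, 7, 10, 15, 19, 25]
        events = [1, 0, 1, 1, 0, 1]
        curve = km_estimate(times, events)
        hand = km_by_hand(times, events)
        got = {t: s for t, s in zip(curve.times, curve.survival)
               if curve.deaths[list(curve.times).index(t)] > 0}
        for t, s in hand:
            assert got[t] == pytest.approx(s)
        # hand values: S(6)=5/6, S(10)=5/6*3/4, S(15)=5/6*3/4*2/3, S(25)=0
        assert hand[0][1] == pytest.approx(5 / 6)
        assert hand[1][1] == pytest.approx(5 / 6 * 3 / 4)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogRank:
    def test_identical_groups_give_p_one(self):
        t = [3.0, 5.0, 8.0, 12.0]
        e = [1, 1, 0, 1]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_risk_set_oracle(self):
        ta, ea = [1, 2, 3, 4, 10, 12], [1, 1, 1, 1, 0, 1]
        tb, eb = [8, 9, 14, 20, 30, 31], [1, 0, 1, 1, 1, 0]
        stat, p = logrank_test(ta, ea, tb, eb)
        assert stat == pytest.approx(logrank_by_hand(ta, ea, tb, eb), rel=1e-9)

    def test_label_swap_invariance(self):
        ta, ea = [1, 4, 6, 9], [1, 1, 0, 1]
        tb, eb = [2, 5, 11, 13], [0, 1, 1, 1]
        s1, p1 = logrank_test(ta, ea, tb, eb)
        s2, p2 = logrank_test(tb, eb, ta, ea)
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_no_events_warns_p_one(self):
        with pytest.warns(UserWarning):
            stat, p = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert p == 1.0


class TestRMST:
    def test_no_censoring_closed_form(self):
        """RMST equals the mean of min(T, tau) when nothing is censored."""
        ta = [10.0, 50.0, 200.0, 400.0]
        tb = [30.0, 90.0, 500.0, 600.0]
        out = rmst_compare(ta, [1] * 4, tb, [1] * 4, tau=300.0)
        assert out.rmst_a == pytest.approx(np.mean(np.minimum(ta, 300.0)))
        assert out.rmst_b == pytest.approx(np.mean(np.minimum(tb, 300.0)))

    def test_tau_zero_gives_zero(self):
        out = rmst_compare([1, 2], [1, 1], [3, 4], [1, 1], tau=0.0)
        assert out.rmst_a == out.rmst_b == 0.0

    def test_step_curve_area_matches_rectangle_oracle(self):
        times = [6, 7, 10, 15, 19, 25]
        events = [1, 0, 1, 1, 0, 1]
        out = rmst_compare(times, events, times, events, tau=20.0)
        hand = rmst_rectangles(km_by_hand(times, events), 20.0)
        assert out.rmst_a == pytest.approx(hand)
        assert out.difference == pytest.approx(0.0, abs=1e-12)
        assert out.p_value == pytest.approx(1.0)

    def test_tau_beyond_followup_truncates_with_warning(self):
        with pytest.warns(UserWarning, match="truncated"):
            out = rmst_compare([5, 8], [1, 1], [4, 9], [1, 0], tau=100.0)
        assert out.tau == 8.0


def _toy_safety(aucs, events):
    subjects = pd.DataFrame({
        "subject_id": [f"P{i}" for i in range(len(aucs))],
        "followup_days": 500.0,
        "discontinuation_day": 500.0,
        "auc24ss": aucs})
    rows = []
    for i, ev in enumerate(events):
        if ev is not None:
            onset, grade = ev
            rows.append({"subject_id": f"P{i}", "event_type": "low haemoglobin",
                         "grade": grade, "onset_day": onset, "related": 1})
    return SafetyDataset(subjects=subjects,
                         events=pd.DataFrame(rows, columns=[
                             "subject_id", "event_type", "grade", "onset_day",
                             "related"]))


class TestExposureByEventGroup:
    def test_identical_groups_p_one(self):
        ds = _toy_safety([100, 100, 100, 100],
                         [(30, 2), (40, 2), None, None])
        # both groups share the same exposure values
        out = exposure_by_event_group(ds, split="any")
        assert out.p_value == pytest.approx(1.0)

    def test_extreme_separation_exact_p(self):
        """{1,2,3} vs {4,5,6} is the most extreme rank arrangement: p = 0.1."""
        ds = _toy_safety([4, 5, 6, 1, 2, 3],
                         [(30, 3), (40, 3), (60, 4), None, None, None])
        out = exposure_by_event_group(ds, split="any")
        assert out.median_event == 5.0
        assert out.median_no_event == 2.0
        assert out.p_value == pytest.approx(0.1)

    def test_grade34_split_ignores_low_grade_events(self):
        ds = _toy_safety([150, 90, 80, 120],
                         [(30, 4), (40, 1), None, None])
        out = exposure_by_event_group(ds, split="grade34")
        assert out.n_event == 1 and out.n_no_event == 3
        tte = time_to_event(ds, grade34=True)
        lowgrade = tte[tte.subject_id == "P1"]
        assert int(lowgrade["event"].iloc[0]) == 0
        assert float(lowgrade["time"].iloc[0]) == 500.0  # not censored at day 40

    def test_exposure_toxicity_simulation_separates_groups(self, final_model):
        """An AUC-driven hazard makes event medians exceed non-event medians."""
        rng = np.random.default_rng(5)
        tox = ToxicityModel()
        wins = 0
        for rep in range(40):
            aucs = rng.uniform(40.0, 250.0, 30)
            subjects = pd.DataFrame({"ID": [f"Q{i}" for i in range(30)],
                                     "auc24ss": aucs})
            rec = generate_safety(subjects, tox, seed=1000 + rep)
            ds = SafetyDataset(
                subjects=rec[["subject_id", "followup_days",
                              "discontinuation_day", "auc24ss"]],
                events=rec[rec.event_type != ""][[
                    "subject_id", "event_type", "grade", "onset_day",
                    "related"]])
            out = exposure_by_event_group(ds, split="any")
            if out.n_event and out.n_no_event and \
                    out.median_event > out.median_no_event:
                wins += 1
        assert wins >= 36  # >= 90% of replicates

    def test_person_time_accounting(self):
        ds = _toy_safety([100, 120, 90], [None, None, None])
        assert ds.person_years == pytest.approx(1500 / 365.25)
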