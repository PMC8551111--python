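import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pursuitkit import behavior_analysis as ba
from pursuitkit.synthetic_data import simulate_trialset
from pursuitkit.trajectory_io import TrialSet

from conftest import make_trial, zigzag_trial


def trial_from_vx(vx, rate=120.0, vy=0.01, **kw):
    """Positions whose attacker forward differences equal ``vx`` (x) and vy."""
    vx = np.asarray(vx, dtype=float)
    x = np.concatenate([[0.0], np.cumsum(vx)])
    y = np.concatenate([[0.0], np.cumsum(np.full(len(vx), vy))])
    return make_trial(np.c_[x, y], sample_rate=rate, **kw)


def brute_force_events(vx):
    """Independent oracle: scan signs, zeros inherit, strict flips only."""
    out = []
    prev = 0
    for i, v in enumerate(vx):
        s = int(v > 0) - int(v < 0)
        if s == 0:
            continue
        if prev != 0 and s != prev:
            out.append((i, s))
        prev = s
    return out


class TestDetection:
    def test_single_crossing(self):
        t = trial_from_vx([0.01, 0.01, -0.01, -0.01])
        ev = ba.detect_direction_changes(t, "attacker")
        assert len(ev) == 1
        assert ev[0].sign == "pos_to_neg"
        assert ev[0].time == pytest.approx(2 / 120.0)

    def test_touch_without_cross(self):
        t = trial_from_vx([0.01, 0.0, 0.01])
        assert ba.detect_direction_changes(t, "attacker") == []

    def test_three_alternating(self):
        t = trial_from_vx([0.01, -0.01, 0.01, -0.01])
        ev = ba.detect_direction_changes(t, "attacker")
        assert [e.sign for e in ev] == ["pos_to_neg", "neg_to_pos", "pos_to_neg"]

    def test_all_zero(self):
        t = trial_from_vx([0.0, 0.0, 0.0])
        assert ba.detect_direction_changes(t, "attacker") == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1234)
        for _ in range(1000):
            n = rng.integers(2, 40)
            vx = rng.choice([-0.02, -0.01, 0.0, 0.01, 0.02], size=n)
            t = trial_from_vx(vx)
            got = [
                (int(round(e.time * 120)), e.new_sign)
                for e in ba.detect_direction_changes(t, "attacker")
            ]
            assert got == brute_force_events(vx)

    def test_signs_alternate_within_trial(self, small_reference_sets):
        for ts in small_reference_sets.values():
            for t in ts:
                ev = ba.detect_direction_changes(t, "attacker")
                for a, b in zip(ev, ev[1:]):
                    assert a.sign != b.sign


class TestMatching:
    def ev(self, time, sign, agent="attacker"):
        return ba.ChangeEvent(agent=agent, time=time, sign=sign, x_at_change=0.0, trial_id="t")

    def test_simple_match_short(self):
        recs = ba.match_responses(
            [self.ev(1.0, "pos_to_neg")], [self.ev(1.120, "pos_to_neg", "defender")]
        )
        assert len(recs) == 1
        assert recs[0].latency_ms == pytest.approx(120.0)
        assert recs[0].is_short

    def test_latency_window(self):
        recs = ba.match_responses(
            [self.ev(2.0, "pos_to_neg")], [self.ev(2.6, "pos_to_neg", "defender")]
        )
        assert recs == []

    def test_sign_mismatch(self):
        recs = ba.match_responses(
            [self.ev(1.0, "pos_to_neg")], [self.ev(1.05, "neg_to_pos", "defender")]
        )
        assert recs == []

    def test_one_to_one_greedy(self):
        atk = [self.ev(1.0, "pos_to_neg"), self.ev(1.2, "pos_to_neg")]
        dfn = [self.ev(1.3, "pos_to_neg", "defender")]
        recs = ba.match_responses(atk, dfn)
        assert len(recs) == 1
        assert recs[0].attacker_event.time == 1.0

    def test_negative_latency_not_matched(self):
        recs = ba.match_responses(
            [self.ev(1.0, "pos_to_neg")], [self.ev(0.9, "pos_to_neg", "defender")]
        )
        assert recs == []

    def test_latency_bounds_on_simulation(self, small_reference_sets):
        for ts in small_reference_sets.values():
            for recs in ba.trialset_responses(ts).values():
                for r in recs:
                    assert 0.0 <= r.latency <= 0.5
                    assert r.is_short == (r.latency < 0.150)


class TestShortLatency:
    def rec(self, ms):
        e = ba.ChangeEvent("attacker", 1.0, "pos_to_neg", 0.0, "t")
        d = ba.ChangeEvent("defender", 1.0 + ms / 1000.0, "pos_to_neg", 0.0, "t")
        return ba.ResponseRecord(e, d, ms / 1000.0)

    def test_half_short(self):
        recs = [self.rec(ms) for ms in (100, 200, 300, 120)]
        assert ba.short_latency_proportion(recs) == 0.5

    def test_none_short(self):
        recs = [self.rec(ms) for ms in (150, 200)]
        assert ba.short_latency_proportion(recs) == 0.0

    def test_empty_is_nan(self):
        assert math.isnan(ba.short_latency_proportion([]))

    def test_participant_averaging(self):
        recs = [self.rec(100), self.rec(100), self.rec(100), self.rec(200)]
        # trial "t" all belong to one participant -> pooled == averaged
        assert ba.short_latency_proportion(recs, {"t": "p0"}) == 0.75


class TestHeadingHistogram:
    def test_straight_line_all_mass_at_zero(self):
        # steps exactly representable in binary so headings are identical
        i = np.arange(60)
        att = np.c_[i * 0.25, 5.0 - i * 0.0625]
        h = ba.heading_change_histogram(TrialSet([make_trial(att)]))
        zero_bin = np.argmax(h.counts)
        edges = h.edges
        assert edges[zero_bin] < 0 <= edges[zero_bin + 1]
        assert h.counts[zero_bin] == h.n_total

    def test_single_left_turn_bin(self):
        # 20 Hz trial: straight +x, then straight +y (one +90 degree turn)
        pos = [(i * 0.3, 0.0) for i in range(3)] + [(0.6, (i + 1) * 0.3) for i in range(2)]
        t = make_trial(pos, sample_rate=20.0)
        h = ba.heading_change_histogram(TrialSet([t]), rate=20.0)
        idx = np.nonzero(h.counts)[0]
        turn_bins = [i for i in idx if not (h.edges[i] < 0 <= h.edges[i + 1])]
        assert len(turn_bins) == 1
        b = turn_bins[0]
        assert h.edges[b] == pytest.approx(85.0)
        assert h.edges[b + 1] == pytest.approx(90.0)

    def test_relative_frequencies_sum_to_one(self, small_reference_sets):
        for ts in small_reference_sets.values():
            h = ba.heading_change_histogram(ts)
            assert h.relative_frequencies.sum() == pytest.approx(1.0)

    def test_zero_speed_steps_counted(self):
        att = np.r_[np.c_[np.linspace(0, 1, 5), np.zeros(5)], [[1.0, 0.0]] * 3]
        t = make_trial(att, sample_rate=20.0)
        h = ba.heading_change_histogram(TrialSet([t]), rate=20.0)
        assert h.n_skipped > 0

    @given(st.floats(min_value=-1e5, max_value=1e5, allow_nan=False))
    def test_wrap_angle_range(self, a):
        w = ba.wrap_angle_deg(a)
        assert -180.0 < w <= 180.0


class TestEntropy:
    def hist(self, counts, bw=5.0):
        counts = np.asarray(counts, dtype=np.int64)
        return ba.HeadingChangeHistogram(bw, counts, int(counts.sum()))

    def test_degenerate_zero(self):
        counts = np.zeros(72, dtype=int)
        counts[3] = 50
        assert ba.entropy(self.hist(counts)) == 0.0

    def test_uniform_is_log2_nbins(self):
        assert ba.entropy(self.hist(np.full(72, 10))) == pytest.approx(math.log2(72))

    def test_two_equal_bins_one_bit(self):
        counts = np.zeros(72, dtype=int)
        counts[0] = counts[40] = 7
        assert ba.entropy(self.hist(counts)) == pytest.approx(1.0)

    def test_empty_is_nan(self):
        assert math.isnan(ba.entropy(self.hist(np.zeros(72, dtype=int))))

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=72, max_size=72))
    @settings(max_examples=50, deadline=None)
    def test_bounds(self, counts):
        h = self.hist(counts)
        if h.n_total == 0:
            return
        e = ba.entropy(h)
        assert 0.0 <= e <= math.log2(72) + 1e-12


class TestColumnStats:
    def test_missing_column_flagged(self):
        # narrow pitch, 4 columns; attacker stays in x > 0 (columns 2, 3)
        att = np.c_[np.full(240, 1.0), np.linspace(5, -5, 240)]
        ts = TrialSet([make_trial(att, condition="narrow")])
        cs = ba.column_stats(ts, "attacker")
        assert cs.n_columns == 4
        assert cs.missing[0] and cs.missing[1]
        assert not cs.missing[2]
        assert np.isnan(cs.freq_per_s[0])

    def test_frequency_division(self):
        t = zigzag_trial(n_flips=1, period=120, step=0.004, condition="narrow")
        ts = TrialSet([t])
        cs = ba.column_stats(ts, "attacker")
        total_time = t.n_samples / 120.0
        assert cs.time_spent_s.sum() == pytest.approx(total_time)
        assert cs.n_changes.sum() == 1
        occupied = ~cs.missing
        np.testing.assert_allclose(
            cs.freq_per_s[occupied], cs.n_changes[occupied] / cs.time_spent_s[occupied]
        )

    def test_column_count_per_condition(self, small_reference_sets):
        expected = {"narrow": 4, "square": 8, "wide": 16}
        for cond, ts in small_reference_sets.items():
            assert ba.column_stats(ts, "attacker").n_columns == expected[cond]

    def test_mixed_conditions_rejected(self, small_reference_sets):
        mixed = TrialSet(
            list(small_reference_sets["narrow"])[:1] + list(small_reference_sets["wide"])[:1]
        )
        with pytest.raises(ValueError):
            ba.column_stats(mixed, "attacker")


class TestChangeRatio:
    def test_ratio_value(self):
        trials = [
            zigzag_trial(8, trial_id="a", participant="p0"),
            zigzag_trial(10, trial_id="b", participant="p0"),
        ]
        # attacker changes: 8 + 10; defender stationary: 0
        ts = TrialSet(trials)
        r = ba.change_ratio(ts)
        assert r.pooled == 0.0

    def test_explicit_counts(self):
        att = zigzag_trial(8, trial_id="a", participant="p0")
        # defender trace with 10 flips: use zigzag attacker positions as defender
        don = zigzag_trial(10, trial_id="b", participant="p0")
        t = make_trial(
            att.attacker_xy[: min(att.n_samples, don.n_samples)],
            don.attacker_xy[: min(att.n_samples, don.n_samples)],
            trial_id="c",
            participant="p0",
        )
        r = ba.change_ratio(TrialSet([t]))
        n_att = len(ba.detect_direction_changes(t, "attacker"))
        n_def = len(ba.detect_direction_changes(t, "defender"))
        assert r.pooled == pytest.approx(n_def / n_att)

    def test_reactive_defender_ratio_le_1_and_no_short(self, reactive_config):
        ts = simulate_trialset(reactive_config())
        r = ba.change_ratio(ts)
        assert r.pooled <= 1.0
        recs = [x for rs in ba.trialset_responses(ts).values() for x in rs]
        assert recs, "reactive defender should still produce matched responses"
        assert ba.short_latency_proportion(recs) <= 0.02

    def test_anticipation_raises_short_and_spurious_raises_ratio(self, reactive_config):
        cfg = reactive_config(seed=22)
        cfg.defender.anticipation_prob = 0.5
        cfg.defender.spurious_rate = 0.5
        ts = simulate_trialset(cfg)
        base = simulate_trialset(reactive_config(seed=22))
        r_base = ba.change_ratio(base)
        r_ant = ba.change_ratio(ts)
        assert r_ant.pooled > r_base.pooled
        recs = [x for rs in ba.trialset_responses(ts).values() for x in rs]
        assert ba.short_latency_proportion(recs) > 0.1


class TestIntervals:
    def test_periodic_survival_step(self):
        evs = [
            ba.ChangeEvent("attacker", float(k), "pos_to_neg" if k % 2 else "neg_to_pos", 0.0, "t")
            for k in range(12)
        ]
        iv = ba.interval_analysis({"t": evs})
        assert np.all(iv.intervals == 1.0)
        assert iv.survival_p[-1] == 0.0

    def test_intervals_non_negative(self, small_reference_sets):
        for ts in small_reference_sets.values():
            iv = ba.interval_analysis(ba.trialset_events(ts, "attacker"))
            assert np.all(iv.intervals >= 0)

    def test_low_confidence_flag(self):
        evs = [ba.ChangeEvent("attacker", t, "pos_to_neg", 0.0, "t") for t in (0.0, 0.1)]
        iv = ba.interval_analysis({"t": evs})
        assert iv.low_confidence

    def test_empty(self):
        iv = ba.interval_analysis({})
        assert len(iv.intervals) == 0
        assert math.isnan(iv.tail_rate)


class TestSpeedSaturation:
    def test_stationary_zero(self):
        ts = TrialSet([make_trial(np.zeros((10, 2)))])
        assert ba.speed_saturation(ts)["attacker"] == 0.0

    def test_full_speed_one(self):
        step = 5.5 / 120.0
        att = np.c_[np.zeros(50), np.linspace(0, -49 * step, 50)]
        ts = TrialSet([make_trial(att)])
        assert ba.speed_saturation(ts)["attacker"] == 1.0


class TestDistanceBins:
    def test_counts_conserved(self, small_reference_sets):
        ts = small_reference_sets["square"]
        events = ba.trialset_events(ts, "attacker")
        db = ba.distance_binned_changes(ts, "attacker", events=events)
        assert db.n_changes.sum() == sum(len(v) for v in events.values())

    def test_single_occupied_bin(self):
        att = np.c_[np.linspace(0, 0.5, 20), np.full(20, 3.0)]
        dfd = np.c_[np.linspace(0, 0.5, 20), np.zeros(20)]
        ts = TrialSet([make_trial(att, dfd)])
        db = ba.distance_binned_changes(ts, "attacker")
        assert np.count_nonzero(db.time_spent_s) == 1

    def test_memoryless_attacker_flat_frequency(self, small_reference_sets):
        ts = small_reference_sets["square"]
        db = ba.distance_binned_changes(ts, "attacker", bin_width=1.0)
        # restrict to well-occupied bins to avoid small-sample noise
        occ = db.time_spent_s > np.percentile(db.time_spent_s[db.time_spent_s > 0], 50)
        f = db.freq_per_s[occ]
        assert np.std(f) / np.mean(f) < 0.4


def test_participant_summary_shape(small_reference_sets):
    df = ba.participant_summary(small_reference_sets["narrow"])
    assert len(df) == 4
    assert "heading_change_entropy_bits" in df.columns
    assert df["n_trials"].sum() == len(small_reference_sets["narrow"])
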