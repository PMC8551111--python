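import math

import numpy as np
import pytest

from pursuitkit import rollout_eval as re_
from pursuitkit.prediction_models import ModelSpec, build_inputs
from pursuitkit.prediction_models.features import trial_features
from pursuitkit.prediction_models.networks import build_network
from pursuitkit.prediction_models.training import TrainedModel
from pursuitkit.synthetic_data import SimConfig, simulate_trialset
from pursuitkit.trajectory_io import TrialSet

from conftest import make_trial


def untrained(kind, seed=4):
    net = build_network(kind, np.random.default_rng(seed))
    return TrainedModel(spec=ModelSpec(kind=kind, epochs=1, seed=seed), network=net)


def circle_features(n=80, R=2.0, omega=0.12):
    th = omega * np.arange(n)
    att = R * np.c_[np.cos(th), np.sin(th)] + [0.0, 3.0]
    dfd = np.zeros((n, 2))
    t = make_trial(att, dfd, condition="wide", sample_rate=20.0, trial_id="circle")
    return trial_features(t, rate=20.0)


def straight_features(n=40):
    att = np.c_[np.linspace(0, 4, n), np.linspace(5, 1, n)]
    dfd = np.zeros((n, 2))
    return trial_features(make_trial(att, dfd, condition="wide", sample_rate=20.0), rate=20.0)


class TestRelativeDirection:
    def test_toward_pursuer_is_zero(self):
        assert re_.relative_direction([0.0, -1.0], [0.0, 2.0]) == pytest.approx(0.0)

    def test_ccw_is_positive_left(self):
        # toward-pursuer direction is -r = (0, -1); +90 deg CCW from it is (1, 0)
        assert re_.relative_direction([1.0, 0.0], [0.0, 1.0]) == pytest.approx(90.0)

    def test_reversal_flips_180(self):
        a = re_.relative_direction([1.0, 0.3], [2.0, 1.0])
        b = re_.relative_direction([-1.0, -0.3], [2.0, 1.0])
        assert abs(re_.wrap_angle_deg(a - b)) == pytest.approx(180.0)

    def test_zero_displacement_nan(self):
        assert math.isnan(re_.relative_direction([0.0, 0.0], [1.0, 1.0]))


class TestPhase:
    @pytest.mark.parametrize(
        "delta,phase",
        [(0, "ST"), (19.9, "ST"), (-10, "ST"), (20, "GC"), (45, "GC"), (60, "GC"), (61, "SC"), (-170, "SC")],
    )
    def test_thresholds(self, delta, phase):
        assert re_.phase_of(delta) == phase


class TestOneStep:
    def test_linear_exact_on_constant_velocity(self):
        df = re_.one_step_eval("L", [straight_features()])
        assert df.angular_error.max() == pytest.approx(0.0, abs=1e-9)

    def test_ninety_degree_turn_error(self):
        pos = [(0.0, 0.0), (0.5, 0.0), (1.0, 0.0), (1.0, 0.5), (1.0, 1.0)]
        dfd = np.tile([0.0, -3.0], (5, 1))
        f = trial_features(make_trial(pos, dfd, sample_rate=20.0), rate=20.0)
        df = re_.one_step_eval("L", [f])
        turn = df[df.phase == "SC"]
        assert len(turn) == 1
        assert turn.angular_error.iloc[0] == pytest.approx(90.0)

    def test_perfect_prediction_zero_error(self):
        class Oracle(re_.Predictor):
            name = "oracle"

            def one_step(self, f):
                return f.Y.copy()

        df = re_.one_step_eval(Oracle(), [circle_features()])
        assert df.angular_error.max() == pytest.approx(0.0, abs=1e-9)

    def test_angular_errors_bounded(self, long_trial_features):
        for model in ("L", "C", untrained("NN")):
            df = re_.one_step_eval(model, long_trial_features)
            assert df.angular_error.between(0, 180).all()


class TestRollout:
    def test_linear_on_straight_is_exact(self):
        f = straight_features()
        res = re_.rollout("L", f, start=3, horizon=5)
        assert res.ade == pytest.approx(0.0, abs=1e-9)
        assert res.fde == pytest.approx(0.0, abs=1e-9)

    def test_perfect_stub_zero_error(self):
        f = circle_features()

        class Oracle(re_.Predictor):
            name = "oracle"

            def __init__(self, f):
                self.f = f

            def start_rollout(self, f, k0):
                return {"k": k0}

            def rollout_step(self, ctx, x):
                y = self.f.Y[ctx["k"]]
                ctx["k"] += 1
                return y.copy()

        res = re_.rollout(Oracle(f), f, start=2, horizon=5)
        assert res.ade == pytest.approx(0.0, abs=1e-9)

    def test_circle_c_beats_l(self):
        f = circle_features()
        l_res = re_.rollout("L", f, start=10, horizon=5)
        c_res = re_.rollout("C", f, start=10, horizon=5)
        assert l_res.fde > l_res.ade > 0
        assert c_res.fde < l_res.fde
        assert c_res.fde == pytest.approx(0.0, abs=1e-9)  # perfect circular motion

    def test_insufficient_context_raises(self):
        f = straight_features(n=20)
        with pytest.raises(ValueError):
            re_.rollout("L", f, start=len(f) - 2, horizon=5)
        with pytest.raises(ValueError):
            re_.rollout(untrained("RNN"), f, start=5, horizon=5)

    @pytest.mark.parametrize("model", ["L", "C"])
    def test_horizon1_equals_one_step(self, model, long_trial_features):
        f = long_trial_features[0]
        predictor = re_.make_predictor(model)
        onestep = predictor.one_step(f)
        for start in range(0, len(f) - 1, 7):
            res = re_.rollout(model, f, start, horizon=1)
            disp = res.predicted_xy[0] - f.attacker_xy[start + 1]
            np.testing.assert_allclose(disp, onestep[start], atol=1e-12)

    @pytest.mark.parametrize("kind", ["NN", "RNN", "LSTM"])
    def test_horizon1_equals_one_step_networks(self, kind, long_trial_features):
        f = long_trial_features[0]
        predictor = re_.make_predictor(untrained(kind))
        onestep = predictor.one_step(f)
        # for recurrent kinds context matches one-step only where the
        # warm-up window covers the full history (start == warm-up length)
        start = predictor.min_start
        res = re_.rollout(predictor, f, start, horizon=1)
        disp = res.predicted_xy[0] - f.attacker_xy[start + 1]
        np.testing.assert_allclose(disp, onestep[start], atol=1e-9)

    def test_l_error_non_decreasing_in_horizon(self):
        cfg = SimConfig(condition="square", n_pairs=2, trials_per_pair=10, seed=13)
        feats = build_inputs(simulate_trialset(cfg))
        df = re_.rollout_eval("L", feats, horizon=5)
        means = [df[f"err_h{h}"].mean() for h in range(1, 6)]
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))

    def test_rollout_never_crosses_trial_boundary(self):
        f = straight_features(n=12)  # 10 feature rows
        df = re_.rollout_eval("L", [f], horizon=5)
        assert df["start"].max() <= len(f) - 5


class TestAggregation:
    def make_folds(self, n, seed=0):
        cfg = SimConfig(condition="square", n_pairs=n, trials_per_pair=6, seed=seed)
        ts = simulate_trialset(cfg)
        feats = build_inputs(ts)
        folds = []
        for p in ts.defender_participants():
            test = [f for f in feats if f.defender_participant == p]
            folds.append(re_.evaluate_fold("L", test, rollout_stride=3))
        return folds

    def test_single_fold_sem_nan(self):
        agg = re_.aggregate_folds(self.make_folds(1))
        assert agg["sem"].isna().all()

    def test_identical_folds_sem_zero(self):
        fold = self.make_folds(1)[0]
        twin = re_.FoldResult("other", fold.model, fold.one_step, fold.rollouts)
        agg = re_.aggregate_folds([fold, twin])
        row = agg[(agg.metric == "angular_error") & (agg["slice"] == "all")]
        assert row["sem"].iloc[0] == pytest.approx(0.0)

    def test_summary_structure(self):
        agg = re_.aggregate_folds(self.make_folds(2))
        assert set(agg.metric) == {"angular_error", "ADE", "FDE"}
        assert {"ST", "GC", "SC", "all"} <= set(agg[agg.metric == "angular_error"]["slice"])
        assert (agg[agg.metric == "ADE"]["mean"] >= 0).all()

    def test_no_folds_raises(self):
        with pytest.raises(ValueError):
            re_.aggregate_folds([])


class TestDirectionHistogram2d:
    def test_marginals_match_1d(self, long_trial_features):
        df = re_.one_step_eval("C", long_trial_features)
        H, edges = re_.direction_histogram_2d(df)
        assert H.sum() == pytest.approx(1.0)
        pred_1d, _ = np.histogram(df.pred_angle, bins=edges)
        act_1d, _ = np.histogram(df.actual_angle, bins=edges)
        np.testing.assert_allclose(H.sum(axis=1) * len(df), pred_1d)
        np.testing.assert_allclose(H.sum(axis=0) * len(df), act_1d)
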