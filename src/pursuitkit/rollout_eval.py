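"""One-step and closed-loop (5-step / 250 ms) evaluation of predictors.

Angular metrics use the target's movement direction relative to the
pursuer: 0 degrees = moving directly toward the pursuer, positive =
to the left (counterclockwise), wrapped to (-180, 180]. Each evaluated
step is labeled by the actual one-step heading change: straight (ST,
< 20 deg), gentle curve (GC, 20-60 deg), sharp curve (SC, > 60 deg).

In the closed-loop rollout the predicted attacker position and the
displacement that produced it are fed back as the attacker part of the
next input, while the defender part is read from the actual recorded
defender trajectory (own-state assumed known up to 250 ms ahead).
Recurrent models get a 2.5 s (50-step) observation period to warm their
hidden state; rollouts never cross a trial boundary.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior_analysis import wrap_angle_deg
from .prediction_models.extrapolation import rotate, turn_angle
from .prediction_models.features import TrialFeatures
from .prediction_models.gaussian import head_to_params
from .prediction_models.training import TrainedModel

PHASES = ("ST", "GC", "SC")
ST_MAX_DEG = 20.0
SC_MIN_DEG = 60.0
DEFAULT_HORIZON = 5
WARMUP_STEPS = 50  # 2.5 s at 20 Hz


def relative_direction(disp: np.ndarray, range_vec: np.ndarray) -> float:
    """Signed angle (deg) of a displacement relative to the pursuer.

    ``range_vec`` points from the pursuer to the target; 0 means moving
    straight at the pursuer, positive counterclockwise (left). NaN for
    a zero displacement or zero range.
    """
    toward = (-np.asarray(range_vec, dtype=float))
    disp = np.asarray(disp, dtype=float)
    if np.hypot(*disp) == 0 or np.hypot(*toward) == 0:
        return math.nan
    cross = toward[0] * disp[1] - toward[1] * disp[0]
    dot = toward[0] * disp[0] + toward[1] * disp[1]
    return float(wrap_angle_deg(math.degrees(math.atan2(cross, dot))))


def phase_of(delta_deg: float) -> str:
    """ST/GC/SC label from an actual one-step heading change."""
    a = abs(delta_deg)
    if a < ST_MAX_DEG:
        return "ST"
    if a <= SC_MIN_DEG:
        return "GC"
    return "SC"


def angular_error(pred_deg: float, actual_deg: float) -> float:
    """Absolute wrapped angular difference in [0, 180]."""
    return abs(float(wrap_angle_deg(pred_deg - actual_deg)))


# ---------------------------------------------------------------------------
# predictor wrappers


class Predictor:
    """Uniform interface over extrapolators and trained networks."""

    name: str

    def one_step(self, f: TrialFeatures) -> np.ndarray:
        """Predicted displacement (T, 2) for every step of a trial."""
        raise NotImplementedError

    def start_rollout(self, f: TrialFeatures, k0: int) -> dict:
        """Initialize per-rollout context at start row ``k0``."""
        raise NotImplementedError

    def rollout_step(self, ctx: dict, x: np.ndarray) -> np.ndarray:
        """Predicted displacement from the (possibly fed-back) input."""
        raise NotImplementedError

    @property
    def min_start(self) -> int:
        """Minimum feature-row index a rollout may start from."""
        return 0


class LinearPredictor(Predictor):
    name = "L"

    def one_step(self, f: TrialFeatures) -> np.ndarray:
        return f.X[:, 0:2].copy()

    def start_rollout(self, f: TrialFeatures, k0: int) -> dict:
        return {}

    def rollout_step(self, ctx: dict, x: np.ndarray) -> np.ndarray:
        return x[0:2].copy()


class CurvilinearPredictor(Predictor):
    name = "C"

    def one_step(self, f: TrialFeatures) -> np.ndarray:
        v = f.X[:, 0:2]
        preds = np.empty_like(v)
        prev = np.zeros(2)
        for k in range(len(v)):
            preds[k] = rotate(v[k], turn_angle(prev, v[k]))
            prev = v[k]
        return preds

    def start_rollout(self, f: TrialFeatures, k0: int) -> dict:
        prev = f.X[k0 - 1, 0:2].copy() if k0 >= 1 else np.zeros(2)
        return {"prev": prev}

    def rollout_step(self, ctx: dict, x: np.ndarray) -> np.ndarray:
        curr = x[0:2]
        pred = rotate(curr, turn_angle(ctx["prev"], curr))
        ctx["prev"] = curr.copy()
        return pred


class NetworkPredictor(Predictor):
    def __init__(self, model: TrainedModel) -> None:
        self.model = model
        self.name = model.spec.kind

    @property
    def recurrent(self) -> bool:
        return self.model.network.recurrent

    @property
    def min_start(self) -> int:
        return WARMUP_STEPS if self.recurrent else 0

    def one_step(self, f: TrialFeatures) -> np.ndarray:
        h = self.model.network.forward(f.X)
        mu, _, _ = head_to_params(h)
        return mu

    def start_rollout(self, f: TrialFeatures, k0: int) -> dict:
        net = self.model.network
        state = net.init_state()
        if self.recurrent:
            for k in range(max(0, k0 - WARMUP_STEPS), k0):
                _, state = net.step(f.X[k], state)
        return {"state": state}

    def rollout_step(self, ctx: dict, x: np.ndarray) -> np.ndarray:
        h, ctx["state"] = self.model.network.step(x, ctx["state"])
        mu, _, _ = head_to_params(h)
        return mu


def make_predictor(model: str | TrainedModel | Predictor) -> Predictor:
    if isinstance(model, Predictor):
        return model
    if isinstance(model, TrainedModel):
        return NetworkPredictor(model)
    if model == "L":
        return LinearPredictor()
    if model == "C":
        return CurvilinearPredictor()
    raise ValueError(f"cannot build a predictor from {model!r}")


# ---------------------------------------------------------------------------
# one-step evaluation


def one_step_eval(
    model: str | TrainedModel | Predictor,
    features: Sequence[TrialFeatures],
) -> pd.DataFrame:
    """Per-step predicted/actual relative directions and angular errors.

    Steps where the actual (or predicted) displacement is zero are
    skipped; the number skipped is recorded in ``df.attrs['n_skipped']``.
    """
    predictor = make_predictor(model)
    rows = []
    n_skipped = 0
    for f in features:
        preds = predictor.one_step(f)
        r = f.X[:, 4:6]
        for k in range(len(f)):
            actual = f.Y[k]
            a_ang = relative_direction(actual, r[k])
            p_ang = relative_direction(preds[k], r[k])
            if math.isnan(a_ang) or math.isnan(p_ang):
                n_skipped += 1
                continue
            delta = wrap_angle_deg(
                math.degrees(
                    math.atan2(actual[1], actual[0])
                    - math.atan2(f.X[k, 1], f.X[k, 0])
                )
            ) if np.hypot(*f.X[k, 0:2]) > 0 else math.nan
            rows.append(
                {
                    "trial_id": f.trial_id,
                    "participant": f.defender_participant,
                    "condition": f.condition,
                    "step": k,
                    "pred_angle": p_ang,
                    "actual_angle": a_ang,
                    "angular_error": angular_error(p_ang, a_ang),
                    "phase": phase_of(delta) if not math.isnan(delta) else "ST",
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "trial_id", "participant", "condition", "step",
            "pred_angle", "actual_angle", "angular_error", "phase",
        ],
    )
    df.attrs["n_skipped"] = n_skipped
    df.attrs["model"] = predictor.name
    return df


# ---------------------------------------------------------------------------
# closed-loop rollout


@dataclass
class RolloutResult:
    trial_id: str
    start_step: int
    predicted_xy: np.ndarray  # (horizon, 2)
    errors: np.ndarray  # (horizon,) Euclidean error per horizon step (cm)
    phases: list[str]

    @property
    def ade(self) -> float:
        return float(self.errors.mean())

    @property
    def fde(self) -> float:
        return float(self.errors[-1])


def rollout(
    model: str | TrainedModel | Predictor,
    f: TrialFeatures,
    start: int,
    horizon: int = DEFAULT_HORIZON,
) -> RolloutResult:
    """Closed-loop prediction from feature row ``start`` for ``horizon`` steps.

    Raises ValueError if the trial does not provide enough context
    (warm-up for recurrent kinds) or enough subsequent actual steps.
    """
    predictor = make_predictor(model)
    T = len(f)
    if start < predictor.min_start:
        raise ValueError(f"start {start} < required context {predictor.min_start}")
    if start + horizon > T:
        raise ValueError("not enough subsequent steps for the requested horizon")

    ctx = predictor.start_rollout(f, start)
    # feature row k corresponds to sample index k+1 in the position arrays
    p_hat = f.attacker_xy[start + 1].copy()
    v_hat = f.X[start, 0:2].copy()
    preds = np.empty((horizon, 2))
    errors = np.empty(horizon)
    phases = []
    for j in range(horizon):
        row = start + j
        v_def = f.X[row, 2:4]
        d_pos = f.defender_xy[row + 1]
        x = np.concatenate([v_hat, v_def, p_hat - d_pos])
        disp = predictor.rollout_step(ctx, x)
        p_hat = p_hat + disp
        v_hat = disp
        preds[j] = p_hat
        errors[j] = float(np.hypot(*(p_hat - f.attacker_xy[row + 2])))
        v_act = f.X[row, 0:2]
        if np.hypot(*v_act) > 0 and np.hypot(*f.Y[row]) > 0:
            delta = wrap_angle_deg(
                math.degrees(
                    math.atan2(f.Y[row][1], f.Y[row][0])
                    - math.atan2(v_act[1], v_act[0])
                )
            )
            phases.append(phase_of(float(delta)))
        else:
            phases.append("ST")
    return RolloutResult(f.trial_id, start, preds, errors, phases)


def rollout_eval(
    model: str | TrainedModel | Predictor,
    features: Sequence[TrialFeatures],
    horizon: int = DEFAULT_HORIZON,
    stride: int = 1,
) -> pd.DataFrame:
    """Rollouts from every valid start row (sliding origin) of each trial."""
    predictor = make_predictor(model)
    rows = []
    for f in features:
        T = len(f)
        for start in range(predictor.min_start, T - horizon + 1, stride):
            res = rollout(predictor, f, start, horizon)
            rec = {
                "trial_id": f.trial_id,
                "participant": f.defender_participant,
                "condition": f.condition,
                "start": start,
                "ade": res.ade,
                "fde": res.fde,
            }
            for j in range(horizon):
                rec[f"err_h{j + 1}"] = res.errors[j]
            rows.append(rec)
    df = pd.DataFrame(rows)
    df.attrs["model"] = predictor.name
    df.attrs["horizon"] = horizon
    return df


# ---------------------------------------------------------------------------
# fold-level aggregation


@dataclass
class FoldResult:
    """Evaluation of one held-out participant for one model."""

    fold_id: str
    model: str
    one_step: pd.DataFrame
    rollouts: pd.DataFrame
    n_test_steps: int = 0


def evaluate_fold(
    model: str | TrainedModel | Predictor,
    test_features: Sequence[TrialFeatures],
    horizon: int = DEFAULT_HORIZON,
    rollout_stride: int = 1,
) -> FoldResult:
    predictor = make_predictor(model)
    fold = test_features[0].defender_participant if test_features else "?"
    return FoldResult(
        fold_id=fold,
        model=predictor.name,
        one_step=one_step_eval(predictor, test_features),
        rollouts=rollout_eval(predictor, test_features, horizon, rollout_stride),
        n_test_steps=sum(len(f) for f in test_features),
    )


def _mean_sem(values: list[float]) -> tuple[float, float]:
    arr = np.asarray([v for v in values if not math.isnan(v)])
    if len(arr) == 0:
        return math.nan, math.nan
    sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else math.nan
    return float(arr.mean()), sem


def aggregate_folds(fold_results: Sequence[FoldResult]) -> pd.DataFrame:
    """Mean +/- s.e.m. across folds of angular errors and ADE/FDE.

    Steps are pooled within each held-out participant, then averaged
    across folds. Rows are tidy: (model, metric, phase_or_horizon,
    mean, sem, n_folds).
    """
    if not fold_results:
        raise ValueError("need at least one fold")
    rows = []
    by_model: dict[str, list[FoldResult]] = {}
    for fr in fold_results:
        by_model.setdefault(fr.model, []).append(fr)
    for model_name, frs in by_model.items():
        # one-step angular error, overall and per phase
        for phase in ("all",) + PHASES:
            vals = []
            for fr in frs:
                df = fr.one_step
                if phase != "all":
                    df = df[df["phase"] == phase]
                vals.append(float(df["angular_error"].mean()) if len(df) else math.nan)
            mean, sem = _mean_sem(vals)
            rows.append(
                {
                    "model": model_name,
                    "metric": "angular_error",
                    "slice": phase,
                    "mean": mean,
                    "sem": sem,
                    "n_folds": len(frs),
                }
            )
        # rollout ADE / FDE per horizon
        horizon = max(fr.rollouts.attrs.get("horizon", DEFAULT_HORIZON) for fr in frs)
        for h in range(1, horizon + 1):
            cols = [f"err_h{j + 1}" for j in range(h)]
            ade_vals, fde_vals = [], []
            for fr in frs:
                df = fr.rollouts
                if len(df) == 0:
                    ade_vals.append(math.nan)
                    fde_vals.append(math.nan)
                    continue
                ade_vals.append(float(df[cols].mean(axis=1).mean()))
                fde_vals.append(float(df[f"err_h{h}"].mean()))
            for metric, vals in (("ADE", ade_vals), ("FDE", fde_vals)):
                mean, sem = _mean_sem(vals)
                rows.append(
                    {
                        "model": model_name,
                        "metric": metric,
                        "slice": f"h{h}",
                        "mean": mean,
                        "sem": sem,
                        "n_folds": len(frs),
                    }
                )
    return pd.DataFrame(rows)


def direction_histogram_2d(
    one_step: pd.DataFrame, bin_width: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """2-D relative-frequency histogram of (predicted, actual) directions.

    Returns (H, edges); H sums to 1 and its marginals equal the 1-D
    predicted and actual direction histograms at the same bin width.
    """
    edges = np.arange(-180.0, 180.0 + bin_width, bin_width)
    H, _, _ = np.histogram2d(
        one_step["pred_angle"], one_step["actual_angle"], bins=(edges, edges)
    )
    total = H.sum()
    if total > 0:
        H = H / total
    return H, edges
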