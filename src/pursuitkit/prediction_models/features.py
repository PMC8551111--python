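"""Model input construction from trial sets.

At the analysis rate (20 Hz), the model input at step t is the
6-component vector

    x_t = (v_x^a, v_y^a, v_x^d, v_y^d, r_x, r_y)

where the velocities are the displacements ending at t and r points
from the defender (pursuer) to the attacker (target); the training
target y_t is the attacker displacement from t to t+1. Pairs never
cross trial boundaries: an N-sample trial yields N-2 (input, target)
pairs (t = 1 .. N-2).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..geometry import ANALYSIS_RATE_HZ
from ..trajectory_io import Trial, TrialSet, downsample

logger = logging.getLogger(__name__)


@dataclass
class TrialFeatures:
    """Per-trial model inputs, targets, and the positions behind them."""

    trial_id: str
    defender_participant: str
    condition: str
    X: np.ndarray  # (T, 6) inputs at steps t = 1 .. N-2
    Y: np.ndarray  # (T, 2) attacker displacement t -> t+1
    attacker_xy: np.ndarray  # (N, 2) positions at the analysis rate
    defender_xy: np.ndarray
    rate: float

    def __len__(self) -> int:
        return len(self.X)


def trial_features(trial: Trial, rate: float = ANALYSIS_RATE_HZ) -> TrialFeatures | None:
    """Build (input, target) pairs for one trial; None if too short."""
    t = downsample(trial, rate)
    n = t.n_samples
    if n < 3:
        logger.info("trial %s: only %d samples at %g Hz, skipped", trial.trial_id, n, rate)
        return None
    a = t.attacker_xy
    d = t.defender_xy
    va = np.diff(a, axis=0)  # va[i] = displacement ending at sample i+1
    vd = np.diff(d, axis=0)
    # steps t = 1 .. n-2: velocity ending at t, target displacement t -> t+1
    X = np.concatenate([va[:-1], vd[:-1], a[1:-1] - d[1:-1]], axis=1)
    Y = va[1:]
    return TrialFeatures(
        trial_id=trial.trial_id,
        defender_participant=trial.defender_participant,
        condition=trial.condition.value,
        X=X,
        Y=Y,
        attacker_xy=a,
        defender_xy=d,
        rate=rate,
    )


def build_inputs(ts: TrialSet, rate: float = ANALYSIS_RATE_HZ) -> list[TrialFeatures]:
    """Per-trial feature blocks; trials too short to form a pair are skipped."""
    out = []
    n_skipped = 0
    for trial in ts:
        feats = trial_features(trial, rate)
        if feats is None:
            n_skipped += 1
            continue
        out.append(feats)
    if n_skipped:
        logger.info("build_inputs: skipped %d short trials", n_skipped)
    return out


def stack_features(features: list[TrialFeatures]) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate all per-trial pairs into (X, Y) arrays."""
    if not features:
        return np.zeros((0, 6)), np.zeros((0, 2))
    X = np.concatenate([f.X for f in features], axis=0)
    Y = np.concatenate([f.Y for f in features], axis=0)
    return X, Y
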