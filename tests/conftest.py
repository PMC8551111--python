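import numpy as np
import pytest

from pursuitkit.geometry import Condition
from pursuitkit.synthetic_data import (
    AttackerPolicyParams,
    DefenderPolicyParams,
    SimConfig,
    reference_configs,
    simulate_trialset,
)
from pursuitkit.trajectory_io import Trial, TrialSet


def make_trial(
    attacker_xy,
    defender_xy=None,
    condition="square",
    sample_rate=120.0,
    outcome="timeout",
    trial_id="t0",
    participant="p0",
):
    """Build a Trial from raw position arrays (defender defaults to rest)."""
    attacker_xy = np.asarray(attacker_xy, dtype=float)
    if defender_xy is None:
        defender_xy = np.zeros_like(attacker_xy)
    return Trial(
        trial_id=trial_id,
        participant_pair=participant,
        defender_participant=participant,
        condition=Condition(condition),
        sample_rate=sample_rate,
        attacker_xy=attacker_xy,
        defender_xy=np.asarray(defender_xy, dtype=float),
        outcome=outcome,
    )


def zigzag_trial(n_flips, period=24, step=0.04, condition="square", trial_id="zz", participant="p0", defender_flips=None):
    """Attacker vx alternates sign every ``period`` samples, ``n_flips`` times."""
    vx = []
    sign = 1.0
    for _ in range(n_flips + 1):
        vx.extend([sign * step] * period)
        sign = -sign
    vx = np.asarray(vx)
    x = np.concatenate([[0.0], np.cumsum(vx)])
    y = np.linspace(5.0, -5.0, len(x))
    att = np.c_[x, y]
    return make_trial(att, condition=condition, trial_id=trial_id, participant=participant)


@pytest.fixture
def trial_factory():
    return make_trial


@pytest.fixture(scope="session")
def small_reference_sets():
    """Modest-size reference simulations, one per condition (shared)."""
    out = {}
    for cond in ("narrow", "square", "wide"):
        cfg = reference_configs(cond, seed=11)
        cfg.n_pairs = 4
        cfg.trials_per_pair = 12
        out[cond] = simulate_trialset(cfg)
    return out


@pytest.fixture(scope="session")
def reactive_config():
    """Purely reactive defender: no anticipation, no noise, no spurious flips."""

    def _make(condition="square", seed=21, n_pairs=2, trials_per_pair=15):
        return SimConfig(
            condition=condition,
            n_pairs=n_pairs,
            trials_per_pair=trials_per_pair,
            seed=seed,
            attacker=AttackerPolicyParams(switch_hazard=1.2, goal_bias=0.5),
            defender=DefenderPolicyParams(
                reaction_delay=0.25,
                anticipation_prob=0.0,
                noise_sd=0.0,
                spurious_rate=0.0,
                delay_jitter=0.0,
                vertical_cap=0.15,
            ),
        )

    return _make


@pytest.fixture(scope="session")
def long_trial_features():
    """A trial set with trials long enough for recurrent warm-up (>55 steps)."""
    from pursuitkit.prediction_models import build_inputs

    cfg = SimConfig(
        condition="wide",
        n_pairs=1,
        trials_per_pair=6,
        seed=33,
        attacker=AttackerPolicyParams(switch_hazard=1.0, goal_bias=0.25),
        defender=DefenderPolicyParams(reaction_delay=1.0, vertical_cap=0.0),
        max_trial_duration=10.0,
    )
    ts = simulate_trialset(cfg)
    feats = [f for f in build_inputs(ts) if len(f) >= 60]
    assert feats, "expected at least one long trial"
    return feats
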