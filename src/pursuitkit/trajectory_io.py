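"""Trial data model, CSV/JSON persistence, resampling, and velocities.

On-disk layout of a trial set::

    <dir>/manifest.json          index of trials + metadata
    <dir>/<trial_id>.csv         columns: t_index, ax, ay, dx, dy

Positions are stored with ``repr`` (shortest round-trip) formatting, so a
write/read cycle reproduces float64 coordinates bit-exactly.

Velocities are expressed in cm per sample interval (forward differences),
because the predictors operate on per-time-step displacements; use
:meth:`VelocityTrack.speed_cmps` to convert to cm/s.
"""
from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .geometry import Condition, PitchGeometry

logger = logging.getLogger(__name__)

Agent = Literal["attacker", "defender"]

#: Trial outcomes. ``timeout`` marks a censored trial that hit the
#: simulator's duration cap; such trials are excluded from outcome
#: proportions but still usable for trajectory analysis.
OUTCOMES = ("catch", "endline_reached", "out_of_bounds", "timeout")

MANIFEST_NAME = "manifest.json"
_CSV_FIELDS = ("t_index", "ax", "ay", "dx", "dy")


@dataclass
class Trial:
    """One chase/escape episode: two synchronized position series."""

    trial_id: str
    participant_pair: str
    defender_participant: str
    condition: Condition
    sample_rate: float
    attacker_xy: np.ndarray
    defender_xy: np.ndarray
    outcome: str

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        self.attacker_xy = np.asarray(self.attacker_xy, dtype=np.float64)
        self.defender_xy = np.asarray(self.defender_xy, dtype=np.float64)
        if self.attacker_xy.ndim != 2 or self.attacker_xy.shape[1] != 2:
            raise ValueError(f"trial {self.trial_id}: attacker_xy must be (N, 2)")
        if self.attacker_xy.shape != self.defender_xy.shape:
            raise ValueError(
                f"trial {self.trial_id}: attacker/defender series lengths differ "
                f"({self.attacker_xy.shape[0]} vs {self.defender_xy.shape[0]})"
            )
        if len(self.attacker_xy) < 2:
            raise ValueError(f"trial {self.trial_id}: needs at least 2 samples")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"trial {self.trial_id}: unknown outcome {self.outcome!r}")

    @property
    def n_samples(self) -> int:
        return len(self.attacker_xy)

    @property
    def duration_s(self) -> float:
        return (self.n_samples - 1) / self.sample_rate

    @property
    def geometry(self) -> PitchGeometry:
        return PitchGeometry.for_condition(self.condition)

    def positions(self, agent: Agent) -> np.ndarray:
        if agent == "attacker":
            return self.attacker_xy
        if agent == "defender":
            return self.defender_xy
        raise ValueError(f"unknown agent {agent!r}")

    def validate_bounds(self, tol: float = 1e-9) -> None:
        """Check the positional invariants against the pitch rectangle.

        All defender positions must lie inside the pitch; attacker
        positions too, except possibly the final sample of a trial that
        ended by leaving the rectangle (out of bounds, or crossing the
        end line at the bottom edge).
        """
        geom = self.geometry
        hw, hh = geom.half_width + tol, geom.half_height + tol
        d = self.defender_xy
        if np.any(np.abs(d[:, 0]) > hw) or np.any(np.abs(d[:, 1]) > hh):
            raise ValueError(f"trial {self.trial_id}: defender leaves the pitch")
        a = self.attacker_xy
        if self.outcome in ("out_of_bounds", "endline_reached"):
            a = a[:-1]
        if np.any(np.abs(a[:, 0]) > hw) or np.any(np.abs(a[:, 1]) > hh):
            raise ValueError(f"trial {self.trial_id}: attacker leaves the pitch")


@dataclass
class VelocityTrack:
    """Forward-difference velocities, in cm per sample interval."""

    vx: np.ndarray
    vy: np.ndarray
    sample_rate: float

    @property
    def speed(self) -> np.ndarray:
        """Per-interval displacement magnitude (cm per sample interval)."""
        return np.hypot(self.vx, self.vy)

    @property
    def speed_cmps(self) -> np.ndarray:
        """Speed in cm/s."""
        return self.speed * self.sample_rate

    def __len__(self) -> int:
        return len(self.vx)


@dataclass
class TrialSet:
    """A collection of trials plus a tabular manifest."""

    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate trial_ids in TrialSet")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    def __getitem__(self, key: int) -> Trial:
        return self.trials[key]

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "trial_id": t.trial_id,
                    "participant_pair": t.participant_pair,
                    "defender_participant": t.defender_participant,
                    "condition": t.condition.value,
                    "outcome": t.outcome,
                    "sample_rate": t.sample_rate,
                    "n_samples": t.n_samples,
                    "duration_s": t.duration_s,
                }
                for t in self.trials
            ]
        )

    def defender_participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.defender_participant, None)
        return list(seen)

    def by_defender(self, participant: str) -> "TrialSet":
        return TrialSet([t for t in self.trials if t.defender_participant == participant])

    def by_condition(self, condition: Condition | str) -> "TrialSet":
        cond = Condition(condition)
        return TrialSet([t for t in self.trials if t.condition == cond])

    def conditions(self) -> list[Condition]:
        seen: dict[Condition, None] = {}
        for t in self.trials:
            seen.setdefault(t.condition, None)
        return list(seen)


# ---------------------------------------------------------------------------
# persistence


def write_trialset(ts: TrialSet, path: str | Path) -> None:
    """Write one CSV per trial plus a JSON manifest under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for trial in ts:
        csv_name = f"{trial.trial_id}.csv"
        with open(path / csv_name, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_FIELDS)
            for i in range(trial.n_samples):
                writer.writerow(
                    [
                        i,
                        repr(float(trial.attacker_xy[i, 0])),
                        repr(float(trial.attacker_xy[i, 1])),
                        repr(float(trial.defender_xy[i, 0])),
                        repr(float(trial.defender_xy[i, 1])),
                    ]
                )
        entries.append(
            {
                "trial_id": trial.trial_id,
                "participant_pair": trial.participant_pair,
                "defender_participant": trial.defender_participant,
                "condition": trial.condition.value,
                "sample_rate": trial.sample_rate,
                "outcome": trial.outcome,
                "n_samples": trial.n_samples,
                "duration_s": trial.duration_s,
                "csv": csv_name,
            }
        )
    manifest = {"format_version": 1, "trials": entries}
    with open(path / MANIFEST_NAME, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)


def read_trialset(path: str | Path) -> TrialSet:
    """Read a trial set written by :func:`write_trialset`.

    A directory without a manifest is fatal unless it is completely
    empty, in which case an empty TrialSet is returned with a warning.
    """
    path = Path(path)
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.exists():
        if not path.exists() or not any(path.iterdir()):
            warnings.warn(f"no manifest at {path}; returning empty TrialSet")
            return TrialSet([])
        raise FileNotFoundError(f"missing manifest file {manifest_path}")
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    trials = []
    for entry in manifest["trials"]:
        csv_path = path / entry["csv"]
        att, dfd = _read_trial_csv(csv_path, entry["trial_id"])
        trial = Trial(
            trial_id=entry["trial_id"],
            participant_pair=entry["participant_pair"],
            defender_participant=entry["defender_participant"],
            condition=Condition(entry["condition"]),
            sample_rate=entry["sample_rate"],
            attacker_xy=att,
            defender_xy=dfd,
            outcome=entry["outcome"],
        )
        if entry.get("n_samples") is not None and trial.n_samples != entry["n_samples"]:
            raise ValueError(
                f"trial {trial.trial_id}: manifest says {entry['n_samples']} samples, "
                f"CSV has {trial.n_samples}"
            )
        trials.append(trial)
    return TrialSet(trials)


def _read_trial_csv(csv_path: Path, trial_id: str) -> tuple[np.ndarray, np.ndarray]:
    if not csv_path.exists():
        raise FileNotFoundError(f"trial {trial_id}: missing CSV {csv_path}")
    att, dfd = [], []
    with open(csv_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(header) != _CSV_FIELDS:
            raise ValueError(
                f"{csv_path}:1: bad header {header!r}, expected {_CSV_FIELDS}"
            )
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 5:
                raise ValueError(f"{csv_path}:{lineno}: expected 5 columns, got {len(row)}")
            try:
                att.append((float(row[1]), float(row[2])))
                dfd.append((float(row[3]), float(row[4])))
            except ValueError as exc:
                raise ValueError(f"{csv_path}:{lineno}: non-numeric value") from exc
    return np.asarray(att), np.asarray(dfd)


# ---------------------------------------------------------------------------
# resampling and velocities


def downsample(trial: Trial, target_rate: float) -> Trial:
    """Decimate a trial to ``target_rate`` (keep every k-th sample from 0).

    Plain decimation (no filtering) so that successive samples are
    exactly ``1/target_rate`` apart.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    ratio = trial.sample_rate / target_rate
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9:
        raise ValueError(
            f"sample_rate {trial.sample_rate} not divisible by target {target_rate}"
        )
    if k == 1:
        return trial
    return replace(
        trial,
        sample_rate=target_rate,
        attacker_xy=trial.attacker_xy[::k].copy(),
        defender_xy=trial.defender_xy[::k].copy(),
    )


def velocities(trial: Trial, agent: Agent) -> VelocityTrack:
    """Forward-difference velocities of one agent, cm per sample interval."""
    pos = trial.positions(agent)
    if len(pos) < 2:
        raise ValueError(f"trial {trial.trial_id}: need >= 2 samples for velocities")
    diff = np.diff(pos, axis=0)
    return VelocityTrack(vx=diff[:, 0], vy=diff[:, 1], sample_rate=trial.sample_rate)
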