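"""Adapter for ingesting externally deposited trial data.

The exact layout of the public deposit is not documented alongside the
data, so this adapter accepts two layouts:

1. the package's own on-disk format (manifest.json + per-trial CSVs),
   which a conversion script can target; or
2. a flat directory of per-trial CSVs named
   ``<condition>_<pair>_<defender>_<trialno>.csv`` with columns
   ``ax, ay, dx, dy`` (header required, 120 Hz assumed), in which case
   outcomes are reconstructed from the task rules: contact of the disk
   edges (center distance <= 1 cm) = catch; attacker crossing the end
   line = endline_reached; attacker outside the pitch = out_of_bounds.
"""
from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np

from .geometry import Condition, PitchGeometry
from .trajectory_io import MANIFEST_NAME, Trial, TrialSet, read_trialset

logger = logging.getLogger(__name__)


def classify_outcome(trial_like: Trial) -> str:
    """Reconstruct the outcome of a trial from its final positions."""
    geom = trial_like.geometry
    a = trial_like.attacker_xy[-1]
    d = trial_like.defender_xy[-1]
    if np.hypot(*(a - d)) <= geom.disk_diameter + 1e-6:
        return "catch"
    if a[1] <= -geom.half_height + 1e-6:
        return "endline_reached"
    if not geom.contains(a[0], a[1]):
        return "out_of_bounds"
    return "timeout"


def ingest_directory(path: str | Path, sample_rate: float = 120.0) -> TrialSet:
    """Load a deposited dataset from ``path`` (see module docstring)."""
    path = Path(path)
    if (path / MANIFEST_NAME).exists():
        return read_trialset(path)
    csvs = sorted(path.glob("*.csv"))
    if not csvs:
        raise FileNotFoundError(
            f"{path} contains neither a {MANIFEST_NAME} nor per-trial CSV files"
        )
    trials = []
    for csv_path in csvs:
        parts = csv_path.stem.split("_")
        if len(parts) < 4:
            raise ValueError(
                f"{csv_path.name}: expected <condition>_<pair>_<defender>_<trial>.csv"
            )
        condition = Condition(parts[0])
        att, dfd = _read_xy_csv(csv_path)
        trial = Trial(
            trial_id=csv_path.stem,
            participant_pair=parts[1],
            defender_participant=parts[2],
            condition=condition,
            sample_rate=sample_rate,
            attacker_xy=att,
            defender_xy=dfd,
            outcome="timeout",  # placeholder; reconstructed below
        )
        trial.outcome = classify_outcome(trial)
        trials.append(trial)
    logger.info("ingested %d trials from %s", len(trials), path)
    return TrialSet(trials)


def _read_xy_csv(csv_path: Path) -> tuple[np.ndarray, np.ndarray]:
    att, dfd = [], []
    with open(csv_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{csv_path}: empty file")
        cols = [c.strip().lower() for c in header]
        try:
            ia, ja = cols.index("ax"), cols.index("ay")
            id_, jd = cols.index("dx"), cols.index("dy")
        except ValueError as exc:
            raise ValueError(f"{csv_path}: header must contain ax, ay, dx, dy") from exc
        for row in reader:
            att.append((float(row[ia]), float(row[ja])))
            dfd.append((float(row[id_]), float(row[jd])))
    return np.asarray(att), np.asarray(dfd)
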