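"""Serialization of trial sets and trajectories.

One CSV dialect everywhere: comma-separated, UTF-8, header row, '.'
decimal, empty field = missing.  Every CSV gets a JSON sidecar carrying
the config fingerprint, master seed and artifact version so any output can
be regenerated from its metadata alone.  Absent reaction times are written
as empty fields (never 0) and read back as absent.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .decision import TrialOutcome, TrialSet
from .network import StateTrajectory

__all__ = [
    "write_trials",
    "read_trials",
    "write_trajectory",
    "write_sidecar",
]

TRIAL_COLUMNS = ("trial", "condition", "label", "rt_ms", "crossed", "seed")


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, (bool, np.bool_)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        return repr(float(x))
    if isinstance(x, np.integer):
        return str(int(x))
    return str(x)


def write_sidecar(path, *, master_seed: Optional[int] = None,
                  fingerprint: str = "", extra: Optional[dict] = None) -> Path:
    """JSON sidecar (<path>.meta.json) with provenance for one artifact."""
    meta = {
        "artifact_version": __version__,
        "master_seed": master_seed,
        "config_fingerprint": fingerprint,
    }
    if extra:
        meta.update(extra)
    side = Path(str(path) + ".meta.json")
    side.write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n")
    return side


def write_trials(ts: TrialSet, path) -> Path:
    """Write a trial set as CSV plus JSON sidecar; see :func:`read_trials`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(TRIAL_COLUMNS)
        for k, o in enumerate(ts.outcomes):
            w.writerow([k, o.condition, o.label, _fmt(o.rt),
                        _fmt(o.crossed), _fmt(o.seed)])
    write_sidecar(path, master_seed=ts.base_seed, fingerprint=ts.fingerprint,
                  extra={"n": ts.n, "metadata": ts.metadata})
    return path


def read_trials(path) -> TrialSet:
    """Read back a trial set written by :func:`write_trials` (field-equal)."""
    path = Path(path)
    outcomes = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if tuple(reader.fieldnames or ()) != TRIAL_COLUMNS:
            raise ValueError(f"{path}: unexpected columns {reader.fieldnames}")
        for row in reader:
            rt = float(row["rt_ms"]) if row["rt_ms"] != "" else None
            seed = int(row["seed"]) if row["seed"] != "" else None
            outcomes.append(TrialOutcome(
                label=row["label"], rt=rt, crossed=bool(int(row["crossed"])),
                condition=row["condition"], seed=seed,
            ))
    meta_path = Path(str(path) + ".meta.json")
    base_seed, fingerprint, metadata = None, "", {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        base_seed = meta.get("master_seed")
        fingerprint = meta.get("config_fingerprint", "")
        metadata = meta.get("metadata", {})
    return TrialSet(outcomes=tuple(outcomes), n=len(outcomes),
                    base_seed=base_seed, fingerprint=fingerprint,
                    metadata=metadata)


def write_trajectory(traj: StateTrajectory, path) -> Path:
    """TSV trajectory export (time_ms, d_rate, i_rate) with JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["time_ms", "d_rate", "i_rate"])
        for t, d, i in zip(traj.times, traj.d_rate, traj.i_rate):
            w.writerow([repr(float(t)), repr(float(d)), repr(float(i))])
    write_sidecar(path, master_seed=traj.seed,
                  fingerprint=traj.params_fingerprint)
    return path
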