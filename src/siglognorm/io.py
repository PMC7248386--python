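"""File formats: trajectory CSV dialect, session manifests, reports.

Trajectory CSV: comma separated, '.' decimal, '#'-prefixed ``key: value``
metadata lines before the ``t,x,y`` header.  Required metadata keys:
``units_time`` (must be ``s``), ``units_xy`` (must be ``mm``) and
``sample_rate_hz``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import PopulationConfig, Trajectory, default_population_config

__all__ = [
    "TrajectoryParseError",
    "write_trajectory",
    "read_trajectory",
    "write_manifest",
    "read_manifest",
    "write_report_json",
    "load_config",
]

REQUIRED_METADATA = ("units_time", "units_xy", "sample_rate_hz")


class TrajectoryParseError(ValueError):
    """Raised with the offending line number when a trajectory CSV is bad."""

    def __init__(self, path, line: int | None, message: str):
        self.path = str(path)
        self.line = line
        where = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{where}: {message}")


def write_trajectory(trajectory: Trajectory, path: str | Path) -> Path:
    """Write one trial to the trajectory CSV dialect."""
    path = Path(path)
    meta = {
        "trial_id": trajectory.trial_id,
        "test_type": trajectory.test_type,
        "participant": trajectory.participant,
        "fatigue_type": trajectory.fatigue_type,
        "condition": trajectory.condition,
        "stimulus_time": trajectory.stimulus_time,
        "sample_rate_hz": trajectory.sample_rate_hz,
        "units_time": "s",
        "units_xy": "mm",
    }
    with path.open("w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("t,x,y\n")
        for t, x, y in zip(trajectory.t, trajectory.x, trajectory.y):
            fh.write(f"{float(t)!r},{float(x)!r},{float(y)!r}\n")
    return path


def read_trajectory(path: str | Path) -> Trajectory:
    """Parse and validate a trajectory CSV; errors carry line numbers."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[float, float, float]] = []
    header_line = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if header_line is not None:
                    raise TrajectoryParseError(path, lineno, "metadata after header")
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
                continue
            if header_line is None:
                cols = [c.strip() for c in line.split(",")]
                if cols != ["t", "x", "y"]:
                    raise TrajectoryParseError(
                        path, lineno, f"expected header 't,x,y', got {line!r}")
                header_line = lineno
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise TrajectoryParseError(path, lineno, f"expected 3 columns, got {len(parts)}")
            try:
                rows.append(tuple(float(p) for p in parts))
            except ValueError:
                raise TrajectoryParseError(path, lineno, f"non-numeric value in {line!r}")
    if header_line is None:
        raise TrajectoryParseError(path, None, "missing 't,x,y' header")
    for key in REQUIRED_METADATA:
        if key not in meta:
            raise TrajectoryParseError(path, None, f"missing required metadata key {key!r}")
    if meta["units_time"] != "s" or meta["units_xy"] != "mm":
        raise TrajectoryParseError(
            path, None,
            f"units must be s/mm, got {meta['units_time']}/{meta['units_xy']}")
    data = np.asarray(rows, dtype=float)
    if data.shape[0] < 2:
        raise TrajectoryParseError(path, None, "need at least two samples")
    t = data[:, 0]
    steps = np.diff(t)
    bad = np.nonzero(steps <= 0)[0]
    if bad.size:
        raise TrajectoryParseError(path, header_line + int(bad[0]) + 2,
                                   "time column is not strictly increasing")
    try:
        return Trajectory(
            trial_id=meta.get("trial_id", path.stem),
            test_type=meta.get("test_type", "unknown"),
            participant=meta.get("participant", "unknown"),
            fatigue_type=meta.get("fatigue_type", "unknown"),
            condition=meta.get("condition", "unknown"),
            t=t, x=data[:, 1], y=data[:, 2],
            stimulus_time=float(meta.get("stimulus_time", 0.0)),
        )
    except ValueError as exc:
        raise TrajectoryParseError(path, None, str(exc))


def write_manifest(trials: list[Trajectory], directory: str | Path,
                   study_id: str = "synthetic", seed: int | None = None,
                   config: PopulationConfig | None = None) -> Path:
    """Write every trial CSV plus a JSON session manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for trial in trials:
        fname = f"{trial.trial_id}.csv"
        write_trajectory(trial, directory / fname)
        entries.append({
            "path": fname,
            "trial_id": trial.trial_id,
            "participant": trial.participant,
            "fatigue_type": trial.fatigue_type,
            "condition": trial.condition,
            "test_type": trial.test_type,
        })
    manifest = {
        "study_id": study_id,
        "participants": sorted({t.participant for t in trials}),
        "seed": seed,
        "trials": entries,
    }
    if config is not None:
        manifest["config"] = _config_snapshot(config)
    out = directory / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2))
    return out


def read_manifest(path: str | Path) -> tuple[dict, list[Trajectory]]:
    """Load a manifest and every trajectory it references.

    Duplicate trial keys or missing files abort with a named error.
    """
    path = Path(path)
    manifest = json.loads(path.read_text())
    seen = set()
    trials = []
    for entry in manifest["trials"]:
        key = (entry["participant"], entry["fatigue_type"], entry["condition"],
               entry["test_type"], entry["trial_id"])
        if key in seen:
            raise ValueError(f"duplicate trial in manifest: {key}")
        seen.add(key)
        trial_path = path.parent / entry["path"]
        if not trial_path.exists():
            raise FileNotFoundError(f"manifest references missing file: {trial_path}")
        trials.append(read_trajectory(trial_path))
    return manifest, trials


def _config_snapshot(config: PopulationConfig) -> dict:
    snap = {}
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if f.name == "roles":
            snap["roles"] = {
                "|".join(key): {name: [spec.mean, spec.sd]
                                for name, spec in role.params().items()}
                for key, role in value.items()
            }
        else:
            snap[f.name] = value
    return snap


def write_report_json(reports: dict, path: str | Path) -> Path:
    """Serialize an analysis result set (reports + summaries) to JSON."""
    path = Path(path)

    def default(obj):
        if hasattr(obj, "to_dict"):
            return obj.to_dict()
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict(orient="records")
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"cannot serialize {type(obj)!r}")

    serializable = {k: v for k, v in reports.items()
                    if k not in ("session", "components", "trials", "classified")}
    path.write_text(json.dumps(serializable, indent=2, default=default, allow_nan=True))
    return path


def load_config(path: str | Path | None) -> PopulationConfig:
    """Build a population config from a YAML/JSON override file.

    The file may set any scalar field of :class:`PopulationConfig`
    (``n_participants``, ``strokes_per_test``, ``oscillation_duration_s``,
    ``sample_rate_hz``, ``noise_snr_db``, ...); role distributions keep
    their defaults.
    """
    if path is None:
        return default_population_config()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    allowed = {f.name for f in dataclasses.fields(PopulationConfig)} - {"roles"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return default_population_config(**raw)
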