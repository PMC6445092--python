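"""File schemas, configuration loading and run manifests."""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .protocol import TRIAL_COLUMNS

__all__ = [
    "SchemaError",
    "read_trials",
    "write_trials",
    "load_config",
    "write_manifest",
]

#: Columns every trial-log CSV must provide for the analysis pipeline.
REQUIRED_TRIAL_COLUMNS = [
    "subject_id",
    "session_feedback",
    "run_index",
    "run_type",
    "cue",
    "true_stimulus",
    "decision",
]


class SchemaError(ValueError):
    """A file does not match the expected schema; names the offenders."""


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial-log CSV, checking the required columns are present."""
    trials = pd.read_csv(path)
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial log {path} is missing columns: {missing}")
    return trials


def write_trials(trials: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ordered = [c for c in TRIAL_COLUMNS if c in trials.columns]
    extra = [c for c in trials.columns if c not in ordered]
    trials[ordered + extra].to_csv(path, index=False)
    return path


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SchemaError(f"config {path} must be a mapping, got {type(data).__name__}")
    return data


def validate_config_keys(data: dict, config_cls) -> dict:
    """Reject unknown keys against a dataclass's field names."""
    allowed = {f.name for f in dataclasses.fields(config_cls)}
    unknown = sorted(set(data) - allowed)
    if unknown:
        raise SchemaError(
            f"unknown config keys for {config_cls.__name__}: {unknown}"
        )
    return data


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: dict,
    seed: int | None,
    outputs: list[Path],
) -> Path:
    """Write a JSON manifest listing the run's configuration and outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "command": command,
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": [
            {"path": str(p.relative_to(out_dir)), "sha256": _sha256(p)}
            for p in outputs
        ],
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
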