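"""Readers, writers and run configuration.

CSV is the canonical interchange format: a long trial-response table
(unit_id, [unit_type], stimulus_id, trial, response_hz) paired with a
stimulus-metadata table (stimulus_id, secretion, strain, state, dilution);
spike-event tables use (unit_id, stimulus_id, trial, spike_time_s).
MATLAB .mat arrays (units x stimuli x trials, in any dimension order) are
supported read-only through a mapping configuration, since published
single-trial datasets in this field commonly ship as MAT files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.io import loadmat

from .core import (
    AnalysisWindows,
    StimulusDescriptor,
    TrialResponseTable,
    stimuli_from_frame,
    stimuli_to_frame,
)


# ---------------------------------------------------------------------------
# CSV round trips
# ---------------------------------------------------------------------------

def write_trial_responses(
    table: TrialResponseTable, responses_csv: str | Path, stimuli_csv: str | Path
) -> None:
    table.to_frame().to_csv(responses_csv, index=False)
    stimuli_to_frame(table.stimuli).to_csv(stimuli_csv, index=False)


def read_trial_responses(
    responses_csv: str | Path, stimuli_csv: str | Path
) -> TrialResponseTable:
    """Load and validate a trial-response table and its stimulus metadata.

    Raises on missing columns, duplicate (unit, stimulus, trial) keys,
    responses referencing unknown stimuli, and missing unit x stimulus
    cells (the offending cells are named).
    """
    frame = pd.read_csv(responses_csv)
    stimuli = stimuli_from_frame(pd.read_csv(stimuli_csv))
    if frame.empty:
        raise ValueError(f"{responses_csv}: no response rows")
    if frame["response_hz"].isna().any():
        raise ValueError(f"{responses_csv}: non-numeric or missing response values")
    return TrialResponseTable.from_frame(frame, stimuli)


def write_spikes(spikes: pd.DataFrame, path: str | Path) -> None:
    spikes.to_csv(path, index=False)


def read_spikes(path: str | Path) -> pd.DataFrame:
    spikes = pd.read_csv(path)
    required = {"unit_id", "stimulus_id", "trial", "spike_time_s"}
    missing = required - set(spikes.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return spikes


# ---------------------------------------------------------------------------
# MAT loader
# ---------------------------------------------------------------------------

@dataclass
class MatMapping:
    """How to interpret a MAT file's arrays as a trial-response table.

    ``array`` names the numeric array holding the responses; ``dims`` gives
    the meaning of its axes as a permutation of ("units", "stimuli",
    "trials").  Stimulus metadata comes from a CSV path or a descriptor
    list; unit ids are generated when the file provides none.
    """

    array: str
    dims: tuple[str, str, str] = ("units", "stimuli", "trials")
    stimuli: str | Sequence[StimulusDescriptor] | None = None
    unit_ids_array: str | None = None
    max_trials: int = 20  # sanity bound: more "trials" than this means wrong dims

    def __post_init__(self) -> None:
        if sorted(self.dims) != ["stimuli", "trials", "units"]:
            raise ValueError("dims must be a permutation of units/stimuli/trials")


def read_matfile_responses(path: str | Path, mapping: MatMapping) -> TrialResponseTable:
    """Load single-trial responses from a MATLAB (v5/v7) .mat file."""
    contents = loadmat(path)
    if mapping.array not in contents:
        available = [k for k in contents if not k.startswith("__")]
        raise KeyError(f"array {mapping.array!r} not in {path} (found {available})")
    arr = np.asarray(contents[mapping.array], dtype=float)
    if arr.ndim != 3:
        raise ValueError(f"array {mapping.array!r} is {arr.ndim}-D, expected 3-D")
    order = [mapping.dims.index(d) for d in ("units", "stimuli", "trials")]
    arr = np.transpose(arr, order)
    if arr.shape[2] > mapping.max_trials:
        raise ValueError(
            f"{arr.shape[2]} trials exceeds the plausible bound {mapping.max_trials}; "
            "check the dimension mapping"
        )
    if isinstance(mapping.stimuli, (str, Path)):
        stimuli = stimuli_from_frame(pd.read_csv(mapping.stimuli))
    elif mapping.stimuli is not None:
        stimuli = list(mapping.stimuli)
    else:
        raise ValueError("mapping must supply stimulus metadata")
    if mapping.unit_ids_array and mapping.unit_ids_array in contents:
        unit_ids = [str(u) for u in np.ravel(contents[mapping.unit_ids_array])]
    else:
        unit_ids = [f"u{i:03d}" for i in range(arr.shape[0])]
    return TrialResponseTable(arr, stimuli, unit_ids)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Defaults of the full analysis, serializable to/from YAML."""

    windows: AnalysisWindows = field(default_factory=AnalysisWindows)
    alpha: float = 0.05
    n_train: int = 100
    n_test: int = 100
    n_cycles: int = 10
    max_epochs: int = 100
    n_shuffles: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("n_train", "n_test", "n_cycles", "max_epochs", "n_shuffles"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "windows" in d and isinstance(d["windows"], dict):
            d["windows"] = AnalysisWindows(**d["windows"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(
    results: dict[str, Any],
    out_dir: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> Path:
    """Write an analysis bundle: results JSON plus per-table CSVs.

    Any value that is a DataFrame is written as ``<key>.csv``; everything
    else lands in ``report.json``.  The report always records the config
    hash and seed so a run can be reproduced exactly.  Missing sections
    (values of None) are listed explicitly rather than dropped.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload: dict[str, Any] = {
        "config": config.to_dict() if config else None,
        "config_digest": config.digest() if config else None,
        "seed": seed,
        "missing": sorted(k for k, v in results.items() if v is None),
        "results": {},
    }
    for key, value in sorted(results.items()):
        if value is None:
            continue
        if isinstance(value, pd.DataFrame):
            value.to_csv(out / f"{key}.csv", index=False)
            payload["results"][key] = f"{key}.csv"
        else:
            payload["results"][key] = _jsonable(value)
    path = out / "report.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
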