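"""Core containers for stimulus metadata and trial-response data.

The unit of analysis throughout the package is the *single-trial response*:
the change in a unit's mean firing rate (Hz) between a post-stimulation
window and a pre-stimulation baseline.  Responses are organised as a
units x stimuli x trials array, with each stimulus annotated by the factor
levels of its donor (secretion, strain, reproductive state, dilution).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SECRETIONS = ("urine", "vaginal_secretion", "saliva")
STRAINS = ("BC", "C57")
STATES = ("estrus", "non_estrus")
DILUTIONS = ("L", "M", "H", "undiluted")

#: Canonical factor name -> allowed levels.
FACTOR_LEVELS = {
    "secretion": SECRETIONS,
    "strain": STRAINS,
    "state": STATES,
    "dilution": DILUTIONS,
}


@dataclass(frozen=True)
class StimulusDescriptor:
    """Factor labels of one stimulus within a panel.

    Parameters
    ----------
    stimulus_id
        Unique identifier within a panel.
    secretion, strain, state, dilution
        Donor secretion type, donor strain (BALB/c "BC" or C57BL/6 "C57"),
        donor reproductive state, and the dilution level at presentation
        ("L"/"M"/"H" for diluted series, "undiluted" otherwise).
    """

    stimulus_id: str
    secretion: str
    strain: str
    state: str
    dilution: str

    def __post_init__(self) -> None:
        for factor in FACTOR_LEVELS:
            value = getattr(self, factor)
            if value not in FACTOR_LEVELS[factor]:
                raise ValueError(
                    f"invalid {factor} {value!r}; expected one of {FACTOR_LEVELS[factor]}"
                )

    def level(self, factor: str) -> str:
        """Return this stimulus's level of ``factor`` (e.g. ``'strain'``)."""
        if factor not in FACTOR_LEVELS:
            raise KeyError(f"unknown factor {factor!r}")
        return getattr(self, factor)


@dataclass(frozen=True)
class AnalysisWindows:
    """Time windows (seconds) around sympathetic-trunk stimulation at t=0.

    The stimulus is applied to the nostril at ``application_time`` (default
    -20 s); pump activation drives it into the vomeronasal organ at t=0.
    Rate change compares ``(0, response_end]`` against
    ``[baseline_start, 0)``; the significance screen uses the quiet span
    ``[baseline_start, application_time)`` before nostril application.
    """

    baseline_start: float = -30.0
    application_time: float = -20.0
    response_end: float = 40.0

    def __post_init__(self) -> None:
        if not (self.baseline_start < self.application_time < 0.0 < self.response_end):
            raise ValueError(
                "windows must satisfy baseline_start < application_time < 0 < response_end"
            )

    @property
    def baseline_duration(self) -> float:
        return -self.baseline_start

    @property
    def significance_baseline(self) -> tuple[float, float]:
        """Span used for the per-trial baseline rate in the significance screen."""
        return (self.baseline_start, self.application_time)


def _as_unique_list(values: Iterable[str], what: str) -> list[str]:
    out = list(values)
    if len(set(out)) != len(out):
        raise ValueError(f"duplicate {what}")
    return out


@dataclass
class TrialResponseTable:
    """Single-trial rate changes for a recorded or simulated population.

    ``responses`` has shape (n_units, n_stimuli, max_trials); absent trials
    (for stimuli presented fewer times) are NaN.  Every unit x stimulus cell
    must contain at least one finite trial.
    """

    responses: np.ndarray
    stimuli: list[StimulusDescriptor]
    unit_ids: list[str]
    unit_types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 3:
            raise ValueError("responses must be (n_units, n_stimuli, n_trials)")
        n_units, n_stimuli, _ = self.responses.shape
        if len(self.stimuli) != n_stimuli:
            raise ValueError("stimulus metadata does not match responses")
        self.unit_ids = _as_unique_list(self.unit_ids, "unit ids")
        if len(self.unit_ids) != n_units:
            raise ValueError("unit ids do not match responses")
        _as_unique_list((s.stimulus_id for s in self.stimuli), "stimulus ids")
        if not self.unit_types:
            self.unit_types = ["single"] * n_units
        if len(self.unit_types) != n_units:
            raise ValueError("unit types do not match responses")
        if np.isinf(self.responses).any():
            raise ValueError("responses must be finite or NaN")
        if (self.trial_counts() < 1).any():
            raise ValueError("every unit x stimulus cell needs at least one trial")

    # -- basic geometry -------------------------------------------------
    @property
    def n_units(self) -> int:
        return self.responses.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.responses.shape[1]

    @property
    def stimulus_ids(self) -> list[str]:
        return [s.stimulus_id for s in self.stimuli]

    def trial_counts(self) -> np.ndarray:
        """Finite-trial count per unit x stimulus cell."""
        return np.isfinite(self.responses).sum(axis=2)

    def stimulus_index(self, stimulus_id: str) -> int:
        try:
            return self.stimulus_ids.index(stimulus_id)
        except ValueError:
            raise KeyError(f"unknown stimulus {stimulus_id!r}") from None

    # -- views ----------------------------------------------------------
    def subset_units(self, indices: Sequence[int]) -> "TrialResponseTable":
        idx = np.asarray(indices, dtype=int)
        return TrialResponseTable(
            responses=self.responses[idx],
            stimuli=list(self.stimuli),
            unit_ids=[self.unit_ids[i] for i in idx],
            unit_types=[self.unit_types[i] for i in idx],
        )

    def subset_stimuli(self, stimulus_ids: Sequence[str]) -> "TrialResponseTable":
        idx = [self.stimulus_index(s) for s in stimulus_ids]
        return TrialResponseTable(
            responses=self.responses[:, idx, :],
            stimuli=[self.stimuli[i] for i in idx],
            unit_ids=list(self.unit_ids),
            unit_types=list(self.unit_types),
        )

    def mean_matrix(self) -> np.ndarray:
        """Mean-across-trials response matrix, shape (n_units, n_stimuli)."""
        return np.nanmean(self.responses, axis=2)

    # -- interchange -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per (unit, stimulus, trial) response."""
        rows = []
        for u, unit in enumerate(self.unit_ids):
            for s, stim in enumerate(self.stimuli):
                for t, value in enumerate(self.responses[u, s]):
                    if np.isfinite(value):
                        rows.append(
                            (unit, self.unit_types[u], stim.stimulus_id, t, value)
                        )
        return pd.DataFrame(
            rows, columns=["unit_id", "unit_type", "stimulus_id", "trial", "response_hz"]
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, stimuli: Sequence[StimulusDescriptor]
    ) -> "TrialResponseTable":
        """Build a table from long format; raises on duplicate or missing cells."""
        required = {"unit_id", "stimulus_id", "trial", "response_hz"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        dupes = frame.duplicated(subset=["unit_id", "stimulus_id", "trial"])
        if dupes.any():
            bad = frame.loc[dupes, ["unit_id", "stimulus_id", "trial"]].iloc[0]
            raise ValueError(
                f"duplicate (unit, stimulus, trial) key: {tuple(bad)}"
            )
        stimuli = list(stimuli)
        stim_ids = [s.stimulus_id for s in stimuli]
        unknown = set(frame["stimulus_id"]) - set(stim_ids)
        if unknown:
            raise ValueError(f"responses reference unknown stimuli: {sorted(unknown)}")
        unit_ids = list(pd.unique(frame["unit_id"]))
        if "unit_type" in frame.columns:
            type_map = (
                frame.drop_duplicates("unit_id").set_index("unit_id")["unit_type"]
            )
            unit_types = [str(type_map[u]) for u in unit_ids]
        else:
            unit_types = ["single"] * len(unit_ids)

        counts = frame.groupby(["unit_id", "stimulus_id"]).size()
        absent = [
            (u, s)
            for u in unit_ids
            for s in stim_ids
            if (u, s) not in counts.index
        ]
        if absent:
            raise ValueError(
                "missing unit x stimulus cells: "
                + ", ".join(f"({u}, {s})" for u, s in absent[:10])
            )
        max_trials = int(counts.max())
        data = np.full((len(unit_ids), len(stim_ids), max_trials), np.nan)
        u_idx = {u: i for i, u in enumerate(unit_ids)}
        s_idx = {s: i for i, s in enumerate(stim_ids)}
        for (u, s), group in frame.groupby(["unit_id", "stimulus_id"], sort=False):
            vals = group.sort_values("trial")["response_hz"].to_numpy(dtype=float)
            data[u_idx[u], s_idx[s], : len(vals)] = vals
        return cls(data, stimuli, unit_ids, unit_types)


def stimuli_to_frame(stimuli: Sequence[StimulusDescriptor]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.stimulus_id, s.secretion, s.strain, s.state, s.dilution)
            for s in stimuli
        ],
        columns=["stimulus_id", "secretion", "strain", "state", "dilution"],
    )


def stimuli_from_frame(frame: pd.DataFrame) -> list[StimulusDescriptor]:
    required = {"stimulus_id", "secretion", "strain", "state", "dilution"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"stimulus metadata missing columns: {sorted(missing)}")
    return [
        StimulusDescriptor(
            stimulus_id=str(row.stimulus_id),
            secretion=str(row.secretion),
            strain=str(row.strain),
            state=str(row.state),
            dilution=str(row.dilution),
        )
        for row in frame.itertuples(index=False)
    ]
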