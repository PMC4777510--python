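import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from aobdecode import (
    PopulationSpec,
    generate_population,
    generate_stimulus_panel,
    simulate_trials,
)
from aobdecode.core import StimulusDescriptor, TrialResponseTable


@pytest.fixture
def set1_panel():
    return generate_stimulus_panel(1)


@pytest.fixture
def set3_panel():
    return generate_stimulus_panel(3)


@pytest.fixture
def structured_table(set1_panel):
    """92-unit population with strain/state tuning and the balanced
    strain x state sign-flip interaction (the study-condition default)."""
    pop = generate_population(PopulationSpec(seed=11))
    return simulate_trials(pop, set1_panel, seed=12)


@pytest.fixture
def null_table(set1_panel):
    """Zero-effect population: responses are pure trial noise."""
    spec = PopulationSpec(
        seed=21, fraction_tuned={"strain": 0.0, "state": 0.0, "secretion": 0.0}
    )
    pop = generate_population(spec)
    return simulate_trials(pop, set1_panel, seed=22)


def make_tiny_table(responses, panel=None):
    """Wrap a (units x stimuli x trials) array with minimal metadata."""
    responses = np.asarray(responses, dtype=float)
    n_stim = responses.shape[1]
    if panel is None:
        panel = [
            StimulusDescriptor(
                stimulus_id=f"s{i}",
                secretion="urine",
                strain="BC" if i % 2 == 0 else "C57",
                state="estrus",
                dilution="undiluted",
            )
            for i in range(n_stim)
        ]
    unit_ids = [f"u{i}" for i in range(responses.shape[0])]
    return TrialResponseTable(responses, panel, unit_ids)
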