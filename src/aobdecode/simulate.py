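"""Synthetic AOB populations with ground-truth trait tuning.

The generator emulates the measured quantity of the recordings — the
units x stimuli x trials table of firing-rate changes — under the factorial
stimulus designs used experimentally: two diluted series (vaginal
secretions, urine; 2 strains x 2 reproductive states x 3 dilutions) and one
undiluted multi-secretion panel (3 secretions x 2 strains x 2 states).

Each simulated unit has a baseline rate and additive tuning effects (Hz)
for the strain, state and secretion factors.  A configurable fraction of
state-tuned units has a strain x state interaction: the sign of the state
effect flips between the two strains, the structure that makes reproductive
state hard to generalise across strains.  Dilution scales the stimulus-
evoked effect multiplicatively.  Trial-to-trial variability is additive
Gaussian on the rate change; a Poisson spike-train option supports
end-to-end testing of the response-quantification stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    SECRETIONS,
    STRAINS,
    STATES,
    AnalysisWindows,
    StimulusDescriptor,
    TrialResponseTable,
)

#: Multiplicative gain applied to stimulus-evoked effects per dilution level.
DEFAULT_DILUTION_GAIN = {"L": 0.5, "M": 1.0, "H": 2.0, "undiluted": 1.0}

_SET_SECRETION = {1: "vaginal_secretion", 2: "urine"}


def generate_stimulus_panel(set_id: int) -> list[StimulusDescriptor]:
    """Build the stimulus panel of one of the three experimental designs.

    Sets 1 (vaginal secretions) and 2 (urine): 2 strains x 2 states x 3
    dilutions (L, M, H) of a single secretion.  Set 3: urine, vaginal
    secretions and saliva from both strains and states, all undiluted.
    Ordering is deterministic (strain-major, then state, then dilution or
    secretion).
    """
    if set_id in (1, 2):
        secretion = _SET_SECRETION[set_id]
        return [
            StimulusDescriptor(
                stimulus_id=f"{secretion}_{strain}_{state}_{dilution}",
                secretion=secretion,
                strain=strain,
                state=state,
                dilution=dilution,
            )
            for strain in STRAINS
            for state in STATES
            for dilution in ("L", "M", "H")
        ]
    if set_id == 3:
        return [
            StimulusDescriptor(
                stimulus_id=f"{secretion}_{strain}_{state}_undiluted",
                secretion=secretion,
                strain=strain,
                state=state,
                dilution="undiluted",
            )
            for secretion in SECRETIONS
            for strain in STRAINS
            for state in STATES
        ]
    raise ValueError(f"unknown stimulus set {set_id!r}; expected 1, 2 or 3")


@dataclass
class PopulationSpec:
    """Parameters of a simulated AOB unit population.

    Tuning effects are magnitudes in Hz; each tuned unit receives a random
    sign.  ``fraction_tuned`` gives the probability that a unit carries an
    effect for a factor; ``interaction_fraction`` is the fraction of
    state-tuned units whose state effect flips sign between strains (an
    exactly balanced half by default, so that a classifier trained on one
    strain carries no net state signal for the other).
    """

    n_units: int = 92
    baseline_rate_mean: float = 4.0
    baseline_rate_sd: float = 2.0
    strain_effect: float = 2.0
    state_effect: float = 2.0
    secretion_effect: float = 2.0
    fraction_tuned: dict = field(
        default_factory=lambda: {"strain": 0.5, "state": 0.5, "secretion": 0.5}
    )
    interaction_fraction: float = 0.5
    dilution_gain: dict = field(default_factory=lambda: dict(DEFAULT_DILUTION_GAIN))
    trial_noise_sd: float = 1.0
    n_trials: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be positive")
        if self.n_trials < 2:
            raise ValueError("n_trials must be at least 2")
        if self.trial_noise_sd < 0:
            raise ValueError("trial_noise_sd must be non-negative")
        if self.baseline_rate_mean < 0 or self.baseline_rate_sd < 0:
            raise ValueError("baseline rate parameters must be non-negative")
        for factor, frac in self.fraction_tuned.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction_tuned[{factor!r}] outside [0, 1]")
        if not 0.0 <= self.interaction_fraction <= 1.0:
            raise ValueError("interaction_fraction outside [0, 1]")


@dataclass
class GroundTruthPopulation:
    """Per-unit baseline rates and additive tuning effects.

    ``state_effect`` / ``strain_effect`` are signed Hz effects applied when
    the stimulus donor is in estrus / of strain BC (zero contribution for
    the opposite level).  ``state_flips_with_strain`` marks interaction
    units, whose state effect is negated for C57 donors.
    ``secretion_effect`` maps secretion -> per-unit signed effect.
    """

    baseline: np.ndarray
    strain_effect: np.ndarray
    state_effect: np.ndarray
    state_flips_with_strain: np.ndarray
    secretion_effect: dict[str, np.ndarray]
    dilution_gain: dict[str, float]
    spec: PopulationSpec

    @property
    def n_units(self) -> int:
        return self.baseline.size

    def mean_response(self, stimulus: StimulusDescriptor) -> np.ndarray:
        """Expected rate change (Hz) of every unit for one stimulus."""
        effect = np.where(stimulus.strain == "BC", self.strain_effect, 0.0)
        state_sign = np.where(
            self.state_flips_with_strain & (stimulus.strain == "C57"), -1.0, 1.0
        )
        if stimulus.state == "estrus":
            effect = effect + state_sign * self.state_effect
        effect = effect + self.secretion_effect[stimulus.secretion]
        return self.dilution_gain[stimulus.dilution] * effect


def generate_population(spec: PopulationSpec) -> GroundTruthPopulation:
    """Draw a ground-truth population from a :class:`PopulationSpec`.

    Tuned units are Bernoulli(fraction_tuned) per factor; effect signs are
    Rademacher.  Among state-tuned units, ``round(interaction_fraction * k)``
    are flagged as strain x state interaction units (balanced count rather
    than per-unit coin flips, so sign-flip cancellation is exact).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_units
    baseline = np.clip(
        rng.normal(spec.baseline_rate_mean, spec.baseline_rate_sd, size=n), 0.0, None
    )

    def tuned_effect(fraction: float, magnitude: float) -> np.ndarray:
        mask = rng.random(n) < fraction
        signs = rng.choice([-1.0, 1.0], size=n)
        return np.where(mask, signs * magnitude, 0.0)

    strain_effect = tuned_effect(spec.fraction_tuned.get("strain", 0.0), spec.strain_effect)
    state_effect = tuned_effect(spec.fraction_tuned.get("state", 0.0), spec.state_effect)

    state_tuned = np.flatnonzero(state_effect != 0.0)
    n_flip = int(round(spec.interaction_fraction * state_tuned.size))
    flips = np.zeros(n, dtype=bool)
    if n_flip:
        flips[rng.choice(state_tuned, size=n_flip, replace=False)] = True

    sec_frac = spec.fraction_tuned.get("secretion", 0.0)
    sec_mask = rng.random(n) < sec_frac
    preferred = rng.integers(0, len(SECRETIONS), size=n)
    sec_signs = rng.choice([-1.0, 1.0], size=n)
    secretion_effect = {
        secretion: np.where(
            sec_mask & (preferred == k), sec_signs * spec.secretion_effect, 0.0
        )
        for k, secretion in enumerate(SECRETIONS)
    }

    return GroundTruthPopulation(
        baseline=baseline,
        strain_effect=strain_effect,
        state_effect=state_effect,
        state_flips_with_strain=flips,
        secretion_effect=secretion_effect,
        dilution_gain=dict(spec.dilution_gain),
        spec=spec,
    )


def simulate_trials(
    pop: GroundTruthPopulation,
    panel: list[StimulusDescriptor],
    seed: int | None = None,
) -> TrialResponseTable:
    """Simulate the units x stimuli x trials rate-change table.

    Each trial is the unit's ground-truth mean response for the stimulus
    plus independent Gaussian noise of sd ``trial_noise_sd``.
    """
    if not panel:
        raise ValueError("stimulus panel is empty")
    spec = pop.spec
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    means = np.stack([pop.mean_response(s) for s in panel], axis=1)  # units x stimuli
    noise = rng.normal(0.0, spec.trial_noise_sd, size=(pop.n_units, len(panel), spec.n_trials))
    responses = means[:, :, None] + (noise if spec.trial_noise_sd > 0 else 0.0)
    unit_ids = [f"u{i:03d}" for i in range(pop.n_units)]
    return TrialResponseTable(responses, list(panel), unit_ids)


def simulate_spike_trains(
    pop: GroundTruthPopulation,
    panel: list[StimulusDescriptor],
    windows: AnalysisWindows | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate piecewise-homogeneous Poisson spike trains per trial.

    Rates are ``baseline`` on ``[baseline_start, 0)`` and
    ``baseline + ground-truth effect`` on ``(0, response_end]`` (clipped at
    0).  Returns a long table with columns unit_id, stimulus_id, trial,
    spike_time_s; trials without spikes are simply absent from the table.
    """
    if not panel:
        raise ValueError("stimulus panel is empty")
    windows = windows or AnalysisWindows()
    rng = np.random.default_rng(pop.spec.seed if seed is None else seed)
    means = np.stack([pop.mean_response(s) for s in panel], axis=1)
    rows: list[tuple[str, str, int, float]] = []
    for u in range(pop.n_units):
        unit_id = f"u{u:03d}"
        for s, stim in enumerate(panel):
            pre_rate = pop.baseline[u]
            post_rate = max(pop.baseline[u] + means[u, s], 0.0)
            for trial in range(pop.spec.n_trials):
                for rate, lo, hi in (
                    (pre_rate, windows.baseline_start, 0.0),
                    (post_rate, 0.0, windows.response_end),
                ):
                    count = rng.poisson(rate * (hi - lo))
                    if count:
                        times = np.sort(rng.uniform(lo, hi, size=count))
                        rows.extend(
                            (unit_id, stim.stimulus_id, trial, float(t)) for t in times
                        )
    return pd.DataFrame(
        rows, columns=["unit_id", "stimulus_id", "trial", "spike_time_s"]
    )
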