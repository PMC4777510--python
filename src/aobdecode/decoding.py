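"""Perceptron decoding of donor traits from single-trial population vectors.

Each classification is defined by a :class:`DecodingTask`: a two-label map
over training stimuli and a (possibly different) map over test stimuli.
Population vectors are assembled by drawing, independently for every unit,
one of its single-trial responses for a stimulus of the requested label —
with ~5 recorded repeats per stimulus this gives an effectively unlimited
supply of distinct vectors.  The classifier is the classic online
perceptron (hard threshold, error-driven updates, samples visited in fresh
random order each epoch, at most 100 epochs), trained on 100 vectors and
tested on an independently drawn set of 100.  Because training is slightly
non-deterministic, every classification cycle is repeated (10 times by
default) and results are averaged.

Ensemble-size dependence comes from sequential unit removal: retrain after
dropping the unit with the smallest absolute weight, down to a single unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import StimulusDescriptor, TrialResponseTable

TASK_CATEGORIES = (
    "simple_pairwise",
    "cross_dilution_generalization",
    "dilution_invariant",
    "cross_strain_generalization",
    "general",
    "per_secretion",
    "cross_secretion_generalization",
    "across_secretions",
)

#: Task categories whose test stimuli differ from the training stimuli.
GENERALIZATION_CATEGORIES = (
    "cross_dilution_generalization",
    "cross_strain_generalization",
    "cross_secretion_generalization",
)


@dataclass(frozen=True)
class DecodingTask:
    """One classification or generalization test.

    ``train_map`` / ``test_map`` map stimulus_id -> binary label (0/1).
    For plain classifications the two maps coincide; for generalization
    tests the classifier trained on ``train_map`` is evaluated on stimuli
    it never saw.
    """

    name: str
    category: str
    trait: str
    train_map: Mapping[str, int]
    test_map: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.category not in TASK_CATEGORIES:
            raise ValueError(f"unknown task category {self.category!r}")
        for label, mapping in (("train", self.train_map), ("test", self.test_map)):
            if not mapping:
                raise ValueError(f"{label} map is empty")
            if set(mapping.values()) - {0, 1}:
                raise ValueError(f"{label} labels must be 0/1")

    @property
    def is_generalization(self) -> bool:
        return self.category in GENERALIZATION_CATEGORIES


@dataclass
class LinearClassifier:
    """A trained perceptron: weights (one per unit), bias, training metadata."""

    weights: np.ndarray
    bias: float
    epochs_run: int
    training_error: float
    n_updates: int

    def decide(self, X: np.ndarray) -> np.ndarray:
        """Hard-threshold decision; activations exactly 0 go to label 0."""
        return (np.asarray(X) @ self.weights + self.bias > 0.0).astype(int)

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.decide(X) == np.asarray(y)))


@dataclass
class CycleResult:
    """Accuracies and weight vectors over repeated training cycles."""

    task: DecodingTask
    accuracies: np.ndarray
    classifiers: list[LinearClassifier]
    unit_ids: list[str]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def best_accuracy(self) -> float:
        return float(np.max(self.accuracies))

    def weight_matrix(self) -> np.ndarray:
        """Weights stacked as (n_cycles, n_units)."""
        return np.stack([c.weights for c in self.classifiers])

    def mean_normalized_abs_weights(self) -> np.ndarray:
        """Mean |weight| across cycles after per-cycle L2 normalization.

        Normalization removes the arbitrary overall scale a perceptron's
        weight vector acquires from its update count, so cycles contribute
        comparably to the removal ranking.
        """
        W = self.weight_matrix()
        norms = np.linalg.norm(W, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return np.abs(W / norms).mean(axis=0)


@dataclass
class RemovalCurve:
    """Accuracy as a function of remaining ensemble size, N down to 1."""

    unit_counts: np.ndarray
    accuracies: np.ndarray
    removal_order: list[str]  # all N unit ids, in order of removal

    def accuracy_at(self, n_units: int) -> float:
        idx = np.flatnonzero(self.unit_counts == n_units)
        if idx.size == 0:
            raise KeyError(f"curve not defined at {n_units} units")
        return float(self.accuracies[idx[0]])


# ---------------------------------------------------------------------------
# Task construction
# ---------------------------------------------------------------------------

def _ids(stimuli: Sequence[StimulusDescriptor], **levels: str) -> list[str]:
    out = []
    for s in stimuli:
        if all(s.level(f) == v for f, v in levels.items()):
            out.append(s.stimulus_id)
    return out


def _label_map(
    stimuli: Sequence[StimulusDescriptor], trait: str, restrict: dict[str, str]
) -> dict[str, int]:
    from .core import FACTOR_LEVELS

    levels = FACTOR_LEVELS[trait][:2]
    mapping: dict[str, int] = {}
    for s in stimuli:
        if all(s.level(f) == v for f, v in restrict.items()):
            mapping[s.stimulus_id] = levels.index(s.level(trait))
    return mapping


def build_task_suite(
    panel: Sequence[StimulusDescriptor], trait: str
) -> list[DecodingTask]:
    """Enumerate every classification and generalization test for a panel.

    ``trait`` is ``"state"`` or ``"strain"``.  For a diluted single-secretion
    panel (designs 1-2) this yields, per trait: one simple pairwise task per
    (context level, dilution), all reciprocal cross-dilution generalization
    tests, one dilution-invariant task per context level, the reciprocal
    cross-context generalizations of those, and one general task over all
    stimuli.  The "context" is the other binary trait (strain when decoding
    state and vice versa).  For the undiluted multi-secretion panel (design
    3): per-secretion tasks, their reciprocal cross-secretion
    generalizations, and one across-secretions task.
    """
    if trait not in ("state", "strain"):
        raise ValueError("trait must be 'state' or 'strain'")
    panel = list(panel)
    other = "strain" if trait == "state" else "state"
    trait_levels = sorted({s.level(trait) for s in panel})
    if len(trait_levels) < 2:
        raise ValueError(f"panel lacks both {trait} levels (found {trait_levels})")

    secretions = list(dict.fromkeys(s.secretion for s in panel))
    dilutions = list(dict.fromkeys(s.dilution for s in panel))
    multi_secretion = len(secretions) > 1

    tasks: list[DecodingTask] = []
    if multi_secretion:
        per_secretion: dict[str, dict[str, int]] = {}
        for secretion in secretions:
            m = _label_map(panel, trait, {"secretion": secretion})
            if len(set(m.values())) == 2:
                per_secretion[secretion] = m
                tasks.append(
                    DecodingTask(
                        name=f"{trait}|{secretion}",
                        category="per_secretion",
                        trait=trait,
                        train_map=m,
                        test_map=m,
                    )
                )
        for sec_a, map_a in per_secretion.items():
            for sec_b, map_b in per_secretion.items():
                if sec_a != sec_b:
                    tasks.append(
                        DecodingTask(
                            name=f"{trait}|train:{sec_a}->test:{sec_b}",
                            category="cross_secretion_generalization",
                            trait=trait,
                            train_map=map_a,
                            test_map=map_b,
                        )
                    )
        if len(per_secretion) > 1:
            full = _label_map(panel, trait, {})
            tasks.append(
                DecodingTask(
                    name=f"{trait}|across_secretions",
                    category="across_secretions",
                    trait=trait,
                    train_map=full,
                    test_map=full,
                )
            )
        return tasks

    other_levels = list(dict.fromkeys(s.level(other) for s in panel))
    # simple pairwise: one per (context level, dilution)
    pairwise: dict[tuple[str, str], dict[str, int]] = {}
    for ctx in other_levels:
        for dil in dilutions:
            m = _label_map(panel, trait, {other: ctx, "dilution": dil})
            if len(set(m.values())) == 2:
                pairwise[(ctx, dil)] = m
                tasks.append(
                    DecodingTask(
                        name=f"{trait}|{other}={ctx},dilution={dil}",
                        category="simple_pairwise",
                        trait=trait,
                        train_map=m,
                        test_map=m,
                    )
                )
    # reciprocal cross-dilution generalizations within each context level
    for ctx in other_levels:
        for dil_a in dilutions:
            for dil_b in dilutions:
                if dil_a == dil_b:
                    continue
                if (ctx, dil_a) in pairwise and (ctx, dil_b) in pairwise:
                    tasks.append(
                        DecodingTask(
                            name=f"{trait}|{other}={ctx},train:{dil_a}->test:{dil_b}",
                            category="cross_dilution_generalization",
                            trait=trait,
                            train_map=pairwise[(ctx, dil_a)],
                            test_map=pairwise[(ctx, dil_b)],
                        )
                    )
    # dilution-invariant task per context level (needs >=2 dilutions)
    invariant: dict[str, dict[str, int]] = {}
    if len(dilutions) > 1:
        for ctx in other_levels:
            m = _label_map(panel, trait, {other: ctx})
            if len(set(m.values())) == 2:
                invariant[ctx] = m
                tasks.append(
                    DecodingTask(
                        name=f"{trait}|{other}={ctx},all_dilutions",
                        category="dilution_invariant",
                        trait=trait,
                        train_map=m,
                        test_map=m,
                    )
                )
    # reciprocal generalization across the context trait
    for ctx_a, map_a in invariant.items():
        for ctx_b, map_b in invariant.items():
            if ctx_a != ctx_b:
                tasks.append(
                    DecodingTask(
                        name=f"{trait}|train:{other}={ctx_a}->test:{other}={ctx_b}",
                        category="cross_strain_generalization",
                        trait=trait,
                        train_map=map_a,
                        test_map=map_b,
                    )
                )
    # general task across everything (only when there is something to pool)
    if len(pairwise) > 1:
        full = _label_map(panel, trait, {})
        tasks.append(
            DecodingTask(
                name=f"{trait}|general",
                category="general",
                trait=trait,
                train_map=full,
                test_map=full,
            )
        )
    return tasks


# ---------------------------------------------------------------------------
# Vector sampling and training
# ---------------------------------------------------------------------------

def sample_population_vectors(
    table: TrialResponseTable,
    label_map: Mapping[str, int],
    n: int,
    rng: np.random.Generator,
    trial_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` labeled single-trial population vectors.

    Labels are balanced (n//2 each, label 0 taking the extra vector when n
    is odd); for each vector a stimulus is drawn uniformly among that
    label's stimuli, then every unit independently contributes one of its
    trials for that stimulus (with replacement).

    ``trial_mask`` (units x stimuli x trials, boolean) optionally restricts
    which trials may be drawn — used by the held-out-trial evaluation mode.
    """
    if not label_map:
        raise ValueError("empty stimulus -> label map")
    by_label: dict[int, list[int]] = {0: [], 1: []}
    for stim_id, label in label_map.items():
        by_label[int(label)].append(table.stimulus_index(stim_id))
    if not by_label[0] or not by_label[1]:
        raise ValueError("both labels need at least one stimulus")

    allowed = np.isfinite(table.responses)
    if trial_mask is not None:
        allowed = allowed & trial_mask
    counts = allowed.sum(axis=2)
    if (counts < 1).any():
        raise ValueError("trial mask leaves an empty unit x stimulus cell")
    # allowed trial indices packed to the front, per unit x stimulus
    packed = np.argsort(~allowed, axis=2, kind="stable")

    y = np.concatenate([np.zeros(n - n // 2, dtype=int), np.ones(n // 2, dtype=int)])
    rng.shuffle(y)
    X = np.empty((n, table.n_units))
    units = np.arange(table.n_units)
    for i, label in enumerate(y):
        stims = by_label[int(label)]
        s = stims[rng.integers(len(stims))]
        r = rng.integers(0, counts[:, s])
        trial_idx = packed[units, s, r]
        X[i] = table.responses[units, s, trial_idx]
    return X, y


def train_perceptron(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    max_epochs: int = 100,
) -> LinearClassifier:
    """Online perceptron training with random sample order per epoch.

    Weights and bias start at zero.  Each epoch visits the training
    vectors in a fresh random order; a misclassified sample (decision
    ``w.x + b > 0`` -> 1, ties -> 0) triggers the update
    ``w += (t - y) x``, ``b += (t - y)``.  Training stops at the first
    error-free epoch or after ``max_epochs``.
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.isfinite(X).all():
        raise ValueError("training vectors must be finite")
    n, d = X.shape
    w = np.zeros(d)
    b = 0.0
    n_updates = 0
    epochs_run = 0
    for _ in range(max_epochs):
        epochs_run += 1
        errors = 0
        for i in rng.permutation(n):
            pred = 1 if X[i] @ w + b > 0.0 else 0
            t = y[i]
            if pred != t:
                delta = float(t - pred)
                w += delta * X[i]
                b += delta
                errors += 1
                n_updates += 1
        if errors == 0:
            break
    clf = LinearClassifier(w, b, epochs_run, 0.0, n_updates)
    clf.training_error = 1.0 - clf.accuracy(X, y)
    return clf


def run_cycles(
    task: DecodingTask,
    table: TrialResponseTable,
    rng: np.random.Generator,
    n_train: int = 100,
    n_test: int = 100,
    n_cycles: int = 10,
    max_epochs: int = 100,
    unit_indices: Sequence[int] | None = None,
    test_table: TrialResponseTable | None = None,
    holdout_trials: bool = False,
) -> CycleResult:
    """Repeat train/test cycles for one task and return per-cycle results.

    Each cycle draws an independent training set from the task's train map,
    trains a perceptron, and evaluates it on an independently drawn test
    set from the task's test map (which differs from the train map for
    generalization tests).

    By default both sets are resampled from the same recorded trials, as
    with real recordings where only ~5 repeats per stimulus exist.  Because
    shared trials let a classifier exploit trial-specific noise, two
    honest-evaluation modes are available: ``test_table`` draws the test
    vectors from a separately measured/simulated table (same units and
    stimuli), and ``holdout_trials`` reserves one trial index per cycle for
    testing, training only on the rest.
    """
    if test_table is not None and holdout_trials:
        raise ValueError("choose either test_table or holdout_trials, not both")
    sub = table if unit_indices is None else table.subset_units(unit_indices)
    te_tab = sub
    if test_table is not None:
        te_tab = (
            test_table
            if unit_indices is None
            else test_table.subset_units(unit_indices)
        )
        if te_tab.stimulus_ids != sub.stimulus_ids or te_tab.n_units != sub.n_units:
            raise ValueError("test table must match units and stimuli of the table")
    accs = np.empty(n_cycles)
    classifiers = []
    min_trials = int(sub.trial_counts().min())
    for c in range(n_cycles):
        tr_mask = te_mask = None
        if holdout_trials:
            if min_trials < 2:
                raise ValueError("held-out-trial mode needs >=2 trials per cell")
            held = int(rng.integers(min_trials))
            te_mask = np.zeros_like(sub.responses, dtype=bool)
            te_mask[:, :, held] = True
            tr_mask = ~te_mask
        X_tr, y_tr = sample_population_vectors(
            sub, task.train_map, n_train, rng, trial_mask=tr_mask
        )
        clf = train_perceptron(X_tr, y_tr, rng, max_epochs=max_epochs)
        X_te, y_te = sample_population_vectors(
            te_tab, task.test_map, n_test, rng, trial_mask=te_mask
        )
        accs[c] = clf.accuracy(X_te, y_te)
        classifiers.append(clf)
    return CycleResult(task, accs, classifiers, list(sub.unit_ids))


def removal_curve_least(
    task: DecodingTask,
    table: TrialResponseTable,
    rng: np.random.Generator,
    n_train: int = 100,
    n_test: int = 100,
    n_cycles: int = 10,
    max_epochs: int = 100,
    test_table: TrialResponseTable | None = None,
) -> RemovalCurve:
    """Sequentially drop the unit with the smallest mean absolute weight.

    At every ensemble size (N down to 1) the classifier is retrained over
    ``n_cycles`` cycles; the removal ranking uses the cycle-mean of
    L2-normalized absolute weights, with ties broken toward the lower unit
    index.  The final surviving unit closes the removal order.
    """
    if table.n_units < 2:
        raise ValueError("removal curve needs at least 2 units")
    remaining = list(range(table.n_units))
    counts, accs, order = [], [], []
    while remaining:
        result = run_cycles(
            task, table, rng,
            n_train=n_train, n_test=n_test, n_cycles=n_cycles,
            max_epochs=max_epochs, unit_indices=remaining,
            test_table=test_table,
        )
        counts.append(len(remaining))
        accs.append(result.mean_accuracy)
        if len(remaining) == 1:
            order.append(table.unit_ids[remaining[0]])
            break
        ranking = result.mean_normalized_abs_weights()
        drop = int(np.argmin(ranking))  # argmin takes the first (lowest index) tie
        order.append(table.unit_ids[remaining[drop]])
        remaining.pop(drop)
    return RemovalCurve(np.asarray(counts), np.asarray(accs), order)


def best_single_unit(
    task: DecodingTask,
    table: TrialResponseTable,
    rng: np.random.Generator,
    n_train: int = 100,
    n_test: int = 100,
    n_cycles: int = 10,
    max_epochs: int = 100,
    test_table: TrialResponseTable | None = None,
) -> tuple[str, float]:
    """Best mean accuracy attainable with any one unit on its own.

    The sequential-removal path does not always converge onto the single
    best unit, so this exhaustive one-unit sweep is reported alongside
    every removal curve.
    """
    best_id, best_acc = table.unit_ids[0], -1.0
    for u in range(table.n_units):
        result = run_cycles(
            task, table, rng,
            n_train=n_train, n_test=n_test, n_cycles=n_cycles,
            max_epochs=max_epochs, unit_indices=[u],
            test_table=test_table,
        )
        if result.mean_accuracy > best_acc:
            best_id, best_acc = table.unit_ids[u], result.mean_accuracy
    return best_id, best_acc
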