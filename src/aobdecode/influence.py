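"""How much does classification depend on individual units?

Three complementary probes: (1) greatest-|weight| removal — repeatedly
delete the currently most influential unit and count how many can go before
performance falls below the best single unit's; (2) correlations between
weight vectors, across the repeated training cycles of one classifier
(stability) or between classifiers for different traits (overlap of the
unit populations each trait recruits); (3) response-profile correlations among
the top-weighted units, and a comparison against a quadratic-kernel SVM.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .core import TrialResponseTable
from .decoding import (
    CycleResult,
    DecodingTask,
    best_single_unit,
    run_cycles,
    sample_population_vectors,
    train_perceptron,
)


@dataclass
class GreatestRemovalResult:
    """Units removable (most influential first) before dropping below the
    best-single-unit reference accuracy."""

    counts: np.ndarray  # per removal cycle
    reference_accuracy: float
    reference_unit: str

    @property
    def mean_count(self) -> float:
        return float(np.mean(self.counts))


def removal_curve_greatest(
    task: DecodingTask,
    table: TrialResponseTable,
    rng: np.random.Generator,
    n_cycles: int = 10,
    n_train: int = 100,
    n_test: int = 100,
    max_epochs: int = 100,
    reference: tuple[str, float] | None = None,
    test_table=None,
) -> GreatestRemovalResult:
    """Greatest-|weight| sequential removal, repeated over ``n_cycles``.

    Within each removal cycle the classifier is trained once per stage; if
    its test accuracy is still at or above the best-single-unit reference,
    the unit with the highest absolute weight is removed and the remainder
    retrained.  The recorded count is how many units were removed before
    accuracy first dropped below the reference (0 if the full ensemble is
    already below it).  ``test_table`` switches every evaluation (including
    the reference, when computed here) to the independent-test-table mode.
    """
    if reference is None:
        reference = best_single_unit(
            task, table, rng, n_train=n_train, n_test=n_test,
            n_cycles=n_cycles, max_epochs=max_epochs, test_table=test_table,
        )
    ref_unit, ref_acc = reference
    counts = np.empty(n_cycles, dtype=int)
    for c in range(n_cycles):
        remaining = list(range(table.n_units))
        removed = 0
        while True:
            result = run_cycles(
                task, table, rng,
                n_train=n_train, n_test=n_test, n_cycles=1,
                max_epochs=max_epochs, unit_indices=remaining,
                test_table=test_table,
            )
            if result.mean_accuracy < ref_acc or len(remaining) == 1:
                break
            w = np.abs(result.classifiers[0].weights)
            drop = int(np.argmax(w))
            remaining.pop(drop)
            removed += 1
        counts[c] = removed
    return GreatestRemovalResult(counts, ref_acc, ref_unit)


@dataclass
class WeightCorrelationReport:
    """Mean +/- SD of Pearson correlations between weight vectors."""

    correlations: np.ndarray
    mean: float
    sd: float
    n_missing: int
    kind: str  # "cross_classifier" | "within_classifier"


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def weight_correlations(
    weights_a: np.ndarray, weights_b: np.ndarray | None = None
) -> WeightCorrelationReport:
    """Correlate weight vectors across classifiers or across cycles.

    With two weight matrices (n_cycles x n_units, matched unit order),
    cycle i of A is paired with cycle i of B.  With one matrix, all
    unordered cycle pairs are correlated.  Constant vectors yield an
    undefined correlation, reported as missing.
    """
    A = np.atleast_2d(np.asarray(weights_a, dtype=float))
    if weights_b is not None:
        B = np.atleast_2d(np.asarray(weights_b, dtype=float))
        if A.shape != B.shape:
            raise ValueError("weight sets must have matching shape/unit order")
        rs = np.array([_pearson(a, b) for a, b in zip(A, B)])
        kind = "cross_classifier"
    else:
        rs = np.array([_pearson(A[i], A[j]) for i, j in combinations(range(len(A)), 2)])
        kind = "within_classifier"
    valid = rs[np.isfinite(rs)]
    return WeightCorrelationReport(
        correlations=rs,
        mean=float(valid.mean()) if valid.size else float("nan"),
        sd=float(valid.std(ddof=1)) if valid.size > 1 else float("nan"),
        n_missing=int(np.isnan(rs).sum()),
        kind=kind,
    )


@dataclass
class TopUnitProfileReport:
    correlations: np.ndarray
    fraction_below_half: float
    n_missing: int
    top_unit_indices: np.ndarray


def top_unit_profile_correlations(
    normalized_matrix: np.ndarray,
    weights: np.ndarray,
    k: int = 20,
) -> TopUnitProfileReport:
    """Pairwise response-profile correlations among the top-k weighted units.

    Selects the k units with the largest |weight| (ties toward lower
    index), correlates all k(k-1)/2 pairs of normalized response rows, and
    reports the fraction of correlations below 0.5.  Pairs involving a
    constant row are skipped and counted as missing.
    """
    R = np.asarray(normalized_matrix, dtype=float)
    w = np.asarray(weights, dtype=float)
    if k > R.shape[0]:
        raise ValueError(f"k={k} exceeds the {R.shape[0]} available units")
    # stable sort on -|w| keeps lower indices first among ties
    top = np.argsort(-np.abs(w), kind="stable")[:k]
    rs = np.array([_pearson(R[i], R[j]) for i, j in combinations(top, 2)])
    valid = rs[np.isfinite(rs)]
    frac = float((valid < 0.5).mean()) if valid.size else float("nan")
    return TopUnitProfileReport(
        correlations=rs,
        fraction_below_half=frac,
        n_missing=int(np.isnan(rs).sum()),
        top_unit_indices=top,
    )


@dataclass
class SvmComparisonResult:
    """Best-over-cycles accuracy of the quadratic-kernel SVM vs the perceptron."""

    svm_accuracies: np.ndarray
    perceptron_accuracies: np.ndarray
    by_unit_count: dict[int, tuple[float, float]]  # n_units -> (svm, perceptron)

    @property
    def best_svm(self) -> float:
        return float(np.max(self.svm_accuracies))

    @property
    def best_perceptron(self) -> float:
        return float(np.max(self.perceptron_accuracies))


def _make_svm(C: float = 1.0, coef0: float = 1.0) -> SVC:
    # kernel (x.y + coef0)^2 with box constraint C
    return SVC(kernel="poly", degree=2, gamma=1.0, coef0=coef0, C=C)


def svm_compare(
    task: DecodingTask,
    table: TrialResponseTable,
    rng: np.random.Generator,
    n_cycles: int = 10,
    n_train: int = 100,
    n_test: int = 100,
    max_epochs: int = 100,
    unit_counts: list[int] | None = None,
    C: float = 1.0,
) -> SvmComparisonResult:
    """Train both classifiers on identical sampled sets, cycle by cycle.

    ``unit_counts`` optionally repeats the comparison on random unit
    subsets of the given sizes (one subset per size, mean accuracy over
    cycles), to expose how the non-linear advantage grows with ensemble
    size.
    """
    def run(sub: TrialResponseTable) -> tuple[np.ndarray, np.ndarray]:
        svm_acc = np.full(n_cycles, np.nan)
        per_acc = np.empty(n_cycles)
        for c in range(n_cycles):
            X_tr, y_tr = sample_population_vectors(sub, task.train_map, n_train, rng)
            X_te, y_te = sample_population_vectors(sub, task.test_map, n_test, rng)
            per_acc[c] = train_perceptron(X_tr, y_tr, rng, max_epochs).accuracy(X_te, y_te)
            try:
                svm = _make_svm(C=C).fit(X_tr, y_tr)
                svm_acc[c] = float(np.mean(svm.predict(X_te) == y_te))
            except ValueError:  # degenerate training set; skip this cycle
                continue
        return svm_acc, per_acc

    svm_acc, per_acc = run(table)
    by_count: dict[int, tuple[float, float]] = {}
    for count in unit_counts or []:
        idx = rng.choice(table.n_units, size=count, replace=False)
        s, p = run(table.subset_units(sorted(idx)))
        by_count[count] = (float(np.nanmean(s)), float(np.mean(p)))
    return SvmComparisonResult(svm_acc, per_acc, by_count)
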