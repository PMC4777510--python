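"""Population-level trait representation: shuffle-tested index and PCA.

The trait-representation index asks whether a trait (strain or reproductive
state) leaves a larger imprint on the normalized response matrix than
expected by chance.  For unit *i* and a two-group stimulus partition
(G1, G2) the per-unit index is

    I_i = | sum_{s in G1} R_is  -  sum_{s in G2} R_is |

with R the row-normalized mean response matrix; the population index is the
mean of I_i over units.  The null distribution comes from shuffles that
independently permute each unit's responses across stimuli — destroying any
trait dependence while preserving each unit's response-magnitude
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA


def _group_columns(
    stimulus_ids: Sequence[str], group1: Sequence[str], group2: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    if not group1 or not group2:
        raise ValueError("both stimulus groups must be non-empty")
    if set(group1) & set(group2):
        raise ValueError("stimulus groups must be disjoint")
    index = {s: i for i, s in enumerate(stimulus_ids)}
    try:
        return (
            np.asarray([index[s] for s in group1]),
            np.asarray([index[s] for s in group2]),
        )
    except KeyError as e:
        raise KeyError(f"partition references unknown stimulus {e.args[0]!r}") from None


def trait_index(
    normalized_matrix: np.ndarray,
    stimulus_ids: Sequence[str],
    group1: Sequence[str],
    group2: Sequence[str],
) -> tuple[np.ndarray, float]:
    """Per-unit indices and their population mean for one trait partition."""
    R = np.asarray(normalized_matrix, dtype=float)
    g1, g2 = _group_columns(stimulus_ids, group1, group2)
    per_unit = np.abs(R[:, g1].sum(axis=1) - R[:, g2].sum(axis=1))
    return per_unit, float(per_unit.mean())


@dataclass
class TraitIndexResult:
    per_unit: np.ndarray
    observed: float
    n_shuffles: int
    null_mean: float
    null_sd: float
    null_quantiles: dict[str, float]
    p_value: float        # add-one estimator, never exactly 0
    p_value_raw: float    # plain exceedance fraction

    def __post_init__(self) -> None:
        assert 0.0 < self.p_value <= 1.0


def bootstrap_index_pvalue(
    normalized_matrix: np.ndarray,
    stimulus_ids: Sequence[str],
    group1: Sequence[str],
    group2: Sequence[str],
    rng: np.random.Generator,
    n_shuffles: int = 10_000,
    batch_size: int = 1000,
) -> TraitIndexResult:
    """Shuffle test of the population trait index.

    Each of ``n_shuffles`` shuffles independently permutes every unit's
    row across stimuli and recomputes the population index.  The headline
    p-value is the add-one estimator (1 + #{null >= observed}) /
    (1 + n_shuffles); the plain exceedance fraction is reported alongside.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    R = np.asarray(normalized_matrix, dtype=float)
    n_units, n_stimuli = R.shape
    g1, g2 = _group_columns(stimulus_ids, group1, group2)
    per_unit, observed = trait_index(R, stimulus_ids, group1, group2)

    # signed contrast vector: +1 on G1 columns, -1 on G2, 0 elsewhere
    contrast = np.zeros(n_stimuli)
    contrast[g1] = 1.0
    contrast[g2] = -1.0

    null = np.empty(n_shuffles)
    done = 0
    while done < n_shuffles:
        m = min(batch_size, n_shuffles - done)
        # batch of independent row permutations via argsort of random keys
        perms = np.argsort(rng.random((m, n_units, n_stimuli)), axis=2)
        shuffled = np.take_along_axis(R[None, :, :].repeat(m, axis=0), perms, axis=2)
        null[done : done + m] = np.abs(shuffled @ contrast).mean(axis=1)
        done += m

    exceed = int(np.sum(null >= observed))
    qs = np.quantile(null, [0.5, 0.95, 0.99])
    return TraitIndexResult(
        per_unit=per_unit,
        observed=observed,
        n_shuffles=n_shuffles,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_shuffles > 1 else 0.0,
        null_quantiles={"q50": float(qs[0]), "q95": float(qs[1]), "q99": float(qs[2])},
        p_value=(1 + exceed) / (1 + n_shuffles),
        p_value_raw=exceed / n_shuffles,
    )


@dataclass
class PCASummary:
    variance_ratio: np.ndarray   # fraction of variance per component, sums to 1
    components: np.ndarray       # first <=3 component loadings over stimuli
    scores: np.ndarray           # unit scores on those components


def pca_summary(normalized_matrix: np.ndarray) -> PCASummary:
    """PCA of the unit x stimulus matrix (units = observations).

    Stimuli are the variables; columns are mean-centered.  Returns the
    variance-explained fractions for all components and the loadings and
    unit scores of the first three.
    """
    R = np.asarray(normalized_matrix, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2 or R.shape[1] < 2:
        raise ValueError("PCA needs at least 2 units and 2 stimuli")
    centered = R - R.mean(axis=0, keepdims=True)
    if not np.any(centered):
        raise ValueError("matrix has rank 0 after centering")
    pca = PCA(n_components=min(R.shape[0], R.shape[1]))
    scores = pca.fit_transform(R)
    k = min(3, pca.n_components_)
    return PCASummary(
        variance_ratio=pca.explained_variance_ratio_,
        components=pca.components_[:k],
        scores=scores[:, :k],
    )


def trait_partition(stimuli, trait: str) -> tuple[list[str], list[str]]:
    """Split a panel's stimulus ids into the two level groups of ``trait``."""
    from .core import FACTOR_LEVELS

    levels = FACTOR_LEVELS[trait][:2]
    g1 = [s.stimulus_id for s in stimuli if s.level(trait) == levels[0]]
    g2 = [s.stimulus_id for s in stimuli if s.level(trait) == levels[1]]
    if not g1 or not g2:
        raise ValueError(f"panel does not contain both {trait} levels")
    return g1, g2
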