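"""Trial-response quantification, responsiveness screening, normalization.

A trial response is the average firing-rate change between the 40 s
post-pump window and the 30 s pre-pump baseline.  Units enter the decoding
analyses only if a rank-based two-group test (Kruskal-Wallis, equivalent to
a Wilcoxon rank-sum for two groups) finds their post-stimulation rates for
at least one stimulus to differ from their pooled pre-application baseline
rates at the 0.05 level.  Screening is deliberately uncorrected across the
12 stimuli of a panel — the screen defines dataset membership, not an
inferential claim per stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnalysisWindows, StimulusDescriptor, TrialResponseTable

#: Total observations at or below which the exact rank-sum variant is used.
EXACT_TEST_MAX_N = 20


def compute_trial_response(spike_times, windows: AnalysisWindows | None = None) -> float:
    """Firing-rate change (Hz) of one trial.

    ``count((0, response_end]) / response_end  -  count([baseline_start, 0)) / |baseline|``.
    Spikes outside both windows are ignored; an empty spike list gives 0.
    """
    windows = windows or AnalysisWindows()
    t = np.asarray(spike_times, dtype=float)
    post = np.count_nonzero((t > 0.0) & (t <= windows.response_end))
    pre = np.count_nonzero((t >= windows.baseline_start) & (t < 0.0))
    return post / windows.response_end - pre / windows.baseline_duration


def _window_rate(t: np.ndarray, lo: float, hi: float) -> float:
    return np.count_nonzero((t >= lo) & (t < hi)) / (hi - lo)


def spike_table_to_responses(
    spikes: pd.DataFrame,
    stimuli: list[StimulusDescriptor],
    windows: AnalysisWindows | None = None,
    n_trials: int | None = None,
) -> TrialResponseTable:
    """Quantify a spike-event table into a :class:`TrialResponseTable`.

    ``spikes`` holds columns unit_id, stimulus_id, trial, spike_time_s;
    trials absent from the table (no spikes at all) count as 0 Hz change,
    which is why the full trial grid must be given via ``n_trials`` (or it
    is inferred as the max trial index + 1).
    """
    windows = windows or AnalysisWindows()
    if n_trials is None:
        n_trials = int(spikes["trial"].max()) + 1 if len(spikes) else 1
    unit_ids = sorted(spikes["unit_id"].unique())
    stim_ids = [s.stimulus_id for s in stimuli]
    data = np.zeros((len(unit_ids), len(stimuli), n_trials))
    u_idx = {u: i for i, u in enumerate(unit_ids)}
    s_idx = {s: i for i, s in enumerate(stim_ids)}
    for (u, s, trial), group in spikes.groupby(["unit_id", "stimulus_id", "trial"]):
        data[u_idx[u], s_idx[s], int(trial)] = compute_trial_response(
            group["spike_time_s"].to_numpy(), windows
        )
    return TrialResponseTable(data, list(stimuli), unit_ids)


def baseline_rates_from_spikes(
    spikes: pd.DataFrame,
    unit_ids: list[str],
    windows: AnalysisWindows | None = None,
    n_trials: int | None = None,
) -> dict[str, np.ndarray]:
    """Per-trial baseline rates on the pre-application span, pooled across stimuli."""
    windows = windows or AnalysisWindows()
    lo, hi = windows.significance_baseline
    if n_trials is None:
        n_trials = int(spikes["trial"].max()) + 1 if len(spikes) else 1
    stim_ids = sorted(spikes["stimulus_id"].unique())
    out: dict[str, np.ndarray] = {}
    grouped = spikes.groupby(["unit_id", "stimulus_id", "trial"])["spike_time_s"]
    for u in unit_ids:
        rates = []
        for s in stim_ids:
            for trial in range(n_trials):
                try:
                    t = grouped.get_group((u, s, trial)).to_numpy()
                except KeyError:
                    t = np.empty(0)
                rates.append(_window_rate(t, lo, hi))
        out[u] = np.asarray(rates)
    return out


def post_rates_from_spikes(
    spikes: pd.DataFrame,
    unit_ids: list[str],
    stimuli: list[StimulusDescriptor],
    windows: AnalysisWindows | None = None,
    n_trials: int | None = None,
) -> np.ndarray:
    """Per-trial post-stimulation rates, shape (n_units, n_stimuli, n_trials)."""
    windows = windows or AnalysisWindows()
    if n_trials is None:
        n_trials = int(spikes["trial"].max()) + 1 if len(spikes) else 1
    stim_ids = [s.stimulus_id for s in stimuli]
    rates = np.zeros((len(unit_ids), len(stim_ids), n_trials))
    u_idx = {u: i for i, u in enumerate(unit_ids)}
    s_idx = {s: i for i, s in enumerate(stim_ids)}
    for (u, s, trial), group in spikes.groupby(["unit_id", "stimulus_id", "trial"]):
        if u in u_idx and s in s_idx:
            rates[u_idx[u], s_idx[s], int(trial)] = _window_rate(
                group["spike_time_s"].to_numpy(), 0.0, windows.response_end
            )
    return rates


def rank_test_pvalue(post: np.ndarray, baseline: np.ndarray) -> float:
    """Two-group non-parametric p-value (post rates vs pooled baseline rates).

    Kruskal-Wallis with tie correction for larger samples; the exact
    Wilcoxon rank-sum when the total sample is small enough to enumerate.
    Identical values in both groups give p = 1; fewer than 2 observations
    in either group gives NaN.
    """
    post = np.asarray(post, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if post.size < 2 or baseline.size < 2:
        return float("nan")
    pooled = np.concatenate([post, baseline])
    if np.all(pooled == pooled[0]):
        return 1.0
    if pooled.size <= EXACT_TEST_MAX_N:
        return float(
            stats.mannwhitneyu(post, baseline, alternative="two-sided", method="exact").pvalue
        )
    return float(stats.kruskal(post, baseline).pvalue)


@dataclass
class ScreenResult:
    """Per-stimulus significance p-values and the retained (responsive) units."""

    pvalues: np.ndarray  # (n_units, n_stimuli); NaN = undefined
    alpha: float
    unit_ids: list[str]
    stimulus_ids: list[str]

    @property
    def responsive_mask(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.pvalues, nan=1.0) <= self.alpha

    @property
    def responsive_units(self) -> np.ndarray:
        """Indices of units significant for at least one stimulus."""
        return np.flatnonzero(self.responsive_mask.any(axis=1))

    def significant_counts(self) -> np.ndarray:
        """Number of significant responses per retained unit."""
        return self.responsive_mask[self.responsive_units].sum(axis=1)


def significance_screen(
    post_rates: np.ndarray,
    baseline_rates: dict[str, np.ndarray] | np.ndarray,
    unit_ids: list[str],
    stimulus_ids: list[str],
    alpha: float = 0.05,
) -> ScreenResult:
    """Screen units for significant responsiveness to any stimulus.

    ``post_rates`` is (n_units, n_stimuli, n_trials); ``baseline_rates``
    holds each unit's pre-application rates pooled across all stimuli
    (dict keyed by unit id, or an (n_units, n_baseline) array).
    """
    post_rates = np.asarray(post_rates, dtype=float)
    n_units, n_stimuli, _ = post_rates.shape
    pvals = np.full((n_units, n_stimuli), np.nan)
    for u in range(n_units):
        base = (
            baseline_rates[unit_ids[u]]
            if isinstance(baseline_rates, dict)
            else baseline_rates[u]
        )
        base = np.asarray(base)[np.isfinite(np.asarray(base, dtype=float))]
        for s in range(n_stimuli):
            post = post_rates[u, s]
            post = post[np.isfinite(post)]
            pvals[u, s] = rank_test_pvalue(post, base)
    return ScreenResult(pvals, alpha, list(unit_ids), list(stimulus_ids))


def normalize(matrix: np.ndarray, mode: str = "minmax") -> np.ndarray:
    """Normalize each unit's mean-response row.

    ``minmax`` (default): affine map per row onto [-1, 1], so the maximal
    response is exactly 1 and the minimal exactly -1; constant rows map to
    all-zero (keeping downstream indices defined).  ``maxabs``: divide by
    the row's max absolute response.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("expected a units x stimuli matrix")
    if mode == "minmax":
        lo = matrix.min(axis=1, keepdims=True)
        hi = matrix.max(axis=1, keepdims=True)
        span = hi - lo
        out = np.zeros_like(matrix)
        ok = (span > 0).ravel()
        out[ok] = 2.0 * (matrix[ok] - lo[ok]) / span[ok] - 1.0
        return out
    if mode == "maxabs":
        scale = np.abs(matrix).max(axis=1, keepdims=True)
        out = np.zeros_like(matrix)
        ok = (scale > 0).ravel()
        out[ok] = matrix[ok] / scale[ok]
        return out
    raise ValueError(f"unknown normalization mode {mode!r}")


@dataclass
class ResponseSummary:
    """Descriptive summary of a screened dataset."""

    n_responsive: int
    counts_mode: int
    counts_median: float
    counts_mean: float
    fraction_responsive_by_level: dict[str, float]
    grouping_factor: str


def response_summary(
    table: TrialResponseTable,
    screen: ScreenResult,
    by: str = "dilution",
) -> ResponseSummary:
    """Summarise significant-response counts and per-level responsive fractions.

    Counts (mode/median/mean of significant responses per unit) are over
    retained units; mode ties break toward the smaller count.  The fraction
    responsive per level of ``by`` (dilution or secretion) is the share of
    retained units significant for at least one stimulus at that level.
    """
    if table.n_units == 0 or table.n_stimuli == 0:
        raise ValueError("empty response table")
    responsive = screen.responsive_units
    if responsive.size == 0:
        raise ValueError("no responsive units to summarise")
    counts = screen.significant_counts()
    values, freq = np.unique(counts, return_counts=True)
    mode = int(values[np.flatnonzero(freq == freq.max())[0]])

    mask = screen.responsive_mask[responsive]
    levels = [s.level(by) for s in table.stimuli]
    fractions = {}
    for level in dict.fromkeys(levels):  # first-seen order
        cols = [i for i, lv in enumerate(levels) if lv == level]
        fractions[level] = float(mask[:, cols].any(axis=1).mean())
    return ResponseSummary(
        n_responsive=int(responsive.size),
        counts_mode=mode,
        counts_median=float(np.median(counts)),
        counts_mean=float(np.mean(counts)),
        fraction_responsive_by_level=fractions,
        grouping_factor=by,
    )
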