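"""Resampling statistics and descriptive performance metrics.

Two bespoke procedures:

* a trial-wise permutation test comparing per-trial median learning curves
  between two conditions, with a single familywise threshold obtained by
  pooling the permutation null across all trial positions; and
* a randomization test for the consistency of learning-trial differences
  across sliding windows of within-session block positions.

Routine two-sample comparisons delegate to SciPy's rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .task import trials_to_frame

__all__ = [
    "TrialwisePermutationResult",
    "trialwise_permutation_test",
    "ConsistencyResult",
    "consistency_randomization",
    "performance_metrics",
    "curves_matrix",
]


def curves_matrix(block_curves: pd.DataFrame, n_trials: int = 30):
    """Pivot long-format per-block curves into (blocks x trials) matrices.

    Returns ``(matrix, labels)`` where rows are blocks (NaN where a block is
    shorter than ``n_trials``) and ``labels`` is the per-block condition.
    """
    key = ["session_id", "block_index"]
    sub = block_curves[block_curves["trial"] <= n_trials]
    wide = sub.pivot_table(index=key, columns="trial", values="mode")
    wide = wide.reindex(columns=np.arange(1, n_trials + 1))
    labels = sub.drop_duplicates(key).set_index(key)["condition"].reindex(wide.index)
    return wide.to_numpy(dtype=float), labels.to_numpy()


@dataclass
class TrialwisePermutationResult:
    observed: np.ndarray  # per-trial median difference, cond_a - cond_b
    threshold: float  # pooled 95% null threshold
    significant: np.ndarray  # bool per trial
    level: float
    n_perm: int
    seed: int
    cond_a: str
    cond_b: str

    @property
    def significant_trials(self):
        return np.flatnonzero(self.significant) + 1  # 1-based


def trialwise_permutation_test(
    curves,
    labels,
    cond_a=None,
    cond_b=None,
    n_perm: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> TrialwisePermutationResult:
    """Permutation test of per-trial median differences with a pooled threshold.

    ``curves`` is a (blocks x trials) matrix of probability-of-rewarded-choice
    curves aligned on the reversal; ``labels`` assigns each block to one of
    two conditions. The observed statistic per trial is
    ``median(cond_a) - median(cond_b)``. The null pools the ``n_perm``
    label-shuffled differences across all trial positions into a single
    distribution whose ``level`` quantile is the familywise threshold; trials
    whose observed difference exceeds it are flagged (one-sided, a > b).
    """
    curves = np.asarray(curves, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two condition labels are required")
    if cond_a is None or cond_b is None:
        cond_a, cond_b = uniq[0], uniq[1]
    mask_a = labels == cond_a
    mask_b = labels == cond_b
    if mask_a.sum() < 5 or mask_b.sum() < 5:
        raise ValueError("need at least 5 blocks per condition")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse null distribution")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN trail columns
        observed = np.nanmedian(curves[mask_a], axis=0) - np.nanmedian(
            curves[mask_b], axis=0
        )
        rng = np.random.default_rng(seed)
        n_blocks = len(labels)
        n_a = int(mask_a.sum())
        null = np.empty((n_perm, curves.shape[1]))
        for p in range(n_perm):
            perm = rng.permutation(n_blocks)
            ga = curves[perm[:n_a]]
            gb = curves[perm[n_a:]]
            null[p] = np.nanmedian(ga, axis=0) - np.nanmedian(gb, axis=0)
    pooled = null[np.isfinite(null)]
    threshold = float(np.quantile(pooled, level))
    with np.errstate(invalid="ignore"):
        significant = observed > threshold
    return TrialwisePermutationResult(
        observed=observed,
        threshold=threshold,
        significant=significant,
        level=level,
        n_perm=n_perm,
        seed=seed,
        cond_a=str(cond_a),
        cond_b=str(cond_b),
    )


@dataclass
class ConsistencyResult:
    statistic: float  # proportion of window positions earlier under cond_a
    p_value: float
    window_medians_a: np.ndarray
    window_medians_b: np.ndarray
    n_positions: int
    n_perm: int
    seed: int


def _window_medians(sessions, window: int = 4, n_forward: int = 8, n_backward: int = 7):
    """Median learning trial over sliding windows of block positions.

    ``sessions`` is a list of per-session learning-trial sequences (NaN for
    unlearned blocks). Forward windows cover block positions 1-4 .. 8-11;
    backward windows cover the last 4 .. seventh-to-last 4 blocks.
    """
    usable = [np.asarray(s, dtype=float) for s in sessions if len(s) >= window]
    if not usable:
        return np.full(n_forward + n_backward, np.nan)
    out = np.full(n_forward + n_backward, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for k in range(n_forward):
            vals = np.concatenate(
                [s[k : k + window] for s in usable if len(s) >= k + window] or [[]]
            )
            if vals.size:
                out[k] = np.nanmedian(vals)
        for k in range(n_backward):
            stop = None if k == 0 else -k
            vals = np.concatenate(
                [s[-(k + window) : stop] for s in usable if len(s) >= k + window] or [[]]
            )
            if vals.size:
                out[n_forward + k] = np.nanmedian(vals)
    return out


def consistency_randomization(
    sessions_a,
    sessions_b,
    n_perm: int = 1000,
    seed: int = 0,
    window: int = 4,
    n_forward: int = 8,
    n_backward: int = 7,
) -> ConsistencyResult:
    """Randomization test for consistently earlier learning under condition a.

    ``sessions_a``/``sessions_b`` are lists of per-session block
    learning-trial sequences. The statistic is the proportion of the
    ``n_forward + n_backward`` sliding window positions whose median learning
    trial is strictly earlier under condition a (ties count as not earlier);
    the p-value is one minus the observed statistic's rank in the
    label-shuffled null.
    """

    sessions_a = [np.asarray(s, dtype=float) for s in sessions_a]
    sessions_b = [np.asarray(s, dtype=float) for s in sessions_b]
    n_short = sum(len(s) < window for s in sessions_a + sessions_b)
    if n_short:
        warnings.warn(f"{n_short} session(s) shorter than the {window}-block window excluded")
        sessions_a = [s for s in sessions_a if len(s) >= window]
        sessions_b = [s for s in sessions_b if len(s) >= window]

    def stat(sa, sb):
        ma = _window_medians(sa, window, n_forward, n_backward)
        mb = _window_medians(sb, window, n_forward, n_backward)
        valid = ~(np.isnan(ma) | np.isnan(mb))
        if not valid.any():
            raise ValueError("no window position with data in both conditions")
        return float(np.mean(ma[valid] < mb[valid])), ma, mb

    observed, ma, mb = stat(sessions_a, sessions_b)
    pooled = sessions_a + sessions_b
    n_a = len(sessions_a)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p in range(n_perm):
            perm = rng.permutation(len(pooled))
            sa = [pooled[i] for i in perm[:n_a]]
            sb = [pooled[i] for i in perm[n_a:]]
            null[p], _, _ = stat(sa, sb)
    p_value = float(1.0 - np.mean(observed > null))
    return ConsistencyResult(
        statistic=observed,
        p_value=p_value,
        window_medians_a=ma,
        window_medians_b=mb,
        n_positions=int(np.sum(~(np.isnan(ma) | np.isnan(mb)))),
        n_perm=n_perm,
        seed=seed,
    )


def performance_metrics(trials) -> pd.DataFrame:
    """Per session x condition summary of task performance.

    Columns: proportion of rewarded choices overall and per dimming
    condition, premature-abort and fixation-break rates, blocks and
    completed choices per session.
    """
    df = trials_to_frame(trials)
    if len(df) == 0:
        raise ValueError("empty trial table")
    rows = []
    for (sid, cond), g in df.groupby(["session_id", "condition"], sort=True):
        choices = g[g["choice"] != "none"]
        if len(choices) == 0:
            raise ValueError(f"session {sid!r} has no completed choices")
        row = {
            "session_id": sid,
            "condition": cond,
            "n_trials": len(g),
            "n_choices": len(choices),
            "n_blocks": g["block_index"].nunique(),
            "prop_rewarded": float(choices["reward"].mean()),
            "premature_rate": float((g["outcome_class"] == "premature").mean()),
            "fixation_break_rate": float((g["outcome_class"] == "fixation_break").mean()),
        }
        for dim in ("simultaneous", "rewarded_first", "rewarded_second"):
            sub = choices[choices["dimming_condition"] == dim]
            row[f"prop_rewarded_{dim}"] = (
                float(sub["reward"].mean()) if len(sub) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def ranksum_compare(values_a, values_b):
    """Thin wrapper over the two-sided Wilcoxon rank-sum routine."""
    stat, p = mannwhitneyu(values_a, values_b, alternative="two-sided")
    return {"statistic": float(stat), "p_value": float(p)}
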