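"""State-space estimation of trial-wise probability of rewarded choice.

A latent Gaussian random walk ``x_t = x_{t-1} + e_t``, ``e_t ~ N(0, s2)``
drives Bernoulli outcomes through ``p_t = logistic(mu + x_t)`` with ``mu``
anchored at the chance level. The state-noise variance is estimated by EM
(approximate forward filter with a Newton mode-finder, fixed-interval
smoother); the smoothed state and its variance give the per-trial
probability-correct mode and confidence bounds. Bounds are one-sided at
``level`` (default 0.95), so the lower bound exceeding chance means the
posterior certainty that performance is above chance exceeds ``level``; the
learning trial is the first trial from which that holds for the remainder
of the block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from ._kernels import filter_smoother_kernel
from .task import trials_to_frame

__all__ = [
    "LearningCurve",
    "fit_learning_curve",
    "learning_trial",
    "learning_trial_table",
    "learning_trial_distribution",
    "block_curves",
]


@dataclass
class LearningCurve:
    p_mode: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    learning_trial: int | None
    chance: float
    level: float
    sigma2_eps: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray

    def __len__(self) -> int:
        return len(self.p_mode)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self.p_mode) + 1),
                "mode": self.p_mode,
                "lo": self.lower,
                "hi": self.upper,
            }
        )


def _filter_smoother(y, mu, sigma2_eps, x0=0.0, sigma2_0=None):
    """One forward-filter / backward-smoother pass; returns smoothed moments."""
    if sigma2_0 is None:
        sigma2_0 = sigma2_eps
    return filter_smoother_kernel(
        np.ascontiguousarray(y, dtype=np.float64),
        float(mu),
        float(sigma2_eps),
        float(x0),
        float(sigma2_0),
    )


def fit_learning_curve(
    outcomes,
    chance: float = 0.5,
    level: float = 0.95,
    max_iter: int = 500,
    tol: float = 1e-6,
    sigma2_init: float = 0.005,
    sigma2_fixed: float | None = None,
) -> LearningCurve:
    """EM fit of the state-space learning curve to one block's outcomes.

    ``outcomes`` is the binary rewarded/unrewarded sequence of completed
    choices; ``chance`` anchors the curve's baseline probability. Passing
    ``sigma2_fixed`` skips the EM estimation of the state-noise variance.
    """
    y = np.asarray(outcomes, dtype=float)
    if y.ndim != 1 or len(y) < 5:
        raise ValueError("need a 1-d outcome sequence of length >= 5")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("outcomes must be binary")
    if not 0 < chance < 1:
        raise ValueError("chance must be in (0, 1)")
    mu = float(logit(chance))
    T = len(y)
    trace = []
    it = 0
    sigma2 = float(sigma2_fixed) if sigma2_fixed is not None else float(sigma2_init)
    em_iters = 0 if sigma2_fixed is not None else max_iter
    converged = sigma2_fixed is not None
    for it in range(1, em_iters + 1):
        xs, vs, x0s, v0s, cov, loglik = _filter_smoother(y, mu, sigma2)
        trace.append(loglik)
        # E[(x_t - x_{t-1})^2] summed over t = 1..T (x_0 smoothed)
        sq = (xs[1:] - xs[:-1]) ** 2 + vs[1:] + vs[:-1] - 2 * cov[1:]
        first = (xs[0] - x0s) ** 2 + vs[0] + v0s - 2 * cov[0]
        sigma2_new = float((sq.sum() + first) / T)
        sigma2_new = max(sigma2_new, 1e-10)
        if it > 1 and abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1e-12):
            converged = True
            sigma2 = sigma2_new
            break
        sigma2 = sigma2_new
    xs, vs, _, _, _, _ = _filter_smoother(y, mu, sigma2)
    # one-sided bounds: lower > chance iff P(p_t > chance | data) > level,
    # the ideal-observer learning criterion
    z = norm.ppf(level)
    sd = np.sqrt(np.maximum(vs, 0.0))
    p_mode = expit(mu + xs)
    lower = expit(mu + xs - z * sd)
    upper = expit(mu + xs + z * sd)
    lt = learning_trial(lower, chance)
    return LearningCurve(
        p_mode=p_mode,
        lower=lower,
        upper=upper,
        learning_trial=lt,
        chance=chance,
        level=level,
        sigma2_eps=sigma2,
        n_iter=it,
        converged=converged,
        loglik_trace=np.asarray(trace),
    )


def learning_trial(lower, chance: float) -> int | None:
    """First (1-based) trial whose lower bound exceeds chance through block end."""
    lower = np.asarray(lower, dtype=float)
    above = lower > chance
    if not above[-1]:
        return None
    # walk back through the trailing run of above-chance trials
    t = len(above) - 1
    while t > 0 and above[t - 1]:
        t -= 1
    return t + 1


def block_curves(trials, chance=0.5, level=0.95, max_trial=None) -> pd.DataFrame:
    """Fit a learning curve per (session, block); long-format results.

    Only completed choices enter the outcome sequence; blocks with fewer
    than 5 completed choices are skipped.
    """
    df = trials_to_frame(trials)
    rows = []
    for (sid, block), g in df.groupby(["session_id", "block_index"], sort=True):
        y = g.loc[g["choice"] != "none", "reward"].to_numpy(dtype=float)
        if len(y) < 5:
            continue
        curve = fit_learning_curve(y, chance=chance, level=level)
        n = len(y) if max_trial is None else min(len(y), max_trial)
        for t in range(n):
            rows.append(
                {
                    "session_id": sid,
                    "condition": g["condition"].iloc[0],
                    "block_index": block,
                    "trial": t + 1,
                    "mode": curve.p_mode[t],
                    "lo": curve.lower[t],
                    "hi": curve.upper[t],
                    "learning_trial": curve.learning_trial,
                }
            )
    return pd.DataFrame(rows)


def learning_trial_table(trials, chance=0.5, level=0.95) -> pd.DataFrame:
    """One row per block: detected learning trial (NaN if never learned)."""
    df = trials_to_frame(trials)
    rows = []
    for (sid, block), g in df.groupby(["session_id", "block_index"], sort=True):
        y = g.loc[g["choice"] != "none", "reward"].to_numpy(dtype=float)
        if len(y) < 5:
            continue
        curve = fit_learning_curve(y, chance=chance, level=level)
        rows.append(
            {
                "session_id": sid,
                "condition": g["condition"].iloc[0],
                "block_index": block,
                "n_trials": len(g),
                "learning_trial": np.nan
                if curve.learning_trial is None
                else curve.learning_trial,
            }
        )
    return pd.DataFrame(rows)


def learning_trial_distribution(learning_trials, fast_threshold: int = 10) -> dict:
    """Summary of a condition's learning-trial distribution.

    ``learning_trials`` may contain NaN for unlearned blocks, which are
    excluded (statistics describe blocks that showed learning).
    """
    lt = np.asarray(learning_trials, dtype=float)
    learned = lt[~np.isnan(lt)]
    if len(learned) == 0:
        raise ValueError("no learned blocks")
    values, counts = np.unique(learned.astype(int), return_counts=True)
    return {
        "n_blocks": int(len(lt)),
        "n_learned": int(len(learned)),
        "median": float(np.median(learned)),
        "prop_fast": float(np.mean(learned <= fast_threshold)),
        "histogram": {int(v): int(c) for v, c in zip(values, counts)},
    }
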