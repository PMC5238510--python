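"""Maximum-likelihood fitting, cross-validation and model comparison.

Models are fit by minimizing the negative log-likelihood (NLL) of observed
choices with a two-stage scheme: a short simplex warm-up (<=20 iterations)
followed by bounded gradient-based refinement, repeated from several seeded
random starts. Cross-validation resamples at the reversal-block level
(blocks, not trials, are the exchangeable unit); AIC = 2k + 2*NLL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from . import models as _m
from ._kernels import MODEL_IDS, nll_kernel
from .models import ModelParams, PARAM_FIELDS, n_free_params
from .task import TrialRecord, trials_to_frame

__all__ = [
    "PARAM_BOUNDS",
    "FitConfig",
    "TrialArrays",
    "prepare_data",
    "negative_loglik",
    "fit_model",
    "fit_standard_errors",
    "cross_validate",
    "compare_models",
    "param_correlations",
    "model_behavior_ssd",
    "ModelFitResult",
    "CrossValidationResult",
]

#: optimization box constraints per parameter
PARAM_BOUNDS = {
    "eta": (0.0, 2.0),
    "eta1": (0.0, 2.0),
    "eta0": (0.0, 2.0),
    "beta": (0.0, 20.0),
    "omega": (1.0, 3.0),
    "alpha": (0.0, 5.0),
    "gamma": (0.0, 1.0),
}


@dataclass(frozen=True)
class FitConfig:
    n_starts: int = 5
    nm_maxiter: int = 20
    seed: int = 0
    bounds: dict = field(default_factory=dict)  # per-parameter overrides

    def bounds_for(self, model: str):
        return [self.bounds.get(p, PARAM_BOUNDS[p]) for p in PARAM_FIELDS[model]]


@dataclass
class TrialArrays:
    """Preprocessed trial table for the likelihood kernel."""

    left_feats: np.ndarray  # (n, 3) int64
    right_feats: np.ndarray  # (n, 3) int64
    choice: np.ndarray  # (n,) int64; -1 = no completed choice
    reward: np.ndarray  # (n,) float64
    session_start: np.ndarray  # (n,) bool
    block_id: np.ndarray  # (n,) int64, global block code
    n_blocks: int

    @property
    def n_trials(self) -> int:
        return int(self.choice.shape[0])

    @property
    def n_choice_trials(self) -> int:
        return int((self.choice >= 0).sum())

    def include_mask(self, blocks) -> np.ndarray:
        return np.isin(self.block_id, np.asarray(list(blocks)))


_MOTION_CODE = {"up": 2, "down": 3}
_CHOICE_CODE = {"left": 0, "right": 1, "none": -1}


def prepare_data(trials) -> TrialArrays:
    """Convert a trial table (records or DataFrame) into kernel arrays.

    Rows must be in chronological order within each session; sessions are
    delimited by changes of ``session_id``.
    """
    df = trials_to_frame(trials)
    if len(df) == 0:
        raise ValueError("empty trial table")
    left_color = df["left_color"].to_numpy(dtype=np.int64)
    left_motion = df["left_motion"].map(_MOTION_CODE).to_numpy(dtype=np.int64)
    left = np.column_stack(
        [np.zeros(len(df), dtype=np.int64), left_motion, left_color + 3]
    )
    right = np.column_stack(
        [np.ones(len(df), dtype=np.int64), 5 - left_motion, 9 - (left_color + 3)]
    )
    choice = df["choice"].map(_CHOICE_CODE).to_numpy(dtype=np.int64)
    reward = df["reward"].to_numpy(dtype=np.float64)
    sid = df["session_id"].to_numpy()
    session_start = np.zeros(len(df), dtype=np.bool_)
    session_start[0] = True
    session_start[1:] = sid[1:] != sid[:-1]
    block_key = pd.MultiIndex.from_arrays([df["session_id"], df["block_index"]])
    block_id, uniques = pd.factorize(block_key)
    return TrialArrays(
        left_feats=np.ascontiguousarray(left),
        right_feats=np.ascontiguousarray(right),
        choice=choice,
        reward=reward,
        session_start=session_start,
        block_id=block_id.astype(np.int64),
        n_blocks=len(uniques),
    )


def _theta_to_params(model: str, theta) -> ModelParams:
    return ModelParams.from_vector(model, np.asarray(theta, dtype=float))


def negative_loglik(model: str, theta, data: TrialArrays, include=None) -> float:
    """NLL of the trials selected by ``include`` (default: all trials).

    Excluded trials still drive state updates, so likelihoods of held-out
    blocks are evaluated in their true within-session context.
    """
    if model not in MODEL_IDS:
        raise ValueError(f"unknown model {model!r}")
    p = _theta_to_params(model, theta)
    if include is None:
        include = np.ones(data.n_trials, dtype=np.bool_)
    return float(
        nll_kernel(
            MODEL_IDS[model],
            p.eta,
            p.beta,
            p.omega,
            p.alpha,
            p.eta1,
            p.eta0,
            p.gamma,
            p.p_r,
            data.left_feats,
            data.right_feats,
            data.choice,
            data.reward,
            data.session_start,
            np.ascontiguousarray(include, dtype=np.bool_),
        )
    )


@dataclass
class ModelFitResult:
    model: str
    params: ModelParams
    param_names: tuple
    theta: np.ndarray
    nll: float
    aic: float
    n_trials: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": {n: float(v) for n, v in zip(self.param_names, self.theta)},
            "nll": float(self.nll),
            "aic": float(self.aic),
            "n_trials": int(self.n_trials),
            "converged": bool(self.converged),
        }


def fit_model(
    model: str,
    trials,
    config: FitConfig = FitConfig(),
    data: TrialArrays | None = None,
    include=None,
) -> ModelFitResult:
    """Two-stage multi-start maximum-likelihood fit of one model."""
    if data is None:
        data = prepare_data(trials)
    bounds = config.bounds_for(model)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def objective(theta):
        return negative_loglik(model, np.clip(theta, lo, hi), data, include)

    # stratified (latin hypercube) starts cover each parameter's range even
    # with few starts; some likelihood surfaces have wide flat ridges
    starts = [0.5 * (lo + hi)]
    n_rand = max(config.n_starts - 1, 0)
    if n_rand:
        sampler = qmc.LatinHypercube(d=len(bounds), seed=config.seed)
        starts += list(lo + sampler.random(n_rand) * (hi - lo))

    best_theta, best_nll, any_success = None, np.inf, False
    for x0 in starts:
        warm = optimize.minimize(
            objective, x0, method="Nelder-Mead", options={"maxiter": config.nm_maxiter}
        )
        refine = optimize.minimize(
            objective,
            np.clip(warm.x, lo, hi),
            method="L-BFGS-B",
            bounds=bounds,
        )
        any_success = any_success or refine.success
        if refine.fun < best_nll:
            best_nll, best_theta = float(refine.fun), np.clip(refine.x, lo, hi)
    if best_theta is None:  # pragma: no cover - objective always finite
        raise RuntimeError("optimization failed at every start")
    # polish the incumbent: a longer simplex run escapes flat ridges where
    # the finite-difference gradient vanishes, then one more bounded refine
    polish = optimize.minimize(
        objective,
        best_theta,
        method="Nelder-Mead",
        options={"maxiter": 400, "xatol": 1e-6, "fatol": 1e-8},
    )
    if polish.fun < best_nll:
        best_nll, best_theta = float(polish.fun), np.clip(polish.x, lo, hi)
    final = optimize.minimize(
        objective, best_theta, method="L-BFGS-B", bounds=bounds
    )
    if final.fun < best_nll:
        best_nll, best_theta = float(final.fun), np.clip(final.x, lo, hi)
    if not any_success:
        warnings.warn(f"no optimizer start converged for {model}; best incumbent returned")
    k = n_free_params(model)
    n_inc = data.n_choice_trials if include is None else int(
        ((data.choice >= 0) & include).sum()
    )
    return ModelFitResult(
        model=model,
        params=_theta_to_params(model, best_theta),
        param_names=PARAM_FIELDS[model],
        theta=best_theta,
        nll=best_nll,
        aic=2.0 * k + 2.0 * best_nll,
        n_trials=n_inc,
        converged=any_success,
    )


def fit_standard_errors(model: str, theta, data: TrialArrays, include=None, step=1e-4):
    """Asymptotic SEs from a central finite-difference Hessian of the NLL."""
    theta = np.asarray(theta, dtype=float)
    k = len(theta)
    h = step * np.maximum(1.0, np.abs(theta))
    hess = np.empty((k, k))

    def f(x):
        return negative_loglik(model, x, data, include)

    f0 = f(theta)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                ei = np.zeros(k)
                ei[i] = h[i]
                hess[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
            else:
                ei = np.zeros(k)
                ej = np.zeros(k)
                ei[i] = h[i]
                ej[j] = h[j]
                hess[i, j] = hess[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    diag = np.diag(cov).copy()
    diag[diag < 0] = np.nan
    return np.sqrt(diag)


@dataclass
class CrossValidationResult:
    model: str
    param_names: tuple
    params_per_rep: np.ndarray  # (n_reps, k)
    train_ll: np.ndarray  # total log-likelihood of training blocks
    test_ll: np.ndarray  # total log-likelihood of held-out blocks
    train_ll_per_trial: np.ndarray
    test_ll_per_trial: np.ndarray
    full_fit: ModelFitResult

    @property
    def mean_test_ll(self) -> float:
        return float(np.mean(self.test_ll))

    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.params_per_rep, columns=list(self.param_names))

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "full_fit": self.full_fit.to_dict(),
            "mean_train_ll": float(np.mean(self.train_ll)),
            "mean_test_ll": float(np.mean(self.test_ll)),
            "mean_test_ll_per_trial": float(np.mean(self.test_ll_per_trial)),
            "param_means": {
                n: float(v)
                for n, v in zip(self.param_names, self.params_per_rep.mean(axis=0))
            },
            "param_stds": {
                n: float(v)
                for n, v in zip(self.param_names, self.params_per_rep.std(axis=0, ddof=1))
            },
        }


def cross_validate(
    model: str,
    trials,
    n_reps: int = 100,
    train_frac: float = 0.8,
    seed: int = 0,
    config: FitConfig | None = None,
    data: TrialArrays | None = None,
) -> CrossValidationResult:
    """Repeated 80/20 block-level cross-validation.

    Each replicate fits on a random ``train_frac`` subset of reversal blocks
    and evaluates the held-out blocks' log-likelihood at the training optimum.
    """
    if data is None:
        data = prepare_data(trials)
    if data.n_blocks < 5:
        raise ValueError("cross-validation requires at least 5 blocks")
    if config is None:
        config = FitConfig()
    full = fit_model(model, None, config=config, data=data)
    rng = np.random.default_rng(seed)
    blocks = np.arange(data.n_blocks)
    n_train = max(int(round(train_frac * data.n_blocks)), 1)
    k = n_free_params(model)
    params = np.empty((n_reps, k))
    train_ll = np.empty(n_reps)
    test_ll = np.empty(n_reps)
    train_pt = np.empty(n_reps)
    test_pt = np.empty(n_reps)
    for r in range(n_reps):
        perm = rng.permutation(blocks)
        train_blocks = perm[:n_train]
        train_mask = data.include_mask(train_blocks)
        test_mask = ~train_mask
        rep_cfg = FitConfig(
            n_starts=config.n_starts,
            nm_maxiter=config.nm_maxiter,
            seed=int(rng.integers(2**31)),
            bounds=config.bounds,
        )
        fit = fit_model(model, None, config=rep_cfg, data=data, include=train_mask)
        params[r] = fit.theta
        train_ll[r] = -fit.nll
        test_nll = negative_loglik(model, fit.theta, data, include=test_mask)
        test_ll[r] = -test_nll
        n_tr = int(((data.choice >= 0) & train_mask).sum())
        n_te = int(((data.choice >= 0) & test_mask).sum())
        train_pt[r] = -fit.nll / max(n_tr, 1)
        test_pt[r] = -test_nll / max(n_te, 1)
    return CrossValidationResult(
        model=model,
        param_names=PARAM_FIELDS[model],
        params_per_rep=params,
        train_ll=train_ll,
        test_ll=test_ll,
        train_ll_per_trial=train_pt,
        test_ll_per_trial=test_pt,
        full_fit=full,
    )


def compare_models(results) -> pd.DataFrame:
    """Rank fit results by AIC (lowest first).

    Accepts :class:`ModelFitResult` or :class:`CrossValidationResult`
    objects; all must be fit on the same number of scored trials.
    """
    rows = []
    n_trials = None
    for res in results:
        fit = res.full_fit if isinstance(res, CrossValidationResult) else res
        if n_trials is None:
            n_trials = fit.n_trials
        elif fit.n_trials != n_trials:
            raise ValueError("model comparison requires identical datasets")
        row = {
            "model": fit.model,
            "k": n_free_params(fit.model),
            "nll": fit.nll,
            "aic": fit.aic,
        }
        if isinstance(res, CrossValidationResult):
            row["mean_train_ll"] = float(np.mean(res.train_ll))
            row["mean_test_ll"] = float(np.mean(res.test_ll))
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("aic", kind="mergesort").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table


def param_correlations(params, names=None) -> pd.DataFrame:
    """Pairwise Pearson correlations of per-replicate parameter estimates.

    Constant parameters yield NaN (flagged rather than raising).
    """
    if isinstance(params, pd.DataFrame):
        names = list(params.columns)
        mat = params.to_numpy(dtype=float)
    else:
        mat = np.asarray(params, dtype=float)
        if names is None:
            names = [f"p{i}" for i in range(mat.shape[1])]
    if mat.shape[0] < 3:
        raise ValueError("need at least 3 replicates")
    stds = mat.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    corr = np.atleast_2d(corr)
    for i, s in enumerate(stds):
        if s == 0:
            corr[i, :] = np.nan
            corr[:, i] = np.nan
            corr[i, i] = np.nan
    return pd.DataFrame(corr, index=names, columns=names)


def model_behavior_ssd(model: str, params: ModelParams, trials, max_trial: int = 30):
    """Sum of squared deviations between model and observed learning curves.

    The model is replayed over the observed choices/rewards (teacher
    forcing); its probability of choosing the rewarded-colour stimulus is
    averaged per trial-since-reversal (1..``max_trial``) across blocks and
    compared to the observed proportion of rewarded choices.

    Returns ``(ssd, model_curve, observed_curve)``.
    """
    df = trials_to_frame(trials)
    if len(df) == 0:
        raise ValueError("empty trial table")
    params.validate(model)
    p_model = np.zeros(max_trial)
    p_obs = np.zeros(max_trial)
    counts = np.zeros(max_trial)
    for _, sess in df.groupby("session_id", sort=False):
        state = _m.ModelState()
        for row in sess.itertuples(index=False):
            stim_left = (0, _MOTION_CODE[row.left_motion], int(row.left_color) + 3)
            stim_right = (1, 5 - stim_left[1], 9 - stim_left[2])
            c = _CHOICE_CODE[row.choice]
            if c < 0:
                continue
            p_l, p_r = _m.choice_probs(model, params, state, stim_left, stim_right)
            rewarded_left = int(row.left_color) == int(row.rewarded_color)
            t = int(row.trial_in_block)
            if t <= max_trial:
                p_model[t - 1] += p_l if rewarded_left else p_r
                p_obs[t - 1] += float(row.reward)
                counts[t - 1] += 1
            _m.step_trial(model, params, state, stim_left, stim_right, c, float(row.reward))
    if counts.sum() == 0:
        raise ValueError("no scored trials within the alignment window")
    valid = counts > 0
    model_curve = np.full(max_trial, np.nan)
    obs_curve = np.full(max_trial, np.nan)
    model_curve[valid] = p_model[valid] / counts[valid]
    obs_curve[valid] = p_obs[valid] / counts[valid]
    ssd = float(np.nansum((model_curve - obs_curve) ** 2))
    return ssd, model_curve, obs_curve
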