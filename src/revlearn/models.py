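"""Learning models for two-alternative feature-based choice.

Eight models share a common trial interface: six elementary feature values
(left/right location, up/down motion, colour 1/2) compose the two stimuli on
every trial; each model turns its internal state into a choice probability
over the two sides, scores the observed choice, and updates its state from
the observed reward.

Feature index convention
------------------------
``0=L, 1=R, 2=U, 3=D, 4=C1, 5=C2``; the dimension of feature ``f`` is
``f // 2`` (0=location, 1=motion, 2=colour).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MODEL_NAMES",
    "PARAM_FIELDS",
    "N_FEATURES",
    "ModelParams",
    "ModelState",
    "delta_update",
    "decay_update",
    "two_eta_update",
    "softmax_choice",
    "bayes_update",
    "bi_choice_value",
    "dimension_weights",
    "fw_stimulus_value",
    "fw_update",
    "choice_history_probs",
    "choice_history_filter",
    "choice_probs",
    "step_trial",
    "trial_loglik",
    "session_loglik",
    "n_free_params",
]

N_FEATURES = 6
FEATURE_NAMES = ("L", "R", "U", "D", "C1", "C2")

#: registry keys for the eight models
MODEL_NAMES = (
    "FV",
    "FV+Decay",
    "FV+2Eta",
    "BI",
    "FW",
    "FW+ChoiceHistory",
    "FW+2Eta",
    "FW+Decay",
)

#: free parameters of each model, in fitting order
PARAM_FIELDS = {
    "FV": ("eta", "beta"),
    "FV+Decay": ("eta", "beta", "omega"),
    "FV+2Eta": ("eta1", "eta0", "beta"),
    "BI": ("beta",),
    "FW": ("eta", "beta", "alpha"),
    "FW+ChoiceHistory": ("eta", "beta", "alpha", "gamma"),
    "FW+2Eta": ("eta1", "eta0", "beta", "alpha"),
    "FW+Decay": ("eta", "beta", "alpha", "omega"),
}

#: models that carry a Bayesian posterior over the six candidate targets
BAYESIAN_MODELS = frozenset({"BI", "FW", "FW+ChoiceHistory", "FW+2Eta", "FW+Decay"})


def n_free_params(model: str) -> int:
    """Number of free parameters ``k`` of a registered model."""
    return len(PARAM_FIELDS[model])


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector; only the fields of the chosen model are used.

    ``p_r`` is the models' assumed reward reliability and is fixed at 0.99
    (it is not a free parameter of any model); ``p_n = 1 - p_r``.
    """

    eta: float = 0.5
    beta: float = 2.0
    omega: float = 1.0
    alpha: float = 1.0
    eta1: float = 0.5
    eta0: float = 0.5
    gamma: float = 1.0
    p_r: float = 0.99

    def validate(self, model: str) -> None:
        if model not in PARAM_FIELDS:
            raise ValueError(f"unknown model {model!r}")
        for name in ("eta", "eta1", "eta0", "beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.omega < 1:
            raise ValueError("omega must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if not 0.0 < self.p_r < 1.0:
            raise ValueError("p_r must be in (0, 1)")

    def to_vector(self, model: str) -> np.ndarray:
        return np.array([getattr(self, f) for f in PARAM_FIELDS[model]], dtype=float)

    @classmethod
    def from_vector(cls, model: str, theta: np.ndarray) -> "ModelParams":
        fields = PARAM_FIELDS[model]
        if len(theta) != len(fields):
            raise ValueError(f"{model} expects {len(fields)} parameters")
        return cls(**dict(zip(fields, map(float, theta))))


@dataclass
class ModelState:
    """Mutable per-session learner state.

    Values start at 0.5 and carry over across blocks (reversals are un-cued);
    the posterior starts uniform. ``prev_color`` is the colour feature index
    of the previous completed choice (-1 before the first choice).
    """

    values: np.ndarray = field(default_factory=lambda: np.full(N_FEATURES, 0.5))
    belief: np.ndarray = field(default_factory=lambda: np.full(N_FEATURES, 1.0 / 6))
    prev_color: int = -1

    def copy(self) -> "ModelState":
        return ModelState(self.values.copy(), self.belief.copy(), self.prev_color)


# ---------------------------------------------------------------------------
# elementary update rules
# ---------------------------------------------------------------------------

def delta_update(values: np.ndarray, chosen_features, reward: float, eta: float) -> np.ndarray:
    """Delta rule on the three features of the chosen stimulus.

    ``V_i <- V_i + eta * (R - V_i)`` for chosen ``i``; others unchanged.
    """
    if eta < 0:
        raise ValueError("eta must be >= 0")
    out = np.asarray(values, dtype=float).copy()
    idx = list(chosen_features)
    out[idx] += eta * (reward - out[idx])
    return out


def decay_update(values: np.ndarray, unchosen_features, omega: float) -> np.ndarray:
    """Divisive decay ``V_i <- V_i / omega`` of the non-chosen stimulus' features.

    ``omega = 1`` is the identity; larger ``omega`` means stronger decay.
    """
    if omega < 1:
        raise ValueError("omega must be >= 1")
    out = np.asarray(values, dtype=float).copy()
    idx = list(unchosen_features)
    out[idx] /= omega
    return out


def two_eta_update(values, chosen_features, reward, eta1: float, eta0: float) -> np.ndarray:
    """Delta rule with separate learning rates for rewarded / unrewarded trials."""
    if eta1 < 0 or eta0 < 0:
        raise ValueError("learning rates must be >= 0")
    return delta_update(values, chosen_features, reward, eta1 if reward == 1 else eta0)


def softmax_choice(value_left: float, value_right: float, beta: float):
    """Boltzmann choice probabilities ``P_j ∝ exp(beta * V_j)``.

    Computed with max-subtraction so large ``beta * V`` cannot overflow.
    """
    a = beta * value_left
    b = beta * value_right
    m = a if a > b else b
    ea = np.exp(a - m)
    eb = np.exp(b - m)
    z = ea + eb
    return ea / z, eb / z


def bayes_update(belief: np.ndarray, chosen_features, reward: float, p_r: float) -> np.ndarray:
    """One Bayesian posterior update over the six candidate targets.

    Candidates contained in the chosen stimulus are weighted by
    ``p_r*R + (1-p_r)*(1-R)``, the rest by ``p_n*R + (1-p_n)*(1-R)`` with
    ``p_n = 1 - p_r``; the posterior is renormalized.
    """
    p_n = 1.0 - p_r
    lik_in = p_r * reward + (1.0 - p_r) * (1.0 - reward)
    lik_out = p_n * reward + (1.0 - p_n) * (1.0 - reward)
    out = np.asarray(belief, dtype=float) * lik_out
    idx = list(chosen_features)
    out[idx] = np.asarray(belief, dtype=float)[idx] * lik_in
    total = out.sum()
    if total <= 0:
        raise ValueError("degenerate all-zero posterior")
    return out / total


def bi_choice_value(belief: np.ndarray, left_features, right_features, p_r: float):
    """Predicted reward probability of each side under the current posterior.

    ``P(R=1 | choose j) = sum_f p(R=1 | j, f) p(f)``; with ``p_n = 1 - p_r``
    the two sides' values sum to 1.
    """
    p_n = 1.0 - p_r
    b = np.asarray(belief, dtype=float)
    mass_left = b[list(left_features)].sum()
    mass_right = b[list(right_features)].sum()
    v_left = p_r * mass_left + p_n * (1.0 - mass_left)
    v_right = p_r * mass_right + p_n * (1.0 - mass_right)
    return v_left, v_right


def dimension_weights(belief: np.ndarray, alpha: float) -> np.ndarray:
    """Attention weights over (location, motion, colour).

    ``g_d`` is the posterior mass on dimension d's two feature values;
    ``w_d = g_d**alpha / sum_d' g_d'**alpha``.
    """
    b = np.asarray(belief, dtype=float)
    g = b.reshape(3, 2).sum(axis=1)
    ga = g ** alpha
    return ga / ga.sum()


def fw_stimulus_value(values: np.ndarray, weights: np.ndarray, stim_features) -> float:
    """Weighted stimulus value ``sum_d w_d * V(f_d of stimulus)``."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    return float(sum(w[f // 2] * v[f] for f in stim_features))


def fw_update(values, chosen_features, v_stim_chosen: float, reward, eta: float) -> np.ndarray:
    """Delta rule driven by the object-level prediction error ``R - V_stim``."""
    if eta < 0:
        raise ValueError("eta must be >= 0")
    out = np.asarray(values, dtype=float).copy()
    idx = list(chosen_features)
    out[idx] += eta * (reward - v_stim_chosen)
    return out


def choice_history_probs(p_left, p_right, left_color, right_color, prev_color, gamma):
    """Final choice probabilities after the colour-repetition filter.

    A provisional softmax choice matching the previously chosen colour is
    always accepted; a mismatching one is accepted with probability ``gamma``
    and otherwise switched to the colour-matching stimulus. With no previous
    choice the filter is the identity.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    if prev_color < 0:
        return p_left, p_right
    if left_color == prev_color:
        return p_left + p_right * (1.0 - gamma), p_right * gamma
    return p_left * gamma, p_right + p_left * (1.0 - gamma)


def choice_history_filter(provisional_choice, left_color, right_color, prev_color, gamma, rng):
    """Sampled version of the filter for generative simulation.

    ``provisional_choice`` is 0 (left) or 1 (right); returns the final choice.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    if prev_color < 0:
        return provisional_choice
    chosen_color = left_color if provisional_choice == 0 else right_color
    if chosen_color == prev_color or rng.random() < gamma:
        return provisional_choice
    return 1 - provisional_choice


# ---------------------------------------------------------------------------
# trial-level interface
# ---------------------------------------------------------------------------

def _stimulus_sum(values, feats):
    return float(np.asarray(values)[list(feats)].sum())


def choice_probs(model, params, state, left_features, right_features):
    """Probability of choosing (left, right) under the model's current state."""
    if model in ("FV", "FV+Decay", "FV+2Eta"):
        v_l = _stimulus_sum(state.values, left_features)
        v_r = _stimulus_sum(state.values, right_features)
    elif model == "BI":
        v_l, v_r = bi_choice_value(state.belief, left_features, right_features, params.p_r)
    elif model in ("FW", "FW+ChoiceHistory", "FW+2Eta", "FW+Decay"):
        w = dimension_weights(state.belief, params.alpha)
        v_l = fw_stimulus_value(state.values, w, left_features)
        v_r = fw_stimulus_value(state.values, w, right_features)
    else:
        raise ValueError(f"unknown model {model!r}")
    p_l, p_r = softmax_choice(v_l, v_r, params.beta)
    if model == "FW+ChoiceHistory":
        p_l, p_r = choice_history_probs(
            p_l, p_r, left_features[2], right_features[2], state.prev_color, params.gamma
        )
    return p_l, p_r


def step_trial(model, params, state, left_features, right_features, choice, reward):
    """Score the observed choice and update the state in place.

    ``choice`` is 0 (left) or 1 (right). Returns the log probability the
    model assigned to the observed choice *before* learning from its outcome.
    """
    p_l, p_r = choice_probs(model, params, state, left_features, right_features)
    p_obs = p_l if choice == 0 else p_r
    loglik = float(np.log(max(p_obs, 1e-12)))  # likelihood floor keeps NLL finite

    chosen = left_features if choice == 0 else right_features
    unchosen = right_features if choice == 0 else left_features

    if model == "FV":
        state.values = delta_update(state.values, chosen, reward, params.eta)
    elif model == "FV+Decay":
        state.values = delta_update(state.values, chosen, reward, params.eta)
        state.values = decay_update(state.values, unchosen, params.omega)
    elif model == "FV+2Eta":
        state.values = two_eta_update(state.values, chosen, reward, params.eta1, params.eta0)
    elif model == "BI":
        pass
    else:  # FW family: object-level prediction error from choice-time weights
        w = dimension_weights(state.belief, params.alpha)
        v_chosen = fw_stimulus_value(state.values, w, chosen)
        if model == "FW+2Eta":
            rate = params.eta1 if reward == 1 else params.eta0
            state.values = fw_update(state.values, chosen, v_chosen, reward, rate)
        else:
            state.values = fw_update(state.values, chosen, v_chosen, reward, params.eta)
        if model == "FW+Decay":
            state.values = decay_update(state.values, unchosen, params.omega)

    if model in BAYESIAN_MODELS:
        state.belief = bayes_update(state.belief, chosen, reward, params.p_r)
    state.prev_color = chosen[2]
    return loglik


_CHOICE_CODE = {"left": 0, "right": 1, "none": -1}


def trial_loglik(model, params, state, trial):
    """Log-likelihood increment of one :class:`~revlearn.task.TrialRecord`.

    Trials without a completed choice contribute zero and leave the state
    untouched.
    """
    c = _CHOICE_CODE[trial.choice] if isinstance(trial.choice, str) else trial.choice
    if c < 0:
        return 0.0
    left, right = trial.stimulus.feature_indices()
    return step_trial(model, params, state, left, right, c, trial.reward)


def session_loglik(model, params, trials):
    """Total log-likelihood of one session's trials (reference implementation).

    The state is initialized fresh; callers are responsible for passing a
    single session (values and beliefs carry over across its blocks).
    """
    params.validate(model)
    state = ModelState()
    return sum(trial_loglik(model, params, state, t) for t in trials)
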