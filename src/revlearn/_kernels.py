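"""Fast trial-loop likelihood kernel.

The optimizer evaluates the negative log-likelihood thousands of times, so
the per-trial recursion lives in a single numba-compiled loop over
preprocessed integer/float arrays. The readable reference implementation in
:mod:`revlearn.models` is the source of truth; a test asserts the two paths
agree to machine precision. If numba is unavailable the same function runs
as plain Python.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=False)
def filter_smoother_kernel(y, mu, sigma2_eps, x0, sigma2_0):
    """Forward filter / fixed-interval smoother for the Bernoulli state-space
    model; returns smoothed means & variances, smoothed x0 moments, lag-one
    covariances and the one-step predictive log-likelihood."""
    T = y.shape[0]
    xp = np.empty(T)
    vp = np.empty(T)
    xf = np.empty(T)
    vf = np.empty(T)
    loglik = 0.0
    x_prev = x0
    v_prev = sigma2_0
    for t in range(T):
        xp[t] = x_prev
        vp[t] = v_prev + sigma2_eps
        p_pred = 1.0 / (1.0 + np.exp(-(mu + xp[t])))
        if p_pred < 1e-12:
            p_pred = 1e-12
        elif p_pred > 1.0 - 1e-12:
            p_pred = 1.0 - 1e-12
        loglik += y[t] * np.log(p_pred) + (1.0 - y[t]) * np.log(1.0 - p_pred)
        x = xp[t]
        for _ in range(50):
            p = 1.0 / (1.0 + np.exp(-(mu + x)))
            g = (x - xp[t]) / vp[t] - (y[t] - p)
            h = 1.0 / vp[t] + p * (1.0 - p)
            step = g / h
            x -= step
            if abs(step) < 1e-10:
                break
        p = 1.0 / (1.0 + np.exp(-(mu + x)))
        xf[t] = x
        vf[t] = 1.0 / (1.0 / vp[t] + p * (1.0 - p))
        x_prev = xf[t]
        v_prev = vf[t]
    xs = xf.copy()
    vs = vf.copy()
    A = np.zeros(T)
    for t in range(T - 2, -1, -1):
        A[t] = vf[t] / vp[t + 1]
        xs[t] = xf[t] + A[t] * (xs[t + 1] - xp[t + 1])
        vs[t] = vf[t] + A[t] ** 2 * (vs[t + 1] - vp[t + 1])
    A0 = sigma2_0 / vp[0]
    x0s = x0 + A0 * (xs[0] - xp[0])
    v0s = sigma2_0 + A0 ** 2 * (vs[0] - vp[0])
    cov = np.empty(T)
    cov[0] = A0 * vs[0]
    for t in range(1, T):
        cov[t] = A[t - 1] * vs[t]
    return xs, vs, x0s, v0s, cov, loglik


MODEL_IDS = {
    "FV": 0,
    "FV+Decay": 1,
    "FV+2Eta": 2,
    "BI": 3,
    "FW": 4,
    "FW+ChoiceHistory": 5,
    "FW+2Eta": 6,
    "FW+Decay": 7,
}

LIK_FLOOR = 1e-12


@njit(cache=False)
def nll_kernel(
    model_id,
    eta,
    beta,
    omega,
    alpha,
    eta1,
    eta0,
    gamma,
    p_r,
    left_feats,
    right_feats,
    choice,
    reward,
    session_start,
    include,
):
    """Negative log-likelihood of included trials under one model.

    Arrays are trial-major: ``left_feats``/``right_feats`` are (n, 3) feature
    indices, ``choice`` is 0/1/-1 (-1 = no completed choice: skipped, no
    update), ``session_start`` marks state resets, ``include`` selects the
    trials whose likelihood is accumulated (all trials still drive updates).
    """
    n = choice.shape[0]
    values = np.full(6, 0.5)
    belief = np.full(6, 1.0 / 6.0)
    prev_color = -1
    p_n = 1.0 - p_r
    bayesian = model_id >= 3
    total = 0.0

    for t in range(n):
        if session_start[t]:
            for i in range(6):
                values[i] = 0.5
                belief[i] = 1.0 / 6.0
            prev_color = -1
        c = choice[t]
        if c < 0:
            continue
        lf0, lf1, lf2 = left_feats[t, 0], left_feats[t, 1], left_feats[t, 2]
        rf0, rf1, rf2 = right_feats[t, 0], right_feats[t, 1], right_feats[t, 2]

        if model_id <= 2:
            v_l = values[lf0] + values[lf1] + values[lf2]
            v_r = values[rf0] + values[rf1] + values[rf2]
        elif model_id == 3:
            mass_l = belief[lf0] + belief[lf1] + belief[lf2]
            v_l = p_r * mass_l + p_n * (1.0 - mass_l)
            v_r = p_r * (1.0 - mass_l) + p_n * mass_l
        else:
            g0 = belief[0] + belief[1]
            g1 = belief[2] + belief[3]
            g2 = belief[4] + belief[5]
            w0 = g0 ** alpha
            w1 = g1 ** alpha
            w2 = g2 ** alpha
            wz = w0 + w1 + w2
            w0 /= wz
            w1 /= wz
            w2 /= wz
            v_l = w0 * values[lf0] + w1 * values[lf1] + w2 * values[lf2]
            v_r = w0 * values[rf0] + w1 * values[rf1] + w2 * values[rf2]

        a = beta * v_l
        b = beta * v_r
        m = a if a > b else b
        ea = np.exp(a - m)
        eb = np.exp(b - m)
        p_l = ea / (ea + eb)
        p_rr = 1.0 - p_l

        if model_id == 5 and prev_color >= 0:
            if lf2 == prev_color:
                p_l = p_l + p_rr * (1.0 - gamma)
                p_rr = 1.0 - p_l
            else:
                p_rr = p_rr + p_l * (1.0 - gamma)
                p_l = 1.0 - p_rr

        if include[t]:
            p_obs = p_l if c == 0 else p_rr
            if p_obs < LIK_FLOOR:
                p_obs = LIK_FLOOR
            total -= np.log(p_obs)

        r = reward[t]
        if c == 0:
            ch0, ch1, ch2 = lf0, lf1, lf2
            un0, un1, un2 = rf0, rf1, rf2
            v_ch = v_l
        else:
            ch0, ch1, ch2 = rf0, rf1, rf2
            un0, un1, un2 = lf0, lf1, lf2
            v_ch = v_r

        if model_id == 0 or model_id == 1:
            values[ch0] += eta * (r - values[ch0])
            values[ch1] += eta * (r - values[ch1])
            values[ch2] += eta * (r - values[ch2])
            if model_id == 1:
                values[un0] /= omega
                values[un1] /= omega
                values[un2] /= omega
        elif model_id == 2:
            rate = eta1 if r == 1.0 else eta0
            values[ch0] += rate * (r - values[ch0])
            values[ch1] += rate * (r - values[ch1])
            values[ch2] += rate * (r - values[ch2])
        elif model_id >= 4:
            if model_id == 6:
                rate = eta1 if r == 1.0 else eta0
            else:
                rate = eta
            pe = rate * (r - v_ch)
            values[ch0] += pe
            values[ch1] += pe
            values[ch2] += pe
            if model_id == 7:
                values[un0] /= omega
                values[un1] /= omega
                values[un2] /= omega

        if bayesian:
            lik_in = p_r * r + (1.0 - p_r) * (1.0 - r)
            lik_out = p_n * r + (1.0 - p_n) * (1.0 - r)
            z = 0.0
            for i in range(6):
                if i == ch0 or i == ch1 or i == ch2:
                    belief[i] *= lik_in
                else:
                    belief[i] *= lik_out
                z += belief[i]
            for i in range(6):
                belief[i] /= z
        prev_color = ch2
    return total
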