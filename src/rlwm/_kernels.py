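"""Jit-compiled likelihood kernels.

The per-trial recursion is small but runs hundreds of thousands of times
during MAP fitting (capacity grid x multi-start x optimizer evaluations), so
the hot path is compiled with numba.  A transparent pure-Python fallback keeps
the package importable without a working JIT.

Parameter vector layout used throughout: [alpha_rl, gamma, phi, rho, nu].
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


I_ALPHA, I_GAMMA, I_PHI, I_RHO, I_NU = 0, 1, 2, 3, 4


@njit(cache=True)
def _softmax_prob(values, beta, idx):
    """P(action ``idx``) under softmax(beta * values), max-subtracted."""
    m = values[0]
    for j in range(1, values.shape[0]):
        if values[j] > m:
            m = values[j]
    denom = 0.0
    for j in range(values.shape[0]):
        denom += math.exp(beta * (values[j] - m))
    return math.exp(beta * (values[idx] - m)) / denom


@njit(cache=True)
def train_loglik_fill(
    params,
    wm_cap,
    beta,
    n_actions,
    block_ptr,
    block_n_stim,
    stim_local,
    stim_global,
    action,
    reward,
    critic_reward,
    pair_level_decay,
    v_out,
    logp_out,
):
    """Training-phase per-trial log-probabilities and end-of-training critic.

    State resets at each block start.  Per trial, in order: choice probability
    from the current state, delay-counter update, WM/RL/critic updates for the
    observed (stimulus, action) pair, then WM decay of all other entries.

    ``v_out`` must be prefilled with the 1/n_a prior; it is updated in place
    and holds end-of-training stimulus values on return.  ``logp_out`` receives
    log p(observed action) per trial.
    """
    alpha = params[I_ALPHA]
    gamma = params[I_GAMMA]
    phi = params[I_PHI]
    rho = params[I_RHO]
    inv_na = 1.0 / n_actions
    n_blocks = block_ptr.shape[0] - 1

    for b in range(n_blocks):
        ns = block_n_stim[b]
        Q = np.full((ns, n_actions), inv_na)
        WM = np.full((ns, n_actions), inv_na)
        seen = np.zeros((ns, ns), np.bool_)
        delay = np.zeros(ns, np.int64)

        for t in range(block_ptr[b], block_ptr[b + 1]):
            s = stim_local[t]
            g = stim_global[t]
            a = action[t]
            r = reward[t]

            # mixture policy; omega = rho * min(1, cap / n_delay), n_delay=0 -> rho
            if delay[s] <= wm_cap:
                omega = rho
            else:
                omega = rho * wm_cap / delay[s]
            p_rl = _softmax_prob(Q[s], beta, a)
            p_wm = _softmax_prob(WM[s], beta, a)
            p = (1.0 - omega) * p_rl + omega * p_wm
            logp_out[t] = math.log(p)

            # delay counters: presenting s makes it a unique intervening item
            # for every other stimulus that has not seen it since its last
            # correct response; a correct response to s resets s's counter
            for k in range(ns):
                if k != s and not seen[k, s]:
                    seen[k, s] = True
                    delay[k] += 1
            if r == 1.0:
                delay[s] = 0
                for j in range(ns):
                    seen[s, j] = False

            # learning updates for the observed pair
            if r == 1.0:
                Q[s, a] += alpha * (1.0 - Q[s, a])
                WM[s, a] = 1.0
                v_out[g] += alpha * (critic_reward[t] - v_out[g])
            else:
                Q[s, a] += alpha * gamma * (0.0 - Q[s, a])
                WM[s, a] += gamma * (0.0 - WM[s, a])
                v_out[g] += alpha * gamma * (critic_reward[t] - v_out[g])

            # WM decay toward the uniform prior for all non-observed entries
            for i in range(ns):
                for j in range(n_actions):
                    if i == s:
                        if pair_level_decay:
                            if j == a:
                                continue
                        else:
                            continue
                    WM[i, j] += phi * (inv_na - WM[i, j])


@njit(cache=True)
def test_loglik_fill(v, beta, nu, left, right, choice, logp_out):
    """Test-phase per-trial log-probabilities.

    p(left) = nu/2 + (1-nu) * softmax_2(beta*(v_left, v_right)); ``choice`` is
    0 for left, 1 for right.
    """
    for t in range(left.shape[0]):
        x = beta * (v[left[t]] - v[right[t]])
        if x >= 0.0:
            p_soft = 1.0 / (1.0 + math.exp(-x))
        else:
            e = math.exp(x)
            p_soft = e / (1.0 + e)
        p_left = 0.5 * nu + (1.0 - nu) * p_soft
        p = p_left if choice[t] == 0 else 1.0 - p_left
        if p < 1e-300:
            p = 1e-300
        logp_out[t] = math.log(p)
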