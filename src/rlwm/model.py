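"""The RLWM mixture model.

Two parallel learners drive training-phase choice.  An incremental
reinforcement-learning (RL) actor tracks Q(s, a) with Rescorla-Wagner updates
whose learning rate alpha_rl is discounted by gamma on incorrect trials
(punishment neglect).  A working-memory (WM) store tracks WM(s, a) with
one-shot encoding of correct outcomes, the same gamma-discounted update for
errors, and per-trial decay (rate phi) of all unobserved entries back to the
uniform prior 1/n_a.  Both tables are mapped to action probabilities through a
softmax with fixed inverse temperature beta = 50 and mixed linearly:

    p = (1 - omega) * p_RL + omega * p_WM,
    omega = rho * min(1, wm_cap / n_delay),

where n_delay counts the unique other stimuli presented since the stimulus's
last correct response, so WM reliance falls off once interference exceeds the
integer capacity wm_cap.  A critic V(s), learning at the RL rate, supplies
values for the surprise test phase, where choice follows a two-option softmax
mixed with uniform guessing at rate nu.

Six free parameters: alpha_rl, gamma, phi, rho (all in [0, 1]), wm_cap in
{2..5}, nu in [0, 1].  beta is a fixed constant, not fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import test_loglik_fill, train_loglik_fill

__all__ = [
    "BETA_FIXED",
    "PARAM_NAMES",
    "CONTINUOUS_PARAMS",
    "ModelParams",
    "ModelState",
    "ChoiceProbs",
    "ModelOptions",
    "init_state",
    "rl_update",
    "wm_update",
    "wm_decay",
    "critic_update",
    "wm_weight",
    "policy_probs",
    "test_choice_prob",
    "PackedSession",
    "pack_session",
    "session_loglik",
]

#: Fixed softmax inverse temperature; deliberately high so that choice noise is
#: absorbed by the mixture weights rather than a temperature parameter.
BETA_FIXED = 50.0

PARAM_NAMES = ("alpha_rl", "gamma", "phi", "rho", "wm_cap", "nu")
CONTINUOUS_PARAMS = ("alpha_rl", "gamma", "phi", "rho", "nu")

WM_CAP_GRID = (2, 3, 4, 5)


@dataclass(frozen=True)
class ModelParams:
    """The model's six free parameters plus the fixed inverse temperature."""

    alpha_rl: float
    gamma: float
    phi: float
    rho: float
    wm_cap: int
    nu: float
    beta: float = BETA_FIXED

    def validate(self) -> None:
        for name in ("alpha_rl", "gamma", "phi", "rho", "nu"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.wm_cap not in WM_CAP_GRID:
            raise ValueError(f"wm_cap={self.wm_cap} outside {{2..5}}")

    def continuous_array(self) -> np.ndarray:
        """[alpha_rl, gamma, phi, rho, nu] in kernel layout."""
        return np.array(
            [self.alpha_rl, self.gamma, self.phi, self.rho, self.nu], dtype=float
        )

    @classmethod
    def from_continuous(cls, x: np.ndarray, wm_cap: int, beta: float = BETA_FIXED):
        return cls(
            alpha_rl=float(x[0]),
            gamma=float(x[1]),
            phi=float(x[2]),
            rho=float(x[3]),
            wm_cap=int(wm_cap),
            nu=float(x[4]),
            beta=beta,
        )

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}


@dataclass
class ModelOptions:
    """Variants of the update rules that the model exposes as switches.

    ``pair_level_decay``: if True (default, the literal reading of the decay
    rule) only the single observed (stimulus, action) pair is exempt from WM
    decay; if False, all actions of the current stimulus are exempt.
    ``point_critic``: if True the critic learns from the earned points
    {0, 1, 2} instead of the binary correct/incorrect code.
    ``skip_pre_first_correct``: if True, training trials before a stimulus's
    first correct response contribute no likelihood (state updates still run).
    """

    pair_level_decay: bool = True
    point_critic: bool = False
    skip_pre_first_correct: bool = False


@dataclass
class ModelState:
    """Evolving within-block state: Q/WM tables, critic, delay counters."""

    Q: np.ndarray  # (set_size, n_actions)
    WM: np.ndarray  # (set_size, n_actions)
    V: np.ndarray  # (set_size,)
    delay_count: np.ndarray  # (set_size,) ints
    seen_since_correct: np.ndarray  # (set_size, set_size) bools
    n_actions: int


@dataclass
class ChoiceProbs:
    p_rl: np.ndarray
    p_wm: np.ndarray
    omega: float
    p: np.ndarray


def init_state(set_size: int, n_actions: int) -> ModelState:
    """Uniform-prior state: all actions equally likely for every stimulus."""
    if set_size < 1 or n_actions < 1:
        raise ValueError("set_size and n_actions must be >= 1")
    u = 1.0 / n_actions
    return ModelState(
        Q=np.full((set_size, n_actions), u),
        WM=np.full((set_size, n_actions), u),
        V=np.full(set_size, u),
        delay_count=np.zeros(set_size, dtype=int),
        seen_since_correct=np.zeros((set_size, set_size), dtype=bool),
        n_actions=n_actions,
    )


def _check_reward(r: float) -> None:
    if r not in (0, 1):
        raise ValueError(f"reward must be binary 0/1, got {r}")


def rl_update(q: float, r: int, params: ModelParams) -> float:
    """Rescorla-Wagner update with punishment neglect on incorrect trials."""
    _check_reward(r)
    if r == 1:
        return q + params.alpha_rl * (1.0 - q)
    return q + params.alpha_rl * params.gamma * (0.0 - q)


def wm_update(w: float, r: int, params: ModelParams) -> float:
    """One-shot WM encoding: correct -> 1 exactly; errors discounted by gamma."""
    _check_reward(r)
    if r == 1:
        return 1.0
    return w + params.gamma * (0.0 - w)


def wm_decay(
    state: ModelState,
    observed: tuple[int, int],
    params: ModelParams,
    pair_level: bool = True,
) -> ModelState:
    """Decay all non-observed WM entries toward the uniform prior, in place."""
    s_obs, a_obs = observed
    u = 1.0 / state.n_actions
    mask = np.ones_like(state.WM, dtype=bool)
    if pair_level:
        mask[s_obs, a_obs] = False
    else:
        mask[s_obs, :] = False
    state.WM[mask] += params.phi * (u - state.WM[mask])
    return state


def critic_update(v: float, r: float, params: ModelParams, correct: bool | None = None) -> float:
    """Stimulus-value update at the RL rate; same form as the actor.

    With binary coding ``r`` doubles as the correctness flag.  With point
    coding (r in {0, 1, 2}) pass ``correct`` explicitly, since +1-point trials
    are correct trials and must use the undiscounted rate.
    """
    if correct is None:
        _check_reward(r)
        correct = r == 1
    if correct:
        return v + params.alpha_rl * (r - v)
    return v + params.alpha_rl * params.gamma * (r - v)


def wm_weight(params: ModelParams, n_delay: int) -> float:
    """Effective WM weight omega = rho * min(1, wm_cap / n_delay)."""
    if n_delay < 0:
        raise ValueError("n_delay must be >= 0")
    if n_delay <= params.wm_cap:
        return params.rho
    return params.rho * params.wm_cap / n_delay


def _softmax(values: np.ndarray, beta: float) -> np.ndarray:
    z = beta * values
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def policy_probs(state: ModelState, stimulus: int, params: ModelParams) -> ChoiceProbs:
    """Mixture policy for one stimulus given the current state."""
    p_rl = _softmax(state.Q[stimulus], params.beta)
    p_wm = _softmax(state.WM[stimulus], params.beta)
    omega = wm_weight(params, int(state.delay_count[stimulus]))
    p = (1.0 - omega) * p_rl + omega * p_wm
    return ChoiceProbs(p_rl=p_rl, p_wm=p_wm, omega=omega, p=p)


def test_choice_prob(v_a: float, v_b: float, params: ModelParams) -> float:
    """P(choose a) in the test phase: softmax over (v_a, v_b) mixed with guessing."""
    x = params.beta * (v_a - v_b)
    if x >= 0:
        p_soft = 1.0 / (1.0 + np.exp(-x))
    else:
        e = np.exp(x)
        p_soft = e / (1.0 + e)
    return 0.5 * params.nu + (1.0 - params.nu) * p_soft


def update_after_trial(
    state: ModelState,
    stimulus: int,
    action: int,
    reward: int,
    params: ModelParams,
    critic_reward: float | None = None,
    pair_level_decay: bool = True,
) -> ModelState:
    """Post-choice state transition: delay counters, pair updates, WM decay.

    This is the single transition used by both the simulator and (in compiled
    form) the likelihood; order matters and is identical in both.
    """
    set_size = state.Q.shape[0]
    for k in range(set_size):
        if k != stimulus and not state.seen_since_correct[k, stimulus]:
            state.seen_since_correct[k, stimulus] = True
            state.delay_count[k] += 1
    if reward == 1:
        state.delay_count[stimulus] = 0
        state.seen_since_correct[stimulus, :] = False

    state.Q[stimulus, action] = rl_update(state.Q[stimulus, action], reward, params)
    state.WM[stimulus, action] = wm_update(state.WM[stimulus, action], reward, params)
    cr = reward if critic_reward is None else critic_reward
    state.V[stimulus] = critic_update(state.V[stimulus], cr, params, correct=reward == 1)

    wm_decay(state, (stimulus, action), params, pair_level=pair_level_decay)
    return state


# ---------------------------------------------------------------------------
# Session likelihood
# ---------------------------------------------------------------------------


@dataclass
class PackedSession:
    """A subject-session flattened into kernel-ready arrays.

    Packing is done once per fit; the arrays are reused across every
    likelihood evaluation of the optimizer.
    """

    n_actions: int
    block_ptr: np.ndarray
    block_n_stim: np.ndarray
    stim_local: np.ndarray
    stim_global: np.ndarray
    action: np.ndarray
    reward: np.ndarray
    critic_reward_binary: np.ndarray
    critic_reward_points: np.ndarray
    test_left: np.ndarray
    test_right: np.ndarray
    test_choice: np.ndarray
    stim_index: dict[int, int]  # original stimulus id -> global index
    train_weight: np.ndarray  # 0/1 mask; 0 marks pre-first-correct trials
    _v_buf: np.ndarray = field(repr=False, default=None)
    _logp_buf: np.ndarray = field(repr=False, default=None)

    @property
    def n_train(self) -> int:
        return self.stim_local.shape[0]

    @property
    def n_test(self) -> int:
        return self.test_left.shape[0]

    @property
    def n_stimuli(self) -> int:
        return len(self.stim_index)

    def loglik(
        self, params: ModelParams, options: ModelOptions | None = None
    ) -> float:
        """Joint training + test log-likelihood."""
        ll, _, _ = self.loglik_detail(params, options)
        return ll

    def loglik_detail(
        self, params: ModelParams, options: ModelOptions | None = None
    ) -> tuple[float, np.ndarray, np.ndarray]:
        """(total, per-trial training log-p, end-of-training V)."""
        options = options or ModelOptions()
        if self._v_buf is None or self._v_buf.shape[0] != self.n_stimuli:
            self._v_buf = np.empty(self.n_stimuli)
            self._logp_buf = np.empty(self.n_train)
        v = self._v_buf
        v.fill(1.0 / self.n_actions)
        logp = self._logp_buf
        cr = (
            self.critic_reward_points
            if options.point_critic
            else self.critic_reward_binary
        )
        train_loglik_fill(
            params.continuous_array(),
            int(params.wm_cap),
            float(params.beta),
            self.n_actions,
            self.block_ptr,
            self.block_n_stim,
            self.stim_local,
            self.stim_global,
            self.action,
            self.reward,
            cr,
            options.pair_level_decay,
            v,
            logp,
        )
        if options.skip_pre_first_correct:
            total = float(logp @ self.train_weight)
        else:
            total = float(logp.sum())
        if self.n_test:
            test_logp = np.empty(self.n_test)
            test_loglik_fill(
                v,
                float(params.beta),
                float(params.nu),
                self.test_left,
                self.test_right,
                self.test_choice,
                test_logp,
            )
            total += float(test_logp.sum())
        return total, logp, v


def pack_session(
    training: pd.DataFrame, test: pd.DataFrame | None = None, n_actions: int = 3
) -> PackedSession:
    """Flatten trial tables for one subject-session into a :class:`PackedSession`.

    ``training`` needs columns block_id, stimulus_id, action, correct (and
    points for the point-coded critic); rows must be time-ordered within
    block.  ``test`` needs left_stimulus, right_stimulus, choice (0=left,
    1=right, or "left"/"right").
    """
    required = {"block_id", "stimulus_id", "action", "correct"}
    missing = required - set(training.columns)
    if missing:
        raise ValueError(f"training table missing columns: {sorted(missing)}")
    if "trial_index" in training.columns:
        ti = training.groupby("block_id", sort=False)["trial_index"]
        if (ti.diff().dropna() <= 0).any():
            raise ValueError("training trials are not time-ordered within block")

    block_ids = training["block_id"].to_numpy()
    # preserve first-appearance block order
    uniq_blocks = pd.unique(block_ids)
    stim_index: dict[int, int] = {}
    block_ptr = [0]
    block_n_stim = []
    stim_local = np.empty(len(training), dtype=np.int64)
    stim_global = np.empty(len(training), dtype=np.int64)
    stims_all = training["stimulus_id"].to_numpy()
    pos = 0
    for b in uniq_blocks:
        mask = block_ids == b
        stims = stims_all[mask]
        local: dict[int, int] = {}
        for s in stims:
            if s not in local:
                local[s] = len(local)
        for s in local:
            if s in stim_index:
                raise ValueError(f"stimulus {s} appears in more than one block")
            stim_index[s] = len(stim_index)
        n = int(mask.sum())
        stim_local[pos : pos + n] = [local[s] for s in stims]
        stim_global[pos : pos + n] = [stim_index[s] for s in stims]
        pos += n
        block_ptr.append(pos)
        block_n_stim.append(len(local))

    # rows were consumed block-by-block above (within-block time order kept);
    # reorder the remaining columns identically
    row_order = np.concatenate([np.flatnonzero(block_ids == b) for b in uniq_blocks])
    action = training["action"].to_numpy(dtype=np.int64)[row_order]
    correct = training["correct"].to_numpy(dtype=float)[row_order]
    if "points" in training.columns:
        points = training["points"].to_numpy(dtype=float)[row_order]
    else:
        points = correct.copy()

    # pre-first-correct mask per stimulus
    weight = np.ones(len(training))
    seen_correct: set[int] = set()
    for t in range(len(training)):
        g = stim_global[t]
        if g not in seen_correct:
            weight[t] = 0.0
            if correct[t] == 1.0:
                seen_correct.add(g)

    if test is not None and len(test):
        for col in ("left_stimulus", "right_stimulus", "choice"):
            if col not in test.columns:
                raise ValueError(f"test table missing column: {col}")
        def _lookup(s):
            try:
                return stim_index[s]
            except KeyError:
                raise ValueError(
                    f"test trial references stimulus {s} absent from training"
                ) from None

        left = np.array([_lookup(s) for s in test["left_stimulus"]], dtype=np.int64)
        right = np.array([_lookup(s) for s in test["right_stimulus"]], dtype=np.int64)
        ch = test["choice"]
        if ch.dtype == object:
            choice = np.array([0 if c == "left" else 1 for c in ch], dtype=np.int64)
        else:
            choice = ch.to_numpy(dtype=np.int64)
    else:
        left = right = choice = np.empty(0, dtype=np.int64)

    return PackedSession(
        n_actions=n_actions,
        block_ptr=np.array(block_ptr, dtype=np.int64),
        block_n_stim=np.array(block_n_stim, dtype=np.int64),
        stim_local=stim_local,
        stim_global=stim_global,
        action=action,
        reward=correct,
        critic_reward_binary=correct,
        critic_reward_points=points,
        test_left=left,
        test_right=right,
        test_choice=choice,
        stim_index=stim_index,
        train_weight=weight,
    )


def session_loglik(
    training: pd.DataFrame,
    test: pd.DataFrame | None,
    params: ModelParams,
    n_actions: int = 3,
    options: ModelOptions | None = None,
) -> float:
    """Joint log-likelihood of one subject-session under ``params``.

    Convenience wrapper over :func:`pack_session`; fitting code packs once and
    calls :meth:`PackedSession.loglik` directly.
    """
    params.validate()
    return pack_session(training, test, n_actions=n_actions).loglik(params, options)
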