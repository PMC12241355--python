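"""Synthetic behavioral data: simulated agents and study-like cohorts.

Agents are simulated directly from the generative model, trial by trial, with
the same state transition the likelihood uses.  Cohorts embed agents in a
covariate structure emulating the study: a standardized dopamine-synthesis
proxy per subject, three drug sessions (placebo PBO, methylphenidate MPH,
sulpiride SUL) in counterbalanced order, and a configurable map from
covariates to model parameters on transformed (logit) scales.  An optional
effort-cost knob ``kappa_effort`` devalues test-phase stimulus values in
proportion to the set size they were learned under, emulating implicit effort
discounting; it affects test-choice generation only.

The covariate->parameter link functions are conveniences of this package, not
part of the cognitive model: unit-interval parameters shift on the logit
scale, capacity shifts additively and is rounded into {2..5}.  Default effect
sizes are loosely scaled to the standardized regression coefficients the
phenomenon is known by (positive dopamine-proxy effect on rho, negative
sulpiride effect on rho, positive methylphenidate-by-dopamine interaction on
alpha_rl, positive sulpiride effect on phi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelOptions, ModelParams, init_state, policy_probs, test_choice_prob, update_after_trial
from .task import TaskConfig, TaskDesign, build_test_pairs, generate_task

__all__ = [
    "SESSION_LABELS",
    "PopulationSpec",
    "SyntheticDataset",
    "simulate_subject",
    "generate_population",
]

SESSION_LABELS = ("PBO", "MPH", "SUL")

#: Default RT distribution: lognormal with median ~1.07 s, the scale of
#: observed median response times; exists so RT-based filters are exercisable.
RT_MEDIAN = 1.07
RT_SIGMA = 0.4


def simulate_subject(
    design: TaskDesign,
    params: ModelParams,
    rng: np.random.Generator,
    kappa_effort: float = 0.0,
    options: ModelOptions | None = None,
    rt_median: float = RT_MEDIAN,
    rt_sigma: float = RT_SIGMA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one session: training trials then test-phase choices.

    Returns ``(training, test)`` DataFrames.  Training actions are sampled
    from the mixture policy; points on correct trials follow the configured
    +2/+1 split.  Test choices are sampled from the test choice rule applied
    to end-of-training critic values minus ``kappa_effort * set_size``.
    """
    params.validate()
    options = options or ModelOptions()
    cfg = design.config
    point_vals = np.array(sorted(cfg.reward_points), dtype=int)
    point_p = np.array([cfg.reward_points[v] for v in point_vals])

    train_rows = []
    V: dict[int, float] = {}
    for block in design.blocks:
        state = init_state(block.set_size, cfg.n_actions)
        local = {s: i for i, s in enumerate(block.stimulus_ids)}
        for t, stim in enumerate(block.trial_sequence):
            i = local[stim]
            probs = policy_probs(state, i, params)
            action = int(rng.choice(cfg.n_actions, p=probs.p))
            correct = action == block.correct_action[stim]
            if correct:
                points = int(rng.choice(point_vals, p=point_p))
            else:
                points = cfg.incorrect_points
            reward = 1 if correct else 0
            critic_r = float(points) if options.point_critic else float(reward)
            update_after_trial(
                state,
                i,
                action,
                reward,
                params,
                critic_reward=critic_r,
                pair_level_decay=options.pair_level_decay,
            )
            train_rows.append(
                {
                    "block_id": block.block_id,
                    "set_size": block.set_size,
                    "trial_index": t,
                    "stimulus_id": stim,
                    "action": action,
                    "correct": int(correct),
                    "points": points,
                    "rt": float(rng.lognormal(np.log(rt_median), rt_sigma)),
                }
            )
        for s, i in local.items():
            V[s] = float(state.V[i])

    test_rows = []
    for left, right in design.test_pairs:
        v_l = V[left] - kappa_effort * design.set_size_of(left)
        v_r = V[right] - kappa_effort * design.set_size_of(right)
        p_left = test_choice_prob(v_l, v_r, params)
        choice = "left" if rng.random() < p_left else "right"
        test_rows.append(
            {
                "left_stimulus": left,
                "right_stimulus": right,
                "choice": choice,
                "rt": float(rng.lognormal(np.log(rt_median), rt_sigma)),
            }
        )
    train = pd.DataFrame(train_rows)
    test = pd.DataFrame(test_rows, columns=["left_stimulus", "right_stimulus", "choice", "rt"])
    return train, test


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


def _expit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


@dataclass
class PopulationSpec:
    """Covariate structure and covariate->parameter effects for a cohort.

    ``effect_map`` maps parameter name -> {term: coefficient} where terms are
    ``da`` (standardized dopamine-synthesis proxy), ``mph``/``sul`` (drug
    indicator vs placebo), and the interactions ``mph:da``/``sul:da``.
    Coefficients act on the logit scale for unit-interval parameters and
    additively (then rounded and clipped into {2..5}) for ``wm_cap``.
    ``param_sd`` adds independent logit-scale subject noise per parameter.
    """

    n_subjects: int = 30
    sessions: tuple[str, ...] = SESSION_LABELS
    base_params: ModelParams = field(
        default_factory=lambda: ModelParams(
            alpha_rl=0.02, gamma=0.44, phi=0.15, rho=0.85, wm_cap=3, nu=0.08
        )
    )
    effect_map: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "rho": {"da": 0.3, "sul": -0.4},
            "alpha_rl": {"mph:da": 0.3},
            "phi": {"sul": 0.3},
        }
    )
    param_sd: dict[str, float] = field(default_factory=dict)
    kappa_effort: float = 0.0
    rng_seed: int | None = None

    def params_for(
        self, da: float, session: str, noise: dict[str, float] | None = None
    ) -> ModelParams:
        """Per-session parameters implied by the covariates (before trial noise)."""
        terms = {
            "da": da,
            "mph": 1.0 if session == "MPH" else 0.0,
            "sul": 1.0 if session == "SUL" else 0.0,
        }
        terms["mph:da"] = terms["mph"] * da
        terms["sul:da"] = terms["sul"] * da
        out = {}
        for name in ("alpha_rl", "gamma", "phi", "rho", "nu"):
            base = getattr(self.base_params, name)
            shift = sum(
                coef * terms[t] for t, coef in self.effect_map.get(name, {}).items()
            )
            if noise:
                shift += noise.get(name, 0.0)
            out[name] = base if shift == 0.0 else _expit(_logit(base) + shift)
        cap_shift = sum(
            coef * terms[t] for t, coef in self.effect_map.get("wm_cap", {}).items()
        )
        if noise:
            cap_shift += noise.get("wm_cap", 0.0)
        cap = int(np.clip(round(self.base_params.wm_cap + cap_shift), 2, 5))
        return ModelParams(wm_cap=cap, **out)


@dataclass
class SyntheticDataset:
    """A full simulated cohort: trials, covariates, truths, and designs."""

    subjects: pd.DataFrame  # subject_id, da
    training: pd.DataFrame
    test: pd.DataFrame
    true_params: pd.DataFrame  # one row per subject-session
    designs: dict[tuple[int, str], TaskDesign]

    def session_tables(
        self, subject_id: int, session: str
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        tr = self.training[
            (self.training.subject_id == subject_id)
            & (self.training.session_label == session)
        ]
        te = self.test[
            (self.test.subject_id == subject_id)
            & (self.test.session_label == session)
        ]
        return tr, te


def generate_population(
    spec: PopulationSpec,
    config: TaskConfig,
    rng: np.random.Generator,
    options: ModelOptions | None = None,
) -> SyntheticDataset:
    """Simulate a whole cohort: one fresh task design per subject-session.

    Subject covariates are drawn once (standard-normal dopamine proxy); drug
    session order is counterbalanced by rotating the label tuple across
    subjects.
    """
    subjects = []
    train_parts, test_parts, truth_rows = [], [], []
    designs: dict[tuple[int, str], TaskDesign] = {}
    n_sessions = len(spec.sessions)
    for sid in range(spec.n_subjects):
        da = float(rng.standard_normal())
        subjects.append({"subject_id": sid, "da": da})
        noise = {
            name: float(rng.normal(0.0, sd)) for name, sd in spec.param_sd.items()
        }
        order = [
            spec.sessions[(sid + k) % n_sessions] for k in range(n_sessions)
        ]
        for sess_num, label in enumerate(order, start=1):
            params = spec.params_for(da, label, noise=noise)
            design = generate_task(config, rng)
            design.test_pairs = build_test_pairs(design, rng=rng)
            designs[(sid, label)] = design
            train, test = simulate_subject(
                design, params, rng, kappa_effort=spec.kappa_effort, options=options
            )
            for df in (train, test):
                df.insert(0, "subject_id", sid)
                df.insert(1, "session_label", label)
                df.insert(2, "session_number", sess_num)
            train_parts.append(train)
            test_parts.append(test)
            truth_rows.append(
                {
                    "subject_id": sid,
                    "session_label": label,
                    "session_number": sess_num,
                    "da": da,
                    **params.as_dict(),
                }
            )
    return SyntheticDataset(
        subjects=pd.DataFrame(subjects),
        training=pd.concat(train_parts, ignore_index=True),
        test=pd.concat(test_parts, ignore_index=True),
        true_params=pd.DataFrame(truth_rows),
        designs=designs,
    )
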