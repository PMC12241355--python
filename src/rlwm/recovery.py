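"""Validation harnesses: parameter recovery and posterior predictive checks.

Recovery samples generating parameters (by default uniformly over the range
of values the model plausibly takes in fitted data, where recoverability
claims actually apply), simulates one session per draw, refits by MAP and
correlates truth with estimates.  Posterior predictive checks simulate
sessions at each subject's MAP estimates on that subject's own realized
stimulus sequences — conditioning on the design isolates model misfit from
design variance — and compare accuracy-by-iteration-by-set-size curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .analysis import summarize_learning_curves
from .fitting import FitConfig, fit_packed
from .model import ModelParams, pack_session
from .simulate import SyntheticDataset, simulate_subject
from .task import TaskConfig, build_test_pairs, generate_task

__all__ = [
    "FITTED_RANGES",
    "sample_fitted_range",
    "RecoveryReport",
    "run_recovery",
    "PPCReport",
    "run_ppc",
]

#: Observed range of fitted values after outlier screening; the default
#: sampling region for recovery exercises.
FITTED_RANGES: dict[str, tuple[float, float]] = {
    "alpha_rl": (0.0, 0.04),
    "gamma": (0.039, 0.84),
    "phi": (0.0, 0.30),
    "rho": (0.62, 1.0),
    "wm_cap": (2, 5),
    "nu": (0.026, 0.14),
}


def sample_fitted_range(rng: np.random.Generator) -> ModelParams:
    """One parameter draw, uniform over :data:`FITTED_RANGES` (integer-uniform
    for wm_cap)."""
    lo, hi = FITTED_RANGES["wm_cap"]
    draws = {
        name: float(rng.uniform(*FITTED_RANGES[name]))
        for name in ("alpha_rl", "gamma", "phi", "rho", "nu")
    }
    return ModelParams(wm_cap=int(rng.integers(lo, hi + 1)), **draws)


@dataclass
class RecoveryReport:
    per_param: pd.DataFrame  # param, r, bias, rmse, degenerate flag
    truths: pd.DataFrame
    estimates: pd.DataFrame
    cap_confusion: pd.DataFrame  # rows: true capacity, cols: recovered
    n_subjects: int
    n_nonconverged: int
    seed: int | None

    def r(self, param: str) -> float:
        row = self.per_param[self.per_param.param == param]
        return float(row["r"].iloc[0])

    def cap_match_rate(self) -> float:
        conf = self.cap_confusion.to_numpy()
        return float(np.trace(conf) / conf.sum())

    def summary(self) -> dict[str, float]:
        out = {f"r_{p}": self.r(p) for p in self.per_param.param}
        out["wm_cap_match"] = self.cap_match_rate()
        out["n_subjects"] = self.n_subjects
        return out


def run_recovery(
    n_subjects: int,
    task_config: TaskConfig | None = None,
    fit_config: FitConfig | None = None,
    rng: np.random.Generator | None = None,
    param_sampler=sample_fitted_range,
) -> RecoveryReport:
    """Simulate -> fit -> correlate, one synthetic session per subject."""
    task_config = task_config or TaskConfig()
    fit_config = fit_config or FitConfig()
    if rng is None:
        rng = np.random.default_rng(fit_config.rng_seed)

    truth_rows, est_rows = [], []
    n_nonconv = 0
    for i in range(n_subjects):
        true = param_sampler(rng)
        design = generate_task(task_config, rng)
        design.test_pairs = build_test_pairs(design, rng=rng)
        train, test = simulate_subject(design, true, rng, options=fit_config.options)
        packed = pack_session(train, test, n_actions=task_config.n_actions)
        fit = fit_packed(packed, fit_config, rng)
        if not fit.converged:
            n_nonconv += 1
            continue
        truth_rows.append({"subject": i, **true.as_dict()})
        est_rows.append({"subject": i, **fit.params.as_dict()})

    truths = pd.DataFrame(truth_rows)
    ests = pd.DataFrame(est_rows)
    per_param = []
    for p in ("alpha_rl", "gamma", "phi", "rho", "nu"):
        t, e = truths[p].to_numpy(), ests[p].to_numpy()
        degenerate = np.ptp(t) == 0 or np.ptp(e) == 0
        r = np.nan if degenerate else float(stats.pearsonr(t, e).statistic)
        per_param.append(
            {
                "param": p,
                "r": r,
                "bias": float(np.mean(e - t)),
                "rmse": float(np.sqrt(np.mean((e - t) ** 2))),
                "degenerate": degenerate,
            }
        )
    caps = sorted(set(range(2, 6)))
    conf = pd.DataFrame(0, index=caps, columns=caps)
    for t, e in zip(truths["wm_cap"], ests["wm_cap"]):
        conf.loc[int(t), int(e)] += 1
    return RecoveryReport(
        per_param=pd.DataFrame(per_param),
        truths=truths,
        estimates=ests,
        cap_confusion=conf,
        n_subjects=len(truths),
        n_nonconverged=n_nonconv,
        seed=fit_config.rng_seed,
    )


@dataclass
class PPCReport:
    observed: pd.DataFrame  # set_size x previous_iterations accuracy cells
    simulated: pd.DataFrame
    cells: pd.DataFrame  # merged with per-cell signed and absolute differences
    n_ppc_draws: int

    @property
    def max_abs_diff(self) -> float:
        return float(self.cells["abs_diff"].max())

    def mean_signed_diff(self) -> float:
        return float(self.cells["diff"].mean())


def run_ppc(
    dataset: SyntheticDataset,
    fits: dict[tuple[int, str], ModelParams] | pd.DataFrame,
    n_ppc_draws: int,
    rng: np.random.Generator,
) -> PPCReport:
    """Posterior predictive check of training learning curves.

    ``fits`` maps (subject_id, session_label) to MAP parameters, either as a
    dict or as a fit table from :func:`rlwm.fitting.fit_dataset`.  Each
    subject-session is re-simulated ``n_ppc_draws`` times on its own design;
    sessions without a fit are skipped.
    """
    if n_ppc_draws < 1:
        raise ValueError("n_ppc_draws must be >= 1")
    if isinstance(fits, pd.DataFrame):
        fits = {
            (row.subject_id, row.session_label): ModelParams(
                alpha_rl=row.alpha_rl,
                gamma=row.gamma,
                phi=row.phi,
                rho=row.rho,
                wm_cap=int(row.wm_cap),
                nu=row.nu,
            )
            for row in fits.itertuples()
        }
    sim_parts = []
    for key, design in dataset.designs.items():
        if key not in fits:
            continue
        params = fits[key]
        for d in range(n_ppc_draws):
            train, _ = simulate_subject(design, params, rng)
            # distinct per-draw subject key so iteration/delay counters never
            # run across draws of the same session
            train["subject_id"] = f"{key[0]}#draw{d}"
            train["session_label"] = key[1]
            train["draw"] = d
            sim_parts.append(train)
    simulated = pd.concat(sim_parts, ignore_index=True)

    fitted_keys = set(fits)
    obs = dataset.training[
        [
            (s, l) in fitted_keys
            for s, l in zip(
                dataset.training["subject_id"], dataset.training["session_label"]
            )
        ]
    ]
    obs_curve = summarize_learning_curves(obs, by="iteration")
    sim_curve = summarize_learning_curves(simulated, by="iteration")
    merged = obs_curve.merge(
        sim_curve,
        on=["set_size", "previous_iterations"],
        suffixes=("_obs", "_sim"),
    )
    merged["diff"] = merged["accuracy_sim"] - merged["accuracy_obs"]
    merged["abs_diff"] = merged["diff"].abs()
    return PPCReport(
        observed=obs_curve,
        simulated=sim_curve,
        cells=merged,
        n_ppc_draws=n_ppc_draws,
    )
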