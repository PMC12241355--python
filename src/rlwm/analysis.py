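"""Model-independent trial-level analyses.

Derived training variables (previous iterations, previous correct responses,
delay since last correct), preprocessing exclusions (late-block accuracy
below 53% in all sessions; test trials faster than 250 ms; test sessions with
response capture below 80% or left/right alternation above 75%), learning
curve summaries, test-phase pair features (reward-rate difference, set-size
difference, means), and a fixed-effects logistic regression used as a
qualitative stand-in for hierarchical trial-level regressions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "derive_training_features",
    "apply_training_exclusions",
    "apply_test_exclusions",
    "derive_test_features",
    "summarize_learning_curves",
    "standardize",
    "fit_logistic",
]

LATE_ACCURACY_CUTOFF = 0.53
MIN_RT_SECONDS = 0.25
MAX_ALTERNATION_RATE = 0.75
MIN_CAPTURE_RATE = 0.80

_SESSION_KEYS = ["subject_id", "session_label"]


def _session_groups(df: pd.DataFrame) -> list[str]:
    return [k for k in _SESSION_KEYS if k in df.columns]


def derive_training_features(
    trials: pd.DataFrame, early_late: str = "iterations", n_iterations: int | None = None
) -> pd.DataFrame:
    """Attach per-trial counters computed per stimulus within block.

    Adds ``previous_iterations`` (prior presentations of this stimulus),
    ``previous_correct`` (prior correct responses), ``delay`` (trials since
    the stimulus's last correct response; NaN before the first one), and
    ``early_flag``/``late_flag``.

    Two early/late definitions are selectable: ``"iterations"`` (default)
    flags the first two and last two iterations of each stimulus;
    ``"pcor"`` flags trials with fewer than three previous correct responses
    as early (late unchanged).  Features are a pure per-session function of
    the trial sequence.
    """
    if early_late not in ("iterations", "pcor"):
        raise ValueError("early_late must be 'iterations' or 'pcor'")
    out = trials.reset_index(drop=True).copy()

    block_keys = _session_groups(out) + ["block_id"]
    stim_keys = block_keys + ["stimulus_id"]
    by_block = out.groupby(block_keys, sort=False)
    by_stim = out.groupby(stim_keys, sort=False)

    out["previous_iterations"] = by_stim.cumcount()
    correct = out["correct"].astype(int)
    out["previous_correct"] = (
        correct.groupby([out[k] for k in stim_keys]).cumsum() - correct
    )
    # delay = trials since this stimulus's last correct response (block position
    # arithmetic); NaN before the first correct response
    pos = by_block.cumcount().astype(float)
    pos_if_correct = pos.where(correct == 1)
    stim_grouper = [out[k] for k in stim_keys]
    # shift within stimulus group (drop the current trial's own outcome), then
    # forward-fill within group to carry the last correct position
    last_cor_pos = pos_if_correct.groupby(stim_grouper).shift(1)
    last_cor_pos = last_cor_pos.groupby(stim_grouper).ffill()
    out["delay"] = pos - last_cor_pos

    n_iter_col = by_stim["stimulus_id"].transform("size").to_numpy()
    if n_iterations is not None:
        n_iter_col = np.full(len(out), n_iterations)
    out["late_flag"] = out["previous_iterations"] >= n_iter_col - 2
    if early_late == "iterations":
        out["early_flag"] = out["previous_iterations"] < 2
    else:
        out["early_flag"] = out["previous_correct"] < 3
    return out


def apply_training_exclusions(
    trials: pd.DataFrame, cutoff: float = LATE_ACCURACY_CUTOFF
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject-level screen on late-block training accuracy.

    A subject is excluded only when late-trial accuracy falls below ``cutoff``
    in *all* of their sessions.  Pre-first-correct trials are marked with
    ``post_first_correct = False`` rather than dropped, so model fitting can
    still consume them.  Empty sessions are flagged incomplete and excluded
    from that session only.

    Returns ``(trials, report)`` where the report has one row per
    subject-session with its late accuracy and disposition.
    """
    df = trials
    if "previous_correct" not in df.columns:
        df = derive_training_features(df)
    df = df.copy()
    # a trial is "post first correct" once the stimulus has >=1 prior correct
    df["post_first_correct"] = df["previous_correct"] > 0

    keys = _session_groups(df)
    rows = []
    late_acc: dict = {}
    for key, sess in df.groupby(keys, sort=True):
        late = sess[sess["late_flag"]]
        acc = float(late["correct"].mean()) if len(late) else np.nan
        late_acc[key] = acc
        rows.append(
            {
                **dict(zip(keys, key if isinstance(key, tuple) else (key,))),
                "late_accuracy": acc,
                "incomplete": len(sess) == 0,
            }
        )
    report = pd.DataFrame(rows)
    if "subject_id" in report.columns:
        below = report.groupby("subject_id")["late_accuracy"].agg(
            lambda a: bool((a < cutoff).all()) and len(a) > 0
        )
        report["subject_excluded"] = report["subject_id"].map(below)
        bad_subjects = set(below[below].index)
        kept = df[~df["subject_id"].isin(bad_subjects)]
    else:
        report["subject_excluded"] = report["late_accuracy"] < cutoff
        kept = df if not report["subject_excluded"].any() else df.iloc[0:0]
    return kept, report


def _alternation_rate(choices: pd.Series) -> float:
    c = choices.dropna().to_numpy()
    if len(c) < 2:
        return 0.0
    return float(np.mean(c[1:] != c[:-1]))


def apply_test_exclusions(
    test: pd.DataFrame,
    min_rt: float = MIN_RT_SECONDS,
    max_alternation: float = MAX_ALTERNATION_RATE,
    min_capture: float = MIN_CAPTURE_RATE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trial- and session-level test-phase screens.

    Drops trials faster than ``min_rt`` seconds; drops whole sessions whose
    response-capture rate (non-missing choices) is below ``min_capture`` or
    whose left/right alternation rate is *strictly* above ``max_alternation``.
    """
    keys = _session_groups(test)
    rows = []
    kept_parts = []
    grouped = test.groupby(keys, sort=True) if keys else [((), test)]
    for key, sess in grouped:
        capture = float(sess["choice"].notna().mean()) if len(sess) else 0.0
        altern = _alternation_rate(sess["choice"])
        session_ok = capture >= min_capture and altern <= max_alternation
        n_fast = int((sess["rt"] < min_rt).sum())
        if session_ok:
            kept_parts.append(sess[(sess["rt"] >= min_rt) & sess["choice"].notna()])
        rows.append(
            {
                **dict(zip(keys, key if isinstance(key, tuple) else (key,))),
                "capture_rate": capture,
                "alternation_rate": altern,
                "n_fast_trials": n_fast,
                "session_excluded": not session_ok,
            }
        )
    kept = (
        pd.concat(kept_parts) if kept_parts else test.iloc[0:0]
    )
    return kept, pd.DataFrame(rows)


def stimulus_reward_rates(
    training: pd.DataFrame, statistic: str = "rate"
) -> pd.DataFrame:
    """Reward earned per stimulus during training: mean points per
    presentation (``"rate"``, default) or the raw sum (``"sum"``)."""
    agg = {"rate": "mean", "sum": "sum"}[statistic]
    keys = _session_groups(training) + ["stimulus_id"]
    out = (
        training.groupby(keys, sort=True)
        .agg(reward=("points", agg), set_size=("set_size", "first"))
        .reset_index()
    )
    return out


def derive_test_features(
    test: pd.DataFrame, training: pd.DataFrame, statistic: str = "rate"
) -> pd.DataFrame:
    """Pair-level test features oriented to the more-rewarded stimulus.

    ``delta_v`` >= 0 is the difference in reward earned (higher minus lower),
    ``delta_ns`` the signed set-size difference (more-rewarded minus
    less-rewarded), plus ``mean_set_size``, ``mean_value`` and ``accuracy``
    (chose the objectively more-rewarded stimulus).  Equal-earning pairs are
    flagged ``tie`` and carry NaN accuracy.
    """
    rates = stimulus_reward_rates(training, statistic=statistic)
    keys = _session_groups(test)
    ridx = rates.set_index(keys + ["stimulus_id"]) if keys else rates.set_index(
        "stimulus_id"
    )
    rows = []
    for _, row in test.iterrows():
        kl = tuple(row[k] for k in keys)
        left, right = row["left_stimulus"], row["right_stimulus"]
        rl_ = ridx.loc[kl + (left,)] if keys else ridx.loc[left]
        rr_ = ridx.loc[kl + (right,)] if keys else ridx.loc[right]
        v_l, v_r = float(rl_["reward"]), float(rr_["reward"])
        ns_l, ns_r = int(rl_["set_size"]), int(rr_["set_size"])
        tie = v_l == v_r
        if v_l >= v_r:
            hi_side, v_hi, v_lo, ns_hi, ns_lo = "left", v_l, v_r, ns_l, ns_r
        else:
            hi_side, v_hi, v_lo, ns_hi, ns_lo = "right", v_r, v_l, ns_r, ns_l
        acc = np.nan if tie else float(row["choice"] == hi_side)
        rows.append(
            {
                **dict(zip(keys, kl)),
                "left_stimulus": left,
                "right_stimulus": right,
                "delta_v": v_hi - v_lo,
                "delta_ns": ns_hi - ns_lo,
                "mean_set_size": 0.5 * (ns_l + ns_r),
                "mean_value": 0.5 * (v_l + v_r),
                "tie": tie,
                "accuracy": acc,
            }
        )
    return pd.DataFrame(rows)


def summarize_learning_curves(
    trials: pd.DataFrame,
    by: str = "iteration",
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Accuracy cell means and SEs by set size x bin (x optional groups).

    ``by`` is ``"iteration"`` (previous presentations) or
    ``"previous_correct"``.
    """
    df = trials
    if "previous_iterations" not in df.columns:
        df = derive_training_features(df)
    bin_col = {"iteration": "previous_iterations", "previous_correct": "previous_correct"}[by]
    keys = ["set_size", bin_col] + (groups or [])
    out = (
        df.groupby(keys, sort=True)["correct"]
        .agg(accuracy="mean", n="size", sd="std")
        .reset_index()
    )
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")


def standardize(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Z-score the given columns (population SD); zero-variance columns pass
    through unchanged."""
    out = df.copy()
    for c in cols:
        x = out[c].astype(float)
        sd = x.std(ddof=0)
        if sd > 0:
            out[c] = (x - x.mean()) / sd
    return out


def fit_logistic(
    data: pd.DataFrame,
    formula: str,
    standardize_cols: list[str] | None = None,
    ridge_alpha: float = 1.0,
) -> pd.DataFrame:
    """Fixed-effects logistic regression via IRLS (statsmodels GLM).

    A deliberately plain stand-in for hierarchical trial-level models: use it
    for signs and qualitative structure, not for population inference.  Under
    (quasi-)separation the fit falls back to a small L2 ridge on the IRLS
    working equations; the result carries ``ridge_fallback=True`` and
    penalized-information standard errors.

    Returns a coefficient table (term, coef, se, z, p) with the fallback flag
    in ``DataFrame.attrs["ridge_fallback"]``.
    """
    df = data
    if standardize_cols:
        df = standardize(df, standardize_cols)
    ridge = False
    try:
        model = smf.glm(formula, data=df, family=sm.families.Binomial())
        res = model.fit(maxiter=200)
        params, bse = res.params, res.bse
        if not np.all(np.isfinite(bse)) or np.abs(params.to_numpy()).max() > 15.0:
            raise sm.tools.sm_exceptions.PerfectSeparationError("suspect separation")
    except Exception:
        ridge = True
        model = smf.glm(formula, data=df, family=sm.families.Binomial())
        y, X = model.endog, model.exog
        params_arr = _ridge_irls(y, X, alpha=ridge_alpha)
        cov = _ridge_cov(X, params_arr, alpha=ridge_alpha)
        params = pd.Series(params_arr, index=model.exog_names)
        bse = pd.Series(np.sqrt(np.diag(cov)), index=model.exog_names)
    z = params / bse
    from scipy.stats import norm

    table = pd.DataFrame(
        {
            "term": params.index,
            "coef": params.to_numpy(),
            "se": bse.to_numpy(),
            "z": z.to_numpy(),
            "p": 2 * norm.sf(np.abs(z.to_numpy())),
        }
    )
    table.attrs["ridge_fallback"] = ridge
    return table


def _ridge_irls(
    y: np.ndarray, X: np.ndarray, alpha: float, maxiter: int = 100, tol: float = 1e-10
) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    I = np.eye(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - alpha * beta
        H = X.T @ (X * w[:, None]) + alpha * I
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta


def _ridge_cov(X: np.ndarray, beta: np.ndarray, alpha: float) -> np.ndarray:
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = X.T @ (X * w[:, None]) + alpha * np.eye(X.shape[1])
    return np.linalg.inv(H)
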