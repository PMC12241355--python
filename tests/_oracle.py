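"""Naive dict-based scalar trace of the session likelihood.

Deliberately independent of the package's compiled kernel: plain Python
dictionaries, explicit per-trial arithmetic straight from the update rules.
Used as the ground-truth reference for likelihood equivalence tests.
"""

from __future__ import annotations

import math


def naive_session_loglik(
    training_rows: list[dict],
    test_rows: list[dict],
    alpha: float,
    gamma: float,
    phi: float,
    rho: float,
    wm_cap: int,
    nu: float,
    beta: float = 50.0,
    n_actions: int = 3,
    pair_level_decay: bool = True,
    point_critic: bool = False,
) -> float:
    """Training rows need block_id, stimulus_id, action, correct (and points);
    test rows need left_stimulus, right_stimulus, choice ('left'/'right')."""
    u = 1.0 / n_actions
    V: dict = {}
    total = 0.0

    blocks: dict = {}
    for row in training_rows:
        blocks.setdefault(row["block_id"], []).append(row)

    for rows in blocks.values():
        stims = []
        for r in rows:
            if r["stimulus_id"] not in stims:
                stims.append(r["stimulus_id"])
        Q = {(s, a): u for s in stims for a in range(n_actions)}
        WM = {(s, a): u for s in stims for a in range(n_actions)}
        for s in stims:
            V[s] = u
        delay = {s: 0 for s in stims}
        seen = {s: set() for s in stims}

        for r in rows:
            s, a, cor = r["stimulus_id"], r["action"], int(r["correct"])

            # choice probability
            def smax(table):
                vals = [beta * table[(s, j)] for j in range(n_actions)]
                m = max(vals)
                es = [math.exp(v - m) for v in vals]
                return [e / sum(es) for e in es]

            p_rl = smax(Q)
            p_wm = smax(WM)
            omega = rho * min(1.0, wm_cap / delay[s]) if delay[s] > 0 else rho
            p = (1 - omega) * p_rl[a] + omega * p_wm[a]
            total += math.log(p)

            # delay counters
            for k in stims:
                if k != s and s not in seen[k]:
                    seen[k].add(s)
                    delay[k] += 1
            if cor:
                delay[s] = 0
                seen[s] = set()

            # updates
            cr = float(r["points"]) if point_critic else float(cor)
            if cor:
                Q[(s, a)] = Q[(s, a)] + alpha * (1.0 - Q[(s, a)])
                WM[(s, a)] = 1.0
                V[s] = V[s] + alpha * (cr - V[s])
            else:
                Q[(s, a)] = Q[(s, a)] + alpha * gamma * (0.0 - Q[(s, a)])
                WM[(s, a)] = WM[(s, a)] + gamma * (0.0 - WM[(s, a)])
                V[s] = V[s] + alpha * gamma * (cr - V[s])

            # decay
            for key in WM:
                if pair_level_decay:
                    if key == (s, a):
                        continue
                elif key[0] == s:
                    continue
                WM[key] = WM[key] + phi * (u - WM[key])

    for r in test_rows:
        v_l, v_r = V[r["left_stimulus"]], V[r["right_stimulus"]]
        x = beta * (v_l - v_r)
        p_soft = 1.0 / (1.0 + math.exp(-x)) if x >= 0 else math.exp(x) / (1 + math.exp(x))
        p_left = 0.5 * nu + (1 - nu) * p_soft
        p = p_left if r["choice"] == "left" else 1.0 - p_left
        total += math.log(max(p, 1e-300))
    return total
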