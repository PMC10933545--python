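"""Rescorla-Wagner learner for the reinforcement-learning blocks.

Each RL block presents the same two shapes throughout; exactly one of them
is rewarded on every trial (probabilities p and 1-p).  Feedback is complete:
a green frame marks the rewarded shape whether or not it was chosen, so the
default update touches both shapes' value estimates (``full_information``).

Value estimates follow the delta rule q <- q + alpha * (r - q) with
r in {0, 1}; choices during simulation are softmax over the two q-values
with inverse temperature beta.  Correct choices add 2 pence to the running
total; incorrect choices have no monetary effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import qmc

from .design import RLBlockSpec

Q_INIT = 0.5  # uninformative midpoint of [0, 1]
REWARD_PENCE = 2

ALPHA_BOUNDS = (0.01, 1.0)
BETA_BOUNDS = (0.05, 30.0)


class LearningError(ValueError):
    pass


@dataclass
class QState:
    """Value estimates of the stimuli in play."""

    q_values: dict[str, float]
    trial_index: int = 0


def rw_update(q: QState, chosen_stim: str, rewarded_stim: str, alpha: float,
              full_information: bool = True) -> QState:
    """One delta-rule update; returns a new state.

    With ``full_information`` both stimuli are updated toward their realised
    outcome (the rewarded one toward 1, the other toward 0); otherwise only
    the chosen stimulus is updated.
    """
    if not 0.0 < alpha <= 1.0:
        raise LearningError(f"alpha must be in (0, 1], got {alpha}")
    for s in (chosen_stim, rewarded_stim):
        if s not in q.q_values:
            raise LearningError(f"stimulus {s!r} not in state")
    new_q = dict(q.q_values)
    targets = list(new_q) if full_information else [chosen_stim]
    for s in targets:
        r = 1.0 if s == rewarded_stim else 0.0
        new_q[s] = new_q[s] + alpha * (r - new_q[s])
    return QState(new_q, q.trial_index + 1)


def simulate_learning_block(block: RLBlockSpec, alpha: float, beta: float,
                            seed: int, full_information: bool = True,
                            start_total_pence: int = 1500) -> pd.DataFrame:
    """Simulate one RL block with a softmax Rescorla-Wagner agent."""
    rng = np.random.default_rng(seed)
    hi, lo = block.stimuli
    p_hi = max(block.prob_pair)
    q = QState({hi: Q_INIT, lo: Q_INIT})
    total = start_total_pence
    rows = []
    # left/right placement alternates pseudo-randomly
    for t in range(block.n_trials):
        left, right = (hi, lo) if rng.random() < 0.5 else (lo, hi)
        p_choose_left = expit(beta * (q.q_values[left] - q.q_values[right]))
        choice = "left" if rng.random() < p_choose_left else "right"
        chosen = left if choice == "left" else right
        rewarded = hi if rng.random() < p_hi else lo
        correct = chosen == rewarded
        if correct:
            total += REWARD_PENCE
        rows.append({
            "day": block.day, "block": block.position_in_day,
            "phase": block.phase, "trial_idx": t,
            "left_stim": left, "right_stim": right,
            "left_prob": p_hi if left == hi else 1 - p_hi,
            "right_prob": p_hi if right == hi else 1 - p_hi,
            "choice": choice, "chosen_stim": chosen,
            "rewarded_stim": rewarded, "correct": correct,
            "rt": float(rng.lognormal(mean=-0.1, sigma=0.35)),
            "running_total": total,
        })
        q = rw_update(q, chosen, rewarded, alpha, full_information)
    return pd.DataFrame(rows)


def _nll_rw(theta: np.ndarray, trials: pd.DataFrame,
            full_information: bool) -> float:
    alpha, beta = theta
    nll = 0.0
    for (_, _), block_trials in trials.groupby(["day", "block"], sort=True):
        stims = {block_trials.iloc[0]["left_stim"],
                 block_trials.iloc[0]["right_stim"]}
        q = {s: Q_INIT for s in stims}
        for row in block_trials.itertuples():
            dq = q[row.left_stim] - q[row.right_stim]
            p_left = expit(beta * dq)
            p_obs = p_left if row.choice == "left" else 1.0 - p_left
            nll -= np.log(max(p_obs, 1e-12))
            targets = list(q) if full_information else [row.chosen_stim]
            for s in targets:
                r = 1.0 if s == row.rewarded_stim else 0.0
                q[s] = q[s] + alpha * (r - q[s])
    return nll


def fit_rw(trials: pd.DataFrame, full_information: bool = True,
           n_restarts: int = 10, seed: int = 0) -> dict:
    """Bounded maximum-likelihood fit of (alpha, beta) with Latin-hypercube
    multi-restart.  Returns the best fit and convergence metadata."""
    if len(trials) == 0:
        raise LearningError("need at least one trial")
    lo = np.array([ALPHA_BOUNDS[0], BETA_BOUNDS[0]])
    hi = np.array([ALPHA_BOUNDS[1], BETA_BOUNDS[1]])
    sampler = qmc.LatinHypercube(d=2, seed=seed)
    starts = lo + sampler.random(n_restarts) * (np.array([1.0, 10.0]) - lo)
    best, n_conv = None, 0
    for x0 in starts:
        res = optimize.minimize(_nll_rw, x0, args=(trials, full_information),
                                method="L-BFGS-B",
                                bounds=[ALPHA_BOUNDS, BETA_BOUNDS],
                                options={"ftol": 1e-10})
        if res.success:
            n_conv += 1
        if best is None or res.fun < best.fun:
            best = res
    alpha, beta = best.x
    at_bound = bool(np.isclose(beta, BETA_BOUNDS[0]) or
                    np.isclose(beta, BETA_BOUNDS[1]))
    return {"alpha": float(alpha), "beta": float(beta),
            "nll": float(best.fun), "nll_per_trial": float(best.fun / len(trials)),
            "n_restarts_converged": n_conv, "beta_at_bound": at_bound}


def accuracy_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per block x phase proportion of choices of the higher-probability
    shape.  Empty blocks are simply absent from the grouped output."""
    t = trials.copy()
    chose_left = t["choice"] == "left"
    chosen_prob = np.where(chose_left, t["left_prob"], t["right_prob"])
    other_prob = np.where(chose_left, t["right_prob"], t["left_prob"])
    t["correct_choice"] = chosen_prob > other_prob
    out = (t.groupby(["day", "block", "phase"], as_index=False)
            .agg(p_correct=("correct_choice", "mean"),
                 n_trials=("correct_choice", "size"),
                 prob_level=("left_prob", "max")))
    return out
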