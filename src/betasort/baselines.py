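"""Comparator models: betaQ and Q/softmax.

betaQ is betasort with the implicit-inference stage removed — identical
choice policy and relaxation, but feedback only ever touches the two
stimuli on screen.  It isolates the contribution of implicit updating.

Q/softmax is a minimal reward-prediction-error model: one expected value
per stimulus, updated by a temporal-difference delta rule, with softmax
action selection.  It is the associative-learning baseline that fails
transitive inference under adjacent-pair training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .memory import BetaMemory, QMemory
from .model import BetasortParams, Trial, choose, relax

__all__ = [
    "QParams",
    "betaq_feedback",
    "betaq_trial",
    "softmax_prob",
    "q_update",
    "qsoftmax_trial",
]


@dataclass(frozen=True)
class QParams:
    """Q/softmax free parameters: learning rate and inverse temperature.

    ``symmetric_update`` selects whether the unchosen present stimulus is
    updated in mirror image of the chosen one (default), or only the
    chosen stimulus is updated.
    """

    alpha: float = 0.03
    beta: float = 10.0
    symmetric_update: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")


def betaq_feedback(memory: BetaMemory, trial: Trial) -> BetaMemory:
    """betaQ feedback: betasort's explicit update restricted to the pair.

    Reward: consolidate the two present stimuli at their current position
    estimates.  Non-reward: ``L_ch + 1`` and ``U_nc + 1`` only.  Absent
    stimuli are never touched.  R/N tallies as in betasort (present only).
    """
    n = memory.n_stimuli
    for s in trial.present:
        if not (0 <= s < n):
            raise ValueError(f"stimulus index {s} outside memory of size {n}")
    V = memory.positions
    U = memory.U.copy()
    L = memory.L.copy()
    R = memory.R.copy()
    N = memory.N.copy()
    present = list(trial.present)
    if trial.reward == 1:
        U[present] += V[present]
        L[present] += 1.0 - V[present]
        R[present] += 1.0
    else:
        L[trial.choice] += 1.0
        U[trial.not_chosen] += 1.0
        N[present] += 1.0
    return BetaMemory(U, L, R, N)


def betaq_trial(
    memory: BetaMemory,
    present: Sequence[int],
    params: BetasortParams,
    reward_rule: Callable[[Sequence[int], int], int],
    rng: np.random.Generator,
    phase: str = "",
) -> tuple[int, int, BetaMemory]:
    """One betaQ trial: betasort's choose → relax, then pair-only feedback."""
    choice = choose(memory, present, params.tau, rng)
    reward = int(reward_rule(present, choice))
    memory = relax(memory, params.xi)
    pres = list(present)
    trial = Trial(left=pres[0], right=pres[1], choice=choice, reward=reward, phase=phase)
    memory = betaq_feedback(memory, trial)
    return choice, reward, memory


def softmax_prob(q: QMemory, present: Sequence[int], beta: float) -> np.ndarray:
    """Softmax choice probabilities over the present stimuli.

    ``p(i) = exp(β Q_i) / Σ_j exp(β Q_j)`` for ``j`` present, computed
    with max-shifting so large β cannot overflow.  Returned in the order
    of ``present``.
    """
    present = list(present)
    if len(present) < 2:
        raise ValueError("at least two stimuli must be presented")
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    z = beta * q.Q[np.asarray(present, dtype=int)]
    z = z - z.max()
    ez = np.exp(z)
    return ez / ez.sum()


def q_update(
    q: QMemory, trial: Trial, alpha: float, symmetric_update: bool = True
) -> QMemory:
    """Temporal-difference delta-rule update of the value vector.

    For present stimuli the prediction error is ``1 − Q_i`` when the
    outcome favours ``i`` (rewarded-and-chosen, or unrewarded-and-not-
    chosen) and ``−Q_i`` otherwise; absent stimuli are untouched.  With
    ``symmetric_update`` off, only the chosen stimulus is updated.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    Q = q.Q.copy()
    if symmetric_update:
        targets = list(trial.present)
    else:
        targets = [trial.choice]
    for i in targets:
        favourable = (trial.reward == 1) == (trial.choice == i)
        delta = (1.0 - Q[i]) if favourable else (-Q[i])
        Q[i] += alpha * delta
    return QMemory(Q)


def qsoftmax_trial(
    q: QMemory,
    present: Sequence[int],
    params: QParams,
    reward_rule: Callable[[Sequence[int], int], int],
    rng: np.random.Generator,
    phase: str = "",
) -> tuple[int, int, QMemory]:
    """One Q/softmax trial: softmax choice, then delta-rule update."""
    pres = list(present)
    probs = softmax_prob(q, pres, params.beta)
    choice = int(pres[rng.choice(len(pres), p=probs)])
    reward = int(reward_rule(pres, choice))
    trial = Trial(left=pres[0], right=pres[1], choice=choice, reward=reward, phase=phase)
    q = q_update(q, trial, params.alpha, params.symmetric_update)
    return choice, reward, q
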