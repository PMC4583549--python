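"""The betasort algorithm.

Betasort represents each stimulus of a serial list as a beta distribution
over the unit span and performs transitive inference with three moves:

1. **Choice** — draw one random position per visible stimulus from
   ``Beta(U_i + 1, L_i + 1)`` and pick the largest (with probability
   ``tau`` the draws are uniform instead, i.e. memory is ignored).
2. **Relaxation** — multiplicatively decay all tallies by the recall
   parameter ``xi``, with extra decay of the position evidence when the
   recent reward rate is poor (explore more after mistakes).
3. **Feedback** — on reward, *consolidate* every stimulus (present or
   not) at its current position estimate; on non-reward, shift the chosen
   stimulus down and the unchosen one up by a unit count, then adjust the
   absent stimuli relative to the pair: those between the pair are
   consolidated, those outside are pushed toward the margins.

Step 3's updating of stimuli that were not on screen ("implicit
inference") is what lets the model order a whole list from adjacent-pair
feedback alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .memory import BetaMemory

__all__ = [
    "BetasortParams",
    "Trial",
    "beta_density",
    "estimate_position",
    "choose",
    "relax",
    "apply_feedback",
    "betasort_trial",
]


@dataclass(frozen=True)
class BetasortParams:
    """Betasort's two free parameters.

    tau : float in [0, 1]
        Noise — probability that a trial's choice ignores memory entirely
        and draws uniformly.
    xi : float in [0, 1]
        Recall — per-trial multiplicative retention of all memory tallies.
    """

    tau: float = 0.05
    xi: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau <= 1.0):
            raise ValueError(f"tau must lie in [0, 1], got {self.tau}")
        if not (0.0 <= self.xi <= 1.0):
            raise ValueError(f"xi must lie in [0, 1], got {self.xi}")


@dataclass(frozen=True)
class Trial:
    """One completed two-alternative trial.

    ``left``/``right`` record the on-screen arrangement (counterbalanced in
    the schedules but behaviourally inert for every model here); ``choice``
    is the selected stimulus index and ``reward`` the binary outcome.
    """

    left: int
    right: int
    choice: int
    reward: int
    phase: str = ""

    def __post_init__(self) -> None:
        if self.left == self.right:
            raise ValueError("trial must present two distinct stimuli")
        if self.choice not in (self.left, self.right):
            raise ValueError(
                f"choice {self.choice} not among presented stimuli "
                f"({self.left}, {self.right})"
            )
        if self.reward not in (0, 1):
            raise ValueError(f"reward must be 0 or 1, got {self.reward}")

    @property
    def present(self) -> tuple[int, int]:
        return (self.left, self.right)

    @property
    def pair(self) -> tuple[int, int]:
        """Order-free pair identity (sorted indices)."""
        return tuple(sorted((self.left, self.right)))  # type: ignore[return-value]

    @property
    def not_chosen(self) -> int:
        return self.right if self.choice == self.left else self.left


def beta_density(x: float, u: float, l: float) -> float:
    """Beta density ``Γ(u+l)/(Γ(u)Γ(l)) x^(u-1) (1-x)^(l-1)`` on [0, 1].

    Requires strictly positive shapes; callers working from memory tallies
    should pass the ``+1`` choice-policy offsets themselves.
    """
    x = float(x)
    if not np.isfinite(x) or not (0.0 <= x <= 1.0):
        raise ValueError(f"x must lie in [0, 1], got {x}")
    if not (np.isfinite(u) and np.isfinite(l)) or u <= 0 or l <= 0:
        raise ValueError(f"shape parameters must be positive, got ({u}, {l})")
    return float(stats.beta.pdf(x, u, l))


def estimate_position(u, l):
    """Position point estimate ``u/(u+l)``; 0.5 when ``u = l = 0``.

    Accepts scalars or arrays (elementwise).
    """
    u = np.asarray(u, dtype=float)
    l = np.asarray(l, dtype=float)
    if np.any(u < 0) or np.any(l < 0):
        raise ValueError("u and l must be non-negative")
    total = u + l
    v = np.where(total > 0, u / np.where(total > 0, total, 1.0), 0.5)
    if v.ndim == 0:
        return float(v)
    return v


def choose(
    memory: BetaMemory,
    present: Sequence[int],
    tau: float,
    rng: np.random.Generator,
) -> int:
    """Betasort's choice policy over the currently visible stimuli.

    A single uniform draw decides, once per trial, whether memory is
    ignored (probability ``tau``): if so every present stimulus receives an
    independent Uniform(0, 1) value; otherwise stimulus ``i`` receives
    ``X_i ~ Beta(U_i + 1, L_i + 1)``.  The stimulus with the largest value
    is chosen; exact ties (possible only with degenerate generators) are
    broken uniformly at random.
    """
    present = list(present)
    if len(present) < 2:
        raise ValueError("at least two stimuli must be presented")
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    idx = np.asarray(present, dtype=int)
    if rng.random() < tau:
        x = rng.random(len(present))
    else:
        x = rng.beta(memory.U[idx] + 1.0, memory.L[idx] + 1.0)
    winners = np.flatnonzero(x == x.max())
    if len(winners) > 1:
        return int(idx[rng.choice(winners)])
    return int(idx[winners[0]])


def relax(memory: BetaMemory, xi: float) -> BetaMemory:
    """Relaxation step: multiplicative decay of all tallies.

    Per stimulus: ``R ← R·ξ``, ``N ← N·ξ``; then with reward rate
    ``ρ = R/(R+N)`` the extra factor ``ξ_R = ρ/(ρ+1) + 0.5`` (1 when the
    recent record is perfect, down to 0.5 when it is all failures; defined
    as 1 when no trials have been tallied) scales the positional evidence:
    ``U ← U·ξ_R·ξ``, ``L ← L·ξ_R·ξ``.

    Position estimates ``U/(U+L)`` are invariant: both shapes scale by the
    same factor.  Returns a new memory; the input is untouched.
    """
    if not (0.0 <= xi <= 1.0):
        raise ValueError(f"xi must lie in [0, 1], got {xi}")
    R = memory.R * xi
    N = memory.N * xi
    total = R + N
    safe = np.where(total > 0, total, 1.0)
    rate = R / safe
    xi_r = np.where(total > 0, rate / (rate + 1.0) + 0.5, 1.0)
    U = memory.U * xi_r * xi
    L = memory.L * xi_r * xi
    return BetaMemory(U, L, R, N)


def apply_feedback(memory: BetaMemory, trial: Trial) -> BetaMemory:
    """Explicit feedback plus implicit inference for one trial.

    Position estimates ``V`` are taken as a snapshot of the (already
    relaxed) memory before any update.

    Rewarded trial: every stimulus — present or absent — is consolidated,
    ``U_i ← U_i + V_i``, ``L_i ← L_i + (1 - V_i)``, which sharpens the
    position distribution without moving its mean.

    Unrewarded trial: the chosen stimulus is pushed down (``L_ch + 1``) and
    the unchosen one up (``U_nc + 1``).  Each absent stimulus is then
    updated relative to the pair: consolidated if its estimate falls
    weakly between ``V_ch`` and ``V_nc`` (boundary equalities consolidate),
    pushed up by a unit count if it sits above the unchosen stimulus, and
    pushed down if it sits below the chosen one (an inverted pair estimate
    can trigger both unit pushes).

    Finally the outcome is tallied for the present stimuli only:
    ``R + 1`` on reward, else ``N + 1``.
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

    if trial.reward == 1:
        U += V
        L += 1.0 - V
    else:
        ch = trial.choice
        nc = trial.not_chosen
        L[ch] += 1.0
        U[nc] += 1.0
        absent = np.ones(n, dtype=bool)
        absent[[ch, nc]] = False
        between = absent & (V[nc] >= V) & (V >= V[ch])
        above = absent & ~between & (V > V[nc])
        below = absent & ~between & (V[ch] > V)
        U[between] += V[between]
        L[between] += 1.0 - V[between]
        U[above] += 1.0
        L[below] += 1.0

    present = list(trial.present)
    if trial.reward == 1:
        R[present] += 1.0
    else:
        N[present] += 1.0
    return BetaMemory(U, L, R, N)


def betasort_trial(
    memory: BetaMemory,
    present: Sequence[int],
    params: BetasortParams,
    reward_rule: Callable[[Sequence[int], int], int],
    rng: np.random.Generator,
    phase: str = "",
) -> tuple[int, int, BetaMemory]:
    """Run one full betasort trial: choose → relax → feedback.

    Relaxation happens after the choice but before the trial's feedback is
    processed.  Returns the realised choice, the reward assigned by
    ``reward_rule(present, choice)``, and the updated memory.
    """
    choice = choose(memory, present, params.tau, rng)
    reward = int(reward_rule(present, choice))
    memory = relax(memory, params.xi)
    pres = list(present)
    trial = Trial(left=pres[0], right=pres[1], choice=choice, reward=reward, phase=phase)
    memory = apply_feedback(memory, trial)
    return choice, reward, memory
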