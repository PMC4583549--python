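"""The transitive-inference task: schedules, reward rule, and simulation.

A session trains a latent ordering over ``n`` arbitrary stimuli (indices
0..n-1, with 0 the earliest/"best" item, conventionally lettered A..G for
n = 7).  Only pairs are shown; choosing the earlier item of the pair is
rewarded.  Blocks are counterbalanced for screen position: each scheduled
pair appears once per left/right arrangement within a block, in random
order.

Three protocol builders mirror the study designs this package models:

* ``make_monkey_schedule`` — 20 blocks of the 6 adjacent pairs (240
  trials) then 10 blocks of all 21 pairs (420 trials).
* ``make_human_schedule`` — 3 adjacent blocks (36), 3 blocks of the 15
  non-adjacent pairs (90), one all-pairs block (42).
* ``make_massed_schedule`` — 200 adjacent trials, 200 all-pair trials,
  then 200 massed presentations of the single pair FG, used to probe
  whether a learned ordering survives lopsided training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .baselines import QParams, betaq_trial, qsoftmax_trial, softmax_prob
from .memory import BetaMemory, QMemory
from .model import BetasortParams, Trial, betasort_trial

__all__ = [
    "MODELS",
    "ScheduledTrial",
    "SessionSchedule",
    "Session",
    "SessionRecord",
    "reward_rule",
    "adjacent_pairs",
    "all_pairs",
    "nonadjacent_pairs",
    "make_block",
    "make_adjacent_schedule",
    "make_monkey_schedule",
    "make_human_schedule",
    "make_massed_schedule",
    "run_session",
    "probe_accuracy",
]

MODELS = ("betasort", "betaq", "qsoftmax")


@dataclass(frozen=True)
class ScheduledTrial:
    """A planned presentation: screen arrangement plus phase label."""

    left: int
    right: int
    phase: str

    @property
    def pair(self) -> tuple[int, int]:
        return tuple(sorted((self.left, self.right)))  # type: ignore[return-value]


@dataclass
class SessionSchedule:
    """An ordered trial list with block structure.

    ``block_starts`` holds the index of the first trial of each block;
    blocks cut short by a phase-length cap keep their start index, so
    counterbalancing holds exactly for every complete block.
    """

    n_stimuli: int
    trials: list[ScheduledTrial]
    block_starts: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def phase_slice(self, phase: str) -> list[int]:
        """Trial indices belonging to the given phase label."""
        return [i for i, t in enumerate(self.trials) if t.phase == phase]

    @property
    def phases(self) -> list[str]:
        seen: list[str] = []
        for t in self.trials:
            if not seen or seen[-1] != t.phase:
                seen.append(t.phase)
        return seen

    def blocks(self) -> list[list[ScheduledTrial]]:
        bounds = list(self.block_starts) + [len(self.trials)]
        return [self.trials[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


@dataclass
class Session:
    """Observed (or simulated) choice data for one session."""

    trials: list[Trial]
    n_stimuli: int = 7
    subject: str = "sim"
    session_id: str = "0"

    def __len__(self) -> int:
        return len(self.trials)

    def phase_trials(self, phase: str) -> list[Trial]:
        return [t for t in self.trials if t.phase == phase]


@dataclass
class SessionRecord:
    """A simulated session plus (optionally) its memory trajectory.

    ``snapshots[t]`` is the model's value vector (position estimates for
    the beta models, Q for Q/softmax) *at the onset* of trial ``t``; row 0
    is therefore always the uniform initial state.  ``final_values`` is
    the state after the last trial.
    """

    schedule: SessionSchedule
    trials: list[Trial]
    model: str
    params: BetasortParams | QParams
    seed: int | None = None
    snapshots: np.ndarray | None = None
    final_values: np.ndarray | None = None
    final_memory: BetaMemory | QMemory | None = None

    def __post_init__(self) -> None:
        if len(self.trials) != len(self.schedule):
            raise ValueError("record length must equal schedule length")
        if self.snapshots is not None and len(self.snapshots) != len(self.trials):
            raise ValueError("snapshots must align one-to-one with trials")

    def to_session(self, subject: str = "sim", session_id: str = "0") -> Session:
        return Session(
            trials=list(self.trials),
            n_stimuli=self.schedule.n_stimuli,
            subject=subject,
            session_id=session_id,
        )


def reward_rule(pair: Sequence[int], choice: int) -> int:
    """1 iff the chosen stimulus is the earlier (lower-index) list item."""
    a, b = pair
    if choice not in (a, b):
        raise ValueError(f"choice {choice} not in pair ({a}, {b})")
    return int(choice == min(a, b))


def adjacent_pairs(n_stimuli: int) -> list[tuple[int, int]]:
    return [(i, i + 1) for i in range(n_stimuli - 1)]


def all_pairs(n_stimuli: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n_stimuli) for j in range(i + 1, n_stimuli)]


def nonadjacent_pairs(n_stimuli: int) -> list[tuple[int, int]]:
    return [(i, j) for (i, j) in all_pairs(n_stimuli) if j - i > 1]


def make_block(
    pairs: Sequence[tuple[int, int]], phase: str, rng: np.random.Generator
) -> list[ScheduledTrial]:
    """One counterbalanced block: each pair in both arrangements, permuted."""
    trials = [ScheduledTrial(a, b, phase) for (a, b) in pairs]
    trials += [ScheduledTrial(b, a, phase) for (a, b) in pairs]
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def _phase(
    pairs: Sequence[tuple[int, int]],
    phase: str,
    n_trials: int,
    rng: np.random.Generator,
    start: int,
) -> tuple[list[ScheduledTrial], list[int]]:
    """Whole counterbalanced blocks truncated at ``n_trials``."""
    trials: list[ScheduledTrial] = []
    starts: list[int] = []
    while len(trials) < n_trials:
        starts.append(start + len(trials))
        trials.extend(make_block(pairs, phase, rng))
    return trials[:n_trials], starts


def make_adjacent_schedule(
    rng: np.random.Generator, n_trials: int = 200, n_stimuli: int = 7
) -> SessionSchedule:
    """Adjacent-pair-only training of a given length (default 200 trials)."""
    trials, starts = _phase(adjacent_pairs(n_stimuli), "adjacent", n_trials, rng, 0)
    return SessionSchedule(n_stimuli, trials, starts)


def make_monkey_schedule(rng: np.random.Generator, n_stimuli: int = 7) -> SessionSchedule:
    """240 adjacent trials (20 blocks of 12) then 420 all-pair trials (10 blocks of 42)."""
    trials: list[ScheduledTrial] = []
    starts: list[int] = []
    adj = adjacent_pairs(n_stimuli)
    for _ in range(20):
        starts.append(len(trials))
        trials.extend(make_block(adj, "adjacent", rng))
    allp = all_pairs(n_stimuli)
    for _ in range(10):
        starts.append(len(trials))
        trials.extend(make_block(allp, "all_pairs", rng))
    return SessionSchedule(n_stimuli, trials, starts)


def make_human_schedule(rng: np.random.Generator, n_stimuli: int = 7) -> SessionSchedule:
    """36 adjacent + 90 non-adjacent + 42 all-pair trials (168 total)."""
    trials: list[ScheduledTrial] = []
    starts: list[int] = []
    for _ in range(3):
        starts.append(len(trials))
        trials.extend(make_block(adjacent_pairs(n_stimuli), "adjacent", rng))
    for _ in range(3):
        starts.append(len(trials))
        trials.extend(make_block(nonadjacent_pairs(n_stimuli), "nonadjacent", rng))
    starts.append(len(trials))
    trials.extend(make_block(all_pairs(n_stimuli), "all_pairs", rng))
    return SessionSchedule(n_stimuli, trials, starts)


def make_massed_schedule(rng: np.random.Generator, n_stimuli: int = 7) -> SessionSchedule:
    """200 adjacent + 200 all-pair + 200 massed trials of the last adjacent pair."""
    trials, starts = _phase(adjacent_pairs(n_stimuli), "adjacent", 200, rng, 0)
    more, more_starts = _phase(all_pairs(n_stimuli), "all_pairs", 200, rng, len(trials))
    trials += more
    starts += more_starts
    fg = [(n_stimuli - 2, n_stimuli - 1)]
    more, more_starts = _phase(fg, "massed", 200, rng, len(trials))
    trials += more
    starts += more_starts
    return SessionSchedule(n_stimuli, trials, starts)


def run_session(
    model: str,
    params: BetasortParams | QParams,
    schedule: SessionSchedule,
    rng: np.random.Generator | int,
    snapshot: bool = False,
) -> SessionRecord:
    """Simulate a full session of one model on a schedule.

    ``model`` is one of ``betasort``, ``betaq``, ``qsoftmax``.  ``rng``
    may be a seeded Generator or an integer seed; results are a pure
    function of (model, params, schedule, seed).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    seed = None
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)

    n = schedule.n_stimuli
    if model == "qsoftmax":
        if not isinstance(params, QParams):
            raise TypeError("qsoftmax requires QParams")
        state: BetaMemory | QMemory = QMemory.initial(n)
        step = qsoftmax_trial
    else:
        if not isinstance(params, BetasortParams):
            raise TypeError(f"{model} requires BetasortParams")
        state = BetaMemory.zeros(n)
        step = betasort_trial if model == "betasort" else betaq_trial

    trials: list[Trial] = []
    snaps = np.empty((len(schedule), n)) if snapshot else None
    for t, sched in enumerate(schedule.trials):
        if snaps is not None:
            snaps[t] = state.positions
        choice, reward, state = step(
            state, (sched.left, sched.right), params, reward_rule, rng, sched.phase
        )
        trials.append(
            Trial(sched.left, sched.right, choice, reward, sched.phase)
        )
    return SessionRecord(
        schedule=schedule,
        trials=trials,
        model=model,
        params=params,
        seed=seed,
        snapshots=snaps,
        final_values=state.positions,
        final_memory=state,
    )


def probe_accuracy(
    memory: BetaMemory | QMemory,
    pair: Sequence[int],
    params: BetasortParams | QParams,
) -> float:
    """Analytic probability of choosing the earlier item of ``pair``.

    For beta-memory models this is the exact choice-probability integral
    at the model's noise level; for Q/softmax it is the softmax
    probability.  The memory is not modified, so this serves as a
    non-disruptive probe trial.
    """
    a, b = sorted(pair)
    if a == b:
        raise ValueError("probe pair must contain two distinct stimuli")
    if isinstance(memory, QMemory):
        if not isinstance(params, QParams):
            raise TypeError("Q memory requires QParams")
        return float(softmax_prob(memory, (a, b), params.beta)[0])
    if not isinstance(params, BetasortParams):
        raise TypeError("beta memory requires BetasortParams")
    from .fitting import choice_prob

    return choice_prob(
        (memory.U[a], memory.L[a]), (memory.U[b], memory.L[b]), params.tau
    )
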