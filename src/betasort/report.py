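"""Headline simulation quantities, recomputed from scratch.

These are the package's standing summary numbers: the critical-pair
transfer accuracy betasort reaches under short adjacent-pair training,
the chance-level performance of the Q/softmax baseline on non-terminal
adjacent pairs, and the worked relaxation arithmetic.  They back both the
``betasort report`` CLI subcommand and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .baselines import QParams
from .memory import BetaMemory
from .metrics import critical_pairs, is_terminal_pair, pair_distance
from .model import BetasortParams, relax
from .task import make_adjacent_schedule, probe_accuracy, run_session

__all__ = [
    "betasort_critical_pair_probe_pct",
    "qsoftmax_nonterminal_adjacent_pct",
    "relaxed_upper_tally",
    "headline_metrics",
]


def betasort_critical_pair_probe_pct(
    seed: int,
    n_sessions: int = 200,
    n_trials: int = 200,
    tau: float = 0.05,
    xi: float = 0.95,
    n_stimuli: int = 7,
) -> tuple[float, int]:
    """Mean analytic probe accuracy (%) on the critical transfer pairs.

    Simulates independent 7-item sessions of counterbalanced
    adjacent-pair-only betasort training; at the end of training the
    exact choice-probability of the earlier item is computed for each
    critical pair (no extra trials are presented) and averaged across
    pairs and sessions.
    """
    params = BetasortParams(tau=tau, xi=xi)
    crit = critical_pairs(n_stimuli)
    accs = np.empty(n_sessions)
    for i, stream in enumerate(np.random.SeedSequence(seed).spawn(n_sessions)):
        rng = np.random.default_rng(stream)
        schedule = make_adjacent_schedule(rng, n_trials=n_trials, n_stimuli=n_stimuli)
        record = run_session("betasort", params, schedule, rng)
        mem = record.final_memory
        assert isinstance(mem, BetaMemory)
        accs[i] = np.mean([probe_accuracy(mem, p, params) for p in crit])
    return float(accs.mean() * 100.0), n_sessions


def qsoftmax_nonterminal_adjacent_pct(
    seed: int,
    n_sessions: int = 200,
    n_trials: int = 240,
    alpha: float = 0.03,
    beta: float = 10.0,
    n_stimuli: int = 7,
) -> tuple[float, int]:
    """Mean Q/softmax probe accuracy (%) on non-terminal adjacent pairs.

    Simulates the counterbalanced adjacent-pair training phase and, at
    every trial onset, evaluates the analytic softmax probability of the
    correct response for each adjacent pair that contains no terminal
    item (BC, CD, DE, EF for 7 items) — the noise-free hypothetical
    accuracy a non-disruptive probe trial would measure.  The delta rule
    leaves these stimuli at equal expected value, so the mean sits at
    chance.

    (Realised choice accuracy restricted to a pair's own trials runs a
    few points *below* chance at large beta: a pair's value difference is
    sampled at the trough of the sawtooth its own trials create.  The
    probe average is free of that sampling correlation.)
    """
    params = QParams(alpha=alpha, beta=beta)
    probe_pairs = [
        p for p in ((i, i + 1) for i in range(n_stimuli - 1))
        if not is_terminal_pair(p, n_stimuli)
    ]
    means = np.empty(n_sessions)
    for i, stream in enumerate(np.random.SeedSequence(seed).spawn(n_sessions)):
        rng = np.random.default_rng(stream)
        schedule = make_adjacent_schedule(rng, n_trials=n_trials, n_stimuli=n_stimuli)
        record = run_session("qsoftmax", params, schedule, rng, snapshot=True)
        traj = record.snapshots
        probs = [
            1.0 / (1.0 + np.exp(-beta * (traj[:, a] - traj[:, b])))
            for a, b in probe_pairs
        ]
        means[i] = np.mean(probs)
    return float(means.mean() * 100.0), n_sessions


def relaxed_upper_tally(
    u: float = 20.0, l: float = 10.0, xi: float = 0.9
) -> tuple[float, int]:
    """Upper tally after one relaxation from (U, L) with a perfect reward record.

    With rewards only (R > 0, N = 0) the accuracy-dependent factor is 1,
    so the update is the bare recall scaling: U=20, xi=0.9 gives 18.
    """
    mem = BetaMemory(
        U=np.array([u, 0.0]),
        L=np.array([l, 0.0]),
        R=np.array([5.0, 0.0]),
        N=np.array([0.0, 0.0]),
    )
    out = relax(mem, xi)
    return float(out.U[0]), 1


def headline_metrics(seed: int) -> dict[str, dict[str, float | int]]:
    """All headline quantities keyed by descriptive name."""
    t1, n1 = betasort_critical_pair_probe_pct(seed)
    t2, n2 = qsoftmax_nonterminal_adjacent_pct(seed + 1)
    t3, n3 = relaxed_upper_tally()
    return {
        "betasort_critical_pair_probe_pct": {"value": t1, "n": n1},
        "qsoftmax_nonterminal_adjacent_pct": {"value": t2, "n": n2},
        "relaxed_upper_tally": {"value": t3, "n": n3},
    }
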