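"""Behavioural summaries: distance curves, transfer accuracy, orderings.

Terminology for an n-item list (indices 0..n-1):

* *adjacent* pairs differ by one rank; *terminal* pairs contain the first
  (always-rewarded) or last (never-rewarded) item.
* the *critical transfer pairs* are non-adjacent AND non-terminal — for a
  7-item list exactly BD, BE, BF, CE, CF, DF.  Above-chance accuracy on
  these at the moment of transfer is the strongest evidence of transitive
  inference, uncontaminated by terminal-item effects.
* the *symbolic distance effect* is accuracy increasing with the ordinal
  separation of the two items of a pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .task import Session, SessionRecord

__all__ = [
    "PairAccuracy",
    "critical_pairs",
    "pair_distance",
    "is_terminal_pair",
    "accuracy_by_distance",
    "transfer_accuracy",
    "holm_bonferroni",
    "memory_trajectory",
    "OrderingCheck",
    "ordering_intact",
]


@dataclass(frozen=True)
class PairAccuracy:
    """Accuracy for one stimulus pair with a bootstrap CI."""

    pair: tuple[int, int]
    label: str
    distance: int
    n_trials: int
    accuracy: float
    ci_low: float
    ci_high: float
    critical: bool

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.accuracy <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def _n_stimuli(record: Session | SessionRecord) -> int:
    n = getattr(record, "n_stimuli", None)
    if n is None:
        n = record.schedule.n_stimuli
    return int(n)


def pair_distance(pair: Sequence[int]) -> int:
    a, b = sorted(pair)
    return b - a


def is_terminal_pair(pair: Sequence[int], n_stimuli: int) -> bool:
    a, b = sorted(pair)
    return a == 0 or b == n_stimuli - 1


def critical_pairs(n_stimuli: int) -> list[tuple[int, int]]:
    """Non-adjacent, non-terminal pairs (BD, BE, BF, CE, CF, DF for n=7)."""
    return [
        (i, j)
        for i in range(1, n_stimuli - 1)
        for j in range(i + 2, n_stimuli - 1)
    ]


def pair_label(pair: Sequence[int]) -> str:
    a, b = sorted(pair)
    return chr(ord("A") + a) + chr(ord("A") + b)


def accuracy_by_distance(
    records: Sequence[Session | SessionRecord],
    phase: str | None = None,
    window: int = 12,
) -> pd.DataFrame:
    """Moving-average accuracy curves for non-terminal pairs by distance.

    Returns a long-format frame with columns ``distance``, ``trial``
    (index within the filtered trial sequence), ``accuracy`` (centred
    moving average over ``window`` trials of the across-record mean) and
    ``n`` (records contributing at that index).  Terminal-item pairs are
    excluded, so distances run 1..n-3.
    """
    if not records:
        raise ValueError("no records supplied")
    n_stim = _n_stimuli(records[0])
    rows = []
    for rec in records:
        trials = [
            (k, t) for k, t in enumerate(rec.trials)
            if phase is None or t.phase == phase
        ]
        for pos, (_, t) in enumerate(trials):
            if is_terminal_pair(t.pair, n_stim):
                continue
            rows.append(
                {
                    "distance": pair_distance(t.pair),
                    "trial": pos,
                    "correct": float(t.choice == min(t.pair)),
                }
            )
    if not rows:
        raise ValueError("filter left no non-terminal trials")
    df = pd.DataFrame(rows)
    out = []
    for dist, grp in df.groupby("distance"):
        mean = grp.groupby("trial")["correct"].mean()
        count = grp.groupby("trial")["correct"].size()
        smooth = mean.rolling(window, center=True, min_periods=1).mean()
        out.append(
            pd.DataFrame(
                {
                    "distance": dist,
                    "trial": smooth.index,
                    "accuracy": smooth.values,
                    "n": count.values,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def transfer_accuracy(
    records: Sequence[Session | SessionRecord],
    first_block_only: bool = True,
    n_boot: int = 10_000,
    ci: float = 0.95,
    seed: int | None = None,
    transfer_phase: str = "all_pairs",
) -> list[PairAccuracy]:
    """Per-pair accuracy at transfer with bootstrap percentile CIs.

    Accuracy is pooled over each record's first all-pairs block (or the
    whole phase when ``first_block_only`` is off).  The bootstrap
    resamples *sessions*, matching between-session variability; with one
    resample the CI degenerates to the point estimate.
    """
    if not records:
        raise ValueError("no records supplied")
    n_stim = _n_stimuli(records[0])
    from .task import all_pairs

    pairs = all_pairs(n_stim)
    block_len = 2 * len(pairs)

    per_session: dict[tuple[int, int], list[tuple[float, float]]] = {
        p: [] for p in pairs
    }
    for rec in records:
        idx = [k for k, t in enumerate(rec.trials) if t.phase == transfer_phase]
        if not idx:
            raise ValueError("a record has no transfer-phase trials")
        if first_block_only:
            idx = idx[:block_len]
        counts = {p: [0.0, 0.0] for p in pairs}
        for k in idx:
            t = rec.trials[k]
            counts[t.pair][0] += float(t.choice == min(t.pair))
            counts[t.pair][1] += 1.0
        for p in pairs:
            per_session[p].append(tuple(counts[p]))

    rng = np.random.default_rng(seed)
    crit = set(critical_pairs(n_stim))
    results = []
    n_sessions = len(records)
    for p in pairs:
        arr = np.asarray(per_session[p])  # (sessions, 2): successes, totals
        tot = arr[:, 1].sum()
        if tot == 0:
            raise ValueError(f"pair {pair_label(p)} absent from the transfer phase")
        acc = arr[:, 0].sum() / tot
        boots = np.empty(n_boot)
        for b in range(n_boot):
            pick = rng.integers(0, n_sessions, n_sessions)
            s = arr[pick, 0].sum()
            n = arr[pick, 1].sum()
            boots[b] = s / n if n > 0 else np.nan
        boots = boots[np.isfinite(boots)]
        alpha = (1.0 - ci) / 2.0
        lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
        results.append(
            PairAccuracy(
                pair=p,
                label=pair_label(p),
                distance=pair_distance(p),
                n_trials=int(tot),
                accuracy=float(acc),
                ci_low=float(min(lo, acc)),
                ci_high=float(max(hi, acc)),
                critical=p in crit,
            )
        )
    return results


def holm_bonferroni(
    pvalues: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down multiple-comparison correction.

    Returns ``(reject, p_adjusted)`` with monotonised adjusted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, p_adj


def memory_trajectory(record: SessionRecord) -> np.ndarray:
    """Per-trial value matrix (trials x stimuli) from a snapshot record.

    Row ``t`` holds position estimates ``U/(U+L)`` (beta models) or Q
    values at the onset of trial ``t``; row 0 is the uniform 0.5 state.
    """
    if record.snapshots is None:
        raise ValueError("record was captured without snapshots")
    return np.asarray(record.snapshots)


class OrderingCheck(NamedTuple):
    intact: bool
    tied: bool

    def __bool__(self) -> bool:  # truthiness == ordering intact
        return self.intact


def ordering_intact(
    values: Sequence[float], true_order: Sequence[int] | None = None
) -> OrderingCheck:
    """Whether descending sort of ``values`` recovers the true order exactly.

    ``true_order`` defaults to 0..n-1 (earlier items should hold larger
    values).  Ties make the ordering ambiguous: the check reports
    ``intact=False`` with the tie flagged.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    order = np.argsort(-v, kind="stable")
    expected = np.arange(len(v)) if true_order is None else np.asarray(true_order)
    tied = len(np.unique(v)) < len(v)
    intact = (not tied) and bool(np.array_equal(order, expected))
    return OrderingCheck(intact=intact, tied=tied)
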