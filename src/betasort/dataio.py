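"""Session-file input/output and synthetic dataset generation.

Sessions are stored in a flat CSV dialect, one row per completed trial:

    subject,session,trial,phase,stim_left,stim_right,choice,reward

Stimuli are lettered ``A``.. in files (``A`` being the earliest/"best"
list item) and 0-based integer indices in memory.  Trial indices are
0-based and contiguous within a session.  The reader validates every row
and reports problems with the offending line number.

``generate_synthetic_dataset`` produces simulated sessions under any of
the built-in protocols together with a ground-truth parameter sidecar,
for parameter-recovery experiments.  An adapter for a lab's own raw
export format would slot in front of :func:`read_sessions` by converting
to this dialect.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .baselines import QParams
from .model import BetasortParams, Trial
from .task import (
    Session,
    make_adjacent_schedule,
    make_human_schedule,
    make_massed_schedule,
    make_monkey_schedule,
    run_session,
)

__all__ = [
    "COLUMNS",
    "SCHEDULE_MAKERS",
    "stimulus_label",
    "stimulus_index",
    "read_sessions",
    "write_sessions",
    "sessions_to_frame",
    "generate_synthetic_dataset",
]

COLUMNS = [
    "subject",
    "session",
    "trial",
    "phase",
    "stim_left",
    "stim_right",
    "choice",
    "reward",
]

SCHEDULE_MAKERS = {
    "monkey": make_monkey_schedule,
    "human": make_human_schedule,
    "massed": make_massed_schedule,
    "adjacent": make_adjacent_schedule,
}


def stimulus_label(index: int) -> str:
    if not (0 <= index < 26):
        raise ValueError("stimulus index must be in 0..25 for letter labels")
    return chr(ord("A") + index)


def stimulus_index(label: str) -> int:
    label = str(label).strip()
    if len(label) == 1 and label.isalpha():
        return ord(label.upper()) - ord("A")
    try:
        return int(label)
    except ValueError as err:
        raise ValueError(f"unrecognised stimulus label {label!r}") from err


def sessions_to_frame(sessions: Sequence[Session]) -> pd.DataFrame:
    rows = []
    for sess in sessions:
        for k, t in enumerate(sess.trials):
            rows.append(
                {
                    "subject": sess.subject,
                    "session": sess.session_id,
                    "trial": k,
                    "phase": t.phase,
                    "stim_left": stimulus_label(t.left),
                    "stim_right": stimulus_label(t.right),
                    "choice": stimulus_label(t.choice),
                    "reward": int(t.reward),
                }
            )
    return pd.DataFrame(rows, columns=COLUMNS)


def write_sessions(sessions: Sequence[Session], path: str | Path) -> None:
    """Write sessions to CSV with a fixed column order (round-trip safe)."""
    frame = sessions_to_frame(sessions)
    frame.to_csv(path, index=False)


def read_sessions(path: str | Path, n_stimuli: int | None = None) -> list[Session]:
    """Read and validate a session CSV.

    Malformed rows raise ValueError naming the 1-based file line (header
    is line 1).  An empty file yields an empty list with a warning.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if frame.empty:
        warnings.warn(f"{path}: no trial rows found", stacklevel=2)
        return []

    sessions: list[Session] = []
    for (subject, session_id), grp in frame.groupby(
        ["subject", "session"], sort=False
    ):
        trials: list[Trial] = []
        max_idx = -1
        for expected, (row_pos, row) in enumerate(grp.iterrows()):
            line = int(row_pos) + 2  # header occupies line 1
            try:
                trial_idx = int(row["trial"])
                left = stimulus_index(row["stim_left"])
                right = stimulus_index(row["stim_right"])
                choice = stimulus_index(row["choice"])
                reward = int(row["reward"])
            except (ValueError, TypeError) as err:
                raise ValueError(f"{path}:{line}: {err}") from err
            if trial_idx != expected:
                raise ValueError(
                    f"{path}:{line}: non-contiguous trial index {trial_idx} "
                    f"(expected {expected}) in session {subject}/{session_id}"
                )
            if choice not in (left, right):
                raise ValueError(
                    f"{path}:{line}: choice {row['choice']} not among presented "
                    f"stimuli ({row['stim_left']}, {row['stim_right']})"
                )
            if reward not in (0, 1):
                raise ValueError(f"{path}:{line}: reward must be 0 or 1")
            trials.append(
                Trial(left=left, right=right, choice=choice, reward=reward,
                      phase=str(row["phase"]))
            )
            max_idx = max(max_idx, left, right)
        n = n_stimuli if n_stimuli is not None else max_idx + 1
        sessions.append(
            Session(trials=trials, n_stimuli=n, subject=str(subject),
                    session_id=str(session_id))
        )
    return sessions


def generate_synthetic_dataset(
    model: str,
    params: BetasortParams | QParams,
    schedule_kind: str,
    n_sessions: int,
    seed: int,
    n_stimuli: int = 7,
) -> tuple[list[Session], dict]:
    """Simulate ``n_sessions`` independent sessions under a named protocol.

    Each session gets its own freshly randomised schedule and its own
    child RNG stream, so the whole dataset is a pure function of
    ``seed``.  Returns the sessions plus a ground-truth sidecar (model,
    parameters, seed) for parameter-recovery experiments.
    """
    if schedule_kind not in SCHEDULE_MAKERS:
        raise ValueError(
            f"unknown schedule kind {schedule_kind!r}; "
            f"expected one of {sorted(SCHEDULE_MAKERS)}"
        )
    maker = SCHEDULE_MAKERS[schedule_kind]
    streams = np.random.SeedSequence(seed).spawn(n_sessions)
    sessions = []
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        schedule = maker(rng, n_stimuli=n_stimuli)
        record = run_session(model, params, schedule, rng)
        sessions.append(record.to_session(subject=model, session_id=str(i)))
    truth = {
        "model": model,
        "schedule": schedule_kind,
        "seed": int(seed),
        "n_sessions": int(n_sessions),
        "n_stimuli": int(n_stimuli),
        "params": {
            k: (v if isinstance(v, bool) else float(v))
            for k, v in vars(params).items()
        },
    }
    return sessions, truth
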