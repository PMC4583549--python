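"""Memory containers for the transitive-inference models.

Two kinds of model state are used throughout the package:

* :class:`BetaMemory` — four per-stimulus tallies (``U``, ``L``, ``R``,
  ``N``) that jointly define the beta-distribution position code used by
  betasort and betaQ.  ``U`` and ``L`` are evidence that a stimulus sits
  near the top or bottom of the unit span; ``R`` and ``N`` count rewarded
  and unrewarded trials in which the stimulus appeared (they drive the
  explore/exploit relaxation).
* :class:`QMemory` — a single expected-value vector for the Q/softmax
  reward-prediction-error baseline.

All tallies support fractional values: the per-trial relaxation step
scales them multiplicatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BetaMemory", "QMemory"]


@dataclass
class BetaMemory:
    """Position-evidence state for the beta-distribution models.

    Parameters
    ----------
    U, L : ndarray of float
        Upper- and lower-position evidence per stimulus.  The position of
        stimulus ``i`` is represented by ``Beta(U[i] + 1, L[i] + 1)`` at
        choice time; its point estimate is ``U[i] / (U[i] + L[i])``.
    R, N : ndarray of float
        Rewarded / unrewarded trial tallies per stimulus (only trials in
        which the stimulus was present are tallied).

    All vectors start at zero for a fresh session and remain non-negative
    under every model operation.
    """

    U: np.ndarray
    L: np.ndarray
    R: np.ndarray
    N: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("U", "L", "R", "N"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"{name} must be a 1-D vector")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} entries must be finite and non-negative")
            arrays[name] = arr
        lengths = {a.shape[0] for a in arrays.values()}
        if len(lengths) != 1:
            raise ValueError("U, L, R, N must have equal length")
        for name, arr in arrays.items():
            object.__setattr__(self, name, arr)

    @classmethod
    def zeros(cls, n_stimuli: int) -> "BetaMemory":
        """Fresh all-zero memory for ``n_stimuli`` items (session start)."""
        if n_stimuli < 2:
            raise ValueError("need at least two stimuli")
        z = np.zeros(n_stimuli)
        return cls(z.copy(), z.copy(), z.copy(), z.copy())

    @property
    def n_stimuli(self) -> int:
        return self.U.shape[0]

    @property
    def positions(self) -> np.ndarray:
        """Point estimate of each stimulus position, ``U/(U+L)``.

        Defined as 0.5 where ``U + L == 0`` (no positional evidence yet).
        """
        total = self.U + self.L
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(total > 0, self.U / np.where(total > 0, total, 1.0), 0.5)
        return v

    @property
    def reward_rate(self) -> np.ndarray:
        """Estimated per-stimulus reward probability, ``R/(R+N)``.

        E.g. tallies ``R=10.5, N=4.5`` give an estimate of 0.70.  Returns
        NaN where no trials have been tallied.
        """
        total = self.R + self.N
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, self.R / np.where(total > 0, total, 1.0), np.nan)

    def copy(self) -> "BetaMemory":
        return BetaMemory(self.U.copy(), self.L.copy(), self.R.copy(), self.N.copy())


@dataclass
class QMemory:
    """Expected-value vector for the Q/softmax baseline.

    Values live on [0, 1] and are initialised to 0.5 (reward is binary, so
    0.5 is the uninformed expectation).
    """

    Q: np.ndarray = field(default_factory=lambda: np.full(7, 0.5))

    def __post_init__(self) -> None:
        arr = np.asarray(self.Q, dtype=float)
        if arr.ndim != 1:
            raise ValueError("Q must be a 1-D vector")
        if not np.all(np.isfinite(arr)):
            raise ValueError("Q entries must be finite")
        object.__setattr__(self, "Q", arr)

    @classmethod
    def initial(cls, n_stimuli: int) -> "QMemory":
        if n_stimuli < 2:
            raise ValueError("need at least two stimuli")
        return cls(np.full(n_stimuli, 0.5))

    @property
    def n_stimuli(self) -> int:
        return self.Q.shape[0]

    @property
    def positions(self) -> np.ndarray:
        """Alias so value-trajectory code treats Q like the beta models."""
        return self.Q.copy()

    def copy(self) -> "QMemory":
        return QMemory(self.Q.copy())
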