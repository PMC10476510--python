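"""Anagenetic rate matrices for the DEC process.

Along a branch a lineage may expand its range by dispersal into a new
area, or contract it by local extinction from an occupied area; losing the
last area puts the lineage in the absorbing null range.  The instantaneous
rate matrix ``Q`` over the range space encodes these events:

* expansion ``R -> R ∪ {a}`` at rate ``d * sum_{b in R} m[b, a]`` where
  ``m`` is the dispersal-multiplier matrix (and 0 if area ``a`` is not
  available in the current epoch);
* contraction ``R -> R \\ {a}`` at rate ``e`` per occupied area (a
  single-area range contracts to ``∅``).

Dispersal multipliers encode geological hypotheses: pairs of areas with a
(hypothesised) land connection carry weight 1, disallowed pairs carry a
small floor (0.001 by default) rather than exact zero so that constrained
models remain fittable.  Epoch stratification makes areas unavailable
before they existed: expansions into an unavailable area get rate exactly
zero, a hard constraint distinct from multiplier softening.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .range_space import RangeSpace

__all__ = [
    "DecParams",
    "DispersalMultipliers",
    "Epoch",
    "EpochStratification",
    "build_q",
    "transition_probabilities",
    "epoch_matrices",
]


@dataclass(frozen=True)
class DecParams:
    """Rates of the anagenetic process, in events per million years.

    ``d`` is the base dispersal rate per (source-area, target-area) pair;
    ``e`` is the local extinction rate per occupied area.
    """

    d: float
    e: float

    def __post_init__(self) -> None:
        for name, v in (("d", self.d), ("e", self.e)):
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {v}")


class DispersalMultipliers:
    """Square non-negative matrix of relative dispersal feasibilities.

    ``m[b, a]`` scales the rate of dispersal out of area ``b`` into area
    ``a``.  The diagonal is ignored by the rate construction.
    """

    def __init__(self, m: np.ndarray, codes: Sequence[str] | None = None):
        m = np.asarray(m, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"multiplier matrix must be square, got {m.shape}")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ValueError("multipliers must be finite and non-negative")
        self.m = m
        self.codes = list(codes) if codes is not None else None

    @classmethod
    def ones(cls, n: int) -> "DispersalMultipliers":
        return cls(np.ones((n, n)))

    @property
    def n(self) -> int:
        return self.m.shape[0]

    def __eq__(self, other) -> bool:
        return isinstance(other, DispersalMultipliers) and np.array_equal(
            self.m, other.m
        )

    def to_text(self) -> str:
        codes = self.codes or [str(i) for i in range(self.n)]
        lines = ["\t" + "\t".join(codes)]
        for code, row in zip(codes, self.m):
            lines.append(code + "\t" + "\t".join(format(v, ".17g") for v in row))
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class Epoch:
    """One time stratum: ``[start_age, end_age)`` in Ma, older to younger."""

    start_age: float
    end_age: float
    available: frozenset[int]

    def __post_init__(self) -> None:
        if self.start_age <= self.end_age:
            raise ValueError(
                f"epoch start_age ({self.start_age}) must exceed end_age "
                f"({self.end_age})"
            )
        if not self.available:
            raise ValueError("epoch must have at least one available area")


class EpochStratification:
    """Contiguous sequence of epochs covering root-to-present.

    Epochs are ordered oldest first; the youngest must end at 0 Ma and
    have every area available (extant tips occupy every sampled area).
    """

    def __init__(self, epochs: Sequence[Epoch]):
        epochs = list(epochs)
        if not epochs:
            raise ValueError("need at least one epoch")
        for older, younger in zip(epochs, epochs[1:]):
            if abs(older.end_age - younger.start_age) > 1e-9:
                raise ValueError(
                    "epochs must be contiguous (older.end_age == younger.start_age)"
                )
        if abs(epochs[-1].end_age) > 1e-9:
            raise ValueError("youngest epoch must end at 0 Ma")
        self.epochs = epochs

    @classmethod
    def single(cls, n_areas: int, start_age: float = np.inf) -> "EpochStratification":
        """Trivial stratification: one epoch, all areas always available."""
        return cls([Epoch(start_age, 0.0, frozenset(range(n_areas)))])

    @property
    def is_trivial(self) -> bool:
        return len(self.epochs) == 1

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def epoch_index_at(self, age: float) -> int:
        """Index of the epoch containing ``age`` (Ma before present)."""
        # boundary ages resolve to the older epoch (first match, oldest first)
        for i, ep in enumerate(self.epochs):
            if ep.end_age <= age <= ep.start_age:
                return i
        raise ValueError(f"age {age} Ma is older than the oldest epoch")

    def boundaries_within(self, younger: float, older: float) -> list[float]:
        """Epoch boundary ages strictly inside the interval (younger, older)."""
        cuts = [ep.end_age for ep in self.epochs[:-1]]
        return sorted(c for c in cuts if younger < c < older)


def build_q(
    space: RangeSpace,
    params: DecParams,
    mult: DispersalMultipliers | None = None,
    available: Sequence[int] | frozenset[int] | None = None,
) -> np.ndarray:
    """Instantaneous rate matrix of the DEC process over ``space``.

    Rows are source ranges, columns destination ranges; each row sums to
    zero and the null-range row is identically zero (absorbing).
    """
    n = space.n_areas
    if mult is None:
        mult = DispersalMultipliers.ones(n)
    if mult.n != n:
        raise ValueError(
            f"multiplier matrix is {mult.n}x{mult.n} but the space has {n} areas"
        )
    avail = frozenset(range(n)) if available is None else frozenset(available)
    S = len(space)
    Q = np.zeros((S, S))
    for i, state in enumerate(space.states):
        if state.is_null:
            continue
        occ = state.areas
        # range expansions
        if state.size < space.max_size:
            for a in range(n):
                if a in state or a not in avail:
                    continue
                rate = params.d * sum(mult.m[b, a] for b in occ)
                if rate:
                    j = space.index(occ + (a,))
                    Q[i, j] = rate
        # per-area local extinction (size-1 ranges contract to the null range)
        for a in occ:
            j = space.index(tuple(b for b in occ if b != a))
            Q[i, j] = params.e
        Q[i, i] = -Q[i].sum() + Q[i, i]
    return Q


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """Finite-time transition matrix ``P(t) = expm(Q t)``.

    Rows sum to one; ``P(0)`` is the identity.
    """
    if t < 0:
        raise ValueError(f"elapsed time must be >= 0, got {t}")
    Q = np.asarray(Q, dtype=float)
    if t == 0:
        return np.eye(Q.shape[0])
    P = expm(Q * t)
    # expm can leave tiny negative round-off; clip without renormalising
    np.clip(P, 0.0, None, out=P)
    return P


def epoch_matrices(
    space: RangeSpace,
    params: DecParams,
    mult: DispersalMultipliers | None = None,
    strat: EpochStratification | None = None,
) -> list[np.ndarray]:
    """One Q matrix per epoch, sharing a single multiplier matrix."""
    if strat is None:
        strat = EpochStratification.single(space.n_areas)
    return [build_q(space, params, mult, ep.available) for ep in strat]
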