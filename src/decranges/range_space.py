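"""Discrete state space of geographic ranges.

A lineage's geographic range is a set of occupied areas.  The DEC process
operates on the space of all such sets up to a maximum occupancy, plus the
null range ``∅`` representing total (global) extinction of the lineage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Sequence

__all__ = ["Area", "RangeState", "RangeSpace", "enumerate_ranges", "range_index"]

#: Allowed area categories; used when classifying range transitions.
AREA_CATEGORIES = ("mainland-terrane", "island", "outgroup-region")


@dataclass(frozen=True)
class Area:
    """One discrete geographic unit (tectonic terrane, island, ...).

    Parameters
    ----------
    code:
        Short unique label, e.g. ``"E"`` for the East Papua Composite
        Terrane.
    name:
        Free-text description.
    category:
        One of ``"mainland-terrane"``, ``"island"`` or
        ``"outgroup-region"``; drives the mainland/island classification of
        inferred dispersal events.
    """

    code: str
    name: str = ""
    category: str = "mainland-terrane"

    def __post_init__(self) -> None:
        if self.category not in AREA_CATEGORIES:
            raise ValueError(
                f"unknown area category {self.category!r}; "
                f"expected one of {AREA_CATEGORIES}"
            )


@dataclass(frozen=True)
class RangeState:
    """A set of occupied area indices; the empty tuple is the null range."""

    areas: tuple[int, ...]

    def __init__(self, areas: Iterable[int] = ()) -> None:
        ordered = tuple(sorted(set(int(a) for a in areas)))
        object.__setattr__(self, "areas", ordered)

    @property
    def size(self) -> int:
        return len(self.areas)

    @property
    def is_null(self) -> bool:
        return not self.areas

    def __iter__(self):
        return iter(self.areas)

    def __contains__(self, area: int) -> bool:
        return area in self.areas

    def label(self, areas: Sequence[Area] | None = None) -> str:
        if self.is_null:
            return "∅"
        if areas is None:
            return "".join(str(a) for a in self.areas)
        return "".join(areas[a].code for a in self.areas)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RangeState({self.label()})"


class RangeSpace:
    """Ordered enumeration of all ranges over a fixed area set.

    States are ordered canonically: the null range first, then all
    single-area ranges in area order, then two-area ranges in
    lexicographic order of their (sorted) index tuples, and so on up to
    ``max_size``.  The ordering is deterministic, so matrix layouts built
    on top of it are reproducible byte-for-byte.
    """

    def __init__(self, areas: Sequence[Area], max_size: int = 2, include_null: bool = True):
        areas = list(areas)
        codes = [a.code for a in areas]
        if len(set(codes)) != len(codes):
            raise ValueError("area codes must be unique")
        if not areas:
            raise ValueError("need at least one area")
        if not 1 <= max_size <= len(areas):
            raise ValueError(
                f"max_size must be in [1, {len(areas)}], got {max_size}"
            )
        self.areas: list[Area] = areas
        self.max_size = int(max_size)
        states: list[RangeState] = []
        if include_null:
            states.append(RangeState(()))
        for k in range(1, max_size + 1):
            for combo in itertools.combinations(range(len(areas)), k):
                states.append(RangeState(combo))
        self.states: list[RangeState] = states
        self._index: dict[tuple[int, ...], int] = {
            s.areas: i for i, s in enumerate(states)
        }
        self.include_null = include_null

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    def __getitem__(self, i: int) -> RangeState:
        return self.states[i]

    def index(self, state: RangeState | Iterable[int]) -> int:
        if not isinstance(state, RangeState):
            state = RangeState(state)
        try:
            return self._index[state.areas]
        except KeyError:
            raise ValueError(
                f"range {state.label()} is not a state of this space "
                f"(n_areas={self.n_areas}, max_size={self.max_size})"
            ) from None

    def index_of_codes(self, codes: Iterable[str]) -> int:
        code_to_idx = {a.code: i for i, a in enumerate(self.areas)}
        try:
            return self.index(RangeState(code_to_idx[c] for c in codes))
        except KeyError as err:
            raise ValueError(f"unknown area code {err.args[0]!r}") from None

    def labels(self) -> list[str]:
        return [s.label(self.areas) for s in self.states]

    def to_table(self) -> str:
        """Plain-text dump of the enumeration (index, label, size)."""
        lines = ["index\trange\tsize"]
        for i, s in enumerate(self.states):
            lines.append(f"{i}\t{s.label(self.areas)}\t{s.size}")
        return "\n".join(lines) + "\n"

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"RangeSpace(n_areas={self.n_areas}, max_size={self.max_size}, "
            f"n_states={len(self)})"
        )


def enumerate_ranges(
    n_areas: int, max_size: int = 2, include_null: bool = True
) -> RangeSpace:
    """Enumerate all ranges over ``n_areas`` generic areas.

    With three areas and ``max_size=2`` the enumeration is
    ``{∅, 1, 2, 3, 12, 13, 23}`` (seven states).  The total count is
    ``include_null + sum_{k=1..max_size} C(n_areas, k)``.
    """
    areas = [Area(code=str(i + 1)) for i in range(n_areas)]
    return RangeSpace(areas, max_size=max_size, include_null=include_null)


def range_index(space: RangeSpace, state: RangeState | Iterable[int]) -> int:
    """Canonical integer index of ``state`` within ``space`` (``∅`` is 0)."""
    return space.index(state)


def n_states(n_areas: int, max_size: int, include_null: bool = True) -> int:
    """Closed-form size of the range space."""
    return int(include_null) + sum(comb(n_areas, k) for k in range(1, max_size + 1))
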