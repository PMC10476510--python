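"""Range inheritance at speciation nodes.

At a node the ancestral range is partitioned between the two daughters
under the classic DEC convention (no founder-event "jump" dispersal):

* a single-area ancestor is copied to both daughters (sympatry);
* a wider ancestor either splits into two disjoint non-empty parts
  (vicariance) or one daughter inherits the full range while the other
  inherits a single member area (subset sympatry).

All allowed (ordered) daughter pairs for a given ancestor are
equiprobable.  For a two-area ancestor ``{a, b}`` this yields the six
events ``a|b, b|a, a|ab, ab|a, b|ab, ab|b`` each with probability 1/6.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .range_space import RangeSpace, RangeState

__all__ = ["CladoEvent", "enumerate_daughter_events", "event_arrays"]


@dataclass(frozen=True)
class CladoEvent:
    ancestor: RangeState
    left: RangeState
    right: RangeState
    prob: float


def _daughter_pairs(ancestor: RangeState, max_size: int) -> list[tuple[RangeState, RangeState]]:
    occ = ancestor.areas
    if len(occ) == 1:
        s = RangeState(occ)
        return [(s, s)]
    pairs: list[tuple[RangeState, RangeState]] = []
    # vicariance: ordered splits into two disjoint non-empty parts
    for k in range(1, len(occ)):
        for left in itertools.combinations(occ, k):
            right = tuple(a for a in occ if a not in left)
            if len(left) <= max_size and len(right) <= max_size:
                pairs.append((RangeState(left), RangeState(right)))
    # subset sympatry: one daughter keeps the full range, the other a single area
    full = RangeState(occ)
    if len(occ) <= max_size:
        for a in occ:
            single = RangeState((a,))
            pairs.append((single, full))
            pairs.append((full, single))
    return pairs


def enumerate_daughter_events(
    ancestor: RangeState, max_size: int = 2
) -> list[CladoEvent]:
    """All equiprobable ordered daughter-range pairs for ``ancestor``."""
    if ancestor.is_null:
        raise ValueError("the null range cannot speciate")
    pairs = _daughter_pairs(ancestor, max_size)
    p = 1.0 / len(pairs)
    return [CladoEvent(ancestor, l, r, p) for l, r in pairs]


def event_arrays(space: RangeSpace) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flat (ancestor, left, right, prob) index arrays over a whole space.

    Vectorised form of :func:`enumerate_daughter_events` used by the
    pruning likelihood: conditional likelihoods combine as
    ``L[anc] = sum_events prob * L_left[left] * L_right[right]``.
    """
    anc, left, right, prob = [], [], [], []
    for state in space.states:
        if state.is_null:
            continue
        i = space.index(state)
        for ev in enumerate_daughter_events(state, space.max_size):
            anc.append(i)
            left.append(space.index(ev.left))
            right.append(space.index(ev.right))
            prob.append(ev.prob)
    return (
        np.asarray(anc, dtype=np.intp),
        np.asarray(left, dtype=np.intp),
        np.asarray(right, dtype=np.intp),
        np.asarray(prob, dtype=float),
    )


def event_table(space: RangeSpace) -> str:
    """Plain-text dump of the cladogenetic event table (debugging aid)."""
    lines = ["ancestor\tleft\tright\tprob"]
    for state in space.states:
        if state.is_null:
            continue
        for ev in enumerate_daughter_events(state, space.max_size):
            lines.append(
                "\t".join(
                    (
                        ev.ancestor.label(space.areas),
                        ev.left.label(space.areas),
                        ev.right.label(space.areas),
                        format(ev.prob, "g"),
                    )
                )
            )
    return "\n".join(lines) + "\n"
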