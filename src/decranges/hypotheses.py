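"""The competing geological hypotheses as DEC model builders.

Each hypothesis encodes a scenario for the assembly of New Guinea and its
satellite islands as a dispersal-multiplier matrix (and, for scenarios
about land emergence, an epoch stratification).  Connected area pairs
carry multiplier 1; unconnected pairs carry a small floor (0.001) rather
than exact zero so constrained models remain fittable; the Island
Distance scenario uses intermediate distance-class weights.

Hypotheses are declared on the 11-region display layout in which the two
sampled D'Entrecasteaux islands (Normanby, Fergusson) are collapsed into
a single region ``D`` and Southeast Asia is omitted; working models
expand ``D`` back into the two islands (each inheriting ``D``'s
connections, connected to each other with 1) and attach Southeast Asia at
the floor value.  The epoch boundaries of the time-stratified scenarios
are interpretive defaults and can be overridden via a custom
:class:`HypothesisSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .likelihood import DecModel
from .range_space import Area, RangeSpace
from .rate_model import DispersalMultipliers, Epoch, EpochStratification

__all__ = [
    "HypothesisSpec",
    "build_hypothesis",
    "builtin_hypotheses",
    "study_areas",
    "display_multiplier_matrix",
    "DEFAULT_FLOOR",
]

DEFAULT_FLOOR = 0.001

#: The 13 georegions of the study system.
_STUDY_AREAS = (
    ("V", "Vogelkop Peninsula", "mainland-terrane"),
    ("C", "Australian Craton", "mainland-terrane"),
    ("F", "Fold Belt", "mainland-terrane"),
    ("A", "Accreted Terranes", "mainland-terrane"),
    ("E", "East Papua Composite Terrane", "mainland-terrane"),
    ("Y", "Normanby Island", "island"),
    ("G", "Fergusson Island", "island"),
    ("W", "Woodlark Island", "island"),
    ("M", "Misima Island", "island"),
    ("S", "Sudest Island", "island"),
    ("R", "Rossel Island", "island"),
    ("B", "New Britain Island", "island"),
    ("N", "Southeast Asia", "outgroup-region"),
)


def study_areas() -> list[Area]:
    """The 13 georegions: 5 mainland terranes, 7 islands, Southeast Asia."""
    return [Area(code=c, name=n, category=k) for c, n, k in _STUDY_AREAS]


@dataclass(frozen=True)
class HypothesisSpec:
    """Declarative description of one dispersal hypothesis.

    ``pairwise_connections`` lists unordered area-code pairs joined by a
    land connection (multiplier 1); ``multiway_blocks`` lists code sets
    whose members are all mutually connected; ``distance_weights`` maps
    unordered pairs to explicit multipliers (overriding the above); pairs
    mentioned nowhere default to ``floor``.
    """

    name: str
    pairwise_connections: tuple[tuple[str, str], ...] = ()
    multiway_blocks: tuple[frozenset, ...] = ()
    distance_weights: tuple[tuple[frozenset, float], ...] = ()
    epochs: tuple[tuple[float, float, frozenset], ...] = ()  # (start, end, available)
    floor: float = DEFAULT_FLOOR
    unconstrained: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.floor < 1:
            raise ValueError(f"floor must be in (0, 1), got {self.floor}")


def build_hypothesis(
    spec: HypothesisSpec, areas: list[Area], max_size: int = 2
) -> DecModel:
    """Materialise a spec as a :class:`DecModel` over ``areas``."""
    codes = [a.code for a in areas]
    pos = {c: i for i, c in enumerate(codes)}

    def _at(code: str) -> int:
        try:
            return pos[code]
        except KeyError:
            raise ValueError(
                f"hypothesis {spec.name!r} references unknown area code {code!r}"
            ) from None

    n = len(areas)
    if spec.unconstrained:
        m = np.ones((n, n))
    else:
        m = np.full((n, n), spec.floor)
        np.fill_diagonal(m, 1.0)
        for c1, c2 in spec.pairwise_connections:
            i, j = _at(c1), _at(c2)
            m[i, j] = m[j, i] = 1.0
        for block in spec.multiway_blocks:
            idx = [_at(c) for c in block]
            for i in idx:
                for j in idx:
                    if i != j:
                        m[i, j] = 1.0
        for pair, w in spec.distance_weights:
            c1, c2 = sorted(pair)
            i, j = _at(c1), _at(c2)
            m[i, j] = m[j, i] = w

    strat = None
    if spec.epochs:
        strat = EpochStratification(
            [
                Epoch(start, end, frozenset(_at(c) for c in avail))
                for start, end, avail in spec.epochs
            ]
        )
    space = RangeSpace(areas, max_size=max_size)
    return DecModel(
        space=space,
        mult=DispersalMultipliers(m, codes=codes),
        strat=strat,
        name=spec.name,
    )


# ---------------------------------------------------------------------------
# built-in hypothesis set (display layout: V C F A E D W M S R B)

DISPLAY_CODES = ("V", "C", "F", "A", "E", "D", "W", "M", "S", "R", "B")

_MAINLAND = ("V", "C", "F", "A", "E")
_ISLANDS_D = ("D", "W", "M", "S", "R", "B")

# present-day accretion margins: which terranes share a suture today
_PAIRS_CURRENT = (
    ("V", "C"),
    ("V", "F"),
    ("V", "A"),
    ("C", "F"),
    ("F", "A"),
    ("F", "E"),
    ("A", "E"),
)
# prolonged piecewise accretion: every terrane pair shared a margin at some time
_PAIRS_SLOW_STEADY = _PAIRS_CURRENT + (("V", "E"), ("C", "E"), ("C", "A"))

_ALWAYS = frozenset(DISPLAY_CODES)


def _island_distance_weights() -> tuple[tuple[frozenset, float], ...]:
    near, far = ("D", "B"), ("W", "M", "S", "R")
    weights = []
    for isl in near:
        for ml in _MAINLAND:
            weights.append((frozenset((isl, ml)), 0.1))
    for isl in far:
        for ml in _MAINLAND:
            weights.append((frozenset((isl, ml)), 0.001))
    return tuple(weights)


_DISPLAY_SPECS: dict[str, HypothesisSpec] = {
    "a": HypothesisSpec(
        name="a: Current Connectivity",
        pairwise_connections=_PAIRS_CURRENT,
    ),
    "b": HypothesisSpec(
        name="b: Slow and Steady",
        pairwise_connections=_PAIRS_SLOW_STEADY,
    ),
    "c": HypothesisSpec(
        name="c: Mobile Belt",
        pairwise_connections=_PAIRS_CURRENT,
        # Accreted Terranes assembled offshore (25-23 Ma) and docked onto the
        # mainland 15-11 Ma; they become occupiable once docking completes.
        epochs=(
            (np.inf, 11.0, _ALWAYS - {"A"}),
            (11.0, 0.0, _ALWAYS),
        ),
    ),
    "d": HypothesisSpec(
        name="d: Recent Emergence",
        pairwise_connections=_PAIRS_CURRENT,
        # most of mainland New Guinea submerged until ~5 Ma; only the central
        # high mountains (Fold Belt) and the offshore islands stand above water
        epochs=(
            (np.inf, 5.0, frozenset(("F",) + _ISLANDS_D)),
            (5.0, 0.0, _ALWAYS),
        ),
    ),
    "e": HypothesisSpec(
        name="e: Louisiade Archipelago",
        pairwise_connections=_PAIRS_SLOW_STEADY,
        multiway_blocks=(frozenset(("M", "S", "R")),),
    ),
    "f": HypothesisSpec(
        name="f: Woodlark w/ Louisiades",
        pairwise_connections=_PAIRS_SLOW_STEADY,
        multiway_blocks=(frozenset(("W", "M", "S", "R")),),
    ),
    "g": HypothesisSpec(
        name="g: Owen Stanleys",
        pairwise_connections=_PAIRS_CURRENT,
        multiway_blocks=(frozenset(("E",) + _ISLANDS_D),),
    ),
    "h": HypothesisSpec(
        name="h: Historical Owen Stanleys",
        pairwise_connections=_PAIRS_SLOW_STEADY,
        multiway_blocks=(frozenset(("E", "D", "W", "M", "S", "R")),),
    ),
    "i": HypothesisSpec(
        name="i: Offshore w/ EPCT",
        pairwise_connections=_PAIRS_SLOW_STEADY,
        multiway_blocks=(frozenset(("E",) + _ISLANDS_D),),
    ),
    "j": HypothesisSpec(
        name="j: Offshore w/ Nearest Mainland",
        pairwise_connections=_PAIRS_SLOW_STEADY + (("A", "B"),),
        multiway_blocks=(frozenset(("E", "D", "W", "M", "S", "R")),),
    ),
    "k": HypothesisSpec(
        name="k: Offshore Islands w/ Accreted",
        pairwise_connections=_PAIRS_SLOW_STEADY,
        multiway_blocks=(frozenset(("A",) + _ISLANDS_D),),
    ),
    "l": HypothesisSpec(
        name="l: Island Distance",
        pairwise_connections=_PAIRS_SLOW_STEADY,
        multiway_blocks=(frozenset(("W", "M", "S", "R")),),
        distance_weights=_island_distance_weights(),
    ),
    "unconstrained": HypothesisSpec(name="Unconstrained DEC", unconstrained=True),
}


def _expand_display_spec(spec: HypothesisSpec) -> HypothesisSpec:
    """Translate an 11-region display spec to the 13-region working layout.

    ``D`` splits into Normanby (Y) and Fergusson (G), each inheriting
    ``D``'s connections and connected to each other with 1; Southeast
    Asia (N) attaches at the floor value everywhere.
    """

    def expand_codes(codes) -> list[str]:
        out = []
        for c in codes:
            out.extend(("Y", "G") if c == "D" else (c,))
        return out

    pairs: list[tuple[str, str]] = []
    for c1, c2 in spec.pairwise_connections:
        for e1 in expand_codes((c1,)):
            for e2 in expand_codes((c2,)):
                pairs.append((e1, e2))
    pairs.append(("Y", "G"))
    blocks = tuple(frozenset(expand_codes(b)) for b in spec.multiway_blocks)
    weights = []
    for pair, w in spec.distance_weights:
        c1, c2 = sorted(pair)
        for e1 in expand_codes((c1,)):
            for e2 in expand_codes((c2,)):
                if e1 != e2:
                    weights.append((frozenset((e1, e2)), w))
    epochs = tuple(
        (start, end, frozenset(expand_codes(avail)) | {"N"})
        for start, end, avail in spec.epochs
    )
    return replace(
        spec,
        pairwise_connections=tuple(pairs),
        multiway_blocks=blocks,
        distance_weights=tuple(weights),
        epochs=epochs,
    )


def display_multiplier_matrix(key: str) -> tuple[tuple[str, ...], np.ndarray]:
    """Multiplier matrix of a built-in hypothesis on the 11-region layout.

    Returns ``(codes, matrix)`` with rows/columns ordered
    ``V C F A E D W M S R B``.
    """
    spec = _DISPLAY_SPECS[key]
    areas = [Area(code=c) for c in DISPLAY_CODES]
    model = build_hypothesis(spec, areas)
    return DISPLAY_CODES, model.mult.m


def builtin_hypotheses(
    areas: list[Area] | None = None, max_size: int = 2
) -> dict[str, DecModel]:
    """All thirteen built-in models on the 13-region working layout."""
    if areas is None:
        areas = study_areas()
    codes = {a.code for a in areas}
    required = {c for c, _, _ in _STUDY_AREAS}
    missing = required - codes
    if missing:
        raise ValueError(f"area set is missing study georegions: {sorted(missing)}")
    return {
        key: build_hypothesis(_expand_display_spec(spec), areas, max_size=max_size)
        for key, spec in _DISPLAY_SPECS.items()
    }


def builtin_spec(key: str, expanded: bool = True) -> HypothesisSpec:
    """The declarative spec behind a built-in hypothesis (for overriding)."""
    spec = _DISPLAY_SPECS[key]
    return _expand_display_spec(spec) if expanded else spec
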