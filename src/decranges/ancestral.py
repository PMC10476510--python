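"""Ancestral range reconstruction and dispersal-event tabulation.

Marginal range probabilities at internal nodes are obtained by the
standard two-pass algorithm: the pruning downpass gives conditional
likelihoods of the data below each node, a rootward pass propagates the
likelihood of the rest of the tree through the cladogenetic event table
and down each branch, and their product (normalised) is the marginal
posterior at the node.

Because the study taxa are single-area endemics, multi-area range
probabilities are apportioned equally among their member areas before
assigning a majority-rule area to each node; range shifts are then read
off parent-to-child edges and binned by the age of the parent node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .likelihood import DecModel, _PruningEngine
from .range_space import Area, RangeSpace, RangeState
from .rate_model import DecParams

__all__ = [
    "AncestralReconstruction",
    "TransitionTable",
    "reconstruct_ancestral_ranges",
    "apportion_to_areas",
    "count_transitions",
    "summarize_transitions",
    "DEFAULT_BINS",
]

#: default time bins (Ma), oldest first, as (older, younger) edges
DEFAULT_BINS = ((20.0, 15.0), (15.0, 10.0), (10.0, 3.0), (3.0, 0.0))


def apportionment_matrix(space: RangeSpace) -> np.ndarray:
    """(n_states x n_areas) matrix spreading each range's mass over its areas."""
    A = np.zeros((len(space), space.n_areas))
    for i, s in enumerate(space.states):
        if s.is_null:
            continue
        for a in s.areas:
            A[i, a] = 1.0 / s.size
    return A


def apportion_to_areas(range_probs: np.ndarray, space: RangeSpace) -> np.ndarray:
    """Spread a probability vector over ranges onto single areas.

    A k-area range contributes ``prob / k`` to each member area; mass on
    the null range is renormalised away with a warning.
    """
    p = np.asarray(range_probs, dtype=float)
    if p.shape != (len(space),):
        raise ValueError(
            f"expected a vector of length {len(space)}, got shape {p.shape}"
        )
    out = apportionment_matrix(space).T @ p
    total = out.sum()
    null_mass = p.sum() - total
    if null_mass > 1e-8:
        warnings.warn(
            f"null-range mass {null_mass:.3g} renormalised away", stacklevel=2
        )
    if total <= 0:
        raise ValueError("no probability mass on non-null ranges")
    return out / total if abs(total - 1.0) > 1e-12 else out


@dataclass
class AncestralReconstruction:
    """Per-node marginal range probabilities and derived area assignments.

    Nodes are indexed in postorder (the root last); tips carry their
    observed range with probability 1.
    """

    space: RangeSpace
    node_ages: np.ndarray  # (n_nodes,)
    is_leaf: np.ndarray  # (n_nodes,) bool
    parent: np.ndarray  # (n_nodes,) postorder parent index, -1 at root
    labels: list  # tip label or None per node
    range_probs: np.ndarray  # (n_nodes, n_states)
    area_probs: np.ndarray  # (n_nodes, n_areas)
    majority_area: np.ndarray  # (n_nodes,) area index

    @property
    def n_nodes(self) -> int:
        return len(self.node_ages)

    def to_dataframe(self) -> pd.DataFrame:
        codes = [a.code for a in self.space.areas]
        df = pd.DataFrame(self.area_probs, columns=codes)
        df.insert(0, "node", np.arange(self.n_nodes))
        df.insert(1, "label", [l if l else "" for l in self.labels])
        df.insert(2, "age", self.node_ages)
        df.insert(3, "majority_area", [codes[a] for a in self.majority_area])
        return df


def reconstruct_ancestral_ranges(
    tree,
    tips: Mapping[str, RangeState],
    model: DecModel,
    params: DecParams,
    root: str = "sum",
    mode: str = "marginal",
) -> AncestralReconstruction:
    """Marginal (default) or joint max-product ancestral reconstruction.

    ``params`` would normally be ML estimates, but reconstruction at
    arbitrary rates is permitted (useful for testing).
    """
    engine = _PruningEngine(tree, tips, model)
    idx = engine.index
    n = len(idx.nodes)
    S = engine.n_states
    below, up, log_scale, prop = engine.downpass(params)
    if below is None:
        raise ValueError("data have zero likelihood under these parameters")

    parent = np.full(n, -1, dtype=int)
    for i, ch in enumerate(idx.children):
        if ch is not None:
            parent[ch[0]] = i
            parent[ch[1]] = i

    if mode == "marginal":
        post = _marginal_posteriors(engine, below, up, prop, root)
    elif mode == "joint":
        post = _joint_assignment(engine, prop, root)
    else:
        raise ValueError(f"unknown reconstruction mode {mode!r}")

    A = apportionment_matrix(engine.space)
    area_probs = post @ A
    area_probs /= area_probs.sum(axis=1, keepdims=True)
    majority = area_probs.argmax(axis=1)  # argmax ties resolve to lowest area index
    near_tie = (
        np.sort(area_probs, axis=1)[:, -1] - np.sort(area_probs, axis=1)[:, -2]
    ) < 1e-12
    if near_tie.any():
        warnings.warn(
            f"majority-rule tie at {int(near_tie.sum())} node(s); "
            "broken by area order",
            stacklevel=2,
        )
    return AncestralReconstruction(
        space=engine.space,
        node_ages=idx.age.copy(),
        is_leaf=idx.is_leaf.copy(),
        parent=parent,
        labels=list(idx.taxon_label),
        range_probs=post,
        area_probs=area_probs,
        majority_area=majority,
    )


def _marginal_posteriors(engine, below, up, prop, root) -> np.ndarray:
    idx = engine.index
    n = len(idx.nodes)
    S = engine.n_states
    anc, left, right, prob = engine.anc, engine.left, engine.right, engine.prob
    G = [None] * n
    g_root = engine.nonnull.astype(float)
    if root == "uniform":
        g_root = g_root / g_root.sum()
    G[idx.root] = g_root
    # preorder = reversed postorder
    for u in range(n - 1, -1, -1):
        ch = idx.children[u]
        if ch is None:
            continue
        l, r = ch
        gu = G[u]
        w = gu[anc] * prob
        H_l = np.bincount(left, weights=w * up[r][right], minlength=S)
        H_r = np.bincount(right, weights=w * up[l][left], minlength=S)
        for child, H in ((l, H_l), (r, H_r)):
            vec = H
            # rootward propagation applies the transposes oldest -> youngest
            for ei, dt in reversed(idx.segments[child]):
                vec = prop.apply_transpose(ei, dt, vec)
            G[child] = vec
    post = np.zeros((n, S))
    for i in range(n):
        p = below[i] * G[i]
        total = p.sum()
        if total <= 0:
            raise ValueError(f"zero posterior mass at node {i}")
        post[i] = p / total
    return post


def _joint_assignment(engine, prop, root) -> np.ndarray:
    """Max-product (best joint history) assignment, one-hot per node."""
    idx = engine.index
    n = len(idx.nodes)
    S = engine.n_states
    anc, left, right, prob = engine.anc, engine.left, engine.right, engine.prob
    # Viterbi-style downpass over node states (max over events and branches)
    best = [None] * n
    back = [None] * n
    upm = [None] * n  # max-propagated vectors and argmax tables
    upb = [None] * n
    for i in range(n):
        if idx.is_leaf[i]:
            vec = engine.tip_vecs[i].copy()
        else:
            l, r = idx.children[i]
            score = prob * upm[l][left] * upm[r][right]
            vec = np.zeros(S)
            choice = np.zeros(S, dtype=int)
            np.maximum.at(vec, anc, score)
            for k in range(len(anc)):
                if score[k] >= vec[anc[k]]:
                    choice[anc[k]] = k
            back[i] = choice
        m = vec.max()
        vec = vec / m if m > 0 else vec
        best[i] = vec
        # propagate with full matrices, tracking argmax per segment chain
        out = vec
        bchain = []
        for ei, dt in idx.segments[i]:
            P = prop_matrix(prop, ei, dt)
            scores = P * out[None, :]
            bchain.append(scores.argmax(axis=1))
            out = scores.max(axis=1)
        upm[i] = out
        upb[i] = bchain
    # backtrack
    state = np.zeros(n, dtype=int)
    rv = best[idx.root] * engine.nonnull
    state[idx.root] = int(rv.argmax())
    order = list(range(n - 1, -1, -1))
    for u in order:
        ch = idx.children[u]
        if ch is None:
            continue
        k = back[u][state[u]]
        for child, s0 in ((ch[0], left[k]), (ch[1], right[k])):
            s = int(s0)
            for amax in reversed(upb[child]):
                s = int(amax[s])
            # amax chains map parent-end states to child-end states
            state[child] = s
    post = np.zeros((n, S))
    post[np.arange(n), state] = 1.0
    return post


def prop_matrix(prop, ei, dt):
    if dt == 0:
        return np.eye(prop.qs[ei].shape[0])
    from scipy.linalg import expm

    return np.clip(expm(prop.qs[ei] * dt), 0.0, None)


# ---------------------------------------------------------------------------
# transition counting


class TransitionTable:
    """Counts of inferred range shifts by source area, target area, time bin."""

    def __init__(
        self,
        areas: Sequence[Area],
        bins: Sequence[tuple[float, float]] = DEFAULT_BINS,
    ):
        self.areas = list(areas)
        self.bins = [tuple(map(float, b)) for b in bins]
        for older, younger in self.bins:
            if older <= younger:
                raise ValueError(f"bin ({older}, {younger}) must run older->younger")
        na, nb = len(self.areas), len(self.bins)
        self.counts = np.zeros((nb, na, na), dtype=int)
        self.overflow: list[tuple[int, int, float]] = []

    def bin_of(self, age: float) -> int | None:
        """Half-open bins [older, younger): a boundary age joins the bin it
        opens; the youngest bin is additionally closed at its younger edge."""
        for k, (older, younger) in enumerate(self.bins):
            top = older + 1e-9 * max(1.0, older) if k == 0 else older  # root-age fuzz
            if younger < age <= top or (k == len(self.bins) - 1 and age == younger):
                return k
        return None

    def record(self, src: int, dst: int, age: float) -> None:
        k = self.bin_of(age)
        if k is None:
            self.overflow.append((src, dst, age))
            warnings.warn(
                f"transition at age {age:.4g} Ma falls outside all bins", stacklevel=2
            )
            return
        self.counts[k, src, dst] += 1

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + len(self.overflow)

    def _category(self, i: int) -> str:
        return self.areas[i].category

    def category_total(self, src_cat: str, dst_cat: str) -> int:
        mask_s = np.array([self._category(i) == src_cat for i in range(len(self.areas))])
        mask_d = np.array([self._category(i) == dst_cat for i in range(len(self.areas))])
        return int(self.counts[:, mask_s][:, :, mask_d].sum())

    @property
    def mainland_to_mainland(self) -> int:
        return self.category_total("mainland-terrane", "mainland-terrane")

    @property
    def mainland_to_island(self) -> int:
        return self.category_total("mainland-terrane", "island")

    def source_counts(self, dst_cat: str, src_cat: str = "mainland-terrane") -> dict[str, int]:
        out = {}
        for i, a in enumerate(self.areas):
            if a.category != src_cat:
                continue
            mask_d = np.array([self._category(j) == dst_cat for j in range(len(self.areas))])
            out[a.code] = int(self.counts[:, i, mask_d].sum())
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for k, (older, younger) in enumerate(self.bins):
            for i, src in enumerate(self.areas):
                for j, dst in enumerate(self.areas):
                    c = self.counts[k, i, j]
                    if c:
                        rows.append(
                            {
                                "bin": f"{older:g}-{younger:g}",
                                "from": src.code,
                                "to": dst.code,
                                "count": int(c),
                            }
                        )
        return pd.DataFrame(rows, columns=["bin", "from", "to", "count"])


def count_transitions(
    reconstruction: AncestralReconstruction,
    bins: Sequence[tuple[float, float]] = DEFAULT_BINS,
) -> TransitionTable:
    """Tabulate majority-rule range shifts along every edge of the tree.

    A shift on a parent->child edge (tips included) is assigned the
    source and target majority-rule areas and the time bin containing the
    parent node's age.
    """
    rec = reconstruction
    table = TransitionTable(rec.space.areas, bins=bins)
    for child in range(rec.n_nodes):
        p = rec.parent[child]
        if p < 0:
            continue
        src, dst = int(rec.majority_area[p]), int(rec.majority_area[child])
        if src != dst:
            table.record(src, dst, float(rec.node_ages[p]))
    return table


def summarize_transitions(table: TransitionTable) -> dict:
    """Totals and per-source percentage shares of the tabulated dispersals.

    Percentages are rounded to the nearest integer; an empty table yields
    an all-zero summary.
    """
    mm = table.mainland_to_mainland
    mi = table.mainland_to_island
    mm_src = table.source_counts("mainland-terrane")
    mi_src = table.source_counts("island")

    def pct(counts: dict[str, int], denom: int) -> dict[str, int]:
        if denom == 0:
            return {k: 0 for k in counts}
        return {k: round(100.0 * v / denom) for k, v in counts.items()}

    return {
        "total": table.total,
        "mainland_to_mainland": mm,
        "mainland_to_island": mi,
        "mainland_source_pct_of_mainland_to_mainland": pct(mm_src, mm),
        "mainland_source_pct_of_mainland_to_island": pct(mi_src, mi),
    }
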