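"""DEC likelihood on a time-calibrated tree, ML fitting, AIC comparison.

The likelihood integrates over every combination of ancestral ranges at
internal nodes and every cladogenetic inheritance event compatible with
the observed tip ranges.  It is computed by the standard pruning
recursion: conditional likelihood vectors at the tips are indicator
vectors of the observed range; branch propagation multiplies per-epoch
transition matrices over the branch's age segments (oldest epoch first,
rows indexing the older end); at each node the two propagated daughter
vectors are combined over the cladogenetic event table; at the root the
vector is summed over non-null ranges (optionally averaged under a
uniform root prior).

Per-epoch transition probabilities are obtained from an eigendecomposition
of ``Q`` when it is well conditioned (two matrix-vector products per
branch) and fall back to dense ``expm`` otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .cladogenesis import event_arrays
from .range_space import RangeSpace, RangeState
from .rate_model import (
    DecParams,
    DispersalMultipliers,
    EpochStratification,
    build_q,
)

__all__ = [
    "DecModel",
    "FitResult",
    "compute_log_likelihood",
    "fit_dec",
    "compare_models",
    "selection_frequency",
]

RATE_BOUNDS = (1e-9, 10.0)
#: deterministic multi-start grid for the two rates (log-spaced)
DEFAULT_STARTS = ((1e-3, 1e-3), (1e-3, 1e-1), (1e-1, 1e-3), (1e-1, 1e-1))


@dataclass
class DecModel:
    """A DEC hypothesis: range space + dispersal multipliers + epochs."""

    space: RangeSpace
    mult: DispersalMultipliers | None = None
    strat: EpochStratification | None = None
    name: str = "DEC"

    def __post_init__(self) -> None:
        n = self.space.n_areas
        if self.mult is not None and self.mult.n != n:
            raise ValueError(
                f"model {self.name!r}: multiplier matrix is "
                f"{self.mult.n}x{self.mult.n} but the space has {n} areas"
            )
        if self.strat is not None:
            for ep in self.strat:
                if any(a >= n or a < 0 for a in ep.available):
                    raise ValueError(
                        f"model {self.name!r}: epoch availability references "
                        f"an area outside the {n}-area set"
                    )

    @property
    def max_size(self) -> int:
        return self.space.max_size

    def stratification(self) -> EpochStratification:
        if self.strat is None:
            return EpochStratification.single(self.space.n_areas)
        return self.strat

    def q_matrices(self, params: DecParams) -> list[np.ndarray]:
        return [
            build_q(self.space, params, self.mult, ep.available)
            for ep in self.stratification()
        ]


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model on one tree."""

    d: float
    e: float
    log_likelihood: float
    model_name: str
    tree_id: str = ""
    converged: bool = True
    n_evaluations: int = 0
    message: str = ""

    @property
    def aic(self) -> float:
        # every DEC model here has exactly two free parameters (d, e)
        return 4.0 - 2.0 * self.log_likelihood


# ---------------------------------------------------------------------------
# tree preprocessing


class TreeIndex:
    """Flat postorder arrays for a rooted binary dendropy tree.

    Ages are measured backward from the youngest tip (0 Ma = present,
    taken as the maximum root-to-tip path length).  Branches crossing
    epoch boundaries are split at the boundary ages.
    """

    def __init__(self, tree, strat: EpochStratification, ultrametric_rtol: float = 1e-3):
        post = list(tree.postorder_node_iter())
        self.nodes = post
        self.node_id = {id(nd): i for i, nd in enumerate(post)}
        n = len(post)
        # depths from root, then ages from the deepest tip
        depth = {}
        for nd in tree.preorder_node_iter():
            el = nd.edge.length or 0.0
            if el < 0:
                raise ValueError("negative branch length")
            depth[id(nd)] = (depth[id(nd.parent_node)] if nd.parent_node else 0.0) + (
                el if nd.parent_node else 0.0
            )
        leaves = [nd for nd in post if nd.is_leaf()]
        height = max(depth[id(nd)] for nd in leaves)
        tip_depths = np.array([depth[id(nd)] for nd in leaves])
        if height > 0 and np.max(height - tip_depths) > ultrametric_rtol * height:
            warnings.warn(
                "tree is not ultrametric within tolerance; ages are measured "
                "from the deepest tip",
                stacklevel=2,
            )
        self.age = np.array([max(height - depth[id(nd)], 0.0) for nd in post])
        self.height = height
        self.is_leaf = np.array([nd.is_leaf() for nd in post])
        self.children: list[tuple[int, int] | None] = []
        for nd in post:
            ch = nd.child_nodes()
            if not ch:
                self.children.append(None)
            elif len(ch) == 2:
                self.children.append((self.node_id[id(ch[0])], self.node_id[id(ch[1])]))
            else:
                raise ValueError(
                    f"tree must be strictly binary; node {nd!r} has {len(ch)} children"
                )
        self.taxon_label = [
            nd.taxon.label if nd.taxon is not None else None for nd in post
        ]
        # per-node branch segments (epoch index, duration), youngest first,
        # so vectors propagate child -> parent by successive application
        self.segments: list[list[tuple[int, float]]] = []
        for i, nd in enumerate(post):
            if nd.parent_node is None:
                self.segments.append([])
                continue
            a_child = self.age[i]
            a_parent = self.age[self.node_id[id(nd.parent_node)]]
            if a_parent > strat.epochs[0].start_age:
                raise ValueError(
                    f"branch spans age {a_parent:.4g} Ma, older than the oldest epoch"
                )
            cuts = strat.boundaries_within(a_child, a_parent)
            edges = [a_child] + cuts + [a_parent]
            segs = []
            for lo, hi in zip(edges[:-1], edges[1:]):
                mid = 0.5 * (lo + hi)
                segs.append((strat.epoch_index_at(mid), hi - lo))
            self.segments.append(segs)
        self.root = len(post) - 1


def tip_vector(space: RangeSpace, state: RangeState) -> np.ndarray:
    if state.is_null:
        raise ValueError("tips cannot be observed in the null range")
    v = np.zeros(len(space))
    v[space.index(state)] = 1.0
    return v


class Propagator:
    """Applies per-epoch transition matrices ``P(t) = expm(Q t)`` to vectors."""

    def __init__(self, qs: Sequence[np.ndarray], cond_limit: float = 1e8):
        self._decomp = []
        for Q in qs:
            try:
                lam, V = np.linalg.eig(Q)
                cond = np.linalg.cond(V)
                if np.isfinite(cond) and cond < cond_limit:
                    self._decomp.append((lam, V, np.linalg.inv(V), None))
                    continue
            except np.linalg.LinAlgError:
                pass
            self._decomp.append((None, None, None, Q))
        self._expm_cache: dict[tuple[int, float], np.ndarray] = {}
        self.qs = list(qs)

    def _expm(self, ei: int, t: float) -> np.ndarray:
        key = (ei, float(t))
        P = self._expm_cache.get(key)
        if P is None:
            P = expm(self.qs[ei] * t)
            self._expm_cache[key] = P
        return P

    def apply(self, ei: int, t: float, vec: np.ndarray) -> np.ndarray:
        """``P(t) @ vec`` for epoch ``ei``."""
        if t == 0:
            return vec
        lam, V, Vinv, Q = self._decomp[ei]
        if Q is not None:
            out = self._expm(ei, t) @ vec
        else:
            out = (V @ (np.exp(lam * t) * (Vinv @ vec))).real
        np.clip(out, 0.0, None, out=out)
        return out

    def apply_transpose(self, ei: int, t: float, vec: np.ndarray) -> np.ndarray:
        """``P(t).T @ vec`` for epoch ``ei``."""
        if t == 0:
            return vec
        lam, V, Vinv, Q = self._decomp[ei]
        if Q is not None:
            out = self._expm(ei, t).T @ vec
        else:
            out = (Vinv.T @ (np.exp(lam * t) * (V.T @ vec))).real
        np.clip(out, 0.0, None, out=out)
        return out


class _PruningEngine:
    """Reusable pruning machinery for one (tree, tips, model) triple."""

    def __init__(self, tree, tips: Mapping[str, RangeState], model: DecModel):
        self.model = model
        self.space = model.space
        self.strat = model.stratification()
        self.index = TreeIndex(tree, self.strat)
        labels = [l for l, leaf in zip(self.index.taxon_label, self.index.is_leaf) if leaf]
        missing = [l for l in labels if l not in tips]
        if missing:
            raise ValueError(f"tip ranges missing for: {missing[:5]}")
        self.tip_vecs = {}
        for i, nd_is_leaf in enumerate(self.index.is_leaf):
            if nd_is_leaf:
                label = self.index.taxon_label[i]
                state = tips[label]
                for a in state.areas:
                    if a >= self.space.n_areas:
                        raise ValueError(
                            f"tip {label!r} occupies area index {a}, outside the model"
                        )
                self.tip_vecs[i] = tip_vector(self.space, state)
        self.anc, self.left, self.right, self.prob = event_arrays(self.space)
        self.n_states = len(self.space)
        self.nonnull = np.array([not s.is_null for s in self.space.states])

    def propagator(self, params: DecParams) -> Propagator:
        return Propagator(self.model.q_matrices(params))

    def downpass(self, params: DecParams):
        """Conditional likelihoods below each node, with log-scaling.

        Returns (below, up, log_scale) where ``below[i]`` is the scaled
        conditional likelihood vector at node ``i`` and ``up[i]`` the
        vector propagated to the top (parent end) of ``i``'s branch.
        """
        prop = self.propagator(params)
        idx = self.index
        n = len(idx.nodes)
        below = [None] * n
        up = [None] * n
        log_scale = 0.0
        for i in range(n):
            if idx.is_leaf[i]:
                vec = self.tip_vecs[i].copy()
            else:
                l, r = idx.children[i]
                contrib = self.prob * up[l][self.left] * up[r][self.right]
                vec = np.bincount(self.anc, weights=contrib, minlength=self.n_states)
            s = vec.max()
            if s <= 0:
                return None, None, -np.inf, prop
            vec /= s
            log_scale += np.log(s)
            below[i] = vec
            out = vec
            for ei, dt in idx.segments[i]:
                out = prop.apply(ei, dt, out)
            up[i] = out
        return below, up, log_scale, prop

    def log_likelihood(self, params: DecParams, root: str = "sum") -> float:
        below, _up, log_scale, _ = self.downpass(params)
        if below is None:
            return -np.inf
        root_vec = below[self.index.root]
        mass = root_vec[self.nonnull]
        if root == "sum":
            total = mass.sum()
        elif root == "uniform":
            total = mass.mean()
        else:
            raise ValueError(f"unknown root treatment {root!r}")
        if total <= 0:
            return -np.inf
        return float(np.log(total) + log_scale)


def compute_log_likelihood(
    tree,
    tips: Mapping[str, RangeState],
    model: DecModel,
    params: DecParams,
    root: str = "sum",
) -> float:
    """DEC log-likelihood of the observed tip ranges.

    Parameters
    ----------
    tree:
        Rooted binary time-calibrated ``dendropy.Tree`` (branch lengths in
        My).
    tips:
        Mapping from tip label to observed :class:`RangeState`.
    model:
        The hypothesis (range space, multipliers, stratification).
    params:
        Dispersal and extinction rates.
    root:
        ``"sum"`` (default): unweighted sum of the root vector over
        non-null ranges; ``"uniform"``: average (uniform root prior).
    """
    return _PruningEngine(tree, tips, model).log_likelihood(params, root=root)


def fit_dec(
    tree,
    tips: Mapping[str, RangeState],
    model: DecModel,
    starts: Sequence[tuple[float, float]] = DEFAULT_STARTS,
    bounds: tuple[float, float] = RATE_BOUNDS,
    root: str = "sum",
    tree_id: str = "",
) -> FitResult:
    """Maximise the DEC log-likelihood over ``(d, e)``.

    Box-constrained quasi-Newton search on log-rates from a fixed grid of
    starting points; deterministic given the inputs.
    """
    engine = _PruningEngine(tree, tips, model)
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    n_eval = 0

    def objective(x):
        nonlocal n_eval
        n_eval += 1
        d, e = np.exp(x)
        ll = engine.log_likelihood(DecParams(d, e), root=root)
        return -ll if np.isfinite(ll) else 1e12

    best = None
    any_converged = False
    for d0, e0 in starts:
        res = minimize(
            objective,
            np.log([d0, e0]),
            method="L-BFGS-B",
            bounds=[(lo, hi), (lo, hi)],
            options={"ftol": 1e-10, "gtol": 1e-7},
        )
        any_converged = any_converged or res.success
        if best is None or res.fun < best.fun:
            best = res
    d_hat, e_hat = np.exp(best.x)
    return FitResult(
        d=float(d_hat),
        e=float(e_hat),
        log_likelihood=float(-best.fun),
        model_name=model.name,
        tree_id=tree_id,
        converged=bool(any_converged),
        n_evaluations=n_eval,
        message="" if any_converged else "no start converged; best point returned",
    )


def compare_models(fits: Sequence[FitResult]):
    """AIC ranking table (best first) for fits on the same tree and data.

    Columns: model, -2logL, AIC, dAIC, d, e.  AIC ties are broken by
    model name for determinism.
    """
    import pandas as pd

    if not fits:
        raise ValueError("no fits to compare")
    tree_ids = {f.tree_id for f in fits}
    if len(tree_ids) > 1:
        raise ValueError(f"fits come from different trees: {sorted(tree_ids)}")
    rows = sorted(fits, key=lambda f: (f.aic, f.model_name))
    best = rows[0].aic
    return pd.DataFrame(
        {
            "model": [f.model_name for f in rows],
            "neg2logL": [-2.0 * f.log_likelihood for f in rows],
            "AIC": [f.aic for f in rows],
            "dAIC": [f.aic - best for f in rows],
            "d": [f.d for f in rows],
            "e": [f.e for f in rows],
        }
    )


def selection_frequency(
    trees: Sequence,
    tips: Mapping[str, RangeState],
    models: Sequence[DecModel],
    tie_tol: float = 1e-6,
    **fit_kwargs,
) -> dict[str, float]:
    """Fraction of trees on which each model is AIC-best (ties split equally)."""
    if not trees:
        raise ValueError("need at least one tree")
    freq = {m.name: 0.0 for m in models}
    for k, tree in enumerate(trees):
        fits = [fit_dec(tree, tips, m, tree_id=str(k), **fit_kwargs) for m in models]
        best = min(f.aic for f in fits)
        winners = [f.model_name for f in fits if f.aic - best <= tie_tol]
        for name in winners:
            freq[name] += 1.0 / len(winners)
    total = len(trees)
    return {name: v / total for name, v in freq.items()}
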