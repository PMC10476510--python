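"""Readers and writers for trees, geography files, multipliers and epochs.

Trees are Newick/Nexus via dendropy.  Tip ranges use the LAGRANGE-style
geography format: a header ``<n_taxa> <n_areas> (CODE1 CODE2 ...)``
followed by one ``taxon 0/1-string`` row per taxon (a plain
``<n_taxa> <n_areas>`` header is also accepted).  Dispersal-multiplier
files are whitespace-delimited square matrices with a header row and a
leading label column; epoch files carry one
``start_age end_age code1,code2,...`` line per stratum, oldest first.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .range_space import Area, RangeState
from .rate_model import DispersalMultipliers, Epoch, EpochStratification

__all__ = [
    "read_tree",
    "write_tree",
    "read_geography",
    "write_geography",
    "read_multipliers",
    "write_multipliers",
    "read_epochs",
    "write_epochs",
    "annotate_node_ids",
]


def _as_text(source: str | Path) -> str:
    p = Path(source)
    if p.exists():
        return p.read_text()
    text = str(source)
    if "(" in text or ";" in text:  # a bare newick string
        return text
    raise FileNotFoundError(f"no such file: {source}")


def read_tree(source: str | Path, schema: str = "newick") -> dendropy.Tree:
    """Read a rooted, strictly binary, time-calibrated tree.

    Polytomies and unifurcations are rejected with the offending node
    named.  The tree is treated as rooted regardless of annotation.
    """
    text = _as_text(source)
    try:
        tree = dendropy.Tree.get(
            data=text, schema=schema, rooting="force-rooted", preserve_underscores=True
        )
    except Exception as err:
        raise ValueError(f"could not parse {schema} tree: {err}") from err
    for nd in tree.preorder_node_iter():
        n_children = len(nd.child_nodes())
        if n_children not in (0, 2):
            where = nd.taxon.label if nd.taxon else (nd.label or "unnamed internal node")
            raise ValueError(
                f"tree must be strictly binary: node {where!r} has "
                f"{n_children} children"
            )
        if nd.edge.length is None:
            nd.edge.length = 0.0
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"
    if path is not None:
        Path(path).write_text(s)
    return s


def annotate_node_ids(tree: dendropy.Tree, prefix: str = "nd") -> dendropy.Tree:
    """Label internal nodes with stable postorder ids (``nd0``, ``nd1``...)."""
    for i, nd in enumerate(tree.postorder_node_iter()):
        if not nd.is_leaf():
            nd.label = f"{prefix}{i}"
    return tree


# ---------------------------------------------------------------------------
# geography matrices


def read_geography(source: str | Path) -> tuple[dict[str, RangeState], list[str]]:
    """Parse a geography file into tip ranges and the area-code order.

    Returns ``(tips, codes)`` where ``tips`` maps taxon label to
    :class:`RangeState` over area indices in ``codes`` order.
    """
    text = _as_text(source) if not str(source).count("\n") else str(source)
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty geography file")
    header = lines[0]
    if "(" in header:
        head, _, paren = header.partition("(")
        codes = paren.rstrip(")").split()
    else:
        head, codes = header, []
    parts = head.split()
    if len(parts) < 2:
        raise ValueError(f"malformed geography header: {header!r}")
    n_taxa, n_areas = int(parts[0]), int(parts[1])
    if codes and len(codes) != n_areas:
        raise ValueError(
            f"header declares {n_areas} areas but lists {len(codes)} codes"
        )
    if not codes:
        codes = [str(i + 1) for i in range(n_areas)]
    body = lines[1:]
    if len(body) != n_taxa:
        raise ValueError(f"header declares {n_taxa} taxa but found {len(body)} rows")
    tips: dict[str, RangeState] = {}
    for ln in body:
        try:
            name, bits = ln.rsplit(None, 1)
        except ValueError:
            raise ValueError(f"malformed geography row: {ln!r}") from None
        if name in tips:
            raise ValueError(f"duplicate taxon {name!r} in geography file")
        if len(bits) != n_areas or set(bits) - {"0", "1"}:
            raise ValueError(
                f"row for {name!r} must be a {n_areas}-digit 0/1 string, got {bits!r}"
            )
        areas = tuple(i for i, b in enumerate(bits) if b == "1")
        if not areas:
            raise ValueError(f"taxon {name!r} occupies no area (tips cannot be null)")
        tips[name] = RangeState(areas)
    return tips, codes


def write_geography(
    tips: Mapping[str, RangeState],
    areas: Sequence[Area] | Sequence[str],
    path: str | Path | None = None,
) -> str:
    """Serialise tip ranges in the parenthesized-header geography dialect."""
    codes = [a.code if isinstance(a, Area) else str(a) for a in areas]
    out = _io.StringIO()
    out.write(f"{len(tips)} {len(codes)} ({' '.join(codes)})\n")
    for name, state in tips.items():
        bits = "".join("1" if i in state else "0" for i in range(len(codes)))
        out.write(f"{name}\t{bits}\n")
    s = out.getvalue()
    if path is not None:
        Path(path).write_text(s)
    return s


# ---------------------------------------------------------------------------
# multipliers and epochs


def read_multipliers(source: str | Path) -> DispersalMultipliers:
    text = _as_text(source) if not str(source).count("\n") else str(source)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    codes = lines[0].split()
    n = len(codes)
    rows = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != n + 1:
            raise ValueError(f"multiplier row has {len(parts) - 1} entries, expected {n}")
        rows.append([float(x) for x in parts[1:]])
    if len(rows) != n:
        raise ValueError(f"multiplier matrix has {len(rows)} rows, expected {n}")
    row_codes = [ln.split()[0] for ln in lines[1:]]
    if row_codes != codes:
        raise ValueError("row labels do not match column header")
    return DispersalMultipliers(np.array(rows), codes=codes)


def write_multipliers(mult: DispersalMultipliers, path: str | Path | None = None) -> str:
    s = mult.to_text()
    if path is not None:
        Path(path).write_text(s)
    return s


def read_epochs(source: str | Path, codes: Sequence[str]) -> EpochStratification:
    """Parse an epoch file against a known area-code order."""
    text = _as_text(source) if not str(source).count("\n") else str(source)
    pos = {c: i for i, c in enumerate(codes)}
    epochs = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        start_s, end_s, avail_s = ln.split(None, 2)
        try:
            avail = frozenset(pos[c.strip()] for c in avail_s.split(","))
        except KeyError as err:
            raise ValueError(f"epoch file references unknown area code {err.args[0]!r}")
        epochs.append(Epoch(float(start_s), float(end_s), avail))
    return EpochStratification(epochs)


def write_epochs(
    strat: EpochStratification, codes: Sequence[str], path: str | Path | None = None
) -> str:
    lines = []
    for ep in strat:
        avail = ",".join(codes[i] for i in sorted(ep.available))
        lines.append(f"{ep.start_age:g}\t{ep.end_age:g}\t{avail}")
    s = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(s)
    return s
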