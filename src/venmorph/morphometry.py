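"""L-measure-style morphometry of SWC reconstructions.

A reconstruction is decomposed into *branches*: maximal node paths between
topological points (soma attachment, bifurcation, tip).  Stems — branches
arising directly from the soma — have order 1; the order increments after
each bifurcation.  A *compartment* is the frustum between a node and its
parent; its diameter is taken from the child node, matching the SWC
convention that a section "extends until it reaches the next set of
coordinates".

From the branch decomposition the module computes the study's feature
vector: 19 named whole-cell metrics (extents, counts, lengths, diameters,
fragmentation, contraction, partition asymmetry, Rall's ratio, soma
surface, total volume, branch orders) plus the soma height-to-width ratio.
All features are registered in ``FEATURE_COLUMNS`` in a stable order so
tables serialize reproducibly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .swc_io import NeuronTree, SwcNode

__all__ = [
    "Branch",
    "decompose_branches",
    "compute_features",
    "feature_table",
    "standardize",
    "FEATURE_COLUMNS",
    "LABEL_COLUMN",
]

#: metric columns in canonical order (label column appended last in tables)
FEATURE_COLUMNS = [
    "average_length",
    "overall_width",
    "number_of_stems",
    "total_number_of_trees",
    "average_diameter",
    "overall_depth",
    "average_fragmentation",
    "max_path_distance",
    "max_fragmentation",
    "overall_height",
    "average_ralls_ratio",
    "average_contraction",
    "soma_surface",
    "number_of_branches",
    "partition_asymmetry",
    "total_volume",
    "max_branch_order",
    "average_branch_order",
    "height_to_width_ratio",
]

LABEL_COLUMN = "label"


@dataclass(frozen=True)
class Branch:
    """A maximal unbranched path between topological points.

    ``path`` runs from the branch's start node (a soma attachment point or a
    bifurcation) to its end node (a bifurcation or a tip); the start node
    itself belongs to the upstream structure, so ``n_compartments`` equals
    ``len(path) - 1``.
    """

    path: tuple[int, ...]  # node ids, start → end
    path_length: float  # µm, summed compartment lengths
    euclidean_length: float  # µm, straight-line start → end
    n_compartments: int
    order: int  # stems = 1
    mean_diameter: float  # µm, mean of 2·child radius over compartments

    @property
    def contraction(self) -> float:
        return self.euclidean_length / self.path_length if self.path_length else 1.0


def _seg_len(a: SwcNode, b: SwcNode) -> float:
    return math.dist(a.position(), b.position())


def _neurite_children(tree: NeuronTree, node_id: int) -> list[SwcNode]:
    return [c for c in tree.children(node_id) if not c.is_soma]


def decompose_branches(tree: NeuronTree) -> list[Branch]:
    """Split all non-soma structure into branches.

    Every non-soma compartment belongs to exactly one branch.  Branch order
    starts at 1 for stems and increments after each branch point (nodes with
    ≥ 2 neurite children; multifurcations increment once per level, like
    bifurcations).
    """
    if not tree.soma_nodes:
        raise ValueError("soma required for branch decomposition")

    branches: list[Branch] = []
    # start points: (start node, first neurite node, order)
    stack: list[tuple[SwcNode, SwcNode, int]] = []
    for s in tree.soma_nodes:
        for child in _neurite_children(tree, s.id):
            stack.append((s, child, 1))
    # non-soma roots are their own trees; their first branch is order 1
    for r in tree.roots:
        if not r.is_soma:
            for child in _neurite_children(tree, r.id):
                stack.append((r, child, 1))

    while stack:
        start, first, order = stack.pop()
        path = [start.id]
        plen = 0.0
        diams: list[float] = []
        prev, cur = start, first
        while True:
            path.append(cur.id)
            plen += _seg_len(prev, cur)
            diams.append(2.0 * cur.radius)
            nxt = _neurite_children(tree, cur.id)
            if len(nxt) == 1:
                prev, cur = cur, nxt[0]
            else:
                break
        end = tree.node(path[-1])
        branches.append(
            Branch(
                path=tuple(path),
                path_length=plen,
                euclidean_length=_seg_len(start, end),
                n_compartments=len(path) - 1,
                order=order,
                mean_diameter=float(np.mean(diams)),
            )
        )
        for child in _neurite_children(tree, end.id):
            stack.append((end, child, order + 1))

    return branches


def _bifurcations(tree: NeuronTree, branches: list[Branch]):
    """Branch end nodes with exactly two daughter branches."""
    by_start: dict[int, list[Branch]] = {}
    for b in branches:
        by_start.setdefault(b.path[0], []).append(b)
    for b in branches:
        daughters = by_start.get(b.path[-1], [])
        if len(daughters) == 2:
            yield tree.node(b.path[-1]), daughters


def _subtree_tip_count(tree: NeuronTree, first: SwcNode) -> int:
    count, stack = 0, [first]
    while stack:
        n = stack.pop()
        kids = _neurite_children(tree, n.id)
        if not kids:
            count += 1
        stack.extend(kids)
    return count


def _frustum_volume(r1: float, r2: float, length: float) -> float:
    return math.pi * length / 3.0 * (r1 * r1 + r1 * r2 + r2 * r2)


def _frustum_lateral(r1: float, r2: float, length: float) -> float:
    slant = math.hypot(length, r1 - r2)
    return math.pi * (r1 + r2) * slant


def _soma_geometry(soma: list[SwcNode]) -> tuple[float, float]:
    """(surface, volume) of the soma: sphere for one node, frustum chain else."""
    if len(soma) == 1:
        r = soma[0].radius
        return 4.0 * math.pi * r * r, 4.0 / 3.0 * math.pi * r**3
    surf = vol = 0.0
    for a, b in zip(soma, soma[1:]):
        length = _seg_len(a, b)
        surf += _frustum_lateral(a.radius, b.radius, length)
        vol += _frustum_volume(a.radius, b.radius, length)
    return surf, vol


def compute_features(tree: NeuronTree, label: str = "unknown") -> dict:
    """Compute the full morphometric feature vector of one reconstruction.

    Returns a dict keyed by ``FEATURE_COLUMNS`` plus ``label``.  Trees with
    a soma but no neurite structure get NaN for branch statistics (never a
    silent zero).
    """
    soma = tree.soma_nodes
    if not soma:
        raise ValueError("soma required for morphometry")

    xs = [n.x for n in tree.nodes]
    ys = [n.y for n in tree.nodes]
    zs = [n.z for n in tree.nodes]
    feats: dict = {
        "overall_width": max(xs) - min(xs),
        "overall_height": max(ys) - min(ys),
        "overall_depth": max(zs) - min(zs),
        LABEL_COLUMN: label,
    }

    soma_ids = {n.id for n in soma}
    stems = sum(
        1
        for s in soma
        for c in tree.children(s.id)
        if not c.is_soma
    )
    feats["number_of_stems"] = stems
    feats["total_number_of_trees"] = stems + sum(
        1 for r in tree.roots if not r.is_soma
    )

    if len(soma) >= 2:
        sx = [n.x for n in soma]
        sy = [n.y for n in soma]
        width = max(sx) - min(sx)
        height = max(sy) - min(sy)
        feats["height_to_width_ratio"] = height / width if width > 0 else math.nan
    else:
        feats["height_to_width_ratio"] = 1.0

    soma_surface, soma_volume = _soma_geometry(soma)
    feats["soma_surface"] = soma_surface

    branches = decompose_branches(tree) if stems or any(
        not r.is_soma for r in tree.roots
    ) else []

    if not branches:
        for key in (
            "average_length",
            "average_diameter",
            "average_fragmentation",
            "max_fragmentation",
            "max_path_distance",
            "average_ralls_ratio",
            "average_contraction",
            "number_of_branches",
            "partition_asymmetry",
            "max_branch_order",
            "average_branch_order",
        ):
            feats[key] = math.nan
        feats["total_volume"] = soma_volume
        return feats

    feats["average_length"] = float(np.mean([b.path_length for b in branches]))
    feats["average_fragmentation"] = float(
        np.mean([b.n_compartments for b in branches])
    )
    feats["max_fragmentation"] = max(b.n_compartments for b in branches)
    feats["average_contraction"] = float(np.mean([b.contraction for b in branches]))
    feats["number_of_branches"] = len(branches)
    feats["max_branch_order"] = max(b.order for b in branches)
    feats["average_branch_order"] = float(np.mean([b.order for b in branches]))

    # per-compartment statistics over all non-soma compartments
    diam_sum = n_comp = 0
    volume = soma_volume
    for n in tree.nodes:
        if n.id in soma_ids:
            continue
        p = tree.parent(n.id)
        if p is None:
            continue
        length = _seg_len(p, n)
        diam_sum += 2.0 * n.radius
        n_comp += 1
        volume += _frustum_volume(p.radius, n.radius, length)
    feats["average_diameter"] = diam_sum / n_comp if n_comp else math.nan
    feats["total_volume"] = volume

    # max path distance: summed compartment lengths from the soma to a tip
    dist_to: dict[int, float] = {}

    def dist_from_root(node: SwcNode) -> float:
        if node.id in dist_to:
            return dist_to[node.id]
        p = tree.parent(node.id)
        if p is None or node.id in soma_ids:
            d = 0.0
        else:
            base = 0.0 if p.id in soma_ids else dist_from_root(p)
            d = base + _seg_len(p, node)
        dist_to[node.id] = d
        return d

    tip_dists = [
        dist_from_root(t) for t in tree.tips() if t.id not in soma_ids
    ]
    feats["max_path_distance"] = max(tip_dists) if tip_dists else math.nan

    # bifurcation statistics (binary branch points only)
    asym: list[float] = []
    ralls: list[float] = []
    for parent_node, daughters in _bifurcations(tree, branches):
        n1 = _subtree_tip_count(tree, tree.node(daughters[0].path[1]))
        n2 = _subtree_tip_count(tree, tree.node(daughters[1].path[1]))
        if n1 == n2 == 1:
            asym.append(0.0)
        else:
            asym.append(abs(n1 - n2) / (n1 + n2 - 2))
        dp = 2.0 * parent_node.radius
        d1 = 2.0 * tree.node(daughters[0].path[1]).radius
        d2 = 2.0 * tree.node(daughters[1].path[1]).radius
        if dp > 0:
            ralls.append((d1**1.5 + d2**1.5) / dp**1.5)
    feats["partition_asymmetry"] = float(np.mean(asym)) if asym else math.nan
    feats["average_ralls_ratio"] = float(np.mean(ralls)) if ralls else math.nan

    return feats


def feature_table(
    trees: dict[str, NeuronTree] | list[tuple[str, NeuronTree]],
    labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Compute the cells × features table for a labeled collection.

    ``trees`` maps cell id → NeuronTree (or is a list of pairs); ``labels``
    maps cell id → class label (defaults to "unknown").  Columns follow
    ``FEATURE_COLUMNS`` + label; the index is the cell id.
    """
    items = list(trees.items()) if isinstance(trees, dict) else list(trees)
    if not items:
        raise ValueError("at least one tree required")
    ids = [cid for cid, _ in items]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate cell ids: {dupes}")
    rows = []
    for cid, tree in items:
        label = (labels or {}).get(cid, "unknown")
        rows.append(compute_features(tree, label=label))
    df = pd.DataFrame(rows, index=pd.Index(ids, name="cell_id"))
    return df[FEATURE_COLUMNS + [LABEL_COLUMN]]


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each numeric column (mean 0, sample SD 1).

    Constant columns map to 0 with a warning instead of dividing by zero;
    non-numeric columns (the label) pass through untouched.
    """
    if len(table) < 2:
        raise ValueError("standardize requires at least 2 rows")
    out = table.copy()
    for col in table.columns:
        if not pd.api.types.is_numeric_dtype(table[col]):
            continue
        vals = table[col].astype(float)
        sd = vals.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            warnings.warn(
                f"column {col!r} is constant; standardized to 0", stacklevel=2
            )
            out[col] = 0.0
        else:
            out[col] = (vals - vals.mean()) / sd
    return out
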