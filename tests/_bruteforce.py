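"""Independent brute-force morphometry oracle.

Re-derives every metric from first principles — explicit path enumeration,
recursive tip counting, per-edge summation — without touching the package's
branch-decomposition code, so it can serve as an independent cross-check on
small trees.
"""

from __future__ import annotations

import math

from venmorph.swc_io import NeuronTree, SwcNode


def _children_map(tree: NeuronTree) -> dict[int, list[SwcNode]]:
    cm: dict[int, list[SwcNode]] = {n.id: [] for n in tree.nodes}
    for n in tree.nodes:
        if n.parent_id != -1:
            cm[n.parent_id].append(n)
    return cm


def _dist(a: SwcNode, b: SwcNode) -> float:
    return math.dist(a.position(), b.position())


def _neurite_kids(cm, node_id):
    return [c for c in cm[node_id] if not c.is_soma]


def bf_branches(tree: NeuronTree):
    """All (path, order) pairs by explicit recursive walking."""
    cm = _children_map(tree)
    out = []

    def walk(start: SwcNode, first: SwcNode, order: int):
        path = [start, first]
        cur = first
        while True:
            kids = _neurite_kids(cm, cur.id)
            if len(kids) == 1:
                cur = kids[0]
                path.append(cur)
            else:
                break
        out.append((path, order))
        for k in _neurite_kids(cm, path[-1].id):
            walk(path[-1], k, order + 1)

    for n in tree.nodes:
        if n.is_soma or (n.parent_id == -1 and not n.is_soma):
            for k in _neurite_kids(cm, n.id):
                walk(n, k, 1)
    return out


def bf_tip_count(tree: NeuronTree, node: SwcNode) -> int:
    cm = _children_map(tree)

    def rec(n):
        kids = _neurite_kids(cm, n.id)
        if not kids:
            return 1
        return sum(rec(k) for k in kids)

    return rec(node)


def bf_features(tree: NeuronTree) -> dict:
    cm = _children_map(tree)
    soma = [n for n in tree.nodes if n.is_soma]
    soma_ids = {n.id for n in soma}
    assert soma, "oracle requires a soma"

    xs = [n.x for n in tree.nodes]
    ys = [n.y for n in tree.nodes]
    zs = [n.z for n in tree.nodes]
    out = {
        "overall_width": max(xs) - min(xs),
        "overall_height": max(ys) - min(ys),
        "overall_depth": max(zs) - min(zs),
    }

    stems = sum(
        1 for s in soma for c in cm[s.id] if not c.is_soma
    )
    out["number_of_stems"] = stems
    out["total_number_of_trees"] = stems + sum(
        1 for n in tree.nodes if n.parent_id == -1 and not n.is_soma
    )

    if len(soma) >= 2:
        sx = [n.x for n in soma]
        sy = [n.y for n in soma]
        w = max(sx) - min(sx)
        out["height_to_width_ratio"] = (
            (max(sy) - min(sy)) / w if w > 0 else math.nan
        )
    else:
        out["height_to_width_ratio"] = 1.0

    # soma surface / volume
    if len(soma) == 1:
        r = soma[0].radius
        soma_surf = 4 * math.pi * r * r
        soma_vol = 4 / 3 * math.pi * r**3
    else:
        soma_surf = soma_vol = 0.0
        for a, b in zip(soma, soma[1:]):
            h = _dist(a, b)
            soma_surf += math.pi * (a.radius + b.radius) * math.hypot(
                h, a.radius - b.radius
            )
            soma_vol += (
                math.pi * h / 3
                * (a.radius**2 + a.radius * b.radius + b.radius**2)
            )
    out["soma_surface"] = soma_surf

    branches = bf_branches(tree)
    if not branches:
        out["total_volume"] = soma_vol
        return out

    def plen(path):
        return sum(_dist(a, b) for a, b in zip(path, path[1:]))

    lengths = [plen(p) for p, _ in branches]
    out["average_length"] = sum(lengths) / len(lengths)
    out["average_fragmentation"] = sum(
        len(p) - 1 for p, _ in branches
    ) / len(branches)
    out["max_fragmentation"] = max(len(p) - 1 for p, _ in branches)
    out["average_contraction"] = sum(
        _dist(p[0], p[-1]) / plen(p) for p, _ in branches
    ) / len(branches)
    out["number_of_branches"] = len(branches)
    orders = [o for _, o in branches]
    out["max_branch_order"] = max(orders)
    out["average_branch_order"] = sum(orders) / len(orders)

    # per-compartment sums
    diam, ncomp, vol = 0.0, 0, soma_vol
    for n in tree.nodes:
        if n.id in soma_ids or n.parent_id == -1:
            continue
        p = next(m for m in tree.nodes if m.id == n.parent_id)
        h = _dist(p, n)
        diam += 2 * n.radius
        ncomp += 1
        vol += math.pi * h / 3 * (
            p.radius**2 + p.radius * n.radius + n.radius**2
        )
    out["average_diameter"] = diam / ncomp if ncomp else math.nan
    out["total_volume"] = vol

    # max path distance by full path enumeration from every tip
    def dist_to_soma(n: SwcNode) -> float:
        d = 0.0
        cur = n
        while cur.parent_id != -1 and cur.id not in soma_ids:
            p = next(m for m in tree.nodes if m.id == cur.parent_id)
            d += _dist(p, cur)
            if p.id in soma_ids:
                break
            cur = p
        return d

    tips = [
        n for n in tree.nodes
        if not cm[n.id] and n.id not in soma_ids
    ]
    out["max_path_distance"] = max(dist_to_soma(t) for t in tips)

    # bifurcation statistics (exactly-binary branch points)
    asym, ralls = [], []
    for path, _ in branches:
        end = path[-1]
        kids = _neurite_kids(cm, end.id)
        if len(kids) != 2:
            continue
        n1, n2 = bf_tip_count(tree, kids[0]), bf_tip_count(tree, kids[1])
        asym.append(
            0.0 if n1 == n2 == 1 else abs(n1 - n2) / (n1 + n2 - 2)
        )
        dp = 2 * end.radius
        d1, d2 = 2 * kids[0].radius, 2 * kids[1].radius
        if dp > 0:
            ralls.append((d1**1.5 + d2**1.5) / dp**1.5)
    out["partition_asymmetry"] = (
        sum(asym) / len(asym) if asym else math.nan
    )
    out["average_ralls_ratio"] = (
        sum(ralls) / len(ralls) if ralls else math.nan
    )
    return out
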