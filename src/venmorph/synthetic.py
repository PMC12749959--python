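"""Synthetic SWC morphology generator for the two-class VEN/pyramidal contrast.

The generator emulates the qualitative morphological contrast between von
Economo neurons and pyramidal neurons: VENs have an elongated, stick-shaped
soma with few stems (a single apical and a single basal trunk, terminally
branching), while pyramidal neurons have a roughly isometric soma with many
basal stems and deeper, bushier arbors.  Each class is a parameter bundle
(:class:`ClassParams`) controlling soma elongation, stem count, branch
length, diameter taper, branching depth and probability, and coordinate
jitter.

Generated trees are quality-control clean by construction: the soma is a
closed multi-node contour with a few micrometers of z-depth, every process
attaches to the soma, and z steps stay far below the drift threshold.
:func:`inject_defect` then produces the four defect classes the QC and
morphometry stages are designed to detect.

Reproducibility contract: every neuron draws from its own RNG stream seeded
by ``(cohort seed, index)``, so cohorts are byte-identical across runs and
stable under parallel generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .swc_io import (
    APICAL_DENDRITE,
    BASAL_DENDRITE,
    SOMA,
    NeuronTree,
    SwcNode,
)

__all__ = [
    "ClassParams",
    "GeneratorConfig",
    "VEN_PRESET",
    "PYR_PRESET",
    "generate_neuron",
    "generate_cohort",
    "soma_signal_cohort",
    "branching_signal_cohort",
    "inject_defect",
    "DEFECT_KINDS",
]


@dataclass(frozen=True)
class ClassParams:
    """Generative parameters of one morphological class (units: µm).

    ``soma_elongation`` is the ratio of the soma contour's y-extent to its
    x-extent; ``taper`` the child/parent diameter ratio applied at each
    branch point; ``bifurcation_prob`` the chance a branch splits (until
    ``max_order``); ``jitter_sd`` the coordinate noise per segment.
    """

    soma_elongation: tuple[float, float] = (1.5, 0.2)  # (mean, sd)
    n_stems: tuple[float, float] = (4.0, 1.0)
    branch_length: tuple[float, float] = (100.0, 20.0)
    taper: tuple[float, float] = (0.8, 0.05)
    max_order: int = 4
    bifurcation_prob: float = 0.7
    jitter_sd: float = 2.0
    stem_diameter: tuple[float, float] = (3.0, 0.5)
    soma_radius: float = 8.0  # base x semi-axis of the soma contour
    segments_per_branch: int = 5
    #: the apical stem starts with a long unbranched trunk of this length,
    #: in units of mean branch_length — the apical dendrite is the dominant
    #: path in both classes, as in cortex (trunk then terminal tuft)
    apical_trunk_factor: float = 1.5

    def __post_init__(self) -> None:
        for name in ("soma_elongation", "n_stems", "branch_length", "taper",
                     "stem_diameter"):
            mean, sd = getattr(self, name)
            if mean <= 0:
                raise ValueError(f"{name} mean must be > 0")
            if sd < 0:
                raise ValueError(f"{name} sd must be ≥ 0")
        if not (0.0 <= self.bifurcation_prob <= 1.0):
            raise ValueError("bifurcation_prob must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be ≥ 0")
        if self.max_order < 1:
            raise ValueError("max_order must be ≥ 1")


#: Elongated stick soma, two sparse long stems — the VEN archetype.
VEN_PRESET = ClassParams(
    soma_elongation=(3.0, 0.4),
    n_stems=(2.0, 0.5),
    branch_length=(180.0, 30.0),
    taper=(0.65, 0.05),
    max_order=3,
    bifurcation_prob=0.6,
    jitter_sd=2.0,
    stem_diameter=(4.0, 0.5),
    soma_radius=7.0,
)

#: Isometric soma, many stems, deeper bushier arbor — the pyramidal archetype.
PYR_PRESET = ClassParams(
    soma_elongation=(1.1, 0.15),
    n_stems=(6.0, 1.0),
    branch_length=(90.0, 20.0),
    taper=(0.8, 0.05),
    max_order=5,
    bifurcation_prob=0.7,
    jitter_sd=2.0,
    stem_diameter=(3.0, 0.5),
    soma_radius=9.0,
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort recipe: per-class parameters, sizes and the master seed."""

    ven_params: ClassParams = VEN_PRESET
    pyr_params: ClassParams = PYR_PRESET
    n_ven: int = 55
    n_pyr: int = 706
    seed: int = 0


DEFECT_KINDS = ("z_drift", "detached_process", "soma_distortion", "truncated_apical")

_N_SOMA_CONTOUR = 13  # 12 contour points + a closing point near the first


def _soma_contour(rng: np.random.Generator, params: ClassParams) -> list[SwcNode]:
    """Closed elliptical soma contour, elongated along y, with z depth.

    The z coordinate zig-zags ±1.6 µm so the contour spans > 2 µm in depth
    (the "reconstructed in 3D" QC criterion); the final point sits 0.5 µm
    from the first so the closure check passes.
    """
    elong = max(1.0, rng.normal(*params.soma_elongation))
    a = params.soma_radius  # x semi-axis
    b = a * elong  # y semi-axis
    nodes = []
    n_pts = _N_SOMA_CONTOUR - 1
    for i in range(n_pts):
        t = 2.0 * math.pi * i / n_pts
        z = 1.6 if i % 2 else -1.6
        nodes.append(
            SwcNode(
                id=i + 1,
                type_code=SOMA,
                x=a * math.cos(t),
                y=b * math.sin(t),
                z=z,
                radius=2.0,
                parent_id=-1 if i == 0 else i,
            )
        )
    first = nodes[0]
    nodes.append(
        SwcNode(
            id=n_pts + 1,
            type_code=SOMA,
            x=first.x - 0.5,
            y=first.y,
            z=first.z,
            radius=2.0,
            parent_id=n_pts,
        )
    )
    return nodes


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rotate_xy(v: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], v[2]])


class _TreeBuilder:
    def __init__(self, nodes: list[SwcNode]):
        self.nodes = nodes
        self.next_id = max(n.id for n in nodes) + 1

    def add(self, type_code, pos, radius, parent_id) -> int:
        nid = self.next_id
        self.next_id += 1
        self.nodes.append(
            SwcNode(nid, type_code, float(pos[0]), float(pos[1]), float(pos[2]),
                    float(radius), parent_id)
        )
        return nid


def _grow_branch(
    builder: _TreeBuilder,
    rng: np.random.Generator,
    params: ClassParams,
    start_pos: np.ndarray,
    direction: np.ndarray,
    diameter: float,
    parent_id: int,
    order: int,
    type_code: int,
    length_override: float | None = None,
    force_bifurcate: bool = False,
) -> None:
    length = max(10.0, rng.normal(*params.branch_length))
    if length_override is not None:
        length = length_override + rng.normal(0, params.branch_length[1])
    n_seg = params.segments_per_branch
    seg = length / n_seg
    pos = start_pos.copy()
    pid = parent_id
    radius = max(0.1, diameter / 2.0)
    for _ in range(n_seg):
        step = direction * seg
        step[0] += rng.normal(0, params.jitter_sd)
        step[1] += rng.normal(0, params.jitter_sd)
        step[2] += rng.normal(0, min(params.jitter_sd, 1.0))  # stay below drift
        pos = pos + step
        pid = builder.add(type_code, pos, radius, pid)
    if order < params.max_order and (
        rng.random() < params.bifurcation_prob or force_bifurcate
    ):
        child_d = diameter * max(0.3, rng.normal(*params.taper))
        spread = math.radians(30.0 + rng.uniform(-10, 10))
        for sign in (-1.0, 1.0):
            new_dir = _unit(_rotate_xy(direction, sign * spread))
            _grow_branch(
                builder, rng, params, pos, new_dir, child_d, pid, order + 1,
                type_code,
            )


def generate_neuron(
    params: ClassParams, seed: int, cell_id: str = "synthetic"
) -> NeuronTree:
    """Generate one QC-clean synthetic neuron.

    One apical stem grows along +y; the remaining stems fan out on the basal
    (−y) side.  The same ``(params, seed)`` pair always yields byte-identical
    SWC output.
    """
    rng = np.random.default_rng(seed)
    nodes = _soma_contour(rng, params)
    builder = _TreeBuilder(nodes)

    n_stems = max(1, int(round(rng.normal(*params.n_stems))))
    soma_top = max(nodes[: _N_SOMA_CONTOUR], key=lambda n: n.y)
    soma_bot = min(nodes[: _N_SOMA_CONTOUR], key=lambda n: n.y)

    # apical stem straight up: long trunk, then a terminal tuft
    stem_d = max(0.5, rng.normal(*params.stem_diameter))
    trunk = params.apical_trunk_factor * params.max_order * params.branch_length[0]
    _grow_branch(
        builder, rng, params,
        np.array(soma_top.position()), np.array([0.0, 1.0, 0.0]),
        stem_d, soma_top.id, 1, APICAL_DENDRITE,
        length_override=trunk,
        force_bifurcate=True,  # the trunk always ends in a terminal tuft
    )
    # basal stems fan out downward
    for k in range(n_stems - 1):
        angle = math.pi + (k - (n_stems - 2) / 2.0) * math.radians(35.0)
        direction = _unit(np.array([math.sin(angle), -abs(math.cos(angle)), 0.0]))
        stem_d = max(0.5, rng.normal(*params.stem_diameter))
        _grow_branch(
            builder, rng, params,
            np.array(soma_bot.position()), direction,
            stem_d, soma_bot.id, 1, BASAL_DENDRITE,
        )
    return NeuronTree(nodes=builder.nodes, provenance=f"{cell_id}:seed={seed}")


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[dict[str, NeuronTree], dict[str, str]]:
    """Generate a labeled two-class cohort.

    Returns ``(trees, labels)`` keyed by cell id (``VEN_000`` …,
    ``PYR_000`` …).  Each neuron's RNG stream is seeded from
    ``(config.seed, index)`` so any subset regenerates identically.
    """
    if config.n_ven < 1 or config.n_pyr < 1:
        raise ValueError("n per class must be ≥ 1")
    trees: dict[str, NeuronTree] = {}
    labels: dict[str, str] = {}
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.n_ven + config.n_pyr)
    idx = 0
    for i in range(config.n_ven):
        cid = f"VEN_{i:03d}"
        seed = int(child_seeds[idx].generate_state(1)[0] % (2**31))
        trees[cid] = generate_neuron(config.ven_params, seed, cell_id=cid)
        labels[cid] = "VEN"
        idx += 1
    for i in range(config.n_pyr):
        cid = f"PYR_{i:03d}"
        seed = int(child_seeds[idx].generate_state(1)[0] % (2**31))
        trees[cid] = generate_neuron(config.pyr_params, seed, cell_id=cid)
        labels[cid] = "pyramidal"
        idx += 1
    return trees, labels


# ---------------------------------------------------------------------------
# signal-isolated cohorts for the masking experiments


def _reshape_soma(tree: NeuronTree, elongation: float) -> NeuronTree:
    """Stretch the soma contour to a y/x extent ratio of ``elongation``
    while roughly preserving its area (y × √f, x ÷ √f about the centroid).

    Dendrite nodes are untouched, so the class signal stays strictly
    somatic — and because the stretch is area-preserving, soma surface and
    volume shift far less than the height-to-width ratio does.
    """
    soma = tree.soma_nodes
    cx = float(np.mean([n.x for n in soma]))
    cy = float(np.mean([n.y for n in soma]))
    f = math.sqrt(elongation)
    soma_ids = {n.id for n in soma}
    return tree.with_nodes([
        replace(n, x=cx + (n.x - cx) / f, y=cy + f * (n.y - cy))
        if n.id in soma_ids
        else n
        for n in tree.nodes
    ])


_SIGNAL_BASE = ClassParams(
    soma_elongation=(1.0, 0.0),
    n_stems=(3.0, 0.5),
    branch_length=(60.0, 10.0),
    taper=(0.75, 0.05),
    max_order=2,
    bifurcation_prob=0.5,
    jitter_sd=2.0,
    stem_diameter=(3.0, 0.4),
    soma_radius=10.0,
    apical_trunk_factor=1.0,
)


def soma_signal_cohort(
    n_per_class: int, seed: int, elongation: float = 3.0
) -> tuple[dict[str, NeuronTree], dict[str, str]]:
    """Paired cohort whose classes differ *only* in soma shape.

    Each VEN/pyramidal pair shares one dendritic tree (same seed, same
    parameters); the VEN member's soma contour is stretched ``elongation``-
    fold in y.  Because the dendrites are pixel-identical and dominate the
    bounding box, any classifier signal must come from the soma region.
    """
    trees: dict[str, NeuronTree] = {}
    labels: dict[str, str] = {}
    ss = np.random.SeedSequence(seed)
    for i, child in enumerate(ss.spawn(n_per_class)):
        rng = np.random.default_rng(child)
        s = int(rng.integers(2**31))
        # per-pair soma size jitter: soma surface and volume vary widely
        # within each class, so only the shape ratio separates the classes
        params = replace(_SIGNAL_BASE, soma_radius=float(rng.uniform(6.0, 14.0)))
        base = generate_neuron(params, s, cell_id=f"pair_{i:03d}")
        trees[f"PYR_{i:03d}"] = base
        labels[f"PYR_{i:03d}"] = "pyramidal"
        trees[f"VEN_{i:03d}"] = _reshape_soma(base, elongation)
        labels[f"VEN_{i:03d}"] = "VEN"
    return trees, labels


def branching_signal_cohort(
    n_per_class: int, seed: int
) -> tuple[dict[str, NeuronTree], dict[str, str]]:
    """Cohort whose classes differ only in dendritic branching, not soma.

    Both classes draw the identical isometric soma and the same four stems;
    the "VEN" class's stems never bifurcate while the "pyramidal" class's
    branch recursively — the class signal is strictly distal, outside the
    soma disc (render with ``common_scale`` and ``center_on_soma`` so the
    projection itself carries no soma-position or cell-size cue).
    """
    sparse = replace(
        _SIGNAL_BASE, n_stems=(4.0, 0.0), max_order=1, bifurcation_prob=0.0,
        branch_length=(80.0, 10.0),
    )
    bushy = replace(
        _SIGNAL_BASE, n_stems=(4.0, 0.0), max_order=4, bifurcation_prob=0.8,
        branch_length=(80.0, 10.0),
    )
    cfg = GeneratorConfig(
        ven_params=sparse, pyr_params=bushy,
        n_ven=n_per_class, n_pyr=n_per_class, seed=seed,
    )
    return generate_cohort(cfg)


# ---------------------------------------------------------------------------
# defect injection


def _apical_tip_path(tree: NeuronTree) -> list[SwcNode]:
    """Node path of the longest apical route (soma → tip)."""
    apical = [n for n in tree.nodes if n.type_code == APICAL_DENDRITE]
    if not apical:
        raise ValueError("tree has no apical dendrite to target")
    tips = [n for n in apical if not tree.children(n.id)]
    best, best_len = None, -1.0
    for tip in tips:
        path, cur = [], tip
        length = 0.0
        while cur is not None and cur.type_code == APICAL_DENDRITE:
            path.append(cur)
            parent = tree.parent(cur.id)
            if parent is not None:
                length += math.dist(cur.position(), parent.position())
            cur = parent
        if length > best_len:
            best, best_len = list(reversed(path)), length
    return best


def inject_defect(tree: NeuronTree, kind: str, shift: float = 50.0) -> NeuronTree:
    """Return a modified copy of ``tree`` carrying one reconstruction defect.

    - ``z_drift``: one dendritic subtree jumps ``shift`` µm in z at a single
      compartment — the Z-drift signature run_qc flags.
    - ``detached_process``: one stem's root is detached from the soma.
    - ``soma_distortion``: the soma contour collapses to a single spherical
      node (height-to-width ratio becomes 1.0 by convention).
    - ``truncated_apical``: the distal half of the longest apical path is
      removed, shrinking max_path_distance.
    """
    if kind not in DEFECT_KINDS:
        raise ValueError(f"unknown defect kind {kind!r}; choose from {DEFECT_KINDS}")

    if kind == "z_drift":
        dendrites = [
            n for n in tree.nodes
            if n.type_code in (BASAL_DENDRITE, APICAL_DENDRITE)
        ]
        if not dendrites:
            raise ValueError("tree has no dendrite to drift")
        # Shift one subtree so exactly one edge carries the drift signature:
        # the subtree jumps `shift` µm in z while resuming at (almost) the
        # same xy position as its parent — a large dz over a tiny dxy step.
        target = dendrites[len(dendrites) // 2]
        parent = tree.parent(target.id)
        dx = parent.x + 1.0 - target.x
        dy = parent.y - target.y
        affected = {target.id}
        stack = [target.id]
        while stack:
            for c in tree.children(stack.pop()):
                affected.add(c.id)
                stack.append(c.id)
        new_nodes = [
            replace(n, x=n.x + dx, y=n.y + dy, z=n.z + shift)
            if n.id in affected
            else n
            for n in tree.nodes
        ]
        return tree.with_nodes(new_nodes)

    if kind == "detached_process":
        stem_roots = [
            n for n in tree.nodes
            if not n.is_soma
            and n.parent_id != -1
            and tree.node(n.parent_id).is_soma
        ]
        if not stem_roots:
            raise ValueError("tree has no soma-attached stem to detach")
        target = stem_roots[-1]
        new_nodes = [
            replace(n, parent_id=-1) if n.id == target.id else n
            for n in tree.nodes
        ]
        return tree.with_nodes(new_nodes)

    if kind == "soma_distortion":
        soma = tree.soma_nodes
        if len(soma) < 2:
            raise ValueError("soma is already a single node")
        cx = float(np.mean([n.x for n in soma]))
        cy = float(np.mean([n.y for n in soma]))
        cz = float(np.mean([n.z for n in soma]))
        r = max(
            math.dist((n.x, n.y, n.z), (cx, cy, cz)) for n in soma
        )
        soma_ids = {n.id for n in soma}
        new_id = soma[0].id
        new_nodes = [SwcNode(new_id, SOMA, cx, cy, cz, max(r, 1.0), -1)]
        for n in tree.nodes:
            if n.id in soma_ids:
                continue
            pid = new_id if n.parent_id in soma_ids else n.parent_id
            new_nodes.append(replace(n, parent_id=pid))
        return tree.with_nodes(new_nodes)

    # truncated_apical
    path = _apical_tip_path(tree)
    if len(path) < 2:
        raise ValueError("apical path too short to truncate")
    cut = path[len(path) // 2]
    removed = {cut.id}
    stack = [cut.id]
    while stack:
        for c in tree.children(stack.pop()):
            removed.add(c.id)
            stack.append(c.id)
    new_nodes = [n for n in tree.nodes if n.id not in removed]
    return tree.with_nodes(new_nodes)
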