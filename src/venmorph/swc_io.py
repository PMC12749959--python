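"""Reading, writing and quality control of SWC neuron reconstructions.

SWC is the plain-text interchange format used by NeuroMorpho.Org: one node
per line, seven whitespace-separated values — id, structure type code,
x, y, z (micrometers), radius (micrometers) and the id of the parent node
(-1 for a root).  Type code 1 marks the soma, 2 the axon, 3 basal and 4
apical dendrites; codes 0 and 5-10 occur in the wild and are treated as
generic neurite here (they participate in geometry but never in soma
logic).

Beyond parsing, this module implements the reconstruction-quality checks
recommended for repository submissions — soma reconstructed in 3D, soma
contour closed, all processes attached to the soma, no Z-drift between
parent and child nodes, endings properly terminated — and a geometric
comparison of two reconstructions of the same cell, used to verify that a
format conversion did not distort the morphology.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "SwcNode",
    "NeuronTree",
    "SwcParseError",
    "QcThresholds",
    "QcCheck",
    "QcReport",
    "GeometryReport",
    "parse_swc",
    "read_swc",
    "write_swc",
    "run_qc",
    "compare_geometry",
]

SOMA = 1
AXON = 2
BASAL_DENDRITE = 3
APICAL_DENDRITE = 4


class SwcParseError(ValueError):
    """Raised for malformed SWC content; the message names the line."""


@dataclass(frozen=True)
class SwcNode:
    """A single SWC record: one point of the reconstruction."""

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise ValueError(f"node id must be positive, got {self.id}")
        if not (0 <= self.type_code <= 10):
            raise ValueError(f"type code must be in 0..10, got {self.type_code}")
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")

    @property
    def is_soma(self) -> bool:
        return self.type_code == SOMA

    def position(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class NeuronTree:
    """An ordered collection of SWC nodes forming one or more rooted trees.

    ``provenance`` records where the morphology came from (a file path or a
    generator seed); it is written back into the SWC header on export.
    """

    nodes: list[SwcNode]
    provenance: str = ""
    _by_id: dict[int, SwcNode] = field(init=False, repr=False)
    _children: dict[int, list[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        by_id: dict[int, SwcNode] = {}
        for n in self.nodes:
            if n.id in by_id:
                raise SwcParseError(f"duplicate node id {n.id}")
            by_id[n.id] = n
        children: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id != -1:
                if n.parent_id not in by_id:
                    raise SwcParseError(
                        f"node {n.id} references missing parent {n.parent_id}"
                    )
                children[n.parent_id].append(n.id)
        self._by_id = by_id
        self._children = children

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, node_id: int) -> SwcNode:
        return self._by_id[node_id]

    def children(self, node_id: int) -> list[SwcNode]:
        return [self._by_id[c] for c in self._children[node_id]]

    def parent(self, node_id: int) -> SwcNode | None:
        pid = self._by_id[node_id].parent_id
        return None if pid == -1 else self._by_id[pid]

    @property
    def roots(self) -> list[SwcNode]:
        return [n for n in self.nodes if n.parent_id == -1]

    @property
    def soma_nodes(self) -> list[SwcNode]:
        return [n for n in self.nodes if n.is_soma]

    def tips(self) -> list[SwcNode]:
        return [n for n in self.nodes if not self._children[n.id]]

    def has_cycles(self) -> bool:
        # parent pointers can only cycle if an id chain revisits itself
        for n in self.nodes:
            seen = set()
            cur: SwcNode | None = n
            while cur is not None:
                if cur.id in seen:
                    return True
                seen.add(cur.id)
                cur = self.parent(cur.id)
        return False

    def with_nodes(self, nodes: list[SwcNode]) -> "NeuronTree":
        return NeuronTree(nodes=list(nodes), provenance=self.provenance)

    def copy(self) -> "NeuronTree":
        return self.with_nodes(list(self.nodes))


# ---------------------------------------------------------------------------
# parse / write


def parse_swc(text: str, provenance: str = "") -> NeuronTree:
    """Parse SWC-format text into a :class:`NeuronTree`.

    Lines starting with ``#`` are comments; each data line must hold exactly
    seven whitespace-separated numeric values.  Node order is preserved.
    """
    nodes: list[SwcNode] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SwcParseError(
                f"line {lineno}: expected 7 columns, got {len(parts)}"
            )
        try:
            nid = int(parts[0])
            tc = int(parts[1])
            x, y, z, r = (float(v) for v in parts[2:6])
            pid = int(parts[6])
        except ValueError as exc:
            raise SwcParseError(f"line {lineno}: non-numeric field ({exc})") from exc
        try:
            nodes.append(SwcNode(nid, tc, x, y, z, r, pid))
        except ValueError as exc:
            raise SwcParseError(f"line {lineno}: {exc}") from exc
    if not nodes:
        raise SwcParseError("no data lines found")
    return NeuronTree(nodes=nodes, provenance=provenance)


def read_swc(path) -> NeuronTree:
    with open(path) as fh:
        return parse_swc(fh.read(), provenance=str(path))


def _fmt(v: float) -> str:
    """Full-precision numeric formatting that round-trips through float()."""
    return repr(float(v))


def write_swc(tree: NeuronTree) -> str:
    """Serialize a tree to SWC text with a provenance header."""
    if not tree.nodes:
        raise ValueError("cannot write an empty tree")
    lines = ["# SWC written by venmorph"]
    if tree.provenance:
        lines.append(f"# provenance: {tree.provenance}")
    for n in tree.nodes:
        lines.append(
            f"{n.id} {n.type_code} {_fmt(n.x)} {_fmt(n.y)} {_fmt(n.z)} "
            f"{_fmt(n.radius)} {n.parent_id}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# quality control


@dataclass(frozen=True)
class QcThresholds:
    """Numeric criteria for the reconstruction-quality checks.

    Defaults are conservative artifact choices (no published values exist):
    a soma reconstructed in 3D should span more than ``z_span_min`` µm in z;
    a closed soma contour ends within ``closure_tol`` µm of its start; a
    parent→child step is flagged as Z-drift when it jumps more than
    ``z_jump_max`` µm in z while moving less than ``xy_step_max`` µm in xy.
    """

    z_span_min: float = 2.0
    closure_tol: float = 2.0
    z_jump_max: float = 20.0
    xy_step_max: float = 5.0


@dataclass(frozen=True)
class QcCheck:
    status: str  # "pass" | "fail" | "not-applicable"
    detail: str = ""


@dataclass(frozen=True)
class QcReport:
    soma_3d_complete: QcCheck
    soma_contour_closed: QcCheck
    all_processes_attached: QcCheck
    z_alignment: QcCheck
    endings_marked: QcCheck

    CHECKS = (
        "soma_3d_complete",
        "soma_contour_closed",
        "all_processes_attached",
        "z_alignment",
        "endings_marked",
    )

    @property
    def passed(self) -> bool:
        return all(
            getattr(self, name).status != "fail" for name in self.CHECKS
        )

    def failures(self) -> list[str]:
        return [n for n in self.CHECKS if getattr(self, n).status == "fail"]

    def to_dict(self) -> dict:
        d = {
            name: {
                "status": getattr(self, name).status,
                "detail": getattr(self, name).detail,
            }
            for name in self.CHECKS
        }
        d["passed"] = self.passed
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _dist(a: SwcNode, b: SwcNode) -> float:
    return math.dist(a.position(), b.position())


def _reaches_soma(tree: NeuronTree, node: SwcNode) -> bool:
    cur: SwcNode | None = node
    while cur is not None:
        if cur.is_soma:
            return True
        cur = tree.parent(cur.id)
    return False


def run_qc(tree: NeuronTree, thresholds: QcThresholds | None = None) -> QcReport:
    """Run the five reconstruction-quality checks on a parsed tree.

    Failures never raise; they are entries in the returned report.  The two
    soma-shape checks are not applicable to single-node (spherical) somas.
    """
    th = thresholds or QcThresholds()
    soma = tree.soma_nodes

    # (1) soma reconstructed in 3D: the contour must have depth in z
    if len(soma) < 2:
        c1 = QcCheck("not-applicable", "single-node soma")
    else:
        span = max(n.z for n in soma) - min(n.z for n in soma)
        if span > th.z_span_min:
            c1 = QcCheck("pass", f"soma z-span {span:.3g} µm")
        else:
            c1 = QcCheck(
                "fail", f"soma z-span {span:.3g} µm ≤ {th.z_span_min} µm"
            )

    # (2) soma contour closed: first and last contour points must meet
    if len(soma) < 2:
        c2 = QcCheck("not-applicable", "single-node soma")
    else:
        gap = _dist(soma[0], soma[-1])
        if gap <= th.closure_tol:
            c2 = QcCheck("pass", f"contour gap {gap:.3g} µm")
        else:
            c2 = QcCheck("fail", f"contour gap {gap:.3g} µm > {th.closure_tol} µm")

    # (3) every process must attach to the soma through its parent chain
    if not soma:
        c3 = QcCheck("fail", "no soma node present")
    else:
        detached = [
            n.id
            for n in tree.roots
            if not n.is_soma and not _reaches_soma(tree, n)
        ]
        if detached:
            c3 = QcCheck(
                "fail", f"detached process root(s): {sorted(detached)}"
            )
        else:
            c3 = QcCheck("pass", "all processes attach to soma")

    # (4) Z alignment: a large z jump over a tiny xy step is a drift artifact
    jumps = []
    for n in tree.nodes:
        p = tree.parent(n.id)
        if p is None:
            continue
        dz = abs(n.z - p.z)
        dxy = math.hypot(n.x - p.x, n.y - p.y)
        if dz > th.z_jump_max and dxy < th.xy_step_max:
            jumps.append((p.id, n.id, dz))
    if jumps:
        worst = max(jumps, key=lambda t: t[2])
        c4 = QcCheck(
            "fail",
            f"z-jump {worst[2]:.3g} µm at edge {worst[0]}→{worst[1]} "
            f"({len(jumps)} edge(s) total)",
        )
    else:
        c4 = QcCheck("pass", "no z-drift signature")

    # (5) endings marked: ids resolve, tips terminate with a valid radius
    problems = []
    ids = {n.id for n in tree.nodes}
    for n in tree.nodes:
        if n.parent_id != -1 and n.parent_id not in ids:
            problems.append(f"node {n.id} orphaned")
    for tip in tree.tips():
        if not tip.is_soma and tip.radius <= 0:
            problems.append(f"tip {tip.id} unmarked")
    c5 = (
        QcCheck("fail", "; ".join(problems))
        if problems
        else QcCheck("pass", "all endings terminate cleanly")
    )

    return QcReport(c1, c2, c3, c4, c5)


# ---------------------------------------------------------------------------
# conversion fidelity


@dataclass(frozen=True)
class GeometryReport:
    """Result of comparing two reconstructions of the same cell."""

    topology_equal: bool
    max_displacement: float | None
    max_radius_deviation: float | None
    within_tolerance: bool

    def to_dict(self) -> dict:
        return {
            "topology_equal": self.topology_equal,
            "max_displacement": self.max_displacement,
            "max_radius_deviation": self.max_radius_deviation,
            "within_tolerance": self.within_tolerance,
        }


def compare_geometry(
    a: NeuronTree, b: NeuronTree, tol: float = 1e-6
) -> GeometryReport:
    """Compare two reconstructions node-by-node (matched by order).

    Used to verify conversion fidelity: identical parent maps mean equal
    topology; the maximum Euclidean displacement and radius deviation
    quantify geometric distortion.  A node-count mismatch yields a report
    with ``topology_equal`` False and no displacement.
    """
    if len(a) != len(b):
        return GeometryReport(False, None, None, False)
    topo = all(
        na.parent_id == nb.parent_id for na, nb in zip(a.nodes, b.nodes)
    )
    disp = max(_dist(na, nb) for na, nb in zip(a.nodes, b.nodes))
    rdev = max(abs(na.radius - nb.radius) for na, nb in zip(a.nodes, b.nodes))
    return GeometryReport(topo, disp, rdev, topo and disp <= tol and rdev <= tol)


def translated(tree: NeuronTree, dx: float, dy: float, dz: float) -> NeuronTree:
    """Rigidly translate a tree (convenience used by tests and rendering)."""
    return tree.with_nodes(
        [replace(n, x=n.x + dx, y=n.y + dy, z=n.z + dz) for n in tree.nodes]
    )
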