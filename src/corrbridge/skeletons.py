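"""Neuron skeleton data model, SWC I/O and arc-length geometry.

Skeletons are rooted trees of 3D nodes with coordinates held internally in
nanometres (float64).  The module provides cubic-spline resampling of
root-to-tip paths at a fixed arc-length step (default 320 nm, matching the
evaluation convention used throughout the package) and decomposition of a
tree into maximal unbranched runs ("branchlets"), the pooling unit for
spine-density statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import CubicSpline, interp1d

__all__ = [
    "SkeletonNode",
    "SkeletonTree",
    "ResampledPath",
    "Branchlet",
    "SwcFormatError",
    "read_swc",
    "write_swc",
    "root_to_tip_path",
    "resample_path",
    "path_length",
    "split_branchlets",
    "branchlet_table",
]

DEFAULT_SPACING_NM = 320.0


class SwcFormatError(ValueError):
    """Raised when an SWC file violates the structural contract."""


@dataclass(frozen=True)
class SkeletonNode:
    """A single tracing node: id, position (nm), radius (nm), parent link."""

    id: int
    position: np.ndarray  # shape (3,), nm
    radius: float = 0.0
    parent_id: int | None = None
    type_id: int = 0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"node {self.id}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


class SkeletonTree:
    """A rooted, connected, acyclic tree of :class:`SkeletonNode`.

    Parameters
    ----------
    name:
        Free-text identifier (cell id).
    nodes:
        Iterable of nodes; exactly one must have ``parent_id is None``.
    """

    def __init__(self, name: str, nodes: Iterable[SkeletonNode]):
        self.name = name
        self.nodes: dict[int, SkeletonNode] = {}
        for n in nodes:
            if n.id in self.nodes:
                raise SwcFormatError(f"duplicate node id {n.id}")
            self.nodes[n.id] = n
        roots = [n.id for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise SwcFormatError(f"tree must have exactly one root, found {len(roots)}")
        self.root_id = roots[0]
        self._children: dict[int, list[int]] = {i: [] for i in self.nodes}
        for n in self.nodes.values():
            if n.parent_id is not None:
                if n.parent_id not in self.nodes:
                    raise SwcFormatError(
                        f"node {n.id} references missing parent {n.parent_id}"
                    )
                self._children[n.parent_id].append(n.id)
        # connectivity + acyclicity: every node reachable from root
        seen = set()
        stack = [self.root_id]
        while stack:
            i = stack.pop()
            if i in seen:
                raise SwcFormatError("cycle detected")
            seen.add(i)
            stack.extend(self._children[i])
        if seen != set(self.nodes):
            raise SwcFormatError("tree is not connected")

    def children(self, node_id: int) -> list[int]:
        return list(self._children[node_id])

    def leaves(self) -> list[int]:
        return [i for i, c in self._children.items() if not c]

    def __len__(self) -> int:
        return len(self.nodes)

    def cable_length(self) -> float:
        """Total cable length in nm (sum over parent-child edges)."""
        total = 0.0
        for n in self.nodes.values():
            if n.parent_id is not None:
                total += float(
                    np.linalg.norm(n.position - self.nodes[n.parent_id].position)
                )
        return total

    def positions(self) -> np.ndarray:
        """(N, 3) array of node positions in node-id sorted order."""
        ids = sorted(self.nodes)
        return np.array([self.nodes[i].position for i in ids])

    def map_positions(self, fn) -> "SkeletonTree":
        """Return a new tree with every position mapped through ``fn``.

        ``fn`` receives an (N, 3) array and must return an (N, 3) array;
        topology, ids, radii and types are preserved.
        """
        ids = sorted(self.nodes)
        pts = np.array([self.nodes[i].position for i in ids])
        out = np.asarray(fn(pts), dtype=float)
        new_nodes = [
            SkeletonNode(
                id=i,
                position=out[k],
                radius=self.nodes[i].radius,
                parent_id=self.nodes[i].parent_id,
                type_id=self.nodes[i].type_id,
            )
            for k, i in enumerate(ids)
        ]
        return SkeletonTree(self.name, new_nodes)


@dataclass
class ResampledPath:
    """A polyline resampled at (near-)constant arc-length spacing.

    ``points`` are (N, 3) in nm; ``cumulative_arc_length`` is per-point arc
    position starting at 0.  The final segment may be shorter than
    ``spacing`` because the path endpoint is always emitted.
    """

    points: np.ndarray
    spacing: float
    cumulative_arc_length: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.cumulative_arc_length is None:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            self.cumulative_arc_length = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length(self) -> float:
        return float(self.cumulative_arc_length[-1])

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Branchlet:
    """Maximal unbranched dendritic run between root / branch points / leaves."""

    cell_id: str
    branchlet_id: str
    polyline: np.ndarray  # (N, 3) nm
    dendrite_type: str  # "trunk" | "apical_oblique"

    def __post_init__(self):
        self.polyline = np.asarray(self.polyline, dtype=float)
        if len(self.polyline) < 2:
            raise ValueError("branchlet polyline needs >= 2 points")

    @property
    def length(self) -> float:
        return path_length(self.polyline)


# ---------------------------------------------------------------------------
# SWC I/O


def read_swc(path: str | Path, unit: str = "um") -> SkeletonTree:
    """Read an SWC file into a single :class:`SkeletonTree`.

    The SWC table is seven whitespace-separated columns
    ``id type x y z radius parent`` with parent ``-1`` marking the root.
    Coordinates are converted to nm according to ``unit`` ("um" scales by
    1000, "nm" leaves them untouched).

    Raises
    ------
    SwcFormatError
        On duplicate ids, dangling parent references, or a component with
        more than one root; the message names the offending line.
    """
    scale = {"um": 1000.0, "nm": 1.0}[unit]
    nodes: list[SkeletonNode] = []
    seen_ids: set[int] = set()
    path = Path(path)
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SwcFormatError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
        nid, ntype = int(parts[0]), int(parts[1])
        x, y, z, r = (float(v) for v in parts[2:6])
        parent = int(parts[6])
        if nid in seen_ids:
            raise SwcFormatError(f"{path}:{lineno}: duplicate node id {nid}")
        seen_ids.add(nid)
        nodes.append(
            SkeletonNode(
                id=nid,
                position=np.array([x, y, z]) * scale,
                radius=r * scale,
                parent_id=None if parent == -1 else parent,
                type_id=ntype,
            )
        )
    if not nodes:
        raise SwcFormatError(f"{path}: no nodes")
    dangling = [n for n in nodes if n.parent_id is not None and n.parent_id not in seen_ids]
    if dangling:
        raise SwcFormatError(
            f"{path}: node {dangling[0].id} references missing parent {dangling[0].parent_id}"
        )
    return SkeletonTree(path.stem, nodes)


def write_swc(tree: SkeletonTree, path: str | Path, unit: str = "um") -> None:
    """Write a tree as SWC. Inverse of :func:`read_swc` for the same unit."""
    scale = {"um": 1000.0, "nm": 1.0}[unit]
    lines = [f"# {tree.name}", "# id type x y z radius parent"]
    for nid in sorted(tree.nodes):
        n = tree.nodes[nid]
        x, y, z = n.position / scale
        parent = -1 if n.parent_id is None else n.parent_id
        lines.append(
            f"{n.id} {n.type_id} {x:.6f} {y:.6f} {z:.6f} {n.radius / scale:.6f} {parent}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Geometry


def path_length(polyline: np.ndarray) -> float:
    """Polyline length in nm: sum of consecutive Euclidean distances."""
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or len(pts) < 1:
        raise ValueError("polyline must be (N, 3) with N >= 1")
    if len(pts) == 1:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def root_to_tip_path(tree: SkeletonTree, tip_id: int) -> np.ndarray:
    """Ordered (N, 3) polyline of node positions from the root to ``tip_id``."""
    if tip_id not in tree.nodes:
        raise KeyError(f"tip {tip_id} not in tree")
    chain = [tip_id]
    while tree.nodes[chain[-1]].parent_id is not None:
        chain.append(tree.nodes[chain[-1]].parent_id)
    chain.reverse()
    return np.array([tree.nodes[i].position for i in chain])


def _dedupe(pts: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicate points (zero-length chords break the spline)."""
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 0
    return pts[keep]


def resample_path(
    polyline: np.ndarray, spacing: float = DEFAULT_SPACING_NM
) -> ResampledPath:
    """Fit a cubic spline through ``polyline`` and resample at equal arc steps.

    The spline uses cumulative chord-length parameterisation with natural
    boundary conditions.  Arc length along the spline is computed by
    adaptive numeric integration of the speed, then inverted on a dense
    grid so output points sit at arc positions 0, s, 2s, ... plus the exact
    endpoint (the tip is never truncated).  Inputs with three or fewer
    distinct points fall back to piecewise-linear interpolation, where the
    cubic fit is under-determined.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    pts = _dedupe(np.asarray(polyline, dtype=float))
    if len(pts) < 2:
        raise ValueError("need >= 2 distinct points to resample")

    chord = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    )
    if len(pts) <= 3:
        curve = interp1d(chord, pts, axis=0)
        speed = None
    else:
        curve = CubicSpline(chord, pts, bc_type="natural")
        dcurve = curve.derivative()
        speed = lambda t: float(np.linalg.norm(dcurve(t)))

    # arc length per chord knot (exact for the linear fallback)
    if speed is None:
        knot_arc = chord.copy()
    else:
        seg_arc = [
            quad(speed, chord[i], chord[i + 1], limit=200)[0]
            for i in range(len(chord) - 1)
        ]
        knot_arc = np.concatenate([[0.0], np.cumsum(seg_arc)])
    total = float(knot_arc[-1])

    # invert arc(t) on a dense per-segment grid
    n_dense = max(8 * len(pts), 256)
    t_dense = np.linspace(chord[0], chord[-1], n_dense)
    p_dense = curve(t_dense)
    arc_dense = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(p_dense, axis=0), axis=1))]
    )
    if arc_dense[-1] > 0:  # rescale dense approximation to the quadrature total
        arc_dense *= total / arc_dense[-1]
    t_of_arc = interp1d(
        arc_dense, t_dense, bounds_error=False,
        fill_value=(t_dense[0], t_dense[-1]),  # guards fp overshoot at the ends
    )

    targets = np.arange(0.0, total, spacing)
    if total - targets[-1] > 1e-9:
        targets = np.concatenate([targets, [total]])
    out = curve(t_of_arc(targets))
    return ResampledPath(points=out, spacing=spacing, cumulative_arc_length=targets)


def split_branchlets(
    tree: SkeletonTree,
    type_labels: Mapping[int, str] | None = None,
    default_type: str = "trunk",
) -> list[Branchlet]:
    """Decompose a tree into maximal unbranched runs.

    A branchlet runs from the root or a branch point to the next branch
    point or leaf; every edge belongs to exactly one branchlet, so branchlet
    lengths sum to the tree's cable length.  The branchlet's type is taken
    from the label of its distal segment nodes (first labelled node wins).
    """
    labels = dict(type_labels) if type_labels is not None else None
    if labels is not None:
        missing = set(tree.nodes) - set(labels)
        if missing:
            raise ValueError(f"missing type labels for nodes {sorted(missing)[:5]}")

    branchlets: list[Branchlet] = []
    counter = 0
    # start a run below the root and below every branch point
    starts = [
        (nid, child)
        for nid in tree.nodes
        for child in tree.children(nid)
        if nid == tree.root_id or len(tree.children(nid)) > 1
    ]
    # also runs continuing through pass-through nodes are absorbed below
    for anchor, first in sorted(starts):
        run = [anchor, first]
        while len(tree.children(run[-1])) == 1:
            run.append(tree.children(run[-1])[0])
        poly = np.array([tree.nodes[i].position for i in run])
        if labels is not None:
            btype = next((labels[i] for i in run[1:]), default_type)
        else:
            btype = default_type
        branchlets.append(
            Branchlet(
                cell_id=tree.name,
                branchlet_id=f"{tree.name}.b{counter}",
                polyline=poly,
                dendrite_type=btype,
            )
        )
        counter += 1
    return branchlets


def branchlet_table(branchlets: Sequence[Branchlet]):
    """Branchlets as a tidy DataFrame (cell_id, branchlet_id, type, length_nm, n_points)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "cell_id": [b.cell_id for b in branchlets],
            "branchlet_id": [b.branchlet_id for b in branchlets],
            "type": [b.dendrite_type for b in branchlets],
            "length_nm": [b.length for b in branchlets],
            "n_points": [len(b.polyline) for b in branchlets],
        }
    )
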