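"""Landmark-based coordinate transforms between named dataset spaces.

Correlative imaging produces several volumes of the same tissue (2-photon,
lab and synchrotron micro-CT, volume EM), each in its own coordinate
system.  Point annotations move between them through transforms fitted to
manually placed landmark pairs: per-axis scale+offset, full 3D affine, or
3D thin-plate splines (biharmonic kernel U(r) = r).  Transforms are edges
of a :class:`DatasetGraph`; composing the shortest path between two spaces
yields the mapping used to warp skeletons across modalities.

The TPS forward model is exact at its defining landmarks (at zero
regularisation); its registered inverse is a TPS fitted to the swapped
pairs and is therefore approximate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .skeletons import SkeletonTree

__all__ = [
    "LandmarkSet",
    "Transform",
    "ScaleOffsetTransform",
    "AffineTransform",
    "ThinPlateSplineTransform",
    "IdentityTransform",
    "CompositeTransform",
    "DatasetGraph",
    "NoPathError",
    "fit_scale_offset",
    "fit_affine",
    "fit_tps",
    "apply_transform",
    "compose_path",
    "warp_skeleton",
    "read_landmarks_json",
    "write_landmarks_json",
]


class NoPathError(KeyError):
    """No transform path exists between the requested spaces."""


@dataclass
class LandmarkSet:
    """Paired landmarks between two named spaces, coordinates in nm."""

    source_space: str
    target_space: str
    source: np.ndarray  # (N, 3)
    target: np.ndarray  # (N, 3)

    def __post_init__(self):
        self.source = np.asarray(self.source, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.source.shape != self.target.shape or self.source.ndim != 2:
            raise ValueError("source/target must be matching (N, 3) arrays")
        uniq = np.unique(self.source, axis=0)
        if len(uniq) != len(self.source):
            raise ValueError("duplicated source landmarks")

    def __len__(self) -> int:
        return len(self.source)

    def swapped(self) -> "LandmarkSet":
        return LandmarkSet(self.target_space, self.source_space, self.target, self.source)


class Transform:
    """Base class: a deterministic mapping of (N, 3) point arrays."""

    source_space: str = ""
    target_space: str = ""

    def apply(self, points: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def inverse(self) -> "Transform | None":
        """Exact or approximate inverse, or None when not invertible."""
        return None


@dataclass
class IdentityTransform(Transform):
    source_space: str = ""
    target_space: str = ""

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float).copy()

    def inverse(self) -> "IdentityTransform":
        return IdentityTransform(self.target_space, self.source_space)


@dataclass
class ScaleOffsetTransform(Transform):
    """Per-axis y = scale * x + offset."""

    scale: np.ndarray
    offset: np.ndarray
    source_space: str = ""
    target_space: str = ""

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) * self.scale + self.offset

    def inverse(self) -> "ScaleOffsetTransform":
        return ScaleOffsetTransform(
            1.0 / self.scale, -self.offset / self.scale,
            self.target_space, self.source_space,
        )


@dataclass
class AffineTransform(Transform):
    """y = A x + b with A a full 3x3 matrix."""

    matrix: np.ndarray  # (3, 3)
    offset: np.ndarray  # (3,)
    source_space: str = ""
    target_space: str = ""

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.matrix.T + self.offset

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.offset,
                               self.target_space, self.source_space)


@dataclass
class ThinPlateSplineTransform(Transform):
    """3D thin-plate spline: affine part + biharmonic kernel U(r) = r.

    f(x) = A x + b + sum_i w_i * |x - c_i|, fitted per output axis with the
    usual orthogonality constraints sum w = 0, sum w c = 0.  The inverse is
    a TPS fitted to the swapped landmark pairs (approximate).
    """

    centres: np.ndarray  # (N, 3)
    weights: np.ndarray  # (N, 3) kernel weights per output axis
    matrix: np.ndarray   # (3, 3)
    offset: np.ndarray   # (3,)
    source_space: str = ""
    target_space: str = ""
    _inverse: "ThinPlateSplineTransform | None" = field(default=None, repr=False)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        # kernel matrix between query points and centres
        diff = pts[:, None, :] - self.centres[None, :, :]
        K = np.linalg.norm(diff, axis=2)  # U(r) = r in 3D
        return pts @ self.matrix.T + self.offset + K @ self.weights

    def inverse(self) -> "ThinPlateSplineTransform | None":
        return self._inverse


@dataclass
class CompositeTransform(Transform):
    """Left-to-right chain of transforms along a graph path."""

    steps: Sequence[Transform]
    source_space: str = ""
    target_space: str = ""

    def apply(self, points: np.ndarray) -> np.ndarray:
        out = np.asarray(points, dtype=float)
        for t in self.steps:
            out = t.apply(out)
        return out

    def inverse(self) -> "CompositeTransform | None":
        invs = []
        for t in reversed(self.steps):
            ti = t.inverse()
            if ti is None:
                return None
            invs.append(ti)
        return CompositeTransform(invs, self.target_space, self.source_space)


# ---------------------------------------------------------------------------
# Fitting


def fit_scale_offset(landmarks: LandmarkSet) -> ScaleOffsetTransform:
    """Per-axis least-squares scale + offset."""
    if len(landmarks) < 2:
        raise ValueError("need >= 2 landmark pairs")
    src, dst = landmarks.source, landmarks.target
    scale = np.empty(3)
    offset = np.empty(3)
    for ax in range(3):
        x, y = src[:, ax], dst[:, ax]
        vx = np.var(x)
        if vx == 0:
            raise np.linalg.LinAlgError(f"zero variance on axis {ax}")
        scale[ax] = np.cov(x, y, bias=True)[0, 1] / vx
        offset[ax] = y.mean() - scale[ax] * x.mean()
    return ScaleOffsetTransform(scale, offset,
                                landmarks.source_space, landmarks.target_space)


def fit_affine(landmarks: LandmarkSet) -> AffineTransform:
    """Least-squares 3x4 affine. Source points must span 3D (non-coplanar)."""
    if len(landmarks) < 4:
        raise ValueError("need >= 4 landmark pairs for a 3D affine")
    src, dst = landmarks.source, landmarks.target
    X = np.hstack([src, np.ones((len(src), 1))])
    if np.linalg.matrix_rank(X) < 4:
        raise np.linalg.LinAlgError("source landmarks are coplanar/collinear")
    coef, *_ = np.linalg.lstsq(X, dst, rcond=None)
    return AffineTransform(coef[:3].T, coef[3],
                           landmarks.source_space, landmarks.target_space)


def _tps_system(src: np.ndarray, regularisation: float) -> np.ndarray:
    n = len(src)
    K = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=2)
    K += regularisation * np.eye(n)
    P = np.hstack([src, np.ones((n, 1))])
    L = np.zeros((n + 4, n + 4))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    return L


def fit_tps(
    landmarks: LandmarkSet, regularisation: float = 0.0, fit_inverse: bool = True
) -> ThinPlateSplineTransform:
    """Fit a 3D thin-plate spline; exact interpolation at regularisation 0.

    When ``fit_inverse`` is set (default) a TPS on the swapped pairs is
    attached as the approximate inverse.
    """
    if len(landmarks) < 4:
        raise ValueError("need >= 4 landmark pairs for a 3D TPS")
    src, dst = landmarks.source, landmarks.target
    if np.linalg.matrix_rank(np.hstack([src, np.ones((len(src), 1))])) < 4:
        raise np.linalg.LinAlgError("source landmarks are coplanar/collinear")
    n = len(src)
    L = _tps_system(src, regularisation)
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = dst
    sol = np.linalg.solve(L, rhs)
    t = ThinPlateSplineTransform(
        centres=src.copy(),
        weights=sol[:n],
        matrix=sol[n : n + 3].T,
        offset=sol[n + 3],
        source_space=landmarks.source_space,
        target_space=landmarks.target_space,
    )
    if fit_inverse:
        t._inverse = fit_tps(landmarks.swapped(), regularisation, fit_inverse=False)
        t._inverse._inverse = t
    return t


def apply_transform(t: Transform, points: np.ndarray) -> np.ndarray:
    """Map an (N, 3) point array through a transform (order preserved)."""
    return t.apply(np.asarray(points, dtype=float))


# ---------------------------------------------------------------------------
# Dataset graph


class DatasetGraph:
    """Directed graph of dataset spaces linked by transforms.

    Adding an invertible transform auto-registers the reverse edge, so any
    two connected spaces can be bridged.  Paths are chosen by fewest edges,
    ties broken lexicographically by the sequence of space ids.
    """

    def __init__(self):
        self._g = nx.DiGraph()

    @property
    def spaces(self) -> set[str]:
        return set(self._g.nodes)

    def add_transform(self, t: Transform, register_inverse: bool = True) -> None:
        if not t.source_space or not t.target_space:
            raise ValueError("transform must carry source/target space ids")
        self._g.add_edge(t.source_space, t.target_space, transform=t)
        if register_inverse:
            inv = t.inverse()
            if inv is not None:
                self._g.add_edge(t.target_space, t.source_space, transform=inv)

    def compose_path(self, src: str, dst: str) -> Transform:
        return compose_path(self, src, dst)

    def _shortest_path(self, src: str, dst: str) -> list[str]:
        if src not in self._g or dst not in self._g:
            raise NoPathError(f"unknown space in ({src!r}, {dst!r})")
        # BFS by edge count with lexicographic tie-break on the node sequence
        try:
            paths = list(nx.all_shortest_paths(self._g, src, dst))
        except nx.NetworkXNoPath:
            raise NoPathError(f"no transform path {src!r} -> {dst!r}") from None
        return min(paths)

    def edge_transform(self, a: str, b: str) -> Transform:
        return self._g.edges[a, b]["transform"]


def compose_path(graph: DatasetGraph, src: str, dst: str) -> Transform:
    """Shortest-path composite transform from ``src`` space to ``dst`` space."""
    if src == dst:
        if src not in graph.spaces:
            raise NoPathError(f"unknown space {src!r}")
        return IdentityTransform(src, dst)
    nodes = graph._shortest_path(src, dst)
    steps = [graph.edge_transform(a, b) for a, b in zip(nodes[:-1], nodes[1:])]
    if len(steps) == 1:
        return steps[0]
    return CompositeTransform(steps, src, dst)


def warp_skeleton(
    graph: DatasetGraph, tree: SkeletonTree, src: str, dst: str
) -> SkeletonTree:
    """Warp every node of a skeleton from ``src`` space to ``dst`` space."""
    t = compose_path(graph, src, dst)
    return tree.map_positions(t.apply)


# ---------------------------------------------------------------------------
# Landmark JSON I/O
#
# Schema: {"source_space": str, "target_space": str, "unit": "nm"|"um",
#          "pairs": [[sx, sy, sz, tx, ty, tz], ...]}


def read_landmarks_json(path: str | Path) -> LandmarkSet:
    data = json.loads(Path(path).read_text())
    scale = {"nm": 1.0, "um": 1000.0}[data.get("unit", "nm")]
    pairs = np.asarray(data["pairs"], dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 6:
        raise ValueError("pairs must be an Nx6 array")
    return LandmarkSet(
        data["source_space"], data["target_space"],
        pairs[:, :3] * scale, pairs[:, 3:] * scale,
    )


def write_landmarks_json(landmarks: LandmarkSet, path: str | Path) -> None:
    pairs = np.hstack([landmarks.source, landmarks.target])
    Path(path).write_text(
        json.dumps(
            {
                "source_space": landmarks.source_space,
                "target_space": landmarks.target_space,
                "unit": "nm",
                "pairs": pairs.tolist(),
            },
            indent=1,
        )
    )
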