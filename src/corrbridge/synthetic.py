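"""Seeded generators emulating the statistical structure of the study data.

Each generator produces inputs satisfying the invariants of the module it
feeds, from a single integer seed fanned out into independent substreams
(module tests must not perturb each other's randomness):

* dendrite cohorts — near-straight persistent-random-walk apical
  dendrites (~200 um, mimicking mitral-cell dendrites crossing the
  external plexiform layer) plus per-tracer copies with node jitter and,
  with probability q, a sustained wrong-turn departure concentrated in
  the first 40 um "linkage region";
* half-volume pairs sharing a band-limited Gaussian random field plus
  independent noise at a controlled per-shell SNR (FSC closed forms);
* spiny CA1-like cells with homogeneous-Poisson spine placement and a
  soma-depth-dependent spine-apparatus probability;
* landmark sets under a known affine plus a smooth low-frequency
  deformation, with a held-out ground-truth grid;
* analytic 2D phantoms for tomography round trips.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .fsc import VolumePair
from .skeletons import Branchlet, SkeletonNode, SkeletonTree
from .spines import DepthModel, Spine, SpineAnnotation
from .warp import LandmarkSet

__all__ = [
    "substream",
    "DendriteCohort",
    "gen_dendrite_cohort",
    "gen_fsc_pair",
    "SpinyCohort",
    "gen_spiny_cells",
    "LandmarkScenario",
    "gen_landmark_deformation",
    "gen_phantom",
]

NM_PER_UM = 1000.0
LINKAGE_REGION_UM = 40.0


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible substream derived from (seed, label)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode()) % 2**31])
    )


# ---------------------------------------------------------------------------
# Dendrite cohorts


def _persistent_walk(
    rng: np.random.Generator,
    n_steps: int,
    step_nm: float,
    persistence: float,
) -> np.ndarray:
    """Nearly straight 3D random walk: direction relaxes toward its running
    mean with small angular noise controlled by ``persistence`` in [0, 1)."""
    d = np.array([0.0, 0.0, 1.0])
    pts = np.zeros((n_steps + 1, 3))
    for i in range(n_steps):
        noise = rng.normal(scale=1.0 - persistence, size=3)
        d = d + noise * 0.15
        d /= np.linalg.norm(d)
        pts[i + 1] = pts[i] + d * step_nm
    return pts


def _chain_tree(name: str, pts: np.ndarray) -> SkeletonTree:
    nodes = [
        SkeletonNode(id=i + 1, position=p, parent_id=None if i == 0 else i)
        for i, p in enumerate(pts)
    ]
    return SkeletonTree(name, nodes)


@dataclass
class DendriteCohort:
    truth: list[SkeletonTree]
    tests: dict[str, list[SkeletonTree]]  # tracer id -> per-cell test trees
    departure_arc_nm: dict[tuple[str, str], float | None]  # (tracer, cell) -> arc


def gen_dendrite_cohort(
    n_cells: int = 50,
    full_length_um: float = 200.0,
    tortuosity: float = 0.97,
    linkage_fail_prob: float = 0.25,
    late_fail_prob: float = 0.1,
    jitter_nm: float = 100.0,
    n_tracers: int = 3,
    step_nm: float = 2000.0,
    linkage_depart_max_um: float = 20.0,
    seed: int = 0,
) -> DendriteCohort:
    """Cohort of truth dendrites plus per-tracer error-bearing copies.

    Each tracer copy receives Gaussian node jitter and, with probability
    ``linkage_fail_prob``, takes a sustained wrong turn at an arc position
    uniform in the soma-linkage zone ``[0, linkage_depart_max_um]``;
    otherwise, with probability ``late_fail_prob``, it departs at a
    position uniform over the dendrite beyond the 40 um linkage region.
    A departure is a straight divergent branch, long enough to exceed any
    realistic lost threshold.

    The detected loss position trails the wrong turn by about the lost
    threshold (distance to the reference can only grow with arc), so
    departures in the first 20 um register as losses within the first
    ~32 um of dendrite — inside the 40 um linkage region and below the
    35 um "linked" criterion — while late departures register well beyond
    it.  This keeps the generative labels and the four-way classification
    in one-to-one correspondence.
    """
    rng = substream(seed, "dendrite_cohort")
    n_steps = int(round(full_length_um * NM_PER_UM / step_nm))
    truth, tests = [], {f"tracer{t}": [] for t in range(n_tracers)}
    departures: dict[tuple[str, str], float | None] = {}
    for c in range(n_cells):
        cell = f"cell{c:03d}"
        pts = _persistent_walk(rng, n_steps, step_nm, tortuosity)
        truth.append(_chain_tree(cell, pts))
        arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        total = arc[-1]
        for tracer in tests:
            test_pts = pts + rng.normal(scale=jitter_nm, size=pts.shape)
            u = rng.uniform()
            if u < linkage_fail_prob:
                dep = rng.uniform(0.0, linkage_depart_max_um * NM_PER_UM)
            elif u < linkage_fail_prob + late_fail_prob:
                dep = rng.uniform(LINKAGE_REGION_UM * NM_PER_UM, total * 0.95)
            else:
                dep = None
            if dep is not None:
                k = int(np.searchsorted(arc, dep))
                k = min(max(k, 1), len(pts) - 2)
                # replace everything beyond the departure node with a straight
                # run in a strongly divergent direction
                local = pts[k] - pts[k - 1]
                local /= np.linalg.norm(local)
                perp = np.cross(local, [1.0, 0.0, 0.0])
                if np.linalg.norm(perp) < 1e-6:
                    perp = np.cross(local, [0.0, 1.0, 0.0])
                perp /= np.linalg.norm(perp)
                n_away = len(pts) - k
                away = test_pts[k] + np.outer(np.arange(1, n_away + 1) * step_nm, perp)
                test_pts = np.vstack([test_pts[: k + 1], away])
                departures[(tracer, cell)] = float(arc[k])
            else:
                departures[(tracer, cell)] = None
            tests[tracer].append(_chain_tree(cell, test_pts))
    return DendriteCohort(truth, tests, departures)


# ---------------------------------------------------------------------------
# FSC half-volume pairs


def gen_fsc_pair(
    shape: tuple[int, int, int] = (64, 64, 64),
    cutoff: float = 0.25,
    snr: float = 1.0,
    voxel_size: float = 100.0,
    seed: int = 0,
) -> VolumePair:
    """Two half-volumes sharing a band-limited signal plus independent noise.

    The shared signal is a Gaussian random field with a hard Fourier
    cutoff (cycles/voxel); per-coefficient signal power below the cutoff
    is ``snr`` times the white-noise power, so the expected FSC is
    snr/(snr+1) below the cutoff and 0 above.  ``snr=np.inf`` yields
    noise-free halves.
    """
    if not 0 < cutoff <= 0.5:
        raise ValueError("cutoff must be in (0, 0.5]")
    rng = substream(seed, "fsc_pair")
    freq = np.meshgrid(*[np.fft.fftfreq(n) for n in shape], indexing="ij", sparse=True)
    r = np.sqrt(sum(f * f for f in freq))
    mask = r <= cutoff
    coeffs = (rng.normal(size=shape) + 1j * rng.normal(size=shape)) * mask
    signal = np.fft.ifftn(coeffs).real
    # taking the real part Hermitian-symmetrises the spectrum: every in-band
    # coefficient of fftn(signal) has expected power exactly 1
    if np.isinf(snr):
        return VolumePair(signal.copy(), signal.copy(), voxel_size)
    # white real noise with std sigma has per-coefficient Fourier power
    # N * sigma^2; set it to 1/snr so the in-band per-shell SNR equals `snr`
    noise_std = float(1.0 / np.sqrt(np.prod(shape) * snr))
    a = signal + rng.normal(scale=noise_std, size=shape)
    b = signal + rng.normal(scale=noise_std, size=shape)
    return VolumePair(a, b, voxel_size)


# ---------------------------------------------------------------------------
# Spiny cells


@dataclass
class SpinyCohort:
    annotations: list[SpineAnnotation]
    somata_xy: dict[str, np.ndarray]  # cell -> (2,) nm
    depth_model: DepthModel
    true_depths_nm: dict[str, float]
    sa_prob: dict[str, float]


def gen_spiny_cells(
    n_cells: int = 7,
    branchlets_per_cell: int = 8,
    branchlet_length_um: float = 30.0,
    spine_rate_per_um: float = 1.5,
    sa_base_prob: float = 0.1,
    sa_depth_slope_per_um: float = 0.0,
    depth_range_um: float = 40.0,
    dendrite_type: str = "apical_oblique",
    seed: int = 0,
) -> SpinyCohort:
    """CA1-like cells: Poisson spines, depth-dependent spine-apparatus flags.

    Somata sit on a known layer line (y = 0 through the origin, deep side
    +y) at depths spread uniformly over ``[-depth_range_um/2, +depth_range_um/2]``.
    Each cell's spine-apparatus probability is
    ``sa_base_prob + sa_depth_slope_per_um * depth_um``, clipped into [0, 1]
    only if already inside it — out-of-range probabilities raise.
    """
    rng = substream(seed, "spiny_cells")
    depths = np.linspace(-depth_range_um / 2, depth_range_um / 2, n_cells)
    model = DepthModel(point=np.zeros(2), direction=np.array([1.0, 0.0]), deep_side_sign=1.0)
    annotations, somata, true_depths, sa_probs = [], {}, {}, {}
    L_nm = branchlet_length_um * NM_PER_UM
    for c in range(n_cells):
        cell = f"ca1_{c:02d}"
        depth_um = float(depths[c])
        p_sa = sa_base_prob + sa_depth_slope_per_um * depth_um
        if not 0.0 <= p_sa <= 1.0:
            raise ValueError(f"spine-apparatus probability {p_sa:.3f} outside [0, 1]")
        somata[cell] = np.array([rng.uniform(0, 100_000.0), depth_um * NM_PER_UM])
        true_depths[cell] = depth_um * NM_PER_UM
        sa_probs[cell] = p_sa
        branchlets = []
        for b in range(branchlets_per_cell):
            start = rng.uniform(-50_000, 50_000, size=3)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            poly = np.vstack([start, start + direction * L_nm])
            br = Branchlet(cell, f"{cell}.b{b}", poly, dendrite_type)
            n_spines = rng.poisson(spine_rate_per_um * branchlet_length_um)
            arcs = np.sort(rng.uniform(0.0, L_nm, size=n_spines))
            spines = [
                Spine(attachment_arc=float(a), has_spine_apparatus=bool(rng.uniform() < p_sa))
                for a in arcs
            ]
            branchlets.append((br, spines))
        annotations.append(SpineAnnotation(cell, branchlets))
    return SpinyCohort(annotations, somata, model, true_depths, sa_probs)


# ---------------------------------------------------------------------------
# Landmark deformations


@dataclass
class LandmarkScenario:
    landmarks: LandmarkSet
    grid_source: np.ndarray  # held-out points, (M, 3) nm
    grid_target: np.ndarray  # exact ground-truth images of grid_source
    amplitude_nm: float


def gen_landmark_deformation(
    n_landmarks: int = 60,
    box_nm: float = 100_000.0,
    affine_matrix: np.ndarray | None = None,
    affine_offset: np.ndarray | None = None,
    warp_amplitude_nm: float = 2_000.0,
    n_grid: int = 5,
    seed: int = 0,
    source_space: str = "SXRT",
    target_space: str = "SBEM",
) -> LandmarkScenario:
    """Landmarks under known affine + smooth sinusoidal displacement field.

    The nonlinear part is a superposition of three low-frequency sine
    modes (a quarter period across the box, the gentle bulk deformation
    regime of fixed-tissue shrinkage and mounting) so a thin-plate spline
    fitted to a few dozen landmarks can represent it; the held-out regular
    grid carries the exact ground truth for generalisation error
    measurements.
    """
    if n_landmarks < 4:
        raise ValueError("need >= 4 landmarks")
    rng = substream(seed, "landmarks")
    A = np.eye(3) if affine_matrix is None else np.asarray(affine_matrix, float)
    b = np.zeros(3) if affine_offset is None else np.asarray(affine_offset, float)

    def deform(x: np.ndarray) -> np.ndarray:
        phase = 2 * np.pi * x / (4 * box_nm)
        disp = np.stack(
            [
                np.sin(phase[:, 0]) * np.cos(phase[:, 1]),
                np.sin(phase[:, 1]) * np.cos(phase[:, 2]),
                np.sin(phase[:, 2]) * np.cos(phase[:, 0]),
            ],
            axis=1,
        )
        return x @ A.T + b + warp_amplitude_nm * disp

    src = rng.uniform(0, box_nm, size=(n_landmarks, 3))
    lms = LandmarkSet(source_space, target_space, src, deform(src))
    axes = [np.linspace(0.15 * box_nm, 0.85 * box_nm, n_grid)] * 3
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    return LandmarkScenario(lms, grid, deform(grid), warp_amplitude_nm)


# ---------------------------------------------------------------------------
# Phantoms


def gen_phantom(kind: str = "disc", size: int = 128, seed: int = 0) -> np.ndarray:
    """Deterministic analytic 2D phantoms with known support.

    Kinds: "disc" (centred uniform disc, radius 0.35 * size), "shepp_logan_like"
    (a few nested ellipses of varying intensity), "soft_tissue_blobs"
    (seeded superposition of Gaussian blobs inside a disc support).
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    y, x = (yy - c) / size, (xx - c) / size
    if kind == "disc":
        return (x**2 + y**2 <= 0.35**2).astype(float)
    if kind == "shepp_logan_like":
        img = np.zeros((size, size))
        ellipses = [  # (cx, cy, rx, ry, angle_deg, value)
            (0.0, 0.0, 0.42, 0.35, 0, 1.0),
            (0.0, 0.0, 0.38, 0.31, 0, -0.4),
            (-0.12, 0.0, 0.10, 0.18, 20, 0.3),
            (0.12, 0.0, 0.08, 0.16, -20, 0.3),
            (0.0, 0.18, 0.05, 0.05, 0, 0.5),
        ]
        for cx, cy, rx, ry, ang, val in ellipses:
            th = np.deg2rad(ang)
            xr = (x - cx) * np.cos(th) + (y - cy) * np.sin(th)
            yr = -(x - cx) * np.sin(th) + (y - cy) * np.cos(th)
            img += val * ((xr / rx) ** 2 + (yr / ry) ** 2 <= 1.0)
        return img
    if kind == "soft_tissue_blobs":
        rng = substream(seed, "phantom_blobs")
        img = np.zeros((size, size))
        support = x**2 + y**2 <= 0.4**2
        for _ in range(12):
            bx, by = rng.uniform(-0.3, 0.3, size=2)
            s = rng.uniform(0.02, 0.08)
            amp = rng.uniform(0.3, 1.0)
            img += amp * np.exp(-((x - bx) ** 2 + (y - by) ** 2) / (2 * s**2))
        return img * support
    raise ValueError(f"unknown phantom kind {kind!r}")
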