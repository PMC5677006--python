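"""Synthetic ground-truth phantoms: fiber bundles, masks, orientation fields.

The generator produces desk-scale analogues of a brain-like tractography
phantom: several curved fiber bundles laid out on a voxel grid, including an
orthogonal crossing and a "bottleneck" — a corridor of voxels shared by two
near-parallel bundles whose per-voxel fiber directions cannot tell them
apart.  Bottlenecks are the structural cause of systematic false-positive
bundles in tractography, and the shipped fixtures are designed so that this
effect is reproducible on a laptop-sized grid.

Coordinate conventions
----------------------
Voxels are addressed with 0-based indices; voxel ``v`` covers the half-open
world cube ``[v * voxel_size, (v + 1) * voxel_size)`` mm, so a world point
maps to a voxel by ``floor(p / voxel_size)``.  The NIfTI grid-to-world affine
is diagonal with a half-voxel offset (voxel centers at ``(v + 0.5) * vs``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy import ndimage

from .streamlines import as_streamline

__all__ = [
    "BundleGeometry",
    "PhantomSpec",
    "GroundTruthBundle",
    "OrientationField",
    "build_bundle",
    "assemble_phantom",
    "white_matter_mask",
    "canonical_phantom",
    "bottleneck_phantom",
]


def grid_affine(voxel_size: float) -> np.ndarray:
    """NIfTI grid-to-world affine for the corner-at-origin convention."""
    a = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    a[:3, 3] = voxel_size / 2.0
    return a


def point_to_voxel(points: np.ndarray, voxel_size: float) -> np.ndarray:
    """Map world-mm points to 0-based voxel indices (half-open cube rule)."""
    return np.floor(np.asarray(points) / voxel_size).astype(np.int64)


@dataclass
class BundleGeometry:
    """Parametric description of one bundle: a splined centerline with a
    circular cross-section of given radius, populated by ``n_streamlines``
    parallel-offset copies."""

    name: str
    control_points: np.ndarray  # (m, 3) world mm
    radius: float  # mm
    n_streamlines: int = 30
    profile: str = "disk"  # 'disk' (uniform) or 'gaussian'
    recognition_threshold: float = 5.0  # mm, bundle-specific MDF acceptance

    def __post_init__(self):
        self.control_points = np.asarray(self.control_points, dtype=np.float64)
        if self.control_points.ndim != 2 or self.control_points.shape[1] != 3:
            raise ValueError(f"bundle {self.name}: control_points must be (m, 3)")
        if self.control_points.shape[0] < 2:
            raise ValueError(f"bundle {self.name}: need >= 2 control points")
        if self.radius < 0:
            raise ValueError(f"bundle {self.name}: radius must be >= 0")
        if self.n_streamlines < 1:
            raise ValueError(f"bundle {self.name}: n_streamlines must be >= 1")


@dataclass
class PhantomSpec:
    """Full phantom description: grid, bundles and generation parameters."""

    grid_shape: tuple[int, int, int]
    voxel_size: float
    bundles: list[BundleGeometry]
    rng_seed: int = 0
    endpoint_dilation_radius: float = 1.0  # voxels, euclidean
    angular_merge_deg: float = 20.0  # directions closer than this share a peak
    max_peaks: int = 3
    intra_axonal_fraction: float = 0.7  # of the fiber compartment, rest inter

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.grid_shape = tuple(int(n) for n in self.grid_shape)

    @property
    def affine(self) -> np.ndarray:
        return grid_affine(self.voxel_size)


@dataclass
class GroundTruthBundle:
    """Reference streamlines plus the voxel masks derived from them."""

    name: str
    reference_streamlines: list[np.ndarray]
    mask: np.ndarray  # bool volume: voxels traversed by >= 1 reference
    head_mask: np.ndarray  # dilated first-point voxels
    tail_mask: np.ndarray  # dilated last-point voxels
    recognition_threshold: float  # mm


@dataclass
class OrientationField:
    """Per-voxel fiber peaks, their weights and tissue fractions.

    ``peaks`` is ``(X, Y, Z, K, 3)`` with unit rows (zero rows where absent),
    ``peak_fractions`` is ``(X, Y, Z, K)`` summing per voxel to the voxel's
    total fiber fraction, ``tissue_fractions`` is ``(X, Y, Z, 4)`` ordered
    (intra-axonal, inter-axonal, GM, CSF), summing to 1 in tissue voxels and
    to 0 in background (air) voxels.  ``bundle_map`` records which bundles
    contribute segments to each voxel.
    """

    peaks: np.ndarray
    peak_fractions: np.ndarray
    tissue_fractions: np.ndarray
    affine: np.ndarray
    voxel_size: float
    bundle_map: np.ndarray | None = None  # (X, Y, Z, n_bundles) bool

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.peaks.shape[:3]

    @property
    def n_peaks(self) -> np.ndarray:
        """Per-voxel count of nonzero peaks."""
        return (self.peak_fractions > 0).sum(axis=-1)


# ---------------------------------------------------------------------------
# centerline machinery


def _sample_centerline(control_points: np.ndarray, step: float) -> np.ndarray:
    """Densely sample a natural cubic spline through the control points at
    roughly ``step`` mm arc-length spacing."""
    cp = np.asarray(control_points, dtype=np.float64)
    if cp.shape[0] == 2:
        # straight segment: exact
        length = np.linalg.norm(cp[1] - cp[0])
        n = max(int(np.ceil(length / step)) + 1, 2)
        t = np.linspace(0.0, 1.0, n)[:, None]
        return cp[0] + t * (cp[1] - cp[0])
    chord = np.linalg.norm(np.diff(cp, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(u, cp, axis=0)
    # oversample, then re-parameterize by arc length
    dense_u = np.linspace(0.0, u[-1], max(int(u[-1] / (0.2 * step)), 50))
    dense = spline(dense_u)
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(np.ceil(arc[-1] / step)) + 1, 2)
    targets = np.linspace(0.0, arc[-1], n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(targets, arc, dense[:, k])
    return out


def _parallel_transport_frames(centerline: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normal/binormal frames along a polyline, rotation-minimizing so that
    constant-offset copies stay smooth (no frame flips at inflections)."""
    tangents = np.gradient(centerline, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    n = np.zeros_like(tangents)
    # initial normal: anything perpendicular to the first tangent
    t0 = tangents[0]
    trial = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(trial, t0)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    n[0] = trial - np.dot(trial, t0) * t0
    n[0] /= np.linalg.norm(n[0])
    for i in range(1, len(tangents)):
        v = n[i - 1] - np.dot(n[i - 1], tangents[i]) * tangents[i]
        norm = np.linalg.norm(v)
        if norm < 1e-12:  # degenerate: re-seed
            v = np.cross(tangents[i], n[i - 1])
            norm = np.linalg.norm(v)
        n[i] = v / norm
    b = np.cross(tangents, n)
    return n, b


def _disk_offsets(rng: np.random.Generator, n: int, radius: float, profile: str) -> np.ndarray:
    """(n, 2) cross-section offsets; the first streamline sits on the axis."""
    if radius == 0 or n == 1:
        return np.zeros((n, 2))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    if profile == "disk":
        r = radius * np.sqrt(rng.uniform(0, 1, size=n))
    elif profile == "gaussian":
        r = np.abs(rng.normal(0, radius / 2.0, size=n)).clip(max=radius)
    else:
        raise ValueError(f"unknown profile {profile!r}")
    out = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    out[0] = 0.0  # keep one streamline exactly on the centerline
    return out


def _mask_from_points(points: np.ndarray, grid_shape, voxel_size: float,
                      name: str) -> np.ndarray:
    vox = point_to_voxel(points, voxel_size)
    if np.any(vox < 0) or np.any(vox >= np.asarray(grid_shape)):
        raise ValueError(f"bundle {name!r} exits the grid {grid_shape}")
    mask = np.zeros(grid_shape, dtype=bool)
    mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    return mask


def subdivide_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Insert points so no segment exceeds ``step`` mm, keeping all vertices.

    This is the canonical sampling used for voxel-traversal tests; masks and
    overlap scoring share it so that a bundle's own reference streamlines
    traverse exactly the bundle mask.
    """
    pts = np.asarray(points, dtype=np.float64)
    out = [pts[:1]]
    for a, b in zip(pts[:-1], pts[1:]):
        n = max(int(np.ceil(np.linalg.norm(b - a) / step)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[1:, None]
        out.append(a + t * (b - a))
    return np.vstack(out)


def traversed_voxel_mask(streamlines, voxel_size: float, grid_shape,
                         step: float, clip: bool = True) -> np.ndarray:
    """Boolean volume of voxels visited by any streamline.

    Segments are subdivided at ``step`` mm (vertices preserved); with
    ``clip`` points outside the grid are ignored rather than an error.
    """
    vol = np.zeros(grid_shape, dtype=bool)
    shape = np.asarray(grid_shape)
    for s in streamlines:
        vox = point_to_voxel(subdivide_polyline(s, step), voxel_size)
        if clip:
            keep = np.all((vox >= 0) & (vox < shape), axis=1)
            vox = vox[keep]
        vol[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    return vol


def _euclidean_dilate(mask: np.ndarray, radius_vox: float) -> np.ndarray:
    """Dilate a boolean volume by a euclidean ball of the given voxel radius."""
    if radius_vox <= 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask)
    return dist <= radius_vox + 1e-9


def build_bundle(
    geometry: BundleGeometry,
    seed: int,
    grid_shape,
    voxel_size: float,
    endpoint_dilation_radius: float = 1.0,
    sample_step: float | None = None,
) -> GroundTruthBundle:
    """Realize a bundle geometry as reference streamlines plus voxel masks.

    Streamlines are constant offsets of the splined centerline inside the
    cross-section disk, carried along a rotation-minimizing frame so they stay
    smooth.  The bundle mask is the set of voxels traversed by at least one
    reference streamline (half-open cube rule); head/tail masks are euclidean
    dilations of the first/last streamline points.
    """
    rng = np.random.default_rng(seed)
    step = sample_step if sample_step is not None else voxel_size / 4.0
    centerline = _sample_centerline(geometry.control_points, step)
    normals, binormals = _parallel_transport_frames(centerline)
    offsets = _disk_offsets(rng, geometry.n_streamlines, geometry.radius,
                            geometry.profile)
    refs = []
    for a, b in offsets:
        pts = centerline + a * normals + b * binormals
        refs.append(as_streamline(pts))
    all_points = np.vstack(refs)
    _mask_from_points(all_points, grid_shape, voxel_size, geometry.name)  # bounds check
    mask = traversed_voxel_mask(refs, voxel_size, grid_shape, step=step,
                                clip=False)
    heads = np.array([s[0] for s in refs])
    tails = np.array([s[-1] for s in refs])
    head_mask = _euclidean_dilate(
        _mask_from_points(heads, grid_shape, voxel_size, geometry.name),
        endpoint_dilation_radius)
    tail_mask = _euclidean_dilate(
        _mask_from_points(tails, grid_shape, voxel_size, geometry.name),
        endpoint_dilation_radius)
    if np.any(head_mask & tail_mask):
        raise ValueError(
            f"bundle {geometry.name!r}: head and tail endpoint regions overlap; "
            "increase bundle length or reduce endpoint_dilation_radius")
    return GroundTruthBundle(
        name=geometry.name,
        reference_streamlines=refs,
        mask=mask,
        head_mask=head_mask,
        tail_mask=tail_mask,
        recognition_threshold=geometry.recognition_threshold,
    )


# ---------------------------------------------------------------------------
# orientation-field assembly


def _cluster_directions(dirs: np.ndarray, weights: np.ndarray,
                        merge_deg: float, max_peaks: int,
                        context: str = "") -> tuple[np.ndarray, np.ndarray]:
    """Greedy sign-invariant clustering of unit directions.

    Directions closer than ``merge_deg`` (modulo sign) to an existing cluster
    mean are folded into it; otherwise they found a new cluster.  If more than
    ``max_peaks`` clusters emerge, the lowest-weight ones are merged into
    their nearest neighbour with a warning — this is exactly the limited
    angular resolution that turns several bundles into one signal peak.
    """
    cos_tol = np.cos(np.deg2rad(merge_deg))
    means: list[np.ndarray] = []  # weighted direction sums (sign-aligned)
    wsums: list[float] = []
    for d, w in zip(dirs, weights):
        best_j, best_cos = -1, -1.0
        for j, m in enumerate(means):
            c = abs(float(np.dot(d, m) / np.linalg.norm(m)))
            if c > best_cos:
                best_j, best_cos = j, c
        if best_j >= 0 and best_cos >= cos_tol:
            m = means[best_j]
            sign = 1.0 if np.dot(d, m) >= 0 else -1.0
            means[best_j] = m + sign * w * d
            wsums[best_j] += w
        else:
            means.append(w * d.copy())
            wsums.append(w)
    while len(means) > max_peaks:
        j_small = int(np.argmin(wsums))
        d_small = means[j_small] / np.linalg.norm(means[j_small])
        best_j, best_cos = -1, -1.0
        for j, m in enumerate(means):
            if j == j_small:
                continue
            c = abs(float(np.dot(d_small, m) / np.linalg.norm(m)))
            if c > best_cos:
                best_j, best_cos = j, c
        sign = 1.0 if np.dot(means[j_small], means[best_j]) >= 0 else -1.0
        means[best_j] = means[best_j] + sign * means[j_small]
        wsums[best_j] += wsums[j_small]
        del means[j_small], wsums[j_small]
        warnings.warn(
            f"more direction clusters than max_peaks={max_peaks}{context}; "
            "merged lowest-fraction cluster", stacklevel=2)
    peaks = np.array([m / np.linalg.norm(m) for m in means])
    w = np.asarray(wsums, dtype=np.float64)
    return peaks, w / w.sum()


def assemble_phantom(spec: PhantomSpec) -> tuple[OrientationField, list[GroundTruthBundle]]:
    """Build all bundles and derive the voxel-wise orientation field.

    Each reference-streamline segment votes its direction into the voxel
    containing its midpoint; per voxel the votes are collapsed into at most
    ``max_peaks`` sign-invariant direction clusters (peaks), with fractions
    proportional to vote counts.  Voxels holding at least one peak are white
    matter and receive the configured intra/inter-axonal split; a one-voxel
    shell around white matter is grey matter, a two-voxel shell beyond that
    is CSF, and the rest of the grid is background air (zero signal), which
    doubles as the noise-estimation region.  Deterministic given
    ``spec.rng_seed``.
    """
    bundles = [
        build_bundle(g, seed=spec.rng_seed + 1000 * i,
                     grid_shape=spec.grid_shape, voxel_size=spec.voxel_size,
                     endpoint_dilation_radius=spec.endpoint_dilation_radius)
        for i, g in enumerate(spec.bundles)
    ]
    shape = spec.grid_shape
    nb = len(bundles)
    # directions are voted at the same subdivided points that define the
    # bundle masks, so every mask voxel receives at least one vote
    step = spec.voxel_size / 4.0
    votes: dict[tuple[int, int, int], list] = {}
    for bi, bundle in enumerate(bundles):
        for s in bundle.reference_streamlines:
            pts = subdivide_polyline(s, step)
            seg = np.diff(pts, axis=0)
            seg /= np.linalg.norm(seg, axis=1, keepdims=True)
            # per-point direction: adjacent segment (last point reuses the
            # final segment)
            dirs = np.vstack([seg, seg[-1]])
            vox = point_to_voxel(pts, spec.voxel_size)
            for (i, j, k), d in zip(map(tuple, vox), dirs):
                votes.setdefault((i, j, k), []).append((d, bi))

    K = spec.max_peaks
    peaks = np.zeros(shape + (K, 3))
    peak_fractions = np.zeros(shape + (K,))
    tissue = np.zeros(shape + (4,))
    bundle_map = np.zeros(shape + (nb,), dtype=bool)
    for (i, j, k), entries in votes.items():
        dirs = np.array([e[0] for e in entries])
        bids = [e[1] for e in entries]
        p, f = _cluster_directions(dirs, np.ones(len(dirs)),
                                   spec.angular_merge_deg, K,
                                   context=f" in voxel {(i, j, k)}")
        n = len(p)
        peaks[i, j, k, :n] = p
        peak_fractions[i, j, k, :n] = f  # sums to fiber fraction 1.0
        for bi in set(bids):
            bundle_map[i, j, k, bi] = True
    wm = peak_fractions.sum(axis=-1) > 0
    gm = ndimage.binary_dilation(wm, iterations=1) & ~wm
    csf = ndimage.binary_dilation(wm | gm, iterations=2) & ~wm & ~gm
    tissue[wm, 0] = spec.intra_axonal_fraction
    tissue[wm, 1] = 1.0 - spec.intra_axonal_fraction
    tissue[gm, 2] = 1.0
    tissue[csf, 3] = 1.0
    # remaining voxels are background air: all tissue fractions zero
    field = OrientationField(
        peaks=peaks,
        peak_fractions=peak_fractions,
        tissue_fractions=tissue,
        affine=spec.affine,
        voxel_size=spec.voxel_size,
        bundle_map=bundle_map,
    )
    return field, bundles


def white_matter_mask(field: OrientationField) -> np.ndarray:
    """Boolean volume of voxels carrying at least one fiber peak."""
    return field.peak_fractions.sum(axis=-1) > 0


# ---------------------------------------------------------------------------
# shipped fixtures


def _bottleneck_pair(z: float, thr: float = 7.0, radius: float = 3.0,
                     n_streamlines: int = 25) -> list[BundleGeometry]:
    """Two bundles sharing a straight corridor (x in [32, 48] mm, y = 40).

    Arm angles are deliberately asymmetric: entering the corridor travelling
    -x the shallowest continuation is funnel_b's near arm, travelling +x it is
    funnel_a's far arm.  A straightest-path tracker therefore reconstructs
    both true bundles *and* the spurious head(b)-tail(a) combination — the
    bottleneck ambiguity in miniature.
    """
    a = BundleGeometry(
        name="funnel_a",
        control_points=[(10, 62, z), (22, 52, z), (32, 40, z),
                        (48, 40, z), (62, 34, z), (72, 30, z)],
        radius=radius, n_streamlines=n_streamlines,
        recognition_threshold=thr,
    )
    b = BundleGeometry(
        name="funnel_b",
        control_points=[(10, 28, z), (24, 35, z), (32, 40, z),
                        (48, 40, z), (58, 52, z), (68, 64, z)],
        radius=radius, n_streamlines=n_streamlines,
        recognition_threshold=thr,
    )
    return [a, b]


def canonical_phantom(rng_seed: int = 0) -> PhantomSpec:
    """The canonical 5-bundle fixture: 40^3 voxels at 2 mm (80 mm box).

    Contains an orthogonal crossing (two straight bundles at z = 60 mm), a
    curved arc bundle (z = 40 mm) and a two-bundle bottleneck (z = 20 mm).
    """
    bundles = [
        BundleGeometry("straight_x", [(8, 40, 60), (72, 40, 60)],
                       radius=4.0, recognition_threshold=5.0),
        BundleGeometry("straight_y", [(40, 8, 60), (40, 72, 60)],
                       radius=4.0, recognition_threshold=5.0),
        BundleGeometry("arc", [(16, 12, 40), (28, 32, 40), (40, 38, 40),
                               (52, 32, 40), (64, 12, 40)],
                       radius=4.0, recognition_threshold=7.0),
    ] + _bottleneck_pair(z=20.0)
    return PhantomSpec(grid_shape=(40, 40, 40), voxel_size=2.0,
                       bundles=bundles, rng_seed=rng_seed)


def bottleneck_phantom(rng_seed: int = 0) -> PhantomSpec:
    """Minimal two-bundle bottleneck fixture on a 40 x 40 x 12 grid (2 mm)."""
    return PhantomSpec(grid_shape=(40, 40, 12), voxel_size=2.0,
                       bundles=_bottleneck_pair(z=12.0), rng_seed=rng_seed)
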