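"""Streamline data model, TCK/TRK I/O, resampling, shape distance and clustering.

A streamline is a polyline reconstruction of a putative white-matter fiber
trajectory, stored as an ``(n, 3)`` float array of world-space coordinates in
millimetres.  Everything downstream (phantom bundles, tracking output,
evaluation) speaks this representation.

The shape distance used throughout is the minimum-direct-flip (MDF) distance:
both streamlines are resampled to the same number of points and the mean
pointwise Euclidean distance is taken for the direct and the reversed point
order, keeping the smaller of the two.  It is a pseudometric on streamlines
modulo traversal direction, which is the natural equivalence for tractography
(a fiber has no preferred direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
from nibabel import streamlines as nib_streamlines

__all__ = [
    "as_streamline",
    "streamline_length",
    "resample_streamline",
    "mdf_distance",
    "StreamlineCluster",
    "quickbundles",
    "Tractogram",
    "read_tractogram",
    "write_tractogram",
]

#: default number of points streamlines are resampled to for shape distances
DEFAULT_N_POINTS = 12


def as_streamline(points) -> np.ndarray:
    """Validate and return a streamline as an ``(n, 3)`` float64 array.

    Raises ``ValueError`` for fewer than two points, non-finite coordinates,
    repeated consecutive points or zero total length.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"streamline must be (n, 3), got shape {pts.shape}")
    if pts.shape[0] < 2:
        raise ValueError("streamline needs at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("streamline contains non-finite coordinates")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0.0):
        raise ValueError("streamline has repeated consecutive points")
    return pts


def streamline_length(s) -> float:
    """Polyline length in mm (sum of segment lengths)."""
    pts = np.asarray(s, dtype=np.float64)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def resample_streamline(s, n_points: int) -> np.ndarray:
    """Resample a streamline to ``n_points`` equally spaced by arc length.

    Endpoints are preserved exactly.  Interior points are linearly
    interpolated along the original polyline.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    pts = as_streamline(s)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0.0:
        raise ValueError("cannot resample a zero-length streamline")
    targets = np.linspace(0.0, total, n_points)
    out = np.empty((n_points, 3))
    for k in range(3):
        out[:, k] = np.interp(targets, arc, pts[:, k])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def _mdf_pair(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """MDF of two already-resampled equal-length streamlines.

    Returns ``(distance, flipped)`` where ``flipped`` says whether the
    reversed orientation of ``b`` was the closer one.
    """
    direct = float(np.mean(np.linalg.norm(a - b, axis=1)))
    flipped = float(np.mean(np.linalg.norm(a - b[::-1], axis=1)))
    if flipped < direct:
        return flipped, True
    return direct, False


def mdf_distance(s1, s2, n_points: int = DEFAULT_N_POINTS) -> float:
    """Minimum-direct-flip distance between two streamlines, in mm.

    Symmetric, non-negative, and invariant to reversing the point order of
    either streamline.
    """
    a = resample_streamline(s1, n_points)
    b = resample_streamline(s2, n_points)
    return _mdf_pair(a, b)[0]


@dataclass
class StreamlineCluster:
    """A cluster of streamlines with a running-mean centroid.

    ``centroid`` has exactly the resampling point count used by the
    clustering; members are stored as indices into the clustered sequence.
    """

    member_indices: list[int]
    centroid: np.ndarray

    def __len__(self) -> int:
        return len(self.member_indices)


def quickbundles(
    streamlines,
    threshold: float,
    n_points: int = DEFAULT_N_POINTS,
) -> list[StreamlineCluster]:
    """Single-pass centroid clustering of streamlines under the MDF distance.

    Streamlines are visited in input order.  Each one is assigned to the
    nearest existing cluster whose centroid lies within ``threshold`` mm (MDF),
    flip-aligned, and the centroid is updated as the running mean of the
    aligned resampled members; otherwise it founds a new cluster.  The result
    therefore depends on input order, which is fixed to the given order.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    sums: list[np.ndarray] = []
    clusters: list[StreamlineCluster] = []
    for idx, s in enumerate(streamlines):
        r = resample_streamline(s, n_points)
        best_j, best_d, best_flip = -1, np.inf, False
        for j, cl in enumerate(clusters):
            d, flip = _mdf_pair(cl.centroid, r)
            if d < best_d:
                best_j, best_d, best_flip = j, d, flip
        if best_j >= 0 and best_d <= threshold:
            cl = clusters[best_j]
            sums[best_j] += r[::-1] if best_flip else r
            cl.member_indices.append(idx)
            cl.centroid = sums[best_j] / len(cl.member_indices)
        else:
            clusters.append(StreamlineCluster([idx], r.copy()))
            sums.append(r.copy())
    return clusters


@dataclass
class Tractogram:
    """A collection of streamlines in world (mm) coordinates.

    ``affine`` is the grid-to-world transform of the reference image grid the
    streamlines relate to (identity when there is none); ``space_tag`` records
    the coordinate convention of the source file, purely informational —
    streamlines are always world mm after loading.
    """

    streamlines: list[np.ndarray]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    space_tag: str = "rasmm"

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


def _check_format(path: str, fmt: str | None) -> str:
    if fmt is None:
        fmt = str(path).rsplit(".", 1)[-1].lower()
    fmt = fmt.lower().lstrip(".")
    if fmt not in ("tck", "trk"):
        raise ValueError(f"unknown tractogram format {fmt!r}; expected 'tck' or 'trk'")
    return fmt


def read_tractogram(path, fmt: str | None = None) -> Tractogram:
    """Load a TCK or TRK file; streamlines come back in world (RAS mm) space.

    TRK voxel/voxmm coordinates are converted to world mm using the header
    affine, so both dialects look identical to callers.
    """
    fmt = _check_format(path, fmt)
    try:
        tf = nib_streamlines.load(str(path))
    except Exception as exc:  # malformed header etc.
        raise IOError(f"failed to read {fmt.upper()} file {path}: {exc}") from exc
    sls = [np.asarray(s, dtype=np.float64) for s in tf.streamlines]
    affine = np.asarray(tf.tractogram.affine_to_rasmm, dtype=np.float64)
    return Tractogram(streamlines=sls, affine=np.eye(4), space_tag=fmt)


def write_tractogram(t: Tractogram, path, fmt: str | None = None,
                     reference_shape=None, voxel_size: float | None = None) -> None:
    """Write a tractogram to TCK or TRK.

    Streamlines are assumed to be in world mm already.  For TRK, a header is
    synthesised from ``t.affine`` (plus ``reference_shape``/``voxel_size``
    when given) so that round-tripping preserves world coordinates.
    """
    fmt = _check_format(path, fmt)
    sls = [np.asarray(s, dtype=np.float64) for s in t.streamlines]
    nt = nib_streamlines.Tractogram(sls, affine_to_rasmm=np.eye(4))
    if fmt == "tck":
        nib_streamlines.save(nt, str(path))
        return
    header = nib_streamlines.trk.TrkFile.create_empty_header()
    affine = np.asarray(t.affine, dtype=np.float64)
    header["voxel_to_rasmm"] = affine.astype(np.float32)
    zooms = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    if voxel_size is not None:
        zooms = np.full(3, float(voxel_size))
    header["voxel_sizes"] = zooms.astype(np.float32)
    if reference_shape is not None:
        header["dimensions"] = np.asarray(reference_shape, dtype=np.int16)
    header["voxel_order"] = "".join(nib.orientations.aff2axcodes(affine)).encode()
    nib_streamlines.save(nt, str(path), header=header)
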