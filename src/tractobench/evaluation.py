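"""Tractometer-style scoring of tractograms against ground-truth bundles.

A submitted tractogram is partitioned into

* **valid connections (VC)** — streamlines recognized as members of a
  ground-truth bundle by shape distance (MDF to the bundle's reference
  streamlines, against a bundle-specific threshold in mm);
* **invalid connections (IC)** — coherent clusters of unrecognized
  streamlines connecting a pair of endpoint regions that is *not* a
  ground-truth pair (each distinct pair counted as one invalid bundle, IB);
* **non-connecting (NC)** — too short, or not reaching any endpoint region.

From the partition the challenge metrics follow: VC ratio, valid-bundle
count (VB), invalid-bundle count (IB), per-bundle volumetric overlap (OL)
and overreach (OR), bundle-level precision / recall / specificity, and an
endpoint-region connectivity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .phantom import (GroundTruthBundle, point_to_voxel, subdivide_polyline,
                      traversed_voxel_mask)
from .streamlines import (
    DEFAULT_N_POINTS,
    Tractogram,
    quickbundles,
    resample_streamline,
    streamline_length,
)

__all__ = [
    "EvaluationConfig",
    "ClassifiedTractogram",
    "EvaluationReport",
    "recognize_valid",
    "classify_invalid",
    "overlap_overreach",
    "strict_vc",
    "count_potential_pairs",
    "evaluate",
]


@dataclass
class EvaluationConfig:
    """Evaluator knobs.

    ``capture_radius`` is how far (mm) a terminal point may sit from an
    endpoint region and still be captured by it; ``qb_threshold`` is the MDF
    threshold used to cluster unrecognized streamlines; ``min_length`` sends
    shorter streamlines straight to non-connecting.
    """

    n_points: int = DEFAULT_N_POINTS
    capture_radius: float = 5.0  # mm
    qb_threshold: float = 10.0  # mm
    min_length: float = 10.0  # mm
    traversal_step: float | None = None  # mm; default voxel_size / 4
    voxel_size: float = 2.0


@dataclass
class ClassifiedTractogram:
    """Per-streamline partition labels plus the config that produced them.

    ``kind[i]`` is 'valid', 'invalid' or 'non_connecting'; ``bundle_idx[i]``
    is the assigned bundle for valid streamlines (-1 otherwise),
    ``cluster_idx[i]`` the invalid-cluster id (-1 otherwise).  Each invalid
    cluster carries an unordered endpoint-region pair that is not a
    ground-truth pair.
    """

    kind: np.ndarray
    bundle_idx: np.ndarray
    cluster_idx: np.ndarray
    invalid_pairs: list[tuple[int, int]]
    config: EvaluationConfig


@dataclass
class EvaluationReport:
    """All challenge metrics for one tractogram (percentages 0-100)."""

    n_streamlines: int
    vc_ratio: float
    ic_ratio: float
    nc_ratio: float
    vb_count: int
    ib_count: int
    n_bundles: int
    per_bundle: pd.DataFrame  # name, n_valid, overlap, overreach
    precision: float
    recall: float
    specificity: float
    connectivity_matrix: pd.DataFrame
    classification: ClassifiedTractogram | None = None

    @property
    def mean_overlap(self) -> float:
        return float(self.per_bundle["overlap"].mean())

    @property
    def mean_overreach(self) -> float:
        return float(self.per_bundle["overreach"].mean())

    def to_dict(self) -> dict:
        return {
            "n_streamlines": self.n_streamlines,
            "vc_ratio": self.vc_ratio,
            "ic_ratio": self.ic_ratio,
            "nc_ratio": self.nc_ratio,
            "vb_count": self.vb_count,
            "ib_count": self.ib_count,
            "n_bundles": self.n_bundles,
            "mean_overlap": self.mean_overlap,
            "mean_overreach": self.mean_overreach,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "per_bundle": self.per_bundle.to_dict(orient="records"),
        }

    def summary(self) -> str:
        lines = [
            f"streamlines: {self.n_streamlines}",
            f"VC ratio: {self.vc_ratio:.1f}%  IC: {self.ic_ratio:.1f}%  "
            f"NC: {self.nc_ratio:.1f}%",
            f"VB: {self.vb_count}/{self.n_bundles}   IB: {self.ib_count}",
            f"mean OL: {self.mean_overlap:.1f}%  mean OR: {self.mean_overreach:.1f}%",
            f"precision: {self.precision:.1f}%  recall: {self.recall:.1f}%  "
            f"specificity: {self.specificity:.1f}%",
        ]
        return "\n".join(lines)


def count_potential_pairs(n_bundles: int) -> tuple[int, int]:
    """Endpoint-region pair counting.

    ``n`` bundles have ``2n`` endpoint regions; unordered pairs including
    region self-pairs number ``C(2n, 2) + 2n``.  Removing the ``n``
    ground-truth head-tail pairs leaves the potential invalid bundles.
    For 25 bundles: 1275 total, 1250 potential IBs.
    """
    if n_bundles < 0:
        raise ValueError("n_bundles must be >= 0")
    if n_bundles == 0:
        return 0, 0
    r = 2 * n_bundles
    total = r * (r - 1) // 2 + r
    return total, total - n_bundles


# ---------------------------------------------------------------------------
# valid-connection recognition


def _resampled_array(streamlines, n_points: int) -> np.ndarray:
    return np.array([resample_streamline(s, n_points) for s in streamlines])


def _mdf_matrix(cands: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """(n_cand, n_ref) MDF distances between resampled streamline arrays."""
    direct = np.sqrt(
        ((cands[:, None, :, :] - refs[None, :, :, :]) ** 2).sum(-1)
    ).mean(-1)
    flipped = np.sqrt(
        ((cands[:, None, :, :] - refs[None, :, ::-1, :]) ** 2).sum(-1)
    ).mean(-1)
    return np.minimum(direct, flipped)


def streamline_bundle_distances(
    streamlines,
    bundles: list[GroundTruthBundle],
    n_points: int = DEFAULT_N_POINTS,
    chunk: int = 256,
) -> np.ndarray:
    """(n_streamlines, n_bundles) matrix of min-over-references MDF distances.

    Candidates are processed in chunks to bound the memory of the pairwise
    distance tensor; the result is the exact minimum over each bundle's
    reference streamlines.
    """
    cands = _resampled_array(streamlines, n_points)
    if len(cands) == 0:
        return np.zeros((0, len(bundles)))
    out = np.empty((len(cands), len(bundles)))
    for bi, b in enumerate(bundles):
        refs = _resampled_array(b.reference_streamlines, n_points)
        for lo in range(0, len(cands), chunk):
            sl = slice(lo, min(lo + chunk, len(cands)))
            out[sl, bi] = _mdf_matrix(cands[sl], refs).min(axis=1)
    return out


def recognize_valid(
    tractogram,
    bundles: list[GroundTruthBundle],
    config: EvaluationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each streamline to at most one ground-truth bundle by shape.

    A streamline's distance to a bundle is the minimum MDF over that bundle's
    reference streamlines.  It is assigned to the closest bundle among those
    whose distance is within the bundle-specific recognition threshold; ties
    are broken by the lower bundle index.  Returns ``(assignment, distance)``
    where ``assignment[i]`` is the bundle index or -1, and ``distance[i]``
    the distance to that bundle (or the overall minimum when unassigned).
    Invariant under point-order reversal of any streamline (MDF property).
    """
    if config is None:
        config = EvaluationConfig()
    if not bundles:
        raise ValueError("need at least one ground-truth bundle")
    sls = list(tractogram)
    if len(sls) == 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0)
    dmat = streamline_bundle_distances(sls, bundles, config.n_points)
    thresholds = np.array([b.recognition_threshold for b in bundles])
    within = dmat <= thresholds[None, :]
    masked = np.where(within, dmat, np.inf)
    best = np.argmin(masked, axis=1)  # argmin takes lowest index on ties
    assignment = np.where(within.any(axis=1), best, -1)
    distance = np.where(assignment >= 0,
                        dmat[np.arange(len(sls)), best],
                        dmat.min(axis=1))
    return assignment.astype(np.int64), distance


# ---------------------------------------------------------------------------
# endpoint regions and invalid-connection clustering


class _RegionIndex:
    """Spatial lookup from a terminal point to an endpoint region id.

    Region ids: bundle ``i`` has head ``2i`` and tail ``2i + 1``.  A point is
    captured by the region whose voxel set contains (or is nearest to, within
    the capture radius) the point's voxel center.
    """

    def __init__(self, bundles: list[GroundTruthBundle], voxel_size: float,
                 capture_radius: float):
        self.voxel_size = voxel_size
        self.capture_radius = capture_radius
        coords = []
        labels = []
        for i, b in enumerate(bundles):
            for rid, m in ((2 * i, b.head_mask), (2 * i + 1, b.tail_mask)):
                vox = np.argwhere(m)
                coords.append((vox + 0.5) * voxel_size)
                labels.append(np.full(len(vox), rid))
        self.coords = np.vstack(coords)
        self.labels = np.concatenate(labels)
        self.tree = cKDTree(self.coords)
        # max distance from any point in a voxel to its center
        self._halfdiag = voxel_size * np.sqrt(3) / 2.0

    def capture(self, points: np.ndarray) -> np.ndarray:
        """Region id per point, -1 when nothing is within the capture radius."""
        if len(points) == 0:
            return np.zeros(0, dtype=np.int64)
        r = self.capture_radius + self._halfdiag
        dist, idx = self.tree.query(points, distance_upper_bound=r)
        out = np.full(len(points), -1, dtype=np.int64)
        hit = np.isfinite(dist)
        # inside-the-region voxels always capture; outside ones only within
        # capture_radius of the voxel cube (center distance minus half-diag)
        ok = hit & (dist <= self.capture_radius + self._halfdiag)
        out[ok] = self.labels[idx[ok]]
        return out


def classify_invalid(
    tractogram,
    assignment: np.ndarray,
    bundles: list[GroundTruthBundle],
    config: EvaluationConfig | None = None,
) -> ClassifiedTractogram:
    """Partition unrecognized streamlines into invalid clusters and NC.

    Unrecognized streamlines above the length threshold are clustered with
    QuickBundles; each cluster's endpoint-region pair is decided by majority
    vote of its members' captured terminal regions, and clusters voting the
    same pair are merged.  Clusters whose pair *is* a ground-truth head-tail
    pair are re-examined against that bundle's recognition threshold (members
    within it become valid); the rest of their members are non-connecting, so
    every surviving invalid cluster connects a pair absent from ground truth.
    """
    if config is None:
        config = EvaluationConfig()
    sls = list(tractogram)
    n = len(sls)
    kind = np.array(["non_connecting"] * n, dtype=object)
    bundle_idx = np.asarray(assignment, dtype=np.int64).copy()
    cluster_idx = np.full(n, -1, dtype=np.int64)
    kind[bundle_idx >= 0] = "valid"

    region_index = _RegionIndex(bundles, config.voxel_size, config.capture_radius)
    gt_pairs = {(2 * i, 2 * i + 1) for i in range(len(bundles))}

    cand = [i for i in range(n) if bundle_idx[i] < 0]
    long_enough = [i for i in cand
                   if streamline_length(sls[i]) >= config.min_length]
    if not long_enough:
        return ClassifiedTractogram(kind, bundle_idx, cluster_idx, [], config)

    starts = np.array([sls[i][0] for i in long_enough])
    ends = np.array([sls[i][-1] for i in long_enough])
    r_start = region_index.capture(starts)
    r_end = region_index.capture(ends)
    captured = (r_start >= 0) & (r_end >= 0)
    clusterable = [i for i, c in zip(long_enough, captured) if c]
    pair_of = {
        i: tuple(sorted((int(a), int(b))))
        for i, a, b, c in zip(long_enough, r_start, r_end, captured) if c
    }
    if not clusterable:
        return ClassifiedTractogram(kind, bundle_idx, cluster_idx, [], config)

    clusters = quickbundles([sls[i] for i in clusterable],
                            threshold=config.qb_threshold,
                            n_points=config.n_points)
    # majority vote per cluster, then merge clusters sharing a pair
    merged: dict[tuple[int, int], list[int]] = {}
    for cl in clusters:
        members = [clusterable[j] for j in cl.member_indices]
        votes: dict[tuple[int, int], int] = {}
        for i in members:
            votes[pair_of[i]] = votes.get(pair_of[i], 0) + 1
        pair = max(sorted(votes), key=lambda p: votes[p])
        merged.setdefault(pair, []).extend(members)

    invalid_pairs: list[tuple[int, int]] = []
    for pair, members in sorted(merged.items()):
        if pair in gt_pairs:
            # re-examine against the matching bundle's threshold
            bi = pair[0] // 2
            b = bundles[bi]
            d = streamline_bundle_distances([sls[i] for i in members], [b],
                                            config.n_points)[:, 0]
            for i, di in zip(members, d):
                if di <= b.recognition_threshold:
                    kind[i] = "valid"
                    bundle_idx[i] = bi
                # else: stays non_connecting (pair exists in ground truth,
                # shape does not match -> not a new bundle)
            continue
        cid = len(invalid_pairs)
        invalid_pairs.append(pair)
        for i in members:
            kind[i] = "invalid"
            cluster_idx[i] = cid
    return ClassifiedTractogram(kind, bundle_idx, cluster_idx, invalid_pairs,
                                config)


# ---------------------------------------------------------------------------
# volumetric scores


def _traversed_voxels(streamlines, voxel_size: float, grid_shape,
                      step: float) -> np.ndarray:
    """Boolean volume of voxels visited by any streamline.

    Shares ``traversed_voxel_mask`` with the phantom generator so that a
    bundle's reference streamlines traverse exactly the bundle mask.
    """
    return traversed_voxel_mask(streamlines, voxel_size, grid_shape, step)


def overlap_overreach(
    valid_streamlines,
    bundle: GroundTruthBundle,
    voxel_size: float,
    traversal_step: float | None = None,
) -> tuple[float, float]:
    """Volumetric overlap and overreach of a bundle's valid streamlines, in %.

    Overlap: share of the bundle-mask voxels traversed by at least one valid
    streamline.  Overreach: traversed voxels *outside* the mask, divided by
    the bundle-mask voxel count (so it can exceed 100%).  Zero valid
    streamlines give (0, 0).
    """
    n_mask = int(bundle.mask.sum())
    if n_mask == 0:
        raise ValueError(f"bundle {bundle.name!r} has an empty mask")
    valid_streamlines = list(valid_streamlines)
    if not valid_streamlines:
        return 0.0, 0.0
    step = traversal_step if traversal_step is not None else voxel_size / 4.0
    traversed = _traversed_voxels(valid_streamlines, voxel_size,
                                  bundle.mask.shape, step)
    inside = int((traversed & bundle.mask).sum())
    outside = int((traversed & ~bundle.mask).sum())
    return 100.0 * inside / n_mask, 100.0 * outside / n_mask


def strict_vc(
    tractogram,
    bundles: list[GroundTruthBundle],
    voxel_size: float,
    traversal_step: float | None = None,
) -> np.ndarray:
    """Strict valid-connection test, one boolean per streamline.

    True iff, for some bundle, every traversed voxel lies inside that
    bundle's mask *and* the two terminal points fall one in the head and one
    in the tail endpoint region.  Far stricter than shape recognition; real
    tractograms essentially never satisfy it.
    """
    step = traversal_step if traversal_step is not None else voxel_size / 4.0
    out = np.zeros(len(list(tractogram)), dtype=bool)
    sls = list(tractogram)
    shape = bundles[0].mask.shape
    for i, s in enumerate(sls):
        pts = subdivide_polyline(s, step)
        vox = point_to_voxel(pts, voxel_size)
        if np.any(vox < 0) or np.any(vox >= np.asarray(shape)):
            continue
        v_start = point_to_voxel(s[0][None, :], voxel_size)[0]
        v_end = point_to_voxel(s[-1][None, :], voxel_size)[0]
        for b in bundles:
            if not b.mask[vox[:, 0], vox[:, 1], vox[:, 2]].all():
                continue
            sh = b.head_mask[tuple(v_start)]
            st = b.tail_mask[tuple(v_start)]
            eh = b.head_mask[tuple(v_end)]
            et = b.tail_mask[tuple(v_end)]
            if (sh and et) or (st and eh):
                out[i] = True
                break
    return out


# ---------------------------------------------------------------------------
# top-level evaluation


def evaluate(
    tractogram,
    bundles: list[GroundTruthBundle],
    config: EvaluationConfig | None = None,
) -> EvaluationReport:
    """Full challenge scoring of a tractogram against ground-truth bundles."""
    if config is None:
        config = EvaluationConfig()
    sls = list(tractogram)
    n = len(sls)
    n_bundles = len(bundles)
    region_names = []
    for b in bundles:
        region_names += [f"{b.name}_head", f"{b.name}_tail"]
    conn = pd.DataFrame(np.zeros((2 * n_bundles, 2 * n_bundles), dtype=np.int64),
                        index=region_names, columns=region_names)
    if n == 0:
        per_bundle = pd.DataFrame({
            "name": [b.name for b in bundles],
            "n_valid": 0, "overlap": 0.0, "overreach": 0.0,
        })
        _, pot_ib = count_potential_pairs(n_bundles)
        return EvaluationReport(
            n_streamlines=0, vc_ratio=0.0, ic_ratio=0.0, nc_ratio=0.0,
            vb_count=0, ib_count=0, n_bundles=n_bundles,
            per_bundle=per_bundle, precision=0.0, recall=0.0,
            specificity=100.0 if pot_ib else 0.0,
            connectivity_matrix=conn, classification=None)

    assignment, _ = recognize_valid(sls, bundles, config)
    classification = classify_invalid(sls, assignment, bundles, config)
    kind = classification.kind
    bundle_idx = classification.bundle_idx

    n_vc = int((kind == "valid").sum())
    n_ic = int((kind == "invalid").sum())
    n_nc = n - n_vc - n_ic
    vb = int(len(np.unique(bundle_idx[bundle_idx >= 0])))
    ib = len(classification.invalid_pairs)

    rows = []
    for bi, b in enumerate(bundles):
        members = [sls[i] for i in np.flatnonzero((bundle_idx == bi)
                                                  & (kind == "valid"))]
        ol, orr = overlap_overreach(members, b, config.voxel_size,
                                    config.traversal_step)
        rows.append({"name": b.name, "n_valid": len(members),
                     "overlap": ol, "overreach": orr})
    per_bundle = pd.DataFrame(rows)

    total_pairs, pot_ib = count_potential_pairs(n_bundles)
    precision = 100.0 * vb / (vb + ib) if (vb + ib) else 0.0
    recall = 100.0 * vb / n_bundles if n_bundles else 0.0
    specificity = 100.0 * (pot_ib - ib) / pot_ib if pot_ib else 0.0

    # connectivity matrix: valid streamlines at their bundle's head-tail
    # pair, invalid ones at their cluster's voted pair
    for bi in range(n_bundles):
        cnt = int(((bundle_idx == bi) & (kind == "valid")).sum())
        conn.iloc[2 * bi, 2 * bi + 1] += cnt
        conn.iloc[2 * bi + 1, 2 * bi] += cnt
    for cid, pair in enumerate(classification.invalid_pairs):
        cnt = int((classification.cluster_idx == cid).sum())
        a, b_ = pair
        conn.iloc[a, b_] += cnt
        if a != b_:
            conn.iloc[b_, a] += cnt

    return EvaluationReport(
        n_streamlines=n,
        vc_ratio=100.0 * n_vc / n,
        ic_ratio=100.0 * n_ic / n,
        nc_ratio=100.0 * n_nc / n,
        vb_count=vb,
        ib_count=ib,
        n_bundles=n_bundles,
        per_bundle=per_bundle,
        precision=precision,
        recall=recall,
        specificity=specificity,
        connectivity_matrix=conn,
        classification=classification,
    )
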