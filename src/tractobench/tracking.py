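"""Deterministic streamline tractography on a ground-truth orientation field.

This is the "perfect input" experiment: the tracker never sees diffusion
data, only the per-voxel fiber peaks of the phantom definition.  From each
seed it follows the straightest available peak (maximum |cosine| with the
incoming direction, sign-aligned) in both polarities of the seed voxel's
dominant peak, stepping at a fixed length and stopping when it leaves the
tracking mask, exceeds the per-step turn limit, runs out of peaks, or hits
the length cap.  Even with perfect orientations such a tracker systematically
fabricates bundles in bottleneck regions — the effect the evaluator measures.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .phantom import OrientationField, point_to_voxel
from .streamlines import Tractogram, streamline_length

__all__ = ["TrackingConfig", "seed_from_mask", "track"]


@dataclass
class TrackingConfig:
    """Tracker parameters.

    ``step_size`` defaults to half a voxel.  ``max_angle`` is the turn limit
    in degrees for a step of half a voxel and is scaled linearly with the
    actual step size, so halving the step halves the per-step limit and the
    curvature bound is step-invariant.
    """

    step_size: float | None = None  # mm; default 0.5 * voxel size
    max_angle: float = 45.0  # degrees per half-voxel step
    seeds_per_voxel: int = 5
    min_length: float = 10.0  # mm
    max_length: float = 250.0  # mm
    interpolation: str = "nearest"  # 'nearest' | 'trilinear'
    rng_seed: int = 0

    def resolve_step(self, voxel_size: float) -> float:
        step = self.step_size if self.step_size is not None else 0.5 * voxel_size
        if not (0 < step <= voxel_size):
            raise ValueError("step_size must be in (0, voxel_size]")
        return step

    def resolve_max_angle(self, voxel_size: float) -> float:
        step = self.resolve_step(voxel_size)
        angle = self.max_angle * step / (0.5 * voxel_size)
        if not (0 < self.max_angle < 90):
            raise ValueError("max_angle must be in (0, 90)")
        return min(angle, 89.0)


def seed_from_mask(mask: np.ndarray, voxel_size: float, seeds_per_voxel: int,
                   rng_seed: int = 0) -> np.ndarray:
    """Uniformly jittered seed points (world mm) inside masked voxels.

    Returns ``(n_voxels * seeds_per_voxel, 3)``; reproducible by seed.
    """
    vox = np.argwhere(mask)
    if len(vox) == 0:
        return np.zeros((0, 3))
    rng = np.random.default_rng(rng_seed)
    rep = np.repeat(vox, seeds_per_voxel, axis=0).astype(np.float64)
    jitter = rng.uniform(0.0, 1.0, size=rep.shape)
    return (rep + jitter) * voxel_size


def _peaks_at(field: OrientationField, vox: np.ndarray):
    """Gather (K,3) peaks and (K,) fractions for integer voxel rows."""
    i, j, k = vox[:, 0], vox[:, 1], vox[:, 2]
    return field.peaks[i, j, k], field.peak_fractions[i, j, k]


def _select_direction(
    field: OrientationField,
    pos: np.ndarray,
    incoming: np.ndarray,
    cos_limit: float,
    interpolation: str,
) -> np.ndarray:
    """Vectorized straightest-peak selection for a batch of active tracks.

    Among the peaks at each position (nearest voxel, or a sign-aligned
    trilinear blend of the 8 neighbours), picks the one maximizing
    |cos(incoming, peak)|; returns NaN rows where no admissible peak exists
    (max |cos| below ``cos_limit`` or no peaks at all).
    """
    vs = field.voxel_size
    shape = np.asarray(field.grid_shape)
    if interpolation == "nearest":
        vox = point_to_voxel(pos, vs)
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        vox_c = np.clip(vox, 0, shape - 1)
        peaks, fracs = _peaks_at(field, vox_c)
    elif interpolation == "trilinear":
        # blend each neighbour's best-aligned peak, weighted by trilinear
        # weights; ties inside a voxel broken by larger peak fraction
        idx_f = pos / vs - 0.5  # continuous index of voxel centers
        base = np.floor(idx_f).astype(np.int64)
        frac_pos = idx_f - base
        blended = np.zeros_like(pos)
        weight_total = np.zeros(len(pos))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    corner = base + np.array([dx, dy, dz])
                    w = (np.where(dx, frac_pos[:, 0], 1 - frac_pos[:, 0])
                         * np.where(dy, frac_pos[:, 1], 1 - frac_pos[:, 1])
                         * np.where(dz, frac_pos[:, 2], 1 - frac_pos[:, 2]))
                    ok = np.all((corner >= 0) & (corner < shape), axis=1)
                    corner_c = np.clip(corner, 0, shape - 1)
                    pk, pf = _peaks_at(field, corner_c)
                    cos = np.einsum("nkd,nd->nk", pk, incoming)
                    has = pf > 0
                    score = np.where(has, np.abs(cos), -1.0) + 1e-9 * pf
                    best = np.argmax(score, axis=1)
                    rows = np.arange(len(pos))
                    d = pk[rows, best] * np.sign(cos[rows, best] + 1e-300)[:, None]
                    valid = ok & has[rows, best]
                    blended += np.where(valid[:, None], w[:, None] * d, 0.0)
                    weight_total += np.where(valid, w, 0.0)
        norm = np.linalg.norm(blended, axis=1)
        out = np.full_like(pos, np.nan)
        good = (weight_total > 1e-9) & (norm > 1e-9)
        out[good] = blended[good] / norm[good, None]
        cos_out = np.einsum("nd,nd->n", np.nan_to_num(out), incoming)
        out[np.abs(cos_out) < cos_limit] = np.nan
        return out
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")

    cos = np.einsum("nkd,nd->nk", peaks, incoming)  # (n, K)
    has = fracs > 0
    score = np.where(has, np.abs(cos), -1.0) + 1e-9 * fracs  # frac tie-break
    best = np.argmax(score, axis=1)
    rows = np.arange(len(pos))
    best_cos = cos[rows, best]
    direction = peaks[rows, best] * np.sign(best_cos + 1e-300)[:, None]
    bad = (~inside) | (~has[rows, best]) | (np.abs(best_cos) < cos_limit)
    direction[bad] = np.nan
    return direction


def _half_tracks(field, mask, pos0, dir0, step, cos_limit, max_steps,
                 interpolation):
    """March a batch of half-tracks; returns per-track point lists."""
    n = len(pos0)
    vs = field.voxel_size
    shape = np.asarray(field.grid_shape)
    points = [[p.copy()] for p in pos0]
    pos = pos0.copy()
    direction = dir0.copy()
    alive = np.ones(n, dtype=bool)
    for _ in range(max_steps):
        if not alive.any():
            break
        nxt = pos[alive] + step * direction[alive]
        vox = point_to_voxel(nxt, vs)
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        vox_c = np.clip(vox, 0, shape - 1)
        in_mask = inside & mask[vox_c[:, 0], vox_c[:, 1], vox_c[:, 2]]
        idx_alive = np.flatnonzero(alive)
        stopped = idx_alive[~in_mask]
        alive[stopped] = False
        moved = idx_alive[in_mask]
        if len(moved) == 0:
            continue
        pos[moved] = nxt[in_mask]
        for i in moved:
            points[i].append(pos[i].copy())
        new_dir = _select_direction(field, pos[moved], direction[moved],
                                    cos_limit, interpolation)
        dead = np.isnan(new_dir[:, 0])
        direction[moved] = np.where(dead[:, None], direction[moved], new_dir)
        alive[moved[dead]] = False
    return points


def track(field: OrientationField, mask: np.ndarray, config: TrackingConfig,
          seed_mask: np.ndarray | None = None) -> Tractogram:
    """Deterministic peak tracking from jittered seeds.

    Seeds are drawn from ``seed_mask`` (default: the tracking ``mask``); each
    launches both polarities of its voxel's largest-fraction peak and the two
    half-tracks are concatenated.  Propagation terminates on leaving ``mask``.
    Streamlines shorter than ``min_length`` or longer than ``max_length`` are
    discarded.
    """
    vs = field.voxel_size
    step = config.resolve_step(vs)
    cos_limit = np.cos(np.deg2rad(config.resolve_max_angle(vs)))
    if seed_mask is None:
        seed_mask = mask
    if not (mask.any() and seed_mask.any()):
        warnings.warn("empty tracking mask: returning empty tractogram",
                      stacklevel=2)
        return Tractogram(streamlines=[], affine=field.affine)
    seeds = seed_from_mask(seed_mask, vs, config.seeds_per_voxel,
                           config.rng_seed)
    vox = point_to_voxel(seeds, vs)
    peaks, fracs = _peaks_at(field, vox)
    has_peak = fracs.sum(axis=1) > 0
    seeds, vox = seeds[has_peak], vox[has_peak]
    peaks, fracs = peaks[has_peak], fracs[has_peak]
    main = np.argmax(fracs, axis=1)
    rows = np.arange(len(seeds))
    dir0 = peaks[rows, main]
    max_steps = int(np.ceil(config.max_length / step)) + 1

    fwd = _half_tracks(field, mask, seeds, dir0, step, cos_limit, max_steps,
                       config.interpolation)
    bwd = _half_tracks(field, mask, seeds, -dir0, step, cos_limit, max_steps,
                       config.interpolation)
    streamlines = []
    for f, b in zip(fwd, bwd):
        pts = np.array(b[::-1] + f[1:])
        if len(pts) < 2:
            continue
        length = streamline_length(pts)
        if config.min_length <= length <= config.max_length:
            streamlines.append(pts)
    return Tractogram(streamlines=streamlines, affine=field.affine)
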