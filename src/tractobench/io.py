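"""On-disk layout of phantoms and evaluation reports.

A phantom is exported as a directory with a JSON manifest listing bundle
names and recognition thresholds, NIfTI volumes (masks, tissue fractions,
peaks as a 4D ``K*3``-channel image) and one TCK file of reference
streamlines per bundle — the same shapes of artifact an external tractogram
would be scored against.
"""

from __future__ import annotations

import json
import os

import numpy as np
import nibabel as nib

from .phantom import GroundTruthBundle, OrientationField, grid_affine
from .streamlines import Tractogram, read_tractogram, write_tractogram

__all__ = ["save_phantom", "load_phantom", "save_report"]


def _save_nifti(data, affine, path, dtype=np.float32):
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=dtype), affine), path)


def save_phantom(field: OrientationField, bundles: list[GroundTruthBundle],
                 outdir) -> str:
    """Write field + bundles to ``outdir``; returns the manifest path."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    aff = field.affine
    X, Y, Z, K, _ = field.peaks.shape
    _save_nifti(field.peaks.reshape(X, Y, Z, K * 3), aff,
                os.path.join(outdir, "peaks.nii"))
    _save_nifti(field.peak_fractions, aff,
                os.path.join(outdir, "peak_fractions.nii"))
    _save_nifti(field.tissue_fractions, aff,
                os.path.join(outdir, "tissue_fractions.nii"))
    wm = field.peak_fractions.sum(axis=-1) > 0
    _save_nifti(wm, aff, os.path.join(outdir, "wm_mask.nii"), dtype=np.uint8)
    entries = []
    for b in bundles:
        safe = b.name.replace("/", "_")
        tck = os.path.join(outdir, f"{safe}.tck")
        write_tractogram(Tractogram(b.reference_streamlines, affine=aff), tck)
        for tag, m in (("mask", b.mask), ("head", b.head_mask),
                       ("tail", b.tail_mask)):
            _save_nifti(m, aff, os.path.join(outdir, f"{safe}_{tag}.nii"),
                        dtype=np.uint8)
        entries.append({
            "name": b.name,
            "streamlines": f"{safe}.tck",
            "mask": f"{safe}_mask.nii",
            "head_mask": f"{safe}_head.nii",
            "tail_mask": f"{safe}_tail.nii",
            "recognition_threshold": b.recognition_threshold,
        })
    manifest = {
        "voxel_size": field.voxel_size,
        "grid_shape": list(field.grid_shape),
        "max_peaks": K,
        "bundles": entries,
    }
    mpath = os.path.join(outdir, "manifest.json")
    with open(mpath, "w") as f:
        json.dump(manifest, f, indent=2)
    return mpath


def load_phantom(manifest_path) -> tuple[OrientationField, list[GroundTruthBundle]]:
    """Load a phantom directory back from its manifest."""
    manifest_path = str(manifest_path)
    base = os.path.dirname(manifest_path)
    with open(manifest_path) as f:
        manifest = json.load(f)
    vs = float(manifest["voxel_size"])
    shape = tuple(manifest["grid_shape"])
    K = int(manifest["max_peaks"])

    def vol(name, dtype=np.float64):
        return np.asarray(nib.load(os.path.join(base, name)).dataobj,
                          dtype=dtype)

    peaks = vol("peaks.nii").reshape(*shape, K, 3)
    field = OrientationField(
        peaks=peaks,
        peak_fractions=vol("peak_fractions.nii"),
        tissue_fractions=vol("tissue_fractions.nii"),
        affine=grid_affine(vs),
        voxel_size=vs,
    )
    bundles = []
    for e in manifest["bundles"]:
        refs = read_tractogram(os.path.join(base, e["streamlines"])).streamlines
        bundles.append(GroundTruthBundle(
            name=e["name"],
            reference_streamlines=refs,
            mask=vol(e["mask"], bool),
            head_mask=vol(e["head_mask"], bool),
            tail_mask=vol(e["tail_mask"], bool),
            recognition_threshold=float(e["recognition_threshold"]),
        ))
    return field, bundles


def save_report(report, outdir) -> dict:
    """Write an evaluation report as JSON + per-bundle and connectivity CSVs."""
    os.makedirs(str(outdir), exist_ok=True)
    paths = {
        "json": os.path.join(str(outdir), "report.json"),
        "per_bundle": os.path.join(str(outdir), "per_bundle.csv"),
        "connectivity": os.path.join(str(outdir), "connectivity_matrix.csv"),
    }
    with open(paths["json"], "w") as f:
        json.dump(report.to_dict(), f, indent=2, sort_keys=True)
    report.per_bundle.to_csv(paths["per_bundle"], index=False)
    report.connectivity_matrix.to_csv(paths["connectivity"])
    return paths
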