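"""Four-compartment diffusion-MRI signal simulation with k-space artifacts.

The voxel signal is a fraction-weighted sum over four Gaussian compartments:

* intra-axonal **stick**:    ``exp(-TE/T2) * exp(-b d (g.n)^2)``
* inter-axonal **zeppelin**: ``exp(-TE/T2) * exp(-b (d_r + (d_a - d_r)(g.n)^2))``
* grey matter / CSF **ball**: ``exp(-TE/T2) * exp(-b d)``

with ``g`` the gradient direction, ``n`` the fiber direction, ``b`` in
s mm^-2 and diffusivities in mm^2 s^-1.  Anisotropic compartments are
averaged over a voxel's fiber peaks weighted by the peak fractions.

Artifacts are injected per axial slice in 2D k-space, which is where
echo-planar artifacts live: complex Gaussian noise (magnitude images are
Rician), random k-space spikes, an N/2 ghost from alternating-line modulation,
rigid motion of whole volumes, and optional B0-field-map distortion as a
voxel shift along the phase-encode axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import nibabel as nib
from scipy import ndimage

from .phantom import OrientationField

__all__ = [
    "Compartment",
    "CompartmentParams",
    "AcquisitionScheme",
    "ArtifactConfig",
    "compartment_attenuation",
    "simulate_volume_series",
    "inject_artifacts",
    "export_dataset",
    "synthetic_field_map",
]


@dataclass
class Compartment:
    kind: str  # 'stick' | 'zeppelin' | 'ball'
    t2: float  # ms
    d: float | None = None  # mm^2 s^-1 (stick / ball)
    d_axial: float | None = None  # mm^2 s^-1 (zeppelin)
    d_radial: float | None = None

    def __post_init__(self):
        if self.kind not in ("stick", "zeppelin", "ball"):
            raise ValueError(f"unknown compartment kind {self.kind!r}")
        if self.t2 <= 0:
            raise ValueError("T2 must be positive")
        if self.kind == "zeppelin":
            if not (self.d_axial and self.d_radial) or min(self.d_axial, self.d_radial) <= 0:
                raise ValueError("zeppelin needs positive d_axial and d_radial")
        elif self.d is None or self.d <= 0:
            raise ValueError(f"{self.kind} needs a positive diffusivity d")


@dataclass
class CompartmentParams:
    """The four tissue compartments (intra, inter, GM, CSF)."""

    intra: Compartment
    inter: Compartment
    gm: Compartment
    csf: Compartment

    @classmethod
    def default_brain(cls) -> "CompartmentParams":
        """Representative brain-tissue parameters (diffusivities in mm^2/s):
        stick T2 110 ms / d 1.2e-3; zeppelin T2 110 / 1.2e-3 / 0.3e-3;
        GM ball T2 80 / 1.0e-3; CSF ball T2 2500 / 2.0e-3."""
        return cls(
            intra=Compartment("stick", t2=110.0, d=1.2e-3),
            inter=Compartment("zeppelin", t2=110.0, d_axial=1.2e-3, d_radial=0.3e-3),
            gm=Compartment("ball", t2=80.0, d=1.0e-3),
            csf=Compartment("ball", t2=2500.0, d=2.0e-3),
        )


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """n roughly uniformly spread unit vectors on a hemisphere (z >= 0)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5 ** 0.5) * i
    z = i / n  # (0, 1): upper hemisphere
    r = np.sqrt(1 - z ** 2)
    v = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return v / np.linalg.norm(v, axis=1, keepdims=True)


@dataclass
class AcquisitionScheme:
    """b-values (s mm^-2) and gradient directions, one per volume, plus the
    echo-planar timing parameters that matter for artifact physics."""

    bvalues: np.ndarray
    directions: np.ndarray  # (n, 3); zero rows for b=0 volumes
    te: float = 108.0  # ms
    dwell_time: float = 1.0  # ms
    t2_prime: float = 50.0  # ms
    phase_encode_axis: int = 1

    def __post_init__(self):
        self.bvalues = np.asarray(self.bvalues, dtype=np.float64)
        self.directions = np.asarray(self.directions, dtype=np.float64)
        if len(self.bvalues) != len(self.directions):
            raise ValueError("bvalues and directions must have equal length")
        nz = self.bvalues > 0
        norms = np.linalg.norm(self.directions[nz], axis=1)
        if nz.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("nonzero-b directions must be unit vectors")

    def __len__(self) -> int:
        return len(self.bvalues)

    @classmethod
    def default_dwi(cls, n_directions: int = 32, bvalue: float = 1000.0) -> "AcquisitionScheme":
        """One b=0 volume followed by ``n_directions`` single-shell volumes."""
        dirs = _fibonacci_hemisphere(n_directions)
        bvals = np.concatenate([[0.0], np.full(n_directions, bvalue)])
        directions = np.vstack([np.zeros(3), dirs])
        return cls(bvalues=bvals, directions=directions)


@dataclass
class ArtifactConfig:
    """Artifact injection settings; all effects off by default."""

    target_snr: float | None = None  # mean WM b=0 magnitude / Gaussian sigma
    n_spikes: int = 0
    spike_scale: float = 10.0  # multiple of max |k| in the hit slice
    ghost_amplitude: float = 0.0  # alternating-line modulation depth
    motion_events: list = dc_field(default_factory=list)  # (volume, rot_z deg, trans_x mm)
    field_map: np.ndarray | None = None  # Hz, same grid as the image
    rng_seed: int = 0

    def __post_init__(self):
        if self.target_snr is not None and self.target_snr <= 0:
            raise ValueError("target_snr must be positive")
        if self.n_spikes < 0:
            raise ValueError("n_spikes must be >= 0")
        if self.spike_scale < 0 or self.ghost_amplitude < 0:
            raise ValueError("artifact amplitudes must be >= 0")


def compartment_attenuation(comp: Compartment, b: float, g, n, te: float) -> float:
    """Signal attenuation of one compartment for one measurement, in (0, 1].

    ``g`` and ``n`` must be unit vectors (``n`` is ignored for the ball).
    At b=0 the value is exactly ``exp(-TE/T2)``.
    """
    g = np.asarray(g, dtype=np.float64)
    relax = np.exp(-te / comp.t2)
    if b == 0:
        return float(relax)
    if abs(np.linalg.norm(g) - 1.0) > 1e-6:
        raise ValueError("gradient direction g must be unit-norm")
    if comp.kind == "ball":
        return float(relax * np.exp(-b * comp.d))
    n = np.asarray(n, dtype=np.float64)
    if abs(np.linalg.norm(n) - 1.0) > 1e-6:
        raise ValueError("fiber direction n must be unit-norm")
    c2 = float(np.dot(g, n)) ** 2
    if comp.kind == "stick":
        return float(relax * np.exp(-b * comp.d * c2))
    # zeppelin
    d_eff = comp.d_radial + (comp.d_axial - comp.d_radial) * c2
    return float(relax * np.exp(-b * d_eff))


def simulate_volume_series(
    field: OrientationField,
    scheme: AcquisitionScheme,
    compartments: CompartmentParams | None = None,
    s0: float = 1000.0,
) -> np.ndarray:
    """Noise-free 4D DWI: proton density x fraction-weighted compartment sum.

    The stick and zeppelin attenuations are averaged over each voxel's peaks,
    weighted by the normalized peak fractions.
    """
    if compartments is None:
        compartments = CompartmentParams.default_brain()
    frac = field.tissue_fractions
    fsum = frac.sum(axis=-1)
    tissue_ok = np.isclose(fsum, 1.0, atol=1e-9) | np.isclose(fsum, 0.0, atol=1e-9)
    if not tissue_ok.all():
        raise ValueError("tissue fractions must sum to 1 (tissue) or 0 (air) "
                         "in every voxel")
    shape = field.grid_shape
    nvol = len(scheme)
    te = scheme.te
    cp = compartments
    pk = field.peaks  # (X,Y,Z,K,3)
    pf = field.peak_fractions  # (X,Y,Z,K)
    pf_total = pf.sum(axis=-1)
    wm = pf_total > 0
    pf_norm = np.zeros_like(pf)
    pf_norm[wm] = pf[wm] / pf_total[wm][..., None]

    relax = {name: np.exp(-te / getattr(cp, name).t2)
             for name in ("intra", "inter", "gm", "csf")}
    out = np.zeros(shape + (nvol,))
    for v in range(nvol):
        b = scheme.bvalues[v]
        g = scheme.directions[v]
        if b == 0:
            a_intra = relax["intra"]
            a_inter = relax["inter"]
            a_gm = relax["gm"]
            a_csf = relax["csf"]
            fiber = frac[..., 0] * a_intra + frac[..., 1] * a_inter
        else:
            c2 = np.square(pk @ g)  # (X,Y,Z,K)
            stick = relax["intra"] * np.exp(-b * cp.intra.d * c2)
            d_eff = cp.inter.d_radial + (cp.inter.d_axial - cp.inter.d_radial) * c2
            zep = relax["inter"] * np.exp(-b * d_eff)
            a_intra = (pf_norm * stick).sum(axis=-1)
            a_inter = (pf_norm * zep).sum(axis=-1)
            a_gm = relax["gm"] * np.exp(-b * cp.gm.d)
            a_csf = relax["csf"] * np.exp(-b * cp.csf.d)
            fiber = frac[..., 0] * a_intra + frac[..., 1] * a_inter
        out[..., v] = s0 * (fiber + frac[..., 2] * a_gm + frac[..., 3] * a_csf)
    return out


def synthetic_field_map(grid_shape, amplitude_hz: float = 50.0,
                        rng_seed: int = 0) -> np.ndarray:
    """A smooth synthetic off-resonance map (Hz): low-frequency random field.

    Stands in for a measured B0 field map, which depends on scanner and
    subject and is not part of the phantom definition.
    """
    rng = np.random.default_rng(rng_seed)
    coarse = rng.normal(size=(4, 4, 4))
    zoom = [s / 4 for s in grid_shape]
    smooth = ndimage.zoom(coarse, zoom, order=3)
    smooth = smooth[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
    return amplitude_hz * smooth / np.abs(smooth).max()


def _rigid_transform_volume(vol: np.ndarray, rot_z_deg: float, trans_x_mm: float,
                            voxel_size: float) -> np.ndarray:
    """Rotate about the z-axis through the volume center and translate along x."""
    theta = np.deg2rad(rot_z_deg)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    center = (np.asarray(vol.shape) - 1) / 2.0
    shift_vox = np.array([trans_x_mm / voxel_size, 0.0, 0.0])
    # affine_transform maps output coords via matrix @ out + offset -> input
    matrix = rot.T
    offset = center - matrix @ (center + shift_vox)
    return ndimage.affine_transform(vol, matrix, offset=offset, order=1,
                                    mode="constant", cval=0.0)


def inject_artifacts(
    image4d: np.ndarray,
    config: ArtifactConfig,
    scheme: AcquisitionScheme,
    wm_mask: np.ndarray | None = None,
    voxel_size: float = 2.0,
) -> np.ndarray:
    """Apply motion, distortion, spike/ghost k-space corruption and noise.

    Order of operations per volume: rigid motion (listed volumes), B0
    distortion (phase-encode shift by ``field_map * dwell_time * N_pe``),
    then slice-wise 2D FFT where spikes and the N/2 ghost modulation are
    applied, complex Gaussian noise addition, and magnitude reconstruction.
    Noise sigma is ``mean WM b=0 signal / target_snr``; the returned image is
    the Rician magnitude.  Deterministic given ``config.rng_seed``.
    """
    img = np.asarray(image4d, dtype=np.float64).copy()
    nx, ny, nz, nvol = img.shape
    rng = np.random.default_rng(config.rng_seed)
    pe = scheme.phase_encode_axis
    if pe not in (0, 1):
        raise ValueError("phase_encode_axis must be an in-plane axis (0 or 1)")

    for (vol, rot, trans) in config.motion_events:
        if not (0 <= vol < nvol):
            raise ValueError(f"motion event volume {vol} out of range")
        img[..., vol] = _rigid_transform_volume(img[..., vol], rot, trans, voxel_size)

    if config.field_map is not None:
        fmap = np.asarray(config.field_map, dtype=np.float64)
        if fmap.shape != (nx, ny, nz):
            raise ValueError("field_map grid does not match the image")
        n_pe = img.shape[pe]
        shift_vox = fmap * (scheme.dwell_time * 1e-3) * n_pe
        coords = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
        coords = [c.astype(np.float64) for c in coords]
        coords[pe] = coords[pe] - shift_vox
        for v in range(nvol):
            img[..., v] = ndimage.map_coordinates(img[..., v], coords, order=1,
                                                  mode="constant", cval=0.0)

    sigma = 0.0
    if config.target_snr is not None:
        if wm_mask is None:
            raise ValueError("target_snr requires a white-matter mask to define "
                             "the baseline signal")
        b0 = scheme.bvalues == 0
        if not b0.any():
            raise ValueError("target_snr requires at least one b=0 volume")
        mean_wm = float(img[..., b0].mean(axis=-1)[wm_mask].mean())
        sigma = mean_wm / config.target_snr

    # spikes: uniformly random (volume, slice, kx, ky) positions
    spike_positions = []
    for _ in range(config.n_spikes):
        spike_positions.append((
            int(rng.integers(nvol)), int(rng.integers(nz)),
            int(rng.integers(nx)), int(rng.integers(ny)),
        ))

    out = np.empty_like(img)
    pe_in_plane = pe  # k-space line index runs along the phase-encode axis
    line_idx = np.arange(img.shape[pe_in_plane])
    ghost_mod = 1.0 + config.ghost_amplitude * ((-1.0) ** line_idx)
    for v in range(nvol):
        for z in range(nz):
            sl = img[:, :, z, v]
            k = np.fft.fft2(sl)
            if config.ghost_amplitude > 0:
                if pe_in_plane == 0:
                    k = k * ghost_mod[:, None]
                else:
                    k = k * ghost_mod[None, :]
            for (sv, sz, sx, sy) in spike_positions:
                if sv == v and sz == z:
                    k[sx, sy] = config.spike_scale * np.abs(k).max()
            sl = np.fft.ifft2(k)
            if sigma > 0:
                sl = sl + rng.normal(0.0, sigma, sl.shape) \
                        + 1j * rng.normal(0.0, sigma, sl.shape)
            out[:, :, z, v] = np.abs(sl)
    return out


def measure_snr(image4d: np.ndarray, scheme: AcquisitionScheme,
                wm_mask: np.ndarray, background_mask: np.ndarray) -> float:
    """Estimate the realized SNR of a magnitude image.

    SNR is the mean white-matter b=0 magnitude divided by the Gaussian
    channel sigma, with sigma estimated from the background (air) magnitude.
    The noise-only background is Rayleigh distributed; the *median* of the
    background (``sigma sqrt(2 ln 2)``) is used rather than the mean so the
    estimate is robust to localized artifacts (spikes, ghosts) that leak
    signal into a small share of the background voxels.
    """
    b0 = scheme.bvalues == 0
    if not b0.any():
        raise ValueError("need at least one b=0 volume")
    mean_b0 = np.asarray(image4d)[..., b0].mean(axis=-1)
    sigma = np.median(mean_b0[background_mask]) / np.sqrt(2.0 * np.log(2.0))
    return float(mean_b0[wm_mask].mean() / sigma)


def export_dataset(image4d: np.ndarray, scheme: AcquisitionScheme,
                   affine: np.ndarray, outdir) -> dict:
    """Write a NIfTI 4D image plus FSL-style bval/bvec text files.

    bvec columns follow volume order; returns the written paths.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    dwi_path = os.path.join(str(outdir), "dwi.nii")
    nib.save(nib.Nifti1Image(np.asarray(image4d, dtype=np.float32), affine),
             dwi_path)
    bval_path = os.path.join(str(outdir), "dwi.bval")
    bvec_path = os.path.join(str(outdir), "dwi.bvec")
    np.savetxt(bval_path, scheme.bvalues[None, :], fmt="%.1f")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.8f")
    return {"dwi": dwi_path, "bval": bval_path, "bvec": bvec_path}


def read_scheme(bval_path, bvec_path, **kwargs) -> AcquisitionScheme:
    """Read an FSL bval/bvec pair back into an acquisition scheme."""
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return AcquisitionScheme(bvalues=bvals, directions=bvecs, **kwargs)
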