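# Methods

This note documents the models, algorithms and numerical choices behind
`tractobench`, what the synthetic phantoms do and do not emulate, and the
known limitations.

## Coordinate conventions

All computation is in world millimetres. Voxels use 0-based indices; a world
point belongs to voxel `v` iff it lies in the half-open cube
`[v·s, (v+1)·s)` for voxel size `s` (`point_to_voxel = floor(p / s)`). The
NIfTI grid-to-world affine is diagonal with a half-voxel translation, so
voxel centers sit at `(v + 0.5)·s`. TRK files in voxel or voxmm dialects are
converted to world mm on load via the header affine (nibabel's streamline
machinery handles both dialects); TCK is world mm natively.

## Streamline shape distance and clustering

The shape distance is the minimum-direct-flip (MDF) distance: both
streamlines are resampled to `n_points` equidistant-by-arc-length points
(default **12**, a common operating point for this distance; configurable)
and the mean pointwise Euclidean distance is taken for the direct and the
reversed orderings, keeping the smaller. MDF is a pseudometric on
streamlines modulo traversal direction; symmetry and the triangle inequality
are exercised over 1,000 random triples in the test suite.

Clustering is single-pass centroid clustering under MDF (the QuickBundles
scheme): each streamline, in input order, joins the nearest cluster whose
centroid is within the threshold, updating the centroid as the running mean
of flip-aligned resampled members, or founds a new cluster. The result
depends on input order; the implementation fixes processing order to input
order, and tests assert order-insensitive properties (partition equality,
cluster counts, separation on well-separated groups).

## Phantom generation

A bundle is a natural cubic spline through user control points
(chord-length parameterized, re-sampled to uniform arc length at a quarter
voxel), populated by `n_streamlines` copies offset inside a disk of the
bundle radius. Offsets ride a rotation-minimizing (parallel-transport)
frame so off-axis copies stay smooth; one streamline always sits exactly on
the centerline. Cross-section sampling is uniform-in-disk by default
(`gaussian` optional).

Masks: the bundle mask is the set of voxels traversed by at least one
reference streamline. Traversal uses one shared rule everywhere (segments
subdivided to ≤ ¼ voxel with vertices preserved), so a bundle's own
reference streamlines traverse *exactly* the bundle mask — identity
evaluation is exact by construction, not by tolerance. Head/tail endpoint
regions are Euclidean dilations (default radius 1 voxel) of the first/last
streamline points; generation fails loudly if head and tail overlap.

Orientation field: every subdivided reference point votes its local segment
direction into its voxel. Per voxel, votes are greedily clustered
sign-invariantly with a **20°** merge tolerance (mimicking the limited
angular resolution that fuses near-parallel bundles into one signal peak);
at most **K = 3** peaks are kept, merging lowest-weight clusters with a
warning. Peak fractions are vote proportions and sum to the voxel's fiber
fraction. Tissue fractions: fiber voxels get a **0.7 / 0.3**
intra/inter-axonal split (fraction maps of real tissue are not part of the
phantom definition; this is a declared stand-in), a one-voxel shell around
white matter is GM, a further two-voxel shell is CSF, and the rest of the
grid is background air (zero signal) — which doubles as the noise-estimation
region.

### Shipped fixtures

* `canonical_phantom()` — 40³ voxels at 2 mm (80 mm box), five bundles: two
  straight bundles crossing orthogonally, one arc, and a two-bundle
  bottleneck.
* `bottleneck_phantom()` — the bottleneck pair alone on a 40×40×12 grid.

The bottleneck is two bundles sharing a straight corridor
(x ∈ [32, 48] mm) with *asymmetric* arm angles: travelling −x out of the
corridor the shallowest continuation belongs to one bundle, travelling +x it
belongs to the other. A straightest-path tracker therefore reconstructs
both true bundles *and* a systematic spurious head/tail combination — the
false-positive mechanism realized in the smallest geometry that exhibits it.
Replicating a full 25-bundle brain-like anatomy is deliberately out of
scope; the desk-scale fixtures reproduce the *mechanisms* (crossing,
bottleneck), not the anatomy.

## Signal simulation

Four compartments, all mono-exponential in TE and Gaussian in diffusion
(units: T2 ms, diffusivity mm²/s, b s/mm²):

| compartment | model | T2 (ms) | diffusivity (mm²/s) |
|---|---|---|---|
| intra-axonal | stick | 110 | 1.2e-3 |
| inter-axonal | zeppelin | 110 | 1.2e-3 axial, 0.3e-3 radial |
| grey matter | ball | 80 | 1.0e-3 |
| CSF | ball | 2500 | 2.0e-3 |

Voxel signal = proton density (default **1000**, arbitrary units) × the
fraction-weighted compartment sum; anisotropic terms are averaged over the
voxel's peaks weighted by normalized peak fractions. At b = 0 every
compartment reduces exactly to `exp(-TE/T2)`. The default acquisition is
one b = 0 plus 32 directions (deterministic Fibonacci hemisphere) at
b = 1000 s/mm², TE 108 ms, dwell time 1 ms.

Artifacts are applied in 2D k-space per axial slice per volume, matching the
slice-wise physics of echo-planar acquisition:

* **Noise** — i.i.d. complex Gaussian with
  `σ = mean WM b=0 signal / target_snr`; output is the magnitude, hence
  Rician in tissue and Rayleigh in air. The realized-SNR estimator divides
  the mean WM b = 0 magnitude by σ estimated from the background *median*
  (Rayleigh median = σ√(2 ln 2)); the median is used because localized
  artifacts (spikes, ghosts) leak signal into a small share of background
  voxels and would bias a mean-based estimate.
* **Spikes** — `n_spikes` uniformly random (volume, slice, k-index)
  positions set to `spike_scale` (default **10**) × the slice's max |k|.
* **N/2 ghost** — alternate k-space lines along the phase-encode axis
  multiplied by `1 + a·(−1)^line`; by the shift theorem this superimposes an
  FOV/2-shifted copy with relative amplitude ≈ `a`.
* **Motion** — listed volumes are rigidly rotated about z and translated
  along x (linear interpolation) before "acquisition".
* **Distortion** — optional per-voxel shift along the phase-encode axis of
  `field_map(Hz) × dwell_time × N_pe` voxels; a smooth synthetic field-map
  generator is provided (a measured field map is scanner-specific and not
  part of a phantom definition).

Readout-time T2′ decay within the echo train is not modelled (one effective
TE per volume); multi-coil, partial Fourier and eddy currents are out of
scope.

## Ground-truth tracking

Deterministic propagation on the orientation field. Seeds are uniformly
jittered inside mask voxels (`seeds_per_voxel`, default **5**). Each seed
launches both polarities of its voxel's largest-fraction peak. Per step
(default **half a voxel**): among the peaks at the current position
(nearest-voxel by default; a sign-aligned trilinear blend of the eight
neighbours' best-aligned peaks optionally), choose the one maximizing
|cos| with the incoming direction, sign-aligned; ties inside a voxel are
broken by the larger peak fraction. Terminate on leaving the mask, turning
more than `max_angle` (default **45°** per half-voxel step, scaled linearly
with step size so the curvature bound is step-invariant), or finding no
peak. Halves are concatenated; streamlines outside [`min_length` = 10 mm,
`max_length` = 250 mm] are discarded. Tracking is fully deterministic given
the seed RNG.

## Evaluation

* **Recognition** — a streamline's distance to a bundle is the minimum MDF
  over the bundle's reference streamlines; it is assigned to the closest
  bundle whose distance is within that bundle's threshold (the shipped
  fixtures use 5–7 mm, in the 2–10 mm range typical for bundle-specific
  recognition). Ties break to the lower bundle index for determinism.
  Distances are computed exactly (vectorized, chunked); on ≤ 50 streamlines
  the result is verified against a brute-force nearest-bundle search.
* **Invalid classification** — unrecognized streamlines shorter than
  `min_length` (10 mm) or with a terminal point capturing no endpoint
  region are non-connecting. A terminal point is captured by the region
  containing its voxel, else the nearest region within a **5 mm** capture
  radius (the dilation radius of real endpoint regions is not a universal
  constant; this is the package's declared default). The rest are clustered
  (QuickBundles, 10 mm), each cluster's region pair decided by member
  majority vote, same-pair clusters merged. A cluster voting a pair that
  *is* a ground-truth head/tail pair is re-examined against that bundle's
  threshold — members within it become valid, the rest are non-connecting —
  so every surviving invalid cluster connects a pair absent from ground
  truth, and the IB count is the number of such distinct pairs.
* **Volumetric scores** — overlap = share of bundle-mask voxels traversed by
  the bundle's valid streamlines; overreach = traversed voxels outside the
  mask over the mask size (it may exceed 100% by construction; it is not a
  Dice denominator). Traversal uses the same subdivision rule as mask
  generation.
* **Strict criterion** — `strict_vc` implements the restrictive definition
  (never leave the bundle mask, terminate exactly in head and tail regions);
  it is reported separately and not used for the headline VC ratio.
* **Pair counting** — `n` bundles have `2n` endpoint regions;
  `C(2n,2) + 2n` unordered pairs including self-pairs (1275 at n = 25), of
  which `n` are valid, leaving 1250 potential invalid bundles. Self-pairs
  count as potential IBs; this is the counting that reproduces the
  1275/1250 arithmetic.
* **Bundle-level rates** — precision = VB/(VB+IB), recall = VB/n,
  specificity = (potential IBs − IB)/potential IBs, all as percentages.

## Pipeline and reproducibility

`run_pipeline` executes phantom → simulate → track → evaluate with one
top-level seed fanned out to per-stage seeds by fixed offsets, writes all
artifacts (NIfTI volumes, TCK bundles, a JSON manifest, FSL bval/bvec, JSON
+ CSV reports) and embeds a provenance block (config hash over scientific
settings, package and numpy versions) into the report. Reruns with the same
seed produce byte-identical metric JSON.

## Problem sizes

The shipped fixtures are sized so that the full test suite and the
acceptance script each run in well under a minute of compute: 40³ voxels at
2 mm, 25–30 reference streamlines per bundle, about 2,000 white-matter
voxels, and roughly 8,000 tracked streamlines at 5 seeds per voxel on the
canonical phantom. All metrics scale to larger grids and tractograms
(distance computation is chunked; memory stays bounded).

## What the phantoms do and do not show

The fixtures reproduce the *structural causes* of tractography errors —
crossings and bottlenecks with known ground truth — with exactly
controllable geometry. They do not emulate brain anatomy (25 named bundles,
cortical folding, realistic fraction maps, measured field maps), partial
voluming beyond the voxelized masks, or scanner-specific artifact spectra.
Passing results here demonstrate correctness of the machinery and the
in-principle inevitability of bottleneck-induced false positives under
straightest-path tracking; they do not by themselves predict scores on real
acquisitions, where recognition thresholds, SNR and anatomy all differ.

## Known limitations

* QuickBundles results are input-order dependent (inherent to the
  single-pass scheme); order is fixed and documented.
* The strict connection criterion uses voxelized masks, so it inherits the
  half-open voxel rule at mask boundaries.
* Trilinear peak interpolation blends each neighbour's single best-aligned
  peak; voxel-to-voxel peak correspondence is not tracked explicitly.
* The realized SNR estimator is biased low by a few percent when ghosts
  overlap a large fraction of the background.
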