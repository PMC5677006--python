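# tractobench

Synthetic diffusion-MRI phantoms, deterministic tractography on ground-truth
orientation fields, and Tractometer-style scoring of streamline tractograms.

## Who this is for

Diffusion-MRI tractography reconstructs white-matter pathways as streamlines
from voxel-wise fiber orientations. A long-standing problem is that trackers
systematically fabricate *invalid bundles*: coherent groups of streamlines
connecting region pairs that are not actually connected, caused by
"bottlenecks" — corridors of voxels shared by several near-parallel bundles
whose local orientations cannot tell them apart. `tractobench` lets method
developers reproduce and measure this effect on fully synthetic,
fully-known ground truth, and score any external tractogram (TCK/TRK)
against a phantom with the standard challenge metrics.

The toolkit has four parts:

1. **Phantom generator** — parametric fiber bundles (splined centerlines with
   a circular cross-section) on a voxel grid, producing reference
   streamlines, bundle masks, dilated head/tail endpoint regions, and a
   per-voxel orientation field (up to K peaks with volume fractions plus
   intra-axonal / inter-axonal / GM / CSF tissue fractions). Shipped
   fixtures include a 5-bundle phantom with an orthogonal crossing and a
   two-bundle bottleneck.
2. **Signal simulator** — the four-compartment signal model

   - stick (intra-axonal): `exp(-TE/T2) · exp(-b·d·(g·n)²)`
   - zeppelin (inter-axonal): `exp(-TE/T2) · exp(-b·(d_r + (d_a-d_r)(g·n)²))`
   - ball (GM, CSF): `exp(-TE/T2) · exp(-b·d)`

   with k-space artifact injection per axial slice: complex Gaussian noise
   (Rician magnitude) at a target SNR, random spikes, an N/2 ghost from
   alternating-line modulation, rigid per-volume motion, and optional
   field-map distortion.
3. **Ground-truth tracker** — deterministic streamline propagation directly
   on the orientation field (no diffusion data): straightest-peak selection
   with a per-step turn limit, bidirectional from jittered seeds.
4. **Tractometer evaluator** — partitions a tractogram into valid
   connections (shape recognition by minimum-direct-flip distance against
   bundle-specific thresholds), invalid bundles (QuickBundles clustering of
   the remainder + endpoint-region majority voting), and non-connecting
   streamlines, then reports VC ratio, VB/IB counts, per-bundle overlap and
   overreach, precision/recall/specificity and a connectivity matrix.

## Worked example

```python
import tractobench as tb

spec = tb.bottleneck_phantom(rng_seed=0)        # two bundles, one corridor
field, bundles = tb.assemble_phantom(spec)
wm = tb.white_matter_mask(field)
tracts = tb.track(field, wm, tb.TrackingConfig(seeds_per_voxel=5, rng_seed=1))
report = tb.evaluate(tracts, bundles, tb.EvaluationConfig(voxel_size=2.0))
print(report.summary())
```

prints

```
streamlines: 2789
VC ratio: 36.5%  IC: 30.2%  NC: 33.2%
VB: 2/2   IB: 3
mean OL: 88.8%  mean OR: 9.2%
precision: 40.0%  recall: 100.0%  specificity: 62.5%
```

Both true bundles are fully recovered (VB 2/2, overlap near 90%) from
*perfect* orientation information — yet the tracker still fabricates
invalid bundles (IB ≥ 1): streamlines entering the shared corridor from one
bundle's arm exit through the other's, producing coherent clusters that
connect head/tail regions never connected in the ground truth. That is the
bottleneck ambiguity this toolkit exists to demonstrate and measure.

The same works from the shell:

```bash
tractobench run-all --spec bottleneck --seed 1 -o out/
tractobench evaluate --tracts yourtracks.tck --truth out/phantom/manifest.json -o report/
```

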