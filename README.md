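# fibregrow

Growth-based generation of white-matter numerical phantoms: dense,
pairwise **non-intersecting** 3D axon meshes with user-controlled fibre
volume fraction, radius distribution and orientation dispersion, plus the
morphometry to verify what was actually achieved.

## Who this is for

Simulation studies of diffusion MRI (and other microstructure-sensitive
contrasts) need synthetic white-matter substrates whose ground truth is
known exactly. Packing pre-made tubes gets hard exactly where real tissue
is interesting — high density, dispersion, crossing bundles. `fibregrow`
instead *grows* fibres one at a time through a shared space, the way axons
do, so late fibres adapt to the space the earlier ones left.

## The model

A phantom is generated in three stages on a cubic region of side `L` (µm):

1. **Initialisation.** Fibre radii are drawn from a gamma distribution
   with mean `mu_r` and s.d. `sigma_r`; circles with those radii are
   packed on the bundle's entry face up to the target density `rho`.
   Each packed circle becomes a fibre start; a direction drawn from the
   bundle's orientation distribution — parallel, Watson(`kappa`), or
   elliptically symmetric angular Gaussian (`mu`, `gamma`) — is shot
   through the region to place the target point on the boundary.
   `N` pseudorandom growth nodes fill the (padded) region.

2. **Growth.** The nodes are Delaunay-triangulated; every node stores the
   largest diameter `d_c` a fibre could sustain there (twice the clearance
   to the nearest fibre surface) and the bundle that set it. Each fibre
   walks node-to-node, greedily minimising

       l = l_t + f * l_d,

   where `l_t` penalises long steps and steps away from the target and
   `l_d = max(0, (d0 - d_c)/d0)` penalises squeezing below the fibre's
   target diameter `d0`. Optional mechanisms mirror axonal guidance:
   *collapse* (a stuck fibre retreats `g0 + k*delta` µm and regrows,
   blacklisting the abandoned route), a *dynamic network* (`N_added`
   nodes added around each grown fibre, like contact-guidance cues),
   *fasciculation* (`l_d = |(d0 - d_c)/d0|` when the nearest bundle is the
   fibre's own, rewarding staying close to it) and a *global
   optimisation* that relaxes all skeleton points against their nearest
   other-fibre neighbours and then re-expands radii into the freed space.

3. **Meshing.** Each skeleton is dressed with compactly supported
   metaball sources and its surface extracted by marching cubes from its
   own field minus every other fibre's field, so neighbouring fibres
   deform smoothly away from each other instead of intersecting. The
   output is one watertight PLY per fibre with zero intersecting triangle
   pairs across the phantom.

The morphometry module measures the result the way electron-microscopy
studies measure tissue: centre lines from equidistant cross-section
centroids, equivalent diameters `d = 2*sqrt(A/pi)`, orientation histograms
on a subdivided icosahedral sphere (sr^-1, exactly antipodally symmetric),
voxel-union volume fractions, and virtual histology slices with per-axon
circularity, convexity, eccentricity and area ratio.

## Worked example

```python
from fibregrow import GrowthConfig, MechanismFlags
from fibregrow.pipeline import run_pipeline

config = GrowthConfig(
    region_size=(6, 6, 6),      # µm
    target_density=0.6,         # rho
    radius_mean=0.5,            # mu_r, µm
    radius_std=0.1,             # sigma_r, µm
    dispersion_model="watson",
    watson_kappa=8.0,
    n_nodes=30_000,
    master_seed=1,
)
phantom, meshes, manifest = run_pipeline(config, "out/demo")
print(manifest["fibres"], manifest["morphology"])
```

prints (exact numbers are seed-reproducible):

```
{'seeded': 34, 'completed': 34, 'removed': 0}
{'density': 0.468, 'mu_theta_deg': 29.1, 'sigma_theta_deg': 18.4}
```

— 34 fibres were seeded from the packed face and all completed; the grown
phantom occupies 46.8% of the region (the achieved density always trails
the 60% face-packing target because fibres shrink and bend around each
other), and the mean angle of the smoothed centre lines from the bundle
axis is 29.1°, reflecting both the Watson(κ=8) dispersion that was asked
for (target 19.6°) and the node-to-node jitter of discrete growth.
`out/demo/` then contains the config snapshot, per-fibre skeleton CSV,
growth log, non-intersecting PLY meshes and a rerunnable manifest.

The same pipeline is scriptable from the shell:

```bash
fibregrow grow --L 6 --rho 0.6 --kappa 8 --N 30000 --seed 1 --out out/demo
fibregrow table --kappas 8,100 --out table.csv     # input-vs-output sweep
fibregrow ablation --scenarios parallel --out ablation.csv
```

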