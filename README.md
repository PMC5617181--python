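# fiberslice

Reconstruction and morphometry of individual 3D fibers — collagen fibers in
second-harmonic-generation (SHG) microscopy stacks being the motivating case —
by consistency-optimized curved planar reformation (CPR).

## The problem

Collagen fibers in the vessel wall are thin (~2–3 μm), wavy, and densely
packed.  In the acquired stack a single fiber wanders obliquely through many
slices, so slice-by-slice segmentation sees fragmented, ambiguous blobs.  The
approach implemented here re-slices the volume along the fiber itself: a
cross-sectional plane is placed at every point of a (rough, user-supplied or
auto-detected) centerline, with the plane normal equal to the local curve
tangent.  In this *resliced image space* the fiber appears straightened and
every slice shows one compact bright cross section, which makes segmentation
and 2D/3D skeletonization straightforward.  Segmented voxels are mapped back
through the stored rigid plane transforms, a sub-voxel 3D centerline is
extracted by a fast-marching-style arrival-time solve, trimmed to its main
trunk and spline-refined, and the fiber's morphometry is measured.

Two details carry the method:

- **Frame consistency.**  The Frenet–Serret normal is undefined on straight
  segments and flips at inflections.  Instead, the in-plane axes are
  propagated as a rotation-minimizing frame: at each step the previous normal
  is projected onto the plane orthogonal to the current tangent and
  renormalized — the closed-form angle that maximizes `dot(n_i, n_{i+1})`
  over rotations about the tangent.  Consecutive reslice planes therefore
  never spin about the fiber axis.
- **Sub-voxel skeletons.**  Inside the binary fiber the squared
  distance-to-boundary field serves as propagation speed; arrival times grow
  from the deepest voxel, endpoints appear as arrival-time maxima, and
  RK4 gradient descent on the arrival time traces each endpoint back with
  0.25-voxel steps.

## Measured quantities

| quantity | definition |
|---|---|
| waviness *w* | skeleton arc length / end-to-end chord (≥ 1) |
| tilt *T* | arctan[(max z − min z) / XY endpoint distance], degrees |
| CSA | area of the closed polygon where the plane normal to the local skeleton tangent cuts the surface mesh, μm² |
| equivalent diameter | 2·√(CSA/π), μm; values > 6 μm are flagged as outliers |
| orientation θ | principal axis of the XY-projection second moments, in [0°, 180°); bimodal samples are split by two-means on the doubled-angle circle |

## Worked example

Everything below runs on synthetic phantoms with analytic ground truth — the
package ships a generator for tortuous bright tubes with blur, noise, gaps and
branches at the scales of the motivating acquisition (0.25 μm voxels, radius
≈ 1.3 μm).

```python
import numpy as np
import fiberslice as fs

# a noisy sinusoidal fiber: true waviness 1.37, tilt 5 deg, radius 1.3 um
spec = fs.preset("wavy", seed=1, noise_sigma=10.0)
volume, truth = fs.make_phantom(spec, shape=(128, 128, 128))

# a rough initial centerline, as a user would click it
rng = np.random.default_rng(2)
init = truth.centerline.points[::120] + rng.normal(0, 0.2, (11, 3))

result = fs.process_fiber(volume, init, fs.PipelineConfig(), fiber_id=0)
m = result.morphometry
print(f"waviness {m.waviness:.3f} (truth {truth.waviness:.3f})")
print(f"tilt     {m.tilt_deg:.2f} deg (truth {truth.tilt_deg:.2f})")
print(f"diameter {m.diameter_mean_sd[0]:.2f} um, "
      f"outliers {100 * m.outlier_fraction:.1f} %")
```

prints

```
waviness 1.368 (truth 1.370)
tilt     5.11 deg (truth 5.00)
diameter 2.56 um, outliers 0.0 %
```

i.e. the pipeline recovers the phantom's waviness within well under a percent,
tilt within ~0.1°, and the 2.6 μm diameter within a few percent, with no CSA
point tripping the 6 μm outlier rule.

The same stages are scriptable from the shell:

```sh
fiberslice phantom --preset wavy --seed 7 --out phantom.tif --truth truth.json
fiberslice reslice --stack phantom.tif --centerline init.csv \
    --spacing 0.25 0.25 0.25 --plane-halfwidth 6 --out resliced.tif
fiberslice segment --resliced resliced.tif --method otsu --out mask.tif
fiberslice skeleton --mask mask.tif --spacing 0.25 0.25 0.25 --out skel.csv
fiberslice measure --mask mask.tif --skeleton skel.csv --out results.csv
fiberslice run --config run.yaml     # the whole chain, with provenance
```

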