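# liverreg

Sparse-data image-to-physical liver registration: rigid and deformable
alignment of a preoperative organ model to sparse, feature-labeled
intraoperative point clouds, plus a synthetic phantom challenge generator
and a complete target-registration-error (TRE) evaluation suite.

## The problem

Surgical navigation in the liver requires aligning a preoperative
image-derived organ model with the intraoperative coordinate frame.  The
data available in the operating room is sparse: a point cloud digitized
over only 20–44 % of the organ surface (the exposed anterior face plus
salient feature curves — the falciform ligament and the left and right
inferior ridges), while soft-tissue deformation of up to several
centimetres separates the preoperative shape from the intraoperative one.
The task is to infer, from that sparse surface data alone, a dense
displacement field over the whole organ so that subsurface targets (tumors,
vessels) are localized accurately.

`liverreg` implements:

* **Rigid comparators** — optimal point-based registration (weighted SVD /
  Kabsch), iterative closest point (ICP) with a deterministic multi-start
  stand-in for manual initialization, and fully automatic salient-feature
  weighted ICP (wICP) with an exponentially decaying feature-weight
  schedule `w(k) = 1 + (w0 − 1)·γᵏ`.
* **Deformable registration** by regularized-Kelvinlet boundary-condition
  reconstruction.  The regularized Kelvinlet

  ```
  u_ε(r) = [ (a−b)/r_ε · I + b/r_ε³ · r rᵀ + a ε²/(2 r_ε³) · I ] f₀,
  r_ε = √(|r|² + ε²),   a = 1/(4πμ),   b = a / (4(1−ν))
  ```

  is the closed-form linear-elastic response to a smoothed point load;
  superposing 160 Kelvinlets spread over the organ surface gives an
  analytic deformation basis.  The force vectors and a concurrent rigid
  pose (t, θ) are fit by Levenberg–Marquardt under the weighted
  least-squares objective

  ```
  C = Σ_F (w_F / N_F) Σ_i d_i² + w_E · f_E²
  ```

  where `d_i` is the model-to-data error of point *i* in feature *F*
  (surface-normal distance for anterior points, same-patch closest-point
  distance for features) and `f_E` is a normalized strain energy of the
  nonrigid field.
* **Synthetic challenge generation** — an analytic liver surrogate with
  159 implanted validation targets, 4 posterior contact-load deformation
  states, 28 sparse anterior patterns crossed over the states (112
  instances; 84 with 2-mm sinusoidal digitization noise, 28 clean), and an
  independent uniform random SE(3) pose per instance.
* **Evaluation** — per-target TRE (`TREᵢ = ‖x_GT,i − x_est,i‖₂`), noise
  efficiency `E_N = A_N / TRE̅_N` and degradation
  `D_N = (TRE̅_N − TRE̅_N0)/A_N`, stratification by surface-coverage extent
  and anatomical segment, per-element Green-strain norm
  `‖ε‖ = ½‖∇uᵀ+∇u+∇uᵀ∇u‖₂` and Jacobian determinant `|J| = |∇u + I|`
  field-consistency maps, inter-method TRE correlation, field fusion, and
  nonparametric method comparisons (Friedman/Wilcoxon with Bonferroni,
  Brown–Forsythe, Kolmogorov–Smirnov).

## Worked example

```python
import numpy as np
import liverreg as lr
from liverreg.deformable import register_deformable
from liverreg.fields import interpolate_displacement
from liverreg.kelvinlet import build_control_set
from liverreg.rigid import wicp

phantom = lr.generate_phantom()                       # organ + 159 targets
state = lr.apply_ground_truth_deformation(phantom, 0, seed=0)
cloud = lr.sample_sparse_pattern(state.deformed_surface, 30.0, seed=0)
pose = lr.sample_random_rigid(0)                      # unknown intraop pose
observed = cloud.transformed(pose)

init = wicp(observed, phantom.surface).transform.inverse()
result = register_deformable(
    phantom.surface, phantom.volume, observed, init,
    build_control_set(phantom.surface, 160),
)
u = interpolate_displacement(phantom.volume, result.displacement_field,
                             phantom.targets)
tre = np.linalg.norm(phantom.targets + u - pose.apply(state.deformed_targets),
                     axis=1)
print(f"mean TRE {tre.mean():.2f} mm (rigid wICP alone: "
      f"{np.linalg.norm(init.apply(phantom.targets) - pose.apply(state.deformed_targets), axis=1).mean():.2f} mm)")
```

prints

```
mean TRE 1.69 mm (rigid wICP alone: 1.92 mm)
```

i.e. on this synthetic instance (12 mm peak posterior deformation, 30 %
anterior coverage) the Kelvinlet reconstruction localizes the 159 interior
targets to 1.7 mm on average, improving on the automatic rigid alignment.

A command-line interface mirrors the library:

```bash
liverreg simulate-challenge --out challenge/ --seed 1
liverreg register-rigid --method wicp --mesh challenge/reference_surface.vtk \
    --cloud challenge/pattern_0000.txt --out pose.txt
liverreg register-deformable --mesh challenge/reference_surface.vtk \
    --volume challenge/reference_volume.vtk --cloud challenge/pattern_0000.txt \
    --out submission_0000.txt
```

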