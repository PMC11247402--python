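# synthreg

Anatomy-aware joint affine–deformable image registration, trained entirely
on synthetic images generated from label maps.

## The problem

Registration tools for brain MRI usually assume preprocessed inputs of a
particular contrast and resolution, and most learning-based tools only
generalize to data resembling their training set. `synthreg` implements a
synthesis-based strategy: the networks never see an acquired image. At every
training iteration a pair of label maps is spatially augmented and rendered
into images with randomized contrast, blur, bias field, noise and
resolution. The loss measures the overlap of a chosen anatomy label subset
J ⊂ K only, so the model learns to align the anatomy of interest while
ignoring arbitrary surrounding image content — no skull-stripping needed.

## The model

**Affine stage.** An encoder predicts k non-negative spatial feature maps
F_i per image. Each map is reduced to its center of mass a_i (moving) or
b_i (fixed) and total power p_i. The affine transform is the closed-form
weighted-least-squares fit aligning the two point clouds,

    t̂ᵀ = (XᵀWX)⁻¹ XᵀW y,   W = diag(ε_i),   ε_i = (p_i|m / Σp|m)(p_i|f / Σp|f),

which is exact, fast, and approximately symmetric under swapping the inputs.

**Deformable stage.** A U-Net g predicts a stationary velocity field (SVF)
from the pair, explicitly antisymmetrized as ν = ½[g(m,f) − g(f,m)], and
integrated by scaling and squaring into a diffeomorphic warp φ = exp(ν);
integrating −ν yields φ⁻¹. The kernels η of g come from a hypernetwork
η = Γ_ξ(λ), conditioned on the regularization weight λ ∈ [0,1] of the loss

    L = (1 − λ) · L_overlap + λ · ‖∇u‖²,

so one trained model spans the whole smoothness trade-off at test time.
The deformable step runs in the affine mid-space reached by the matrix
square roots of T, making the joint transform ψ = T^½ ∘ φ ∘ T^½ symmetric.

The trainable networks are optimized through a small reverse-mode autodiff
engine over numpy (`synthreg.autodiff`); geometry, integration and metrics
are dimension-generic, while training runs at a 2D desk scale.

## Worked example

```python
import numpy as np
from synthreg import geometry as geo
from synthreg.affine_model import wls_solve
from synthreg.deformable_model import integrate_svf
from synthreg.metrics import folding_fraction, log_jacobian_spread

# recover a known affine from weighted point correspondences
rng = np.random.default_rng(7)
t_true = geo.build_affine(translation=[2.0, -1.0], rotation=15.0,
                          scale=[1.1, 0.9], shear=0.05)
src = rng.uniform(-10, 10, (8, 2))
t_hat = wls_solve(src, t_true.apply(src), weights=np.ones(8))
print("max |t_hat - t_true| =", np.abs(t_hat.matrix - t_true.matrix).max())

# integrate a smooth SVF and check diffeomorphism quality
from scipy.ndimage import gaussian_filter
nu = np.stack([gaussian_filter(rng.standard_normal((32, 32)), 4.0)
               for _ in range(2)], axis=-1)
nu *= 3.0 / np.abs(nu).max()
phi, phi_inv = integrate_svf(geo.VectorField(nu, "svf"), steps=10)
print("folding fraction: %.1f %%" % folding_fraction(phi))
print("log-Jacobian spread: %.4f" % log_jacobian_spread(phi))
```

Output:

```
max |t_hat - t_true| = 2.220446049250313e-16
folding fraction: 0.0 %
log-Jacobian spread: 0.1489
```

The WLS solve recovers the generating transform to machine precision from
exact correspondences, and the integrated warp is folding-free (no voxel
with a negative Jacobian determinant); its log-Jacobian spread quantifies
how far local volume change strays from 1.

## Command line

```sh
synthreg synth --out pairs --count 2 --seed 3          # synthetic image/label pairs
synthreg train-affine --seed 0 --out affine.npz        # affine Detector stage
synthreg train-joint --affine-checkpoint affine.npz --seed 0 --out model.npz
synthreg register moving.nii.gz fixed.nii.gz --checkpoint model.npz \
    --lambda 0.5 --steps 10 --out-moved moved.nii.gz --out-warp warp.nii.gz \
    --out-affine affine.txt --out-report report.json
synthreg evaluate --moved-labels a.nii.gz --fixed-labels b.nii.gz \
    --warp warp.nii.gz --report metrics.json
```

Raw inputs are conformed (isotropic spacing, standard orientation,
symmetric crop/pad) and min-max normalized internally; `--lambda` selects
the regularization strength without retraining.

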