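# Methods

## Transform model and coordinate conventions

All transforms follow pull-back semantics: registering a moving image m to
a fixed image f produces a map T from the fixed grid into m, and the moved
image is m∘T, evaluated with multilinear (images) or nearest (label maps)
interpolation; out-of-bounds samples read as zero. Affine transforms are
N×(N+1) matrices [A | v] acting on zero-centered voxel indices — a grid of
shape s has its origin at (s−1)/2 — so rotation, scale and shear pivot
about the grid center. World-space (scanner) coordinates enter only at the
I/O boundary, where `index_to_world` conjugates the index-space matrix with
the NIfTI voxel-to-world matrices and the center shifts.

`build_affine` composes elementary matrices in the fixed, documented order
translate ∘ rotate ∘ scale ∘ shear. Rotations are one angle (2D) or
intrinsic Euler angles about x, y, z applied in that order (3D); shear is
upper-triangular. Any fixed order works — training samples parameter ranges,
not a canonical decomposition — but determinism requires choosing one.

Matrix square roots (for the affine mid-space) are principal roots of the
homogeneous (N+1)² matrix via `scipy.linalg.sqrtm`. Transforms with
non-positive determinant or a rotation component at 180° (negative real
eigenvalue) have no principal root and are rejected; imaginary residues
below 1e-9 are truncated.

## Synthetic training data

The generator emulates whole-head segmentations without any acquisition:

- **Shape label maps** (`random_shape_labels`): a smooth centered blob
  stands in for the head; its core is partitioned into anatomy labels J by
  the argmax of independent Gaussian-smoothed random fields, and the
  surrounding shell is split into distractor labels, emulating non-brain
  tissue classes. Real heads can alternatively be binned into six equalized
  non-anatomy intensity classes with `nonbrain_bins`.
- **Augmentation**: per map, a uniform random affine (translation,
  rotation, scale, shear) composed with a Gaussian-smoothed random
  displacement field, applied in a single nearest-neighbor interpolation;
  a random edge slab may be zeroed to emulate a partial field of view.
  The displacement field is white noise smoothed at `warp_smoothness`
  (FWHM) and then rescaled so its RMS magnitude equals `warp_amplitude`
  voxels, making the amplitude parameter meaningful in voxel units.
- **Image synthesis**: each label in K receives a uniform random mean
  intensity; the image is then corrupted by anisotropic Gaussian blur, a
  multiplicative exponential bias field, additive Gaussian noise, global
  gamma exponentiation, and downsample/upsample along a random axis subset,
  each step applied independently with probability 0.5, and finally min-max
  normalized to [0, 1]. The corruption chain deliberately exceeds realistic
  acquisition physics; it is a domain-randomization device, not an MRI
  simulator.

Because image and labels derive from the same augmented map, every training
pair is voxelwise aligned by construction. All sampling is driven by
`numpy` Generators seeded from explicit integers, so the whole pipeline is
bit-reproducible.

What the generator does **not** emulate: real anatomical covariance between
subjects (two "subjects" are independent random shapes), partial-volume
label mixing, pathology, and true MRI noise statistics. Passing tests therefore
demonstrate that the mechanisms work — synthesis, feature-barycenter WLS,
hypernetwork conditioning, diffeomorphic integration, the schedule — not
that the desk-scale model transfers to acquired brain MRI.

## Affine stage

The Detector encoder (LeakyReLU slope 0.2 internals, max-pool halvings, a
final ReLU enforcing non-negativity) turns each min-max-normalized image
into k feature maps at a reduced resolution. Barycenters are computed on
the feature grid and rescaled by the total downsampling factor into
full-resolution zero-centered coordinates. Channel powers yield the
normalized weights ε_i, and the affine follows from the closed-form WLS
solve; the returned transform maps the fixed grid into the moving image
(ready for pull-back), which corresponds to fitting the fixed barycenters
to the moving ones.

Near-singular normal matrices (collinear barycenters) are handled by a 1e-8
ridge *biased toward the identity transform*, so directions the features do
not constrain default to the identity map instead of collapsing; strict
mode raises instead. Zero-power channels are flagged (inference) or
stabilized with a 1e-12 epsilon (training).

Symmetry: the WLS fit of swapped inputs is the exact inverse only for
zero-residual correspondences. With noisy features, symmetry holds as a
tolerance property, quantified by the symmetric inverse consistency
I = ½[E(T₁,T₂) + E(T₂,T₁)]; the desk-scale trained model reaches I ≈ 0.3–0.5
voxels, and the test suite asserts I < 0.5 voxels rather than an exact
identity.

## Deformable stage

The task U-Net g (3^N kernels, LeakyReLU, one max-pool level at desk scale,
factor-2 input downsampling with linear upsampling of the velocity field)
has no trainable parameters of its own: a hypernetwork Γ_ξ — four
ReLU-activated hidden layers of 32 units — maps λ to every kernel and bias
of g. Initialization silences the velocity head (zeros in the output bias
and the corresponding output-weight columns) while the internal kernels
start He-initialized, so the untrained model predicts an exactly zero SVF
and training starts from the identity warp.

The SVF is antisymmetrized, ν = ½[g(m,f) − g(f,m)], making swap-negation
exact by construction. Integration uses scaling and squaring with 10 steps
by default: ν/2¹⁰ followed by ten self-compositions, with bilinear,
edge-clamped interpolation for the composition lookups; the inverse warp is
obtained by integrating −ν (not by numerical inversion). Border voxels are
excluded from accuracy assertions. For the joint transform, both images are
first moved into the affine mid-space (m∘T^½, f∘T^(−½)); only this mode
yields symmetric joint transforms, though applying the deformable step
after the full affine is also supported.

## Losses

- Soft Dice overlap: −(2/|J|) Σ_j [Σ_x m_j f_j / (Σ_x m_j + f_j + 1e-7)],
  in [−1, 0]; per-label normalized.
- One-hot MSE overlap: mean over voxels and channels of the squared
  difference; proportional to each label's mismatch volume, which keeps
  large structures from being out-weighted by small ones.
- Regularizer: mean squared forward-difference gradient of the deformable
  displacement u, averaged over voxels, components and directions (a unit
  slope in one component/direction scores 1/N²). Any fixed reduction
  convention is valid since λ is swept; this one is documented so reported
  λ values are comparable. The regularizer never sees the affine component.
- Total: (1−λ)·overlap + λ·regularizer, λ ∈ [0, 1].

One-hot stacks of the moving map are warped with linear interpolation (soft
labels) inside the loss; the label maps themselves are warped with nearest
interpolation everywhere else. At the 2D desk scale the loss is evaluated
at full resolution; the factor-2 loss-input downsampling used at full 3D
scale is an efficiency measure this package applies only to network inputs.

The **affine stage trains with the Dice loss** at desk scale: on 32² grids
the MSE objective has a degenerate attractor (pushing the moving labels off
the grid can cost less than an imperfect alignment), which the per-label
Dice normalization avoids. The **joint stage trains with the MSE overlap**,
whose size-proportionality favors warp regularity at structure boundaries.
Both losses are available in both stages via `LossConfig`.

## Training protocol

Adaptive-moment SGD (Adam, float64, batch size 1) over consecutive strips.
Strip i uses the i-th entry of a decreasing learning-rate ladder; a
divergence — non-finite loss, or a positive loss exceeding 10× the strip
median after a 20-batch warm-up — reloads the last end-of-strip checkpoint
and steps down to the next rate; exhausting the ladder while diverging
aborts with diagnostics. Validation Dice D(t) is measured every
`val_interval` batches on fixed seeded pairs, and training stops once the
strip progress P = mean(D)/max(D) reaches 0.999. The first affine strip
optimizes a coarse two-group label merge for fast convergence; later strips
use the target grouping. Joint training draws λ ~ U[0,1] per batch and
freezes the affine weights θ (they are excluded from the graph entirely, so
they are bit-identical before and after).

Optimizer moments are reset at each rate change (a fresh Adam instance per
strip). Both training pairs of an iteration come from different pool
entries by default (`two_subjects`); augmenting one map twice
(`same_subject`) is supported.

### Desk-scale study conditions

Chosen once for the 32×32 2D setting and used by the tests and the
acceptance script:

| quantity | value |
| --- | --- |
| grid, labels | 32², 4 anatomy labels + 2-label distractor shell, 8 subjects |
| augmentation | translation ±3 vox, rotation ±20°, scale [0.9, 1.1], shear ±0.05 |
| deformation | RMS 1.5 vox, FWHM 4 vox; crop p = 0.3, fraction ≤ 0.2 |
| Detector | width 32, k = 16 channels, 1 pool level, input downsample 2 |
| U-Net / hypernet | width 12, 1 level; 4×32 hidden units |
| schedule | strips of 1500 (affine) / 1000 (joint), rates 1e-3, 3e-4, 1e-4 |
| integration | 10 scaling-and-squaring steps |

The full-scale defaults remain documented in the config classes (width 256,
k = 64, translation ±20 vox, rotation ±45°, scale [0.8, 1.2], shear ±0.1,
warp-smoothness FWHM 16 vox, rate ladder 1e-4/1e-5/1e-6); the desk values
scale the spatial quantities by the FOV ratio and shorten the million-batch
strips to a few thousand while keeping the schedule logic intact.

Against a per-pair brute-force affine oracle (Nelder–Mead on the soft-Dice
objective), cross-subject random-shape pairs top out around Dice ≈ 0.23;
the desk-scale Detector recovers part of that headroom (Dice above the
unregistered baseline, translations recovered to < 0.5 voxel) within a few
thousand iterations — the published setting trains six orders of magnitude
longer.

## Evaluation metrics

Hard Dice per label; Pearson NCC within a mask; MIND-MSE — the
modality-independent neighborhood descriptor with the standard 2N-neighbor
construction (Gaussian patch weighting, FWHM 2 voxels; local mean distance
as variance normalizer, scaled epsilon preserving intensity-affine
invariance; per-voxel max normalization), with non-anatomy content zeroed
before descriptor extraction. Warp regularity is assessed on the
*deformable* field φ: the Jacobian determinant via central differences
(one-sided at borders, identity included), the log-Jacobian spread
δ = mean |log J| over foreground voxels with J ≠ 0 (negative determinants
contribute |log |J||, with folding reported separately), and the folding
fraction as the percentage of foreground voxels with J < 0. Inverse
consistency E(T₁,T₂) is the mean displacement after composing two
transforms, in voxels; world-mm conversion lives in the I/O layer.

## Numerical choices

- Everything is float64; a fixed seed reproduces training bit-for-bit on
  the same BLAS configuration.
- Bilinear sampling gradients flow into both the image and the coordinates
  (spatial-transformer primitive); zeros mode for image/label pull-back,
  edge clamping for warp self-composition.
- `recode` ignores grouping keys absent from the map's label set, which
  makes it idempotent under the representative-label convention (each group
  id one of its own members).
- The six-bin non-anatomy labeling breaks intensity ties by stable flat
  grid order; bin sizes differ by at most one voxel.
- The stopping statistic can exceed 1.0 by floating-point rounding on a
  constant series; the threshold comparison tolerates this.

## Known limitations

- Trainable networks are 2D; the geometry, integration, metrics and WLS
  algebra are N-dimensional, but 3D training would need a more capable
  backend than the built-in autodiff engine.
- The synthetic shape pairs bound attainable overlap well below 1 (no
  shared anatomy between "subjects"); absolute Dice values are therefore
  not comparable to brain-MRI benchmarks.
- Affine symmetry is approximate (see above); the mid-space construction
  inherits that tolerance.
- The conform step targets a gross LIA orientation and isotropic spacing;
  oblique acquisitions are resampled, not re-sliced exactly.
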