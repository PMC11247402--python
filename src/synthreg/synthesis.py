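"""Training-pair synthesis: shape label maps, augmentation, image generation.

Training never touches acquired images. Each iteration draws a pair of label
maps, augments each with a random affine plus a smooth random deformation,
and synthesizes an intensity image per map with randomized contrast, blur,
bias field, noise, gamma and resolution. Because image and label map derive
from the same augmented map, the pair is voxelwise aligned by construction.

Label maps carry a full label set K (used for synthesis, including
"distractor" labels surrounding the anatomy to emulate non-brain content)
and an anatomy subset J of K whose overlap the losses optimize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .geometry import (AffineTransform, GridSpec, VectorField, build_affine,
                       identity_grid, resample)

__all__ = [
    "LabelMap", "GenerationConfig", "random_shape_labels",
    "sample_augmentation", "augment_labelmap", "synthesize_image", "recode",
    "nonbrain_bins", "one_hot", "simulate_thick_slices", "fwhm_to_sigma",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian full-width at half-maximum to a standard deviation."""
    return float(fwhm) * FWHM_TO_SIGMA


@dataclass
class LabelMap:
    """Integer grid with full label set K and anatomy subset J (J excludes 0)."""

    labels: np.ndarray
    full_set: tuple
    anatomy_set: tuple

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label grid must be integer-valued")
        self.full_set = tuple(int(k) for k in self.full_set)
        self.anatomy_set = tuple(int(j) for j in self.anatomy_set)
        if 0 in self.anatomy_set:
            raise ValueError("background (0) cannot be an anatomy label")
        if not set(self.anatomy_set) <= set(self.full_set):
            raise ValueError("anatomy set J must be a subset of K")
        present = set(np.unique(self.labels)) - {0}
        if not present <= set(self.full_set):
            raise ValueError("grid contains labels outside K")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.labels.shape)

    def anatomy_mask(self) -> np.ndarray:
        return np.isin(self.labels, self.anatomy_set)


@dataclass
class GenerationConfig:
    """Ranges for label-map augmentation and image synthesis.

    Spatial units are voxels; defaults target the full-scale 256-voxel FOV
    (see the 2D desk-scale preset :meth:`desk_2d`). Each corruption step of
    the synthesis chain is applied independently with ``step_probability``.
    """

    translation_range: float = 20.0      # +/- voxels
    rotation_range: float = 45.0         # +/- degrees
    scale_range: tuple = (0.8, 1.2)
    shear_range: float = 0.1             # +/- unitless
    warp_amplitude: float = 3.0          # RMS displacement, voxels
    warp_smoothness: float = 16.0        # Gaussian FWHM, voxels
    crop_probability: float = 0.5
    crop_fraction: float = 0.2
    intensity_mean_range: tuple = (0.25, 1.0)
    noise_sd_range: tuple = (0.0, 0.1)
    blur_fwhm_range: tuple = (0.0, 4.0)  # per axis
    bias_amplitude: float = 0.3
    bias_smoothness: float = 40.0        # Gaussian FWHM, voxels
    gamma_log_sd: float = 0.25
    downsample_factor_range: tuple = (1.0, 4.0)
    step_probability: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("scale_range", "intensity_mean_range", "noise_sd_range",
                     "blur_fwhm_range", "downsample_factor_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is not well-ordered")
        for name in ("crop_probability", "step_probability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def desk_2d(cls, **overrides) -> "GenerationConfig":
        """Desk-scale conditions for 32^2 grids (ranges scaled to the FOV)."""
        base = dict(translation_range=3.0, rotation_range=20.0,
                    scale_range=(0.9, 1.1), shear_range=0.05,
                    warp_amplitude=1.5, warp_smoothness=4.0,
                    crop_probability=0.3, crop_fraction=0.2,
                    blur_fwhm_range=(0.0, 2.0), bias_smoothness=12.0,
                    downsample_factor_range=(1.0, 2.0))
        base.update(overrides)
        return cls(**base)

    def with_seed(self, seed: int) -> "GenerationConfig":
        return replace(self, seed=int(seed))


# ---------------------------------------------------------------------------
# shape label maps
# ---------------------------------------------------------------------------

def _smooth_field(rng, shape, sigma):
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma)


def _normalized(x):
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x


def random_shape_labels(shape, num_labels: int, smoothness: float, seed: int,
                        num_distractors: int = 2) -> LabelMap:
    """Generate a random multi-label shape map with a distractor shell.

    A smooth foreground blob centered on the grid plays the role of the head;
    its core is partitioned into ``num_labels`` anatomy labels (the argmax
    over independent smooth random fields), and the surrounding shell is
    split into ``num_distractors`` labels that stand in for non-anatomy image
    content. If a draw leaves an anatomy label empty, the generator retries
    with a derived seed (documented contract); after 8 attempts it raises.
    """
    if num_labels < 2:
        raise ValueError("need at least two anatomy labels")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    shape = tuple(int(n) for n in shape)
    sigma = fwhm_to_sigma(smoothness)
    radius = np.linalg.norm(identity_grid(shape) /
                            (0.38 * np.asarray(shape, dtype=float)), axis=-1)
    for attempt in range(8):
        rng = np.random.default_rng(int(seed) + 7919 * attempt)
        outline = _normalized(_smooth_field(rng, shape, 2.0 * sigma))
        score = 1.0 - radius + 0.25 * outline
        core = score > 0.35
        head = score > 0.05
        fields = np.stack([_smooth_field(rng, shape, sigma)
                           for _ in range(num_labels)])
        labels = np.zeros(shape, dtype=np.int64)
        labels[core] = fields.argmax(axis=0)[core] + 1
        shell = head & ~core
        if num_distractors > 0 and shell.any():
            dfields = np.stack([_smooth_field(rng, shape, sigma)
                                for _ in range(num_distractors)])
            labels[shell] = dfields.argmax(axis=0)[shell] + num_labels + 1
        anatomy = tuple(range(1, num_labels + 1))
        present = set(np.unique(labels))
        if set(anatomy) <= present:
            full = tuple(sorted(present - {0}))
            return LabelMap(labels, full, anatomy)
    raise RuntimeError("failed to draw a label map with all anatomy labels")


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def sample_augmentation(config: GenerationConfig, shape, seed: int):
    """Draw a random affine and a smooth random displacement field.

    The affine parameters are uniform within the configured ranges; the
    displacement is Gaussian-smoothed white noise rescaled so its RMS
    magnitude equals ``warp_amplitude`` voxels (zero amplitude gives a zero
    field). Deterministic under the seed.
    """
    rng = np.random.default_rng(int(seed))
    shape = tuple(int(n) for n in shape)
    ndim = len(shape)
    n_rot = 1 if ndim == 2 else 3
    n_shear = 1 if ndim == 2 else 3
    t = rng.uniform(-config.translation_range, config.translation_range, ndim)
    r = rng.uniform(-config.rotation_range, config.rotation_range, n_rot)
    s = rng.uniform(config.scale_range[0], config.scale_range[1], ndim)
    sh = rng.uniform(-config.shear_range, config.shear_range, n_shear)
    affine = build_affine(t, r, s, sh)
    if config.warp_amplitude > 0:
        sigma = fwhm_to_sigma(config.warp_smoothness)
        u = np.stack([ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
                      for _ in range(ndim)], axis=-1)
        rms = np.sqrt(np.mean(u ** 2))
        if rms > 0:
            u *= config.warp_amplitude / rms
    else:
        rng.standard_normal(shape)  # keep the stream aligned across configs
        u = np.zeros(shape + (ndim,))
    return affine, VectorField(u, "displacement", GridSpec(shape))


def augment_labelmap(s: LabelMap, affine: AffineTransform, disp: VectorField,
                     config: GenerationConfig, seed: int) -> LabelMap:
    """Warp a label map once (nearest) and optionally zero an edge slab.

    Affine and displacement are combined into the single dense pull-back warp
    psi(x) = T(x) + u(x), so the map is interpolated exactly once. The FOV
    crop zeroes a random edge slab of up to ``crop_fraction`` of the axis
    extent with probability ``crop_probability`` (array shape is preserved).
    """
    shape = s.labels.shape
    if disp.grid.shape != shape:
        raise ValueError("displacement grid does not match the label map")
    warp = VectorField(affine.apply(identity_grid(shape)) + disp.values,
                       "warp", GridSpec(shape))
    moved = resample(s.labels.astype(np.float64), warp, "nearest")
    moved = np.rint(moved).astype(s.labels.dtype)
    rng = np.random.default_rng(int(seed))
    do_crop = rng.random() < config.crop_probability
    axis = int(rng.integers(len(shape)))
    lead = bool(rng.integers(2))
    frac = rng.uniform(0.0, config.crop_fraction)
    if do_crop:
        n = int(np.floor(frac * shape[axis]))
        if n > 0:
            sl = [slice(None)] * len(shape)
            sl[axis] = slice(0, n) if lead else slice(shape[axis] - n, None)
            moved[tuple(sl)] = 0
    return LabelMap(moved, s.full_set, s.anatomy_set)


# ---------------------------------------------------------------------------
# image synthesis
# ---------------------------------------------------------------------------

def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi - lo <= 0:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def synthesize_image(s: LabelMap, config: GenerationConfig, seed: int) -> np.ndarray:
    """Synthesize an intensity image from a label map.

    Chain: per-label random means, anisotropic Gaussian blur, multiplicative
    exponential bias field, additive Gaussian noise, global gamma
    exponentiation (after min-max), random-axis downsample/upsample, final
    min-max normalization to [0, 1]. Each corruption step is applied
    independently with probability ``step_probability``; steps with
    degenerate (zero) ranges are no-ops. Deterministic under the seed.
    """
    present = [k for k in s.full_set if np.any(s.labels == k)]
    if not present:
        raise ValueError("label map has no non-background labels")
    rng = np.random.default_rng(int(seed))
    lo, hi = config.intensity_mean_range
    lut = np.zeros(max(s.full_set) + 1)
    for k in s.full_set:
        lut[k] = rng.uniform(lo, hi)
    img = lut[s.labels]
    ndim = img.ndim

    apply_step = rng.random(5) < config.step_probability
    # 1: anisotropic blur
    fwhm = rng.uniform(config.blur_fwhm_range[0], config.blur_fwhm_range[1], ndim)
    if apply_step[0] and fwhm.max() > 0:
        img = ndimage.gaussian_filter(img, [fwhm_to_sigma(f) for f in fwhm])
    # 2: multiplicative bias field exp(smooth noise)
    bias_noise = rng.standard_normal(img.shape)
    if apply_step[1] and config.bias_amplitude > 0:
        field = ndimage.gaussian_filter(bias_noise,
                                        fwhm_to_sigma(config.bias_smoothness))
        field = _normalized(field) if field.std() > 0 else field
        img = img * np.exp(config.bias_amplitude * field)
    # 3: additive Gaussian noise
    sd = rng.uniform(config.noise_sd_range[0], config.noise_sd_range[1])
    noise = rng.standard_normal(img.shape)
    if apply_step[2] and sd > 0:
        img = img + sd * noise
    # 4: global gamma exponentiation
    gamma = rng.normal(0.0, config.gamma_log_sd) if config.gamma_log_sd > 0 else 0.0
    if apply_step[3] and gamma != 0.0:
        img = _minmax(img) ** np.exp(gamma)
    # 5: resolution simulation along a random axis subset
    f_lo, f_hi = config.downsample_factor_range
    factor = rng.uniform(f_lo, f_hi)
    axes = rng.random(ndim) < 0.5
    if apply_step[4] and factor > 1.0 and axes.any():
        zoom_down = [1.0 / factor if a else 1.0 for a in axes]
        small = ndimage.zoom(img, zoom_down, order=1, grid_mode=True,
                             mode="nearest")
        back = [n / m for n, m in zip(img.shape, small.shape)]
        img = ndimage.zoom(small, back, order=1, grid_mode=True, mode="nearest")
        img = img[tuple(slice(0, n) for n in s.labels.shape)]
    return _minmax(img)


# ---------------------------------------------------------------------------
# label bookkeeping
# ---------------------------------------------------------------------------

def recode(s: LabelMap, grouping: dict) -> LabelMap:
    """Merge labels into groups; labels outside the grouping become 0.

    ``grouping`` maps original label -> group id. Group ids that are not
    themselves keys are treated as mapping to themselves. With the
    representative-label convention (each group id is one of its own members,
    e.g. {1:1, 2:1, 3:3, 4:3}) recode is idempotent. Mapping background to a
    group is an error.
    """
    grouping = {int(k): int(v) for k, v in grouping.items()}
    if 0 in grouping and grouping[0] != 0:
        raise ValueError("background cannot be assigned to a group")
    # keys absent from K are ignored, which keeps recode idempotent when a
    # grouping is re-applied to its own output
    table = {k: v for k, v in grouping.items() if k in s.full_set}
    for v in grouping.values():
        table.setdefault(v, v)
    lut = np.zeros(max(list(table) + list(s.full_set)) + 1, dtype=s.labels.dtype)
    for k, v in table.items():
        lut[k] = v
    out = lut[s.labels]
    groups = sorted({v for v in table.values() if v != 0})
    return LabelMap(out, tuple(groups), tuple(groups))


def nonbrain_bins(image: np.ndarray, anatomy_mask: np.ndarray,
                  num_bins: int = 6, first_label: int = 101) -> LabelMap:
    """Sort non-zero voxels outside the anatomy into equalized intensity bins.

    Voxels are ranked by intensity (stable tie-break by flat grid order) and
    split into ``num_bins`` bins whose sizes differ by at most one voxel.
    The returned map uses labels ``first_label .. first_label+num_bins-1``,
    chosen disjoint from the anatomy labels by the caller.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != anatomy_mask.shape:
        raise ValueError("mask must be aligned with the image")
    exterior = (~np.asarray(anatomy_mask, dtype=bool)) & (image != 0)
    out = np.zeros(image.shape, dtype=np.int64)
    idx = np.flatnonzero(exterior.ravel())
    if idx.size == 0:
        warnings.warn("no non-zero voxels outside the anatomy; empty result")
        return LabelMap(out, (), ())
    order = idx[np.argsort(image.ravel()[idx], kind="stable")]
    flat = out.ravel()
    for b, chunk in enumerate(np.array_split(order, num_bins)):
        flat[chunk] = first_label + b
    out = flat.reshape(image.shape)
    present = tuple(sorted(set(np.unique(out)) - {0}))
    return LabelMap(out, present, ())


def one_hot(s: LabelMap, labels) -> np.ndarray:
    """Per-label binary channels, shape (len(labels), *grid); sums <= 1."""
    labels = [int(x) for x in labels]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels in one-hot request")
    if not set(labels) <= set(s.full_set) | {0}:
        raise ValueError("requested labels outside K")
    return np.stack([(s.labels == j).astype(np.float64) for j in labels])


# ---------------------------------------------------------------------------
# acquisition simulation
# ---------------------------------------------------------------------------

def simulate_thick_slices(image: np.ndarray, dz: float, axis: int = 0) -> np.ndarray:
    """Simulate a thick-slice acquisition along one axis.

    Blurs slice-normal with a Gaussian of FWHM ``dz`` voxels, extracts slices
    ``dz`` apart by linear interpolation, and linearly upsamples back to the
    original size, emulating partial-volume effects of 2D stacks.
    """
    image = np.asarray(image, dtype=float)
    n = image.shape[axis]
    if dz < 1:
        raise ValueError("slice thickness must be at least 1 voxel")
    if dz >= n:
        raise ValueError("slice thickness exceeds the axis extent")
    blurred = ndimage.gaussian_filter1d(image, fwhm_to_sigma(dz), axis=axis)
    x = np.moveaxis(blurred, axis, 0)
    num = int(np.floor((n - 1) / dz)) + 1
    pos = np.arange(num) * dz

    def interp_axis0(arr, positions):
        lo = np.floor(positions).astype(int)
        hi = np.minimum(lo + 1, arr.shape[0] - 1)
        frac = (positions - lo).reshape((-1,) + (1,) * (arr.ndim - 1))
        return (1 - frac) * arr[lo] + frac * arr[hi]

    slices = interp_axis0(x, pos)
    back = np.clip(np.arange(n) / dz, 0, num - 1)
    restored = interp_axis0(slices, back)
    return np.moveaxis(restored, 0, axis)
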