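"""The "Detector" affine network: features -> barycenters -> closed-form WLS.

A shared convolutional encoder maps each image to k non-negative spatial
feature maps. Each map is summarized by its center of mass (barycenter) and
total mass (channel power); the barycenters of the moving and fixed image
form corresponding weighted point clouds. The affine transform is then the
closed-form weighted-least-squares fit aligning the clouds,

    t_hat^T = (X^T W X)^-1 X^T W y,

with per-channel weights eps_i given by the product of the power shares of
channel i on both sides. Because the solve is exact and the encoder is
shared, swapping the input images approximately inverts the transform.

Coordinates are zero-centered voxel indices of the *full-resolution* grid:
barycenters computed on internally downsampled feature maps are rescaled by
the total downsampling factor before the solve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .geometry import AffineTransform, GridSpec, identity_grid

__all__ = ["DetectorConfig", "FeatureStack", "WeightedPointCloud",
           "init_detector_params", "detector_forward", "barycenters",
           "wls_weights", "wls_solve", "estimate_affine",
           "estimate_affine_tensor"]

_POWER_EPS = 1e-12


@dataclass
class DetectorConfig:
    """Architecture constants of the feature encoder.

    Full-scale defaults follow the published architecture (width 256, k=64);
    :meth:`desk_2d` gives the small 2D configuration used for desk-scale
    training and the test suite.
    """

    width: int = 256
    channels: int = 64
    leaky_slope: float = 0.2
    levels: int = 2
    input_downsample: int = 2

    def __post_init__(self):
        if min(self.width, self.channels, self.levels) < 1:
            raise ValueError("width, channels and levels must be positive")
        if not 0.0 < self.leaky_slope < 1.0:
            raise ValueError("leaky_slope must lie in (0, 1)")

    @classmethod
    def desk_2d(cls) -> "DetectorConfig":
        return cls(width=32, channels=16, levels=1, input_downsample=2)

    @property
    def total_downsample(self) -> int:
        return self.input_downsample * 2 ** self.levels


@dataclass
class FeatureStack:
    """k non-negative maps on a (possibly downsampled) grid.

    ``scale`` converts feature-grid centered coordinates into
    full-resolution centered voxel coordinates.
    """

    maps: object            # ndarray or Tensor, shape (k, *feature_grid)
    scale: float = 1.0
    grid: GridSpec = field(default=None)

    def __post_init__(self):
        shape = self.maps.shape[1:]
        if self.grid is None:
            self.grid = GridSpec(tuple(shape))


@dataclass
class WeightedPointCloud:
    """Barycenters (k, N) with channel powers (k,), full-resolution units."""

    points: np.ndarray
    powers: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.powers = np.asarray(self.powers, dtype=float)
        if np.any(self.powers < 0) or not np.all(np.isfinite(self.powers)):
            raise ValueError("powers must be finite and non-negative")
        active = self.powers > 0
        if not np.all(np.isfinite(self.points[active])):
            raise ValueError("barycenters of active channels must be finite")

    @property
    def zero_power(self) -> np.ndarray:
        return self.powers <= 0


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------

def init_detector_params(config: DetectorConfig, seed: int = 0,
                         in_channels: int = 1) -> list:
    """He-initialized kernels/biases for the 2D encoder, as leaf Tensors.

    Layer layout: conv(in->w), then per level [maxpool, conv(w->w)], then a
    final conv(w->k) whose small positive bias keeps channels initially
    active under the output ReLU.
    """
    rng = np.random.default_rng(int(seed))
    params = []

    def conv(cin, cout, bias0=0.0):
        fan_in = cin * 9
        w = rng.standard_normal((cout, cin, 3, 3)) * np.sqrt(2.0 / fan_in)
        params.append(Tensor(w))
        params.append(Tensor(np.full(cout, bias0)))

    conv(in_channels, config.width)
    for _ in range(config.levels):
        conv(config.width, config.width)
    conv(config.width, config.channels, bias0=0.01)
    return params


def _forward_maps(x: Tensor, params: list, config: DetectorConfig) -> Tensor:
    h, w = x.shape[-2:]
    if x.ndim == 2:
        x = x.reshape(1, h, w)
    if config.input_downsample > 1:
        x = ad.resize2d_linear(x, (h // config.input_downsample,
                                   w // config.input_downsample))
    it = iter(params)
    x = ad.leaky_relu(ad.conv2d(x, next(it), next(it)), config.leaky_slope)
    for _ in range(config.levels):
        x = ad.maxpool2d(x, 2)
        x = ad.leaky_relu(ad.conv2d(x, next(it), next(it)), config.leaky_slope)
    return ad.relu(ad.conv2d(x, next(it), next(it)))


def detector_forward(image, params: list, config: DetectorConfig) -> FeatureStack:
    """Run the encoder on a min-max-normalized image.

    Accepts a numpy array (inference; returns numpy maps) or a Tensor
    (training; keeps the graph). Output spatial shape is the input shape
    divided by ``input_downsample * 2**levels``.
    """
    arr = image.value if isinstance(image, Tensor) else np.asarray(image, float)
    if arr.max() > 1.0 + 1e-6 or arr.min() < -1e-6:
        raise ValueError("detector input must be min-max normalized to [0, 1]")
    x = image if isinstance(image, Tensor) else Tensor(arr)
    maps = _forward_maps(x, params, config)
    scale = float(config.total_downsample)
    if not isinstance(image, Tensor):
        return FeatureStack(maps.value, scale)
    return FeatureStack(maps, scale)


# ---------------------------------------------------------------------------
# barycenters and WLS
# ---------------------------------------------------------------------------

def barycenters(stack: FeatureStack):
    """Centers of mass a_i and channel powers p_i of a feature stack.

    Coordinates are zero-centered and rescaled to full-resolution voxel
    units. Channels with zero total power are flagged (numpy path) or
    stabilized with a tiny epsilon (training path); an all-zero stack is a
    degenerate-features error.
    """
    maps = stack.maps
    coords = identity_grid(stack.grid.shape) * stack.scale  # (*grid, N)
    ndim = coords.shape[-1]
    spatial = tuple(range(1, ndim + 1))
    if isinstance(maps, Tensor):
        p = maps.sum(axis=spatial)                      # (k,)
        cols = [(maps * np.moveaxis(coords, -1, 0)[d]).sum(axis=spatial)
                for d in range(ndim)]
        if not np.any(p.value > 0):
            raise ValueError("degenerate features: all channels have zero power")
        denom = p + _POWER_EPS
        pts = ad.concatenate([(c / denom).reshape(-1, 1) for c in cols], axis=1)
        return pts, p
    p = maps.sum(axis=spatial)
    if not np.any(p > 0):
        raise ValueError("degenerate features: all channels have zero power")
    num = np.stack([(maps * coords[..., d]).sum(axis=spatial)
                    for d in range(ndim)], axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pts = num / p[:, None]
    pts[p <= 0] = 0.0
    return WeightedPointCloud(pts, p)


def wls_weights(powers_m, powers_f):
    """Normalized channel weights eps_i = (p_i|m / sum p|m)(p_i|f / sum p|f)."""
    pm = powers_m.value if isinstance(powers_m, Tensor) else np.asarray(powers_m, float)
    pf = powers_f.value if isinstance(powers_f, Tensor) else np.asarray(powers_f, float)
    if pm.sum() <= 0 or pf.sum() <= 0:
        raise ValueError("zero total power on one side")
    if isinstance(powers_m, Tensor) or isinstance(powers_f, Tensor):
        powers_m = ad.as_tensor(powers_m)
        powers_f = ad.as_tensor(powers_f)
        return (powers_m / powers_m.sum()) * (powers_f / powers_f.sum())
    return (pm / pm.sum()) * (pf / pf.sum())


def _wls_tensor(src: Tensor, dst: Tensor, w: Tensor, ridge: float) -> Tensor:
    k, ndim = src.shape
    x = ad.concatenate([src, Tensor(np.ones((k, 1)))], axis=1)  # (k, N+1)
    wx = x * w.reshape(-1, 1)
    xtwx = ad.matmul(_transpose(x), wx)
    xtwy = ad.matmul(_transpose(x), dst * w.reshape(-1, 1))
    if ridge > 0:
        # bias unconstrained directions toward the identity transform
        xtwx = xtwx + Tensor(ridge * np.eye(ndim + 1))
        xtwy = xtwy + Tensor(ridge * np.vstack([np.eye(ndim),
                                                np.zeros((1, ndim))]))
    t_t = ad.matmul(ad.matinv(xtwx), xtwy)                      # (N+1, N)
    return _transpose(t_t)                                       # (N, N+1)


def _transpose(t: Tensor) -> Tensor:
    src = t

    def back(g):
        src.grad += g.T

    return Tensor(t.value.T, (t,), back)


def wls_solve(moving, fixed, weights, ridge: float = 1e-8,
              strict: bool = False):
    """Exact weighted-least-squares affine mapping moving points to fixed.

    Minimizes sum_i eps_i ||fixed_i - t(moving_i)||^2 in closed form. A
    nearly singular normal matrix (collinear barycenters) raises in strict
    mode; otherwise a tiny ridge biased toward the identity transform is
    added with a warning, so directions the data do not constrain default
    to the identity map instead of collapsing.
    """
    src = moving.points if isinstance(moving, WeightedPointCloud) else np.asarray(moving, float)
    dst = fixed.points if isinstance(fixed, WeightedPointCloud) else np.asarray(fixed, float)
    w = np.asarray(weights, dtype=float)
    k, ndim = src.shape
    if k < ndim + 1:
        raise ValueError("need at least N+1 points")
    x = np.hstack([src, np.ones((k, 1))])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w[:, None] * dst)
    cond = np.linalg.cond(xtwx)
    if cond > 1e12:
        if strict:
            raise np.linalg.LinAlgError(
                "rank-deficient WLS system (collinear barycenters)")
        warnings.warn("ill-conditioned WLS system; adding ridge %g" % ridge)
        identity_tt = np.vstack([np.eye(ndim), np.zeros((1, ndim))])
        xtwx = xtwx + ridge * np.eye(ndim + 1)
        xtwy = xtwy + ridge * identity_tt
    t_t = np.linalg.solve(xtwx, xtwy)
    return AffineTransform(t_t.T)


def wls_objective(t: AffineTransform, moving: np.ndarray, fixed: np.ndarray,
                  weights: np.ndarray) -> float:
    """The weighted residual the WLS solve minimizes (for cross-checks)."""
    res = fixed - t.apply(moving)
    return float((np.asarray(weights) * (res ** 2).sum(axis=1)).sum())


# ---------------------------------------------------------------------------
# end-to-end affine estimation
# ---------------------------------------------------------------------------

def estimate_affine_tensor(m, f, params: list, config: DetectorConfig,
                           ridge: float = 1e-8) -> Tensor:
    """Differentiable pipeline: shared encoder on both images, barycenters,
    power weights, WLS solve. Returns the (N, N+1) pull-back transform
    (fixed index -> moving index) as a Tensor."""
    fm = detector_forward(m if isinstance(m, Tensor) else Tensor(np.asarray(m, float)),
                          params, config)
    ff = detector_forward(f if isinstance(f, Tensor) else Tensor(np.asarray(f, float)),
                          params, config)
    a_pts, p_m = barycenters(fm)
    b_pts, p_f = barycenters(ff)
    eps = wls_weights(p_m, p_f)
    # pull-back: source = fixed barycenters, target = moving barycenters
    return _wls_tensor(b_pts, a_pts, eps, ridge)


def estimate_affine(m: np.ndarray, f: np.ndarray, params: list,
                    config: DetectorConfig, strict: bool = False) -> AffineTransform:
    """Estimate the affine pull-back transform T (fixed grid -> moving image).

    Resampling the moving image with T aligns it to the fixed image. The
    mid-space roots T^(1/2), T^(-1/2) follow via geometry.sqrt_affine.
    """
    fm = detector_forward(np.asarray(m, float), params, config)
    ff = detector_forward(np.asarray(f, float), params, config)
    cloud_m = barycenters(fm)
    cloud_f = barycenters(ff)
    eps = wls_weights(cloud_m.powers, cloud_f.powers)
    return wls_solve(cloud_f, cloud_m, eps, strict=strict)
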