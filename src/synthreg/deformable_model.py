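"""Hypernetwork-conditioned diffeomorphic deformable registration.

A U-Net g predicts a stationary velocity field (SVF) from the concatenated
image pair. Its convolution kernels eta are not trained directly: a small
feed-forward hypernetwork Gamma_xi maps the regularization weight lambda in
[0, 1] to eta = Gamma_xi(lambda), so a single trained model covers the whole
regularization trade-off at test time.

Because g is not symmetric in its inputs, the SVF is explicitly
antisymmetrized, nu = 0.5 [g(m, f) - g(f, m)], which makes swapping the
images negate the velocity field exactly. Scaling and squaring integrates
nu into a diffeomorphic warp phi = exp(nu); integrating -nu yields the
inverse warp. For joint registration the deformable step runs in the affine
mid-space reached by the matrix square roots of the affine transform, and
the total transform is psi = T^(1/2) o phi o T^(1/2).

The trainable networks are 2D (desk scale); the surrounding algebra
(integration, composition, metrics) is dimension-generic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .geometry import (AffineTransform, GridSpec, VectorField, compose_joint,
                       identity_grid, invert, resample, sqrt_affine)

__all__ = ["HyperNetConfig", "UNetConfig", "unet_layer_shapes",
           "init_hypernet_params", "hypernet_forward", "unet_svf_tensor",
           "unet_svf", "symmetrize_svf", "integrate_svf_tensor",
           "integrate_svf", "joint_register"]


@dataclass
class HyperNetConfig:
    """Feed-forward lambda -> kernels map: 4 ReLU hidden layers of 32 units."""

    hidden_layers: int = 4
    hidden_units: int = 32

    def __post_init__(self):
        if min(self.hidden_layers, self.hidden_units) < 1:
            raise ValueError("hypernetwork dimensions must be positive")


@dataclass
class UNetConfig:
    """Deformable task network g: U-Net with 3^N kernels, no own parameters."""

    width: int = 256
    levels: int = 2
    integration_steps: int = 10
    input_downsample: int = 2
    leaky_slope: float = 0.2

    def __post_init__(self):
        if min(self.width, self.levels, self.integration_steps) < 1:
            raise ValueError("width, levels, integration_steps must be >= 1")

    @classmethod
    def desk_2d(cls) -> "UNetConfig":
        return cls(width=12, levels=1, input_downsample=2)


def unet_layer_shapes(config: UNetConfig, in_channels: int = 2,
                      ndim: int = 2) -> list:
    """Kernel/bias shapes of g in forward order; defines Gamma's output size."""
    w = config.width
    shapes = [(w, in_channels, 3, 3), (w,)]
    for _ in range(config.levels):
        shapes += [(w, w, 3, 3), (w,)]
    for _ in range(config.levels):
        shapes += [(w, 2 * w, 3, 3), (w,)]
    shapes += [(ndim, w, 3, 3), (ndim,)]
    return shapes


def _param_count(shapes) -> int:
    return int(sum(np.prod(s) for s in shapes))


# ---------------------------------------------------------------------------
# hypernetwork
# ---------------------------------------------------------------------------

def init_hypernet_params(unet_config: UNetConfig, hyper_config: HyperNetConfig,
                         seed: int = 0, in_channels: int = 2,
                         ndim: int = 2) -> list:
    """Initialize xi so the untrained g predicts an exactly zero SVF.

    The hypernetwork's output bias carries He-initialized values for the
    internal U-Net kernels but zeros for the final velocity layer, and the
    output weight matrix is scaled small; hence eta(lambda) starts with sane
    internal features and a silent output head.
    """
    rng = np.random.default_rng(int(seed))
    shapes = unet_layer_shapes(unet_config, in_channels, ndim)
    n_out = _param_count(shapes)
    params = []
    fan = 1
    for _ in range(hyper_config.hidden_layers):
        params.append(Tensor(rng.standard_normal((fan, hyper_config.hidden_units))
                             * np.sqrt(2.0 / fan)))
        params.append(Tensor(np.zeros(hyper_config.hidden_units)))
        fan = hyper_config.hidden_units
    w_out = rng.standard_normal((fan, n_out)) * (np.sqrt(2.0 / fan) * 1e-2)
    bias = []
    for shape in shapes:
        if len(shape) == 4:  # conv kernel
            he = np.sqrt(2.0 / (shape[1] * shape[2] * shape[3]))
            bias.append(rng.standard_normal(int(np.prod(shape))) * he)
        else:
            bias.append(np.zeros(int(np.prod(shape))))
    # silence the output head (last kernel + bias), in bias and weight columns
    bias[-2][...] = 0.0
    bias[-1][...] = 0.0
    n_head = bias[-2].size + bias[-1].size
    w_out[:, n_out - n_head:] = 0.0
    params.append(Tensor(w_out))
    params.append(Tensor(np.concatenate(bias)))
    return params


def hypernet_forward(lam: float, xi: list, unet_config: UNetConfig,
                     in_channels: int = 2, ndim: int = 2) -> list:
    """Map lambda to the kernels/biases eta of g, as graph-connected Tensors."""
    lam = float(lam)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    shapes = unet_layer_shapes(unet_config, in_channels, ndim)
    x = Tensor(np.array([[lam]]))
    n_hidden = (len(xi) - 2) // 2
    for i in range(n_hidden):
        x = ad.relu(ad.matmul(x, xi[2 * i]) + xi[2 * i + 1])
    flat = (ad.matmul(x, xi[-2]) + xi[-1]).reshape(-1)
    eta, off = [], 0
    for shape in shapes:
        n = int(np.prod(shape))
        eta.append(flat[off:off + n].reshape(shape))
        off += n
    return eta


# ---------------------------------------------------------------------------
# task network g
# ---------------------------------------------------------------------------

def unet_svf_tensor(m, f, eta: list, config: UNetConfig) -> Tensor:
    """U-Net SVF prediction on channel-concatenated (m, f); output (N, H, W).

    Inputs are optionally factor-2 downsampled internally and the velocity
    field is linearly upsampled back to the input grid, in full-resolution
    voxel units.
    """
    m = m if isinstance(m, Tensor) else Tensor(np.asarray(m, float))
    f = f if isinstance(f, Tensor) else Tensor(np.asarray(f, float))
    if m.shape != f.shape:
        raise ValueError("images must share a grid")
    h, w = m.shape
    x = ad.concatenate([m.reshape(1, h, w), f.reshape(1, h, w)], axis=0)
    if config.input_downsample > 1:
        x = ad.resize2d_linear(x, (h // config.input_downsample,
                                   w // config.input_downsample))
    it = iter(eta)
    x = ad.leaky_relu(ad.conv2d(x, next(it), next(it)), config.leaky_slope)
    skips = []
    for _ in range(config.levels):
        skips.append(x)
        x = ad.maxpool2d(x, 2)
        x = ad.leaky_relu(ad.conv2d(x, next(it), next(it)), config.leaky_slope)
    for _ in range(config.levels):
        x = ad.upsample2d_linear(x, 2)
        x = ad.concatenate([x, skips.pop()], axis=0)
        x = ad.leaky_relu(ad.conv2d(x, next(it), next(it)), config.leaky_slope)
    x = ad.conv2d(x, next(it), next(it))
    if config.input_downsample > 1:
        x = ad.resize2d_linear(x, (h, w))
    return x


def unet_svf(m: np.ndarray, f: np.ndarray, eta: list,
             config: UNetConfig) -> VectorField:
    """Numpy-facing wrapper around :func:`unet_svf_tensor`."""
    out = unet_svf_tensor(m, f, eta, config)
    return VectorField(np.moveaxis(out.value, 0, -1), "svf")


def symmetrize_svf(v_fwd, v_bwd):
    """nu = 0.5 (g(m,f) - g(f,m)); swapping the inputs negates nu exactly."""
    if isinstance(v_fwd, VectorField):
        if v_fwd.semantics != "svf" or v_bwd.semantics != "svf":
            raise ValueError("symmetrization applies to SVFs")
        return VectorField(0.5 * (v_fwd.values - v_bwd.values), "svf",
                           v_fwd.grid)
    return (v_fwd - v_bwd) * 0.5


# ---------------------------------------------------------------------------
# scaling-and-squaring integration
# ---------------------------------------------------------------------------

def integrate_svf_tensor(v: Tensor, steps: int) -> Tensor:
    """Differentiable scaling and squaring; v and result are (N, H, W).

    Returns the displacement u of phi = exp(v) = id + u. Composition lookups
    use bilinear interpolation with edge clamping.
    """
    if steps < 1:
        raise ValueError("need at least one integration step")
    shape = v.shape[1:]
    grid = np.moveaxis(identity_grid(shape), -1, 0)  # centered, (N, H, W)
    center = ((np.asarray(shape, float) - 1.0) / 2.0).reshape(-1, 1, 1)
    u = v * (1.0 / 2.0 ** steps)
    for _ in range(steps):
        coords = u + (grid + center)  # absolute index coords of x + u(x)
        u = u + ad.bilinear_sample(u, coords, mode="edge")
    return u


def integrate_svf(v: VectorField, steps: int = 10):
    """Integrate an SVF into a diffeomorphic warp and its inverse.

    phi = exp(nu) via scaling and squaring; the inverse is obtained by
    integrating -nu. Returns (phi, phi_inverse) as warp-semantics fields.
    """
    if not isinstance(v, VectorField) or v.semantics != "svf":
        raise ValueError("integration requires a VectorField with svf semantics")
    vt = Tensor(np.moveaxis(v.values, -1, 0))
    shape = v.grid.shape

    def run(t):
        u = integrate_svf_tensor(t, steps).value
        return VectorField(np.moveaxis(u, 0, -1) + identity_grid(shape),
                           "warp", GridSpec(shape))

    return run(vt), run(Tensor(-np.moveaxis(v.values, -1, 0)))


# ---------------------------------------------------------------------------
# joint registration
# ---------------------------------------------------------------------------

def joint_register(m: np.ndarray, f: np.ndarray, lam: float, theta: list,
                   xi: list, det_config, unet_config: UNetConfig,
                   mode: str = "midspace", steps: int | None = None) -> dict:
    """Full affine + deformable registration of a normalized image pair.

    midspace mode (symmetric): T = h_theta(m, f); g sees m o T^(1/2) and
    f o T^(-1/2); psi = T^(1/2) o phi o T^(1/2). moving mode: g sees
    (m o T, f) and psi = T o phi (not symmetric).
    Returns {'T', 'svf', 'phi', 'phi_inv', 'psi', 'psi_inv'}.
    """
    from .affine_model import estimate_affine

    if mode not in ("midspace", "moving"):
        raise ValueError("mode must be 'midspace' or 'moving'")
    steps = unet_config.integration_steps if steps is None else int(steps)
    t = estimate_affine(m, f, theta, det_config)
    eta = [Tensor(e.value) for e in hypernet_forward(lam, xi, unet_config)]
    if mode == "midspace":
        s = sqrt_affine(t)
        m_in = resample(m, s)
        f_in = resample(f, invert(s))
    else:
        m_in = resample(m, t)
        f_in = f
    nu = symmetrize_svf(unet_svf(m_in, f_in, eta, unet_config),
                        unet_svf(f_in, m_in, eta, unet_config))
    phi, phi_inv = integrate_svf(nu, steps)
    if mode == "midspace":
        psi, psi_inv = compose_joint(t, phi, phi_inv)
    else:
        shape = phi.grid.shape
        psi = VectorField(t.apply(phi.values), "warp", GridSpec(shape))
        t_inv = invert(t)
        # psi^-1 = phi^-1 o T^-1: look up phi^-1 at T^-1 x
        from .geometry import _warp_lookup
        psi_inv = VectorField(
            _warp_lookup(phi_inv, t_inv.apply(identity_grid(shape))),
            "warp", GridSpec(shape))
    return {"T": t, "svf": nu, "phi": phi, "phi_inv": phi_inv,
            "psi": psi, "psi_inv": psi_inv}
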