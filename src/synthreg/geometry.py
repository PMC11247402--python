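"""Affine and dense-warp algebra in a zero-centered voxel index convention.

All affine transforms in this package act on zero-centered voxel indices: a
grid of shape ``s`` has its origin at ``(s - 1) / 2``, so rotation, scaling
and shear pivot about the grid center. Conversion to scanner (world)
coordinates is the job of :mod:`synthreg.io_cli`.

Transforms follow pull-back semantics throughout: resampling an image ``m``
by a transform ``T`` evaluates ``m(T(x))`` at every output voxel ``x``, so
``T`` maps the *fixed* grid into the *moving* image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.ndimage import map_coordinates

__all__ = [
    "GridSpec", "AffineTransform", "VectorField", "identity_affine",
    "build_affine", "sqrt_affine", "compose", "invert", "promote", "demote",
    "identity_grid", "affine_to_warp", "resample", "compose_joint",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Sampling grid: integer shape plus the zero-centered origin it implies."""

    shape: tuple

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def center(self) -> np.ndarray:
        return (np.asarray(self.shape, dtype=float) - 1.0) / 2.0


@dataclass(frozen=True)
class AffineTransform:
    """N x (N+1) matrix ``[A | v]`` acting on zero-centered voxel indices."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != m.shape[0] + 1:
            raise ValueError(f"affine matrix must be N x (N+1), got {m.shape}")
        if abs(np.linalg.det(m[:, :-1])) < 1e-15:
            raise ValueError("linear block A is singular")
        object.__setattr__(self, "matrix", m)

    @property
    def ndim(self) -> int:
        return self.matrix.shape[0]

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :-1]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, -1]

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map zero-centered points of shape (..., N)."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.linear.T + self.translation


_SEMANTICS = ("svf", "displacement", "warp")


@dataclass
class VectorField:
    """Dense N-vector field over a grid, in voxel units.

    semantics: 'svf' (stationary velocity), 'displacement' (u), or 'warp'
    (phi = id + u, stored as absolute zero-centered coordinates).
    """

    values: np.ndarray
    semantics: str
    grid: GridSpec = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.semantics not in _SEMANTICS:
            raise ValueError(f"semantics must be one of {_SEMANTICS}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("vector field contains non-finite values")
        shape = self.values.shape[:-1]
        if self.values.shape[-1] != len(shape):
            raise ValueError("last axis must hold one component per grid axis")
        if self.grid is None:
            self.grid = GridSpec(shape)

    @property
    def ndim(self) -> int:
        return self.values.shape[-1]

    def as_displacement(self) -> "VectorField":
        if self.semantics == "displacement":
            return self
        if self.semantics == "warp":
            return VectorField(self.values - identity_grid(self.grid.shape),
                               "displacement", self.grid)
        raise ValueError("an SVF must be integrated before use as a deformation")

    def as_warp(self) -> "VectorField":
        if self.semantics == "warp":
            return self
        if self.semantics == "displacement":
            return VectorField(self.values + identity_grid(self.grid.shape),
                               "warp", self.grid)
        raise ValueError("an SVF must be integrated before use as a deformation")


# ---------------------------------------------------------------------------
# construction and algebra
# ---------------------------------------------------------------------------

def identity_affine(ndim: int) -> AffineTransform:
    return AffineTransform(np.hstack([np.eye(ndim), np.zeros((ndim, 1))]))


def _rotation_matrix(rotation, ndim: int) -> np.ndarray:
    if ndim == 2:
        (a,) = np.atleast_1d(np.deg2rad(rotation))
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s], [s, c]])
    ax, ay, az = np.deg2rad(np.atleast_1d(rotation))
    rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
    return rx @ ry @ rz


def _shear_matrix(shear, ndim: int) -> np.ndarray:
    sh = np.atleast_1d(np.asarray(shear, dtype=float))
    m = np.eye(ndim)
    if ndim == 2:
        m[0, 1] = sh[0]
    else:
        m[0, 1], m[0, 2], m[1, 2] = sh[0], sh[1], sh[2]
    return m


def build_affine(translation, rotation, scale, shear) -> AffineTransform:
    """Compose elementary transforms about the zero-centered origin.

    Fixed, documented order: translate o rotate o scale o shear. Rotation is
    one angle in degrees in 2D; three intrinsic Euler angles about x, y, z
    (applied in that order) in 3D. Shear takes 1 (2D) or 3 (3D) off-diagonal
    upper-triangular coefficients.
    """
    t = np.atleast_1d(np.asarray(translation, dtype=float))
    ndim = t.size
    if ndim not in (2, 3):
        raise ValueError("only 2D and 3D transforms are supported")
    s = np.atleast_1d(np.asarray(scale, dtype=float))
    if np.any(s <= 0):
        raise ValueError("scale factors must be strictly positive")
    a = _rotation_matrix(rotation, ndim) @ np.diag(s) @ _shear_matrix(shear, ndim)
    return AffineTransform(np.hstack([a, t[:, None]]))


def promote(t: AffineTransform) -> np.ndarray:
    """Homogeneous (N+1)^2 matrix."""
    n = t.ndim
    h = np.eye(n + 1)
    h[:n, :] = t.matrix
    return h


def demote(h: np.ndarray) -> AffineTransform:
    return AffineTransform(h[:-1, :])


def compose(t2: AffineTransform, t1: AffineTransform) -> AffineTransform:
    """Transform applying t1 first, then t2: (t2 o t1)(x) = t2(t1(x))."""
    return demote(promote(t2) @ promote(t1))


def invert(t: AffineTransform) -> AffineTransform:
    return demote(np.linalg.inv(promote(t)))


def sqrt_affine(t: AffineTransform) -> AffineTransform:
    """Principal matrix square root S with S o S = t.

    Computed on the homogeneous matrix. Requires a real principal root:
    positive determinant and no 180-degree rotation component.
    """
    h = promote(t)
    if np.linalg.det(t.linear) <= 0:
        raise ValueError("no real principal square root: negative determinant")
    eig = np.linalg.eigvals(h)
    if np.any((eig.real < 0) & (np.abs(eig.imag) < 1e-9 * np.abs(eig.real))):
        raise ValueError(
            "no real principal square root: rotation too close to 180 degrees "
            "(negative real eigenvalue)")
    s = scipy.linalg.sqrtm(h)
    if np.iscomplexobj(s):
        if np.max(np.abs(s.imag)) > 1e-9:
            raise ValueError(
                "no real principal square root: rotation too close to 180 degrees")
        s = s.real
    root = demote(s)
    if np.max(np.abs(promote(compose(root, root)) - h)) > 1e-6:
        raise ValueError("square root verification failed")
    return root


# ---------------------------------------------------------------------------
# dense fields and resampling
# ---------------------------------------------------------------------------

def identity_grid(shape) -> np.ndarray:
    """Zero-centered identity coordinates, shape (*shape, N)."""
    shape = tuple(int(n) for n in shape)
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    axes = [np.arange(n, dtype=float) - c for n, c in zip(shape, center)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def affine_to_warp(t: AffineTransform, shape) -> VectorField:
    """Render an affine transform as a dense warp over a grid."""
    grid = identity_grid(shape)
    return VectorField(t.apply(grid), "warp", GridSpec(tuple(shape)))


def _sample(data: np.ndarray, coords_centered: np.ndarray, order: int,
            mode: str = "constant") -> np.ndarray:
    """Interpolate `data` at zero-centered coords of shape (*out_shape, N)."""
    center = (np.asarray(data.shape, dtype=float) - 1.0) / 2.0
    idx = np.moveaxis(coords_centered + center, -1, 0)
    return map_coordinates(data, idx, order=order, mode=mode, cval=0.0,
                           prefilter=False)


def resample(volume, transform, interpolation: str = "linear"):
    """Pull-back resampling: output(x) = input(transform(x)).

    `volume` may be a bare ndarray or any object with a ``data`` attribute
    (e.g. :class:`synthreg.io_cli.Volume`); the same type is returned.
    Out-of-bounds samples read as 0. The transform is an AffineTransform or a
    VectorField with warp semantics (integrate an SVF first).
    """
    is_volume = hasattr(volume, "replace_data")
    data = volume.data if is_volume else np.asarray(volume)
    order = {"linear": 1, "nearest": 0}[interpolation]
    if isinstance(transform, AffineTransform):
        if transform.ndim != data.ndim:
            raise ValueError("transform dimensionality does not match volume")
        coords = affine_to_warp(transform, data.shape).values
    elif isinstance(transform, VectorField):
        if transform.semantics == "svf":
            raise ValueError("cannot resample with an SVF; integrate it first")
        coords = transform.as_warp().values
        if coords.shape[-1] != data.ndim:
            raise ValueError("transform dimensionality does not match volume")
    else:
        raise TypeError(f"unsupported transform type {type(transform)!r}")
    out = _sample(data, coords, order)
    if is_volume:
        return volume.replace_data(out)
    return out


def _warp_lookup(phi: VectorField, coords: np.ndarray) -> np.ndarray:
    """Evaluate warp phi at arbitrary zero-centered coords (phi = id outside)."""
    disp = phi.as_displacement().values
    u = np.stack([_sample(disp[..., d], coords, order=1)
                  for d in range(disp.shape[-1])], axis=-1)
    return coords + u


def compose_joint(t: AffineTransform, phi: VectorField,
                  phi_inv: VectorField | None = None):
    """Mid-space joint transform psi(x) = S(phi(S(x))) with S = sqrt(t).

    Returns a single dense warp so that the moving image is resampled with
    one interpolation. When `phi_inv` is supplied, the inverse warp
    psi^-1 = S^-1 o phi^-1 o S^-1 is returned as well.
    """
    if phi.semantics == "svf":
        raise ValueError("phi must be a warp or displacement, not an SVF")
    s = sqrt_affine(t)
    shape = phi.grid.shape
    grid = identity_grid(shape)
    mid = s.apply(grid)
    psi = VectorField(s.apply(_warp_lookup(phi, mid)), "warp", GridSpec(shape))
    if phi_inv is None:
        return psi
    s_inv = invert(s)
    mid_inv = s_inv.apply(grid)
    psi_inv = VectorField(s_inv.apply(_warp_lookup(phi_inv, mid_inv)),
                          "warp", GridSpec(shape))
    return psi, psi_inv
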