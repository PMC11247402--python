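"""Registration-quality metrics: overlap, similarity, warp regularity, symmetry.

All metrics operate on numpy arrays in the package's zero-centered voxel
convention and are restricted to a boolean foreground ("brain") mask where
one applies. Warp regularity follows the Jacobian determinant of the dense
warp (central finite differences, one-sided at borders): the log-Jacobian
spread is the mean |log J| over foreground voxels with J != 0, and folding
is the percentage of foreground voxels with J < 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import AffineTransform, VectorField, identity_grid
from .synthesis import LabelMap

__all__ = ["EvaluationMask", "hard_dice", "ncc", "mind_descriptor", "mind_mse",
           "jacobian_determinant", "log_jacobian_spread", "folding_fraction",
           "inverse_consistency", "symmetric_inverse_consistency"]


@dataclass
class EvaluationMask:
    """Foreground voxels, with the J != 0 subset derived on demand."""

    foreground: np.ndarray

    def __post_init__(self):
        self.foreground = np.asarray(self.foreground, dtype=bool)

    def valid_jacobian(self, det: np.ndarray) -> np.ndarray:
        return self.foreground & (det != 0)


def _as_mask(mask, shape) -> np.ndarray:
    if mask is None:
        return np.ones(shape, dtype=bool)
    mask = mask.foreground if isinstance(mask, EvaluationMask) else np.asarray(mask, bool)
    if mask.shape != shape:
        raise ValueError("mask shape does not match data")
    return mask


def _labels_of(x):
    return x.labels if isinstance(x, LabelMap) else np.asarray(x)


def hard_dice(moved_labels, fixed_labels, labels):
    """Per-label hard Dice 2|A&B|/(|A|+|B|) and its mean over requested labels.

    Labels absent from both maps are excluded with a warning.
    """
    a, b = _labels_of(moved_labels), _labels_of(fixed_labels)
    if a.shape != b.shape:
        raise ValueError("label maps must share a grid")
    per_label = {}
    for j in labels:
        na, nb = int((a == j).sum()), int((b == j).sum())
        if na + nb == 0:
            warnings.warn(f"label {j} absent from both maps; excluded")
            continue
        inter = int(((a == j) & (b == j)).sum())
        per_label[int(j)] = 2.0 * inter / (na + nb)
    if not per_label:
        raise ValueError("no requested label present in either map")
    return per_label, float(np.mean(list(per_label.values())))


def ncc(m: np.ndarray, f: np.ndarray, mask=None) -> float:
    """Pearson correlation of masked intensities, in [-1, 1]."""
    m, f = np.asarray(m, float), np.asarray(f, float)
    sel = _as_mask(mask, m.shape)
    x, y = m[sel], f[sel]
    if x.size < 2:
        raise ValueError("need at least two masked voxels")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input within the mask")
    return float(np.corrcoef(x, y)[0, 1])


def mind_descriptor(img: np.ndarray, patch_fwhm: float = 2.0) -> np.ndarray:
    """Modality-independent neighborhood descriptor, shape (2N, *grid).

    For each of the 2N axis-neighbor offsets r, computes a Gaussian-weighted
    patch distance D_r(x) between the patches at x and x + r, normalizes by
    the local mean distance V(x) (a noise/variance estimate), exponentiates,
    and max-normalizes per voxel. The construction is invariant to affine
    intensity rescaling because D and V scale identically.
    """
    img = np.asarray(img, dtype=float)
    ndim = img.ndim
    sigma = patch_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    dists = []
    for ax in range(ndim):
        for step in (+1, -1):
            shifted = np.roll(img, -step, axis=ax)
            # avoid wrap-around: replicate the edge slice
            sl = [slice(None)] * ndim
            sl[ax] = slice(-1, None) if step > 0 else slice(0, 1)
            edge = [slice(None)] * ndim
            edge[ax] = slice(-2, -1) if step > 0 else slice(1, 2)
            shifted[tuple(sl)] = img[tuple(edge)]
            diff = (img - shifted) ** 2
            dists.append(ndimage.gaussian_filter(diff, sigma))
    d = np.stack(dists)
    v = d.mean(axis=0)
    eps = 1e-6 * float(v.mean()) + 1e-30
    desc = np.exp(-d / (v + eps))
    return desc / desc.max(axis=0, keepdims=True)


def mind_mse(m: np.ndarray, f: np.ndarray, mask=None) -> float:
    """Mean squared MIND-descriptor difference within the mask.

    Image content outside the mask is zeroed before descriptor extraction so
    the comparison reflects the anatomy of interest only.
    """
    m, f = np.asarray(m, float), np.asarray(f, float)
    sel = _as_mask(mask, m.shape)
    if not sel.any():
        raise ValueError("empty evaluation mask")
    dm = mind_descriptor(np.where(sel, m, 0.0))
    df = mind_descriptor(np.where(sel, f, 0.0))
    return float((((dm - df) ** 2)[:, sel]).mean())


def jacobian_determinant(phi: VectorField) -> np.ndarray:
    """Jacobian determinant of a dense warp via central finite differences."""
    warp = phi.as_warp().values
    ndim = warp.shape[-1]
    jac = np.empty(warp.shape[:-1] + (ndim, ndim))
    for comp in range(ndim):
        grads = np.gradient(warp[..., comp])
        if ndim == 1:
            grads = [grads]
        for ax in range(ndim):
            jac[..., comp, ax] = grads[ax]
    return np.linalg.det(jac)


def log_jacobian_spread(phi: VectorField, mask=None) -> float:
    """Mean |log |J_phi|| over foreground voxels with J != 0.

    Voxels with non-positive determinant contribute |log |J||; orientation
    reversal itself is reported separately by :func:`folding_fraction`.
    """
    det = jacobian_determinant(phi)
    sel = _as_mask(mask, det.shape) & (det != 0)
    if not sel.any():
        raise ValueError("no foreground voxels with non-zero determinant")
    return float(np.abs(np.log(np.abs(det[sel]))).mean())


def folding_fraction(phi: VectorField, mask=None) -> float:
    """Percentage of foreground voxels with negative Jacobian determinant."""
    det = jacobian_determinant(phi)
    sel = _as_mask(mask, det.shape)
    if not sel.any():
        raise ValueError("empty evaluation mask")
    return float(100.0 * (det[sel] < 0).sum() / sel.sum())


def _apply_transform(transform, points: np.ndarray) -> np.ndarray:
    """Map zero-centered points (n, N) through an affine or dense warp."""
    if isinstance(transform, AffineTransform):
        return transform.apply(points)
    disp = transform.as_displacement().values
    center = (np.asarray(disp.shape[:-1], dtype=float) - 1.0) / 2.0
    idx = (points + center).T
    u = np.stack([ndimage.map_coordinates(disp[..., d], idx, order=1,
                                          mode="constant", cval=0.0,
                                          prefilter=False)
                  for d in range(disp.shape[-1])], axis=-1)
    return points + u


def inverse_consistency(t1, t2, grid_shape, mask=None) -> float:
    """E(T1, T2): mean ||(T2 o T1)(x) - x|| over foreground voxels, in voxels."""
    sel = _as_mask(mask, tuple(grid_shape))
    pts = identity_grid(grid_shape)[sel]
    moved = _apply_transform(t2, _apply_transform(t1, pts))
    return float(np.linalg.norm(moved - pts, axis=-1).mean())


def symmetric_inverse_consistency(h, m, f, grid_shape, mask=None) -> float:
    """I = 0.5 [E(T1, T2) + E(T2, T1)] with T1 = h(m, f) and T2 = h(f, m)."""
    t1, t2 = h(m, f), h(f, m)
    return 0.5 * (inverse_consistency(t1, t2, grid_shape, mask)
                  + inverse_consistency(t2, t1, grid_shape, mask))
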