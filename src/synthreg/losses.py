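"""Training objectives: soft Dice and one-hot MSE overlap, warp regularity.

The overlap losses act on probability stacks of shape (|J|, *grid) — one
channel per anatomy label. They are written against the small array API
shared by numpy arrays and :class:`synthreg.autodiff.Tensor`, so the same
code evaluates losses numerically and differentiates them during training.

The total training objective weighs overlap against a displacement-gradient
regularizer with lambda in [0, 1]:  (1 - lambda) * overlap + lambda * reg.
The regularizer is evaluated on the deformable displacement only, never on
the affine component (a global affine is not penalized for being large).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import VectorField

__all__ = ["LossConfig", "dice_loss", "mse_overlap_loss",
           "gradient_regularizer", "gradient_energy", "total_loss"]

_DICE_EPS = 1e-7


@dataclass
class LossConfig:
    overlap_kind: str = "mse"    # 'dice' (soft Dice) or 'mse' (one-hot MSE)
    lam: float = 0.5
    labels: tuple = ()

    def __post_init__(self):
        if self.overlap_kind not in ("dice", "mse"):
            raise ValueError("overlap_kind must be 'dice' or 'mse'")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")

    def overlap(self, moved, fixed):
        fn = dice_loss if self.overlap_kind == "dice" else mse_overlap_loss
        return fn(moved, fixed)


def _spatial_axes(stack):
    return tuple(range(1, stack.ndim))


def _check_stacks(moved, fixed):
    if moved.shape != fixed.shape:
        raise ValueError("probability stacks must share channel count and grid")


def dice_loss(moved, fixed):
    """Soft Dice overlap loss, in [-1, 0]; -1 at perfect overlap.

    -(2/|J|) * sum_j [ sum_x moved_j * fixed_j / (sum_x moved_j + fixed_j) ],
    with a 1e-7 guard on the denominator for empty channels.
    """
    _check_stacks(moved, fixed)
    ax = _spatial_axes(moved)
    num = (moved * fixed).sum(axis=ax)
    den = (moved + fixed).sum(axis=ax) + _DICE_EPS
    nchan = moved.shape[0]
    return (num / den).sum() * (-2.0 / nchan)


def mse_overlap_loss(moved, fixed):
    """Mean squared difference of one-hot stacks over all voxels and channels.

    Unlike Dice, this term is sensitive to label size: each label contributes
    in proportion to its mismatch volume, which discourages the optimization
    from disproportionately focusing on small structures.
    """
    _check_stacks(moved, fixed)
    d = moved - fixed
    return (d * d).mean()


def gradient_energy(values, channel_axis: int = -1):
    """Mean squared forward-difference gradient of a displacement array.

    One axis holds the N vector components (last by default; training uses
    channels-first Tensors), the rest are spatial. The reduction is the mean
    over the spatial directions of the mean (over valid voxels and the
    components) of the squared forward differences, so a unit-slope single
    component in one direction scores 1/N^2.
    """
    nd = values.ndim
    ca = channel_axis % nd
    spatial = [ax for ax in range(nd) if ax != ca]
    total = None
    for ax in spatial:
        hi = [slice(None)] * nd
        lo = [slice(None)] * nd
        hi[ax], lo[ax] = slice(1, None), slice(None, -1)
        diff = values[tuple(hi)] - values[tuple(lo)]
        term = (diff * diff).mean()
        total = term if total is None else total + term
    return total * (1.0 / len(spatial))


def gradient_regularizer(u) -> float:
    """||grad u||^2 of a displacement field (mean-reduced); 0 iff u constant."""
    if isinstance(u, VectorField):
        if u.semantics != "displacement":
            raise ValueError(
                "regularizer expects displacement semantics; convert warps "
                "with as_displacement()")
        values = u.values
    else:
        values = u
    return gradient_energy(values)


def total_loss(lam: float, overlap, reg):
    """(1 - lambda) * overlap + lambda * reg, lambda in [0, 1]."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return (1.0 - lam) * overlap + lam * reg
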