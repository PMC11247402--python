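"""Optimization protocol: strips, learning-rate ladder, stopping criterion.

Training proceeds in consecutive strips. Each strip uses the next entry of a
decreasing learning-rate ladder; a divergence (non-finite loss, or a loss
spiking past 10x the strip median) reloads the last checkpoint and steps
down to the next rate. Validation Dice D(t) is evaluated on a fixed set of
seeded synthetic pairs throughout a strip, and training stops once the
progress statistic

    P_i = mean_t D(t) / max_t D(t)

meets the stop threshold (default 0.999): a strip whose mean tracks its
maximum that closely is no longer improving.

The affine stage optimizes coarse label groups during its first strip for
fast convergence and the target grouping afterwards. The joint stage
freezes the affine weights theta and fits only the hypernetwork xi, drawing
the regularization weight lambda uniformly from [0, 1] per batch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .affine_model import DetectorConfig, estimate_affine, estimate_affine_tensor, init_detector_params
from .deformable_model import (HyperNetConfig, UNetConfig, hypernet_forward,
                               init_hypernet_params, integrate_svf_tensor,
                               joint_register, symmetrize_svf, unet_svf_tensor)
from .geometry import identity_grid, invert, resample, sqrt_affine
from .losses import LossConfig, gradient_energy, total_loss
from .metrics import hard_dice
from .synthesis import (GenerationConfig, LabelMap, augment_labelmap, one_hot,
                        random_shape_labels, recode, sample_augmentation,
                        synthesize_image)

__all__ = ["TrainConfig", "PairSampler", "make_shape_dataset", "progress",
           "train_affine", "train_joint", "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    """Schedule parameters. The ladder pairs rates with strips; desk-scale
    presets shorten the published million-batch strips to a few hundred."""

    strip_length: int = 2000
    learning_rates: tuple = (1e-4, 1e-5, 1e-6)
    batch_size: int = 1
    stop_threshold: float = 0.999
    val_interval: int = 100
    val_pairs: int = 8
    divergence_factor: float = 10.0
    seed: int = 0

    def __post_init__(self):
        rates = tuple(self.learning_rates)
        if any(b >= a for a, b in zip(rates, rates[1:])):
            raise ValueError("learning rates must be strictly decreasing")
        if not 0.0 < self.stop_threshold <= 1.0:
            raise ValueError("stop threshold must lie in (0, 1]")
        self.learning_rates = rates

    @classmethod
    def desk(cls, seed: int = 0, strip_length: int = 1500) -> "TrainConfig":
        return cls(strip_length=strip_length,
                   learning_rates=(1e-3, 3e-4, 1e-4),
                   val_interval=150, val_pairs=8, seed=seed)


def _derive_seed(*keys) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2 ** 31))


#: public alias: map a tuple of integer keys to an independent 31-bit seed
derive_seed = _derive_seed


def progress(dice_series) -> float:
    """P = mean(D) / max(D) over one strip of validation Dice values."""
    series = np.asarray(list(dice_series), dtype=float)
    if series.size == 0:
        raise ValueError("empty validation series")
    top = series.max()
    if top <= 0:
        raise ValueError("progress undefined: maximum validation Dice is zero")
    return float(series.mean() / top)


# ---------------------------------------------------------------------------
# data stream
# ---------------------------------------------------------------------------

def make_shape_dataset(num_subjects: int = 12, shape=(32, 32),
                       num_labels: int = 4, smoothness: float = 8.0,
                       seed: int = 0) -> list:
    """A pool of random shape label maps standing in for training subjects."""
    return [random_shape_labels(shape, num_labels, smoothness,
                                _derive_seed(seed, 17, i))
            for i in range(num_subjects)]


@dataclass
class PairSampler:
    """Draws augmented label-map pairs and synthesizes their images.

    ``pair_mode='two_subjects'`` draws the moving and fixed map from
    different pool entries; ``'same_subject'`` augments one entry twice
    (both interpretations are supported; cross-subject is the default).
    """

    base_maps: list
    gen: GenerationConfig
    pair_mode: str = "two_subjects"

    def __post_init__(self):
        if self.pair_mode not in ("two_subjects", "same_subject"):
            raise ValueError("pair_mode must be 'two_subjects' or 'same_subject'")
        if not self.base_maps:
            raise ValueError("need at least one base label map")

    @property
    def grid_shape(self):
        return self.base_maps[0].labels.shape

    def sample(self, seed: int):
        """Return (s_m, s_f, m, f), deterministic under the seed."""
        rng = np.random.default_rng(int(seed))
        n = len(self.base_maps)
        if self.pair_mode == "two_subjects" and n > 1:
            i, j = rng.choice(n, size=2, replace=False)
        else:
            i = j = int(rng.integers(n))
        out = []
        for base in (self.base_maps[int(i)], self.base_maps[int(j)]):
            aug_seed = int(rng.integers(2 ** 31))
            syn_seed = int(rng.integers(2 ** 31))
            affine, disp = sample_augmentation(self.gen, base.labels.shape,
                                               aug_seed)
            s = augment_labelmap(base, affine, disp, self.gen, aug_seed)
            out.append((s, synthesize_image(s, self.gen, syn_seed)))
        (s_m, m), (s_f, f) = out
        return s_m, s_f, m, f


def _grouped_onehot(s: LabelMap, grouping: dict):
    g = recode(s, grouping)
    return one_hot(g, g.anatomy_set), g


def identity_grouping(s: LabelMap) -> dict:
    return {j: j for j in s.anatomy_set}


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, params: list, meta: dict | None = None) -> None:
    """Single-file checkpoint: parameter arrays plus a JSON metadata blob."""
    arrays = {f"param_{i}": p.value for i, p in enumerate(params)}
    arrays["meta"] = np.frombuffer(
        json.dumps(meta or {}).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Returns (params as leaf Tensors, metadata dict)."""
    with np.load(path) as data:
        n = sum(1 for k in data.files if k.startswith("param_"))
        params = [Tensor(data[f"param_{i}"]) for i in range(n)]
        meta = json.loads(bytes(data["meta"]).decode()) if "meta" in data else {}
    return params, meta


# ---------------------------------------------------------------------------
# shared strip schedule
# ---------------------------------------------------------------------------

def _run_strips(cfg: TrainConfig, params: list, batch_fn, validate_fn,
                start_strip: int = 0):
    """Generic strip loop with ladder, divergence recovery and stopping.

    ``batch_fn(strip, t)`` returns a scalar loss Tensor; ``validate_fn()``
    returns a mean validation Dice. Returns a history dict.
    """
    history = {"strips": [], "stopped_early": False}
    checkpoint = [p.value.copy() for p in params]
    n_strips = len(cfg.learning_rates)
    strip = start_strip
    while strip < n_strips:
        rate = cfg.learning_rates[strip]
        opt = Adam(params, lr=rate)
        losses, dice_series = [], []
        diverged = False
        for t in range(cfg.strip_length):
            loss = batch_fn(strip, t)
            value = float(loss.value)
            if not np.isfinite(value) or (
                    len(losses) >= 20
                    and value > cfg.divergence_factor * abs(np.median(losses))
                    and value > 0):
                diverged = True
                break
            losses.append(value)
            loss.backward()
            opt.step()
            if (t + 1) % cfg.val_interval == 0:
                dice_series.append(validate_fn())
        if diverged:
            for p, saved in zip(params, checkpoint):
                p.value = saved.copy()
            if strip + 1 >= n_strips:
                raise RuntimeError(
                    "training diverged with the learning-rate ladder exhausted "
                    f"(strip {strip}, rate {rate})")
            history["strips"].append({"rate": rate, "diverged": True,
                                      "losses": losses})
            strip += 1
            continue
        p_stat = progress(dice_series) if dice_series else 0.0
        history["strips"].append({"rate": rate, "diverged": False,
                                  "losses": losses, "val_dice": dice_series,
                                  "progress": p_stat})
        checkpoint = [p.value.copy() for p in params]
        strip += 1
        if dice_series and p_stat >= cfg.stop_threshold:
            history["stopped_early"] = True
            break
    return history


# ---------------------------------------------------------------------------
# affine training
# ---------------------------------------------------------------------------

def _affine_overlap_loss(m, f, onehot_m, onehot_f, params, det_cfg, loss_cfg):
    """Differentiable pull-back of the moving one-hot stack by the predicted
    affine, compared to the fixed stack."""
    shape = m.shape
    t_tensor = estimate_affine_tensor(m, f, params, det_cfg)
    grid = identity_grid(shape).reshape(-1, 2)
    ghom = np.hstack([grid, np.ones((grid.shape[0], 1))])
    coords_c = ad.matmul(Tensor(ghom), _t_transpose(t_tensor))  # (HW, 2)
    center = (np.asarray(shape, float) - 1.0) / 2.0
    comps = [(coords_c[:, d] + center[d]).reshape(1, *shape) for d in (0, 1)]
    coords = ad.concatenate(comps, axis=0)
    moved = ad.bilinear_sample(Tensor(onehot_m), coords, mode="zeros")
    return loss_cfg.overlap(moved, Tensor(onehot_f))


def _t_transpose(t: Tensor) -> Tensor:
    src = t

    def back(g):
        src.grad += g.T

    return Tensor(t.value.T, (t,), back)


def train_affine(sampler: PairSampler, cfg: TrainConfig,
                 det_cfg: DetectorConfig | None = None,
                 target_grouping: dict | None = None,
                 first_strip_grouping: dict | None = None,
                 loss_cfg: LossConfig | None = None,
                 init_params: list | None = None):
    """Fit detector weights theta on synthetic pairs; returns (theta, history).

    The first strip optimizes the coarse ``first_strip_grouping`` (when
    given), later strips the ``target_grouping`` (default: each anatomy
    label its own group). Validation Dice is the hard Dice of the moving
    labels resampled by the predicted transform, on fixed seeded pairs.
    """
    det_cfg = det_cfg or DetectorConfig.desk_2d()
    loss_cfg = loss_cfg or LossConfig()
    base = sampler.base_maps[0]
    target_grouping = target_grouping or identity_grouping(base)
    params = init_params if init_params is not None else \
        init_detector_params(det_cfg, seed=_derive_seed(cfg.seed, 1))
    val_pairs = [sampler.sample(_derive_seed(cfg.seed, 2, i))
                 for i in range(cfg.val_pairs)]

    def batch(strip, t):
        grouping = first_strip_grouping if (strip == 0 and first_strip_grouping) \
            else target_grouping
        s_m, s_f, m, f = sampler.sample(_derive_seed(cfg.seed, 3, strip, t))
        oh_m, _ = _grouped_onehot(s_m, grouping)
        oh_f, _ = _grouped_onehot(s_f, grouping)
        return _affine_overlap_loss(m, f, oh_m, oh_f, params, det_cfg, loss_cfg)

    def validate():
        scores = []
        for s_m, s_f, m, f in val_pairs:
            g_m = recode(s_m, target_grouping)
            g_f = recode(s_f, target_grouping)
            try:
                t_est = estimate_affine(m, f, params, det_cfg)
                moved = resample(g_m.labels.astype(float), t_est, "nearest")
            except (ValueError, np.linalg.LinAlgError):
                moved = g_m.labels
            try:
                _, mean = hard_dice(np.rint(moved).astype(int), g_f.labels,
                                    g_f.anatomy_set)
            except ValueError:
                mean = 0.0
            scores.append(mean)
        return float(np.mean(scores))

    history = _run_strips(cfg, params, batch, validate)
    return params, history


# ---------------------------------------------------------------------------
# joint training
# ---------------------------------------------------------------------------

def _joint_loss(m, f, onehot_m, onehot_f, lam, theta, xi, det_cfg, unet_cfg,
                loss_cfg):
    """Eq.-10-style objective: overlap of s_m o psi vs s_f plus lambda-weighted
    gradient energy of the deformable displacement only."""
    shape = m.shape
    t_aff = estimate_affine(m, f, theta, det_cfg)     # frozen theta, no graph
    s = sqrt_affine(t_aff)
    m_mid = resample(m, s)
    f_mid = resample(f, invert(s))
    eta = hypernet_forward(lam, xi, unet_cfg)
    nu = symmetrize_svf(unet_svf_tensor(m_mid, f_mid, eta, unet_cfg),
                        unet_svf_tensor(f_mid, m_mid, eta, unet_cfg))
    u = integrate_svf_tensor(nu, unet_cfg.integration_steps)  # (2, H, W)
    reg = gradient_energy(u, channel_axis=0)
    # psi(x) = S(phi(Sx)): sample u at Sx, then apply S to Sx + u(Sx)
    grid = identity_grid(shape)
    mid = s.apply(grid)                                # (H, W, 2) centered
    center = (np.asarray(shape, float) - 1.0) / 2.0
    mid_idx = np.moveaxis(mid + center, -1, 0)         # (2, H, W) index coords
    u_at = ad.bilinear_sample(u, Tensor(mid_idx), mode="edge")
    phi_mid = u_at + np.moveaxis(mid, -1, 0)           # centered coords
    a, v = s.linear, s.translation
    psi0 = phi_mid[0] * a[0, 0] + phi_mid[1] * a[0, 1] + (v[0] + center[0])
    psi1 = phi_mid[0] * a[1, 0] + phi_mid[1] * a[1, 1] + (v[1] + center[1])
    coords = ad.concatenate([psi0.reshape(1, *shape), psi1.reshape(1, *shape)],
                            axis=0)
    moved = ad.bilinear_sample(Tensor(onehot_m), coords, mode="zeros")
    overlap = loss_cfg.overlap(moved, Tensor(onehot_f))
    return total_loss(lam, overlap, reg)


def train_joint(theta: list, sampler: PairSampler, cfg: TrainConfig,
                det_cfg: DetectorConfig | None = None,
                unet_cfg: UNetConfig | None = None,
                hyper_cfg: HyperNetConfig | None = None,
                grouping: dict | None = None,
                loss_cfg: LossConfig | None = None,
                init_params: list | None = None,
                lam_override: float | None = None):
    """Fit hypernetwork weights xi with theta frozen; returns (xi, history).

    lambda is drawn uniformly from [0, 1] per batch unless pinned with
    ``lam_override``. Validation registers fixed pairs at lambda = 0.5.
    """
    det_cfg = det_cfg or DetectorConfig.desk_2d()
    unet_cfg = unet_cfg or UNetConfig.desk_2d()
    hyper_cfg = hyper_cfg or HyperNetConfig()
    loss_cfg = loss_cfg or LossConfig()
    grouping = grouping or identity_grouping(sampler.base_maps[0])
    xi = init_params if init_params is not None else \
        init_hypernet_params(unet_cfg, hyper_cfg,
                             seed=_derive_seed(cfg.seed, 4))
    val_pairs = [sampler.sample(_derive_seed(cfg.seed, 5, i))
                 for i in range(cfg.val_pairs)]

    def batch(strip, t):
        rng = np.random.default_rng(_derive_seed(cfg.seed, 6, strip, t))
        lam = float(rng.uniform()) if lam_override is None else float(lam_override)
        s_m, s_f, m, f = sampler.sample(_derive_seed(cfg.seed, 7, strip, t))
        oh_m, _ = _grouped_onehot(s_m, grouping)
        oh_f, _ = _grouped_onehot(s_f, grouping)
        return _joint_loss(m, f, oh_m, oh_f, lam, theta, xi, det_cfg,
                           unet_cfg, loss_cfg)

    def validate():
        scores = []
        for s_m, s_f, m, f in val_pairs:
            g_m = recode(s_m, grouping)
            g_f = recode(s_f, grouping)
            try:
                reg = joint_register(m, f, 0.5, theta, xi, det_cfg, unet_cfg)
                moved = resample(g_m.labels.astype(float), reg["psi"], "nearest")
                _, mean = hard_dice(np.rint(moved).astype(int), g_f.labels,
                                    g_f.anatomy_set)
            except (ValueError, np.linalg.LinAlgError):
                mean = 0.0
            scores.append(mean)
        return float(np.mean(scores))

    history = _run_strips(cfg, xi, batch, validate)
    return xi, history
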