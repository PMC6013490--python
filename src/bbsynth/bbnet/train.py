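"""Patch sampling, optimization and whole-volume inference."""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from ..preprocess import Volume3D
from .config import TrainConfig, TrainLog, lr_at_epoch
from .network import ResidualCNN3D


# ---------------------------------------------------------------------------
# Patch sampling
# ---------------------------------------------------------------------------

def sample_patches(
    input_vol: Volume3D | np.ndarray,
    label_vol: Volume3D | np.ndarray,
    cfg: TrainConfig,
    n_patches: int | None = None,
    fg_mask: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Co-located cubic patch pairs from one registered volume pair.

    Origins are drawn seeded-uniformly over the valid range.  When a
    foreground mask (vessel/lesion truth) is supplied, at least
    ``cfg.fg_min_fraction`` of the patches are forced to contain foreground
    by centering them near foreground voxels.

    Returns ``(X, Y, origins)`` with X, Y of shape (n, s, s, s) float32.
    """
    x = input_vol.data if isinstance(input_vol, Volume3D) else np.asarray(input_vol)
    y = label_vol.data if isinstance(label_vol, Volume3D) else np.asarray(label_vol)
    if x.shape != y.shape:
        raise ValueError("input and label volumes must share one grid")
    s = cfg.patch_size
    if any(dim < s for dim in x.shape):
        raise ValueError(f"volume {x.shape} smaller than patch size {s}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.rng_seed if rng is None else rng)
    n = cfg.patches_per_volume if n_patches is None else int(n_patches)

    hi = np.asarray(x.shape) - s
    origins = np.stack([rng.integers(0, h + 1, size=n) for h in hi], axis=1)

    if fg_mask is not None and fg_mask.any() and cfg.fg_min_fraction > 0:
        n_fg = int(np.ceil(cfg.fg_min_fraction * n))
        fg_idx = np.argwhere(fg_mask)
        pick = fg_idx[rng.integers(0, len(fg_idx), size=n_fg)]
        jitter = rng.integers(-(s // 2), s // 2 + 1, size=(n_fg, 3))
        forced = np.clip(pick - s // 2 + jitter, 0, hi)
        origins[:n_fg] = forced
        rng.shuffle(origins, axis=0)

    X = np.empty((n, s, s, s), np.float32)
    Y = np.empty((n, s, s, s), np.float32)
    for i, (ox, oy, oz) in enumerate(origins):
        X[i] = x[ox : ox + s, oy : oy + s, oz : oz + s]
        Y[i] = y[ox : ox + s, oy : oy + s, oz : oz + s]
    return X, Y, origins


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

def clip_gradients(grads: list[np.ndarray], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most ``max_norm``.

    Returns the pre-clip global norm.
    """
    total = float(np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads)))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads:
            g *= scale
    return total


class Adam:
    """Adaptive-moment optimizer with the conventional secondary constants."""

    def __init__(self, params: list[np.ndarray], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= (lr / bias1) * m / (np.sqrt(v / bias2) + self.eps)


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a.astype(np.float64) - b.astype(np.float64)) ** 2))


def _eval_loss(net: ResidualCNN3D, pairs, batch: int) -> float:
    losses, weights = [], []
    for vx, vy in pairs:
        vx = np.asarray(vx, np.float32)
        vy = np.asarray(vy, np.float32)
        if vx.ndim == 3:
            vx, vy = vx[None], vy[None]
        for i in range(0, len(vx), batch):
            out = net.forward(vx[i : i + batch], training=False)
            losses.append(_mse(out, vy[i : i + batch]))
            weights.append(len(vx[i : i + batch]))
    return float(np.average(losses, weights=weights))


def train(
    network: ResidualCNN3D,
    patches: tuple[np.ndarray, np.ndarray],
    val_pairs=(),
    cfg: TrainConfig | None = None,
) -> tuple[ResidualCNN3D, TrainLog]:
    """Optimize the network on patch pairs with MSE loss.

    Per step: forward in training mode, mean-squared-error loss, backward,
    global-norm gradient clipping at ``cfg.grad_clip``, one Adam update at
    the scheduled learning rate.  Stops at ``cfg.n_epochs`` or earlier when
    the validation loss has not improved for ``cfg.patience`` epochs
    ("validation saturation").
    """
    if cfg is None:
        cfg = TrainConfig()
    X, Y = patches
    X = np.asarray(X, np.float32)
    Y = np.asarray(Y, np.float32)
    if len(X) == 0:
        raise ValueError("empty patch set")

    rng = np.random.default_rng(cfg.rng_seed)
    opt = Adam(network.params)
    log = TrainLog()
    best_val = np.inf
    since_best = 0

    for epoch in range(cfg.n_epochs):
        lr = lr_at_epoch(cfg, epoch)
        order = rng.permutation(len(X))
        epoch_losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = X[idx], Y[idx]
            out = network.forward(xb, training=True)
            diff = out - yb
            loss = float(np.mean(diff.astype(np.float64) ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, step {i // cfg.batch_size}"
                )
            epoch_losses.append(loss)
            network.backward((2.0 / diff.size) * diff)
            grads = network.grads
            clip_gradients(grads, cfg.grad_clip)
            opt.step(grads, lr)

        vloss = _eval_loss(network, val_pairs, cfg.batch_size) if len(val_pairs) else None
        log.train_loss.append(float(np.mean(epoch_losses)))
        log.val_loss.append(vloss)
        log.lr.append(lr)
        log.stop_epoch = epoch

        if vloss is not None:
            if vloss < best_val - 1e-12:
                best_val = vloss
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    log.stop_reason = "validation_saturation"
                    return network, log
    log.stop_reason = "max_epochs"
    return network, log


def fine_tune(
    network: ResidualCNN3D,
    patches: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
    val_pairs=(),
    n_epochs: int | None = None,
) -> tuple[ResidualCNN3D, TrainLog]:
    """Continue training at 1/10 the initial learning rate, other settings equal.

    The epoch cap defaults to 60.  Zero epochs returns the network unchanged.
    """
    epochs = 60 if n_epochs is None else int(n_epochs)
    if epochs == 0:
        return network, TrainLog(stop_reason="max_epochs")
    ft_cfg = replace(cfg, learning_rate=cfg.learning_rate / 10.0, n_epochs=epochs)
    return train(network, patches, val_pairs=val_pairs, cfg=ft_cfg)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def infer(
    network: ResidualCNN3D,
    vol: Volume3D,
    tile_vox: int | None = None,
    max_whole_vox: int = 2_500_000,
    clip_range: tuple[float, float] | None = (0.0, 1.0),
) -> Volume3D:
    """Whole-volume forward pass producing the deep-learned BB volume.

    Batch normalization uses accumulated running statistics (evaluation
    mode).  Volumes larger than ``max_whole_vox`` voxels are processed in
    overlapping tiles whose borders (one receptive-field margin) are
    discarded before stitching, which reproduces the whole-volume result
    exactly away from the volume boundary.  The output is clamped to the
    valid normalized intensity range (``clip_range=None`` disables this).
    """
    data = np.asarray(vol.data, np.float32)
    n_vox = int(np.prod(data.shape))
    if tile_vox is None and n_vox <= max_whole_vox:
        out = network.forward(data[None], training=False)[0]
    else:
        margin = network.cfg.n_conv_layers  # receptive-field radius
        tile = tile_vox if tile_vox is not None else 64
        tile = max(tile, 2 * margin + 8)
        out = np.empty_like(data)
        for ox in range(0, data.shape[0], tile):
            for oy in range(0, data.shape[1], tile):
                for oz in range(0, data.shape[2], tile):
                    lo = np.array([ox, oy, oz])
                    hi = np.minimum(lo + tile, data.shape)
                    lo_pad = np.maximum(lo - margin, 0)
                    hi_pad = np.minimum(hi + margin, data.shape)
                    block = data[lo_pad[0]:hi_pad[0], lo_pad[1]:hi_pad[1], lo_pad[2]:hi_pad[2]]
                    res = network.forward(block[None], training=False)[0]
                    cut_lo = lo - lo_pad
                    cut_hi = cut_lo + (hi - lo)
                    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = res[
                        cut_lo[0]:cut_hi[0], cut_lo[1]:cut_hi[1], cut_lo[2]:cut_hi[2]
                    ]
    if not np.all(np.isfinite(out)):
        raise RuntimeError("inference produced non-finite voxels")
    if clip_range is not None:
        out = np.clip(out, *clip_range)
    return vol.copy(data=out.astype(np.float64), modality="DL_BB")
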