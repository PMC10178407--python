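"""Augmentation, losses with detail guidance, and the training loop.

Augmentation covers random rotation ("flipping" by an
angle drawn from 0–360°), random cropping to a configurable fraction of the
height or width (default one third), Gaussian noise and brightness scaling.
Geometric transforms are applied identically to image and mask; photometric
ones touch the image only, so the mask stays binary.

The loss is cross-entropy + soft dice on the main head, the same on the
auxiliary heads over the two deepest encoder stages, and binary
cross-entropy + dice on the detail head, which is supervised by a
multi-scale Laplacian edge map of the mask (detail guidance: shallow
features learn wound boundaries explicitly).

Training uses SGD with momentum (initial learning rate 0.01, batch size 8 by
default) under polynomial learning-rate decay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .nn import SGD, PolyDecay, Tensor, upsample_bilinear
from .segnet import SegmentationNetwork, _resize_float, _NORM_MEAN, _NORM_STD, segment_image

__all__ = [
    "AugmentationSpec",
    "TrainConfig",
    "TrainResult",
    "augment",
    "expand_dataset",
    "detail_ground_truth",
    "compute_loss",
    "train",
    "predict_mask",
]

_EPS = 1e-7


# -- augmentation --------------------------------------------------------------


@dataclass(frozen=True)
class AugmentationSpec:
    flip_angle_range: tuple[float, float] = (0.0, 360.0)
    crop_fraction: float = 1.0 / 3.0  # fraction of the height or width kept
    gaussian_noise_sigma: float = 10.0 / 255.0  # intensity units on [0, 1]
    brightness_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.crop_fraction <= 1.0):
            raise ValueError("crop_fraction must be in (0, 1]")
        lo, hi = self.flip_angle_range
        if not (0.0 <= lo <= hi <= 360.0):
            raise ValueError("flip_angle_range must lie within [0, 360]")
        if self.gaussian_noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


def _rotate_pair(image, mask, angle):
    if angle % 360 == 0:
        return image, mask
    if angle % 90 == 0:  # axis-aligned rotations are exact
        k = int(angle // 90) % 4
        return np.rot90(image, k), np.rot90(mask, k)
    img = ndimage.rotate(image, angle, axes=(1, 0), reshape=False, order=1,
                         mode="reflect")
    msk = ndimage.rotate(mask, angle, axes=(1, 0), reshape=False, order=0,
                         mode="constant", cval=0)
    return img, msk


def augment(image, mask, spec: AugmentationSpec, rng: np.random.Generator | None = None):
    """One augmented (image, mask) pair.  With the default ``rng=None`` the
    transform is drawn from a generator seeded by ``spec.seed``, so the same
    spec always produces bit-identical output; pass a shared generator to
    draw a stream of different transforms."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError(f"image/mask size mismatch: {image.shape[:2]} vs {mask.shape[:2]}")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)

    angle = float(rng.uniform(*spec.flip_angle_range))
    image, mask = _rotate_pair(image, mask, angle)

    if spec.crop_fraction < 1.0:
        dim = int(rng.integers(2))  # 0: crop the height, 1: crop the width
        side = image.shape[dim]
        new = max(1, round(side * spec.crop_fraction))
        off = int(rng.integers(side - new + 1))
        sl = [slice(None), slice(None)]
        sl[dim] = slice(off, off + new)
        image, mask = image[tuple(sl)], mask[tuple(sl)]

    out = image.astype(np.float64)
    lo, hi = spec.brightness_range
    if (lo, hi) != (1.0, 1.0):
        out = out * rng.uniform(lo, hi)
    if spec.gaussian_noise_sigma > 0:
        out = out + rng.normal(0.0, spec.gaussian_noise_sigma * 255.0, size=out.shape)
    image = np.clip(out, 0, 255).astype(np.uint8)
    return image, np.ascontiguousarray(mask)


def expand_dataset(pairs, factor: int, spec: AugmentationSpec, seed: int = 0):
    """Grow a dataset by augmentation: originals plus (factor-1)·n transformed
    copies (small clinical sets are typically enlarged several-fold)."""
    if factor < 1:
        raise ValueError("expansion factor must be >= 1")
    rng = np.random.default_rng(seed)
    out = list(pairs)
    for _ in range(factor - 1):
        for img, msk in pairs:
            out.append(augment(img, msk, spec, rng=rng))
    return out


# -- detail guidance -----------------------------------------------------------

_LAPLACIAN = np.array([[-1, -1, -1], [-1, 8, -1], [-1, -1, -1]], dtype=np.float64) / 8.0


def detail_ground_truth(mask, scales=(1, 2, 4), threshold: float = 0.1) -> np.ndarray:
    """Multi-scale Laplacian edge map of a binary mask, thresholded to binary.

    The mask is block-averaged at each scale, convolved with a Laplacian
    kernel (nearest-edge padding, so a constant mask yields no response even
    at the border), thresholded, upsampled back, and the scales are OR-ed.
    """
    arr = np.asarray(mask)
    uniq = np.unique(arr)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError("detail_ground_truth expects a binary 0/1 mask")
    arr = arr.astype(np.float64)
    H, W = arr.shape
    out = np.zeros((H, W), dtype=bool)
    for s in scales:
        if s == 1:
            down = arr
        else:
            Hc, Wc = (H // s) * s, (W // s) * s
            down = arr[:Hc, :Wc].reshape(Hc // s, s, Wc // s, s).mean(axis=(1, 3))
        resp = np.abs(ndimage.convolve(down, _LAPLACIAN, mode="nearest")) > threshold
        up = np.repeat(np.repeat(resp, s, axis=0), s, axis=1)
        out[: up.shape[0], : up.shape[1]] |= up
    return out.astype(np.uint8)


# -- losses --------------------------------------------------------------------


def _soft_dice(p: Tensor, target: np.ndarray) -> Tensor:
    t = Tensor(target.astype(p.data.dtype))
    inter = (p * t).sum()
    return (2.0 * inter + _EPS) / (p.sum() + t.sum() + _EPS)


def _ce_dice(logits: Tensor, target: np.ndarray) -> Tensor:
    """Cross-entropy + (1 - soft dice) for 2-class logits (B,2,H,W)."""
    probs = logits.softmax(axis=1)
    onehot = np.stack([1.0 - target, target], axis=1).astype(logits.data.dtype)
    ce = -((Tensor(onehot) * (probs + _EPS).log()).sum(axis=1)).mean()
    p_wound = probs.slice((slice(None), 1))
    return ce + (1.0 - _soft_dice(p_wound, target))


def _bce_dice(logits: Tensor, target: np.ndarray) -> Tensor:
    p = logits.slice((slice(None), 0)).sigmoid()
    t = Tensor(target.astype(p.data.dtype))
    bce = -(t * (p + _EPS).log() + (1.0 - t) * (1.0 - p + _EPS).log()).mean()
    return bce + (1.0 - _soft_dice(p, target))


def compute_loss(
    logits: Tensor,
    aux_logits: list[Tensor],
    detail_logits: Tensor | None,
    mask: np.ndarray,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    detail_target: np.ndarray | None = None,
):
    """Weighted sum of main, auxiliary and detail losses.

    ``mask`` is (B,H,W) binary at the resolution of ``logits``; auxiliary and
    detail logits are upsampled to that resolution.  Returns ``(loss,
    components)`` where components holds the unweighted terms.
    """
    if logits.shape[2:] != mask.shape[1:]:
        raise ValueError("logits/mask spatial mismatch")
    w_seg, w_aux, w_detail = weights
    components = {"seg": _ce_dice(logits, mask)}
    total = w_seg * components["seg"]
    if aux_logits:
        aux_terms = []
        for aux in aux_logits:
            up = upsample_bilinear(aux, mask.shape[1:])
            aux_terms.append(_ce_dice(up, mask))
        components["aux"] = sum(aux_terms[1:], aux_terms[0])
        total = total + w_aux * components["aux"]
    if detail_logits is not None:
        if detail_target is None:
            detail_target = np.stack([detail_ground_truth(m) for m in mask])
        up = upsample_bilinear(detail_logits, detail_target.shape[1:])
        components["detail"] = _bce_dice(up, detail_target)
        total = total + w_detail * components["detail"]
    return total, components


# -- training loop -------------------------------------------------------------


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    batch_size: int = 8
    epochs: int = 10
    max_steps: int | None = None
    lr_power: float = 0.9
    momentum: float = 0.9
    weight_decay: float = 5e-4
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    augmentation: AugmentationSpec | None = None
    expansion_factor: int = 1
    val_fraction: float = 0.2
    pretrained_path: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class TrainResult:
    state_dict: dict                  # best parameters (by validation dice)
    history: pd.DataFrame             # epoch, train_loss, val_loss, val_dice
    best_epoch: int
    best_val_dice: float

    def history_to_csv(self, path: str) -> None:
        self.history.to_csv(path, index=False)


class TrainingDiverged(RuntimeError):
    pass


def _prepare(sample, side: int):
    """Resize one (image, mask) pair to the network's working resolution."""
    if hasattr(sample, "image"):
        img, msk = sample.image, sample.mask
    else:
        img, msk = sample
    x = _resize_float(np.asarray(img, dtype=np.float64) / 255.0, (side, side))
    x = ((x - _NORM_MEAN) / _NORM_STD).transpose(2, 0, 1).astype(np.float32)
    H, W = np.asarray(msk).shape
    iy = np.minimum((np.arange(side) + 0.5) * H // side, H - 1).astype(int)
    ix = np.minimum((np.arange(side) + 0.5) * W // side, W - 1).astype(int)
    m = np.asarray(msk)[np.ix_(iy, ix)].astype(np.float32)
    return x, m


def _epoch_eval(network, xs, ms, weights):
    """Mean loss and hard-threshold dice over a sample list (eval mode)."""
    from .metrics import confusion, dice as dice_metric

    network.eval()
    losses, dices = [], []
    for x, m in zip(xs, ms):
        out = network.forward_full(Tensor(x[None]))
        loss, _ = compute_loss(out["logits"], [out["aux4"], out["aux5"]],
                               out["detail"], m[None], weights)
        losses.append(loss.item())
        pred = (out["logits"].softmax(axis=1).data[0, 1] >= 0.5).astype(np.uint8)
        d = dice_metric(confusion(pred, (m > 0.5).astype(np.uint8)))
        dices.append(1.0 if d is None else d)
    network.train()
    return float(np.mean(losses)), float(np.mean(dices))


def train(dataset, network: SegmentationNetwork, config: TrainConfig) -> TrainResult:
    """Train the network on (image, mask) pairs or rendered scenes.

    Deterministic under ``config.seed`` for fixed data.  Returns the best
    checkpoint by validation dice together with the per-epoch history; the
    network is left holding the best parameters.
    """
    items = list(dataset)
    if not items:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(config.seed)

    if config.augmentation is not None and config.expansion_factor > 1:
        pairs = [(s.image, s.mask) if hasattr(s, "image") else s for s in items]
        items = expand_dataset(pairs, config.expansion_factor, config.augmentation,
                               seed=config.seed)

    side = network.config.input_side
    prepared = [_prepare(s, side) for s in items]
    idx = rng.permutation(len(prepared))
    n_val = int(round(config.val_fraction * len(prepared)))
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    if len(train_idx) == 0:
        train_idx = idx
    if len(val_idx) == 0:
        val_idx = train_idx  # tiny datasets validate on the training set
    tr_x = [prepared[i][0] for i in train_idx]
    tr_m = [prepared[i][1] for i in train_idx]
    va_x = [prepared[i][0] for i in val_idx]
    va_m = [prepared[i][1] for i in val_idx]

    if config.pretrained_path:
        from .segnet import load_checkpoint

        network.load_state_dict(load_checkpoint(config.pretrained_path).state_dict())

    history_rows = []
    best = {"epoch": -1, "dice": -1.0, "state": network.state_dict()}
    if config.epochs == 0:
        return TrainResult(best["state"], pd.DataFrame(
            columns=["epoch", "train_loss", "val_loss", "val_dice"]), -1, -1.0)

    steps_per_epoch = int(np.ceil(len(tr_x) / config.batch_size))
    total_steps = (config.max_steps if config.max_steps is not None
                   else config.epochs * steps_per_epoch)
    opt = SGD(network.parameters(), lr=config.learning_rate,
              momentum=config.momentum, weight_decay=config.weight_decay)
    sched = PolyDecay(opt, total_steps, power=config.lr_power)

    network.train()
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(tr_x))
        epoch_losses = []
        for b0 in range(0, len(order), config.batch_size):
            batch = order[b0 : b0 + config.batch_size]
            xb = np.stack([tr_x[i] for i in batch])
            mb = np.stack([tr_m[i] for i in batch])
            out = network.forward_full(Tensor(xb, requires_grad=False))
            loss, _ = compute_loss(out["logits"], [out["aux4"], out["aux5"]],
                                   out["detail"], mb, config.loss_weights)
            if not np.isfinite(loss.item()):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch} step {step}: {loss.item()}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            sched.step()
            epoch_losses.append(loss.item())
            step += 1
            if config.max_steps is not None and step >= config.max_steps:
                break
        val_loss, val_dice = _epoch_eval(network, va_x, va_m, config.loss_weights)
        history_rows.append(
            {"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
             "val_loss": val_loss, "val_dice": val_dice}
        )
        if val_dice > best["dice"]:
            best = {"epoch": epoch, "dice": val_dice, "state": network.state_dict()}
        if config.max_steps is not None and step >= config.max_steps:
            break

    network.load_state_dict(best["state"])
    network.eval()
    return TrainResult(best["state"], pd.DataFrame(history_rows),
                       best["epoch"], best["dice"])


def predict_mask(network: SegmentationNetwork, image, threshold: float = 0.5):
    """Binary wound mask at the native image resolution."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    prob = segment_image(network, image)
    return (prob >= threshold).astype(np.uint8)
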