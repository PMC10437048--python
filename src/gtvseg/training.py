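"""Training protocol: volume-stratified splitting, augmentation, cosine
annealing with warm restarts, and the Adam training loop with
best-on-validation checkpoint selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import Mask, Volume
from .losses import LossConfig, composite_loss_and_grads
from .metrics import dsc
from .model import SENormUNet3D, predict, save_checkpoint
from .nn.functional import DTYPE
from .nn.optim import Adam

__all__ = ["SplitPlan", "TrainConfig", "AugmentConfig", "stratified_split", "augment",
           "lr_at", "train", "TrainResult"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitPlan:
    train_ids: tuple
    val_ids: tuple
    test_ids: tuple
    n_strata: int
    seed: int

    def __post_init__(self) -> None:
        all_ids = list(self.train_ids) + list(self.val_ids) + list(self.test_ids)
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("split groups are not disjoint")


@dataclass(frozen=True)
class AugmentConfig:
    max_rotation_deg: float = 45.0
    p_flip: float = 0.5
    flip_axes: tuple = (0, 1, 2)


@dataclass(frozen=True)
class TrainConfig:
    """Defaults follow the full-scale protocol (600 epochs, batch 1, Adam,
    cosine annealing 1e-3 -> 1e-6 restarting every 25 epochs); desk-scale
    runs shrink epochs, not the schedule shape."""

    epochs: int = 600
    batch_size: int = 1
    lr_max: float = 1e-3
    lr_min: float = 1e-6
    restart_period: float = 25.0
    warm_restarts: bool = True
    augment: AugmentConfig | None = AugmentConfig()
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lr_min < self.lr_max):
            raise ValueError("lr_min must be below lr_max")
        if self.restart_period < 1:
            raise ValueError("restart_period must be >= 1 epoch")


def stratified_split(cases, n_strata: int = 18, per_stratum_train: int = 3,
                     seed: int = 0, val_test_ratio=(18, 14)) -> SplitPlan:
    """Volume-stratified train selection, random val/test assignment.

    Cases ``(id, gtv_voxels)`` are sorted ascending by tumor volume and cut
    into ``n_strata`` near-equal groups; ``per_stratum_train`` cases per
    group go to training (seeded draw), the remainder is shuffled and split
    val:test at ``val_test_ratio``.
    """
    cases = list(cases)
    if n_strata < 1 or len(cases) < n_strata:
        raise ValueError(f"cannot form {n_strata} strata from {len(cases)} cases")
    order = sorted(cases, key=lambda c: (float(c[1]), str(c[0])))
    ids = [c[0] for c in order]
    strata = np.array_split(np.arange(len(ids)), n_strata)
    rng = np.random.default_rng(seed)
    train, rest = [], []
    for group in strata:
        if len(group) < per_stratum_train:
            raise ValueError(
                f"stratum of size {len(group)} cannot supply {per_stratum_train} training cases"
            )
        picked = rng.choice(group, size=per_stratum_train, replace=False)
        picked_set = set(int(i) for i in picked)
        train += [ids[i] for i in sorted(picked_set)]
        rest += [ids[int(i)] for i in group if int(i) not in picked_set]
    rest = list(rest)
    rng.shuffle(rest)
    rv, rt = val_test_ratio
    n_val = int(round(len(rest) * rv / (rv + rt)))
    return SplitPlan(
        train_ids=tuple(train),
        val_ids=tuple(rest[:n_val]),
        test_ids=tuple(rest[n_val:]),
        n_strata=n_strata,
        seed=seed,
    )


def _rotate(data, angle_deg, order, cval):
    if abs(angle_deg) < 1e-12:
        return data
    return ndimage.rotate(data, angle_deg, axes=(0, 1), reshape=False, order=order,
                          mode="constant", cval=cval)


def augment(ct: Volume, pet: Volume, mask: Mask, cfg: AugmentConfig,
            rng: np.random.Generator):
    """One random rotation about the axial axis (uniform in [0, max]) plus
    independent axis flips, applied identically to CT, PET and mask.

    Images are interpolated trilinearly, the mask nearest-neighbour so it
    stays binary; shapes, spacing and origin are preserved.
    """
    if not (ct.same_grid(pet) and ct.same_grid(mask)):
        raise ValueError("augment requires CT, PET and mask on the same grid")
    angle = float(rng.uniform(0.0, cfg.max_rotation_deg))
    flips = [bool(rng.random() < cfg.p_flip) for _ in cfg.flip_axes]

    def _apply(data, order, cval):
        out = _rotate(np.asarray(data, dtype=float), angle, order, cval)
        for ax, do_flip in zip(cfg.flip_axes, flips):
            if do_flip:
                out = np.flip(out, axis=ax)
        return np.ascontiguousarray(out)

    ct_bg = float(np.min(ct.data))   # normalized CT background (-1 after scaling)
    pet_bg = float(np.min(pet.data))
    ct_a = ct.with_data(_apply(ct.data, 1, ct_bg))
    pet_a = pet.with_data(_apply(pet.data, 1, pet_bg))
    mask_a = Mask(data=np.rint(_apply(mask.data, 0, 0.0)), spacing=mask.spacing, origin=mask.origin)
    return ct_a, pet_a, mask_a


def lr_at(epoch: float, cfg: TrainConfig) -> float:
    """Cosine annealing with warm restarts:
    lr = lr_min + (lr_max - lr_min)/2 * (1 + cos(pi * t / T)), t = epoch mod T."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    T = float(cfg.restart_period)
    t = float(epoch) % T if cfg.warm_restarts else min(float(epoch), T)
    return cfg.lr_min + 0.5 * (cfg.lr_max - cfg.lr_min) * (1.0 + np.cos(np.pi * t / T))


@dataclass
class TrainResult:
    history: pd.DataFrame  # epoch, lr, train_loss, val_dsc
    best_epoch: int
    best_val_dsc: float
    final_val_dsc: float
    best_state: dict
    final_state: dict


def _case_input(model: SENormUNet3D, ct: Volume, pet: Volume) -> np.ndarray:
    if model.cfg.in_channels == 1:
        only = ct if ct is not None else pet
        return np.asarray(only.data, dtype=DTYPE)[None]
    return np.stack([np.asarray(ct.data, dtype=DTYPE), np.asarray(pet.data, dtype=DTYPE)], axis=0)


def _val_dsc(model, data_source, ids) -> float:
    scores = []
    for cid in ids:
        ct, pet, mask = data_source[cid]
        if model.cfg.in_channels == 1:
            pred = predict(model, ct_patch=ct) if ct is not None else predict(model, pet_patch=pet)
        else:
            pred = predict(model, ct_patch=ct, pet_patch=pet)
        scores.append(dsc(mask, pred))
    return float(np.mean(scores)) if scores else float("nan")


def train(model: SENormUNet3D, split: SplitPlan, data_source, cfg: TrainConfig,
          out_dir=None, max_steps: int | None = None) -> TrainResult:
    """Adam training (batch 1) with the deep-supervision Dice+focal loss.

    ``data_source`` maps case-id -> (ct_patch, pet_patch, mask), all
    preprocessed and aligned. After each epoch the mean validation DSC is
    computed; the best-by-validation weights are kept and restored into the
    model on return. Fully seeded: identical configs reproduce identical
    trajectories.
    """
    if not split.train_ids:
        raise ValueError("training split is empty")
    loss_cfg = cfg.loss.for_heads(model.cfg.n_heads)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), lr=cfg.lr_max)
    rows = []
    best = (-np.inf, -1, None)
    steps = 0
    n_train = len(split.train_ids)
    stop = False
    val_score = float("nan")
    for epoch in range(cfg.epochs):
        order = list(split.train_ids)
        rng.shuffle(order)
        losses = []
        for i, cid in enumerate(order):
            ct, pet, mask = data_source[cid]
            if cfg.augment is not None:
                ct, pet, mask = augment(ct, pet, mask, cfg.augment, rng)
            x = _case_input(model, ct, pet)
            out = model.forward(x, train=True)
            value, gmain, gaux = composite_loss_and_grads(out, mask, loss_cfg)
            if not np.isfinite(value.total):
                raise RuntimeError(
                    f"non-finite loss {value.total} at epoch {epoch}, case {cid!r}"
                )
            opt.zero_grad()
            model.backward(gmain, gaux)
            lr = lr_at(epoch + i / n_train, cfg)
            opt.step(lr=lr)
            losses.append(value.total)
            steps += 1
            if max_steps is not None and steps >= max_steps:
                stop = True
                break
        val_score = _val_dsc(model, data_source, split.val_ids)
        rows.append({"epoch": epoch, "lr": lr_at(epoch, cfg),
                     "train_loss": float(np.mean(losses)), "val_dsc": val_score})
        track = val_score if np.isfinite(val_score) else -float(np.mean(losses))
        if track > best[0]:
            best = (track, epoch, model.state_dict())
        logger.info("epoch %d: loss %.4f, val DSC %.4f", epoch, np.mean(losses), val_score)
        if stop:
            break

    final_state = model.state_dict()
    final_val = val_score
    best_state = best[2] if best[2] is not None else final_state
    model.load_state_dict(best_state)
    history = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, out_dir / "best.npz")
        history.to_csv(out_dir / "history.csv", index=False)
    best_val = _val_dsc(model, data_source, split.val_ids)
    return TrainResult(history=history, best_epoch=best[1],
                       best_val_dsc=float(best_val), final_val_dsc=float(final_val),
                       best_state=best_state, final_state=final_state)
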