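"""Training loop: Adam on the combined BCE–Dice objective.

Defaults follow the study protocol: 200 epochs, batch size 8, initial
learning rate 1e-4, learning-rate decay by one half on a validation-loss
plateau (patience 10 epochs), model selection by best validation DSC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import segmentation_metrics
from .network import DEFIFNet
from .nn import Adam
from .objective import LossWeights, bce_loss, combined_loss, dice_loss


@dataclass
class TrainSettings:
    epochs: int = 200
    batch_size: int = 8
    lr: float = 1e-4
    lr_decay: float = 0.5
    patience: int = 10
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    verbose: bool = False


def to_model_input(images: np.ndarray) -> np.ndarray:
    """(N, H, W, 3) uint8/float -> (N, 3, H, W) float32 in [0, 1]."""
    x = np.asarray(images, dtype=np.float32)
    if x.ndim != 4 or x.shape[-1] != 3:
        raise ValueError(f"expected (N, H, W, 3) images, got {x.shape}")
    if x.max() > 1.5:
        x = x / 255.0
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def to_mask_target(masks: np.ndarray) -> np.ndarray:
    """(N, H, W) binary -> (N, 1, H, W) float32."""
    g = np.asarray(masks)
    if g.ndim == 4:
        g = g[:, 0] if g.shape[1] == 1 else g[..., 0]
    if not np.isin(g, (0, 1)).all():
        raise ValueError("masks must be strictly binary")
    return g[:, None].astype(np.float32)


def predict_proba(net: DEFIFNet, images: np.ndarray,
                  batch_size: int = 8) -> np.ndarray:
    """Forward in eval mode; returns (N, H, W) foreground probabilities."""
    x = to_model_input(images)
    was_training = net.training
    net.eval()
    outs = []
    for i in range(0, len(x), batch_size):
        outs.append(net(x[i:i + batch_size]).data[:, 0])
    net.train(was_training)
    return np.concatenate(outs, axis=0)


def _mean_dsc(net: DEFIFNet, images, masks, batch_size) -> float:
    prob = predict_proba(net, images, batch_size)
    pred = (prob >= 0.5).astype(np.uint8)
    rep = segmentation_metrics(pred, np.asarray(masks), with_hausdorff=False)
    return rep.mean["dsc"]


def train_network(net: DEFIFNet, images: np.ndarray, masks: np.ndarray,
                  val_images: np.ndarray | None = None,
                  val_masks: np.ndarray | None = None,
                  settings: TrainSettings = TrainSettings()) -> dict:
    """Train in place; returns a history dict and restores the best state.

    History rows carry per-epoch train loss (with its Dice/BCE decomposition),
    the monitored DSC, and the learning rate.  The best state by monitored
    DSC (validation if provided, else training) is restored into `net` at the
    end and also returned under ``"best_state"``.
    """
    x = to_model_input(images)
    g = to_mask_target(masks)
    has_val = val_images is not None and len(val_images) > 0
    rng = np.random.default_rng(settings.seed)
    opt = Adam(net.parameters(), lr=settings.lr)
    history: list[dict] = []
    best = {"dsc": -1.0, "state": None, "epoch": -1}
    plateau_best = np.inf
    plateau_count = 0
    n = len(x)
    bs = min(settings.batch_size, n)
    for epoch in range(settings.epochs):
        net.train()
        order = rng.permutation(n)
        ep_loss = ep_dice = ep_bce = 0.0
        nb = 0
        for i in range(0, n, bs):
            idx = order[i:i + bs]
            xb, gb = x[idx], g[idx]
            net.zero_grad()
            p = net(xb)
            dl = dice_loss(p, gb)
            bl = bce_loss(p, gb)
            loss = settings.weights.alpha * dl + settings.weights.beta * bl
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}, step {nb + 1}")
            loss.backward()
            opt.step()
            ep_loss += loss.item()
            ep_dice += dl.item()
            ep_bce += bl.item()
            nb += 1
        monitored = _mean_dsc(net, val_images, val_masks, bs) if has_val \
            else _mean_dsc(net, images, masks, bs)
        row = {
            "epoch": epoch + 1,
            "train_loss": ep_loss / nb,
            "train_dice_loss": ep_dice / nb,
            "train_bce_loss": ep_bce / nb,
            "monitored_dsc": monitored,
            "lr": opt.lr,
        }
        history.append(row)
        if settings.verbose:
            print(f"epoch {epoch + 1:4d}  loss {row['train_loss']:.4f}  "
                  f"dsc {monitored:.4f}  lr {opt.lr:.2e}")
        if monitored > best["dsc"]:
            best = {"dsc": monitored, "state": net.state_dict(),
                    "epoch": epoch + 1}
        # lr decay on loss plateau
        crit = row["train_loss"]
        if crit < plateau_best - 1e-6:
            plateau_best = crit
            plateau_count = 0
        else:
            plateau_count += 1
            if plateau_count >= settings.patience:
                opt.lr *= settings.lr_decay
                plateau_count = 0
    if best["state"] is not None:
        net.load_state_dict(best["state"])
    return {"history": history, "best_epoch": best["epoch"],
            "best_dsc": best["dsc"], "best_state": best["state"]}


def overfit_smoke(images, masks, config=None, epochs: int = 300,
                  lr: float = 3e-3, target_dsc: float = 0.90,
                  seed: int = 0) -> dict:
    """Full-batch overfitting probe: can the network memorize a tiny set?

    Trains with the combined loss on the whole set as one batch, stopping as
    soon as the training DSC reaches `target_dsc`.  The learning rate default
    is raised relative to mini-batch training because full-batch mode takes
    exactly one optimization step per epoch.
    """
    from .network import ModelConfig

    cfg = config or ModelConfig(seed=seed)
    net = DEFIFNet(cfg)
    x = to_model_input(images)
    g = to_mask_target(masks)
    opt = Adam(net.parameters(), lr=lr)
    weights = LossWeights()
    dsc = 0.0
    for epoch in range(epochs):
        net.train()
        net.zero_grad()
        loss = combined_loss(net(x), g, weights)
        loss.backward()
        opt.step()
        if (epoch + 1) % 5 == 0 or epoch == epochs - 1:
            dsc = _mean_dsc(net, images, masks, batch_size=len(x))
            if dsc >= target_dsc:
                return {"reached": True, "epochs": epoch + 1, "dsc": dsc}
    return {"reached": dsc >= target_dsc, "epochs": epochs, "dsc": dsc}
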