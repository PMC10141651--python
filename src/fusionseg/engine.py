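"""Training and inference orchestration.

Joint training per batch: build the clean and per-modality-masked inputs,
run both branches through the shared encoders, decode the clean branch,
and step Adam on the combined segmentation + similarity objective. The
learning rate follows a stepped exponential schedule (decay factor applied
every fixed number of epochs). Checkpoints are ``.npz`` weight archives
with the network configuration embedded as JSON; loss history is logged as
line-delimited JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .backbone import HybridFusionNet, NetworkConfig
from .nn import Adam, Tensor
from .objective import LossWeights, evaluate, mean_region_scores, seg_loss, total_loss
from .phantom import ModalityStack
from .preprocess import SliceDataset, restore_labels
from .selfsup import apply_masks, dual_branch_forward, similarity_loss

__all__ = [
    "TrainConfig",
    "lr_schedule",
    "train",
    "predict",
    "predict_raw",
    "evaluate_dataset",
    "save_checkpoint",
    "load_checkpoint",
    "split_dataset",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters and the pretext-task switches."""

    batch_size: int = 8
    initial_lr: float = 1e-5
    lr_decay: float = 0.9
    decay_every: int = 5
    epochs: int = 15
    data_fraction: float = 1.0
    seed: int = 0
    selfsup: bool = True
    mask_strategy: str = "block20"
    mask_fill: float = 0.0
    lambda_sim: float = 1.0
    alpha: float = 1.0
    beta: float = 0.5

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0.0 < self.lr_decay <= 1.0):
            raise ValueError("lr_decay must lie in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0.0 < self.data_fraction <= 1.0):
            raise ValueError("data_fraction must lie in (0, 1]")

    def loss_weights(self) -> LossWeights:
        return LossWeights(alpha=self.alpha, beta=self.beta, lambda_sim=self.lambda_sim)


def lr_schedule(cfg: TrainConfig, epoch: int) -> float:
    """Stepped decay: ``initial_lr * lr_decay ** (epoch // decay_every)``.

    Epochs are 0-based, so the first decay takes effect at epoch
    ``decay_every``.
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.initial_lr * cfg.lr_decay ** (epoch // cfg.decay_every)


def _as_list(dataset) -> list[ModalityStack]:
    if isinstance(dataset, SliceDataset):
        return list(dataset.stacks)
    return list(dataset)


def _batch_arrays(stacks: list[ModalityStack]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.as_array() for s in stacks])
    y = np.stack([s.labels for s in stacks])
    return x, y


def split_dataset(
    stacks: list[ModalityStack], val_fraction: float = 0.2, seed: int = 0
) -> tuple[list[ModalityStack], list[ModalityStack]]:
    """Seeded-shuffle train/validation split."""
    stacks = list(stacks)
    order = np.random.default_rng(seed).permutation(len(stacks))
    n_val = int(round(val_fraction * len(stacks)))
    val_idx = set(order[:n_val].tolist())
    train = [s for i, s in enumerate(stacks) if i not in val_idx]
    val = [s for i, s in enumerate(stacks) if i in val_idx]
    return train, val


def train(
    dataset,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    log_path=None,
    network: HybridFusionNet | None = None,
) -> tuple[HybridFusionNet, list[dict]]:
    """Train a network on a dataset of modality stacks.

    Returns the trained network and a per-epoch history of mean
    segmentation and similarity loss components. Raises on an empty
    dataset or a non-finite loss.
    """
    stacks = _as_list(dataset)
    if not stacks:
        raise ValueError("training dataset is empty")
    rng = np.random.default_rng(train_cfg.seed)
    if train_cfg.data_fraction < 1.0:
        n_keep = max(1, int(round(train_cfg.data_fraction * len(stacks))))
        order = rng.permutation(len(stacks))[:n_keep]
        stacks = [stacks[i] for i in sorted(order.tolist())]
    if network is None:
        network = HybridFusionNet(net_cfg, rng=np.random.default_rng(train_cfg.seed))
    weights = train_cfg.loss_weights()
    opt = Adam(network.parameters(), lr=train_cfg.initial_lr)
    history: list[dict] = []
    log_fh = open(log_path, "a") if log_path else None
    try:
        if log_fh:
            log_fh.write(json.dumps({"net_cfg": _jsonable(net_cfg), "train_cfg": _jsonable(train_cfg)}) + "\n")
        for epoch in range(train_cfg.epochs):
            opt.lr = lr_schedule(train_cfg, epoch)
            order = rng.permutation(len(stacks))
            seg_losses, sim_losses = [], []
            network.train()
            for start in range(0, len(stacks), train_cfg.batch_size):
                batch = [stacks[i] for i in order[start : start + train_cfg.batch_size]]
                x, y = _batch_arrays(batch)
                if train_cfg.selfsup:
                    masked = []
                    for s in batch:
                        mseed = int(rng.integers(2**31))
                        m, _, _ = apply_masks(
                            s, train_cfg.mask_strategy, mseed, fill_value=train_cfg.mask_fill
                        )
                        masked.append(m)
                    xm, _ = _batch_arrays(masked)
                    pair, logits = dual_branch_forward(x, xm, network)
                    sim = similarity_loss(
                        pair.clean_features, pair.masked_features, epsilon=weights.epsilon
                    )
                else:
                    logits = network(Tensor(x))
                    sim = None
                seg = seg_loss(logits, y, weights)
                loss = seg if sim is None else total_loss(seg, sim, weights)
                value = loss.item()
                if not np.isfinite(value):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} "
                        f"(seg={seg.item():.4g}, sim={'0' if sim is None else sim.item()})"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                seg_losses.append(seg.item())
                sim_losses.append(0.0 if sim is None else sim.item())
            record = {
                "epoch": epoch,
                "lr": opt.lr,
                "seg_loss": float(np.mean(seg_losses)),
                "sim_loss": float(np.mean(sim_losses)),
                "n_batches": len(seg_losses),
                "n_samples": len(stacks),
            }
            history.append(record)
            if log_fh:
                log_fh.write(json.dumps(record) + "\n")
                log_fh.flush()
    finally:
        if log_fh:
            log_fh.close()
    network.eval()
    return network, history


def _jsonable(cfg) -> dict:
    out = {}
    for k, v in asdict(cfg).items():
        out[k] = list(v) if isinstance(v, tuple) else v
    return out


def predict(network: HybridFusionNet, stacks, batch_size: int = 8) -> list[np.ndarray]:
    """Per-pixel argmax label maps (internal encoding) for a list of stacks."""
    single = isinstance(stacks, ModalityStack)
    if single:
        stacks = [stacks]
    network.eval()
    preds = []
    for start in range(0, len(stacks), batch_size):
        x, _ = _batch_arrays(stacks[start : start + batch_size])
        logits = network(Tensor(x))
        preds.extend(list(logits.data.argmax(axis=1).astype(np.int64)))
    return preds


def predict_raw(network: HybridFusionNet, stacks, batch_size: int = 8) -> list[np.ndarray]:
    """Predictions in the raw BraTS label encoding {0, 1, 2, 4}."""
    return [restore_labels(p) for p in predict(network, stacks, batch_size)]


def evaluate_dataset(network: HybridFusionNet, stacks) -> dict:
    """Mean WT/TC/ET scores of the network over a list of stacks."""
    stacks = _as_list(stacks)
    preds = predict(network, stacks)
    per_case = [evaluate(p, s.labels) for p, s in zip(preds, stacks)]
    return mean_region_scores(per_case)


def save_checkpoint(path, network: HybridFusionNet) -> None:
    """Write network weights + configuration to an ``.npz`` archive."""
    state = network.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(_jsonable(network.cfg)).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path) -> HybridFusionNet:
    """Rebuild a network from a checkpoint written by :func:`save_checkpoint`."""
    archive = np.load(path)
    cfg_json = bytes(archive["__config__"]).decode()
    data = json.loads(cfg_json)
    data["aspp_dilations"] = tuple(data["aspp_dilations"])
    cfg = NetworkConfig(**data)
    network = HybridFusionNet(cfg)
    state = {k: archive[k] for k in archive.files if k != "__config__"}
    network.load_state_dict(state)
    network.eval()
    return network
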