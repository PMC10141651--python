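"""Masked dual-branch self-supervision.

The pretext task occludes a region of every modality image — at a
different position per modality, so the unmasked modalities can supply the
missing information — and asks the shared encoders to produce the same
bottleneck features for the masked input as for the clean one. Agreement
is scored by a cosine similarity loss over the concatenated post-ASPP
features of the two branches; the segmentation decoder always consumes the
clean branch.

Four occlusion geometries are supported, all seeded and placed uniformly
at random within the image:

- ``block20``: one 20x20 square (400 pixels);
- ``block50``: one 50x50 square (2500 pixels);
- ``grid``: 16 squares of 5x5 on a 10-pixel period inside a 35x35 window
  (400 pixels, same total area as ``block20``);
- ``random``: 400 distinct pixels sampled without replacement inside a
  35x35 window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .phantom import ModalityStack

__all__ = [
    "MASK_STRATEGIES",
    "MaskSpec",
    "make_mask",
    "mask_from_origin",
    "apply_masks",
    "similarity_loss",
    "dual_branch_forward",
    "BranchPair",
]

#: strategy -> (window side, masked-pixel count)
MASK_STRATEGIES = {
    "block20": (20, 400),
    "block50": (50, 2500),
    "grid": (35, 400),
    "random": (35, 400),
}

_GRID_OFFSETS = (0, 10, 20, 30)  # 5-px block + 5-px gap inside the 35x35 window
_GRID_BLOCK = 5
_N_RANDOM = 400


@dataclass(frozen=True)
class MaskSpec:
    """Geometry of one occlusion pattern."""

    strategy: str
    window_origin: tuple[int, int]
    seed: int
    fill_value: float = 0.0

    def __post_init__(self):
        if self.strategy not in MASK_STRATEGIES:
            raise ValueError(f"unknown mask strategy {self.strategy!r}")


def mask_from_origin(
    strategy: str, image_side: int, origin: tuple[int, int], seed: int = 0
) -> np.ndarray:
    """Boolean mask for a given window origin (deterministic given seed)."""
    window, _ = MASK_STRATEGIES[strategy]
    r, c = origin
    if r < 0 or c < 0 or r + window > image_side or c + window > image_side:
        raise ValueError(
            f"{strategy} window at {origin} exceeds a {image_side}x{image_side} image"
        )
    mask = np.zeros((image_side, image_side), dtype=bool)
    if strategy in ("block20", "block50"):
        mask[r : r + window, c : c + window] = True
    elif strategy == "grid":
        for dr in _GRID_OFFSETS:
            for dc in _GRID_OFFSETS:
                mask[r + dr : r + dr + _GRID_BLOCK, c + dc : c + dc + _GRID_BLOCK] = True
    else:  # random
        rng = np.random.default_rng(seed)
        flat = rng.choice(window * window, size=_N_RANDOM, replace=False)
        rows, cols = np.divmod(flat, window)
        mask[r + rows, c + cols] = True
    return mask


def make_mask(
    strategy: str, image_side: int, seed: int
) -> tuple[np.ndarray, MaskSpec]:
    """Sample one seeded occlusion mask with a uniform window origin."""
    if strategy not in MASK_STRATEGIES:
        raise ValueError(f"unknown mask strategy {strategy!r}")
    window, _ = MASK_STRATEGIES[strategy]
    if window > image_side:
        raise ValueError(
            f"{strategy} needs a {window}x{window} window; image side is {image_side}"
        )
    rng = np.random.default_rng(seed)
    hi = image_side - window + 1
    origin = (int(rng.integers(hi)), int(rng.integers(hi)))
    spec = MaskSpec(strategy=strategy, window_origin=origin, seed=seed)
    return mask_from_origin(strategy, image_side, origin, seed=seed), spec


def apply_masks(
    stack: ModalityStack,
    strategy: str,
    seed: int,
    fill_value: float = 0.0,
) -> tuple[ModalityStack, list[MaskSpec], list[np.ndarray]]:
    """Occlude each modality at its own, pairwise-distinct window origin.

    Labels are untouched; pixels outside every mask are bit-identical to
    the clean stack. Origins are redrawn until all modalities differ.
    """
    side = stack.shape[0]
    if stack.shape[0] != stack.shape[1]:
        raise ValueError("masking assumes square slices")
    window, _ = MASK_STRATEGIES[strategy]
    if window > side:
        raise ValueError(f"{strategy} window {window} exceeds image side {side}")
    n = stack.n_modalities
    n_positions = (side - window + 1) ** 2
    if n >= 2 and n_positions < n:
        raise ValueError(
            f"cannot place {n} distinct {window}x{window} windows on a {side}px image"
        )
    rng = np.random.default_rng(seed)
    hi = side - window + 1
    for _ in range(1000):
        origins = [(int(rng.integers(hi)), int(rng.integers(hi))) for _ in range(n)]
        if len(set(origins)) == n:
            break
    else:  # pragma: no cover - astronomically unlikely given the count check
        raise RuntimeError("failed to draw distinct mask origins")
    specs, masks, images = [], [], []
    for m, origin in enumerate(origins):
        sub_seed = int(rng.integers(2**31))
        mask = mask_from_origin(strategy, side, origin, seed=sub_seed)
        img = stack.images[m].copy()
        img[mask] = fill_value
        specs.append(
            MaskSpec(strategy=strategy, window_origin=origin, seed=sub_seed, fill_value=fill_value)
        )
        masks.append(mask)
        images.append(img)
    masked = ModalityStack(
        images=images,
        labels=stack.labels,
        case_id=stack.case_id,
        slice_index=stack.slice_index,
        modality_names=stack.modality_names,
    )
    return masked, specs, masks


def similarity_loss(
    theta_clean: Tensor,
    theta_masked: Tensor,
    epsilon: float = 1e-5,
    literal: bool = False,
) -> Tensor:
    """One minus the smoothed cosine similarity of two feature bundles.

    ``1 - (<a, b> + eps) / (||a||·||b|| + eps)`` over the flattened
    features; identical branches score ~0 and orthogonal (e.g.
    disjoint-support) branches score ~1. With ``literal=True`` the
    denominator is the raw product of squared sums without the square
    root, under which identical inputs no longer score 0.
    """
    if theta_clean.shape != theta_masked.shape:
        raise ValueError(
            f"branch feature shapes differ: {theta_clean.shape} vs {theta_masked.shape}"
        )
    num = (theta_clean * theta_masked).sum() + epsilon
    sq_a = (theta_clean * theta_clean).sum()
    sq_b = (theta_masked * theta_masked).sum()
    denom = (sq_a * sq_b) if literal else (sq_a * sq_b).sqrt()
    return 1.0 - num / (denom + epsilon)


@dataclass
class BranchPair:
    """Post-ASPP bottleneck features of the clean and masked branches."""

    clean_features: Tensor
    masked_features: Tensor


def dual_branch_forward(
    batch: np.ndarray,
    masked_batch: np.ndarray,
    network,
) -> tuple[BranchPair, Tensor]:
    """Run both branches through the shared encoders; decode the clean one.

    ``batch`` and ``masked_batch`` are (N, n_modalities, H, W) arrays. The
    same network modules process both, so encoder weights are shared by
    construction; each branch keeps its own skip store and the decoder
    consumes only the clean branch's features.
    """
    clean = network.encode(Tensor(batch))
    masked = network.encode(Tensor(masked_batch))
    logits = network.decode(clean)
    pair = BranchPair(
        clean_features=nn.concat(clean.bottleneck, axis=1),
        masked_features=nn.concat(masked.bottleneck, axis=1),
    )
    return pair, logits
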