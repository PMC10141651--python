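"""Hybrid attentional fusion of per-modality feature maps.

Skip connections carry one feature map per modality. The hybrid fusion
concatenates three order-invariant reductions of those maps — elementwise
sum, elementwise product, and elementwise maximum — so the fused map always
has 3C channels whatever the number of modalities, and a soft-attention
gate then reweights it. Stabilizing the fused width at 3C is what keeps the
decoder's size independent of the modality count.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor
from .nn.tensor import _attach

__all__ = ["hybrid_fuse", "AttentionGate", "HAFB", "export_attention_map"]

#: magnitude bound applied while accumulating the elementwise product, so
#: products over many modalities cannot overflow float32
PRODUCT_CLIP = 1.0e4


def hybrid_fuse(maps: list[Tensor], product_clip: float = PRODUCT_CLIP) -> Tensor:
    """Concatenate [sum; product; max] over modality feature maps.

    Works for any number of maps n >= 1; all must share one (N, C, H, W)
    shape, and the result has 3C channels. The operands are put into a
    canonical elementwise order before reducing, so the output is
    bit-identical under any permutation of the modalities (plain float
    accumulation would differ in the last ulp). The running product is
    clipped to ``product_clip`` in magnitude so it cannot overflow for
    many modalities; gradients at a clipped step are zeroed, and gradient
    ties in the maximum go to a single input.
    """
    if not maps:
        raise ValueError("hybrid_fuse needs at least one feature map")
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"hybrid_fuse got mismatched shapes: {sorted(shapes)}")
    n = len(maps)
    stack = np.stack([m.data for m in maps])  # (n, N, C, H, W)
    order = np.argsort(stack, axis=0, kind="stable")
    sorted_stack = np.take_along_axis(stack, order, axis=0)

    total = sorted_stack.sum(axis=0)
    peak = sorted_stack[-1]
    # clipped running product in canonical order; keep intermediates for backward
    accs = np.empty_like(sorted_stack)
    accs[0] = np.clip(sorted_stack[0], -product_clip, product_clip)
    inside = np.empty(sorted_stack.shape, dtype=bool)
    inside[0] = np.abs(sorted_stack[0]) < product_clip
    for i in range(1, n):
        raw = accs[i - 1] * sorted_stack[i]
        accs[i] = np.clip(raw, -product_clip, product_clip)
        inside[i] = np.abs(raw) < product_clip

    out = Tensor(np.concatenate([total, accs[-1], peak], axis=1))

    def back(g):
        c = maps[0].shape[1]
        g_sum = g[:, :c]
        g_prod = g[:, c : 2 * c]
        g_max = g[:, 2 * c :]
        grads_sorted = np.empty_like(sorted_stack)
        # product chain, reversed
        dacc = g_prod.copy()
        for i in range(n - 1, 0, -1):
            dacc = dacc * inside[i]
            grads_sorted[i] = dacc * accs[i - 1]
            dacc = dacc * sorted_stack[i]
        grads_sorted[0] = dacc * inside[0]
        # sum part: same gradient to every operand
        grads_sorted += g_sum
        # max part: routed to the largest operand only
        grads_sorted[-1] += g_max
        # undo the elementwise sort
        grads = np.empty_like(grads_sorted)
        np.put_along_axis(grads, order, grads_sorted, axis=0)
        for m, gm in zip(maps, grads):
            m._accumulate(gm)

    _attach(out, tuple(maps), back)
    return out


class AttentionGate(nn.Module):
    """Soft-attention gate over a fused 3C-channel map.

    A 3x3 convolution squeezes 3C -> C, a second 3x3 convolution restores
    C -> 3C, and a sigmoid turns that into a per-element gate in (0, 1).
    The gated residual ``F + F * gate`` is mixed by a final 3x3
    convolution back to 3C channels. All kernels are 3x3.
    """

    def __init__(self, channels_3c: int, rng: np.random.Generator):
        super().__init__()
        if channels_3c % 3:
            raise ValueError(f"fused channel count must be divisible by 3, got {channels_3c}")
        c = channels_3c // 3
        self.phi1 = nn.Conv2d(channels_3c, c, 3, rng, bias=True)
        self.phi2 = nn.Conv2d(c, channels_3c, 3, rng, bias=True)
        self.phi3 = nn.Conv2d(channels_3c, channels_3c, 3, rng, bias=True)
        self.last_gate: np.ndarray | None = None

    def gate(self, fused: Tensor) -> Tensor:
        return self.phi2(self.phi1(fused).relu()).sigmoid()

    def forward(self, fused: Tensor) -> Tensor:
        g = self.gate(fused)
        self.last_gate = g.data
        return self.phi3(fused + fused * g)


class HAFB(nn.Module):
    """Hybrid fusion followed by the attention gate (one block per skip level)."""

    def __init__(self, per_modality_channels: int, rng: np.random.Generator):
        super().__init__()
        self.per_modality_channels = per_modality_channels
        self.out_channels = 3 * per_modality_channels
        self.attention = AttentionGate(self.out_channels, rng)

    def forward(self, maps: list[Tensor]) -> Tensor:
        for m in maps:
            if m.shape[1] != self.per_modality_channels:
                raise ValueError(
                    f"HAFB expects {self.per_modality_channels}-channel maps, got {m.shape[1]}"
                )
        return self.attention(hybrid_fuse(maps))


def export_attention_map(gate: np.ndarray | Tensor) -> np.ndarray:
    """Channel-mean saliency of an attention gate, min-max rescaled to [0, 1].

    Input is the gate for one sample, shaped (C, H, W) or (1, C, H, W); a
    constant gate (degenerate range) maps to all zeros.
    """
    g = gate.data if isinstance(gate, Tensor) else np.asarray(gate)
    if g.ndim == 4:
        if g.shape[0] != 1:
            raise ValueError("pass one sample's gate at a time")
        g = g[0]
    sal = g.mean(axis=0)
    lo, hi = float(sal.min()), float(sal.max())
    if hi - lo < 1e-12:
        return np.zeros_like(sal)
    return (sal - lo) / (hi - lo)
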