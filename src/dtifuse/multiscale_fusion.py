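"""Grouped multi-scale feature fusion.

The block refines a C x H x W feature map by splitting channels into G
groups and, within each group, running three parallel branches: a 1x1 path
driven by directional (H- and W-wise) average pooling with sigmoid gating
and per-channel GroupNorm, and a 3x3 convolution path for spatial context.
The two branches then exchange attention: the softmax-normalised global
descriptor (spatial mean per channel) of each branch is matmul'd with the
flattened map of the other, the two position-weight maps are summed, passed
through a sigmoid, and used to gate the input.  The same block serves the
drug node grid and the protein residue grid.

All spatial statistics are computed over *valid* positions only (a mask
marks padding), so enlarging the padded grid never changes the output at
valid positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

GN_EPS = 1e-5


@dataclass
class GroupedMap:
    """Channel-contiguous group split of a feature map."""

    groups: list          # G arrays, each (..., C/G, H, W)
    group_count: int


def split_groups(x, group_count: int) -> GroupedMap:
    """Split channels (axis -3) into ``group_count`` contiguous groups."""
    x = np.asarray(x)
    c = x.shape[-3]
    if c % group_count:
        raise ValueError(
            f"channel count {c} is not divisible by group count {group_count}")
    return GroupedMap(groups=list(np.split(x, group_count, axis=-3)),
                      group_count=group_count)


def concat_groups(grouped: GroupedMap) -> np.ndarray:
    return np.concatenate(grouped.groups, axis=-3)


def global_descriptor(x, mask=None) -> np.ndarray:
    """Per-channel spatial mean Z_c = (1/HW) sum_ij X_c(i, j).

    With a mask, the mean runs over valid positions only; fully masked maps
    give 0.
    """
    x = np.asarray(x, dtype=np.float64)
    if mask is None:
        return x.mean(axis=(-2, -1))
    mask = np.asarray(mask, dtype=np.float64)
    num = (x * mask).sum(axis=(-2, -1))
    cnt = np.broadcast_to(mask, x.shape).sum(axis=(-2, -1))
    return num / np.where(cnt > 0, cnt, 1.0)


def _masked_mean(x: Tensor, mask: np.ndarray, axis, keepdims=False) -> Tensor:
    """Differentiable mean of ``x`` over valid positions along ``axis``."""
    num = ad.tsum(x * mask, axis=axis, keepdims=keepdims)
    cnt = np.broadcast_to(mask, x.shape).sum(axis=axis, keepdims=keepdims)
    inv = np.where(cnt > 0, 1.0 / np.where(cnt > 0, cnt, 1.0), 0.0)
    return num * inv.astype(np.float32)


def _group_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                mask: np.ndarray) -> Tensor:
    """Per-channel normalisation over valid spatial positions."""
    mu = _masked_mean(x, mask, axis=(-2, -1), keepdims=True)
    centred = (x - mu) * mask
    var = _masked_mean(centred * centred, mask, axis=(-2, -1), keepdims=True)
    xhat = centred / ad.sqrt(var + GN_EPS)
    g = ad.reshape(gamma, (1, -1, 1, 1))
    b = ad.reshape(beta, (1, -1, 1, 1))
    return (xhat * g + b) * mask


class MultiScaleFusion:
    """Parameterised fusion block over a (B, C, H, W) map."""

    def __init__(self, channels: int, groups: int, rng: np.random.Generator,
                 name: str = "fusion"):
        if channels % groups:
            raise ValueError(
                f"channels {channels} not divisible by groups {groups}")
        self.channels = channels
        self.groups = groups
        cg = channels // groups
        self.params = {
            f"{name}.conv1_w": ad.glorot_uniform(rng, (cg, cg, 1, 1), cg, cg),
            f"{name}.conv1_b": ad.parameter(np.zeros(cg)),
            f"{name}.conv3_w": ad.glorot_uniform(rng, (cg, cg, 3, 3),
                                                 cg * 9, cg * 9),
            f"{name}.conv3_b": ad.parameter(np.zeros(cg)),
            f"{name}.gn_gamma": ad.parameter(np.ones(cg)),
            f"{name}.gn_beta": ad.parameter(np.zeros(cg)),
        }
        self._name = name

    def _p(self, key: str) -> Tensor:
        return self.params[f"{self._name}.{key}"]

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        return fuse(x, self.params, self.groups, mask=mask, name=self._name)


def fuse(x, params: dict, groups: int, mask: np.ndarray | None = None,
         name: str = "fusion") -> Tensor:
    """Apply the fusion block; output shape equals input shape.

    ``x`` is (B, C, H, W); ``mask`` is (B, 1, H, W) over valid positions
    (None means all positions are valid).
    """
    x = ad.as_tensor(x)
    B, C, H, W = x.shape
    if C % groups:
        raise ValueError(f"channels {C} not divisible by groups {groups}")
    cg = C // groups
    if mask is None:
        mask = np.ones((B, 1, H, W), dtype=np.float32)
    mask = np.asarray(mask, dtype=np.float32).reshape(B, 1, H, W)

    def p(key):
        return params[f"{name}.{key}"]

    # groups fold into the batch axis; branch weights are shared across groups
    xg = ad.reshape(x, (B * groups, cg, H, W))
    mg = np.broadcast_to(mask[:, None], (B, groups, 1, H, W)) \
        .reshape(B * groups, 1, H, W).copy()

    # 1x1 branch: directional pooling -> shared 1x1 conv -> sigmoid gates
    ph = _masked_mean(xg, mg, axis=-1)                       # (BG, cg, H)
    pw = _masked_mean(xg, mg, axis=-2)                       # (BG, cg, W)
    hw = ad.concat([ph, pw], axis=-1)                        # (BG, cg, H+W)
    hw4 = ad.reshape(hw, (B * groups, cg, 1, H + W))
    t = ad.conv2d(hw4, p("conv1_w"), p("conv1_b"))
    gh = ad.reshape(ad.sigmoid(ad.slice_axis(t, 3, 0, H)),
                    (B * groups, cg, H, 1))
    gw = ad.reshape(ad.sigmoid(ad.slice_axis(t, 3, H, H + W)),
                    (B * groups, cg, 1, W))
    x1 = _group_norm(xg * gh * gw, p("gn_gamma"), p("gn_beta"), mg)

    # 3x3 branch: spatial context
    x2 = ad.conv2d(xg, p("conv3_w"), p("conv3_b"), padding=(1, 1)) * mg

    # cross-branch attention over softmax-normalised global descriptors
    d1 = ad.softmax(_masked_mean(x1, mg, axis=(-2, -1)), axis=-1)
    d2 = ad.softmax(_masked_mean(x2, mg, axis=(-2, -1)), axis=-1)
    flat1 = ad.reshape(x1, (B * groups, cg, H * W))
    flat2 = ad.reshape(x2, (B * groups, cg, H * W))
    y1 = ad.matmul(ad.reshape(d1, (B * groups, 1, cg)), flat2)
    y2 = ad.matmul(ad.reshape(d2, (B * groups, 1, cg)), flat1)
    gate = ad.sigmoid(ad.reshape(y1 + y2, (B * groups, 1, H, W)))

    out = xg * gate * mg
    return ad.reshape(out, (B, C, H, W))
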