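"""Protein branch: embedding, gated convolutions, coordinate attention.

Residues are tokenised over a 22-symbol vocabulary (20 standard amino acids,
an unknown symbol 'X', and a padding token), embedded through a learnable
22 x D_p table, passed through a multi-order gated 1-D convolution encoder
(depthwise GLU-style stack that injects local sequence context before any
reshaping), laid out row-major on a fixed-width H x W grid, re-weighted by
coordinate attention and refined by the multi-scale fusion block, and
flattened back to per-residue states F_P.

Coordinate attention pools the map along the two grid directions
(z^h_c(h) = mean_w x_c(h, w), z^w_c(w) = mean_h x_c(h, w)), mixes the pooled
profiles through a shared 1x1 bottleneck convolution, and emits sigmoid row
and column gates; each position is rescaled by the product of its row gate
and column gate, y_c(i, j) = x_c(i, j) * g^h_c(i) * g^w_c(j).  Unlike global
channel attention this keeps positional information, which is the point for
an oriented (N-to-C) protein chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .config import ModelConfig
from .multiscale_fusion import MultiScaleFusion

logger = logging.getLogger("dtifuse")

PAD_IDX = 0
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
UNK_IDX = 21
VOCAB_SIZE = 22

_TOKEN_OF = {aa: i + 1 for i, aa in enumerate(AA_ORDER)}


@dataclass
class ProteinTensor:
    """Tokenised, embedded, padded protein sequence."""

    tokens: np.ndarray             # (theta_p,) int
    sequence_features: np.ndarray  # (theta_p, D_p)
    valid_mask: np.ndarray         # (theta_p,) in {0, 1}


@dataclass
class CoordinateGates:
    """Directional pooled profiles and the sigmoid gates they induce."""

    pooled_h: np.ndarray   # (..., C, H)
    pooled_w: np.ndarray   # (..., C, W)
    gate_h: np.ndarray     # (..., C, H), entries in (0, 1)
    gate_w: np.ndarray     # (..., C, W), entries in (0, 1)


def encode_tokens(sequence: str, seq_len_max: int) -> tuple:
    """Map a residue string to padded token ids and a validity mask.

    Unknown letters map to the 'X' token; overlong sequences are truncated
    with a logged warning; empty sequences are an error.
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    seq = sequence.upper()
    if len(seq) > seq_len_max:
        logger.warning("sequence of length %d truncated to %d",
                       len(seq), seq_len_max)
        seq = seq[:seq_len_max]
    tokens = np.full(seq_len_max, PAD_IDX, dtype=np.int64)
    for i, aa in enumerate(seq):
        tokens[i] = _TOKEN_OF.get(aa, UNK_IDX)
    mask = np.zeros(seq_len_max, dtype=np.float32)
    mask[:len(seq)] = 1.0
    return tokens, mask


def embed_sequence(sequence: str, table: np.ndarray,
                   seq_len_max: int) -> ProteinTensor:
    """Embed one sequence through a 22 x D_p table (padding rows are zero)."""
    table = np.asarray(table)
    if table.shape[0] != VOCAB_SIZE:
        raise ValueError(
            f"embedding table must have {VOCAB_SIZE} rows; got {table.shape}")
    tokens, mask = encode_tokens(sequence, seq_len_max)
    feats = table[tokens] * mask[:, None]
    return ProteinTensor(tokens=tokens, sequence_features=feats,
                         valid_mask=mask)


def directional_pool(x, mask=None) -> tuple:
    """Masked means along the two grid directions of a (..., C, H, W) map.

    Returns ``(pooled_h, pooled_w)`` with shapes (..., C, H) and (..., C, W);
    fully masked rows/columns pool to 0.
    """
    x = np.asarray(x, dtype=np.float64)
    if mask is None:
        return x.mean(axis=-1), x.mean(axis=-2)
    mask = np.asarray(mask, dtype=np.float64)
    mb = np.broadcast_to(mask, x.shape)
    cnt_h = mb.sum(axis=-1)
    cnt_w = mb.sum(axis=-2)
    ph = (x * mb).sum(axis=-1) / np.where(cnt_h > 0, cnt_h, 1.0)
    pw = (x * mb).sum(axis=-2) / np.where(cnt_w > 0, cnt_w, 1.0)
    return ph, pw


def apply_coordinate_gates(x, gate_h, gate_w) -> Tensor:
    """y_c(i, j) = x_c(i, j) * g^h_c(i) * g^w_c(j)."""
    x = ad.as_tensor(x)
    gh = ad.as_tensor(gate_h)
    gw = ad.as_tensor(gate_w)
    if gh.shape != x.shape[:-1] or gw.shape != x.shape[:-2] + x.shape[-1:]:
        raise ValueError(
            f"gate shapes {gh.shape}/{gw.shape} do not match map {x.shape}")
    gh4 = ad.reshape(gh, gh.shape + (1,))
    gw4 = ad.reshape(gw, gw.shape[:-1] + (1,) + gw.shape[-1:])
    return x * gh4 * gw4


def _masked_mean_t(x: Tensor, mask: np.ndarray, axis) -> Tensor:
    num = ad.tsum(x * mask, axis=axis)
    cnt = np.broadcast_to(mask, x.shape).sum(axis=axis)
    inv = np.where(cnt > 0, 1.0 / np.where(cnt > 0, cnt, 1.0), 0.0)
    return num * inv.astype(np.float32)


class CoordinateAttention:
    """Directional pooling -> shared 1x1 bottleneck -> row/column gates."""

    def __init__(self, channels: int, reduction: int,
                 rng: np.random.Generator, name: str = "ca"):
        cm = max(1, channels // reduction)
        self.channels, self.mid = channels, cm
        self.params = {
            f"{name}.shared_w": ad.glorot_uniform(rng, (cm, channels, 1, 1),
                                                  channels, cm),
            f"{name}.shared_b": ad.parameter(np.zeros(cm)),
            f"{name}.h_w": ad.glorot_uniform(rng, (channels, cm, 1, 1),
                                             cm, channels),
            f"{name}.h_b": ad.parameter(np.zeros(channels)),
            f"{name}.w_w": ad.glorot_uniform(rng, (channels, cm, 1, 1),
                                             cm, channels),
            f"{name}.w_b": ad.parameter(np.zeros(channels)),
        }
        self._name = name

    def _p(self, key):
        return self.params[f"{self._name}.{key}"]

    def gates(self, x: Tensor, mask: np.ndarray | None = None) -> tuple:
        """Return (gate_h, gate_w) Tensors of shapes (B, C, H), (B, C, W)."""
        B, C, H, W = x.shape
        if mask is None:
            mask = np.ones((B, 1, H, W), dtype=np.float32)
        ph = _masked_mean_t(x, mask, axis=-1)          # (B, C, H)
        pw = _masked_mean_t(x, mask, axis=-2)          # (B, C, W)
        cat = ad.reshape(ad.concat([ph, pw], axis=-1), (B, C, 1, H + W))
        mid = ad.relu(ad.conv2d(cat, self._p("shared_w"), self._p("shared_b")))
        fh = ad.slice_axis(mid, 3, 0, H)
        fw = ad.slice_axis(mid, 3, H, H + W)
        gh = ad.sigmoid(ad.conv2d(fh, self._p("h_w"), self._p("h_b")))
        gw = ad.sigmoid(ad.conv2d(fw, self._p("w_w"), self._p("w_b")))
        return (ad.reshape(gh, (B, C, H)), ad.reshape(gw, (B, C, W)))

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        gh, gw = self.gates(x, mask)
        y = apply_coordinate_gates(x, gh, gw)
        if mask is not None:
            y = y * np.asarray(mask, dtype=np.float32)
        return y


class GatedConvStack:
    """Multi-order gated 1-D convolution encoder over (B, C, L).

    Each order computes conv_a(x) * sigmoid(conv_b(x)); stacking orders
    recursively widens the receptive field along the chain.
    """

    def __init__(self, channels: int, depth: int, kernel: int,
                 rng: np.random.Generator, name: str = "gconv"):
        if kernel % 2 == 0:
            raise ValueError("gated-conv kernel must be odd")
        self.depth, self.kernel = depth, kernel
        self.params = {}
        for d in range(depth):
            for branch in ("a", "b"):
                self.params[f"{name}.{d}{branch}_w"] = ad.glorot_uniform(
                    rng, (channels, channels, kernel),
                    channels * kernel, channels * kernel)
                self.params[f"{name}.{d}{branch}_b"] = ad.parameter(
                    np.zeros(channels))
        self._name = name

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        pad = self.kernel // 2
        m = np.asarray(mask, dtype=np.float32)
        for d in range(self.depth):
            a = ad.conv1d(x, self.params[f"{self._name}.{d}a_w"],
                          self.params[f"{self._name}.{d}a_b"], padding=pad)
            b = ad.conv1d(x, self.params[f"{self._name}.{d}b_w"],
                          self.params[f"{self._name}.{d}b_b"], padding=pad)
            x = a * ad.sigmoid(b) * m
        return x


class ProteinEncoder:
    """Embedding -> gated convolutions -> coordinate attention -> fusion."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        dp = config.embed_dim
        table = rng.normal(0.0, 0.1, size=(VOCAB_SIZE, dp))
        table[PAD_IDX] = 0.0
        self.params: dict = {"prot.embed": ad.parameter(table)}
        self.gated = None
        if config.gated_conv:
            self.gated = GatedConvStack(dp, config.gated_conv_depth,
                                        config.gated_conv_kernel, rng,
                                        name="prot.gconv")
            self.params.update(self.gated.params)
        self.ca = None
        if config.ablation != "noco":
            self.ca = CoordinateAttention(dp, config.ca_reduction, rng,
                                          name="prot.ca")
            self.params.update(self.ca.params)
        else:
            # position-independent linear layer of matching shape
            self.params["prot.noco_w"] = ad.glorot_uniform(
                rng, (dp, dp, 1, 1), dp, dp)
            self.params["prot.noco_b"] = ad.parameter(np.zeros(dp))
        self.fusion = None
        if config.fusion_enabled and config.ablation != "single":
            self.fusion = MultiScaleFusion(dp, config.protein_fusion_groups,
                                           rng, name="prot.fusion")
            self.params.update(self.fusion.params)

    def __call__(self, tokens: np.ndarray, mask: np.ndarray,
                 training: bool = False) -> Tensor:
        """Encode a batch of token ids (B, L) into F_P (B, L, D_p)."""
        cfg = self.config
        B, L = tokens.shape
        m = np.asarray(mask, dtype=np.float32)
        h = ad.embedding(self.params["prot.embed"], tokens) * m[..., None]
        hc = ad.transpose(h, (0, 2, 1))                  # (B, D_p, L)
        if self.gated is not None:
            hc = self.gated(hc, m[:, None, :])
        gh, gw = cfg.protein_grid
        grid = ad.reshape(hc, (B, cfg.embed_dim, gh, gw))
        gmask = m.reshape(B, 1, gh, gw)
        if self.ca is not None:
            grid = self.ca(grid, mask=gmask)
        else:
            grid = ad.conv2d(grid, self.params["prot.noco_w"],
                             self.params["prot.noco_b"]) * gmask
        if self.fusion is not None:
            grid = self.fusion(grid, mask=gmask)
        return ad.transpose(ad.reshape(grid, (B, cfg.embed_dim, L)), (0, 2, 1))
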