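"""Cross-attention fusion of drug and protein states, head, and loss.

Each modality queries the other with scaled dot-product attention
(Q = F W^q, K = F W^k, A = softmax(Q K^T / sqrt(d_k)) with padded keys
masked out), and the attention rows aggregate the other modality's value
projection: Z_D = A_D (F_P W_P^v) and symmetrically Z_P.  The fused states
are the equal-weight residual mixes D_f = 0.5 Z_D + 0.5 F_D and
P_f = 0.5 Z_P + 0.5 F_P; global max pooling over valid positions gives
fixed-length vectors whose concatenation f = [D_f^r, P_f^r] feeds an MLP
ending in the sigmoid unit p = sigma(W f + b).  Training minimises mean
binary cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

NEG_BIG = 1e9
BCE_EPS = 1e-7


@dataclass
class CrossAttentionOutput:
    z_d: Tensor        # (B, N_d, D_d) attention-aggregated protein values
    z_p: Tensor        # (B, theta_p, D_p)
    attn_d: Tensor     # (B, N_d, theta_p) rows sum to 1 over valid keys
    attn_p: Tensor     # (B, theta_p, N_d)


class CrossAttention:
    """Bidirectional scaled dot-product attention between F_D and F_P."""

    def __init__(self, d_drug: int, d_prot: int, d_k: int,
                 rng: np.random.Generator, name: str = "cross"):
        self.d_k = d_k
        self.params = {
            f"{name}.wq_d": ad.glorot_uniform(rng, (d_drug, d_k), d_drug, d_k),
            f"{name}.wk_d": ad.glorot_uniform(rng, (d_drug, d_k), d_drug, d_k),
            f"{name}.wv_d": ad.glorot_uniform(rng, (d_drug, d_prot),
                                              d_drug, d_prot),
            f"{name}.wq_p": ad.glorot_uniform(rng, (d_prot, d_k), d_prot, d_k),
            f"{name}.wk_p": ad.glorot_uniform(rng, (d_prot, d_k), d_prot, d_k),
            f"{name}.wv_p": ad.glorot_uniform(rng, (d_prot, d_drug),
                                              d_prot, d_drug),
        }
        self._name = name

    def _p(self, key):
        return self.params[f"{self._name}.{key}"]

    def __call__(self, f_d: Tensor, f_p: Tensor, drug_mask, prot_mask
                 ) -> CrossAttentionOutput:
        return cross_attend(f_d, f_p, self, drug_mask, prot_mask)


def cross_attend(f_d, f_p, params: CrossAttention, drug_mask,
                 prot_mask) -> CrossAttentionOutput:
    """Bidirectional cross-attention with padded keys masked before softmax."""
    f_d = ad.as_tensor(f_d)
    f_p = ad.as_tensor(f_p)
    if f_d.ndim == 2:
        f_d = ad.reshape(f_d, (1,) + f_d.shape)
    if f_p.ndim == 2:
        f_p = ad.reshape(f_p, (1,) + f_p.shape)
    dm = np.atleast_2d(np.asarray(drug_mask, dtype=np.float32))
    pm = np.atleast_2d(np.asarray(prot_mask, dtype=np.float32))
    if (dm.sum(axis=-1) == 0).any():
        raise ValueError("a drug in the batch has no valid atoms to attend to")
    if (pm.sum(axis=-1) == 0).any():
        raise ValueError(
            "a protein in the batch has no valid residues to attend to")
    scale = 1.0 / np.sqrt(params.d_k)

    q_d = ad.matmul(f_d, params._p("wq_d"))
    k_p = ad.matmul(f_p, params._p("wk_p"))
    logits_d = ad.matmul(q_d, ad.transpose(k_p, (0, 2, 1))) * scale
    attn_d = ad.softmax(logits_d + (pm[:, None, :] - 1.0) * NEG_BIG, axis=-1)
    z_d = ad.matmul(attn_d, ad.matmul(f_p, params._p("wv_p")))

    q_p = ad.matmul(f_p, params._p("wq_p"))
    k_d = ad.matmul(f_d, params._p("wk_d"))
    logits_p = ad.matmul(q_p, ad.transpose(k_d, (0, 2, 1))) * scale
    attn_p = ad.softmax(logits_p + (dm[:, None, :] - 1.0) * NEG_BIG, axis=-1)
    z_p = ad.matmul(attn_p, ad.matmul(f_d, params._p("wv_d")))

    return CrossAttentionOutput(z_d=z_d, z_p=z_p, attn_d=attn_d, attn_p=attn_p)


def residual_mix(z, f) -> Tensor:
    """Equal-weight residual mix 0.5 * Z + 0.5 * F."""
    z = ad.as_tensor(z)
    f = ad.as_tensor(f)
    if z.shape != f.shape:
        raise ValueError(f"shape mismatch: {z.shape} vs {f.shape}")
    return z * 0.5 + f * 0.5


def masked_max_pool(x, mask) -> Tensor:
    """Per-dimension max over valid positions (axis -2)."""
    x = ad.as_tensor(x)
    m = np.asarray(mask, dtype=np.float32)
    if (m.sum(axis=-1) == 0).any():
        raise ValueError("max pooling over zero valid rows")
    return ad.tmax(x + (m[..., None] - 1.0) * NEG_BIG, axis=-2)


def pool_and_concat(d_f, p_f, drug_mask, prot_mask) -> Tensor:
    """f = concat(maxpool(D_f), maxpool(P_f)), drug block first."""
    return ad.concat([masked_max_pool(d_f, drug_mask),
                      masked_max_pool(p_f, prot_mask)], axis=-1)


class PredictionHead:
    """MLP decoder ending in the single sigmoid output unit."""

    def __init__(self, in_dim: int, hidden: tuple, dropout: float,
                 rng: np.random.Generator, name: str = "head"):
        self.hidden = tuple(hidden)
        self.dropout = float(dropout)
        self.params = {}
        dims = [in_dim, *self.hidden, 1]
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            self.params[f"{name}.fc{i}_w"] = ad.glorot_uniform(rng, (a, b), a, b)
            self.params[f"{name}.fc{i}_b"] = ad.parameter(np.zeros(b))
        self._name = name
        self._n_layers = len(dims) - 1

    def __call__(self, f: Tensor, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        h = ad.as_tensor(f)
        for i in range(self._n_layers):
            h = ad.matmul(h, self.params[f"{self._name}.fc{i}_w"]) \
                + self.params[f"{self._name}.fc{i}_b"]
            if i < self._n_layers - 1:
                h = ad.relu(h)
                if training and self.dropout > 0:
                    h = ad.dropout(h, self.dropout, rng, training=True)
        return ad.sigmoid(ad.reshape(h, h.shape[:-1]))


def predict(f, head: PredictionHead) -> Tensor:
    """Interaction probability p = sigma(W f + b) through the head MLP."""
    f = ad.as_tensor(f)
    expected = head.params[f"{head._name}.fc0_w"].shape[0]
    if f.shape[-1] != expected:
        raise ValueError(
            f"fused feature length {f.shape[-1]} does not match head input "
            f"width {expected}")
    return head(f, training=False)


def bce_loss(labels, probabilities, eps: float = BCE_EPS) -> Tensor:
    """Mean binary cross-entropy with probabilities clipped to (eps, 1-eps)."""
    y = np.asarray(labels, dtype=np.float32)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be 0 or 1")
    p = ad.clip(ad.as_tensor(probabilities), eps, 1.0 - eps)
    ll = ad.log(p) * y + ad.log(1.0 - p) * (1.0 - y)
    return -tmean_all(ll)


def tmean_all(t: Tensor) -> Tensor:
    return ad.tmean(t, axis=None)
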