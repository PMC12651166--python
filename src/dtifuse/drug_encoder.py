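"""Drug branch: three-layer GCN over the molecular graph, then fusion.

Node features enter through the dense projection X_d = M_d W_d^T, propagate
through three graph-convolution layers
H^{(l+1)} = sigma(A~ H^{(l)} W^{(l)} + b^{(l)}) with the self-loop-augmented
(optionally symmetrically normalised) adjacency A~, are laid out row-major on
a fixed-width 2-D node grid, refined by the multi-scale fusion block, and
flattened back to per-node states F_D.  Padding rows are re-zeroed after
every layer so a molecule's representation never depends on how much padding
surrounds it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .config import ModelConfig
from .multiscale_fusion import MultiScaleFusion

_ACTIVATIONS: dict = {
    "relu": ad.relu,
    "identity": lambda t: t,
}


@dataclass
class GcnLayerParams:
    weights: Tensor          # (D_in, D_out)
    bias: Tensor             # (D_out,)
    activation: str = "relu"


def gcn_layer(states, adjacency, params: GcnLayerParams,
              mask=None) -> Tensor:
    """One graph-convolution layer sigma(A~ H W + b).

    ``states``: (B, N, D_in) or (N, D_in); ``adjacency`` conformable;
    ``mask`` re-zeroes padding rows after the update.
    """
    states = ad.as_tensor(states)
    adjacency = ad.as_tensor(adjacency)
    if states.shape[-1] != params.weights.shape[0]:
        raise ValueError(
            f"state width {states.shape[-1]} does not match layer input "
            f"width {params.weights.shape[0]}")
    if adjacency.shape[-1] != states.shape[-2]:
        raise ValueError(
            f"adjacency {adjacency.shape} does not match states "
            f"{states.shape}")
    act = _ACTIVATIONS[params.activation] if isinstance(params.activation, str) \
        else params.activation
    out = act(ad.matmul(ad.matmul(adjacency, states), params.weights)
              + params.bias)
    if mask is not None:
        m = np.asarray(mask, dtype=np.float32)[..., None]
        out = out * m
    return out


class DrugEncoder:
    """Projection + 3-layer GCN + grid reshape + multi-scale fusion."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        d = config.d_model
        self.params: dict = {
            "drug.proj_w": ad.glorot_uniform(rng, (d, config.atom_feat_dim),
                                             config.atom_feat_dim, d),
        }
        self.layers: list[GcnLayerParams] = []
        for l in range(config.gcn_layers):
            w = ad.glorot_uniform(rng, (d, d), d, d)
            b = ad.parameter(np.zeros(d))
            self.params[f"drug.gcn{l}_w"] = w
            self.params[f"drug.gcn{l}_b"] = b
            self.layers.append(GcnLayerParams(weights=w, bias=b))
        self.fusion = None
        if config.fusion_enabled and config.ablation != "single":
            self.fusion = MultiScaleFusion(d, config.drug_fusion_groups, rng,
                                           name="drug.fusion")
            self.params.update(self.fusion.params)

    def __call__(self, node_features, adjacency, mask,
                 training: bool = False) -> Tensor:
        """Encode a batch: (B, N, 74) features -> (B, N, D) states F_D."""
        cfg = self.config
        B, N, _ = np.asarray(node_features, dtype=np.float32).shape
        m = np.asarray(mask, dtype=np.float32)
        # Eq.-1 projection; padding rows stay zero (no bias)
        h = ad.matmul(ad.as_tensor(node_features),
                      ad.transpose(self.params["drug.proj_w"], (1, 0)))
        for layer in self.layers:
            h = gcn_layer(h, adjacency, layer, mask=m)
        if self.fusion is not None:
            gh, gw = cfg.drug_grid
            grid = ad.reshape(ad.transpose(h, (0, 2, 1)),
                              (B, cfg.d_model, gh, gw))
            gmask = m.reshape(B, 1, gh, gw)
            grid = self.fusion(grid, mask=gmask)
            h = ad.transpose(ad.reshape(grid, (B, cfg.d_model, N)), (0, 2, 1))
        return h
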