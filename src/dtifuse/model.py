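"""End-to-end interaction model: encoders, cross-attention fusion, head.

Wires the drug branch (74-dim atom features -> projection -> three GCN
layers -> grid -> multi-scale fusion) and the protein branch (embedding ->
gated convolutions -> coordinate attention -> multi-scale fusion) into the
cross-attention interaction stage and the MLP head.  The ablation mode in
the config rewires the graph: ``noco`` swaps coordinate attention for a
linear layer, ``single`` drops both fusion blocks, ``nocross`` bypasses
cross-attention and classifies the concatenated pooled branch features.
"""

from __future__ import annotations

import io
import json
import logging

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .config import ModelConfig
from .drug_encoder import DrugEncoder
from .interaction_fusion import (CrossAttention, PredictionHead, bce_loss,
                                 pool_and_concat, residual_mix)
from .mol_featurizer import GraphCache, normalize_adjacency
from .protein_encoder import ProteinEncoder, encode_tokens

logger = logging.getLogger("dtifuse")

CHECKPOINT_VERSION = 1


def featurize_batch(config: ModelConfig, smiles_list, sequences,
                    graph_cache: GraphCache | None = None) -> dict:
    """Build the dense numpy batch the model consumes.

    Returns atom features (B, N_d, 74), adjacency (B, N_d, N_d) in the
    configured variant, drug mask (B, N_d), token ids (B, theta_p) and
    protein mask (B, theta_p).
    """
    cache = graph_cache or GraphCache(config.n_atoms_max)
    n, L = config.n_atoms_max, config.seq_len_max
    B = len(smiles_list)
    feats = np.zeros((B, n, 74), dtype=np.float32)
    adj = np.zeros((B, n, n), dtype=np.float32)
    dmask = np.zeros((B, n), dtype=np.float32)
    tokens = np.zeros((B, L), dtype=np.int64)
    pmask = np.zeros((B, L), dtype=np.float32)
    for i, (smi, seq) in enumerate(zip(smiles_list, sequences)):
        g = cache.get(smi)
        feats[i] = g.node_features
        a = g.adjacency
        adj[i] = normalize_adjacency(a) if config.normalize_adjacency else a
        dmask[i] = g.node_mask
        tokens[i], pmask[i] = encode_tokens(seq, L)
    return {"atom_feats": feats, "adjacency": adj, "drug_mask": dmask,
            "tokens": tokens, "prot_mask": pmask}


class DTIModel:
    """The assembled drug-target interaction classifier."""

    def __init__(self, config: ModelConfig,
                 rng: np.random.Generator | None = None):
        self.config = config
        rng = rng or np.random.default_rng(config.seed)
        self.drug = DrugEncoder(config, rng)
        self.protein = ProteinEncoder(config, rng)
        self.cross = None
        if config.ablation != "nocross":
            self.cross = CrossAttention(config.d_model, config.embed_dim,
                                        config.d_k, rng)
        self.head = PredictionHead(config.d_model + config.embed_dim,
                                   config.head_hidden, config.head_dropout,
                                   rng)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0xD0]))
        self.cross_attend_calls = 0

    # -- parameters ----------------------------------------------------
    def parameters(self) -> dict:
        params = {}
        params.update(self.drug.params)
        params.update(self.protein.params)
        if self.cross is not None:
            params.update(self.cross.params)
        params.update(self.head.params)
        return params

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.parameters().values()))

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state(self, state: dict):
        params = self.parameters()
        if set(state) != set(params):
            missing = set(params) - set(state)
            extra = set(state) - set(params)
            raise ValueError(
                f"checkpoint/model parameter mismatch: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}")
        for k, v in state.items():
            params[k].data = np.asarray(v, dtype=params[k].data.dtype)

    # -- forward -------------------------------------------------------
    def forward(self, batch: dict, training: bool = False,
                capture: bool = False) -> dict:
        f_d = self.drug(batch["atom_feats"], batch["adjacency"],
                        batch["drug_mask"], training=training)
        f_p = self.protein(batch["tokens"], batch["prot_mask"],
                           training=training)
        out: dict = {}
        if self.cross is not None:
            self.cross_attend_calls += 1
            ca = self.cross(f_d, f_p, batch["drug_mask"], batch["prot_mask"])
            d_f = residual_mix(ca.z_d, f_d)
            p_f = residual_mix(ca.z_p, f_p)
            if capture:
                out.update({"z_d": ca.z_d, "z_p": ca.z_p,
                            "attn_d": ca.attn_d, "attn_p": ca.attn_p})
        else:
            d_f, p_f = f_d, f_p
        f = pool_and_concat(d_f, p_f, batch["drug_mask"], batch["prot_mask"])
        p = self.head(f, training=training, rng=self._dropout_rng)
        out["p"] = p
        if capture:
            out.update({"f_d": f_d, "f_p": f_p, "d_f": d_f, "p_f": p_f,
                        "f": f})
        return out

    def loss(self, batch: dict, labels, training: bool = True) -> Tensor:
        out = self.forward(batch, training=training)
        return bce_loss(labels, out["p"])

    # -- convenience ---------------------------------------------------
    def predict_pairs(self, smiles_list, sequences, batch_size: int = 64,
                      graph_cache: GraphCache | None = None) -> np.ndarray:
        """Interaction probabilities for aligned SMILES/sequence lists."""
        cache = graph_cache or GraphCache(self.config.n_atoms_max)
        probs = []
        for lo in range(0, len(smiles_list), batch_size):
            batch = featurize_batch(self.config,
                                    smiles_list[lo:lo + batch_size],
                                    sequences[lo:lo + batch_size], cache)
            probs.append(self.forward(batch)["p"].data)
        return np.concatenate(probs) if probs else np.zeros(0)

    # -- persistence ---------------------------------------------------
    def save(self, path):
        meta = {"version": CHECKPOINT_VERSION, "config": self.config.to_dict()}
        arrays = {f"param/{k}": v for k, v in self.state_dict().items()}
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path) -> "DTIModel":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["meta_json"].tobytes()).decode())
            state = {k[len("param/"):]: npz[k] for k in npz.files
                     if k.startswith("param/")}
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"unsupported checkpoint version {meta.get('version')}")
        model = cls(ModelConfig.from_dict(meta["config"]))
        model.load_state(state)
        return model
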