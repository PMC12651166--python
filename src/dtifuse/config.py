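"""Model and training configuration.

Every architecture and optimisation hyperparameter the method leaves open is
collected in :class:`ModelConfig`, round-trippable through YAML so a single
config file fully determines a run.  ``desk_config`` returns the reduced-width
configuration used for fast CPU-only experiments and by the test suite; the
sizes are documented in ``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

logger = logging.getLogger("dtifuse")

ABLATION_MODES = ("full", "noco", "single", "nocross")


class ConfigError(ValueError):
    """Raised for inconsistent model configuration."""


@dataclass
class ModelConfig:
    # -- drug branch ---------------------------------------------------
    n_atoms_max: int = 290          # N_d: padded atom count per molecule
    drug_grid_width: int = 10       # W of the node grid; H = n_atoms_max / W
    atom_feat_dim: int = 74         # fixed by the featurizer
    d_model: int = 128              # drug channel width after Eq.-1 projection
    gcn_layers: int = 3
    normalize_adjacency: bool = True
    drug_fusion_groups: int = 4

    # -- protein branch ------------------------------------------------
    seq_len_max: int = 1024         # theta_p: padded residue count
    protein_grid_width: int = 32    # W of the residue grid; H = seq_len_max / W
    embed_dim: int = 128            # D_p
    vocab_size: int = 22            # 20 residues + unknown + pad
    gated_conv: bool = True         # multi-order gated 1-D convolution encoder
    gated_conv_depth: int = 2
    gated_conv_kernel: int = 3
    ca_reduction: int = 8           # coordinate-attention bottleneck ratio r
    protein_fusion_groups: int = 8

    # -- fusion / interaction -------------------------------------------
    fusion_enabled: bool = True     # multi-scale fusion on both branches
    d_k: int = 128                  # query/key width of cross-attention
    head_hidden: tuple = (512, 256)
    head_dropout: float = 0.1

    # -- training -------------------------------------------------------
    ablation: str = "full"
    seed: int = 0
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 10              # early stopping on validation AUROC
    threshold: float = 0.5          # decision threshold for Acc/F1/MCC
    split_fractions: tuple = (0.8, 0.1, 0.1)
    unseen_pair_fraction: float = 0.0   # optional generalization hold-out

    def __post_init__(self):
        self.head_hidden = tuple(self.head_hidden)
        self.split_fractions = tuple(self.split_fractions)
        self.validate()

    # -- derived shapes -------------------------------------------------
    @property
    def drug_grid(self) -> tuple:
        return (self.n_atoms_max // self.drug_grid_width, self.drug_grid_width)

    @property
    def protein_grid(self) -> tuple:
        return (self.seq_len_max // self.protein_grid_width,
                self.protein_grid_width)

    def validate(self):
        if self.ablation not in ABLATION_MODES:
            raise ConfigError(
                f"unknown ablation mode {self.ablation!r}; "
                f"expected one of {ABLATION_MODES}")
        if self.n_atoms_max % self.drug_grid_width:
            raise ConfigError(
                f"n_atoms_max={self.n_atoms_max} is not divisible by "
                f"drug_grid_width={self.drug_grid_width}: the node grid "
                "H x W must satisfy H*W == n_atoms_max")
        if self.seq_len_max % self.protein_grid_width:
            raise ConfigError(
                f"seq_len_max={self.seq_len_max} is not divisible by "
                f"protein_grid_width={self.protein_grid_width}: the residue "
                "grid H x W must satisfy H*W == seq_len_max")
        if self.gcn_layers != 3:
            raise ConfigError(
                "the drug encoder applies exactly three graph-convolution "
                f"layers; got gcn_layers={self.gcn_layers}")
        if self.d_model % self.drug_fusion_groups:
            raise ConfigError("d_model must be divisible by drug_fusion_groups")
        if self.embed_dim % self.protein_fusion_groups:
            raise ConfigError(
                "embed_dim must be divisible by protein_fusion_groups")
        if self.vocab_size != 22:
            raise ConfigError("the residue vocabulary is fixed at 22 symbols")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ConfigError("split_fractions must sum to 1")
        if not 0.0 <= self.head_dropout < 1.0:
            raise ConfigError("head_dropout must be in [0, 1)")

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["head_hidden"] = list(self.head_hidden)
        d["split_fractions"] = list(self.split_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)


def desk_config(**overrides) -> ModelConfig:
    """Reduced-width configuration for CPU-scale runs and tests.

    Keeps every architectural element of the full model (three GCN layers,
    gated convolution encoder, coordinate attention, multi-scale fusion,
    cross-attention) at narrower widths and shorter pads so an end-to-end
    training run on synthetic data completes in minutes on one core.
    """
    base = dict(
        n_atoms_max=48, drug_grid_width=8,
        d_model=32, drug_fusion_groups=4,
        seq_len_max=64, protein_grid_width=8,
        embed_dim=32, protein_fusion_groups=4,
        ca_reduction=4, d_k=32,
        head_hidden=(64, 32),
        learning_rate=1e-3,
    )
    base.update(overrides)
    return ModelConfig(**base)
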