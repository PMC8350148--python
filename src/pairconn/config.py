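"""Configuration dataclasses for the model, training loop and simulator.

Defaults follow the reference settings of the pairwise-attention
connectivity network: embedding dimension d=32, attention value
beta=0.9, loss trade-off lambda=0.6, Adam(beta1=0.5, beta2=0.999) at
learning rate 1e-4 divided by 10 every 30 epochs, 100 epochs, batch 20,
five random 80/20 train/test splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

#: full-scale extractor: six conv layers (kernel 3, pad 1, ReLU), max-pool
#: k=2 s=2 after every layer except the 3rd and 5th, then linear -> d
FULL_FILTERS = (64, 128, 256, 256, 512, 512)
POOL_AFTER = (True, True, False, True, False, True)

#: reduced-width preset for desk-scale synthetic experiments
DESK_FILTERS = (8, 16, 16, 32, 32, 32)


@dataclass
class ModelConfig:
    n_regions: int
    n_timepoints: int
    embed_dim: int = 32
    head_size: int = 3                       # l: 3 diagnosis, 20 symptoms, 1 survival
    beta: float = 0.9
    lam: float = 0.6
    conv_filters: tuple = FULL_FILTERS
    similarity_hidden: tuple = (64, 16)      # widths of F's two hidden layers
    classifier_hidden: tuple = (100, 32)     # first width fixed at 100 by design
    dropout: float = 0.5
    regression_mode: bool = False            # CAPS severity MSE variant
    precision: str = "float64"               # "float32" halves memory traffic
    # ablations
    identity_E: bool = False
    pearson_F: bool = False
    no_reweighting: bool = False

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0,1], got {self.beta}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must be in [0,1], got {self.lam}")
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if self.head_size < 1:
            raise ValueError("head_size must be >= 1")
        if len(self.conv_filters) != 6:
            raise ValueError("extractor requires exactly six conv layers")
        if self.precision not in ("float32", "float64"):
            raise ValueError("precision must be 'float32' or 'float64'")
        if self.min_timepoints() > self.n_timepoints:
            raise ValueError(
                f"T={self.n_timepoints} too short: extractor needs at least "
                f"{self.min_timepoints()} timepoints"
            )

    @staticmethod
    def min_timepoints() -> int:
        # four halvings must leave length >= 1
        return 16

    def conv_output_len(self) -> int:
        t = self.n_timepoints
        for pool in POOL_AFTER:
            if pool:
                t //= 2
        return t

    def effective_embed_dim(self) -> int:
        """d seen by F: raw series length under the identity-E ablation."""
        return self.n_timepoints if self.identity_E else self.embed_dim


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 20
    learning_rate: float = 1e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    lr_decay_every: int = 30                 # divide lr by 10 at these epoch marks
    lr_decay_factor: float = 10.0
    n_splits: int = 5
    train_fraction: float = 0.8
    seed: int = 0
    eval_every: int = 0                      # 0: validation metrics only at the end
    weight_decay: float = 0.0                # decoupled (AdamW-style), weights only
    pretrain_epochs: int = 0                 # similarity warm-start epochs
    pretrain_lr: float = 1e-3

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0,1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def lr_at_epoch(self, epoch: int) -> float:
        """Step decay: lr / factor^(epoch // every), epochs counted from 0."""
        steps = epoch // self.lr_decay_every if self.lr_decay_every else 0
        return self.learning_rate / (self.lr_decay_factor ** steps)


def config_to_dict(cfg) -> dict:
    d = asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
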