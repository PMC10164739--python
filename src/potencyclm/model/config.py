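"""Model hyperparameter configuration.

Defaults follow the pipeline's reference training regime: encoding dimension
256, batch size 64, learning rate 1e-4, 200 epochs, with 3 encoder and 3
decoder layers, 8 attention heads, a feed-forward width of 4× the encoding
dimension, dropout 0.1 and sinusoidal positional encoding. Scaled-down
configurations (``ModelConfig.tiny()``) are used for CPU-sized experiments
and the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace


@dataclass(frozen=True)
class ModelConfig:
    encoding_dim: int = 256
    batch_size: int = 64
    learning_rate: float = 1e-4
    epochs: int = 200
    n_encoder_layers: int = 3
    n_decoder_layers: int = 3
    n_heads: int = 8
    ff_dim: int = 1024
    dropout: float = 0.1
    max_len: int = 160
    val_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.encoding_dim % self.n_heads:
            raise ValueError("encoding_dim must be divisible by n_heads")
        for name in ("encoding_dim", "batch_size", "n_encoder_layers",
                     "n_decoder_layers", "n_heads", "ff_dim", "max_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epochs < 0:  # zero epochs = identity training, used by finetune
            raise ValueError("epochs must be non-negative")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """A CPU-sized configuration: 2+2 layers, dimension 64, 4 heads.

        The higher learning rate (1e-3) is the usual choice for such small
        transformers and keeps training runs short.
        """
        base = dict(
            encoding_dim=64, batch_size=32, learning_rate=1e-3, epochs=30,
            n_encoder_layers=2, n_decoder_layers=2, n_heads=4, ff_dim=256,
            dropout=0.0, max_len=96, val_fraction=0.05,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    def with_(self, **overrides) -> "ModelConfig":
        return replace(self, **overrides)
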