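"""Configuration dataclasses with defaults matching the published settings.

Defaults: 4 attention heads per channel, 512-dim embeddings, FFN hidden 2048,
shortest-path clip 8, dropout 0.5, Adam learning rate 1e-4. Desk-scale runs
override the widths/epochs downward.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["GATConfig", "TransformerConfig", "SynthConfig", "TrainConfig", "RunConfig"]


class ConfigError(ValueError):
    """A configuration value violates its contract."""


@dataclass
class GATConfig:
    heads: int = 4
    layers: int = 2
    embed_dim: int = 512
    gcn_layers: int = 1
    dropout: float = 0.5
    negative_slope: float = 0.2
    vanilla: bool = False  # skip GCN pre-encoding and jumping knowledge

    def validate(self) -> None:
        if self.heads < 1:
            raise ConfigError("gat.heads must be >= 1")
        if self.embed_dim % self.heads != 0:
            raise ConfigError("gat.embed_dim must be divisible by gat.heads")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError("gat.dropout must be in [0, 1)")
        if self.layers < 1:
            raise ConfigError("gat.layers must be >= 1")


@dataclass
class TransformerConfig:
    heads: int = 4
    layers: int = 2
    model_dim: int = 512
    ffn_hidden: int = 2048
    dropout: float = 0.5
    spd_clip: int = 8
    degree_max_bucket: int = 64
    use_graph_attrs: bool = True  # False => no degree / SPD encodings
    per_head_bias: bool = False
    strict_no_residual: bool = False
    spd_bias_init: float = -0.5  # initial bias slope per SPD bucket (learned)

    def validate(self) -> None:
        if self.heads < 1:
            raise ConfigError("trf.heads must be >= 1")
        if self.model_dim % self.heads != 0:
            raise ConfigError("trf.model_dim must be divisible by trf.heads")
        if self.ffn_hidden < self.model_dim:
            raise ConfigError("trf.ffn_hidden must be >= trf.model_dim")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError("trf.dropout must be in [0, 1)")


@dataclass
class SynthConfig:
    n_mirna: int = 120
    n_disease: int = 80
    n_blocks: int = 4
    p_within: float = 0.3
    p_background: float = 0.02
    dag_branching: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.p_background < self.p_within <= 1.0):
            raise ConfigError("need 0 <= p_background < p_within <= 1")
        if self.n_blocks < 1 or min(self.n_mirna, self.n_disease) < self.n_blocks:
            raise ConfigError("counts must be >= n_blocks >= 1")


@dataclass
class TrainConfig:
    lr: float = 1e-4
    epochs: int = 300
    patience: int = 30
    seed: int = 0
    threshold: float = 0.5
    sim_threshold: float = 0.0  # similarity-adjacency cutoff
    fusion: str = "max"  # max | lin | dot | mean | add
    scorer: str = "mlp"  # mlp (concat MLP) | dot (weighted inner product)
    channels: tuple[str, ...] = ("gat", "trf")

    def validate(self) -> None:
        if not self.channels:
            raise ConfigError("at least one channel must be enabled")
        bad = set(self.channels) - {"gat", "trf"}
        if bad:
            raise ConfigError(f"unknown channels: {sorted(bad)}")
        if self.fusion not in {"max", "lin", "dot", "mean", "add"}:
            raise ConfigError(f"unknown fusion mode {self.fusion!r}")
        if self.scorer not in {"mlp", "dot"}:
            raise ConfigError(f"unknown scorer {self.scorer!r}")
        if self.lr <= 0 or self.epochs < 1:
            raise ConfigError("lr must be > 0 and epochs >= 1")


@dataclass
class RunConfig:
    gat: GATConfig = field(default_factory=GATConfig)
    trf: TransformerConfig = field(default_factory=TransformerConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def validate(self) -> "RunConfig":
        errors = []
        for sub in (self.gat, self.trf, self.synth, self.train):
            try:
                sub.validate()
            except ConfigError as e:
                errors.append(str(e))
        if errors:
            raise ConfigError("; ".join(errors))
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["train"]["channels"] = list(self.train.channels)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def build(klass, payload):
            allowed = {f.name for f in fields(klass)}
            unknown = set(payload) - allowed
            if unknown:
                raise ConfigError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            return klass(**payload)

        cfg = cls(
            gat=build(GATConfig, data.get("gat", {})),
            trf=build(TransformerConfig, data.get("trf", {})),
            synth=build(SynthConfig, data.get("synth", {})),
            train=build(TrainConfig, data.get("train", {})),
        )
        extra = set(data) - {"gat", "trf", "synth", "train"}
        if extra:
            raise ConfigError(f"unknown config sections: {sorted(extra)}")
        cfg.train.channels = tuple(cfg.train.channels)
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
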