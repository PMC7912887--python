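"""The six-layer hybrid architecture and its serialization.

Layer order: embedding -> 1D convolution (ReLU) -> max pooling ->
bidirectional LSTM -> dense (ReLU) -> dense (sigmoid), with dropout after
the convolution, after the pooling, after the BiLSTM and between the two
dense layers.  The same assembly routine also builds the ablation variants
(see :mod:`mirtarnet.ablation`), so that a variant differs from the full
model only by the removed components.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codec import ALPHABET, PairSchema
from .nn import BiLSTM, Conv1D, Dense, Dropout, Embedding, Flatten, MaxPool1D, Network

#: Valid component names for ablation removal sets.
REMOVABLE = frozenset({"max_pool", "cnn_and_pool", "rnn", "dense_hidden", "dropouts"})


class InvalidSpecError(ValueError):
    pass


@dataclass(frozen=True)
class EmbeddingSpec:
    vocab_size: int = len(ALPHABET)
    embed_dim: int = 5
    trainable: bool = True


@dataclass(frozen=True)
class ConvLayerSpec:
    n_kernels: int = 320
    kernel_size: int = 12


@dataclass(frozen=True)
class PoolSpec:
    pool_size: int = 2
    stride: int = 2


@dataclass(frozen=True)
class RecurrentLayerSpec:
    hidden_units: int = 32
    bidirectional: bool = True
    activation: str = "relu"  # 'tanh' available as fallback


@dataclass(frozen=True)
class ModelSpec:
    input_len: int = 79
    embedding: EmbeddingSpec = field(default_factory=EmbeddingSpec)
    conv: ConvLayerSpec = field(default_factory=ConvLayerSpec)
    pool: PoolSpec = field(default_factory=PoolSpec)
    rnn: RecurrentLayerSpec = field(default_factory=RecurrentLayerSpec)
    dense_hidden_units: int = 16
    output_units: int = 1
    dropout_rate: float = 0.2

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise InvalidSpecError(f"dropout_rate {self.dropout_rate} out of range")
        if self.output_units != 1:
            raise InvalidSpecError("binary classifier requires output_units == 1")

    @classmethod
    def for_schema(cls, schema: PairSchema, **kwargs) -> "ModelSpec":
        return cls(input_len=schema.total_len, **kwargs)

    def conv_out_len(self) -> int:
        return self.input_len - self.conv.kernel_size + 1

    def pooled_len(self) -> int:
        return (self.conv_out_len() - self.pool.pool_size) // self.pool.stride + 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            input_len=d["input_len"],
            embedding=EmbeddingSpec(**d["embedding"]),
            conv=ConvLayerSpec(**d["conv"]),
            pool=PoolSpec(**d["pool"]),
            rnn=RecurrentLayerSpec(**d["rnn"]),
            dense_hidden_units=d["dense_hidden_units"],
            output_units=d["output_units"],
            dropout_rate=d["dropout_rate"],
        )

    @classmethod
    def from_config(cls, config: dict) -> "ModelSpec":
        """Lenient constructor: config keys mirror the spec fields, missing
        keys keep their defaults (for YAML/JSON config files)."""
        base = dataclasses.asdict(cls())
        for key, value in config.items():
            if key not in base:
                raise InvalidSpecError(f"unknown model-config key {key!r}")
            if isinstance(base[key], dict):
                bad = set(value) - set(base[key])
                if bad:
                    raise InvalidSpecError(f"unknown keys in {key}: {sorted(bad)}")
                base[key].update(value)
            else:
                base[key] = value
        return cls.from_dict(base)


def _validate(spec: ModelSpec, removed: frozenset[str]) -> None:
    bad = removed - REMOVABLE
    if bad:
        raise InvalidSpecError(f"unknown removable components: {sorted(bad)}")
    if "max_pool" in removed and "cnn_and_pool" in removed:
        raise InvalidSpecError("max_pool removal is implied by cnn_and_pool")
    if "cnn_and_pool" not in removed:
        if spec.conv_out_len() < 1:
            raise InvalidSpecError(
                f"kernel size {spec.conv.kernel_size} exceeds input {spec.input_len}"
            )
        if "max_pool" not in removed and spec.pooled_len() < 1:
            raise InvalidSpecError(
                f"pool size {spec.pool.pool_size} exceeds conv output "
                f"{spec.conv_out_len()}"
            )
    if "rnn" in removed and not removed >= {"cnn_and_pool"} and spec.conv.n_kernels < 1:
        raise InvalidSpecError("conv must keep at least one kernel")


def build_model(
    spec: ModelSpec,
    rng: np.random.Generator | int | None = None,
    removed: frozenset[str] | set[str] = frozenset(),
) -> Network:
    """Instantiate the network (optionally minus the ``removed`` components)."""
    removed = frozenset(removed)
    _validate(spec, removed)
    rng = np.random.default_rng(rng)
    use_dropout = "dropouts" not in removed
    p = spec.dropout_rate

    layers: list = [Embedding(spec.embedding.vocab_size, spec.embedding.embed_dim, rng)]
    seq_len = spec.input_len
    channels = spec.embedding.embed_dim

    if "cnn_and_pool" not in removed:
        layers.append(Conv1D(channels, spec.conv.n_kernels, spec.conv.kernel_size, rng))
        seq_len = seq_len - spec.conv.kernel_size + 1
        channels = spec.conv.n_kernels
        if use_dropout:
            layers.append(Dropout(p))
        if "max_pool" not in removed:
            pool = MaxPool1D(spec.pool.pool_size, spec.pool.stride)
            layers.append(pool)
            seq_len = pool.n_out(seq_len)
            if use_dropout:
                layers.append(Dropout(p))

    if "rnn" not in removed:
        layers.append(BiLSTM(channels, spec.rnn.hidden_units, rng,
                             activation=spec.rnn.activation))
        width = 2 * spec.rnn.hidden_units
        if use_dropout:
            layers.append(Dropout(p))
    else:
        layers.append(Flatten())
        width = seq_len * channels

    if "dense_hidden" not in removed:
        layers.append(Dense(width, spec.dense_hidden_units, rng, activation="relu"))
        width = spec.dense_hidden_units
        if use_dropout:
            layers.append(Dropout(p))

    layers.append(Dense(width, spec.output_units, rng, activation="sigmoid"))
    return Network(layers)


# ------------------------------------------------------------- serialization

def save_model(
    net: Network, spec: ModelSpec, path: str | Path,
    removed: frozenset[str] | set[str] = frozenset(),
    schema: PairSchema | None = None,
) -> None:
    """Write weights + spec (+ codec schema) to a single ``.npz`` artifact."""
    meta = {
        "format_version": 1,
        "spec": spec.to_dict(),
        "removed": sorted(removed),
        "schema": (
            {"mirna_slot_len": schema.mirna_slot_len,
             "site_slot_len": schema.site_slot_len}
            if schema is not None else None
        ),
    }
    arrays = {f"w:{k}": v for k, v in net.get_weights().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path):
    """Load an artifact; returns ``(network, spec, removed, schema_or_None)``."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        weights = {k[2:]: data[k] for k in data.files if k.startswith("w:")}
    spec = ModelSpec.from_dict(meta["spec"])
    removed = frozenset(meta["removed"])
    net = build_model(spec, rng=0, removed=removed)
    net.set_weights(weights)
    schema = None
    if meta["schema"] is not None:
        schema = PairSchema(**meta["schema"])
    return net, spec, removed, schema


def forward(net: Network, batch: np.ndarray, input_len: int | None = None) -> np.ndarray:
    """Inference probabilities for a batch of encoded pairs."""
    batch = np.asarray(batch)
    if batch.ndim == 1:
        batch = batch[None, :]
    if input_len is not None and batch.shape[1] != input_len:
        raise ValueError(
            f"input length mismatch: model expects {input_len}, got {batch.shape[1]}"
        )
    return net.predict(batch)
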