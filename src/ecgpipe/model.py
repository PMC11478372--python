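"""The CNN-LSTM-SE beat classifier.

The network takes one standardized 360-sample beat and emits a probability
vector over the five classes. Three strided/pooled convolution blocks
extract morphological features, a squeeze-and-excitation (SE) block
reweights the 32 feature channels, an LSTM of width 100 summarizes the
remaining 10-step sequence, and three dense layers (20 -> 10 -> 5,
softmax) classify. The default configuration reproduces this dimension
chain on the sequence axis::

    360 --conv(k20,s3)--> 120 --pool(2,s3)--> 40 --conv(k7,s1)--> 40
        --pool(2,s2)--> 20 --conv(k10,s1)+SE--> 20 --pool(2,s2)--> 10
        --LSTM--> 100 --dense--> 20 --> 10 --> 5

Convolutions use 'same' padding and pooling uses 'valid' padding — the
only combination consistent with that chain. A standalone per-step LSTM
cell (:func:`lstm_reference_step`) written directly from the gate
equations serves as an independent oracle for the batched BPTT layer in
:mod:`ecgpipe.nn`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .nn import conv_output_length, sigmoid, swish  # re-exported

N_CLASSES = 5
INPUT_LENGTH = 360


@dataclass(frozen=True)
class ConvLayerSpec:
    """One convolution block: conv (+ optional batch norm) + ReLU."""

    filters: int
    kernel: int
    stride: int = 1
    padding: str = "same"
    activation: str = "relu"
    batch_norm: bool = True

    def __post_init__(self) -> None:
        if min(self.filters, self.kernel, self.stride) < 1:
            raise ValueError("filters, kernel and stride must be >= 1")


@dataclass(frozen=True)
class PoolSpec:
    pool: int
    stride: int


@dataclass(frozen=True)
class SEBlockSpec:
    """Squeeze-and-excitation block: ``channels`` gated through a
    ``channels // reduction`` bottleneck (Swish), restored and squashed
    to (0, 1) by a sigmoid."""

    channels: int
    reduction: int = 8

    def __post_init__(self) -> None:
        if self.channels < 1 or self.reduction < 1:
            raise ValueError("channels and reduction must be >= 1")

    @property
    def bottleneck(self) -> int:
        return max(self.channels // self.reduction, 1)


@dataclass
class LSTMCellWeights:
    """Per-gate weights acting on the concatenated ``[h, x]`` vector.

    Each matrix has shape ``(hidden, hidden + input)``; biases have shape
    ``(hidden,)``.
    """

    Wi: np.ndarray
    Wf: np.ndarray
    Wo: np.ndarray
    Wc: np.ndarray
    bi: np.ndarray
    bf: np.ndarray
    bo: np.ndarray
    bc: np.ndarray

    def __post_init__(self) -> None:
        h = self.Wi.shape[0]
        for name in ("Wi", "Wf", "Wo", "Wc"):
            if getattr(self, name).shape != self.Wi.shape:
                raise ValueError(f"{name} shape differs from Wi")
        for name in ("bi", "bf", "bo", "bc"):
            if getattr(self, name).shape != (h,):
                raise ValueError(f"{name} must have shape ({h},)")

    @property
    def hidden(self) -> int:
        return self.Wi.shape[0]

    @property
    def input_size(self) -> int:
        return self.Wi.shape[1] - self.hidden

    @classmethod
    def from_fused(cls, W: np.ndarray, U: np.ndarray, b: np.ndarray) -> "LSTMCellWeights":
        """Convert the production layer's fused (i, f, c, o) weights."""
        h = U.shape[0]
        Wi_, Wf_, Wc_, Wo_ = (W[:, k * h : (k + 1) * h] for k in range(4))
        Ui_, Uf_, Uc_, Uo_ = (U[:, k * h : (k + 1) * h] for k in range(4))
        bi_, bf_, bc_, bo_ = (b[k * h : (k + 1) * h] for k in range(4))
        cat = lambda u, w: np.concatenate([u.T, w.T], axis=1)
        return cls(Wi=cat(Ui_, Wi_), Wf=cat(Uf_, Wf_), Wo=cat(Uo_, Wo_),
                   Wc=cat(Uc_, Wc_), bi=bi_, bf=bf_, bo=bo_, bc=bc_)


def lstm_reference_step(
    x_t: np.ndarray,
    state: tuple[np.ndarray, np.ndarray],
    weights: LSTMCellWeights,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM step written directly from the gate equations.

    With ``v = [h_{t-1}, x_t]``::

        c~_t = tanh(Wc v + bc)         candidate memory
        i_t  = sigma(Wi v + bi)        input gate
        f_t  = sigma(Wf v + bf)        forget gate
        C_t  = f_t * C_{t-1} + i_t * c~_t
        o_t  = sigma(Wo v + bo)        output gate
        h_t  = o_t * tanh(C_t)

    Returns ``(h_t, C_t)``. Used as the conformance oracle for the
    batched production layer.
    """
    h_prev, c_prev = state
    v = np.concatenate([np.atleast_1d(h_prev), np.atleast_1d(x_t)])
    if v.shape[0] != weights.Wi.shape[1]:
        raise ValueError(
            f"[h, x] length {v.shape[0]} does not match weight width "
            f"{weights.Wi.shape[1]}")
    c_tilde = np.tanh(weights.Wc @ v + weights.bc)
    i_gate = sigmoid(weights.Wi @ v + weights.bi)
    f_gate = sigmoid(weights.Wf @ v + weights.bf)
    c_t = f_gate * np.atleast_1d(c_prev) + i_gate * c_tilde
    o_gate = sigmoid(weights.Wo @ v + weights.bo)
    h_t = o_gate * np.tanh(c_t)
    return h_t, c_t


def se_block_forward(
    feature_map: np.ndarray,
    spec: SEBlockSpec,
    weights: dict[str, np.ndarray],
) -> np.ndarray:
    """Functional squeeze/excitation/scale on a ``(time, channels)`` map.

    ``weights`` holds ``W1 (c, c/r)``, ``b1``, ``W2 (c/r, c)``, ``b2``.
    Squeeze averages each channel over time; excitation runs the
    bottleneck (Swish) and restore (sigmoid) transforms; scale multiplies
    each channel by its weight. Output shape equals input shape.
    """
    fmap = np.asarray(feature_map, dtype=np.float64)
    if fmap.ndim != 2 or fmap.shape[1] != spec.channels:
        raise ValueError(
            f"expected a (time, {spec.channels}) feature map, got {fmap.shape}")
    if weights["W1"].shape != (spec.channels, spec.bottleneck) or \
       weights["W2"].shape != (spec.bottleneck, spec.channels):
        raise ValueError("excitation weight shapes do not match the spec")
    z = fmap.mean(axis=0)
    s = sigmoid(swish(z @ weights["W1"] + weights["b1"]) @ weights["W2"] + weights["b2"])
    return fmap * s


@dataclass(frozen=True)
class ArchitectureConfig:
    """Complete layer specification of the classifier.

    The defaults are the published operating point; every knob is
    overridable. ``se_reduction`` (the published table does not state it)
    defaults to 8, i.e. a bottleneck of 4 for 32 channels, and the dense
    L2 coefficient defaults to 1e-3.
    """

    input_length: int = INPUT_LENGTH
    conv1: ConvLayerSpec = field(default_factory=lambda: ConvLayerSpec(128, 20, 3))
    pool1: PoolSpec = PoolSpec(2, 3)
    conv2: ConvLayerSpec = field(default_factory=lambda: ConvLayerSpec(32, 7, 1))
    pool2: PoolSpec = PoolSpec(2, 2)
    conv3: ConvLayerSpec = field(
        default_factory=lambda: ConvLayerSpec(32, 10, 1, batch_norm=False))
    se_reduction: int = 8
    pool3: PoolSpec = PoolSpec(2, 2)
    lstm_units: int = 100
    dropout: float = 0.1
    dense_units: tuple[int, ...] = (20, 10)
    l2: float = 1e-3
    n_classes: int = N_CLASSES

    def expected_shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        """The (name, output shape) chain implied by the configuration."""
        t = self.input_length
        chain: list[tuple[str, tuple[int, ...]]] = []
        for i, (conv, pool) in enumerate(
            [(self.conv1, self.pool1), (self.conv2, self.pool2),
             (self.conv3, self.pool3)], start=1):
            t = conv_output_length(t, conv.kernel, conv.stride, conv.padding)
            chain.append((f"conv{i}", (t, conv.filters)))
            if i == 3:
                chain.append(("se", (t, conv.filters)))
            t = conv_output_length(t, pool.pool, pool.stride, "valid")
            chain.append((f"pool{i}", (t, conv.filters)))
        chain.append(("lstm", (self.lstm_units,)))
        for i, units in enumerate(self.dense_units, start=1):
            chain.append((f"dense{i}", (units,)))
        chain.append(("output", (self.n_classes,)))
        return chain

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureConfig":
        raw = json.loads(text)
        for key in ("conv1", "conv2", "conv3"):
            raw[key] = ConvLayerSpec(**raw[key])
        for key in ("pool1", "pool2", "pool3"):
            raw[key] = PoolSpec(**raw[key])
        raw["dense_units"] = tuple(raw["dense_units"])
        return cls(**raw)


def build_model(config: ArchitectureConfig | None = None, seed: int = 0) -> nn.Sequential:
    """Instantiate the classifier with seeded deterministic weights.

    The returned model's :meth:`~ecgpipe.nn.Sequential.forward` yields
    logits; :meth:`~ecgpipe.nn.Sequential.predict_proba` applies the final
    softmax. Layer output dimensions are validated against the
    configuration's expected chain at build time.
    """
    config = config or ArchitectureConfig()
    layers: list[nn.Layer] = []
    for i, (conv, pool) in enumerate(
        [(config.conv1, config.pool1), (config.conv2, config.pool2),
         (config.conv3, config.pool3)], start=1):
        layers.append(nn.Conv1D(conv.filters, conv.kernel, conv.stride, conv.padding))
        if conv.batch_norm:
            layers.append(nn.BatchNorm())
        layers.append(nn.ReLU())
        if i == 3:
            layers.append(nn.SEBlock(reduction=config.se_reduction))
        layers.append(nn.MaxPool1D(pool.pool, pool.stride))
    layers.append(nn.LSTM(config.lstm_units))
    layers.append(nn.Flatten())
    layers.append(nn.Dropout(config.dropout))
    for units in config.dense_units:
        layers.append(nn.Dense(units, activation="relu", l2=config.l2))
    layers.append(nn.Dense(config.n_classes, activation=None, l2=0.0))
    model = nn.Sequential(layers).build((config.input_length, 1), seed=seed)

    expected = dict(_named_shapes(config))
    actual = dict(layer_output_shapes(model, config))
    if expected != actual:
        raise ValueError(
            f"architecture dimension chain is inconsistent:\n"
            f"expected {expected}\nactual   {actual}")
    return model


def _named_shapes(config: ArchitectureConfig) -> list[tuple[str, tuple[int, ...]]]:
    return config.expected_shapes()


def save_model(model: nn.Sequential, config: ArchitectureConfig, path) -> None:
    """Store trained weights plus the architecture as a ``.npz`` checkpoint."""
    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    arrays["architecture_json"] = np.frombuffer(
        config.to_json().encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> tuple[nn.Sequential, ArchitectureConfig]:
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    with np.load(path) as data:
        config = ArchitectureConfig.from_json(
            bytes(data["architecture_json"]).decode())
        model = build_model(config, seed=0)
        weights = [data[f"w{i}"] for i in range(len(model.get_weights()))]
    model.set_weights(weights)
    return model, config


def layer_output_shapes(
    model: nn.Sequential, config: ArchitectureConfig | None = None
) -> list[tuple[str, tuple[int, ...]]]:
    """Named output shapes of the semantically meaningful layers."""
    config = config or ArchitectureConfig()
    shapes = model.output_shapes()
    named: list[tuple[str, tuple[int, ...]]] = []
    conv_i = pool_i = dense_i = 0
    for layer, shape in zip(model.layers, shapes):
        if isinstance(layer, nn.Conv1D):
            conv_i += 1
            named.append((f"conv{conv_i}", shape))
        elif isinstance(layer, nn.SEBlock):
            named.append(("se", shape))
        elif isinstance(layer, nn.MaxPool1D):
            pool_i += 1
            named.append((f"pool{pool_i}", shape))
        elif isinstance(layer, nn.LSTM):
            named.append(("lstm", shape))
        elif isinstance(layer, nn.Dense):
            dense_i += 1
            name = f"dense{dense_i}" if dense_i <= len(config.dense_units) else "output"
            named.append((name, shape))
    return named
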