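"""Model zoo: the convolution block and the four junction-sequence classifiers.

Two architectures share one convolution block design (three stages of
conv -> ReLU -> dropout 0.2 -> max-pool 2/2, with 32/8/8 filters of widths
7/4/3):

* Architecture A: one block on a single 140-nt junction window.  Used for
  CON-ALT3 (acceptor/upstream window) and CON-ALT5 (donor/downstream
  window), each with a 32-node fully connected layer and a sigmoid head.
* Architecture B: two blocks with independent weights, one per window.
  Used for CON-ES (sigmoid) and the four-class general model DSC (softmax),
  each with a 64-node fully connected layer.

In both architectures the flattened block features are concatenated with
the three z-normalized length features (L1, L2, L3) before the fully
connected layer, which is followed by ReLU and dropout 0.5.

Convolution padding is configurable: the default length-preserving "same"
padding gives pooled lengths 140 -> 70 -> 35 -> 17 and a flattened block
dimension of 136; "valid" gives 140 -> 67 -> 32 -> 15 (dimension 120).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .nn import Adam, Conv1D, Dense, Dropout, Flatten, MaxPool1D, ReLU, Sequential, sigmoid, softmax

__all__ = [
    "TASKS",
    "CLASS_TO_INT",
    "INT_TO_CLASS",
    "ConvBlockSpec",
    "ModelSpec",
    "SpliceModel",
    "build_cnn_block",
    "block_output_dim",
    "build_model",
    "init_weights",
    "save_checkpoint",
    "load_checkpoint",
]

TASKS = ("CON-ES", "CON-ALT3", "CON-ALT5", "DSC")

CLASS_TO_INT = {"CON": 0, "ES": 1, "ALT3": 2, "ALT5": 3}
INT_TO_CLASS = {v: k for k, v in CLASS_TO_INT.items()}

# positive (label 1) class of each binary task
POSITIVE_CLASS = {"CON-ES": "ES", "CON-ALT3": "ALT3", "CON-ALT5": "ALT5"}


@dataclass(frozen=True)
class ConvBlockSpec:
    """Three convolution stages, each conv -> ReLU -> dropout -> max-pool."""

    filters: tuple[int, ...] = (32, 8, 8)
    widths: tuple[int, ...] = (7, 4, 3)
    dropout_p: float = 0.2
    pool_size: int = 2

    def __post_init__(self) -> None:
        if len(self.filters) != len(self.widths):
            raise ValueError("filters and widths must have equal length")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one task model."""

    task: str
    architecture: str  # "A" (one block) or "B" (two untied blocks)
    inputs: tuple[str, ...]  # subset of ("acceptor", "donor")
    fc_nodes: int
    head: str  # "sigmoid" or "softmax"
    n_outputs: int
    fc_dropout_p: float = 0.5
    padding: str = "same"
    conv: ConvBlockSpec = field(default_factory=ConvBlockSpec)
    input_length: int = 140

    def __post_init__(self) -> None:
        if self.architecture == "A" and len(self.inputs) != 1:
            raise ValueError("architecture A takes exactly one sequence input")
        if self.architecture == "B" and len(self.inputs) != 2:
            raise ValueError("architecture B takes exactly two sequence inputs")
        if (self.head == "sigmoid") != (self.n_outputs == 1):
            raise ValueError("sigmoid head implies a single output")


def build_cnn_block(spec: ConvBlockSpec, input_length: int, padding: str = "same") -> tuple[Sequential, int]:
    """Construct one convolution block; returns (block, flattened output dim)."""
    layers = []
    length = input_length
    channels = 4
    for nf, w in zip(spec.filters, spec.widths):
        conv = Conv1D(channels, nf, w, padding=padding)
        length = conv.out_length(length)
        pool = MaxPool1D(spec.pool_size)
        layers += [conv, ReLU(), Dropout(spec.dropout_p), pool]
        length = pool.out_length(length)
        if length < 1:
            raise ValueError("input too short for the pooling chain")
        channels = nf
    layers.append(Flatten())
    return Sequential(layers), length * channels


def block_output_dim(spec: ConvBlockSpec, input_length: int = 140, padding: str = "same") -> int:
    """Flattened dimension of the block output without building parameters."""
    length = input_length
    for nf, w in zip(spec.filters, spec.widths):
        if padding == "valid":
            length = length - w + 1
        length = (length - spec.pool_size) // spec.pool_size + 1
        if length < 1:
            raise ValueError("input too short for the pooling chain")
    return length * spec.filters[-1]


def model_spec_for_task(task: str, padding: str = "same") -> ModelSpec:
    if task == "CON-ALT3":
        return ModelSpec(task, "A", ("acceptor",), 32, "sigmoid", 1, padding=padding)
    if task == "CON-ALT5":
        return ModelSpec(task, "A", ("donor",), 32, "sigmoid", 1, padding=padding)
    if task == "CON-ES":
        return ModelSpec(task, "B", ("acceptor", "donor"), 64, "sigmoid", 1, padding=padding)
    if task == "DSC":
        return ModelSpec(task, "B", ("acceptor", "donor"), 64, "softmax", 4, padding=padding)
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


class SpliceModel:
    """An instantiated task model: per-input convolution blocks, the joint
    fully connected layer and the classification head, with exact
    backpropagation through all layers."""

    def __init__(self, spec: ModelSpec, seed: int = 0, init_sigma: float = 0.05):
        self.spec = spec
        self.seed = seed
        self.init_sigma = init_sigma
        self.blocks: dict[str, Sequential] = {}
        dims = []
        for name in spec.inputs:
            block, dim = build_cnn_block(spec.conv, spec.input_length, spec.padding)
            self.blocks[name] = block
            dims.append(dim)
        self.feature_dim = sum(dims) + 3  # + (L1, L2, L3)
        self._block_dims = dims
        self.fc = Dense(self.feature_dim, spec.fc_nodes)
        self.fc_relu = ReLU()
        self.fc_drop = Dropout(spec.fc_dropout_p)
        self.head = Dense(spec.fc_nodes, spec.n_outputs)
        self.rng = np.random.default_rng(seed)  # dropout stream
        init_weights(self, seed, init_sigma)

    # -- parameters ---------------------------------------------------------
    def params(self):
        ps = []
        for name in self.spec.inputs:
            ps += self.blocks[name].params()
        ps += self.fc.params() + self.head.params()
        return ps

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        ps = self.params()
        if len(ps) != len(weights):
            raise ValueError("weight list does not match parameter count")
        for p, w in zip(ps, weights):
            p.value[...] = np.asarray(w, dtype=p.value.dtype).reshape(p.value.shape)

    # -- forward / backward -------------------------------------------------
    def _forward(self, batch: dict, training: bool) -> np.ndarray:
        feats = []
        for name in self.spec.inputs:
            feats.append(self.blocks[name].forward(batch[name], training, self.rng))
        feats.append(np.asarray(batch["lengths"], dtype=np.float32))
        x = np.concatenate(feats, axis=1)
        h = self.fc.forward(x, training, self.rng)
        h = self.fc_relu.forward(h, training, self.rng)
        h = self.fc_drop.forward(h, training, self.rng)
        return self.head.forward(h, training, self.rng)

    def predict(self, batch: dict) -> np.ndarray:
        """Evaluation-mode class probabilities: shape (n,) for sigmoid heads,
        (n, 4) for the softmax head.  Deterministic (no dropout)."""
        logits = self._forward(batch, training=False)
        if self.spec.head == "sigmoid":
            return sigmoid(logits[:, 0])
        return softmax(logits)

    def loss(self, batch: dict, y: np.ndarray, training: bool = False) -> float:
        return self._loss_from_logits(self._forward(batch, training), y)[0]

    def _loss_from_logits(self, logits: np.ndarray, y: np.ndarray):
        n = logits.shape[0]
        if self.spec.head == "sigmoid":
            z = logits[:, 0]
            # stable binary cross-entropy from logits
            loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
            p = sigmoid(z)
            dlogits = ((p - y) / n)[:, None].astype(np.float32)
        else:
            zs = logits - logits.max(axis=1, keepdims=True)
            logp = zs - np.log(np.exp(zs).sum(axis=1, keepdims=True))
            loss = float(-np.mean(logp[np.arange(n), y]))
            p = np.exp(logp)
            onehot = np.zeros_like(p)
            onehot[np.arange(n), y] = 1.0
            dlogits = ((p - onehot) / n).astype(np.float32)
        return loss, dlogits

    def train_step_grads(self, batch: dict, y: np.ndarray) -> float:
        """Forward + backward in training mode; accumulates gradients into
        the parameters and returns the minibatch loss."""
        logits = self._forward(batch, training=True)
        loss, dlogits = self._loss_from_logits(logits, y)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")
        dh = self.head.backward(dlogits)
        dh = self.fc_drop.backward(dh)
        dh = self.fc_relu.backward(dh)
        dx = self.fc.backward(dh)
        off = 0
        for name, dim in zip(self.spec.inputs, self._block_dims):
            self.blocks[name].backward(dx[:, off : off + dim])
            off += dim
        return loss

    def make_optimizer(self, lr: float = 5e-4) -> Adam:
        return Adam(self.params(), lr=lr)

    def first_layer_kernels(self) -> dict[str, np.ndarray]:
        """First-layer convolution filters per input block, each
        (n_filters, width, 4), plus their biases under ``<name>_bias``."""
        out = {}
        for name in self.spec.inputs:
            conv = self.blocks[name].layers[0]
            out[name] = conv.kernels
            out[name + "_bias"] = conv.b.value.copy()
        return out


def build_model(task: str, seed: int = 0, padding: str = "same", init_sigma: float = 0.05) -> SpliceModel:
    """Instantiate one of the four task models with seeded Gaussian init."""
    return SpliceModel(model_spec_for_task(task, padding=padding), seed=seed, init_sigma=init_sigma)


def init_weights(model: SpliceModel, seed: int, sigma: float = 0.05) -> SpliceModel:
    """Gaussian(0, sigma) weights, all biases exactly zero; seed-deterministic."""
    rng = np.random.default_rng(seed)
    for name in model.spec.inputs:
        for layer in model.blocks[name].layers:
            _init_layer(layer, rng, sigma)
    _init_layer(model.fc, rng, sigma)
    _init_layer(model.head, rng, sigma)
    model.rng = np.random.default_rng(np.random.SeedSequence([seed, 1]).generate_state(1)[0])
    return model


def _init_layer(layer, rng, sigma) -> None:
    if isinstance(layer, (Conv1D, Dense)):
        layer.W.value[...] = rng.normal(0.0, sigma, size=layer.W.value.shape).astype(np.float32)
        layer.b.value[...] = 0.0


def save_checkpoint(model: SpliceModel, path) -> None:
    """Self-describing JSON checkpoint: full spec + seed + weights."""
    blob = {
        "spec": asdict(model.spec),
        "seed": model.seed,
        "init_sigma": model.init_sigma,
        "weights": [w.tolist() for w in model.get_weights()],
    }
    with open(path, "w") as fh:
        json.dump(blob, fh)


def load_checkpoint(path) -> SpliceModel:
    with open(path) as fh:
        blob = json.load(fh)
    sd = blob["spec"]
    spec = ModelSpec(
        task=sd["task"],
        architecture=sd["architecture"],
        inputs=tuple(sd["inputs"]),
        fc_nodes=sd["fc_nodes"],
        head=sd["head"],
        n_outputs=sd["n_outputs"],
        fc_dropout_p=sd["fc_dropout_p"],
        padding=sd["padding"],
        conv=ConvBlockSpec(
            filters=tuple(sd["conv"]["filters"]),
            widths=tuple(sd["conv"]["widths"]),
            dropout_p=sd["conv"]["dropout_p"],
            pool_size=sd["conv"]["pool_size"],
        ),
        input_length=sd["input_length"],
    )
    model = SpliceModel(spec, seed=blob["seed"], init_sigma=blob["init_sigma"])
    model.set_weights([np.asarray(w, dtype=np.float32) for w in blob["weights"]])
    return model
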