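"""Multi-branch CNN for per-characteristic binary grading.

Three branches each take one of three consecutive 64x64 nodule slices.
Every branch is four convolution sets C1..C4 (two 3x3 convolutions of
16, 32, 64 and 128 kernels respectively, each set followed by 2x2
stride-2 max pooling). Cross-branch skips enrich the later branches:
branch 2's set s receives the channel concatenation of its own previous
set output and branch 1's corresponding set output; branch 3
additionally receives branch 2's. The three 4x4x128 branch outputs are
channel-concatenated, batch-normalized, passed through a 3x3
convolution with 64 kernels, flattened and classified by dense layers
ending in a 2-way softmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nnet import Adam, BatchNorm, Conv3x3, Dense, MaxPool2x2, ReLU, F32, softmax, softmax_xent_grad

KERNEL_COUNTS = (16, 32, 64, 128)


class ConstructionError(ValueError):
    pass


@dataclass
class MBCNNConfig:
    input_size: int = 64
    kernel_counts: tuple = KERNEL_COUNTS
    fusion_kernels: int = 64
    dense_units: int = 128
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 8
    early_stop_train_acc: float = 0.995
    seed: int = 0

    def __post_init__(self):
        if tuple(self.kernel_counts) != KERNEL_COUNTS:
            raise ConstructionError(
                f"kernel counts must be exactly {KERNEL_COUNTS}, got {self.kernel_counts}")
        if self.input_size % 16 != 0:
            raise ConstructionError("input size must be divisible by 16 (four pool halvings)")


class ConvSet:
    """Two same-padding 3x3 convolutions (ReLU) followed by 2x2 pooling."""

    def __init__(self, name: str, c_in: int, filters: int, rng):
        self.name = name
        self.conv1, self.relu1 = Conv3x3(c_in, filters, rng), ReLU()
        self.conv2, self.relu2 = Conv3x3(filters, filters, rng), ReLU()
        self.pool = MaxPool2x2()
        self.layers = [self.conv1, self.relu1, self.conv2, self.relu2, self.pool]

    def forward(self, x, train):
        try:
            for layer in self.layers:
                x = layer.forward(x, train)
        except ValueError as err:
            raise ConstructionError(f"{self.name}: {err}") from err
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class MBCNNModel:
    """The wired three-branch network. Input x: (N, 3, H, W) float."""

    def __init__(self, config: MBCNNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        kc = config.kernel_counts
        # per-branch input channel counts of each conv set
        self.sets: list[list[ConvSet]] = []
        for b in range(3):
            branch = []
            for s in range(4):
                if s == 0:
                    c_in = 1
                else:
                    c_in = kc[s - 1] * (b + 1)  # own + earlier-branch skips
                branch.append(ConvSet(f"branch{b+1}_set{s+1}", c_in, kc[s], rng))
            branch[0].conv1.skip_input_grad = True  # image input needs no gradient
            self.sets.append(branch)
        fused_channels = 3 * kc[-1]
        self.bn = BatchNorm(fused_channels)
        self.fusion_conv = Conv3x3(fused_channels, config.fusion_kernels, rng)
        self.fusion_relu = ReLU()
        final_hw = config.input_size // 16
        flat = final_hw * final_hw * config.fusion_kernels
        self.dense1, self.dense_relu = Dense(flat, config.dense_units, rng), ReLU()
        self.dense2 = Dense(config.dense_units, 2, rng)

        self._modules = (
            [cs for branch in self.sets for cs in branch]
            + [self.bn, self.fusion_conv, self.dense1, self.dense2]
        )

    # -- parameter plumbing --------------------------------------------------
    def params(self):
        out = []
        for m in self._modules:
            layers = m.layers if isinstance(m, ConvSet) else [m]
            for layer in layers:
                out.extend(layer.params)
        return out

    def grads(self):
        out = []
        for m in self._modules:
            layers = m.layers if isinstance(m, ConvSet) else [m]
            for layer in layers:
                out.extend(layer.grads)
        return out

    def param_count(self, branch: int | None = None) -> int:
        if branch is None:
            return sum(p.size for p in self.params())
        return sum(p.size for cs in self.sets[branch] for layer in cs.layers for p in layer.params)

    # -- forward / backward ----------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2] != self.config.input_size:
            raise ValueError(
                f"expected (N, 3, {self.config.input_size}, {self.config.input_size}) input")
        x = x - F32(0.5)  # centre [0, 1] grayscale inputs
        outs = [[None] * 4 for _ in range(3)]  # per-branch set outputs (post-pool)
        for s in range(4):
            for b in range(3):
                if s == 0:
                    inp = x[:, b, :, :, None]
                else:
                    inp = np.concatenate([outs[bb][s - 1] for bb in range(b, -1, -1)], axis=-1)
                    # order: own previous output first, then earlier branches
                outs[b][s] = self.sets[b][s].forward(inp, train)
        fused = np.concatenate([outs[b][3] for b in range(3)], axis=-1)
        z = self.bn.forward(fused, train)
        z = self.fusion_relu.forward(self.fusion_conv.forward(z, train), train)
        n = z.shape[0]
        self._flat_shape = z.shape
        z = z.reshape(n, -1)
        z = self.dense_relu.forward(self.dense1.forward(z, train), train)
        logits = self.dense2.forward(z, train)
        self._outs_shapes = [[o.shape for o in branch] for branch in outs]
        return logits

    def backward(self, dlogits: np.ndarray):
        dz = self.dense2.backward(dlogits)
        dz = self.dense1.backward(self.dense_relu.backward(dz))
        dz = dz.reshape(self._flat_shape)
        dz = self.fusion_conv.backward(self.fusion_relu.backward(dz))
        dfused = self.bn.backward(dz)
        kc = self.config.kernel_counts
        d_out = [[None] * 4 for _ in range(3)]
        splits = np.cumsum([kc[-1], kc[-1]])
        parts = np.split(dfused, splits, axis=-1)
        for b in range(3):
            d_out[b][3] = parts[b]
        for s in range(3, -1, -1):
            for b in range(2, -1, -1):
                dinp = self.sets[b][s].backward(d_out[b][s])
                if s == 0:
                    continue
                # un-concatenate: own previous output first, then branches b-1..0
                chunks = np.split(dinp, np.cumsum([kc[s - 1]] * b), axis=-1)
                for j, bb in enumerate(range(b, -1, -1)):
                    prev = d_out[bb][s - 1]
                    d_out[bb][s - 1] = chunks[j] if prev is None else prev + chunks[j]

    def recalibrate_bn(self, x: np.ndarray, batch_size: int = 128, max_samples: int = 256):
        """Replace batch-norm running stats with exact moments over ``x``.

        With few optimization steps per epoch, the exponentially
        averaged statistics lag the evolving features; a calibration
        pass after training makes inference-mode normalization
        consistent with the trained network. A strided subsample of
        ``max_samples`` gives the per-channel moments ample support
        (each sample contributes a full spatial map per channel).
        """
        if len(x) > max_samples:
            x = x[:: int(np.ceil(len(x) / max_samples))]
        self.bn.begin_calibration()
        for start in range(0, len(x), batch_size):
            self.forward(x[start:start + batch_size], train=False)
        self.bn.end_calibration()

    def predict_proba(self, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Probability of the high-level label; inference-mode normalization."""
        x = np.asarray(x, dtype=F32)
        out = []
        for start in range(0, len(x), batch_size):
            logits = self.forward(x[start:start + batch_size], train=False)
            out.append(softmax(logits)[:, 1])
        return np.concatenate(out)

    def layer_shapes(self, n: int = 1) -> list:
        """(name, output shape) audit of every conv set and head layer."""
        x = np.zeros((n, 3, self.config.input_size, self.config.input_size), dtype=F32)
        self.forward(x, train=False)
        shapes = []
        for b in range(3):
            for s in range(4):
                shapes.append((f"branch{b+1}_set{s+1}", self._outs_shapes[b][s]))
        hw = self.config.input_size // 16
        shapes.append(("fused", (n, hw, hw, 3 * self.config.kernel_counts[-1])))
        shapes.append(("fusion_conv", (n, hw, hw, self.config.fusion_kernels)))
        shapes.append(("dense1", (n, self.config.dense_units)))
        shapes.append(("logits", (n, 2)))
        return shapes


def build_mbcnn(config: MBCNNConfig | None = None) -> MBCNNModel:
    return MBCNNModel(config or MBCNNConfig())


def stack_triplets(triplets) -> np.ndarray:
    """(N, 3, H, W) float32 array from a list of 3-slice patch groups."""
    arr = np.asarray([[np.asarray(p, dtype=F32) for p in t] for t in triplets], dtype=F32)
    if arr.ndim != 4 or arr.shape[1] != 3:
        raise ValueError("each triplet must hold exactly 3 equal-shape slices")
    return arr


def train_mbcnn(
    triplets,
    labels,
    config: MBCNNConfig | None = None,
    epochs: int | None = None,
    seed: int | None = None,
) -> MBCNNModel:
    """Train a per-characteristic binary MBCNN with Adam.

    ``epochs`` overrides ``config.max_epochs``; training stops early
    once the running training accuracy reaches
    ``config.early_stop_train_acc``. Deterministic given the seed (the
    config seed, unless ``seed`` is passed).
    """
    config = config or MBCNNConfig()
    if seed is not None:
        config = MBCNNConfig(**{**config.__dict__, "seed": seed})
    x = stack_triplets(triplets)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    model = build_mbcnn(config)
    n_epochs = config.max_epochs if epochs is None else epochs
    if n_epochs == 0:
        return model
    opt = Adam(model.params(), lr=config.learning_rate)
    params = model.params()
    rng = np.random.default_rng(config.seed + 1)
    n = len(x)
    for _ in range(n_epochs):
        order = rng.permutation(n)
        correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.forward(x[idx], train=True)
            loss, dlogits = softmax_xent_grad(logits, y[idx])
            correct += int(np.sum(logits.argmax(axis=1) == y[idx]))
            model.backward(dlogits)
            grads = model.grads()
            if config.weight_decay:
                for p, g in zip(params, grads):
                    if p.ndim > 1:  # decay weight matrices, not biases or BN
                        g += config.weight_decay * p
            opt.step(grads)
        if correct / n >= config.early_stop_train_acc:
            break
    model.recalibrate_bn(x)
    return model


def mbcnn_predict(model: MBCNNModel, triplet) -> float | np.ndarray:
    """Probability of the high-level label for one triplet (or a batch)."""
    arr = np.asarray(triplet, dtype=F32)
    if arr.ndim == 3:
        return float(model.predict_proba(arr[None])[0])
    return model.predict_proba(arr)
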