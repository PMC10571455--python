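"""Restricted Boltzmann machines and the two-hidden-layer DBN classifier.

The RBM is Bernoulli-Bernoulli with energy

    E(v, h) = -a'v - b'h - v'Wh

trained by contrastive divergence (CD-k): the positive phase uses the
data, the negative phase k alternations of Gibbs sampling. The
partition function Z is never computed at full scale (it is intractable
and only enumerable for toy models); training relies on the CD gradient
approximation.

The DBN stacks two RBMs (hidden sizes 100 and 100), pretrained greedily
and fine-tuned with full backpropagation under a single logistic output
unit. Two input regimes are supported:

* ``dbn1`` — flattened grayscale patch G scaled to [0, 1] concatenated
  with the flattened binary mask B (visible size 8192);
* ``dbn2`` — flattened G concatenated with the 72-element feature
  vector, min-max scaled to [0, 1] with the scaler fitted on the
  training split only (visible size 4168).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nnet import sigmoid

DBN1_VISIBLE = 64 * 64 * 2   # G + B
DBN2_VISIBLE = 64 * 64 + 72  # G + features
HIDDEN_SIZES = (100, 100)


@dataclass
class RBMParams:
    W: np.ndarray  # (n_visible, n_hidden)
    a: np.ndarray  # visible bias
    b: np.ndarray  # hidden bias

    def __post_init__(self):
        nv, nh = self.W.shape
        if self.a.shape != (nv,) or self.b.shape != (nh,):
            raise ValueError("bias shapes inconsistent with W")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.a))
                and np.all(np.isfinite(self.b))):
            raise ValueError("non-finite RBM parameters")


def rbm_energy(v: np.ndarray, h: np.ndarray, params: RBMParams) -> float:
    """E(v, h) = -a'v - b'h - v'Wh."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    nv, nh = params.W.shape
    if v.shape != (nv,) or h.shape != (nh,):
        raise ValueError(f"expected v of length {nv} and h of length {nh}")
    return float(-params.a @ v - params.b @ h - v @ params.W @ h)


def init_rbm(n_visible: int, n_hidden: int, rng: np.random.Generator,
             visible_means: np.ndarray | None = None) -> RBMParams:
    """Small random weights; visible biases at the data log-odds.

    Seeding the visible bias with logit(mean activation) lets the
    weights model structure instead of the input mean — without it,
    wide visible layers drive the hidden units into saturation.
    """
    a = np.zeros(n_visible)
    if visible_means is not None:
        p = np.clip(visible_means, 0.01, 0.99)
        a = np.log(p / (1 - p))
    return RBMParams(
        W=rng.normal(0, 0.01, size=(n_visible, n_hidden)),
        a=a,
        b=np.zeros(n_hidden),
    )


def train_rbm_cd(
    data: np.ndarray,
    hidden_size: int,
    k: int = 1,
    epochs: int = 30,
    learning_rate: float = 0.05,
    batch_size: int = 32,
    seed: int = 0,
    weight_decay: float = 1e-4,
    monitor: list | None = None,
) -> RBMParams:
    """CD-k training of a Bernoulli-Bernoulli RBM on rows in [0, 1].

    Real-valued inputs are treated as Bernoulli probabilities (the
    standard practice for [0, 1]-scaled pixels). With ``monitor`` a
    list, the mean per-epoch reconstruction cross-entropy is appended
    after each epoch. Deterministic given ``seed``.
    """
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (samples x visible units)")
    if data.min() < 0 or data.max() > 1:
        raise ValueError("RBM inputs must lie in [0, 1]")
    if hidden_size < 1:
        raise ValueError("hidden_size must be >= 1")
    rng = np.random.default_rng(seed)
    params = init_rbm(data.shape[1], hidden_size, rng,
                      visible_means=data.mean(axis=0, dtype=np.float64))
    params.W = params.W.astype(np.float32)
    params.a = params.a.astype(np.float32)
    params.b = params.b.astype(np.float32)
    n = len(data)
    for _ in range(epochs):
        order = rng.permutation(n)
        recon_xent = 0.0
        for start in range(0, n, batch_size):
            v0 = data[order[start:start + batch_size]]
            ph0 = sigmoid(v0 @ params.W + params.b)
            h = (rng.random(ph0.shape) < ph0).astype(np.float32)
            for _ in range(k):
                pv = sigmoid(h @ params.W.T + params.a)
                ph = sigmoid(pv @ params.W + params.b)
                h = (rng.random(ph.shape) < ph).astype(np.float32)
            m = len(v0)
            lr32 = np.float32(learning_rate)
            params.W += lr32 * ((v0.T @ ph0 - pv.T @ ph) / np.float32(m)
                                - np.float32(weight_decay) * params.W)
            params.a += lr32 * (v0 - pv).mean(axis=0, dtype=np.float32)
            params.b += lr32 * (ph0 - ph).mean(axis=0, dtype=np.float32)
            pv_c = np.clip(pv, 1e-10, 1 - 1e-10)
            recon_xent += float(-np.sum(v0 * np.log(pv_c) + (1 - v0) * np.log(1 - pv_c)))
        if monitor is not None:
            monitor.append(recon_xent / n)
    return params


def exact_log_likelihood(data: np.ndarray, params: RBMParams) -> float:
    """Mean log P(v) by brute-force enumeration of the partition function.

    Only tractable for toy RBMs (a dozen units or so); used as an
    independent oracle for CD training.
    """
    nv, nh = params.W.shape
    if nv + nh > 24:
        raise ValueError("exact enumeration only supported for toy RBMs")
    W = params.W.astype(np.float64)
    a = params.a.astype(np.float64)
    b = params.b.astype(np.float64)
    vs = np.array(np.meshgrid(*[[0, 1]] * nv, indexing="ij")).reshape(nv, -1).T.astype(float)
    # free energy F(v) = -a'v - sum_j log(1 + exp(b_j + v'W_j))
    def neg_free_energy(V):
        return V @ a + np.sum(np.logaddexp(0.0, V @ W + b), axis=1)
    log_z = float(np.logaddexp.reduce(neg_free_energy(vs)))
    return float(np.mean(neg_free_energy(np.asarray(data, dtype=float))) - log_z)


# --- input construction -------------------------------------------------------

@dataclass
class FeatureScaler:
    """Min-max scaler to [0, 1], fitted on the training split only.

    Held-out values beyond the training range are clipped.
    """

    lo: np.ndarray = field(default_factory=lambda: np.zeros(0))
    hi: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        self.lo = X.min(axis=0)
        self.hi = X.max(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
        return np.clip((np.asarray(X, dtype=float) - self.lo) / span, 0.0, 1.0)


def _scale_gray(G: np.ndarray) -> np.ndarray:
    g = np.asarray(G, dtype=float)
    if np.issubdtype(np.asarray(G).dtype, np.integer):
        g = g / np.iinfo(np.asarray(G).dtype).max
    return np.clip(g, 0.0, 1.0)


def build_input(patch, features=None, regime: str = "dbn1",
                scaler: FeatureScaler | None = None) -> np.ndarray:
    """Visible vector for one patch under the requested regime."""
    g = _scale_gray(patch.G).ravel()
    if regime == "dbn1":
        return np.concatenate([g, patch.B.astype(float).ravel()])
    if regime == "dbn2":
        if features is None:
            raise ValueError("dbn2 regime requires a feature vector")
        vals = features.values if hasattr(features, "values") else np.asarray(features, dtype=float)
        if scaler is None:
            raise ValueError("dbn2 regime requires a fitted FeatureScaler")
        return np.concatenate([g, scaler.transform(vals[None, :])[0]])
    raise ValueError(f"unknown regime {regime!r}")


# --- the classifier -----------------------------------------------------------

@dataclass
class DBNHyperParams:
    pretrain_epochs: int = 30
    pretrain_lr: float = 0.02
    cd_k: int = 1
    batch_size: int = 16
    weight_decay: float = 2e-4
    finetune_epochs: int = 100
    finetune_lr: float = 3e-4  # Adam; larger rates destabilize wide sigmoid stacks


@dataclass
class DBNModel:
    rbms: list                  # two RBMParams
    head_w: np.ndarray          # (hidden, ) logistic weights
    head_b: float
    input_regime: str
    scaler: FeatureScaler | None = None

    def hidden_activations(self, X: np.ndarray) -> np.ndarray:
        h = np.asarray(X, dtype=float)
        for rbm in self.rbms:
            h = sigmoid(h @ rbm.W + rbm.b)
        return h


def _forward(X, rbms, head_w, head_b):
    acts = [np.asarray(X, dtype=float)]
    for rbm in rbms:
        acts.append(sigmoid(acts[-1] @ rbm.W + rbm.b))
    p = sigmoid(acts[-1] @ head_w + head_b)
    return acts, p


def train_dbn(
    inputs: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    regime: str = "dbn1",
    hp: DBNHyperParams | None = None,
    scaler: FeatureScaler | None = None,
    hidden_sizes: tuple = HIDDEN_SIZES,
) -> DBNModel:
    """Greedy CD pretraining of the two-RBM stack, then supervised
    fine-tuning of the whole network under a logistic output.

    ``inputs`` are pre-built visible vectors in [0, 1] (see
    :func:`build_input`); deterministic given ``seed``.
    """
    X = np.asarray(inputs, dtype=np.float32)
    y = np.asarray(labels).astype(np.float32)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    hp = hp or DBNHyperParams()
    rng = np.random.default_rng(seed)

    # greedy layer-wise pretraining
    rbms = []
    layer_input = X
    for li, nh in enumerate(hidden_sizes):
        rbm = train_rbm_cd(
            layer_input, nh, k=hp.cd_k, epochs=hp.pretrain_epochs,
            learning_rate=hp.pretrain_lr, batch_size=hp.batch_size,
            weight_decay=hp.weight_decay,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rbms.append(rbm)
        layer_input = sigmoid(layer_input @ rbm.W + rbm.b)

    head_w = rng.normal(0, 0.01, size=hidden_sizes[-1]).astype(np.float32)
    head_b = np.zeros(1, dtype=np.float32)

    # supervised fine-tuning: full backprop on cross-entropy with Adam
    from .nnet import Adam

    params = []
    for rbm in rbms:
        params.extend([rbm.W, rbm.b])
    params.extend([head_w, head_b])
    opt = Adam(params, lr=hp.finetune_lr)
    n = len(X)
    for _ in range(hp.finetune_epochs):
        order = rng.permutation(n)
        for start in range(0, n, hp.batch_size):
            idx = order[start:start + hp.batch_size]
            acts, p = _forward(X[idx], rbms, head_w, head_b)
            m = len(idx)
            delta = (p - y[idx]) / m                     # d loss / d logit
            grads = []
            d_h = np.outer(delta, head_w)
            for li in reversed(range(len(rbms))):
                d_pre = d_h * acts[li + 1] * (1 - acts[li + 1])
                grads[:0] = [acts[li].T @ d_pre, d_pre.sum(axis=0)]
                d_h = d_pre @ rbms[li].W.T
            grads.extend([acts[-1].T @ delta, np.array([delta.sum()])])
            opt.step(grads)
    return DBNModel(rbms=rbms, head_w=head_w, head_b=head_b,
                    input_regime=regime, scaler=scaler)


def dbn_predict(model: DBNModel, inputs: np.ndarray) -> np.ndarray:
    """Mean-field forward pass; probability of the high-level label."""
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    nv = model.rbms[0].W.shape[0]
    if X.shape[1] != nv:
        raise ValueError(f"expected visible size {nv}, got {X.shape[1]}")
    _, p = _forward(X, model.rbms, model.head_w, model.head_b)
    return p
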