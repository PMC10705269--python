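"""Conditional variational autoencoder for label-conditioned methylation samples.

The model is a standard CVAE: a fully connected recognition network
(encoder) maps a beta-value sample x concatenated with its one-hot
species/tissue label y to the mean mu and log-variance sigma of a
diagonal Gaussian posterior over a Z-dimensional latent space; the
generation network (decoder) maps a latent vector z concatenated with y
back to per-probe logits.  Sampling uses the reparameterization trick

    z = mu + exp(sigma / 2) * eps,        eps ~ N(0, I)

so the Monte-Carlo estimate of the evidence lower bound stays
differentiable.  Training minimizes

    L_TRAIN = L_RECON + L_REG

where L_RECON is the binary cross entropy between the sample's beta
values (soft targets in [0, 1]) and the logistic of the decoder logits,
summed over probes, and L_REG is the closed-form KL divergence of the
posterior from N(0, I):

    L_REG = 1/2 * sum_k (exp(sigma_k) + mu_k^2 - 1 - sigma_k).

Both terms are summed within a sample and averaged over the batch; one
Monte-Carlo latent draw per sample per step is used.  Optimization is
Adam, implemented here along with the forward and backward passes —
everything is plain numpy, reproducible from a single seed that drives
weight initialization, batch shuffling and the eps draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import pandas as pd

from .data_model import (
    CombinationGrid,
    LabelSpace,
    MethylationDataset,
    encode_labels,
)

CHECKPOINT_VERSION = 1

_ACTIVATIONS = ("tanh", "relu", "sigmoid")


@dataclass
class CVAEHyperparams:
    """Architecture and optimization settings.

    Defaults are the winning grid-search combination on the real
    compendium: hidden dims (1024, 512), tanh, latent dimension 8,
    learning rate 1e-3, Adam epsilon 1e-4, one Monte-Carlo draw.
    Epochs/batch size are training-budget knobs, not searched defaults.
    """

    hidden_dims: tuple[int, ...] = (1024, 512)
    activation: str = "tanh"
    latent_dim: int = 8
    learning_rate: float = 1e-3
    adam_epsilon: float = 1e-4
    mc_samples: int = 1
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        self.hidden_dims = tuple(int(d) for d in self.hidden_dims)
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")

    @property
    def n_hidden(self) -> int:
        return len(self.hidden_dims)


def _act(name: str, u: np.ndarray) -> np.ndarray:
    if name == "tanh":
        return np.tanh(u)
    if name == "relu":
        return np.maximum(u, 0.0)
    return 1.0 / (1.0 + np.exp(-u))


def _act_grad_from_output(name: str, h: np.ndarray) -> np.ndarray:
    # derivative expressed through the activation output
    if name == "tanh":
        return 1.0 - h * h
    if name == "relu":
        return (h > 0).astype(h.dtype)
    return h * (1.0 - h)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class _MLP:
    """Plain fully connected stack: hidden layers with one activation,
    then one or more parallel linear heads."""

    def __init__(self, weights: list, biases: list, heads: list, activation: str):
        self.weights = weights      # hidden-layer weight matrices
        self.biases = biases
        self.heads = heads          # list of (W, b) linear output heads
        self.activation = activation

    @classmethod
    def init(cls, rng, in_dim: int, hidden_dims, head_dims, activation: str) -> "_MLP":
        weights, biases = [], []
        prev = in_dim
        for d in hidden_dims:
            weights.append(_glorot(rng, prev, d))
            biases.append(np.zeros(d))
            prev = d
        heads = [(_glorot(rng, prev, hd), np.zeros(hd)) for hd in head_dims]
        return cls(weights, biases, heads, activation)

    def forward(self, x: np.ndarray):
        """Returns (head outputs, cached layer activations)."""
        cache = [x]
        h = x
        for W, b in zip(self.weights, self.biases):
            h = _act(self.activation, h @ W + b)
            cache.append(h)
        outs = [h @ W + b for W, b in self.heads]
        return outs, cache

    def backward(self, cache, head_grads):
        """Backprop given d(loss)/d(head output) for every head.

        Returns (parameter gradients in self.params() order, gradient
        w.r.t. the input).
        """
        h_last = cache[-1]
        dh = np.zeros_like(h_last)
        head_param_grads = []
        for (W, _b), gout in zip(self.heads, head_grads):
            head_param_grads.append((h_last.T @ gout, gout.sum(axis=0)))
            dh += gout @ W.T
        hidden_param_grads = []
        for i in range(len(self.weights) - 1, -1, -1):
            du = dh * _act_grad_from_output(self.activation, cache[i + 1])
            hidden_param_grads.append((cache[i].T @ du, du.sum(axis=0)))
            dh = du @ self.weights[i].T
        hidden_param_grads.reverse()
        grads = []
        for gW, gb in hidden_param_grads:
            grads.extend([gW, gb])
        for gW, gb in head_param_grads:
            grads.extend([gW, gb])
        return grads, dh

    def params(self) -> list:
        out = []
        for W, b in zip(self.weights, self.biases):
            out.extend([W, b])
        for W, b in self.heads:
            out.extend([W, b])
        return out

    @classmethod
    def from_params(cls, flat: list, n_hidden: int, n_heads: int, activation: str) -> "_MLP":
        weights = [flat[2 * i] for i in range(n_hidden)]
        biases = [flat[2 * i + 1] for i in range(n_hidden)]
        heads = [
            (flat[2 * n_hidden + 2 * j], flat[2 * n_hidden + 2 * j + 1])
            for j in range(n_heads)
        ]
        return cls(weights, biases, heads, activation)


class _Adam:
    def __init__(self, params: list, lr: float, eps: float, beta1=0.9, beta2=0.999):
        self.lr, self.eps, self.b1, self.b2 = lr, eps, beta1, beta2
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list, grads: list) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class LatentState:
    """One reparameterized latent draw: z = mu + exp(sigma/2) * eps."""

    mu: np.ndarray
    sigma: np.ndarray
    eps: np.ndarray
    z: np.ndarray = field(init=False)

    def __post_init__(self):
        self.z = reparameterize(self.mu, self.sigma, self.eps)


class CVAEModel:
    """Trained encoder/decoder pair with its label space and hyperparameters.

    Encoder input width is M + S + T and it emits mu and sigma (log of
    the diagonal posterior covariance), each of length Z; decoder input
    width is Z + S + T and it emits M logits.  The decoder's hidden
    stack mirrors the encoder's (dims reversed).
    """

    def __init__(self, encoder: _MLP, decoder: _MLP, label_space: LabelSpace,
                 probe_ids: list[str], hyper: CVAEHyperparams,
                 loss_trace: list[float] | None = None):
        self.encoder = encoder
        self.decoder = decoder
        self.label_space = label_space
        self.probe_ids = list(probe_ids)
        self.hyper = hyper
        self.loss_trace = list(loss_trace or [])

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @classmethod
    def initialize(cls, space: LabelSpace, probe_ids, hyper: CVAEHyperparams,
                   rng: np.random.Generator | None = None) -> "CVAEModel":
        rng = rng or np.random.default_rng(hyper.seed)
        m, l, z = len(probe_ids), space.width, hyper.latent_dim
        encoder = _MLP.init(rng, m + l, hyper.hidden_dims, [z, z], hyper.activation)
        decoder = _MLP.init(rng, z + l, tuple(reversed(hyper.hidden_dims)), [m],
                            hyper.activation)
        return cls(encoder, decoder, space, probe_ids, hyper)

    # -- forward passes ----------------------------------------------------

    def encode(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior parameters (mu, sigma) for sample(s) x with label(s) y."""
        x, y, single = _as_batch(x, y)
        if x.shape[1] != self.n_probes or y.shape[1] != self.label_space.width:
            raise ValueError(
                f"expected x width {self.n_probes} and y width "
                f"{self.label_space.width}, got {x.shape[1]} and {y.shape[1]}"
            )
        (mu, sigma), _ = self.encoder.forward(np.concatenate([x, y], axis=1))
        if single:
            return mu[0], sigma[0]
        return mu, sigma

    def decode(self, z: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Raw per-probe logits; apply the logistic to get beta-scale values."""
        z, y, single = _as_batch(z, y)
        if z.shape[1] != self.hyper.latent_dim or y.shape[1] != self.label_space.width:
            raise ValueError(
                f"expected z width {self.hyper.latent_dim} and y width "
                f"{self.label_space.width}, got {z.shape[1]} and {y.shape[1]}"
            )
        (logits,), _ = self.decoder.forward(np.concatenate([z, y], axis=1))
        return logits[0] if single else logits

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["version"] = CHECKPOINT_VERSION
            f.attrs["hyper"] = json.dumps(asdict(self.hyper))
            f.attrs["loss_trace"] = json.dumps(self.loss_trace)
            f.create_dataset("species_vocab",
                             data=np.array(self.label_space.species_vocab, dtype="S"))
            f.create_dataset("tissue_vocab",
                             data=np.array(self.label_space.tissue_vocab, dtype="S"))
            f.create_dataset("probe_ids", data=np.array(self.probe_ids, dtype="S"))
            for name, p in zip(_param_names(self), self.encoder.params() + self.decoder.params()):
                f.create_dataset(name, data=p)

    @classmethod
    def load(cls, path) -> "CVAEModel":
        with h5py.File(path, "r") as f:
            raw = json.loads(f.attrs["hyper"])
            raw["hidden_dims"] = tuple(raw["hidden_dims"])
            hyper = CVAEHyperparams(**raw)
            trace = json.loads(f.attrs["loss_trace"])
            space = LabelSpace(
                [s.decode() for s in f["species_vocab"][()]],
                [t.decode() for t in f["tissue_vocab"][()]],
            )
            probes = [p.decode() for p in f["probe_ids"][()]]
            model = cls.initialize(space, probes, hyper)
            flat = [np.asarray(f[name]) for name in _param_names(model)]
        n_enc = len(model.encoder.params())
        model.encoder = _MLP.from_params(flat[:n_enc], hyper.n_hidden, 2, hyper.activation)
        model.decoder = _MLP.from_params(flat[n_enc:], hyper.n_hidden, 1, hyper.activation)
        model.loss_trace = trace
        return model


def _param_names(model: CVAEModel) -> list[str]:
    n_enc = len(model.encoder.params())
    n_dec = len(model.decoder.params())
    return [f"encoder/p{i}" for i in range(n_enc)] + [f"decoder/p{i}" for i in range(n_dec)]


def _as_batch(a: np.ndarray, b: np.ndarray):
    a, b = np.asarray(a, float), np.asarray(b, float)
    single = a.ndim == 1
    if single:
        a, b = a[None, :], b[None, :]
    if a.shape[0] != b.shape[0]:
        raise ValueError("batch sizes differ")
    return a, b, single


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def reparameterize(mu: np.ndarray, sigma: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """z = mu + exp(sigma/2) * eps, elementwise; sigma is the log-variance."""
    mu, sigma, eps = (np.asarray(v, float) for v in (mu, sigma, eps))
    if not (mu.shape == sigma.shape == eps.shape):
        raise ValueError("mu, sigma and eps must have identical shapes")
    return mu + np.exp(sigma / 2.0) * eps


def reconstruction_loss(x: np.ndarray, logits: np.ndarray) -> float:
    """Binary cross entropy with soft targets, summed over probes.

    Computed in the numerically stable logits form:
    sum_m [ max(l, 0) - l*x + log(1 + exp(-|l|)) ].
    """
    x, logits = np.asarray(x, float), np.asarray(logits, float)
    if np.isnan(x).any() or np.isnan(logits).any():
        raise ValueError("NaN input to reconstruction_loss")
    if x.shape != logits.shape:
        raise ValueError("x and logits must have identical shapes")
    per_elem = np.maximum(logits, 0.0) - logits * x + np.log1p(np.exp(-np.abs(logits)))
    return float(per_elem.sum())


def kl_loss(mu: np.ndarray, sigma: np.ndarray) -> float:
    """Closed-form KL( N(mu, diag(exp sigma)) || N(0, I) ):
    1/2 * sum_k (exp(sigma_k) + mu_k^2 - 1 - sigma_k)."""
    mu, sigma = np.asarray(mu, float), np.asarray(sigma, float)
    if not (np.isfinite(mu).all() and np.isfinite(sigma).all()):
        raise ValueError("kl_loss requires finite inputs")
    return float(0.5 * np.sum(np.exp(sigma) + mu * mu - 1.0 - sigma))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _forward_backward(model: CVAEModel, xb: np.ndarray, yb: np.ndarray,
                      eps: np.ndarray):
    """One training step's loss and gradients for a batch.

    Per-sample loss = BCE summed over probes + KL summed over latent
    dims; the batch objective is the mean over samples.
    """
    nb = xb.shape[0]
    enc_in = np.concatenate([xb, yb], axis=1)
    (mu, sigma), enc_cache = model.encoder.forward(enc_in)
    z = reparameterize(mu, sigma, eps)
    dec_in = np.concatenate([z, yb], axis=1)
    (logits,), dec_cache = model.decoder.forward(dec_in)

    p = 1.0 / (1.0 + np.exp(-logits))
    recon = np.maximum(logits, 0.0) - logits * xb + np.log1p(np.exp(-np.abs(logits)))
    kl = 0.5 * (np.exp(sigma) + mu * mu - 1.0 - sigma)
    loss = float(recon.sum(axis=1).mean() + kl.sum(axis=1).mean())

    dlogits = (p - xb) / nb
    dec_grads, ddec_in = model.decoder.backward(dec_cache, [dlogits])
    dz = ddec_in[:, : model.hyper.latent_dim]
    dmu = dz + mu / nb
    dsigma = dz * eps * 0.5 * np.exp(sigma / 2.0) + 0.5 * (np.exp(sigma) - 1.0) / nb
    enc_grads, _ = model.encoder.backward(enc_cache, [dmu, dsigma])
    return loss, enc_grads + dec_grads


def train(dataset: MethylationDataset, space: LabelSpace,
          hyper: CVAEHyperparams) -> CVAEModel:
    """Fit the CVAE on individual samples with Adam.

    One shared seed drives weight initialization, batch shuffling and
    the per-step eps draws, so identical (data, hyper) reruns give
    bit-identical parameters.  The per-epoch mean training loss is kept
    on the returned model as ``loss_trace``.
    """
    if dataset.n_samples < 1:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(hyper.seed)
    model = CVAEModel.initialize(space, dataset.probe_ids, hyper, rng)
    x = dataset.beta
    y = encode_labels(dataset, space)
    n = x.shape[0]
    params = model.encoder.params() + model.decoder.params()
    opt = _Adam(params, hyper.learning_rate, hyper.adam_epsilon)

    for epoch in range(hyper.epochs):
        perm = rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, hyper.batch_size):
            idx = perm[start : start + hyper.batch_size]
            xb, yb = x[idx], y[idx]
            step_loss = 0.0
            grads = None
            for _ in range(hyper.mc_samples):
                eps = rng.standard_normal((len(idx), hyper.latent_dim))
                loss_l, grads_l = _forward_backward(model, xb, yb, eps)
                step_loss += loss_l / hyper.mc_samples
                if grads is None:
                    grads = [g / hyper.mc_samples for g in grads_l]
                else:
                    for g, gl in zip(grads, grads_l):
                        g += gl / hyper.mc_samples
            if not np.isfinite(step_loss):
                raise RuntimeError(f"training loss diverged (NaN/inf) at epoch {epoch}")
            opt.step(params, grads)
            total += step_loss * len(idx)
            seen += len(idx)
        model.loss_trace.append(total / seen)
    return model


# ---------------------------------------------------------------------------
# Hyperparameter grid search
# ---------------------------------------------------------------------------

def grid_search(
    train_set: MethylationDataset,
    validation_combos: CombinationGrid,
    grid: list[CVAEHyperparams],
    space: LabelSpace | None = None,
) -> tuple[CVAEHyperparams, pd.DataFrame]:
    """Select hyperparameters by validation sample-wise Pearson correlation.

    Each candidate is trained on ``train_set``; all validation
    combinations are imputed and scored by the mean Pearson correlation
    between the imputed vector and the held-out validation combination
    mean.  The argmax wins; ties go to the first candidate in grid
    order.  Every validation combination must be absent from training
    yet have at least one same-species and one same-tissue training
    sample.
    """
    from .impute import impute_combination  # local import: impute depends on this module

    if not grid:
        raise ValueError("hyperparameter grid is empty")
    space = space or train_set.label_space()
    train_combos = set(train_set.combos())
    train_species = {s for s, _ in train_combos}
    train_tissues = {t for _, t in train_combos}
    for s, t in validation_combos.combos:
        if (s, t) in train_combos:
            raise ValueError(f"validation combination {(s, t)} present in training data")
        if s not in train_species or t not in train_tissues:
            raise ValueError(
                f"validation combination {(s, t)} lacks same-species or "
                "same-tissue training samples"
            )

    rows = []
    best_idx, best_score, best_hyper = -1, -np.inf, None
    for i, hyper in enumerate(grid):
        model = train(train_set, space, hyper)
        cors = []
        for j, (s, t) in enumerate(validation_combos.combos):
            imputed = impute_combination(model, s, t, latent_seed=(hyper.seed, j))
            cors.append(_pearson(imputed, validation_combos.means[j]))
        score = float(np.nanmean(cors)) if cors else np.nan
        rows.append({"candidate": i, **_hyper_summary(hyper), "mean_pearson": score})
        if score > best_score:
            best_idx, best_score, best_hyper = i, score, hyper
    scores = pd.DataFrame(rows)
    if best_hyper is None:
        best_idx, best_hyper = 0, grid[0]
    return best_hyper, scores


def default_grid(seed: int = 0, epochs: int = 100, batch_size: int = 32) -> list[CVAEHyperparams]:
    """The shipped search grid: the known winning combination plus small
    perturbations of latent dimension and learning rate."""
    base = dict(hidden_dims=(1024, 512), activation="tanh", latent_dim=8,
                learning_rate=1e-3, adam_epsilon=1e-4, epochs=epochs,
                batch_size=batch_size, seed=seed)
    grid = [CVAEHyperparams(**base)]
    for latent in (4, 16):
        grid.append(CVAEHyperparams(**{**base, "latent_dim": latent}))
    for lr in (5e-4, 5e-3):
        grid.append(CVAEHyperparams(**{**base, "learning_rate": lr}))
    return grid


def _hyper_summary(h: CVAEHyperparams) -> dict:
    return {
        "hidden_dims": "x".join(map(str, h.hidden_dims)),
        "activation": h.activation,
        "latent_dim": h.latent_dim,
        "learning_rate": h.learning_rate,
        "adam_epsilon": h.adam_epsilon,
        "epochs": h.epochs,
    }


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])
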