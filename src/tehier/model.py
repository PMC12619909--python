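"""Per-parent-node classifiers: attention-fused hybrid CNN/GRU networks.

Each classifier discriminates the children of one taxonomy parent node
from two parallel encoders:

* **global branch** — the 4**k k-mer frequency vector passes through
  three convolution + max-pooling blocks (64/128/256 kernels at full
  scale), is flattened and projected to a 128-dim feature, ReLU
  throughout, dropout 0.5 on the dense layer;
* **local branch** — the 2L x 4 one-hot both-end matrix runs through two
  stacked GRU layers (128 and 64 units at full scale, sequence outputs
  kept), is flattened, dropped out and projected to a 128-dim feature.

A shared scalar attention head scores each branch feature h_s with
e_s = tanh(W h_s); the two scores are softmax-normalised into weights
(alpha_cnn, alpha_rnn), and the context vector c = alpha_cnn h_cnn +
alpha_rnn h_rnn feeds the softmax output layer directly.  Training
minimises categorical cross-entropy with Adam (default learning rate
5e-4).  GRU gates follow the bias-free formulation

    z_t = sigmoid(W_z x_t + U_z h_{t-1})
    r_t = sigmoid(W_r x_t + U_r h_{t-1})
    h'_t = tanh(W_h x_t + r_t * (U_h h_{t-1}))
    h_t = (1 - z_t) * h'_t + z_t * h_{t-1}

All stochastic steps (init, batching, dropout) derive from explicit
seeds, so a (config, seed) pair reproduces its parameter trajectory
bit-for-bit on a fixed platform.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autodiff import Adam, Tensor, concat, constant, parameter
from .features import FeaturePair

__all__ = ["ModelConfig", "NodeClassifier", "attention_fuse",
           "build_node_classifier", "train_node_classifier", "predict_proba",
           "crossvalidate"]


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    Full-scale defaults follow the reference architecture; the reduced
    values used in the test suite shrink channel counts, not structure.
    """

    k: int = 7
    L: int = 600
    conv_channels: tuple[int, ...] = (64, 128, 256)
    kernel_width: int = 3
    pool_width: int = 2
    gru_units: tuple[int, ...] = (128, 64)
    dense_units: int = 128
    dropout: float = 0.5
    learning_rate: float = 5e-4
    branch: str = "both"          # "both", "global" or "local"

    def __post_init__(self):
        if self.branch not in ("both", "global", "local"):
            raise ValueError(f"unknown branch mode {self.branch!r}")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def attention_fuse(h_cnn: np.ndarray, h_rnn: np.ndarray, W: np.ndarray):
    """Fuse two branch features into a convex-combination context vector.

    ``W`` is the shared projection (dense_units x 1).  Returns
    ``(context, (alpha_cnn, alpha_rnn))``; the weights are the softmax of
    the two scalar scores e_s = tanh(h_s . W) and always sum to 1.
    Inputs may be single vectors or (batch, dim) matrices.
    """
    h_cnn = np.asarray(h_cnn, dtype=float)
    h_rnn = np.asarray(h_rnn, dtype=float)
    if not (np.isfinite(h_cnn).all() and np.isfinite(h_rnn).all()):
        raise ValueError("attention_fuse refused: non-finite branch features")
    squeeze = h_cnn.ndim == 1
    hc = np.atleast_2d(h_cnn)
    hr = np.atleast_2d(h_rnn)
    w = np.asarray(W, dtype=float).reshape(-1)
    e_c = np.tanh(hc @ w)
    e_r = np.tanh(hr @ w)
    # softmax over two scores == logistic of their difference
    a_c = 1.0 / (1.0 + np.exp(e_r - e_c))
    a_r = 1.0 - a_c
    context = a_c[:, None] * hc + a_r[:, None] * hr
    if squeeze:
        return context[0], (float(a_c[0]), float(a_r[0]))
    return context, (a_c, a_r)


class NodeClassifier:
    """One child-discriminating classifier attached to a taxonomy parent node."""

    def __init__(self, parent_label: str, child_labels: list[str],
                 config: ModelConfig | None = None, seed: int = 0):
        if len(child_labels) < 2:
            raise ValueError(
                f"node {parent_label!r}: need >= 2 child labels, got {len(child_labels)}"
            )
        self.parent_label = parent_label
        self.child_labels = list(child_labels)
        self.config = config or ModelConfig()
        self.seed = int(seed)
        self.training_log: list[dict] = []
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(self.seed))

    # -- construction -------------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        p = self.params
        n_out = len(self.child_labels)
        ctx_dim = cfg.dense_units
        if cfg.branch in ("both", "global"):
            in_ch = 1
            length = 4**cfg.k
            for i, out_ch in enumerate(cfg.conv_channels):
                fan_in = cfg.kernel_width * in_ch
                p[f"conv{i}_W"] = parameter(_glorot(rng, fan_in, out_ch))
                p[f"conv{i}_b"] = parameter(np.zeros(out_ch))
                in_ch = out_ch
                length //= cfg.pool_width
            flat = length * in_ch
            p["g_dense_W"] = parameter(_glorot(rng, flat, cfg.dense_units))
            p["g_dense_b"] = parameter(np.zeros(cfg.dense_units))
        if cfg.branch in ("both", "local"):
            in_dim = 4
            for i, units in enumerate(cfg.gru_units):
                for gate in ("z", "r", "h"):
                    p[f"gru{i}_W{gate}"] = parameter(_glorot(rng, in_dim, units))
                    p[f"gru{i}_U{gate}"] = parameter(_glorot(rng, units, units))
                in_dim = units
            flat = 2 * cfg.L * cfg.gru_units[-1]
            p["l_dense_W"] = parameter(_glorot(rng, flat, cfg.dense_units))
            p["l_dense_b"] = parameter(np.zeros(cfg.dense_units))
        if cfg.branch == "both":
            # zero start = balanced attention (alpha 0.5/0.5); a random start
            # can lock onto whichever branch memorizes the training set first
            p["att_W"] = parameter(np.zeros((ctx_dim, 1)))
        p["out_W"] = parameter(_glorot(rng, ctx_dim, n_out))
        p["out_b"] = parameter(np.zeros(n_out))

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    # -- forward pass --------------------------------------------------------

    def _global_branch(self, kv: Tensor, train: bool, rng) -> Tensor:
        cfg = self.config
        b = kv.shape[0]
        # frequencies average 4**-k; rescale so the mean input entry is ~1,
        # which keeps early-layer activations and gradients well-conditioned
        x = (kv * float(4**cfg.k)).reshape(b, 4**cfg.k, 1)
        for i in range(len(cfg.conv_channels)):
            patches = x.unfold_windows(cfg.kernel_width)
            x = (patches @ self.params[f"conv{i}_W"] + self.params[f"conv{i}_b"]).relu()
            x = x.maxpool1d(cfg.pool_width)
        h = x.reshape(b, -1) @ self.params["g_dense_W"] + self.params["g_dense_b"]
        h = h.relu()
        return self._dropout(h, train, rng)

    def _gru_layer(self, x: Tensor, layer: int) -> Tensor:
        p = self.params
        xz = x @ p[f"gru{layer}_Wz"]
        xr = x @ p[f"gru{layer}_Wr"]
        xh = x @ p[f"gru{layer}_Wh"]
        b, t, units = xz.shape
        h = constant(np.zeros((b, units)))
        outs = []
        for s in range(t):
            z = (xz[:, s, :] + h @ p[f"gru{layer}_Uz"]).sigmoid()
            r = (xr[:, s, :] + h @ p[f"gru{layer}_Ur"]).sigmoid()
            hc = (xh[:, s, :] + r * (h @ p[f"gru{layer}_Uh"])).tanh()
            h = hc + z * (h + hc * -1.0)   # (1-z)*hc + z*h
            outs.append(h.reshape(b, 1, units))
        return concat(outs, axis=1)

    def _local_branch(self, oh: Tensor, train: bool, rng) -> Tensor:
        b = oh.shape[0]
        x = oh
        for i in range(len(self.config.gru_units)):
            x = self._gru_layer(x, i)
        x = self._dropout(x.reshape(b, -1), train, rng)
        h = x @ self.params["l_dense_W"] + self.params["l_dense_b"]
        return h.relu()

    def _dropout(self, x: Tensor, train: bool, rng) -> Tensor:
        p = self.config.dropout
        if not train or p <= 0:
            return x
        mask = (rng.random(x.shape) >= p) / (1.0 - p)
        return x * constant(mask)

    def _forward(self, kmers: np.ndarray, onehots: np.ndarray,
                 train: bool = False, rng=None):
        """Returns (logits tensor, alpha array of shape (batch, 2))."""
        cfg = self.config
        b = kmers.shape[0] if cfg.branch != "local" else onehots.shape[0]
        if cfg.branch == "global":
            ctx = self._global_branch(constant(kmers), train, rng)
            alphas = np.tile([1.0, 0.0], (b, 1))
        elif cfg.branch == "local":
            ctx = self._local_branch(constant(onehots), train, rng)
            alphas = np.tile([0.0, 1.0], (b, 1))
        else:
            h_c = self._global_branch(constant(kmers), train, rng)
            h_r = self._local_branch(constant(onehots), train, rng)
            e_c = (h_c @ self.params["att_W"]).tanh()
            e_r = (h_r @ self.params["att_W"]).tanh()
            a_c = (e_c + e_r * -1.0).sigmoid()       # softmax over two scores
            a_r = 1.0 - a_c
            ctx = a_c * h_c + a_r * h_r
            alphas = np.concatenate([a_c.data, a_r.data], axis=1)
        logits = ctx @ self.params["out_W"] + self.params["out_b"]
        return logits, alphas

    # -- inference ------------------------------------------------------------

    def _check_dims(self, kmers: np.ndarray, onehots: np.ndarray) -> None:
        cfg = self.config
        if kmers.shape[1] != 4**cfg.k:
            raise ValueError(
                f"k-mer feature length {kmers.shape[1]} != expected {4**cfg.k} (k={cfg.k})"
            )
        if onehots.shape[1:] != (2 * cfg.L, 4):
            raise ValueError(
                f"one-hot shape {onehots.shape[1:]} != expected ({2*cfg.L}, 4) (L={cfg.L})"
            )

    def predict_proba(self, features):
        """Class probabilities over `child_labels` plus attention weights.

        `features` is a FeaturePair or a ``(kmer matrix, one-hot array)``
        batch.  Returns ``(probs, alphas)``; for a single FeaturePair the
        leading batch axis is squeezed.
        """
        single = isinstance(features, FeaturePair)
        if single:
            kmers = features.kmer[None, :]
            onehots = features.onehot[None, :, :]
        else:
            kmers, onehots = features
            kmers = np.atleast_2d(np.asarray(kmers, dtype=float))
            onehots = np.asarray(onehots, dtype=float)
            if onehots.ndim == 2:
                onehots = onehots[None]
        self._check_dims(kmers, onehots)
        logits, alphas = self._forward(kmers, onehots, train=False)
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        if single:
            return probs[0], (float(alphas[0, 0]), float(alphas[0, 1]))
        return probs, alphas

    # -- training --------------------------------------------------------------

    def fit(self, kmers: np.ndarray, onehots: np.ndarray, labels,
            epochs: int = 100, batch_size: int = 32, seed: int = 0,
            validation=None, patience: int | None = 5) -> list[dict]:
        """Train with Adam on categorical cross-entropy.

        `labels` are child labels of this node's parent; every child
        class must be represented.  Returns (and stores) the per-epoch
        log: ``{"epoch", "loss", "accuracy"}`` plus validation metrics
        when a ``(kmers, onehots, labels)`` validation triple is given.
        Early stopping monitors validation loss with the given patience.
        """
        labels = list(labels)
        missing = set(self.child_labels) - set(labels)
        if missing:
            raise ValueError(
                f"node {self.parent_label!r}: child class(es) absent from "
                f"training data: {sorted(missing)!r}"
            )
        unknown = set(labels) - set(self.child_labels)
        if unknown:
            raise ValueError(f"labels not children of {self.parent_label!r}: {sorted(unknown)!r}")
        kmers = np.asarray(kmers, dtype=float)
        onehots = np.asarray(onehots, dtype=float)
        self._check_dims(kmers, onehots)
        y_idx = np.array([self.child_labels.index(l) for l in labels])
        onehot_y = np.eye(len(self.child_labels))[y_idx]
        log: list[dict] = []
        if epochs == 0:
            self.training_log = log
            return log
        rng = np.random.default_rng(seed)
        opt = Adam(self.parameters(), lr=self.config.learning_rate)
        n = len(labels)
        best_val = np.inf
        stale = 0
        for epoch in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            correct = 0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                logits, _ = self._forward(kmers[idx], onehots[idx], train=True, rng=rng)
                loss, probs = logits.softmax_cross_entropy(onehot_y[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
                correct += int((probs.argmax(axis=1) == y_idx[idx]).sum())
            entry = {"epoch": epoch, "loss": epoch_loss / n, "accuracy": correct / n}
            if validation is not None:
                vk, vo, vl = validation
                ventry = self.evaluate_loss(vk, vo, vl)
                entry.update({"val_loss": ventry[0], "val_accuracy": ventry[1]})
                if patience is not None:
                    if ventry[0] < best_val - 1e-6:
                        best_val = ventry[0]
                        stale = 0
                    else:
                        stale += 1
            log.append(entry)
            if validation is not None and patience is not None and stale >= patience:
                break
        self.training_log = log
        return log

    def evaluate_loss(self, kmers, onehots, labels) -> tuple[float, float]:
        kmers = np.asarray(kmers, dtype=float)
        onehots = np.asarray(onehots, dtype=float)
        y_idx = np.array([self.child_labels.index(l) for l in labels])
        logits, _ = self._forward(kmers, onehots, train=False)
        loss, probs = logits.softmax_cross_entropy(np.eye(len(self.child_labels))[y_idx])
        acc = float((probs.argmax(axis=1) == y_idx).mean())
        return float(loss.data), acc

    # -- persistence -------------------------------------------------------------

    def save(self, directory: str) -> None:
        """Serialize into `directory`: manifest.json, params.npz, log TSV."""
        os.makedirs(directory, exist_ok=True)
        manifest = {
            "parent_label": self.parent_label,
            "child_labels": self.child_labels,
            "seed": self.seed,
            "config": asdict(self.config),
        }
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
        np.savez(os.path.join(directory, "params.npz"),
                 **{name: t.data for name, t in self.params.items()})
        with open(os.path.join(directory, "training_log.tsv"), "w") as fh:
            if self.training_log:
                cols = list(self.training_log[0])
                fh.write("\t".join(cols) + "\n")
                for row in self.training_log:
                    fh.write("\t".join(str(row.get(c, "")) for c in cols) + "\n")

    @classmethod
    def load(cls, directory: str) -> "NodeClassifier":
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        cfg = manifest["config"]
        cfg["conv_channels"] = tuple(cfg["conv_channels"])
        cfg["gru_units"] = tuple(cfg["gru_units"])
        model = cls(manifest["parent_label"], manifest["child_labels"],
                    ModelConfig(**cfg), seed=manifest["seed"])
        with np.load(os.path.join(directory, "params.npz")) as data:
            for name in model.params:
                model.params[name].data = data[name].copy()
        return model


# -- spec-surface wrappers -------------------------------------------------------


def build_node_classifier(parent_label: str, child_labels: list[str],
                          k: int = 7, L: int = 600, seed: int = 0,
                          config: ModelConfig | None = None) -> NodeClassifier:
    """Construct a reproducibly-initialised classifier for one parent node."""
    if config is None:
        config = ModelConfig(k=k, L=L)
    else:
        config.k, config.L = k, L
    return NodeClassifier(parent_label, child_labels, config, seed=seed)


def train_node_classifier(model: NodeClassifier, kmers, onehots, labels,
                          epochs: int = 100, batch_size: int = 32,
                          seed: int = 0, **kwargs):
    """Train `model` in place; returns (model, training log)."""
    log = model.fit(kmers, onehots, labels, epochs=epochs,
                    batch_size=batch_size, seed=seed, **kwargs)
    return model, log


def predict_proba(model: NodeClassifier, features):
    return model.predict_proba(features)


def crossvalidate(kmers, onehots, labels, child_labels, parent_label: str = "node",
                  folds: int = 5, seed: int = 0, config: ModelConfig | None = None,
                  epochs: int = 10, batch_size: int = 32):
    """Stratified k-fold cross-validation of one node classifier.

    Returns a list of per-fold dicts with the fold's held-out
    ConfusionSummary and index arrays.  Every class needs >= `folds`
    members.
    """
    from sklearn.model_selection import StratifiedKFold

    from .metrics import flat_metrics

    labels = np.asarray(list(labels))
    kmers = np.asarray(kmers, dtype=float)
    onehots = np.asarray(onehots, dtype=float)
    values, counts = np.unique(labels, return_counts=True)
    thin = values[counts < folds]
    if len(thin):
        raise ValueError(f"class(es) with fewer than {folds} members: {thin.tolist()!r}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    reports = []
    for fold, (tr, va) in enumerate(skf.split(kmers, labels)):
        model = NodeClassifier(parent_label, list(child_labels), config, seed=seed + fold)
        model.fit(kmers[tr], onehots[tr], labels[tr], epochs=epochs,
                  batch_size=batch_size, seed=seed + fold, patience=None)
        probs, _ = model.predict_proba((kmers[va], onehots[va]))
        pred = [model.child_labels[i] for i in probs.argmax(axis=1)]
        reports.append({
            "fold": fold,
            "train_idx": tr,
            "val_idx": va,
            "report": flat_metrics(labels[va], pred, list(child_labels)),
        })
    return reports
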