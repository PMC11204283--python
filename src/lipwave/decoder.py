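"""Dilated-causal-convolution (TCN) sequence classifier.

The decoder stacks residual blocks, each holding two identical 1-D dilated
causal convolutions (kernel size 2) plus an additive skip connection (a
width-1 projection where channel counts differ), followed by global average
pooling over time and a softmax classification layer.  Dilations double per
block (1, 2, 4, ... ) so the receptive field covers the input.  The network,
its backpropagation and the Adam optimizer are implemented directly on NumPy
arrays; training is fully deterministic under a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .samples import SpeechSample

__all__ = [
    "DecoderConfig",
    "PreparedDataset",
    "prepare",
    "prepare_train_test",
    "TcnClassifier",
    "build",
    "train",
    "evaluate",
    "crossvalidate_words",
]


@dataclass
class DecoderConfig:
    """Architecture and training hyperparameters.

    Word decoding uses 6 residual blocks (dilations 1..32, receptive field
    127 samples); sentence decoding uses 7 (1..64, receptive field 255).
    ``filters`` is shared by every block (400 at full scale; tests and the
    bundled demo use far fewer to stay desk-sized).
    """

    n_blocks: int = 6
    kernel_size: int = 2
    filters: int = 400
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    masked_pool: bool = False
    seed: int = 0

    @property
    def dilations(self) -> tuple[int, ...]:
        return tuple(2**i for i in range(self.n_blocks))

    @property
    def receptive_field(self) -> int:
        return 1 + (self.kernel_size - 1) * 2 * sum(self.dilations)


@dataclass
class PreparedDataset:
    """Zero-padded, z-scored tensor with labels and a train/test split.

    Normalization statistics come from the training split only; padding is
    applied after normalization so the padded region is exactly zero.
    """

    x: np.ndarray  # (N, T_max, 4) float32
    y: np.ndarray  # (N,) int labels
    lengths: np.ndarray
    classes: list[str]
    mu: np.ndarray
    sd: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray

    @property
    def max_length(self) -> int:
        return self.x.shape[1]


def _stack_normalized(
    samples: list[SpeechSample],
    mu: np.ndarray,
    sd: np.ndarray,
    max_len: int,
) -> tuple[np.ndarray, np.ndarray]:
    n = len(samples)
    x = np.zeros((n, max_len, 4), dtype=np.float32)
    lengths = np.empty(n, dtype=np.int64)
    for i, s in enumerate(samples):
        w = ((s.data.T - mu) / sd).astype(np.float32)
        x[i, : s.length] = w[:max_len]
        lengths[i] = min(s.length, max_len)
    return x, lengths


def _channel_stats(samples: list[SpeechSample]) -> tuple[np.ndarray, np.ndarray]:
    cat = np.concatenate([s.data for s in samples], axis=1)
    mu = cat.mean(axis=1)
    sd = cat.std(axis=1)
    sd = np.where(sd > 0, sd, 1.0)  # constant channel: leave centered at zero
    return mu, sd


def prepare(samples: list[SpeechSample], split: float = 0.7, seed: int = 0) -> PreparedDataset:
    """Encode labels, split, z-score on the training split, zero-pad."""
    labels = sorted({s.label for s in samples})
    if len(labels) < 2:
        raise ValueError("need at least two classes")
    lab2idx = {l: i for i, l in enumerate(labels)}
    y = np.array([lab2idx[s.label] for s in samples])
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_train = max(1, int(round(split * len(samples))))
    train_idx, test_idx = order[:n_train], order[n_train:]
    mu, sd = _channel_stats([samples[i] for i in train_idx])
    max_len = max(s.length for s in samples)
    x, lengths = _stack_normalized(samples, mu, sd, max_len)
    return PreparedDataset(
        x=x, y=y, lengths=lengths, classes=labels, mu=mu, sd=sd,
        train_idx=train_idx, test_idx=test_idx,
    )


def prepare_train_test(
    train_samples: list[SpeechSample], test_samples: list[SpeechSample]
) -> PreparedDataset:
    """Prepare with an explicit split (e.g. synthetic train / actual test)."""
    labels = sorted({s.label for s in train_samples})
    lab2idx = {l: i for i, l in enumerate(labels)}
    unknown = {s.label for s in test_samples} - set(labels)
    if unknown:
        raise ValueError(f"test labels absent from training: {sorted(unknown)}")
    all_samples = list(train_samples) + list(test_samples)
    y = np.array([lab2idx[s.label] for s in all_samples])
    mu, sd = _channel_stats(train_samples)
    max_len = max(s.length for s in all_samples)
    x, lengths = _stack_normalized(all_samples, mu, sd, max_len)
    n_train = len(train_samples)
    return PreparedDataset(
        x=x, y=y, lengths=lengths, classes=labels, mu=mu, sd=sd,
        train_idx=np.arange(n_train), test_idx=np.arange(n_train, len(all_samples)),
    )


def _flat(x: np.ndarray) -> np.ndarray:
    return x.reshape(-1, x.shape[-1])


def _shift(x: np.ndarray, d: int) -> np.ndarray:
    """Delay along the time axis by d steps, zero-filling the start (causal)."""
    out = np.zeros_like(x)
    out[:, d:] = x[:, :-d]
    return out


class TcnClassifier:
    """Stacked dilated-causal residual blocks + GAP + softmax, pure NumPy."""

    def __init__(self, config: DecoderConfig, n_classes: int, in_channels: int = 4):
        self.config = config
        self.n_classes = n_classes
        rng = np.random.default_rng(config.seed)
        f = config.filters
        self.params: dict[str, np.ndarray] = {}
        c_in = in_channels
        for b, d in enumerate(config.dilations):
            for conv, ci in (("c1", c_in), ("c2", f)):
                scale = np.sqrt(2.0 / (config.kernel_size * ci))
                self.params[f"b{b}_{conv}_w"] = (
                    rng.normal(scale=scale, size=(config.kernel_size, ci, f)).astype(np.float32)
                )
                self.params[f"b{b}_{conv}_b"] = np.zeros(f, dtype=np.float32)
            if c_in != f:
                self.params[f"b{b}_skip_w"] = (
                    rng.normal(scale=np.sqrt(1.0 / c_in), size=(c_in, f)).astype(np.float32)
                )
            c_in = f
        self.params["fc_w"] = rng.normal(scale=np.sqrt(1.0 / f), size=(f, n_classes)).astype(np.float32)
        self.params["fc_b"] = np.zeros(n_classes, dtype=np.float32)

    # -- forward -----------------------------------------------------------
    def _conv(self, x: np.ndarray, w: np.ndarray, b: np.ndarray, d: int) -> np.ndarray:
        # kernel size 2: tap 1 at t, tap 0 at t - d
        y = x @ w[1] + _shift(x, d) @ w[0]
        return y + b

    def features(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        """Pre-pooling feature sequence (B, T, filters)."""
        h = x.astype(np.float32)
        for b, d in enumerate(self.config.dilations):
            x_in = h
            z1 = self._conv(x_in, self.params[f"b{b}_c1_w"], self.params[f"b{b}_c1_b"], d)
            h1 = np.maximum(z1, 0.0)
            z2 = self._conv(h1, self.params[f"b{b}_c2_w"], self.params[f"b{b}_c2_b"], d)
            h2 = np.maximum(z2, 0.0)
            skip_w = self.params.get(f"b{b}_skip_w")
            s = x_in @ skip_w if skip_w is not None else x_in
            h = h2 + s
            if cache is not None:
                cache.append((x_in, z1, h1, z2))
        return h

    def forward(self, x: np.ndarray, lengths: np.ndarray | None = None, cache: list | None = None):
        feats = self.features(x, cache)
        if self.config.masked_pool and lengths is not None:
            mask = (np.arange(x.shape[1])[None, :] < lengths[:, None]).astype(np.float32)
            pooled = (feats * mask[:, :, None]).sum(axis=1) / lengths[:, None].astype(np.float32)
        else:
            pooled = feats.mean(axis=1)
        logits = pooled @ self.params["fc_w"] + self.params["fc_b"]
        if cache is not None:
            cache.append((feats, pooled))
        return logits

    def predict(self, x: np.ndarray, lengths: np.ndarray | None = None, batch: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch):
            sl = slice(i, i + batch)
            ln = lengths[sl] if lengths is not None else None
            out.append(np.argmax(self.forward(x[sl], ln), axis=1))
        return np.concatenate(out)

    # -- backward ----------------------------------------------------------
    def _loss_and_grads(self, x: np.ndarray, y: np.ndarray, lengths: np.ndarray | None):
        cache: list = []
        logits = self.forward(x, lengths, cache)
        feats, pooled = cache.pop()
        n, t = x.shape[0], x.shape[1]
        shifted = logits - logits.max(axis=1, keepdims=True)
        expl = np.exp(shifted)
        probs = expl / expl.sum(axis=1, keepdims=True)
        loss = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
        grads: dict[str, np.ndarray] = {}
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads["fc_w"] = pooled.T @ dlogits
        grads["fc_b"] = dlogits.sum(axis=0)
        dpooled = dlogits @ self.params["fc_w"].T
        if self.config.masked_pool and lengths is not None:
            mask = (np.arange(t)[None, :] < lengths[:, None]).astype(np.float32)
            dfeats = (dpooled[:, None, :] / lengths[:, None, None].astype(np.float32)) * mask[:, :, None]
        else:
            dfeats = np.repeat(dpooled[:, None, :] / t, t, axis=1)
        dh = dfeats.astype(np.float32)
        for b in reversed(range(len(self.config.dilations))):
            d = self.config.dilations[b]
            x_in, z1, h1, z2 = cache.pop()
            dh2 = dh * (z2 > 0)
            w2 = self.params[f"b{b}_c2_w"]
            grads[f"b{b}_c2_w"] = np.stack([
                _flat(_shift(h1, d)).T @ _flat(dh2),
                _flat(h1).T @ _flat(dh2),
            ])
            grads[f"b{b}_c2_b"] = dh2.sum(axis=(0, 1))
            dh1 = dh2 @ w2[1].T
            tmp = dh2 @ w2[0].T
            dh1[:, :-d] += tmp[:, d:]
            dz1 = dh1 * (z1 > 0)
            w1 = self.params[f"b{b}_c1_w"]
            grads[f"b{b}_c1_w"] = np.stack([
                _flat(_shift(x_in, d)).T @ _flat(dz1),
                _flat(x_in).T @ _flat(dz1),
            ])
            grads[f"b{b}_c1_b"] = dz1.sum(axis=(0, 1))
            dx = dz1 @ w1[1].T
            tmp = dz1 @ w1[0].T
            dx[:, :-d] += tmp[:, d:]
            skip_w = self.params.get(f"b{b}_skip_w")
            if skip_w is not None:
                grads[f"b{b}_skip_w"] = _flat(x_in).T @ _flat(dh)
                dx += dh @ skip_w.T
            else:
                dx += dh
            dh = dx
        return loss, grads

    def save(self, path: str) -> None:
        np.savez(path, n_classes=self.n_classes, n_blocks=self.config.n_blocks,
                 filters=self.config.filters, **self.params)

    @classmethod
    def load(cls, path: str, config: DecoderConfig | None = None) -> "TcnClassifier":
        data = np.load(path)
        cfg = config or DecoderConfig(n_blocks=int(data["n_blocks"]), filters=int(data["filters"]))
        model = cls(cfg, int(data["n_classes"]))
        for k in model.params:
            model.params[k] = data[k]
        return model


def build(config: DecoderConfig, n_classes: int, max_length: int | None = None, in_channels: int = 4) -> TcnClassifier:
    """Construct the classifier, warning when the receptive field is short."""
    if max_length is not None and config.receptive_field < max_length:
        warnings.warn(
            f"receptive field {config.receptive_field} < max input length {max_length}; "
            "late samples only reach the head through pooling",
            stacklevel=2,
        )
    return TcnClassifier(config, n_classes, in_channels)


def train(
    model: TcnClassifier,
    dataset: PreparedDataset,
    config: DecoderConfig | None = None,
    checkpoint: str | None = None,
) -> dict:
    """Adam training on the dataset's training split; returns the history."""
    cfg = config or model.config
    rng = np.random.default_rng(cfg.seed + 1)
    idx = dataset.train_idx.copy()
    m = {k: np.zeros_like(v, dtype=np.float64) for k, v in model.params.items()}
    v = {k: np.zeros_like(v_, dtype=np.float64) for k, v_ in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history = {"loss": [], "train_accuracy": []}
    for _epoch in range(cfg.epochs):
        rng.shuffle(idx)
        losses = []
        for i in range(0, len(idx), cfg.batch_size):
            batch = idx[i : i + cfg.batch_size]
            loss, grads = model._loss_and_grads(
                dataset.x[batch], dataset.y[batch], dataset.lengths[batch]
            )
            if not np.isfinite(loss):
                raise FloatingPointError("training diverged (non-finite loss)")
            losses.append(loss)
            step += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for k, g in grads.items():
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                model.params[k] = (model.params[k] - lr_t * m[k] / (np.sqrt(v[k]) + eps)).astype(np.float32)
        history["loss"].append(float(np.mean(losses)))
        pred = model.predict(dataset.x[dataset.train_idx], dataset.lengths[dataset.train_idx])
        history["train_accuracy"].append(float(np.mean(pred == dataset.y[dataset.train_idx])))
    if checkpoint:
        model.save(checkpoint)
    return history


def evaluate(model: TcnClassifier, dataset: PreparedDataset, indices: np.ndarray | None = None) -> dict:
    """Top-1 accuracy, per-class accuracy and confusion matrix."""
    idx = dataset.test_idx if indices is None else indices
    pred = model.predict(dataset.x[idx], dataset.lengths[idx])
    truth = dataset.y[idx]
    k = len(dataset.classes)
    conf = np.zeros((k, k), dtype=int)
    for t_lab, p_lab in zip(truth, pred):
        conf[t_lab, p_lab] += 1
    row_tot = conf.sum(axis=1)
    per_class = np.divide(np.diag(conf), row_tot, out=np.zeros(k), where=row_tot > 0)
    return {
        "accuracy": float(np.mean(pred == truth)) if len(truth) else float("nan"),
        "per_class": per_class,
        "confusion": conf,
        "classes": dataset.classes,
    }


def crossvalidate_words(
    samples: list[SpeechSample],
    folds: int = 10,
    train_folds: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8),
    config: DecoderConfig | None = None,
    seed: int = 0,
) -> dict[int, float]:
    """Accuracy versus training-set size on a word corpus.

    Samples are randomly assigned to ``folds`` folds (seeded); for each
    requested fold count the model trains on that many folds and is tested
    on the rest.  Returns {n_train_folds: accuracy}.
    """
    cfg = config or DecoderConfig()
    labels = sorted({s.label for s in samples})
    per_label = {l: [s for s in samples if s.label == l] for l in labels}
    count = len(next(iter(per_label.values())))
    if count % folds:
        raise ValueError(f"{count} samples per word cannot split into {folds} folds")
    rng = np.random.default_rng(seed)
    fold_of: dict[int, np.ndarray] = {}
    ordered: list[SpeechSample] = []
    fold_ids: list[int] = []
    for l in labels:
        assign = np.repeat(np.arange(folds), count // folds)
        rng.shuffle(assign)
        ordered.extend(per_label[l])
        fold_ids.extend(assign.tolist())
    fold_ids = np.array(fold_ids)
    results: dict[int, float] = {}
    for n_t in train_folds:
        train_mask = fold_ids < n_t
        ds = prepare_train_test(
            [s for s, m in zip(ordered, train_mask) if m],
            [s for s, m in zip(ordered, train_mask) if not m],
        )
        model = build(cfg, len(ds.classes), ds.max_length)
        train(model, ds, cfg)
        results[n_t] = evaluate(model, ds)["accuracy"]
    return results
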