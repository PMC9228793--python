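"""Sleep-stage sequence classifiers over per-epoch feature vectors.

Three pluggable variants share one training/prediction contract:

* ``conv`` — a small 1-D convolutional network sliding along the feature
  axis within each epoch (epochs classified independently);
* ``recurrent`` — an Elman recurrent network over the epoch sequence,
  carrying hidden state across the night;
* ``conv_recurrent`` — the convolutional encoder feeding the recurrent
  network, combining within-epoch pattern detection with temporal context.

All three are compact numpy networks (manual gradients, Adam, seeded
initialisation) sized to train in minutes on one CPU; cross-entropy loss
with inverse-frequency class weights counters the heavy stage imbalance
(N3 is only a few percent of epochs in typical adult cohorts). Model
selection uses Cohen's κ pooled over validation subjects, the same metric
reported for the final scorer. Splits are always by subject: epochs within
one night are strongly dependent and must never straddle train/test.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .agreement import cohens_kappa, confusion_matrix
from .core import STAGE_ORDER, ConfigurationError, Hypnogram, StageLabel
from .features import FeatureSet

__all__ = [
    "StagerConfig",
    "DataSplit",
    "TrainedStager",
    "make_split",
    "train_stager",
    "predict_hypnogram",
    "select_best_model",
    "apply_continuity_smoothing",
    "majority_class_baseline_kappa",
]

logger = logging.getLogger(__name__)

VARIANTS = ("conv", "recurrent", "conv_recurrent")


@dataclass(frozen=True)
class StagerConfig:
    variant: str = "conv_recurrent"
    context_len: int = 9  # training chunk length (epochs) for recurrent variants
    hidden: int = 32
    conv_channels: int = 16
    kernel: int = 9
    train_epochs: int = 40
    lr: float = 0.01
    seed: int = 0
    class_weighting: str = "inverse_freq"  # or "none"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.context_len < 1 or self.hidden < 1 or self.conv_channels < 1:
            raise ValueError("sizes must be >= 1")


@dataclass(frozen=True)
class DataSplit:
    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.val), set(self.test)]
        for i in range(3):
            for j in range(i + 1, 3):
                if parts[i] & parts[j]:
                    raise ValueError("split parts must be disjoint")


def make_split(subject_ids, fractions: tuple[float, float, float], seed: int) -> DataSplit:
    """Subject-level partition with rounded proportions, reproducible per seed."""
    ids = sorted(str(s) for s in subject_ids)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(ids)
    rng = np.random.default_rng(int(seed) % 2**31)
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    parts = (
        tuple(ids[i] for i in order[:n_train]),
        tuple(ids[i] for i in order[n_train : n_train + n_val]),
        tuple(ids[i] for i in order[n_train + n_val :]),
    )
    for frac, part, name in zip(fractions, parts, ("train", "val", "test")):
        if frac > 0 and not part:
            raise ValueError(f"too few subjects to populate the {name} part")
    return DataSplit(*parts)


# ---------------------------------------------------------------------------
# numpy network internals


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _xent_grad(logits: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, np.ndarray]:
    """Weighted cross-entropy loss and dL/dlogits for integer labels y."""
    p = _softmax(logits)
    n = y.size
    wy = w[y]
    loss = float(-(wy * np.log(np.maximum(p[np.arange(n), y], 1e-12))).sum() / max(wy.sum(), 1e-12))
    g = p * wy[:, None]
    g[np.arange(n), y] -= wy
    return loss, g / max(wy.sum(), 1e-12)


def _unfold(X: np.ndarray, k: int) -> np.ndarray:
    """(B, F) -> (B, L, k) sliding windows along the feature axis, L = F-k+1."""
    B, F = X.shape
    L = F - k + 1
    idx = np.arange(k)[None, :] + np.arange(L)[:, None]
    return X[:, idx]


class _ConvEncoder:
    """Conv1d over the feature axis + ReLU + (mean, max) global pooling."""

    def __init__(self, n_features: int, channels: int, kernel: int):
        self.k = min(kernel, n_features)
        self.C = channels
        self.out_dim = 2 * channels

    def init(self, rng: np.random.Generator, prefix: str) -> dict[str, np.ndarray]:
        scale = math.sqrt(2.0 / self.k)
        return {
            f"{prefix}Wc": rng.normal(0, scale, size=(self.C, self.k)),
            f"{prefix}bc": np.zeros(self.C),
        }

    def forward(self, p: dict, prefix: str, X: np.ndarray):
        Xc = _unfold(X, self.k)  # (B, L, k)
        pre = Xc @ p[f"{prefix}Wc"].T + p[f"{prefix}bc"]  # (B, L, C)
        act = np.maximum(pre, 0.0)
        mean = act.mean(axis=1)
        arg = act.argmax(axis=1)  # (B, C)
        mx = np.take_along_axis(act, arg[:, None, :], axis=1)[:, 0, :]
        out = np.concatenate([mean, mx], axis=1)  # (B, 2C)
        cache = (Xc, pre, act, arg)
        return out, cache

    def backward(self, p: dict, prefix: str, dout: np.ndarray, cache, grads: dict) -> None:
        Xc, pre, act, arg = cache
        B, L, C = act.shape
        dmean, dmax = dout[:, :C], dout[:, C:]
        dact = np.repeat(dmean[:, None, :] / L, L, axis=1)
        bi = np.arange(B)[:, None]
        ci = np.arange(C)[None, :]
        dact[bi, arg, ci] += dmax
        dpre = dact * (pre > 0)
        grads[f"{prefix}Wc"] = grads.get(f"{prefix}Wc", 0) + np.einsum("blc,blk->ck", dpre, Xc)
        grads[f"{prefix}bc"] = grads.get(f"{prefix}bc", 0) + dpre.sum(axis=(0, 1))


class _ConvNet:
    """Per-epoch classifier: conv encoder -> dense ReLU -> logits."""

    recurrent = False

    def __init__(self, n_features: int, cfg: StagerConfig):
        self.enc = _ConvEncoder(n_features, cfg.conv_channels, cfg.kernel)
        self.H = cfg.hidden

    def init(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        d = self.enc.init(rng, "")
        D = self.enc.out_dim
        d["W1"] = rng.normal(0, math.sqrt(2.0 / D), size=(D, self.H))
        d["b1"] = np.zeros(self.H)
        d["W2"] = rng.normal(0, math.sqrt(1.0 / self.H), size=(self.H, 5))
        d["b2"] = np.zeros(5)
        return d

    def logits(self, p: dict, X: np.ndarray):
        emb, c1 = self.enc.forward(p, "", X)
        h = np.maximum(emb @ p["W1"] + p["b1"], 0.0)
        return h @ p["W2"] + p["b2"], (c1, emb, h)

    def loss_grads(self, p: dict, X: np.ndarray, y: np.ndarray, w: np.ndarray):
        logits, (c1, emb, h) = self.logits(p, X)
        loss, dz = _xent_grad(logits, y, w)
        grads: dict[str, np.ndarray] = {}
        grads["W2"] = h.T @ dz
        grads["b2"] = dz.sum(axis=0)
        dh = dz @ p["W2"].T * (h > 0)
        grads["W1"] = emb.T @ dh
        grads["b1"] = dh.sum(axis=0)
        demb = dh @ p["W1"].T
        self.enc.backward(p, "", demb, c1, grads)
        return loss, grads

    def predict_logits(self, p: dict, X: np.ndarray) -> np.ndarray:
        return self.logits(p, X)[0]


class _RecurrentNet:
    """Elman RNN over the epoch sequence, optionally behind a conv encoder.

    With the encoder, the RNN input is the conv embedding concatenated with
    the raw feature vector (a skip connection), so pooling does not
    bottleneck the per-epoch information.
    """

    recurrent = True

    def __init__(self, n_features: int, cfg: StagerConfig, with_conv: bool):
        self.with_conv = with_conv
        self.n_features = n_features
        self.enc = _ConvEncoder(n_features, cfg.conv_channels, cfg.kernel) if with_conv else None
        self.D = self.enc.out_dim + n_features if with_conv else n_features
        self.H = cfg.hidden

    def init(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        d = self.enc.init(rng, "enc_") if self.enc else {}
        d["Wx"] = rng.normal(0, math.sqrt(1.0 / self.D), size=(self.D, self.H))
        d["Wh"] = rng.normal(0, math.sqrt(1.0 / self.H), size=(self.H, self.H))
        d["bh"] = np.zeros(self.H)
        d["Wo"] = rng.normal(0, math.sqrt(1.0 / self.H), size=(self.H, 5))
        d["bo"] = np.zeros(5)
        return d

    def _encode(self, p: dict, X: np.ndarray):
        if self.enc:
            emb, cache = self.enc.forward(p, "enc_", X)
            return np.concatenate([emb, X], axis=1), cache
        return X, None

    def _run(self, p: dict, E: np.ndarray):
        T = E.shape[0]
        hs = np.zeros((T + 1, self.H))
        for t in range(T):
            hs[t + 1] = np.tanh(E[t] @ p["Wx"] + hs[t] @ p["Wh"] + p["bh"])
        return hs

    def loss_grads(self, p: dict, X: np.ndarray, y: np.ndarray, w: np.ndarray):
        E, cenc = self._encode(p, X)
        hs = self._run(p, E)
        logits = hs[1:] @ p["Wo"] + p["bo"]
        loss, dz = _xent_grad(logits, y, w)
        grads: dict[str, np.ndarray] = {}
        grads["Wo"] = hs[1:].T @ dz
        grads["bo"] = dz.sum(axis=0)
        T = E.shape[0]
        dE = np.zeros_like(E)
        dh_next = np.zeros(self.H)
        gWx = np.zeros_like(p["Wx"])
        gWh = np.zeros_like(p["Wh"])
        gbh = np.zeros_like(p["bh"])
        for t in range(T - 1, -1, -1):
            dh = dz[t] @ p["Wo"].T + dh_next
            dpre = dh * (1.0 - hs[t + 1] ** 2)
            gWx += np.outer(E[t], dpre)
            gWh += np.outer(hs[t], dpre)
            gbh += dpre
            dE[t] = dpre @ p["Wx"].T
            dh_next = dpre @ p["Wh"].T
        grads["Wx"], grads["Wh"], grads["bh"] = gWx, gWh, gbh
        if self.enc:
            self.enc.backward(p, "enc_", dE[:, : self.enc.out_dim], cenc, grads)
        return loss, grads

    def predict_logits(self, p: dict, X: np.ndarray) -> np.ndarray:
        E, _ = self._encode(p, X)
        hs = self._run(p, E)
        return hs[1:] @ p["Wo"] + p["bo"]


def _build_net(variant: str, n_features: int, cfg: StagerConfig):
    if variant == "conv":
        return _ConvNet(n_features, cfg)
    if variant == "recurrent":
        return _RecurrentNet(n_features, cfg, with_conv=False)
    return _RecurrentNet(n_features, cfg, with_conv=True)


# ---------------------------------------------------------------------------
# public training / prediction API


@dataclass
class TrainedStager:
    variant: str
    params: dict[str, np.ndarray]
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    layout_fingerprint: str
    config: StagerConfig
    validation_kappa: float = float("nan")
    loss_history: list[float] = field(default_factory=list)
    train_subjects: tuple[str, ...] = ()
    val_subjects: tuple[str, ...] = ()

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def save(self, path) -> str:
        payload = {
            "format": "somnoscore-stager-v1",
            "variant": self.variant,
            "params": {k: v.tolist() for k, v in sorted(self.params.items())},
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "layout_fingerprint": self.layout_fingerprint,
            "config": asdict(self.config),
            "validation_kappa": self.validation_kappa,
            "loss_history": self.loss_history,
            "train_subjects": list(self.train_subjects),
            "val_subjects": list(self.val_subjects),
        }
        with open(path, "w", encoding="utf-8") as f:
            json.dump(payload, f, sort_keys=True, separators=(",", ":"))
        return str(path)

    @classmethod
    def load(cls, path) -> "TrainedStager":
        with open(path, "r", encoding="utf-8") as f:
            d = json.load(f)
        if d.get("format") != "somnoscore-stager-v1":
            raise IOError(f"{path}: not a somnoscore stager bundle")
        return cls(
            variant=d["variant"],
            params={k: np.asarray(v, dtype=np.float64) for k, v in d["params"].items()},
            feature_mean=np.asarray(d["feature_mean"], dtype=np.float64),
            feature_sd=np.asarray(d["feature_sd"], dtype=np.float64),
            layout_fingerprint=d["layout_fingerprint"],
            config=StagerConfig(**d["config"]),
            validation_kappa=d["validation_kappa"],
            loss_history=list(d["loss_history"]),
            train_subjects=tuple(d["train_subjects"]),
            val_subjects=tuple(d["val_subjects"]),
        )


def _coerce_xy(features, labels) -> tuple[np.ndarray, np.ndarray, str]:
    X = features.matrix if isinstance(features, FeatureSet) else np.asarray(features, float)
    fp = features.layout_fingerprint if isinstance(features, FeatureSet) else ""
    y = labels.to_indices() if isinstance(labels, Hypnogram) else np.asarray(labels, np.int64)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} feature rows vs {y.shape[0]} labels")
    return X, y, fp


def train_stager(
    train_subjects: dict[str, tuple],
    config: StagerConfig = StagerConfig(),
    val_subjects: dict[str, tuple] | None = None,
) -> TrainedStager:
    """Train one classifier variant on per-subject (features, labels) pairs.

    ``train_subjects`` / ``val_subjects`` map subject id to a
    (FeatureSet-or-array, Hypnogram-or-label-array) pair. The recorded
    validation κ pools epochs over the validation subjects (over the training
    subjects when no validation set is supplied, flagged in the log).
    """
    if not train_subjects:
        raise ValueError("no training subjects")
    data = {}
    fingerprints = set()
    for sid, (feats, labels) in train_subjects.items():
        X, y, fp = _coerce_xy(feats, labels)
        data[sid] = (X, y)
        fingerprints.add(fp)
    if len(fingerprints) > 1:
        raise ConfigurationError(f"feature layouts differ across subjects: {fingerprints}")
    fingerprint = next(iter(fingerprints))

    all_y = np.concatenate([y for _, y in data.values()])
    if np.unique(all_y).size < 2:
        raise ValueError("training labels cover a single stage; nothing to discriminate")
    all_X = np.vstack([X for X, _ in data.values()])
    mean = all_X.mean(axis=0)
    sd = all_X.std(axis=0)
    sd[sd < 1e-12] = 1.0

    counts = np.bincount(all_y, minlength=5).astype(float)
    if config.class_weighting == "inverse_freq":
        with np.errstate(divide="ignore"):
            w = np.where(counts > 0, all_y.size / (5.0 * np.maximum(counts, 1)), 0.0)
    else:
        w = np.ones(5)

    n_features = all_X.shape[1]
    net = _build_net(config.variant, n_features, config)
    rng = np.random.default_rng(int(config.seed) % 2**31)
    params = net.init(rng)
    opt = _Adam(params, config.lr)

    std = {sid: ((X - mean) / sd, y) for sid, (X, y) in data.items()}
    history: list[float] = []
    order_ids = sorted(std)
    if net.recurrent:
        chunks = []
        for sid in order_ids:
            X, y = std[sid]
            for s in range(0, X.shape[0], config.context_len):
                xc, yc = X[s : s + config.context_len], y[s : s + config.context_len]
                if xc.shape[0] >= 1:
                    chunks.append((xc, yc))
        for it in range(config.train_epochs):
            perm = rng.permutation(len(chunks))
            total, nb = 0.0, 0
            for ci in perm:
                xc, yc = chunks[ci]
                loss, grads = net.loss_grads(params, xc, yc, w)
                opt.step(params, grads)
                total += loss
                nb += 1
            history.append(total / nb)
    else:
        Xa = np.vstack([std[sid][0] for sid in order_ids])
        ya = np.concatenate([std[sid][1] for sid in order_ids])
        batch = 256
        for it in range(config.train_epochs):
            perm = rng.permutation(ya.size)
            total, nb = 0.0, 0
            for s in range(0, ya.size, batch):
                sel = perm[s : s + batch]
                loss, grads = net.loss_grads(params, Xa[sel], ya[sel], w)
                opt.step(params, grads)
                total += loss
                nb += 1
            history.append(total / nb)
    logger.info("trained %s: loss %.4f -> %.4f", config.variant, history[0], history[-1])

    model = TrainedStager(
        variant=config.variant,
        params=params,
        feature_mean=mean,
        feature_sd=sd,
        layout_fingerprint=fingerprint,
        config=config,
        train_subjects=tuple(sorted(train_subjects)),
        val_subjects=tuple(sorted(val_subjects)) if val_subjects else (),
    )
    eval_set = val_subjects if val_subjects else train_subjects
    if not val_subjects:
        logger.warning("no validation subjects; recording kappa on training data")
    model.validation_kappa = _pooled_kappa(model, eval_set)
    model.loss_history = history
    return model


def _pooled_kappa(model: "TrainedStager", subjects: dict[str, tuple]) -> float:
    refs, preds = [], []
    for sid, (feats, labels) in subjects.items():
        X, y, _ = _coerce_xy(feats, labels)
        h = predict_hypnogram(model, feats)
        refs.extend(Hypnogram.from_indices(y).labels)
        preds.extend(h.labels)
    return cohens_kappa(confusion_matrix(Hypnogram(tuple(refs)), Hypnogram(tuple(preds))))


def predict_hypnogram(model: TrainedStager, features) -> Hypnogram:
    """Score a night: one stage per input epoch, argmax with fixed-order tie-break."""
    X = features.matrix if isinstance(features, FeatureSet) else np.asarray(features, float)
    if isinstance(features, FeatureSet) and model.layout_fingerprint and features.layout_fingerprint != model.layout_fingerprint:
        raise ConfigurationError(
            "feature layout fingerprint mismatch: model "
            f"{model.layout_fingerprint} vs features {features.layout_fingerprint}"
        )
    if X.shape[0] == 0:
        return Hypnogram(())
    if X.shape[1] != model.feature_mean.size:
        raise ConfigurationError(
            f"model expects {model.feature_mean.size} features, got {X.shape[1]}"
        )
    net = _build_net(model.variant, X.shape[1], model.config)
    Z = (X - model.feature_mean) / model.feature_sd
    logits = net.predict_logits(model.params, Z)
    # np.argmax already breaks ties by the first (fixed-order) index
    return Hypnogram.from_indices(np.argmax(logits, axis=1))


def select_best_model(candidates: list[TrainedStager]) -> TrainedStager:
    """Highest validation κ wins; ties go to fewer parameters, then earlier registration."""
    if not candidates:
        raise ValueError("no candidate models")
    for m in candidates:
        if np.isnan(m.validation_kappa):
            raise ValueError(f"candidate {m.variant!r} lacks a recorded validation kappa")
    best = min(
        range(len(candidates)),
        key=lambda i: (-candidates[i].validation_kappa, candidates[i].n_parameters, i),
    )
    return candidates[best]


def apply_continuity_smoothing(h: Hypnogram) -> Hypnogram:
    """Relabel isolated single-epoch N1 intrusions flanked by the same stage S ∈ {N2, R}.

    Mirrors the scoring-manual continuity convention that a lone
    low-amplitude mixed-frequency epoch inside an established N2 or REM run
    keeps the surrounding stage. Idempotent; every other label is untouched.
    """
    labels = list(h.labels)
    out = list(labels)
    for i in range(1, len(labels) - 1):
        if (
            labels[i] is StageLabel.N1
            and labels[i - 1] is labels[i + 1]
            and labels[i - 1] in (StageLabel.N2, StageLabel.R)
        ):
            out[i] = labels[i - 1]
    return Hypnogram(tuple(out), h.epoch_len_s)


def majority_class_baseline_kappa(subjects: dict[str, tuple]) -> float:
    """κ of always predicting the overall most frequent stage (≈0 by construction)."""
    ys = np.concatenate([_coerce_xy(f, l)[1] for f, l in subjects.values()])
    mode = np.bincount(ys, minlength=5).argmax()
    ref = Hypnogram.from_indices(ys)
    pred = Hypnogram.from_indices(np.full(ys.size, mode))
    return cohens_kappa(confusion_matrix(ref, pred))
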