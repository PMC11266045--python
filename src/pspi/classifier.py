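"""The recurrent small-protein classifier.

Architecture: the padded one-hot block is reshaped to ``max_len`` time
steps of 20 channels and run through an LSTM whose final hidden state is
the sequence summary (16/32/64/128 units; default 128).  The gapped-mer
count block bypasses the recurrence and is concatenated with the summary;
the concatenation passes through dropout (default rate 0.25) and a single
dense unit with a sigmoid, yielding one score in [0, 1].  A sequence is
called positive when its score is at or above the decision threshold
(default 0.75).

The network is implemented directly on numpy: forward pass, full
backpropagation through time, inverted dropout and Adam.  Conventions
follow common recurrent-layer practice: gate order (input, forget, cell,
output), Glorot-uniform input weights, orthogonal recurrent weights, zero
biases with the forget-gate bias at 1.  Padding positions are all-zero
input vectors and are not masked.  Training minimizes binary cross-entropy;
all randomness (init, batch order, dropout masks) flows from one seed, so a
fixed seed reproduces the training log and weights bit-for-bit.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from pspi.features import FeatureConfig, NkSpec, featurize_batch


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    ``recurrent_units`` (grid 16/32/64/128) is the width of the LSTM
    summary vector; ``dropout_rate`` (grid 0.25/0.5) applies to the
    concatenated summary+count vector during training only; ``threshold``
    is the positive-call cutoff on the sigmoid score.
    """

    recurrent_units: int = 128
    dropout_rate: float = 0.25
    threshold: float = 0.75
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in (0, 1)")
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must be in [0, 1]")
        if self.recurrent_units <= 0:
            raise ValueError("recurrent_units must be positive")
        if not self.feature_config.use_onehot:
            raise ValueError(
                "the recurrent layer consumes the one-hot block; "
                "feature_config.use_onehot must be True"
            )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _orthogonal(rows: int, cols: int, rng: np.random.Generator) -> np.ndarray:
    a = rng.standard_normal((rows, cols))
    q, r = np.linalg.qr(a if rows >= cols else a.T)
    q = q * np.sign(np.diag(r))
    return q if rows >= cols else q.T


class _Params:
    """LSTM + dense weights. Gate order along the 4U axis: i, f, g, o."""

    NAMES = ("Wx", "Wh", "b", "Wd", "bd")

    def __init__(self, units: int, count_dim: int, rng: np.random.Generator):
        U, D = units, 20
        lim = np.sqrt(6.0 / (D + U))
        self.Wx = rng.uniform(-lim, lim, size=(D, 4 * U))
        self.Wh = np.concatenate(
            [_orthogonal(U, U, rng) for _ in range(4)], axis=1
        )
        self.b = np.zeros(4 * U)
        self.b[U : 2 * U] = 1.0  # unit forget-gate bias
        dense_in = U + count_dim
        lim_d = np.sqrt(6.0 / (dense_in + 1))
        self.Wd = rng.uniform(-lim_d, lim_d, size=(dense_in, 1))
        self.bd = np.zeros(1)

    def as_list(self) -> list[np.ndarray]:
        return [getattr(self, n) for n in self.NAMES]


@dataclass
class TrainedModel:
    """A fitted classifier: config, weights, and the per-epoch loss log."""

    config: ModelConfig
    parameters: _Params
    training_log: list[float] = field(default_factory=list)

    @property
    def is_fitted(self) -> bool:
        return len(self.training_log) > 0


def build_model(config: ModelConfig | None = None) -> TrainedModel:
    """Initialize an untrained model (deterministic under ``config.seed``)."""
    if config is None:
        config = ModelConfig()
    rng = np.random.default_rng(config.seed)
    params = _Params(config.recurrent_units, config.feature_config.count_dim, rng)
    return TrainedModel(config=config, parameters=params, training_log=[])


def n_parameters(model: TrainedModel) -> int:
    return sum(p.size for p in model.parameters.as_list())


def _split_blocks(X: np.ndarray, cfg: FeatureConfig, units: int):
    """(N, dim) feature matrix -> (N, T, 20) sequence + (N, count_dim)."""
    N = X.shape[0]
    seq = X[:, : cfg.onehot_dim].reshape(N, cfg.max_len, 20)
    counts = X[:, cfg.onehot_dim :]
    return seq, counts


def _forward(params: _Params, seq: np.ndarray, counts: np.ndarray,
             cache: bool = False):
    """LSTM over T steps, concat counts, dense sigmoid.  Returns (p, cache)."""
    N, T, _ = seq.shape
    U = params.Wh.shape[0]
    xp = seq.reshape(N * T, -1) @ params.Wx
    xp = xp.reshape(N, T, 4 * U)
    h = np.zeros((N, U))
    c = np.zeros((N, U))
    steps = [] if cache else None
    for t in range(T):
        z = xp[:, t] + h @ params.Wh + params.b
        i = _sigmoid(z[:, :U])
        f = _sigmoid(z[:, U : 2 * U])
        g = np.tanh(z[:, 2 * U : 3 * U])
        o = _sigmoid(z[:, 3 * U :])
        c_prev = c
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h_prev = h
        h = o * tc
        if cache:
            steps.append((i, f, g, o, c_prev, tc, h_prev))
    concat = np.concatenate([h, counts], axis=1)
    logit = concat @ params.Wd + params.bd
    p = _sigmoid(logit[:, 0])
    return p, (steps, concat, seq) if cache else None


def _backward(params: _Params, p: np.ndarray, y: np.ndarray, cache,
              drop_mask: np.ndarray | None) -> dict[str, np.ndarray]:
    """Gradients of mean BCE w.r.t. all parameters (full BPTT)."""
    steps, concat, seq = cache
    N, T, _ = seq.shape
    U = params.Wh.shape[0]
    if drop_mask is not None:
        concat = concat * drop_mask
    dlogit = ((p - y) / N)[:, None]            # dL/dlogit, mean-BCE
    gWd = concat.T @ dlogit
    gbd = dlogit.sum(axis=0)
    dconcat = dlogit @ params.Wd.T
    if drop_mask is not None:
        dconcat = dconcat * drop_mask
    dh = dconcat[:, :U]
    dc = np.zeros((N, U))
    gWx = np.zeros_like(params.Wx)
    gWh = np.zeros_like(params.Wh)
    gb = np.zeros_like(params.b)
    dz_all = np.empty((N, T, 4 * U))
    for t in range(T - 1, -1, -1):
        i, f, g, o, c_prev, tc, h_prev = steps[t]
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g),
             do * o * (1 - o)], axis=1
        )
        dz_all[:, t] = dz
        gWh += h_prev.T @ dz
        gb += dz.sum(axis=0)
        dh = dz @ params.Wh.T
        dc = dc * f
    gWx = seq.reshape(N * T, -1).T @ dz_all.reshape(N * T, -1)
    return {"Wx": gWx, "Wh": gWh, "b": gb, "Wd": gWd, "bd": gbd}


class _Adam:
    def __init__(self, params: _Params, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {n: np.zeros_like(getattr(params, n)) for n in _Params.NAMES}
        self.v = {n: np.zeros_like(getattr(params, n)) for n in _Params.NAMES}

    def step(self, params: _Params, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for n in _Params.NAMES:
            g = grads[n]
            self.m[n] = self.b1 * self.m[n] + (1 - self.b1) * g
            self.v[n] = self.b2 * self.v[n] + (1 - self.b2) * g * g
            update = (self.m[n] / bc1) / (np.sqrt(self.v[n] / bc2) + self.eps)
            setattr(params, n, getattr(params, n) - self.lr * update)


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def train(
    peptides: list[str],
    labels: np.ndarray | list[int],
    config: ModelConfig | None = None,
    model: TrainedModel | None = None,
) -> TrainedModel:
    """Fit the classifier on labeled peptides.

    Requires both classes present and every peptide within
    ``feature_config.max_len`` residues.  With a fixed ``config.seed`` two
    runs on the same data produce identical training logs and weights.
    """
    if config is None:
        config = model.config if model is not None else ModelConfig()
    y = np.asarray(labels, dtype=np.float64)
    if len(peptides) != len(y):
        raise ValueError("peptides and labels differ in length")
    if len(set(y.tolist())) < 2:
        raise ValueError("training requires both classes present")
    cfg = config.feature_config
    for idx, p in enumerate(peptides):
        if len(p) > cfg.max_len:
            raise ValueError(
                f"peptide #{idx} has length {len(p)} > max_len {cfg.max_len}"
            )
    if model is None:
        model = build_model(config)
    X = featurize_batch(peptides, cfg)
    seq, counts = _split_blocks(X, cfg, config.recurrent_units)
    N = X.shape[0]
    rng = np.random.default_rng(config.seed + 1)
    opt = _Adam(model.parameters, config.learning_rate)
    keep = 1.0 - config.dropout_rate
    for epoch in range(config.epochs):
        order = rng.permutation(N)
        losses = []
        for start in range(0, N, config.batch_size):
            idx = order[start : start + config.batch_size]
            bseq, bcounts, by = seq[idx], counts[idx], y[idx]
            mask = (rng.random((len(idx), model.parameters.Wd.shape[0]))
                    < keep) / keep
            p, cache = _forward(model.parameters, bseq, bcounts, cache=True)
            # recompute the dense head with the dropout mask applied
            dropped = cache[1] * mask
            logit = dropped @ model.parameters.Wd + model.parameters.bd
            p = _sigmoid(logit[:, 0])
            losses.append(_bce(p, by) * len(idx))
            grads = _backward(model.parameters, p, by, cache, mask)
            opt.step(model.parameters, grads)
        model.training_log.append(sum(losses) / N)
    return model


def score(model: TrainedModel, peptides: list[str]) -> np.ndarray:
    """Sigmoid scores in [0, 1], one per peptide; no dropout at inference.

    Each peptide's score depends only on the model weights and that
    peptide, never on what else is in the batch.
    """
    cfg = model.config.feature_config
    for idx, p in enumerate(peptides):
        if len(p) > cfg.max_len:
            raise ValueError(
                f"peptide #{idx} has length {len(p)} > max_len {cfg.max_len}"
            )
    if not peptides:
        return np.zeros(0)
    X = featurize_batch(peptides, cfg)
    seq, counts = _split_blocks(X, cfg, model.config.recurrent_units)
    out = []
    for start in range(0, len(peptides), 256):
        p, _ = _forward(model.parameters, seq[start : start + 256],
                        counts[start : start + 256])
        out.append(p)
    return np.concatenate(out)


def classify(scores: np.ndarray | list[float], threshold: float = 0.75) -> np.ndarray:
    """Binary calls: positive iff score >= threshold (closed at the cutoff)."""
    s = np.asarray(scores, dtype=np.float64)
    if s.size and (s.min() < 0 or s.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    return (s >= threshold).astype(np.int64)


def _config_to_json(config: ModelConfig) -> str:
    d = asdict(config)
    d["feature_config"]["specs"] = [
        [s.n, s.k] for s in config.feature_config.specs
    ]
    return json.dumps(d)


def _config_from_json(text: str) -> ModelConfig:
    d = json.loads(text)
    fc = d.pop("feature_config")
    fc["specs"] = tuple(NkSpec(n, k) for n, k in fc["specs"])
    return ModelConfig(feature_config=FeatureConfig(**fc), **d)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model as a single self-describing zip archive."""
    buf = io.BytesIO()
    np.savez(buf, **{n: getattr(model.parameters, n) for n in _Params.NAMES})
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", _config_to_json(model.config))
        zf.writestr("training_log.json", json.dumps(model.training_log))
        zf.writestr("weights.npz", buf.getvalue())


def load_model(path: str | Path) -> TrainedModel:
    """Load a model saved by :func:`save_model`; scores identically."""
    try:
        with zipfile.ZipFile(path) as zf:
            config = _config_from_json(zf.read("config.json").decode())
            log = json.loads(zf.read("training_log.json").decode())
            with zf.open("weights.npz") as fh:
                weights = np.load(io.BytesIO(fh.read()))
                arrays = {n: weights[n] for n in _Params.NAMES}
    except (zipfile.BadZipFile, KeyError) as e:
        raise ValueError(f"cannot load model from {path}: {e}") from e
    model = build_model(config)
    expected = {n: getattr(model.parameters, n).shape for n in _Params.NAMES}
    for n, arr in arrays.items():
        if arr.shape != expected[n]:
            raise ValueError(
                f"weight {n!r} has shape {arr.shape}, expected {expected[n]} "
                "for this config (feature dimension mismatch?)"
            )
        setattr(model.parameters, n, arr)
    model.training_log = log
    return model
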