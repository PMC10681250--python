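"""Many-to-one recurrent classifier for variable-length review sequences.

A compact LSTM implemented directly in numpy: a linear input map, one
recurrent layer of LSTM units (hidden size 50, dropout 0.4 on the final
hidden state), and a linear softmax output over the two outcome classes.
Trained with minibatch Adam on the cross-entropy loss, with early stopping
on validation accuracy.  Every client contributes one training example per
observed prefix (sharing the end-of-treatment label), so a single model
answers at every review period.

Backpropagation through time is written out by hand and covered by a
finite-difference gradient check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from icbt_dynamics.features import FeatureSet, Instrument, build_sequence_features, truncate_to_prefix
from icbt_dynamics.labeling import OutcomeLabel
from icbt_dynamics.records import ClientRecord


class TrainingFailureError(RuntimeError):
    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


@dataclass(frozen=True)
class RnnConfig:
    hidden_dim: int = 50
    projection_dim: int = 32
    dropout: float = 0.4
    learning_rate: float = 5e-3
    batch_size: int = 128
    max_epochs: int = 60
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if min(self.hidden_dim, self.projection_dim, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("hidden_dim, projection_dim, batch_size, max_epochs must be positive")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _Params(dict):
    """Named parameter arrays with elementwise arithmetic for Adam."""


class RecurrentClassifier:
    """Trained LSTM handle; maps any feature-sequence prefix to P(RI)."""

    def __init__(
        self,
        config: RnnConfig,
        feature_set: FeatureSet,
        target_instrument: Instrument,
        input_dim: int,
        n_interaction_types: int = 1133,
        include_both_totals: bool = False,
    ):
        self.config = config
        self.feature_set = feature_set
        self.target_instrument = target_instrument
        self.input_dim = input_dim
        self.n_interaction_types = n_interaction_types
        self.include_both_totals = include_both_totals
        self.feature_mean = np.zeros(input_dim)
        self.feature_scale = np.ones(input_dim)
        rng = np.random.default_rng(config.seed)
        P, H, D = config.projection_dim, config.hidden_dim, input_dim
        s = lambda *shape: rng.normal(0.0, 0.1, size=shape)
        self.params = _Params(
            Wp=s(D, P), bp=np.zeros(P),
            Wx=s(P, 4 * H), Wh=s(H, 4 * H), b=np.zeros(4 * H),
            Wo=s(H, 2), bo=np.zeros(2),
        )
        # forget-gate bias starts positive so memory persists early in training
        self.params["b"][H:2 * H] = 1.0
        self.history: list[float] = []

    # ------------------------------------------------------------------
    # forward / backward

    def _forward(
        self,
        x: np.ndarray,
        lengths: np.ndarray,
        dropout_rng: np.random.Generator | None = None,
    ):
        """Forward pass on a padded batch (B, T, D); returns probabilities
        and, when training, a cache for backpropagation."""
        p = self.params
        B, T, _ = x.shape
        H = self.config.hidden_dim
        xs = (x - self.feature_mean) / self.feature_scale
        proj = xs @ p["Wp"] + p["bp"]

        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        h_final = np.zeros((B, H))
        for t in range(T):
            z = proj[:, t] @ p["Wx"] + h @ p["Wh"] + p["b"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            steps.append((proj[:, t].copy(), h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
            ending = lengths - 1 == t
            if ending.any():
                h_final[ending] = h[ending]

        if dropout_rng is not None and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            mask = dropout_rng.random(h_final.shape) < keep
            h_drop = h_final * mask / keep
        else:
            mask = None
            h_drop = h_final
        logits = h_drop @ p["Wo"] + p["bo"]
        logits -= logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        probs = expl / expl.sum(axis=1, keepdims=True)
        cache = (xs, steps, lengths, h_final, h_drop, mask, probs)
        return probs, cache

    def _backward(self, cache, y: np.ndarray) -> _Params:
        p = self.params
        xs, steps, lengths, h_final, h_drop, mask, probs = cache
        B, T, _ = xs.shape
        H = self.config.hidden_dim
        grads = _Params({k: np.zeros_like(v) for k, v in p.items()})

        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads["Wo"] = h_drop.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dh_final = dlogits @ p["Wo"].T
        if mask is not None:
            dh_final = dh_final * mask / (1.0 - self.config.dropout)

        dproj = np.zeros((B, T, self.config.projection_dim))
        dh = np.zeros((B, H))
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            proj_t, h_prev, c_prev, i, f, g, o, c_new = steps[t]
            ending = lengths - 1 == t
            if ending.any():
                dh[ending] += dh_final[ending]
            tc = np.tanh(c_new)
            do = dh * tc
            dct = dc + dh * o * (1.0 - tc**2)
            di = dct * g
            dg = dct * i
            df = dct * c_prev
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            grads["Wx"] += proj_t.T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dproj[:, t] = dz @ p["Wx"].T
            dh = dz @ p["Wh"].T
            dc = dct * f

        grads["Wp"] = np.einsum("btd,btp->dp", xs, dproj)
        grads["bp"] = dproj.sum(axis=(0, 1))
        return grads

    def _loss(self, probs: np.ndarray, y: np.ndarray) -> float:
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))

    # ------------------------------------------------------------------
    # public API

    def predict_proba_sequence(self, vectors: np.ndarray) -> float:
        """P(reliable improvement) from one (t, dim) prefix of features."""
        x = vectors[None, :, :]
        lengths = np.array([vectors.shape[0]])
        probs, _ = self._forward(x, lengths, dropout_rng=None)
        return float(probs[0, 1])

    def predict_at_time(self, record: ClientRecord, t: int) -> float:
        """Probability of end-of-treatment RI given reviews 1..t only."""
        feats = build_sequence_features(
            record,
            self.feature_set,
            self.target_instrument,
            n_interaction_types=self.n_interaction_types,
            include_both_totals=self.include_both_totals,
        )
        prefix = truncate_to_prefix(feats, t)
        return self.predict_proba_sequence(prefix.vectors)


def _prefix_examples(
    records: Sequence[ClientRecord],
    labels: Mapping[str, OutcomeLabel],
    feature_set: FeatureSet,
    target_instrument: Instrument,
    n_interaction_types: int,
    include_both_totals: bool,
) -> tuple[list[np.ndarray], np.ndarray]:
    xs: list[np.ndarray] = []
    ys: list[int] = []
    for r in records:
        lab = labels[r.client_id]
        y = int(lab.ri_phq if target_instrument == "phq9" else lab.ri_gad)
        feats = build_sequence_features(
            r, feature_set, target_instrument,
            n_interaction_types=n_interaction_types,
            include_both_totals=include_both_totals,
        )
        for t in range(1, len(feats) + 1):
            xs.append(feats.vectors[:t])
            ys.append(y)
    return xs, np.asarray(ys, dtype=int)


def _pad(seqs: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([s.shape[0] for s in seqs])
    T = int(lengths.max())
    x = np.zeros((len(seqs), T, seqs[0].shape[1]))
    for i, s in enumerate(seqs):
        x[i, : s.shape[0]] = s
    return x, lengths


def train_rnn(
    train: tuple[Sequence[ClientRecord], Mapping[str, OutcomeLabel]],
    validation: tuple[Sequence[ClientRecord], Mapping[str, OutcomeLabel]],
    feature_set: FeatureSet,
    target_instrument: Instrument,
    config: RnnConfig | None = None,
    n_interaction_types: int = 1133,
    include_both_totals: bool = False,
) -> RecurrentClassifier:
    """Train the LSTM on all observed prefixes; early-stop on validation
    accuracy; deterministic given ``config.seed``."""
    config = config or RnnConfig()
    train_records, train_labels = train
    val_records, val_labels = validation
    if len(train_records) == 0:
        raise ValueError("empty training set")

    xs, ys = _prefix_examples(
        train_records, train_labels, feature_set, target_instrument,
        n_interaction_types, include_both_totals,
    )
    xv, yv = _prefix_examples(
        val_records, val_labels, feature_set, target_instrument,
        n_interaction_types, include_both_totals,
    )
    dims = {s.shape[1] for s in xs} | {s.shape[1] for s in xv}
    if len(dims) != 1:
        raise ValueError(f"inconsistent feature dimensions: {sorted(dims)}")

    model = RecurrentClassifier(
        config, feature_set, target_instrument,
        input_dim=dims.pop(),
        n_interaction_types=n_interaction_types,
        include_both_totals=include_both_totals,
    )
    pooled = np.concatenate(xs, axis=0)
    model.feature_mean = pooled.mean(axis=0)
    model.feature_scale = np.maximum(pooled.std(axis=0), 1e-6)

    rng = np.random.default_rng(config.seed + 1)
    adam_m = {k: np.zeros_like(v) for k, v in model.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    xval, lval = _pad(xv) if len(xv) else (None, None)
    best_acc, best_params, since_best = -1.0, None, 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(xs))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            xb, lb = _pad([xs[i] for i in batch])
            yb = ys[batch]
            probs, cache = model._forward(xb, lb, dropout_rng=rng)
            loss = model._loss(probs, yb)
            if not np.isfinite(loss):
                raise TrainingFailureError("training loss diverged", model.history)
            grads = model._backward(cache, yb)
            step += 1
            for k in model.params:
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * grads[k]
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * grads[k] ** 2
                mhat = adam_m[k] / (1 - beta1**step)
                vhat = adam_v[k] / (1 - beta2**step)
                model.params[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
            epoch_loss += loss
            n_batches += 1
        model.history.append(epoch_loss / max(n_batches, 1))

        if xval is not None:
            probs, _ = model._forward(xval, lval, dropout_rng=None)
            acc = float(np.mean((probs[:, 1] >= 0.5).astype(int) == yv))
            if acc > best_acc:
                best_acc, since_best = acc, 0
                best_params = {k: v.copy() for k, v in model.params.items()}
            else:
                since_best += 1
                if since_best >= config.patience:
                    break

    if best_params is not None:
        model.params.update(best_params)
    return model
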