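"""Stacked LSTM sequence classifier in pure numpy.

The recurrence per unit layer is the standard gated cell

    f_t = sigma(W_f x_t + U_f h_{t-1} + b_f)
    i_t = sigma(W_i x_t + U_i h_{t-1} + b_i)
    o_t = sigma(W_o x_t + U_o h_{t-1} + b_o)
    c_t = f_t * c_{t-1} + i_t * tanh(W_c x_t + U_c h_{t-1} + b_c)
    h_t = o_t * tanh(c_t)

with logistic-sigmoid gates and tanh cell/output activations; ``*`` is the
element-wise product.  Layers are stacked by feeding layer l's hidden state
as layer l+1's input; a single affine+sigmoid head maps the top hidden
state to a per-hour probability of the admission developing septic shock.

Training minimises class-weighted binary cross-entropy (positive hours
weighted ``positive_weight`` times higher) with Adam, inverted dropout on
the non-recurrent (inter-layer) connections only, optional variational
recurrent dropout, global-norm gradient clipping, and back-propagation
through time written out by hand.  Everything is deterministic given the
seed (and a fixed BLAS thread count).

Default hyperparameters are the full-scale configuration: four layers of
100 units, dropout 0.4, 1,000 epochs of 40 mini-batches x 50 samples,
positive weight 3.  ``ModelConfig.desk_scale()`` is a small preset
(2 layers x 16 units, 30 epochs) for tests and laptop runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence as Seq

import numpy as np
import pandas as pd
from scipy.special import expit as _sigmoid

CHECKPOINT_FORMAT_VERSION = 1
#: packed gate order along the last axis of W, U, b
GATE_ORDER = ("i", "f", "c", "o")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    n_layers: int = 4
    units_per_layer: int = 100
    dropout_p: float = 0.4
    recurrent_dropout_p: float = 0.0
    epochs: int = 1000
    #: random mini-batches per epoch; None = one full shuffled pass
    batches_per_epoch: Optional[int] = 40
    batch_size: int = 50
    positive_weight: float = 3.0
    learning_rate: float = 1e-3
    clip_norm: float = 5.0
    val_interval: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.positive_weight <= 0:
            raise ValueError("positive_weight must be positive")

    @classmethod
    def desk_scale(cls, **overrides) -> "ModelConfig":
        """Small preset: 2 layers x 16 units, 30 full-pass epochs."""
        base = dict(n_layers=2, units_per_layer=16, dropout_p=0.2,
                    epochs=30, batches_per_epoch=None, batch_size=32,
                    learning_rate=5e-3)
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# single-cell reference operations
# ---------------------------------------------------------------------------

@dataclass
class LSTMCellWeights:
    """Per-gate weights of one cell layer (reference layout)."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_o: np.ndarray
    W_c: np.ndarray
    U_f: np.ndarray
    U_i: np.ndarray
    U_o: np.ndarray
    U_c: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    def __post_init__(self):
        units = self.W_f.shape[1]
        for g in ("f", "i", "o", "c"):
            W, U, b = (getattr(self, f"{n}_{g}") for n in ("W", "U", "b"))
            if W.shape != self.W_f.shape or U.shape != (units, units) \
                    or b.shape != (units,):
                raise ValueError(f"inconsistent shapes for gate {g!r}")
        if not all(np.isfinite(v).all() for v in vars(self).values()):
            raise ValueError("non-finite weight entries")

    @classmethod
    def from_packed(cls, W: np.ndarray, U: np.ndarray, b: np.ndarray
                    ) -> "LSTMCellWeights":
        """Split packed (input_dim x 4H, H x 4H, 4H) arrays, gate order
        ``GATE_ORDER``."""
        H = U.shape[0]
        parts = {g: i for i, g in enumerate(GATE_ORDER)}
        def chunk(a, g):
            return a[..., parts[g] * H:(parts[g] + 1) * H]
        return cls(
            W_f=chunk(W, "f"), W_i=chunk(W, "i"), W_o=chunk(W, "o"),
            W_c=chunk(W, "c"),
            U_f=chunk(U, "f"), U_i=chunk(U, "i"), U_o=chunk(U, "o"),
            U_c=chunk(U, "c"),
            b_f=chunk(b, "f"), b_i=chunk(b, "i"), b_o=chunk(b, "o"),
            b_c=chunk(b, "c"),
        )


@dataclass
class LSTMState:
    c: np.ndarray
    h: np.ndarray

    @classmethod
    def zeros(cls, units: int) -> "LSTMState":
        return cls(np.zeros(units), np.zeros(units))


def lstm_cell_step(x_t: np.ndarray, prev: LSTMState,
                   w: LSTMCellWeights) -> LSTMState:
    """One cell update, evaluated gate by gate (reference path).

    The vectorized stack cross-checks against this in the test suite.
    """
    if x_t.shape[-1] != w.W_f.shape[0]:
        raise ValueError(
            f"input dim {x_t.shape[-1]} != weight rows {w.W_f.shape[0]}")
    f = _sigmoid(x_t @ w.W_f + prev.h @ w.U_f + w.b_f)
    i = _sigmoid(x_t @ w.W_i + prev.h @ w.U_i + w.b_i)
    o = _sigmoid(x_t @ w.W_o + prev.h @ w.U_o + w.b_o)
    c = f * prev.c + i * np.tanh(x_t @ w.W_c + prev.h @ w.U_c + w.b_c)
    h = o * np.tanh(c)
    return LSTMState(c, h)


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class Sequence:
    """One admission's model input: standardized hours-by-features matrix
    and the admission-level outcome (positives truncated at shock onset by
    the caller, so post-onset hours never leak in)."""

    admission_id: str
    X: np.ndarray  # (T, F)
    label: bool


@dataclass
class PredictionSeries:
    admission_id: str
    probs: np.ndarray  # (T,), in [0, 1]

    @property
    def admission_score(self) -> float:
        """Maximum per-hour probability: the alarm-semantics summary."""
        return float(np.max(self.probs))

    def first_alarm(self, threshold: float) -> Optional[int]:
        idx = np.nonzero(self.probs >= threshold)[0]
        return int(idx[0]) if len(idx) else None


def _pad(batch: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pad variable-length (T,F) arrays to (B, T_max, F) + validity mask."""
    B = len(batch)
    T = max(x.shape[0] for x in batch)
    F = batch[0].shape[1]
    X = np.zeros((B, T, F))
    valid = np.zeros((B, T), dtype=bool)
    for b, x in enumerate(batch):
        X[b, :x.shape[0]] = x
        valid[b, :x.shape[0]] = True
    return X, valid


# ---------------------------------------------------------------------------
# the stacked classifier
# ---------------------------------------------------------------------------

class LSTMClassifier:
    """Stacked LSTM with an affine+sigmoid output head.

    Parameters are packed per layer as ``W`` (input_dim x 4H), ``U``
    (H x 4H) and ``b`` (4H) in gate order ``GATE_ORDER``; the head is a
    weight vector ``w_out`` (H) and scalar bias.
    """

    def __init__(self, n_features: int, config: Optional[ModelConfig] = None,
                 feature_names: Optional[list[str]] = None):
        self.config = config or ModelConfig()
        self.n_features = n_features
        self.feature_names = feature_names
        self.rng = np.random.default_rng(self.config.seed)
        self.params: dict[str, np.ndarray] = {}
        self._init_params()
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self.training_log = pd.DataFrame(
            columns=["epoch", "loss", "train_auroc", "val_auroc"])

    # -- initialisation -------------------------------------------------
    def _init_params(self) -> None:
        H = self.config.units_per_layer
        fan_in = self.n_features
        for layer in range(self.config.n_layers):
            limW = np.sqrt(6.0 / (fan_in + H))
            limU = np.sqrt(6.0 / (2 * H))
            self.params[f"W{layer}"] = self.rng.uniform(
                -limW, limW, (fan_in, 4 * H))
            self.params[f"U{layer}"] = self.rng.uniform(
                -limU, limU, (H, 4 * H))
            b = np.zeros(4 * H)
            b[H:2 * H] = 1.0  # forget-gate bias: remember by default
            self.params[f"b{layer}"] = b
            fan_in = H
        self.params["w_out"] = self.rng.uniform(
            -np.sqrt(6.0 / (H + 1)), np.sqrt(6.0 / (H + 1)), H)
        self.params["b_out"] = np.zeros(1)

    def layer_weights(self, layer: int) -> LSTMCellWeights:
        """Per-gate view of one layer (for the reference cell path)."""
        return LSTMCellWeights.from_packed(
            self.params[f"W{layer}"], self.params[f"U{layer}"],
            self.params[f"b{layer}"])

    # -- forward --------------------------------------------------------
    def _forward(self, X: np.ndarray, training: bool = False,
                 rng: Optional[np.random.Generator] = None):
        """Forward over a padded batch (B,T,F); returns probabilities
        (B,T) and, when training, the caches needed for BPTT."""
        if X.shape[-1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[-1]}")
        if not np.isfinite(X).all():
            raise ValueError("input must be dense and finite")
        cfg = self.config
        B, T, _ = X.shape
        H = cfg.units_per_layer
        p_drop = cfg.dropout_p if training else 0.0
        p_rdrop = cfg.recurrent_dropout_p if training else 0.0
        caches = []
        inp = X
        for layer in range(cfg.n_layers):
            W = self.params[f"W{layer}"]
            U = self.params[f"U{layer}"]
            b = self.params[f"b{layer}"]
            if p_drop > 0:
                dmask = (rng.random(inp.shape) >= p_drop) / (1 - p_drop)
                x_used = inp * dmask
            else:
                dmask = None
                x_used = inp
            rmask = None
            if p_rdrop > 0:  # variational: one mask per sequence
                rmask = (rng.random((B, H)) >= p_rdrop) / (1 - p_rdrop)
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            hs = np.zeros((B, T, H))
            cache_t = []
            for t in range(T):
                h_used = h * rmask if rmask is not None else h
                z = x_used[:, t] @ W + h_used @ U + b
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H:2 * H])
                g = np.tanh(z[:, 2 * H:3 * H])
                o = _sigmoid(z[:, 3 * H:])
                c_new = f * c + i * g
                h_new = o * np.tanh(c_new)
                if training:
                    cache_t.append((i, f, g, o, c, c_new, h_used))
                h, c = h_new, c_new
                hs[:, t] = h
            caches.append({"x_used": x_used, "hs": hs, "steps": cache_t,
                           "dmask": dmask, "rmask": rmask})
            inp = hs
        logits = inp @ self.params["w_out"] + self.params["b_out"][0]
        probs = _sigmoid(logits)
        return (probs, caches, inp) if training else probs

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Inference probabilities for one (T,F) sequence or (B,T,F) batch;
        dropout inactive, states start at zero."""
        single = X.ndim == 2
        Xb = X[None] if single else X
        probs = self._forward(np.asarray(Xb, dtype=float), training=False)
        return probs[0] if single else probs

    def predict(self, seqs: Seq[Sequence] | Seq[np.ndarray],
                batch_size: int = 64) -> list[PredictionSeries]:
        """Per-hour probabilities for each admission (pure function of the
        trained weights and inputs)."""
        out = []
        items = [(s.admission_id, s.X) if isinstance(s, Sequence)
                 else (f"seq{i}", s) for i, s in enumerate(seqs)]
        for start in range(0, len(items), batch_size):
            chunk = items[start:start + batch_size]
            X, valid = _pad([x for _, x in chunk])
            probs = self._forward(X, training=False)
            for (aid, x), p in zip(chunk, probs):
                out.append(PredictionSeries(aid, p[: x.shape[0]].copy()))
        return out

    # -- loss and backward ----------------------------------------------
    def _loss_grad(self, probs, y, valid):
        """Weighted BCE over valid hours; returns (loss, dlogits)."""
        w = np.where(y, self.config.positive_weight, 1.0) * valid
        wsum = w.sum()
        p = np.clip(probs, 1e-9, 1 - 1e-9)
        loss = float((-w * (y * np.log(p) + (1 - y) * np.log(1 - p))).sum()
                     / wsum)
        dlogits = w * (probs - y) / wsum
        return loss, dlogits

    def _backward(self, caches, top_h, dlogits):
        cfg = self.config
        H = cfg.units_per_layer
        B, T = dlogits.shape
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["w_out"] = np.einsum("bt,bth->h", dlogits, top_h)
        grads["b_out"] = np.array([dlogits.sum()])
        d_upper = dlogits[..., None] * self.params["w_out"]  # (B,T,H)
        for layer in range(cfg.n_layers - 1, -1, -1):
            cache = caches[layer]
            W = self.params[f"W{layer}"]
            U = self.params[f"U{layer}"]
            x_used = cache["x_used"]
            steps = cache["steps"]
            rmask = cache["rmask"]
            dW = np.zeros_like(W)
            dU = np.zeros_like(U)
            db = np.zeros_like(self.params[f"b{layer}"])
            dx_used = np.zeros_like(x_used)
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                i, f, g, o, c_prev, c_new, h_used = steps[t]
                dh = d_upper[:, t] + dh_next
                tanh_c = np.tanh(c_new)
                do = dh * tanh_c
                dc = dh * o * (1 - tanh_c**2) + dc_next
                di = dc * g
                dg = dc * i
                df = dc * c_prev
                dc_next = dc * f
                dz = np.concatenate(
                    [di * i * (1 - i), df * f * (1 - f),
                     dg * (1 - g**2), do * o * (1 - o)], axis=1)
                dW += x_used[:, t].T @ dz
                dU += h_used.T @ dz
                db += dz.sum(axis=0)
                dx_used[:, t] = dz @ W.T
                dh_prev = dz @ U.T
                if rmask is not None:
                    dh_prev = dh_prev * rmask
                dh_next = dh_prev
            grads[f"W{layer}"] = dW
            grads[f"U{layer}"] = dU
            grads[f"b{layer}"] = db
            if cache["dmask"] is not None:
                d_upper = dx_used * cache["dmask"]
            else:
                d_upper = dx_used
        return grads

    def _adam_update(self, grads):
        cfg = self.config
        norm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
        scale = min(1.0, cfg.clip_norm / (norm + 1e-12))
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            g = g * scale
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g**2
            mhat = self._adam_m[k] / (1 - b1**self._adam_t)
            vhat = self._adam_v[k] / (1 - b2**self._adam_t)
            self.params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

    def train_step(self, batch: list[Sequence],
                   rng: np.random.Generator) -> float:
        """One forward/backward/update on a mini-batch; returns the loss."""
        X, valid = _pad([s.X for s in batch])
        y = np.zeros(valid.shape)
        for b, s in enumerate(batch):
            y[b, valid[b]] = float(s.label)
        probs, caches, top_h = self._forward(X, training=True, rng=rng)
        loss, dlogits = self._loss_grad(probs, y, valid)
        grads = self._backward(caches, top_h, dlogits)
        self._adam_update(grads)
        return loss

    # -- training loop --------------------------------------------------
    def fit(self, train: list[Sequence],
            val: Optional[list[Sequence]] = None,
            progress: bool = False) -> pd.DataFrame:
        """Train on admission sequences; periodic train/val AUROC rows are
        appended to ``self.training_log`` every ``val_interval`` epochs."""
        from .evaluation import roc_and_auroc  # local import; no cycle at load

        cfg = self.config
        labels = [s.label for s in train]
        if not (any(labels) and not all(labels)):
            raise ValueError("training set must contain both classes")
        rng = np.random.default_rng([cfg.seed, 7_919])
        log_rows = []
        for epoch in range(1, cfg.epochs + 1):
            losses = []
            if cfg.batches_per_epoch is None:
                order = rng.permutation(len(train))
                batches = [order[i:i + cfg.batch_size]
                           for i in range(0, len(order), cfg.batch_size)]
            else:
                batches = [rng.integers(0, len(train), cfg.batch_size)
                           for _ in range(cfg.batches_per_epoch)]
            for idx in batches:
                losses.append(self.train_step([train[j] for j in idx], rng))
            if epoch % cfg.val_interval == 0 or epoch == cfg.epochs:
                row = {"epoch": epoch, "loss": float(np.mean(losses)),
                       "train_auroc": self._auroc_of(train, roc_and_auroc),
                       "val_auroc": (self._auroc_of(val, roc_and_auroc)
                                     if val else np.nan)}
                log_rows.append(row)
                if progress:
                    print(f"epoch {epoch}: loss={row['loss']:.4f} "
                          f"train AUROC={row['train_auroc']:.3f} "
                          f"val AUROC={row['val_auroc']:.3f}")
        self.training_log = pd.DataFrame(log_rows)
        return self.training_log

    def _auroc_of(self, seqs, roc_and_auroc) -> float:
        preds = self.predict(seqs)
        scores = np.array([p.admission_score for p in preds])
        labels = np.array([s.label for s in seqs])
        _, auroc = roc_and_auroc(scores, labels)
        return auroc

    # -- persistence ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Versioned checkpoint: weights (npz) + JSON manifest sidecar."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        manifest = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "config": asdict(self.config),
            "n_features": self.n_features,
            "feature_names": self.feature_names,
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "LSTMClassifier":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        if manifest["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError("unsupported checkpoint format version")
        model = cls(manifest["n_features"], ModelConfig(**manifest["config"]),
                    manifest.get("feature_names"))
        with np.load(path.with_suffix(".npz")) as npz:
            model.params = {k: npz[k] for k in npz.files}
        return model
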