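"""Feed-forward network for the transpiration stress factor, trained by
minimising ``1 - KGE`` between predicted and target stress.

The Kling-Gupta efficiency is a set-level score, so the loss is evaluated
over a whole mini-batch at once (batch size 100 by default) and its analytic
gradient with respect to the batch predictions is backpropagated through the
network. The epoch-level objective on the full training and validation sets
drives early stopping: training halts once the validation objective has not
improved for ``patience`` epochs, and the best-epoch weights are restored.

Architecture default: 12 inputs -> 3 hidden layers x 64 ReLU units with
dropout 0.1 -> sigmoid output, which bounds predictions to [0, 1]. Inputs
are z-scored with training-set moments stored in the model bundle. One model
is trained per vegetation class (short / tall) with the same architecture
and training setup. Everything is plain numpy with manual backpropagation
and an Adam optimizer; runs are deterministic given the seed on a single
thread.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .metrics import kge
from .prep import FEATURE_NAMES

__all__ = ["MLPConfig", "TrainedStressModel", "kge_objective", "kge_objective_grad", "train"]

_EPS = 1e-12


@dataclass(frozen=True)
class MLPConfig:
    """Architecture and training hyper-parameters."""

    hidden: tuple[int, ...] = (64, 64, 64)
    dropout: float = 0.1
    learning_rate: float = 0.000142
    batch_size: int = 100
    max_epochs: int = 1000
    train_fraction: float = 0.85
    patience: int = 20
    min_rows: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train fraction must lie in (0, 1)")
        if any(h <= 0 for h in self.hidden) or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("sizes must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")


def feature_schema_hash(names=FEATURE_NAMES) -> str:
    return hashlib.sha256("|".join(names).encode()).hexdigest()[:16]


def kge_objective(pred, target) -> float:
    """Loss ``1 - KGE(pred, target)``; zero iff pred reproduces target."""
    pred = np.asarray(pred, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if pred.size < 2:
        raise ValueError("need at least two points")
    if target.std() == 0:
        raise ValueError("target has zero variance in this evaluation scope")
    return 1.0 - kge(pred, target).kge


def kge_objective_grad(pred, target) -> tuple[float, np.ndarray]:
    """Loss and its analytic gradient with respect to the predictions.

    Uses population moments; denominators are floored at a small epsilon so
    the gradient stays finite for a (near-)constant prediction batch.
    """
    p = np.asarray(pred, dtype=float).ravel()
    t = np.asarray(target, dtype=float).ravel()
    n = p.size
    mp, mt = p.mean(), t.mean()
    sp = max(p.std(), _EPS)
    st = max(t.std(), _EPS)
    pc, tc = p - mp, t - mt
    r = float(np.dot(pc, tc) / (n * sp * st))
    a = sp / st
    b = mp / mt if abs(mt) > _EPS else mp / _EPS
    L = float(np.sqrt((r - 1.0) ** 2 + (a - 1.0) ** 2 + (b - 1.0) ** 2))
    if L < _EPS:
        return L, np.zeros_like(p)
    dr = tc / (n * sp * st) - r * pc / (n * sp**2)
    da = pc / (n * sp * st)
    db = np.full(n, 1.0 / (n * mt) if abs(mt) > _EPS else 1.0 / (n * _EPS))
    grad = ((r - 1.0) * dr + (a - 1.0) * da + (b - 1.0) * db) / L
    return L, grad


class _Net:
    """Weights and forward/backward passes of the small MLP."""

    def __init__(self, sizes: tuple[int, ...], rng: np.random.Generator):
        self.W, self.b = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialisation for the ReLU stack
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    def forward(self, X, dropout: float = 0.0, rng: np.random.Generator | None = None):
        """Returns predictions and the cache needed for backprop."""
        a = X
        cache = []
        n_hidden = len(self.W) - 1
        for i in range(n_hidden):
            z = a @ self.W[i] + self.b[i]
            h = np.maximum(z, 0.0)
            if dropout > 0.0 and rng is not None:
                mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
                h = h * mask
            else:
                mask = None
            cache.append((a, z, mask))
            a = h
        z_out = a @ self.W[-1] + self.b[-1]
        y = expit(z_out)
        cache.append((a, z_out, None))
        return y.ravel(), cache

    def backward(self, dL_dy, cache):
        """Gradients of the loss w.r.t. all weights, given dL/d(output)."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        a_last, z_out, _ = cache[-1]
        y = expit(z_out)
        delta = dL_dy.reshape(-1, 1) * y * (1.0 - y)
        gW[-1] = a_last.T @ delta
        gb[-1] = delta.sum(axis=0)
        upstream = delta @ self.W[-1].T
        for i in range(len(self.W) - 2, -1, -1):
            a_in, z, mask = cache[i]
            d = upstream * (z > 0)
            if mask is not None:
                d = d * mask
            gW[i] = a_in.T @ d
            gb[i] = d.sum(axis=0)
            upstream = d @ self.W[i].T
        return gW, gb

    def params(self):
        return self.W + self.b

    def copy_weights(self):
        return [w.copy() for w in self.W], [b.copy() for b in self.b]

    def set_weights(self, Wb):
        W, b = Wb
        self.W = [w.copy() for w in W]
        self.b = [x.copy() for x in b]


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedStressModel:
    """A trained network plus everything needed to apply it safely: the
    feature schema hash, input standardisation moments, vegetation class,
    configuration and the per-epoch training history."""

    net: _Net
    x_mean: np.ndarray
    x_std: np.ndarray
    veg_class: str
    config: MLPConfig
    schema_hash: str = field(default_factory=feature_schema_hash)
    history: pd.DataFrame | None = None

    def predict(self, X, feature_names=FEATURE_NAMES) -> np.ndarray:
        """Stress predictions in [0, 1] for a (n, 12) batch or a single
        12-vector; pure function of its inputs."""
        if feature_schema_hash(feature_names) != self.schema_hash:
            raise ValueError("feature schema does not match the trained model")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != self.x_mean.size:
            raise ValueError(f"expected {self.x_mean.size} features, got {X.shape[1]}")
        Xs = (X - self.x_mean) / self.x_std
        y, _ = self.net.forward(Xs)
        return float(y[0]) if single else y

    def predict_stress(self, covariates: dict) -> float:
        """Coupler-facing predictor: reads the 12 named features."""
        x = np.array([covariates[name] for name in FEATURE_NAMES], dtype=float)
        return float(self.predict(x))

    # ---- on-disk bundle -------------------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "veg_class": self.veg_class,
            "schema_hash": self.schema_hash,
            "config": asdict(self.config),
            "feature_names": list(FEATURE_NAMES),
        }
        (d / "model.json").write_text(json.dumps(meta, indent=2))
        arrays = {"x_mean": self.x_mean, "x_std": self.x_std}
        for i, (w, b) in enumerate(zip(self.net.W, self.net.b)):
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = b
        np.savez(d / "weights.npz", **arrays)
        if self.history is not None:
            self.history.to_csv(d / "history.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedStressModel":
        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        cfg = MLPConfig(**{**meta["config"], "hidden": tuple(meta["config"]["hidden"])})
        data = np.load(d / "weights.npz")
        n_layers = sum(1 for k in data.files if k.startswith("W"))
        net = _Net((1, 1), np.random.default_rng(0))
        net.W = [data[f"W{i}"] for i in range(n_layers)]
        net.b = [data[f"b{i}"] for i in range(n_layers)]
        hist = None
        if (d / "history.csv").exists():
            hist = pd.read_csv(d / "history.csv")
        return cls(
            net=net,
            x_mean=data["x_mean"],
            x_std=data["x_std"],
            veg_class=meta["veg_class"],
            config=cfg,
            schema_hash=meta["schema_hash"],
            history=hist,
        )


def train(
    table: pd.DataFrame,
    cfg: MLPConfig = MLPConfig(),
    veg_class: str = "tall",
    target_col: str = "S_t_target",
    verbose: bool = False,
) -> TrainedStressModel:
    """Train a stress network on a covariate + target table.

    The table rows are split 85:15 (seeded, pooled across sites) into
    training and validation sets. Each epoch shuffles the training rows,
    steps Adam on the batch-level ``1 - KGE`` gradient, then records the
    full-set training and validation objectives; the validation objective is
    the early-stopping criterion.
    """
    cols = list(FEATURE_NAMES)
    missing = [c for c in cols + [target_col] if c not in table.columns]
    if missing:
        raise ValueError(f"training table missing columns: {missing}")
    tab = table.dropna(subset=cols + [target_col])
    if len(tab) < cfg.min_rows:
        raise ValueError(f"need at least {cfg.min_rows} rows, got {len(tab)}")

    X = tab[cols].to_numpy(dtype=float)
    y = tab[target_col].to_numpy(dtype=float)

    rng = np.random.default_rng(cfg.seed)
    n = len(X)
    order = rng.permutation(n)
    n_train = int(round(cfg.train_fraction * n))
    tr, va = order[:n_train], order[n_train:]

    x_mean = X[tr].mean(axis=0)
    x_std = X[tr].std(axis=0)
    x_std[x_std == 0] = 1.0
    Xs = (X - x_mean) / x_std

    sizes = (X.shape[1],) + tuple(cfg.hidden) + (1,)
    net = _Net(sizes, rng)
    opt = _Adam(net.params(), cfg.learning_rate)

    best_val = np.inf
    best_weights = net.copy_weights()
    best_epoch = 0
    rows = []
    for epoch in range(1, cfg.max_epochs + 1):
        perm = rng.permutation(tr)
        for start in range(0, len(perm), cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            if len(idx) < 2 or y[idx].std() == 0:
                continue
            pred, cache = net.forward(Xs[idx], dropout=cfg.dropout, rng=rng)
            _, dL_dy = kge_objective_grad(pred, y[idx])
            gW, gb = net.backward(dL_dy, cache)
            opt.step(net.params(), gW + gb)

        pred_tr, _ = net.forward(Xs[tr])
        pred_va, _ = net.forward(Xs[va])
        loss_tr = kge_objective(pred_tr, y[tr])
        loss_va = kge_objective(pred_va, y[va])
        if not (np.isfinite(loss_tr) and np.isfinite(loss_va)):
            raise FloatingPointError(
                f"non-finite objective at epoch {epoch}: train={loss_tr}, val={loss_va}"
            )
        rows.append({"epoch": epoch, "train_loss": loss_tr, "val_loss": loss_va})
        if verbose:
            print(f"epoch {epoch:4d}  train 1-KGE {loss_tr:.4f}  val 1-KGE {loss_va:.4f}")
        if loss_va < best_val - 1e-6:
            best_val = loss_va
            best_weights = net.copy_weights()
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.patience:
            break

    net.set_weights(best_weights)
    history = pd.DataFrame(rows)
    return TrainedStressModel(
        net=net,
        x_mean=x_mean,
        x_std=x_std,
        veg_class=veg_class,
        config=cfg,
        history=history,
    )
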