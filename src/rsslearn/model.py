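"""Dense sequence-to-efficiency regression model.

A small fully connected network maps one-hot nucleotide:position features
to a normalized recombination efficiency in [0, 1].  The default
architecture has two rectified-linear hidden layers (64 and 32 units), a
linear output, inverted dropout on the hidden activations, Adam updates,
and early stopping that monitors the mean squared error of an explicit
validation set and restores the best weights.  All stochastic pieces
(weight initialization, batch shuffling, dropout masks) derive from a
single seed, so training is reproducible.

Model quality is summarized by FVAF (fraction of variance accounted for),
FVAF = 1 - MSE / Var(obs), together with the Spearman rank correlation
and RMSE.  FVAF is 1 for a perfect predictor, 0 for the constant mean
predictor, and unbounded below.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .dataset import FoldRotation


@dataclass
class ModelConfig:
    """Hyperparameters of the efficiency regressor."""

    hidden_layers: tuple[int, ...] = (64, 32)
    dropout_rate: float = 0.2
    max_epochs: int = 100
    early_stopping_patience: int = 10
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_layers"] = list(self.hidden_layers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["hidden_layers"] = tuple(d.get("hidden_layers", (64, 32)))
        return cls(**d)


@dataclass
class MetricsReport:
    fvaf: float
    spearman_rho: float
    rmse: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


class EfficiencyRegressor(RegressorMixin, BaseEstimator):
    """Dense neural regressor for one-hot encoded RSS variants.

    Parameters mirror :class:`ModelConfig`.  ``fit`` accepts an optional
    ``validation_data=(X_val, y_val)`` pair; when given, training stops
    early once validation MSE has not improved for ``patience`` epochs and
    the best-validation weights are restored.  ``score`` (inherited) is the
    coefficient of determination, which on a fixed evaluation set equals
    FVAF.
    """

    def __init__(
        self,
        hidden_layers: tuple[int, ...] = (64, 32),
        dropout_rate: float = 0.2,
        max_epochs: int = 100,
        patience: int = 10,
        batch_size: int = 64,
        learning_rate: float = 1e-3,
        random_state: int = 0,
    ):
        self.hidden_layers = hidden_layers
        self.dropout_rate = dropout_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    # -- internals --------------------------------------------------------

    def _as_array(self, X, check_features: bool) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if check_features:
                want = list(self.feature_names_in_) if self.feature_names_in_ is not None else None
                if want is not None:
                    missing = [c for c in want if c not in X.columns]
                    extra = [c for c in X.columns if c not in want]
                    if missing or extra:
                        raise ValueError(
                            f"feature mismatch; missing={missing}, extra={extra}"
                        )
                    X = X[want]
            return X.to_numpy(dtype=np.float64)
        arr = np.asarray(X, dtype=np.float64)
        if check_features and arr.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {arr.shape[1]}"
            )
        return arr

    def _init_weights(self, n_features: int, rng: np.random.Generator) -> None:
        sizes = [n_features, *self.hidden_layers, 1]
        self.coefs_ = []
        self.intercepts_ = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU
            self.coefs_.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.intercepts_.append(np.zeros(fan_out))

    def _forward(self, X: np.ndarray) -> np.ndarray:
        a = X
        for W, b in zip(self.coefs_[:-1], self.intercepts_[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        return (a @ self.coefs_[-1] + self.intercepts_[-1]).ravel()

    def _train_step(self, X, y, rng, adam_state) -> float:
        # forward with inverted dropout on hidden activations
        acts = [X]
        masks = []
        a = X
        keep = 1.0 - self.dropout_rate
        for W, b in zip(self.coefs_[:-1], self.intercepts_[:-1]):
            a = np.maximum(a @ W + b, 0.0)
            if self.dropout_rate > 0:
                m = (rng.random(a.shape) < keep) / keep
                a = a * m
                masks.append(m)
            else:
                masks.append(None)
            acts.append(a)
        out = (a @ self.coefs_[-1] + self.intercepts_[-1]).ravel()
        err = out - y
        loss = float(np.mean(err**2))
        # backward
        n = len(y)
        grads_W = [None] * len(self.coefs_)
        grads_b = [None] * len(self.coefs_)
        delta = (2.0 / n) * err[:, None]
        grads_W[-1] = acts[-1].T @ delta
        grads_b[-1] = delta.sum(axis=0)
        da = delta @ self.coefs_[-1].T
        for layer in range(len(self.coefs_) - 2, -1, -1):
            a_here = acts[layer + 1]
            if masks[layer] is not None:
                da = da * masks[layer]
            dz = da * (a_here > 0)
            grads_W[layer] = acts[layer].T @ dz
            grads_b[layer] = dz.sum(axis=0)
            if layer > 0:
                da = dz @ self.coefs_[layer].T
        # Adam update
        t = adam_state["t"] = adam_state["t"] + 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        lr = self.learning_rate
        for i, (gW, gb) in enumerate(zip(grads_W, grads_b)):
            for key, g, param in (("W", gW, self.coefs_), ("b", gb, self.intercepts_)):
                m = adam_state[f"m{key}{i}"] = b1 * adam_state[f"m{key}{i}"] + (1 - b1) * g
                v = adam_state[f"v{key}{i}"] = b2 * adam_state[f"v{key}{i}"] + (1 - b2) * g**2
                mhat = m / (1 - b1**t)
                vhat = v / (1 - b2**t)
                param[i] = param[i] - lr * mhat / (np.sqrt(vhat) + eps)
        return loss

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y, validation_data=None):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        else:
            self.feature_names_in_ = None
        Xa = np.asarray(X, dtype=np.float64)
        ya = np.asarray(y, dtype=np.float64).ravel()
        if Xa.size == 0:
            raise ValueError("empty training set")
        if len(Xa) != len(ya):
            raise ValueError("X and y lengths differ")
        self.n_features_in_ = Xa.shape[1]

        if validation_data is not None:
            Xv, yv = validation_data
            if isinstance(Xv, pd.DataFrame) and self.feature_names_in_ is not None:
                if list(Xv.columns) != list(self.feature_names_in_):
                    raise ValueError("validation features differ from training features")
            Xv = np.asarray(Xv, dtype=np.float64)
            yv = np.asarray(yv, dtype=np.float64).ravel()
            if Xv.size == 0:
                raise ValueError("empty validation set")
        else:
            Xv = yv = None

        rng = np.random.default_rng(self.random_state)
        self._init_weights(self.n_features_in_, rng)
        adam_state = {"t": 0}
        for i, W in enumerate(self.coefs_):
            adam_state[f"mW{i}"] = np.zeros_like(W)
            adam_state[f"vW{i}"] = np.zeros_like(W)
            adam_state[f"mb{i}"] = np.zeros_like(self.intercepts_[i])
            adam_state[f"vb{i}"] = np.zeros_like(self.intercepts_[i])

        history = []
        best_val = np.inf
        best_weights = None
        stale = 0
        n = len(ya)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, self.batch_size):
                idx = order[start: start + self.batch_size]
                loss = self._train_step(Xa[idx], ya[idx], rng, adam_state)
                if not np.isfinite(loss):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}")
                epoch_loss += loss
                n_batches += 1
            rec = {"epoch": epoch, "train_mse": epoch_loss / max(n_batches, 1)}
            if Xv is not None:
                val_mse = float(np.mean((self._forward(Xv) - yv) ** 2))
                rec["val_mse"] = val_mse
                if val_mse < best_val - 1e-12:
                    best_val = val_mse
                    best_weights = ([W.copy() for W in self.coefs_],
                                    [b.copy() for b in self.intercepts_])
                    stale = 0
                else:
                    stale += 1
                    if stale >= self.patience:
                        history.append(rec)
                        break
            history.append(rec)
        if best_weights is not None:
            self.coefs_, self.intercepts_ = best_weights
        self.history_ = pd.DataFrame(history)
        self.n_epochs_ = len(history)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "coefs_"):
            raise AttributeError("model is not fitted")
        return self._forward(self._as_array(X, check_features=True))

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Persist weights (.npz) with a JSON sidecar (config, features)."""
        path = Path(path)
        arrays = {}
        for i, (W, b) in enumerate(zip(self.coefs_, self.intercepts_)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()},
            "n_layers": len(self.coefs_),
            "feature_names": (list(self.feature_names_in_)
                              if self.feature_names_in_ is not None else None),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "EfficiencyRegressor":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        params = dict(sidecar["params"])
        params["hidden_layers"] = tuple(params["hidden_layers"])
        est = cls(**params)
        data = np.load(path.with_suffix(".npz"))
        est.coefs_ = [data[f"W{i}"] for i in range(sidecar["n_layers"])]
        est.intercepts_ = [data[f"b{i}"] for i in range(sidecar["n_layers"])]
        est.n_features_in_ = est.coefs_[0].shape[0]
        fn = sidecar["feature_names"]
        est.feature_names_in_ = np.asarray(fn, dtype=object) if fn else None
        return est


def train(
    config: ModelConfig,
    X_train,
    y_train,
    X_val=None,
    y_val=None,
) -> EfficiencyRegressor:
    """Train an :class:`EfficiencyRegressor` from a :class:`ModelConfig`."""
    est = EfficiencyRegressor(
        hidden_layers=tuple(config.hidden_layers),
        dropout_rate=config.dropout_rate,
        max_epochs=config.max_epochs,
        patience=config.early_stopping_patience,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        random_state=config.seed,
    )
    validation = (X_val, y_val) if X_val is not None else None
    return est.fit(X_train, y_train, validation_data=validation)


def fvaf(pred, obs) -> float:
    """Fraction of variance accounted for: 1 - MSE / Var(obs)."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    var = np.var(obs)
    if var == 0:
        raise ValueError("observations have zero variance; FVAF undefined")
    return float(1.0 - np.mean((pred - obs) ** 2) / var)


def evaluate(pred, obs) -> MetricsReport:
    """FVAF, Spearman rank correlation (average ranks for ties), and RMSE."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(pred) != len(obs):
        raise ValueError("prediction and observation lengths differ")
    if len(obs) < 2:
        raise ValueError("need at least 2 samples")
    rho = stats.spearmanr(pred, obs).statistic
    return MetricsReport(
        fvaf=fvaf(pred, obs),
        spearman_rho=float(rho),
        rmse=float(np.sqrt(np.mean((pred - obs) ** 2))),
        n=len(obs),
    )


def cross_validate(
    configs: Sequence[ModelConfig],
    rotations: Sequence[FoldRotation],
    encoding: pd.DataFrame,
    targets: pd.Series,
) -> pd.DataFrame:
    """Train one model per (config, rotation); report train/validation FVAF
    and MSE per fit plus per-config means and standard deviations."""
    if not configs:
        raise ValueError("need at least one config")
    rows = []
    for ci, config in enumerate(configs):
        for rot in rotations:
            masks = rot.role_masks()
            seqs = rot.folds.index
            Xtr = encoding.loc[seqs[masks["train"]]]
            ytr = targets.loc[seqs[masks["train"]]]
            Xval = encoding.loc[seqs[masks["validation"]]]
            yval = targets.loc[seqs[masks["validation"]]]
            model = train(config, Xtr, ytr, Xval, yval)
            rows.append({
                "config": ci,
                "rotation": rot.rotation,
                "train_fvaf": fvaf(model.predict(Xtr), ytr),
                "train_mse": float(np.mean((model.predict(Xtr) - ytr) ** 2)),
                "val_fvaf": fvaf(model.predict(Xval), yval),
                "val_mse": float(np.mean((model.predict(Xval) - yval) ** 2)),
                "n_epochs": model.n_epochs_,
            })
    return pd.DataFrame(rows)


def residual_analysis(
    pred: pd.Series,
    train_targets: pd.Series,
    replicate_targets: pd.DataFrame,
) -> dict:
    """Compare model residuals with across-replicate experimental spread.

    ``replicate_targets`` holds one normalized-target column per replicate,
    indexed by sequence.  Returns per-variant residuals and the Spearman
    correlations of (replicate sd, residual) and (replicate sd, |residual|).
    """
    if replicate_targets.shape[1] < 2:
        raise ValueError("need at least 2 replicates for a standard deviation")
    common = train_targets.index
    if not replicate_targets.index.equals(common):
        replicate_targets = replicate_targets.reindex(common)
        if replicate_targets.isna().any().any():
            raise ValueError("replicate tables do not cover all variants")
    resid = pred.loc[common] - train_targets
    sd = replicate_targets.std(axis=1, ddof=1)
    table = pd.DataFrame({
        "residual": resid,
        "abs_residual": resid.abs(),
        "replicate_sd": sd,
    })
    if sd.nunique() <= 1:  # constant spread: rank correlation undefined
        rho_resid = rho_abs = float("nan")
    else:
        rho_resid = float(stats.spearmanr(sd, resid).statistic)
        rho_abs = float(stats.spearmanr(sd, resid.abs()).statistic)
    return {
        "table": table,
        "rho_sd_residual": rho_resid,
        "rho_sd_abs_residual": rho_abs,
    }
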