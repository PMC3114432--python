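"""Single-hidden-layer perceptron mapping sequence/expression predictors to
log2 protein abundance.

The network is y = w2 . f(W1 x' + b1) + b2 with hidden activation
f(v) = (1 - e^-v)/(1 + e^-v) = tanh(v/2) and a linear output neuron.
Inputs and target are affinely rescaled to [-1, 1] over their training
ranges; predictions are mapped back. The hidden size is selected from a
small range (default 5..12) by K-fold cross-validation on the scaled-target
mean squared error.

Training is deterministic given (data, hidden size, seed): full-batch
gradient descent with momentum and a multiplicative adaptive learning rate,
seeded uniform [-0.5, 0.5] initialization, early stopping on loss plateau,
and a fixed number of restarts keeping the best final loss.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import subseed, substream

__all__ = [
    "MLPModel",
    "CVResult",
    "activation",
    "scale_inputs",
    "inverse_scale_target",
    "forward",
    "train",
    "select_hidden_size",
    "r_squared",
    "impute",
    "partial_dependence",
    "HIDDEN_SIZE_RANGE",
]

#: hidden sizes searched by default
HIDDEN_SIZE_RANGE = tuple(range(5, 13))

_DEFAULT_HYPER = {
    "max_epochs": 2000,
    "tolerance": 1e-7,
    "patience": 25,
    "restarts": 3,
    "learning_rate": 0.05,
    "momentum": 0.9,
}


def activation(v):
    """Hidden-unit activation (1 - e^-v)/(1 + e^-v), i.e. tanh(v/2)."""
    return np.tanh(np.asarray(v, dtype=float) / 2.0)


@dataclasses.dataclass
class MLPModel:
    """A trained one-hidden-layer perceptron with its scaling state."""

    predictor_names: list[str]
    input_min: np.ndarray
    input_max: np.ndarray
    input_mean: np.ndarray
    target_min: float
    target_max: float
    W1: np.ndarray  # hidden x inputs
    b1: np.ndarray
    w2: np.ndarray
    b2: float
    n_hidden: int
    seed: int
    training_log: list[float]
    r_squared: float = float("nan")
    cv_r_squared: float = float("nan")
    converged: bool = True

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "schema": "protimpute-mlp/1",
            "predictor_names": self.predictor_names,
            "input_min": self.input_min.tolist(),
            "input_max": self.input_max.tolist(),
            "input_mean": self.input_mean.tolist(),
            "target_min": self.target_min,
            "target_max": self.target_max,
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "n_hidden": self.n_hidden,
            "seed": self.seed,
            "training_log": self.training_log,
            "r_squared": self.r_squared,
            "cv_r_squared": self.cv_r_squared,
            "converged": self.converged,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MLPModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        if doc.get("schema") != "protimpute-mlp/1":
            raise ValueError(f"unknown model schema {doc.get('schema')!r}")
        return cls(
            predictor_names=doc["predictor_names"],
            input_min=np.asarray(doc["input_min"], dtype=float),
            input_max=np.asarray(doc["input_max"], dtype=float),
            input_mean=np.asarray(doc["input_mean"], dtype=float),
            target_min=doc["target_min"],
            target_max=doc["target_max"],
            W1=np.asarray(doc["W1"], dtype=float),
            b1=np.asarray(doc["b1"], dtype=float),
            w2=np.asarray(doc["w2"], dtype=float),
            b2=doc["b2"],
            n_hidden=doc["n_hidden"],
            seed=doc["seed"],
            training_log=doc["training_log"],
            r_squared=doc["r_squared"],
            cv_r_squared=doc["cv_r_squared"],
            converged=doc["converged"],
        )


@dataclasses.dataclass
class CVResult:
    """Cross-validation summary per candidate hidden size."""

    fold_errors: dict[int, list[float]]  # n_hidden -> K validation MSEs

    @property
    def mean_errors(self) -> dict[int, float]:
        return {h: float(np.mean(e)) for h, e in self.fold_errors.items()}

    @property
    def sd_errors(self) -> dict[int, float]:
        return {h: float(np.std(e, ddof=1)) for h, e in self.fold_errors.items()}


def _check_ranges(lo: np.ndarray, hi: np.ndarray, names: Sequence[str]) -> None:
    flat = np.asarray(hi) - np.asarray(lo)
    if np.any(flat <= 0):
        bad = [n for n, d in zip(names, np.atleast_1d(flat)) if d <= 0]
        raise ValueError(f"constant training column(s): {bad}")


def scale_inputs(X: np.ndarray, scaling: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Affine map of each column onto [-1, 1] over the training range.

    Out-of-range values extend linearly beyond [-1, 1] (no clipping).
    """
    lo, hi = (np.asarray(s, dtype=float) for s in scaling)
    _check_ranges(lo, hi, [str(i) for i in range(lo.size)])
    return 2.0 * (np.asarray(X, dtype=float) - lo) / (hi - lo) - 1.0


def inverse_scale_target(y_scaled, scaling: tuple[float, float]):
    lo, hi = scaling
    if not hi > lo:
        raise ValueError("constant training target")
    return (np.asarray(y_scaled, dtype=float) + 1.0) / 2.0 * (hi - lo) + lo


def _forward_scaled(W1, b1, w2, b2, Xs):
    return activation(Xs @ W1.T + b1) @ w2 + b2


def forward(model: MLPModel, x) -> np.ndarray | float:
    """Predict log2 protein abundance for one predictor vector or a batch."""
    arr = np.asarray(x, dtype=float)
    single = arr.ndim == 1
    X = np.atleast_2d(arr)
    if X.shape[1] != len(model.predictor_names):
        raise ValueError(
            f"expected {len(model.predictor_names)} predictors, got {X.shape[1]}"
        )
    Xs = scale_inputs(X, (model.input_min, model.input_max))
    ys = _forward_scaled(model.W1, model.b1, model.w2, model.b2, Xs)
    y = inverse_scale_target(ys, (model.target_min, model.target_max))
    return float(y[0]) if single else y


def _train_once(Xs, ys, n_hidden, rng, hyper):
    n, d = Xs.shape
    W1 = rng.uniform(-0.5, 0.5, size=(n_hidden, d))
    b1 = rng.uniform(-0.5, 0.5, size=n_hidden)
    w2 = rng.uniform(-0.5, 0.5, size=n_hidden)
    b2 = rng.uniform(-0.5, 0.5)
    params = [W1, b1, w2, b2]
    vel = [np.zeros_like(W1), np.zeros_like(b1), np.zeros_like(w2), 0.0]
    lr = hyper["learning_rate"]
    mom = hyper["momentum"]
    log: list[float] = []

    def loss_of(p):
        H = activation(Xs @ p[0].T + p[1])
        e = H @ p[2] + p[3] - ys
        return float(np.mean(e * e)), H, e

    loss, H, e = loss_of(params)
    best_loss = loss
    best_epoch = 0
    for epoch in range(hyper["max_epochs"]):
        # gradients of mean squared error on the scaled target
        de = (2.0 / n) * e
        gw2 = H.T @ de
        gb2 = float(de.sum())
        dZ = np.outer(de, params[2]) * (1.0 - H * H) / 2.0
        gW1 = dZ.T @ Xs
        gb1 = dZ.sum(axis=0)
        grads = [gW1, gb1, gw2, gb2]
        vel = [mom * v - lr * g for v, g in zip(vel, grads)]
        trial = [p + v for p, v in zip(params, vel)]
        new_loss, new_H, new_e = loss_of(trial)
        if not np.isfinite(new_loss):
            raise FloatingPointError("non-finite training loss")
        if new_loss > loss * 1.04:
            # reject the step, cool down, reset momentum
            lr *= 0.7
            vel = [np.zeros_like(v) if isinstance(v, np.ndarray) else 0.0 for v in vel]
        else:
            params, loss, H, e = trial, new_loss, new_H, new_e
            lr *= 1.05
        log.append(loss)
        if loss < best_loss - hyper["tolerance"]:
            best_loss = loss
            best_epoch = epoch
        elif epoch - best_epoch >= hyper["patience"]:
            break
    converged = len(log) < hyper["max_epochs"]
    return params, loss, log, converged


def train(
    X: np.ndarray,
    y: np.ndarray,
    n_hidden: int,
    seed: int,
    predictor_names: Sequence[str] | None = None,
    **hyper,
) -> MLPModel:
    """Fit the perceptron; deterministic given (X, y, n_hidden, seed).

    Runs ``restarts`` seeded initializations and keeps the lowest final
    scaled-target MSE. A model that exhausts ``max_epochs`` without
    plateauing is returned with ``converged=False`` and a warning.
    """
    h = dict(_DEFAULT_HYPER, **hyper)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing predictor or target values in training data")
    names = list(predictor_names) if predictor_names is not None else [
        f"x{i}" for i in range(X.shape[1])
    ]
    if X.shape[0] < 5 * n_hidden:
        warnings.warn(
            f"only {X.shape[0]} training rows for {n_hidden} hidden units "
            "(recommend >= 5 per unit)",
            stacklevel=2,
        )
    lo, hi = X.min(axis=0), X.max(axis=0)
    _check_ranges(lo, hi, names)
    t_lo, t_hi = float(y.min()), float(y.max())
    if not t_hi > t_lo:
        raise ValueError("constant training target")
    Xs = scale_inputs(X, (lo, hi))
    ys = 2.0 * (y - t_lo) / (t_hi - t_lo) - 1.0

    best = None
    for r in range(h["restarts"]):
        rng = substream(seed, "mlp-init", n_hidden, r)
        params, loss, log, conv = _train_once(Xs, ys, n_hidden, rng, h)
        if best is None or loss < best[1]:
            best = (params, loss, log, conv)
    params, _, log, conv = best
    if not conv:
        warnings.warn("training stopped at max_epochs without plateau", stacklevel=2)
    model = MLPModel(
        predictor_names=names,
        input_min=lo,
        input_max=hi,
        input_mean=X.mean(axis=0),
        target_min=t_lo,
        target_max=t_hi,
        W1=params[0],
        b1=params[1],
        w2=params[2],
        b2=float(params[3]),
        n_hidden=n_hidden,
        seed=seed,
        training_log=log,
        converged=conv,
    )
    model.r_squared = r_squared(y, np.asarray(forward(model, X)))
    return model


def select_hidden_size(
    X: np.ndarray,
    y: np.ndarray,
    sizes: Sequence[int] = HIDDEN_SIZE_RANGE,
    K: int = 10,
    seed: int = 0,
    predictor_names: Sequence[str] | None = None,
    **hyper,
) -> tuple[int, CVResult]:
    """Pick the hidden size minimizing mean K-fold validation MSE.

    Folds come from one seeded permutation and are as equal as possible;
    every fold's scaler is fit on its training part only. Ties go to the
    smallest size. Fold models use a single initialization by default
    (restarts=1); the final refit elsewhere keeps the full restart schedule.
    """
    hyper.setdefault("restarts", 1)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if K > n:
        raise ValueError(f"K={K} folds but only {n} rows")
    if n < 2 * K:
        warnings.warn(f"fewer than 2 rows per fold (n={n}, K={K})", stacklevel=2)
    perm = substream(seed, "cv-folds").permutation(n)
    folds = np.array_split(perm, K)
    fold_errors: dict[int, list[float]] = {}
    for size in sizes:
        errs = []
        for k, val_idx in enumerate(folds):
            train_idx = np.setdiff1d(perm, val_idx, assume_unique=True)
            m = train(
                X[train_idx],
                y[train_idx],
                size,
                subseed(seed, "cv", size, k),
                predictor_names=predictor_names,
                **hyper,
            )
            # validation error on the fold model's scaled-target scale
            ys_val = 2.0 * (y[val_idx] - m.target_min) / (m.target_max - m.target_min) - 1.0
            Xs_val = scale_inputs(X[val_idx], (m.input_min, m.input_max))
            pred = _forward_scaled(m.W1, m.b1, m.w2, m.b2, Xs_val)
            errs.append(float(np.mean((pred - ys_val) ** 2)))
        fold_errors[size] = errs
    cv = CVResult(fold_errors)
    means = cv.mean_errors
    best = min(sorted(means), key=lambda s: means[s])
    return best, cv


def r_squared(y, yhat) -> float:
    """Coefficient of determination 1 - SSE/SST (SST about the mean of y)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("constant y: R^2 undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def impute(
    model: MLPModel,
    features: pd.DataFrame,
    measured_log2: pd.Series | None = None,
) -> pd.DataFrame:
    """Predict abundances for genes, passing measured values through.

    ``features`` must contain the model's predictor columns. Genes with a
    non-missing entry in ``measured_log2`` keep their measured value and
    are flagged ``measured``; the rest get network predictions. Genes with
    missing predictors are skipped with a warning. Output columns:
    ``measured_flag``, ``log2_abundance``, ``linear_abundance``.
    """
    missing_cols = [c for c in model.predictor_names if c not in features.columns]
    if missing_cols:
        raise ValueError(f"feature table lacks predictors {missing_cols}")
    sub = features[list(model.predictor_names)]
    complete = ~sub.isna().any(axis=1)
    if (~complete).any():
        warnings.warn(
            f"skipped {int((~complete).sum())} gene(s) with missing predictors",
            stacklevel=2,
        )
    sub = sub.loc[complete]
    preds = np.asarray(forward(model, sub.to_numpy()))
    out = pd.DataFrame(
        {
            "measured_flag": False,
            "log2_abundance": preds,
            "linear_abundance": np.exp2(preds),
        },
        index=sub.index,
    )
    if measured_log2 is not None:
        meas = measured_log2.reindex(out.index)
        have = meas.notna()
        out.loc[have, "measured_flag"] = True
        out.loc[have, "log2_abundance"] = meas[have]
        out.loc[have, "linear_abundance"] = np.exp2(meas[have])
    out.index.name = "gene_id"
    return out


def partial_dependence(
    model: MLPModel,
    predictor: str,
    grid: np.ndarray,
    extrapolation_margin: float = 0.1,
) -> pd.Series:
    """Prediction over a grid of one predictor, others at training means.

    The grid must stay within ``extrapolation_margin`` (fraction of the
    training range) beyond the observed range of the predictor.
    """
    if predictor not in model.predictor_names:
        raise ValueError(f"unknown predictor {predictor!r}")
    j = model.predictor_names.index(predictor)
    grid = np.asarray(grid, dtype=float)
    span = model.input_max[j] - model.input_min[j]
    lo = model.input_min[j] - extrapolation_margin * span
    hi = model.input_max[j] + extrapolation_margin * span
    if grid.min() < lo or grid.max() > hi:
        raise ValueError(
            f"grid for {predictor!r} outside the allowed range [{lo:g}, {hi:g}]"
        )
    X = np.tile(model.input_mean, (grid.size, 1))
    X[:, j] = grid
    return pd.Series(np.asarray(forward(model, X)), index=grid, name=predictor)
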