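"""Functional-capacity regressor: a small feed-forward network trained from scratch.

The regressor maps one tap attempt's two features (reaction time, touch
error) to a continuous functional-capacity level on [0, 10] — higher means
more motorically capable.  The architecture is deliberately tiny: 2 inputs,
one hidden layer of 10 log-sigmoid units, 1 linear output (41 trainable
parameters), trained by batch gradient descent with an adaptive learning
rate and early stopping on a subject-disjoint validation set.

The training loop is hand-rolled on purpose: the adaptive-rate accept/reject
rule and return-best-validation-weights contract are the modelled procedure,
not an off-the-shelf fit.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .records import DatasetSplit, FeatureRow, log_transform

logger = logging.getLogger(__name__)

Topology = Literal["feed-forward", "cascade-forward"]


class ModelError(ValueError):
    """Inconsistent network state (shape mismatch, missing labels)."""


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss)."""


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description: layer sizes and transfer functions."""

    n_inputs: int = 2
    n_hidden: int = 10
    n_outputs: int = 1
    topology: Topology = "feed-forward"
    hidden_transfer: Literal["logsig"] = "logsig"
    output_transfer: Literal["linear"] = "linear"

    def __post_init__(self) -> None:
        if min(self.n_inputs, self.n_hidden, self.n_outputs) < 1:
            raise ModelError("all layer sizes must be >= 1")
        if self.topology not in ("feed-forward", "cascade-forward"):
            raise ModelError(f"unknown topology {self.topology!r}")


def count_parameters(spec: NetworkSpec) -> int:
    """Number of trainable weight elements (weights + biases).

    Feed-forward: ``(I+1)*H + (H+1)*O``.  Cascade-forward additionally
    connects inputs directly to outputs, adding ``I*O`` weights.
    """
    i, h, o = spec.n_inputs, spec.n_hidden, spec.n_outputs
    n = (i + 1) * h + (h + 1) * o
    if spec.topology == "cascade-forward":
        n += i * o
    return n


@dataclass(frozen=True)
class TrainConfig:
    """Adaptive-rate gradient-descent settings.

    ``lr_increase``/``lr_decrease`` scale the learning rate after an
    accepted/rejected epoch; an epoch is rejected when its training error
    exceeds the previous error by more than ``max_error_increase``
    (a ratio, e.g. 0.04 = 4%).  ``patience`` is the number of consecutive
    epochs without a new validation minimum tolerated before stopping.
    """

    learning_rate: float = 0.01
    lr_increase: float = 1.05
    lr_decrease: float = 0.7
    max_error_increase: float = 0.04
    max_epochs: int = 20_000
    patience: int = 300
    seed: int = 0
    features: Literal["log", "raw"] = "log"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.lr_increase <= 0 or self.lr_decrease <= 0:
            raise ModelError("learning-rate factors must be positive")
        if self.patience < 1:
            raise ModelError("patience must be >= 1")


def logsig(z: np.ndarray) -> np.ndarray:
    """Log-sigmoid transfer 1 / (1 + exp(-z)), numerically stable."""
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class TrainedNet:
    """Fitted capacity regressor: weights at the validation minimum plus the
    input standardization, so inference is self-contained."""

    spec: NetworkSpec
    w1: np.ndarray          # (H, I)
    b1: np.ndarray          # (H,)
    w2: np.ndarray          # (O, H)
    b2: np.ndarray          # (O,)
    input_mean: np.ndarray  # (I,)
    input_std: np.ndarray   # (I,)
    features: Literal["log", "raw"] = "log"
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        i, h, o = self.spec.n_inputs, self.spec.n_hidden, self.spec.n_outputs
        shapes = {"w1": (h, i), "b1": (h,), "w2": (o, h), "b2": (o,)}
        for name, want in shapes.items():
            got = np.asarray(getattr(self, name)).shape
            if got != want:
                raise ModelError(f"{name} has shape {got}, expected {want}")

    # -- inference ---------------------------------------------------------

    def forward(self, x_std: np.ndarray) -> np.ndarray:
        """Raw network output for standardized inputs of shape (n, I) or (I,)."""
        x = np.atleast_2d(np.asarray(x_std, dtype=float))
        if x.shape[1] != self.spec.n_inputs:
            raise ModelError(
                f"expected {self.spec.n_inputs} input features, got {x.shape[1]}"
            )
        if not np.all(np.isfinite(x)):
            raise ModelError("forward requires finite inputs")
        hidden = logsig(x @ self.w1.T + self.b1)
        out = hidden @ self.w2.T + self.b2
        return out[:, 0] if self.spec.n_outputs == 1 else out

    def standardize(self, rt: np.ndarray, delta: np.ndarray) -> np.ndarray:
        rt = np.asarray(rt, dtype=float)
        delta = np.asarray(delta, dtype=float)
        if self.features == "log":
            f1 = np.log(rt + 1e-3)
            f2 = np.log(delta + 1e-3)
        else:
            f1, f2 = rt, delta
        x = np.column_stack([f1, f2])
        return (x - self.input_mean) / self.input_std

    def predict(self, rt, delta, clip: bool = True) -> np.ndarray:
        """Capacity prediction from raw (rt, delta); clipped to [0, 10] by default."""
        y = self.forward(self.standardize(np.atleast_1d(rt), np.atleast_1d(delta)))
        return np.clip(y, 0.0, 10.0) if clip else y

    # -- persistence -------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "spec": {
                "n_inputs": self.spec.n_inputs,
                "n_hidden": self.spec.n_hidden,
                "n_outputs": self.spec.n_outputs,
                "topology": self.spec.topology,
                "hidden_transfer": self.spec.hidden_transfer,
                "output_transfer": self.spec.output_transfer,
            },
            "features": self.features,
            "weights": {
                "w1": self.w1.tolist(),
                "b1": self.b1.tolist(),
                "w2": self.w2.tolist(),
                "b2": self.b2.tolist(),
            },
            "standardization": {
                "mean": self.input_mean.tolist(),
                "std": self.input_std.tolist(),
            },
            "history": self.history,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TrainedNet":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            spec=NetworkSpec(**p["spec"]),
            w1=np.asarray(p["weights"]["w1"], dtype=float),
            b1=np.asarray(p["weights"]["b1"], dtype=float),
            w2=np.asarray(p["weights"]["w2"], dtype=float),
            b2=np.asarray(p["weights"]["b2"], dtype=float),
            input_mean=np.asarray(p["standardization"]["mean"], dtype=float),
            input_std=np.asarray(p["standardization"]["std"], dtype=float),
            features=p.get("features", "log"),
            history=p.get("history", []),
        )


def _design(rows: Sequence[FeatureRow], features: str) -> tuple[np.ndarray, np.ndarray]:
    if any(r.tfc is None for r in rows):
        raise ModelError("all rows must carry a capacity label for training")
    if features == "log":
        x = np.array([[r.log_rt, r.log_delta] for r in rows], dtype=float)
    else:
        x = np.array([[r.rt, r.delta] for r in rows], dtype=float)
    y = np.array([r.tfc for r in rows], dtype=float)
    return x, y


def _mse_and_grads(net_w, x, y):
    w1, b1, w2, b2 = net_w
    n = x.shape[0]
    a1 = logsig(x @ w1.T + b1)            # (n, H)
    yhat = a1 @ w2.T + b2                 # (n, 1)
    err = yhat - y[:, None]
    mse = float(np.mean(err**2))
    d_out = 2.0 * err / n                 # dL/dyhat
    g_w2 = d_out.T @ a1
    g_b2 = d_out.sum(axis=0)
    d_hidden = (d_out @ w2) * a1 * (1.0 - a1)
    g_w1 = d_hidden.T @ x
    g_b1 = d_hidden.sum(axis=0)
    return mse, (g_w1, g_b1, g_w2, g_b2)


def train_ffbp(
    split: DatasetSplit,
    config: TrainConfig = TrainConfig(),
    spec: NetworkSpec = NetworkSpec(),
) -> TrainedNet:
    """Train the feed-forward capacity regressor with adaptive-rate batch descent.

    Each epoch proposes one full-batch gradient step.  If the resulting
    training MSE exceeds the previous MSE by more than the configured ratio
    the step is rejected and the learning rate shrinks; otherwise the step
    is accepted and the rate grows.  Validation MSE is monitored every
    epoch; training stops after ``patience`` consecutive epochs without a
    new validation minimum (or at ``max_epochs``) and the weights at the
    validation minimum are returned.
    """
    if not split.train or not split.validation:
        raise ModelError("training requires non-empty train and validation partitions")
    x_tr, y_tr = _design(split.train, config.features)
    x_va, y_va = _design(split.validation, config.features)

    mean = x_tr.mean(axis=0)
    std = x_tr.std(axis=0, ddof=0)
    std[std == 0] = 1.0
    x_tr = (x_tr - mean) / std
    x_va = (x_va - mean) / std

    rng = np.random.default_rng(config.seed)
    h, i, o = spec.n_hidden, spec.n_inputs, spec.n_outputs
    w1 = rng.uniform(-0.5, 0.5, size=(h, i))
    b1 = rng.uniform(-0.5, 0.5, size=h)
    w2 = rng.uniform(-0.5, 0.5, size=(o, h))
    b2 = rng.uniform(-0.5, 0.5, size=o)
    weights = [w1, b1, w2, b2]

    lr = config.learning_rate
    prev_mse, grads = _mse_and_grads(weights, x_tr, y_tr)
    best = {"val": np.inf, "weights": [w.copy() for w in weights]}
    fails = 0
    history: list[dict] = []

    for epoch in range(1, config.max_epochs + 1):
        proposal = [w - lr * g for w, g in zip(weights, grads)]
        new_mse, new_grads = _mse_and_grads(proposal, x_tr, y_tr)
        if not np.isfinite(new_mse):
            raise TrainingError(f"training diverged at epoch {epoch} (non-finite loss)")
        if new_mse > prev_mse * (1.0 + config.max_error_increase):
            lr *= config.lr_decrease       # reject the step
        else:
            weights = proposal             # accept and speed up
            prev_mse, grads = new_mse, new_grads
            lr *= config.lr_increase

        val_mse = float(np.mean((logsig(x_va @ weights[0].T + weights[1]) @ weights[2].T
                                 + weights[3] - y_va[:, None]) ** 2))
        history.append({"epoch": epoch, "train_mse": prev_mse, "val_mse": val_mse, "lr": lr})
        if val_mse < best["val"]:
            best = {"val": val_mse, "weights": [w.copy() for w in weights]}
            fails = 0
        else:
            fails += 1
            if fails >= config.patience:
                logger.info("early stop at epoch %d (val MSE %.5f)", epoch, best["val"])
                break

    w1, b1, w2, b2 = best["weights"]
    return TrainedNet(
        spec=spec, w1=w1, b1=b1, w2=w2, b2=b2,
        input_mean=mean, input_std=std, features=config.features, history=history,
    )


def regression_metrics(predictions: Sequence[float], targets: Sequence[float]) -> tuple[float, float]:
    """(R, MSE): Pearson correlation of predictions vs targets, and mean squared error.

    Zero-variance predictions make the correlation undefined; R is reported
    as 0 with a degenerate-fit warning in that case.
    """
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape or p.size < 2:
        raise ModelError("predictions and targets must have equal length >= 2")
    mse = float(np.mean((p - t) ** 2))
    if np.std(p) == 0 or np.std(t) == 0:
        warnings.warn("degenerate fit: zero-variance predictions or targets; R set to 0")
        return 0.0, mse
    r = float(np.corrcoef(p, t)[0, 1])
    return r, mse


def evaluate_on(net: TrainedNet, rows: Sequence[FeatureRow]) -> tuple[float, float]:
    """Convenience: (R, MSE) of unclipped network predictions on labeled rows."""
    x, y = _design(rows, net.features)
    x = (x - net.input_mean) / net.input_std
    return regression_metrics(net.forward(x), y)
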