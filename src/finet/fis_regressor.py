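"""Feed-forward regression of gene FIS on the 12 normalized features.

A single hidden layer of 100 ReLU units maps the feature vector to a scalar
estimated FIS.  The output unit is linear by default (standard for
regression); a ReLU output is available behind a flag for sensitivity
experiments, at the cost of clamping negative estimates at zero.

Training minimises mean squared error with mini-batch Adam.  Everything is
plain NumPy so that a fixed seed gives bit-identical weights across runs and
platforms, and the forward pass is trivially auditable against a
pencil-and-paper computation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .feature_space import NORMALIZED, FeatureMatrix

LINEAR = "linear"
RELU = "relu"


@dataclass
class RegressionModel:
    """Weights of the 12 -> 100 -> 1 network plus training metadata.

    The response is standardized internally during training (as adaptive
    optimizers expect unit-scale targets); ``y_mean``/``y_scale`` restore
    the original FIS scale in :meth:`forward`.
    """

    W2: np.ndarray  # (hidden, 12)
    b2: np.ndarray  # (hidden,)
    W3: np.ndarray  # (1, hidden)
    b3: float
    epochs: int
    seed: int
    output_activation: str = LINEAR
    y_mean: float = 0.0
    y_scale: float = 1.0
    training_loss_trace: list[float] = field(default_factory=list)

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Vectorised forward pass for an (n, 12) input block."""
        h = np.maximum(X @ self.W2.T + self.b2, 0.0)
        out = (h @ self.W3.T + self.b3) * self.y_scale + self.y_mean
        if self.output_activation == RELU:
            out = np.maximum(out, 0.0)
        return out[:, 0]

    def save(self, path: str | Path) -> None:
        payload = {
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
            "W3": self.W3.tolist(),
            "b3": self.b3,
            "epochs": self.epochs,
            "seed": self.seed,
            "output_activation": self.output_activation,
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
            "training_loss_trace": self.training_loss_trace,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "RegressionModel":
        d = json.loads(Path(path).read_text())
        return cls(
            W2=np.asarray(d["W2"]),
            b2=np.asarray(d["b2"]),
            W3=np.asarray(d["W3"]),
            b3=float(d["b3"]),
            epochs=int(d["epochs"]),
            seed=int(d["seed"]),
            output_activation=d["output_activation"],
            y_mean=float(d.get("y_mean", 0.0)),
            y_scale=float(d.get("y_scale", 1.0)),
            training_loss_trace=list(d["training_loss_trace"]),
        )


def train(
    features: FeatureMatrix,
    targets: Mapping[str, float],
    seed: int,
    *,
    epochs: int = 10,
    hidden_units: int = 100,
    learning_rate: float = 0.01,
    batch_size: int = 4,
    output_activation: str = LINEAR,
) -> RegressionModel:
    """Fit the network by mini-batch Adam on mean squared error.

    Every gene in ``features`` must have a finite target (its observed FIS,
    possibly 0).  The per-epoch loss trace records full-data MSE after each
    epoch.  Fixed ``seed`` => bit-identical weights.
    """
    if features.state != NORMALIZED:
        raise ValueError("train expects a normalized feature matrix")
    X = features.values
    y = np.empty(features.n_genes)
    for i, g in enumerate(features.genes):
        if g not in targets:
            raise ValueError(f"gene {g} has no training target")
        t = float(targets[g])
        if not math.isfinite(t):
            raise ValueError(f"non-finite training target for gene {g}")
        y[i] = t

    n, p = X.shape
    # standardize the response so Adam's unit-scale steps fit in few epochs
    y_mean = float(y.mean())
    y_scale = float(y.std()) or 1.0
    ys = (y - y_mean) / y_scale
    # output ReLU in original units == clamp at -mean/scale in std units
    clamp_at = -y_mean / y_scale

    rng = np.random.default_rng(seed)
    # He initialisation for the ReLU hidden layer
    W2 = rng.normal(0.0, math.sqrt(2.0 / p), size=(hidden_units, p))
    b2 = np.zeros(hidden_units)
    W3 = rng.normal(0.0, math.sqrt(2.0 / hidden_units), size=(1, hidden_units))
    b3 = 0.0

    params = [W2, b2, W3, np.array([b3])]
    adam_m = [np.zeros_like(q) for q in params]
    adam_v = [np.zeros_like(q) for q in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    trace: list[float] = []

    relu_out = output_activation == RELU
    for _ in range(epochs):
        perm = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = perm[start:start + batch_size]
            xb, yb = X[idx], ys[idx]
            m = len(idx)

            u2 = xb @ params[0].T + params[1]
            h = np.maximum(u2, 0.0)
            u3 = (h @ params[2].T)[:, 0] + params[3][0]
            pred = np.maximum(u3, clamp_at) if relu_out else u3

            # d(MSE)/d(pred); chain through the optional output ReLU
            grad_out = 2.0 * (pred - yb) / m
            if relu_out:
                grad_out = grad_out * (u3 > clamp_at)
            gW3 = grad_out[None, :] @ h
            gb3 = np.array([grad_out.sum()])
            gh = grad_out[:, None] * params[2]
            gu2 = gh * (u2 > 0)
            gW2 = gu2.T @ xb
            gb2 = gu2.sum(axis=0)

            step += 1
            bc1 = 1.0 - beta1 ** step
            bc2 = 1.0 - beta2 ** step
            for q, gq, mm, vv in zip(params, [gW2, gb2, gW3, gb3],
                                     adam_m, adam_v):
                mm *= beta1
                mm += (1 - beta1) * gq
                vv *= beta2
                vv += (1 - beta2) * gq * gq
                q -= learning_rate * (mm / bc1) / (np.sqrt(vv / bc2) + eps)

        model_now = RegressionModel(params[0], params[1], params[2],
                                    params[3][0], epochs, seed,
                                    output_activation, y_mean, y_scale)
        trace.append(float(np.mean((model_now.forward(X) - y) ** 2)))

    return RegressionModel(
        W2=params[0], b2=params[1], W3=params[2], b3=float(params[3][0]),
        epochs=epochs, seed=seed, output_activation=output_activation,
        y_mean=y_mean, y_scale=y_scale, training_loss_trace=trace,
    )


def predict(model: RegressionModel, features: FeatureMatrix) -> dict[str, float]:
    """Estimated FIS per gene from the trained network."""
    if features.values.shape[1] != model.W2.shape[1]:
        raise ValueError(
            f"feature dimension {features.values.shape[1]} != "
            f"model input dimension {model.W2.shape[1]}"
        )
    out = model.forward(features.values)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite prediction")
    return dict(zip(features.genes, out.tolist()))


def write_predictions(pred: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\testimated_fis\n")
        for g in pred:
            fh.write(f"{g}\t{pred[g]!r}\n")
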