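"""Extreme learning machine (ELM).

A single-hidden-layer feedforward network in which the input weights W
and biases b of the L hidden nodes are fixed (randomly drawn, or
supplied by an external optimizer) and only the output weights beta are
learned.  Writing H for the hidden-layer output matrix,
H[p, i] = g(X[p] . W[i] + b[i]), training solves H beta = T by the
Moore-Penrose pseudoinverse: beta = pinv(H) T, the minimum-norm
least-squares solution.  With L >= N distinct samples H generically has
full row rank and the network interpolates the training targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

__all__ = ["ELMModel", "train", "decode_params", "random_params", "ACTIVATIONS"]

ACTIVATIONS = {
    "sigmoid": expit,
    "tanh": np.tanh,
    "identity": lambda z: z,
}


@dataclass
class ELMModel:
    """Hidden-layer parameters plus (after training) output weights."""

    input_weights: np.ndarray  # (L, d)
    biases: np.ndarray  # (L,)
    activation: str = "sigmoid"
    output_weights: np.ndarray | None = None  # (L, o)

    def __post_init__(self) -> None:
        self.input_weights = np.asarray(self.input_weights, dtype=float)
        self.biases = np.asarray(self.biases, dtype=float).ravel()
        if self.input_weights.ndim != 2:
            raise ValueError("input_weights must be a 2-D (L, d) array")
        if len(self.biases) != self.input_weights.shape[0]:
            raise ValueError("biases length must equal the number of hidden nodes")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.output_weights is not None:
            self.output_weights = np.atleast_2d(np.asarray(self.output_weights, dtype=float))
            if self.output_weights.shape[0] != self.hidden_nodes:
                raise ValueError("output_weights rows must equal hidden nodes")

    @property
    def hidden_nodes(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.input_weights.shape[1]

    @property
    def is_trained(self) -> bool:
        return self.output_weights is not None

    def hidden_output(self, X: np.ndarray) -> np.ndarray:
        """Hidden-layer response H = g(X W' + b) of shape (N, L)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {X.shape[1]} != model dimension {self.n_features}"
            )
        g = ACTIVATIONS[self.activation]
        return g(X @ self.input_weights.T + self.biases)

    def fit(self, X: np.ndarray, T: np.ndarray) -> "ELMModel":
        """Solve the output weights beta = pinv(H) T in place and return self."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        T = np.asarray(T, dtype=float)
        if T.ndim == 1:
            T = T[:, None]
        if not np.isfinite(X).all() or not np.isfinite(T).all():
            raise ValueError("features and targets must be finite")
        if X.shape[0] != T.shape[0]:
            raise ValueError("X and T must have the same number of rows")
        H = self.hidden_output(X)
        # gelsd lstsq returns the minimum-norm least-squares solution,
        # equivalent to pinv(H) @ T but cheaper for skinny H.
        self.output_weights, *_ = np.linalg.lstsq(H, T, rcond=None)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Raw scores H beta; shape (N,) for a single output column."""
        if not self.is_trained:
            raise RuntimeError("model has no output weights; call fit/train first")
        scores = self.hidden_output(X) @ self.output_weights
        return scores[:, 0] if scores.shape[1] == 1 else scores

    def predict_label(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict(X) >= threshold).astype(np.int8)

    # -- serialization -------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "input_weights": self.input_weights.tolist(),
            "biases": self.biases.tolist(),
            "activation": self.activation,
            "output_weights": None
            if self.output_weights is None
            else self.output_weights.tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ELMModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        ow = payload["output_weights"]
        return cls(
            np.array(payload["input_weights"]),
            np.array(payload["biases"]),
            payload["activation"],
            None if ow is None else np.array(ow),
        )


def train(
    X: np.ndarray,
    T: np.ndarray,
    input_weights: np.ndarray,
    biases: np.ndarray,
    activation: str = "sigmoid",
) -> ELMModel:
    """Build and train an ELM with the given fixed hidden layer."""
    return ELMModel(input_weights, biases, activation).fit(X, T)


def decode_params(vector: np.ndarray, hidden_nodes: int, n_features: int) -> tuple[np.ndarray, np.ndarray]:
    """Split a flat parameter vector into (W, b).

    The first ``L * d`` entries are the input weights in row-major
    order, the last ``L`` the biases — the layout the spherical-search
    optimizer works on.
    """
    vector = np.asarray(vector, dtype=float).ravel()
    expected = hidden_nodes * (n_features + 1)
    if vector.size != expected:
        raise ValueError(
            f"parameter vector has length {vector.size}, expected "
            f"L*(d+1) = {hidden_nodes}*({n_features}+1) = {expected}"
        )
    W = vector[: hidden_nodes * n_features].reshape(hidden_nodes, n_features)
    b = vector[hidden_nodes * n_features :]
    return W, b


def random_params(
    hidden_nodes: int, n_features: int, rng: np.random.Generator, scale: float = 1.0
) -> np.ndarray:
    """Uniform random flat parameter vector in [-scale, scale]^(L*(d+1))."""
    return rng.uniform(-scale, scale, size=hidden_nodes * (n_features + 1))
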