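"""Dense sigmoid layer — the "spatial" half of the hybrid networks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SigmoidLayer", "ann_forward", "sigmoid_grad_factor"]


@dataclass
class SigmoidLayer:
    """Weights ``w[n, q]`` from input ``n`` (bias included as the last input
    position) to hidden unit ``q``; activation is the logistic sigmoid."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be a 2-D (input, hidden) matrix")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @property
    def n_in(self) -> int:
        return self.weights.shape[0]

    @property
    def n_out(self) -> int:
        return self.weights.shape[1]


def ann_forward(x: np.ndarray, layer: SigmoidLayer) -> np.ndarray:
    """R_q = sigmoid(sum_n w[n, q] x_n); every output lies strictly in (0, 1).

    ``x`` must already carry the bias entry (constant 1) in its last slot.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (layer.n_in,):
        raise ValueError(
            f"input has length {x.shape}, layer expects ({layer.n_in},)"
        )
    z = x @ layer.weights
    # scipy.special.expit semantics without the import: stable logistic
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid_grad_factor(R) -> np.ndarray | float:
    """Derivative factor R(1 - R) of the logistic activation."""
    R = np.asarray(R, dtype=float)
    out = R * (1.0 - R)
    if out.ndim == 0:
        return float(out)
    return out
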