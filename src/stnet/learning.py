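"""SpikeProp / gradient-descent learning rules for the hybrid networks.

The temporal error is differentiated through the threshold-crossing
relation: a small weight change shifts the crossing time by
``-psp / (du/dt)`` evaluated at the firing time.  Near-tangential crossings
make that denominator arbitrarily small, so its magnitude is floored
(``denom_floor``, sign preserved) — the standard SpikeProp stabilization.

Three parameter groups are updated per sample:

* output spiking weights ``v[q, j, k]`` (both architectures),
* the sigmoid layer ``w[n, q]`` behind the reciprocal coding (C-STNet and
  the lower path of P-STNet),
* the upper-path hidden spiking weights ``b[m, p, k]`` (P-STNet only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coding import ExpectedSpikes
from .srm import SpikeVector, SRMLayer, kernel, kernel_time_derivative

__all__ = [
    "LearningConfig",
    "GradientSet",
    "loss",
    "output_delta",
    "output_weight_update",
    "hidden_time_gradient",
    "cstnet_ann_update",
    "pstnet_upper_update",
    "finite_difference_oracle",
]

#: floor on activations inside the reciprocal-coding backward factor
#: -beta/R^2, preventing overflow when a sigmoid output saturates near 0
R_FLOOR = 1e-3


@dataclass(frozen=True)
class LearningConfig:
    """Learning-rate schedule and numerical floors.

    eta : base learning rate, in (0, 1).
    decay : multiplicative per-epoch attenuation of eta (1.0 = fixed rate).
    denom_floor : lower bound on |du/dt| in the SpikeProp delta
        denominators; sign is preserved.
    unfired_denom : reference slope (potential units per time unit) used as
        the delta denominator for output neurons that never crossed the
        threshold.  A silent neuron has no crossing slope; dividing by the
        tiny ``denom_floor`` instead would produce huge corrective deltas
        that saturate the upstream sigmoid layer.
    silent_boost : multiplicative factor applied to a hidden spiking
        neuron's incoming weights each time it fails to fire for a sample.
        SpikeProp carries no gradient for a silent neuron, so without
        boosting a hidden neuron that falls silent is lost permanently.
    """

    eta: float = 0.03
    decay: float = 1.0
    denom_floor: float = 0.1
    unfired_denom: float = 1.0
    silent_boost: float = 1.05

    def __post_init__(self) -> None:
        if not 0 < self.eta < 1:
            raise ValueError("eta must lie in (0, 1)")
        if not 0 < self.decay <= 1:
            raise ValueError("decay must lie in (0, 1]")
        if self.denom_floor < 0:
            raise ValueError("denom_floor must be nonnegative")

    def rate_at(self, epoch: int) -> float:
        """Effective learning rate after ``epoch`` completed epochs."""
        return self.eta * self.decay ** epoch


@dataclass
class GradientSet:
    """Weight increments for one update step; shapes mirror the parameters."""

    d_v: np.ndarray | None = None
    d_w: np.ndarray | None = None
    d_b: np.ndarray | None = None


def loss(actual: SpikeVector, expected: ExpectedSpikes) -> float:
    """Temporal squared error E = 1/2 sum_j (t_j - t_j^d)^2."""
    if len(actual) != len(expected):
        raise ValueError("actual and expected spike vectors differ in length")
    return float(0.5 * np.sum((actual.times - expected.times) ** 2))


def _floored(D: np.ndarray, floor: float) -> np.ndarray:
    sign = np.where(D < 0, -1.0, 1.0)  # D == 0 treated as positive slope
    return sign * np.maximum(np.abs(D), floor)


def output_delta(actual: SpikeVector, expected: ExpectedSpikes,
                 coding_spikes: SpikeVector, layer: SRMLayer,
                 cfg: LearningConfig) -> np.ndarray:
    """SpikeProp output deltas, delta_j = (t_j^d - t_j) / (du_j/dt (t_j)).

    The denominator is the membrane-potential slope at the firing time; its
    magnitude is floored at ``cfg.denom_floor`` with the sign kept.  An
    unfired output has no crossing, so its slope at the clamped time ``T``
    carries no sign information; its denominator is forced positive
    (``max(D, floor)``) so the update always pushes the neuron toward
    firing — otherwise a silent neuron with a decaying potential is driven
    ever more negative and can never recover.  Returns the vector of deltas
    (length J).
    """
    s = actual.times[None, :, None] - coding_spikes.times[:, None, None] \
        - layer.delays[None, None, :]
    D = np.einsum("qjk,qjk->j", layer.weights,
                  kernel_time_derivative(s, layer.kernel))
    D_eff = np.where(actual.fired, _floored(D, cfg.denom_floor),
                     np.maximum(D, cfg.unfired_denom))
    return (expected.times - actual.times) / D_eff


def output_weight_update(deltas: np.ndarray, coding_spikes: SpikeVector,
                         actual: SpikeVector, layer: SRMLayer,
                         eta: float) -> np.ndarray:
    """Increment for the output weights: dv[q,j,k] = -eta delta_j y_q^k(t_j)."""
    s = actual.times[None, :, None] - coding_spikes.times[:, None, None] \
        - layer.delays[None, None, :]
    y = kernel(s, layer.kernel)  # (Q, J, K)
    return -eta * deltas[None, :, None] * y


def hidden_time_gradient(deltas: np.ndarray, actual: SpikeVector,
                         coding_spikes: SpikeVector,
                         layer: SRMLayer) -> np.ndarray:
    """dE/dt_q for every presynaptic (coding-layer) neuron q.

    dE/dt_q = sum_j delta_j sum_k v[q,j,k] * (-eps'(t_j - t_q - d_k)):
    advancing a presynaptic spike shifts each PSP curve, so the derivative
    with respect to t_q is the negated kernel time derivative.
    """
    s = actual.times[None, :, None] - coding_spikes.times[:, None, None] \
        - layer.delays[None, None, :]
    dy = kernel_time_derivative(s, layer.kernel)  # (Q, J, K)
    return -np.einsum("j,qjk,qjk->q", deltas, layer.weights, dy)


def cstnet_ann_update(x: np.ndarray, R: np.ndarray,
                      hidden_time_grads: np.ndarray,
                      coding_spikes: SpikeVector, eta: float,
                      beta: float) -> np.ndarray:
    """Increment for the sigmoid weights behind the reciprocal coding.

    dw[n,q] = eta * beta * (dE/dt_q) * R_q (1 - R_q) x_n / R_q^2, the chain
    rule through t_q = beta / R_q.  Columns whose coding time was clamped at
    T get zero (the clamp is flat); R_q is floored inside the 1/R^2 factor.
    """
    R = np.asarray(R, dtype=float)
    Rf = np.maximum(R, R_FLOOR)
    col = eta * beta * hidden_time_grads * R * (1.0 - R) / Rf ** 2
    if coding_spikes.clamped is not None:
        col = np.where(coding_spikes.clamped, 0.0, col)
    return np.asarray(x, dtype=float)[:, None] * col[None, :]


def pstnet_upper_update(input_spikes: SpikeVector, hidden_spikes: SpikeVector,
                        deltas: np.ndarray, out_layer: SRMLayer,
                        upper_layer: SRMLayer, actual: SpikeVector,
                        cfg: LearningConfig, eta: float) -> np.ndarray:
    """Increment for the upper-path hidden spiking weights ``b[m, p, k]``.

    The hidden delta chains the output deltas through the PSPs the hidden
    spike t_p feeds into the output layer, divided by the slope of the
    hidden neuron's own potential at t_p (floored).  Hidden neurons that
    never fired get zero increment (their crossing time is undefined).

    ``out_layer`` rows must correspond to the upper-path hidden neurons
    (pass a sliced layer when the coding layer concatenates two paths).
    """
    grad_tp = hidden_time_gradient(deltas, actual, hidden_spikes, out_layer)
    s = hidden_spikes.times[None, :, None] - input_spikes.times[:, None, None] \
        - upper_layer.delays[None, None, :]
    dy = kernel_time_derivative(s, upper_layer.kernel)  # (M, P, K)
    D = np.einsum("mpk,mpk->p", upper_layer.weights, dy)
    y = kernel(s, upper_layer.kernel)
    d_b = eta * grad_tp[None, :, None] * y / _floored(D, cfg.denom_floor)[None, :, None]
    return np.where(hidden_spikes.fired[None, :, None], d_b, 0.0)


def finite_difference_oracle(loss_fn, params: np.ndarray, index,
                             h: float = 1e-4) -> float:
    """Central finite difference of ``loss_fn()`` w.r.t. ``params[index]``.

    ``loss_fn`` must re-run the full forward pass reading ``params`` (which
    is perturbed in place and restored).  Independent of the analytic
    backward path; used to verify it.
    """
    orig = params[index]
    try:
        params[index] = orig + h
        up = loss_fn()
        params[index] = orig - h
        down = loss_fn()
    finally:
        params[index] = orig
    return (up - down) / (2.0 * h)
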