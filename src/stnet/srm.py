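"""Spike response model (SRM) primitives.

A spiking neuron integrates kernel-shaped postsynaptic potentials (PSPs)
arriving through ``K`` delayed synapses per connection and emits a single
spike the first time its membrane potential reaches the threshold ``theta``
within the simulation window ``[0, T]``.  Time is simulated on a uniform
grid; all quantities are plain numpy arrays so that layers vectorize over
postsynaptic neurons and grid points at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimulationConfig",
    "KernelConfig",
    "SRMLayer",
    "SpikeVector",
    "kernel",
    "kernel_time_derivative",
    "membrane_potential",
    "membrane_potential_rate",
    "membrane_potential_grid",
    "first_crossing",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation window and threshold.

    Parameters
    ----------
    T : float
        Length of the spiking time window (time units).  Unfired neurons
        carry the clamped time ``T`` downstream.
    theta : float
        Firing threshold on the membrane potential.
    dt : float
        Uniform time-grid step.  The reported firing time is the first grid
        point at or above threshold.
    refine : bool
        If True, refine the crossing by linear interpolation between the
        bracketing grid points, making firing times (piecewise) smooth
        functions of the weights.  Off by default; gradient verification
        turns it on.
    """

    T: float = 10.0
    theta: float = 1.0
    dt: float = 0.01
    refine: bool = False

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if not 0 < self.dt < self.T:
            raise ValueError("dt must satisfy 0 < dt < T")

    @property
    def n_grid(self) -> int:
        return int(np.floor(self.T / self.dt)) + 1

    def grid(self) -> np.ndarray:
        return np.arange(self.n_grid) * self.dt


@dataclass(frozen=True)
class KernelConfig:
    """Time constant of the PSP kernel (peak location and shape)."""

    tau: float = 7.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def kernel(s, cfg: KernelConfig = KernelConfig()):
    """PSP kernel: ``(s/tau) * exp(1 - s/tau)`` for ``s > 0``, else 0.

    Normalized so the peak value is exactly 1, attained at ``s = tau``.
    Accepts scalars or arrays.
    """
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    m = s > 0
    sm = s[m] / cfg.tau
    out[m] = sm * np.exp(1.0 - sm)
    if out.ndim == 0:
        return float(out)
    return out


def kernel_time_derivative(s, cfg: KernelConfig = KernelConfig()):
    """Analytic time derivative of :func:`kernel`; 0 for ``s <= 0``.

    ``(1/tau) e^{1 - s/tau} - (1/tau) kernel(s)``; vanishes at the peak
    ``s = tau``.
    """
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    m = s > 0
    sm = s[m] / cfg.tau
    e = np.exp(1.0 - sm)
    out[m] = (e - sm * e) / cfg.tau
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class SpikeVector:
    """Per-neuron single-spike firing times within the window.

    ``times[i]`` is the firing time of neuron ``i``; neurons that never
    reached threshold carry ``times[i] == T`` with ``fired[i] == False``.
    ``clamped`` marks coding neurons whose analog-to-time conversion was
    saturated at ``T`` (the backward pass zeroes their gradient).
    ``peaks`` optionally records each neuron's maximum membrane potential
    over the window, used to break prediction ties.
    """

    times: np.ndarray
    fired: np.ndarray
    clamped: np.ndarray | None = None
    peaks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fired = np.asarray(self.fired, dtype=bool)
        if self.times.shape != self.fired.shape:
            raise ValueError("times and fired must have the same shape")

    def __len__(self) -> int:
        return self.times.size

    @classmethod
    def all_fired(cls, times) -> "SpikeVector":
        times = np.asarray(times, dtype=float)
        return cls(times=times, fired=np.ones(times.shape, dtype=bool))


@dataclass
class SRMLayer:
    """Fully connected spiking layer with ``K`` delayed synapses per pair.

    ``weights[q, j, k]`` connects presynaptic neuron ``q`` to postsynaptic
    neuron ``j`` through the synapse with delay ``delays[k]``.  Default
    delays are ``1..K``.
    """

    weights: np.ndarray
    delays: np.ndarray
    kernel: KernelConfig = field(default_factory=KernelConfig)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.delays = np.asarray(self.delays, dtype=float)
        if self.weights.ndim != 3:
            raise ValueError("weights must be a (pre, post, synapse) tensor")
        if self.delays.shape != (self.weights.shape[2],):
            raise ValueError("delays must have length K = weights.shape[2]")
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly increasing")

    @property
    def n_pre(self) -> int:
        return self.weights.shape[0]

    @property
    def n_post(self) -> int:
        return self.weights.shape[1]

    @property
    def K(self) -> int:
        return self.weights.shape[2]

    @classmethod
    def zeros(cls, n_pre: int, n_post: int, K: int,
              kernel: KernelConfig = KernelConfig()) -> "SRMLayer":
        return cls(weights=np.zeros((n_pre, n_post, K)),
                   delays=np.arange(1, K + 1, dtype=float), kernel=kernel)


def _check_dims(inputs: SpikeVector, layer: SRMLayer) -> None:
    if len(inputs) != layer.n_pre:
        raise ValueError(
            f"input spike vector has {len(inputs)} neurons, "
            f"layer expects {layer.n_pre}"
        )


def _psp(t, inputs: SpikeVector, layer: SRMLayer, deriv: bool = False) -> np.ndarray:
    """PSP table y[q, k] (or its time derivative) at time(s) t.

    With an array ``t`` of shape (G,), returns shape (Q, K, G).
    """
    s = np.asarray(t, dtype=float) - (
        inputs.times[:, None] + layer.delays[None, :]
    )[..., None] if np.ndim(t) else (
        float(t) - inputs.times[:, None] - layer.delays[None, :]
    )
    f = kernel_time_derivative if deriv else kernel
    return f(s, layer.kernel)


def membrane_potential(t: float, inputs: SpikeVector, layer: SRMLayer,
                       j: int | None = None):
    """Membrane potential u_j(t) = sum_{q,k} v[q,j,k] * eps(t - t_q - d_k).

    Returns the potential of postsynaptic neuron ``j``, or of all
    postsynaptic neurons when ``j`` is None.
    """
    _check_dims(inputs, layer)
    y = _psp(t, inputs, layer)
    if j is None:
        return np.einsum("qjk,qk->j", layer.weights, y)
    return float(np.einsum("qk,qk->", layer.weights[:, j, :], y))


def membrane_potential_rate(t: float, inputs: SpikeVector, layer: SRMLayer,
                            j: int | None = None):
    """Time derivative du_j/dt, from the analytic kernel derivative."""
    _check_dims(inputs, layer)
    dy = _psp(t, inputs, layer, deriv=True)
    if j is None:
        return np.einsum("qjk,qk->j", layer.weights, dy)
    return float(np.einsum("qk,qk->", layer.weights[:, j, :], dy))


def membrane_potential_grid(inputs: SpikeVector, layer: SRMLayer,
                            sim: SimulationConfig) -> np.ndarray:
    """Potentials of every postsynaptic neuron on the whole grid, (J, G)."""
    _check_dims(inputs, layer)
    y = _psp(sim.grid(), inputs, layer)  # (Q, K, G)
    return np.einsum("qjk,qkg->jg", layer.weights, y)


def first_crossing(inputs: SpikeVector, layer: SRMLayer,
                   sim: SimulationConfig) -> SpikeVector:
    """First threshold crossing per postsynaptic neuron (single-spike rule).

    Scans the grid ``0, dt, ..., T`` and reports the first time with
    ``u_j(t) >= theta``.  Neurons that never cross carry ``time = T`` and
    ``fired = False``.  ``peaks`` holds each neuron's maximum potential over
    the window for tie-breaking diagnostics.
    """
    U = membrane_potential_grid(inputs, layer, sim)  # (J, G)
    above = U >= sim.theta
    fired = above.any(axis=1)
    idx = above.argmax(axis=1)  # first True where fired
    times = np.full(layer.n_post, sim.T, dtype=float)
    grid = sim.grid()
    times[fired] = grid[idx[fired]]
    if sim.refine:
        for j in np.nonzero(fired)[0]:
            g = idx[j]
            if g > 0:
                u0, u1 = U[j, g - 1], U[j, g]
                if u1 > u0:  # interpolate within the bracketing step
                    times[j] = grid[g - 1] + sim.dt * (sim.theta - u0) / (u1 - u0)
    return SpikeVector(times=times, fired=fired, peaks=U.max(axis=1))
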