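"""Conversions between analog values and spike times.

Four codings are implemented:

* reciprocal coding ``t = beta / R`` splicing sigmoid activations into the
  spiking layers (higher activation -> earlier spike), clamped at the window
  end ``T``;
* linear time-delay coding mapping a feature range affinely onto ``[0, T]``
  (large values spike early);
* Gaussian population coding spreading each feature over ``G`` overlapping
  receptive fields, each field's spike time set by its tuning response;
* label coding assigning the correct class an early target firing time and
  every other class a late one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .srm import SpikeVector

__all__ = [
    "CodingConfig",
    "ExpectedSpikes",
    "reciprocal_encode",
    "linear_delay_encode",
    "population_encode",
    "encode_labels",
    "add_bias",
]


@dataclass(frozen=True)
class CodingConfig:
    """Constants of the analog<->time conversions.

    beta : reciprocal-coding constant (not learnable).
    T : spiking window, shared with the simulation.
    G : Gaussian receptive fields per feature (>= 3).
    gamma : field-width factor; width = range / (gamma * (G - 2)).
    t_early / t_late : target firing times encoding the correct / wrong
        class.  The correct class must fire strictly earlier.
    """

    beta: float = 1.0
    T: float = 10.0
    G: int = 6
    gamma: float = 1.5
    t_early: float = 3.0
    t_late: float = 10.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0 <= self.t_early < self.t_late <= self.T:
            raise ValueError("need 0 <= t_early < t_late <= T")


@dataclass
class ExpectedSpikes:
    """Per-class target firing times (t_1^d .. t_J^d)."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)

    def __len__(self) -> int:
        return self.times.size


def reciprocal_encode(R: np.ndarray, cfg: CodingConfig) -> SpikeVector:
    """t_q = beta / R_q, clamped to T when it exceeds the window.

    Clamped entries are flagged in ``SpikeVector.clamped`` so the backward
    pass can zero their (flat) gradient.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValueError("reciprocal coding needs strictly positive activations")
    t = cfg.beta / R
    clamped = t > cfg.T
    t = np.where(clamped, cfg.T, t)
    return SpikeVector(times=t, fired=np.ones_like(t, dtype=bool),
                       clamped=clamped)


def linear_delay_encode(x: np.ndarray, xmin: np.ndarray, xmax: np.ndarray,
                        T: float) -> SpikeVector:
    """t = (xmax - x) / (xmax - xmin) * T per feature; large values early.

    Features outside the range are clipped; a degenerate feature
    (xmax == xmin) encodes to ``T`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    xmin = np.broadcast_to(np.asarray(xmin, dtype=float), x.shape)
    xmax = np.broadcast_to(np.asarray(xmax, dtype=float), x.shape)
    span = xmax - xmin
    degenerate = span <= 0
    if np.any(degenerate):
        warnings.warn("degenerate feature range in linear delay coding; "
                      "emitting t = T", stacklevel=2)
    xc = np.clip(x, xmin, xmax)
    t = np.full_like(x, T)
    ok = ~degenerate
    t[ok] = (xmax[ok] - xc[ok]) / span[ok] * T
    return SpikeVector.all_fired(t)


def population_encode(x: np.ndarray, cfg: CodingConfig,
                      xmin, xmax) -> SpikeVector:
    """Gaussian receptive-field coding: each feature -> ``G`` spike times.

    For feature range [I_min, I_max], field g (1-based) is centred at
    ``I_min + (2g - 3)/2 * (I_max - I_min)/(G - 2)`` with width
    ``(I_max - I_min) / (gamma (G - 2))``; its response
    ``phi = exp(-(x - mu)^2 / (2 sigma^2))`` maps to the spike time
    ``t = T (1 - phi)``.  Output length is ``N * G`` (feature-major).
    """
    if cfg.G < 3:
        raise ValueError("population coding needs G >= 3")
    x = np.asarray(x, dtype=float)
    xmin = np.broadcast_to(np.asarray(xmin, dtype=float), x.shape)
    xmax = np.broadcast_to(np.asarray(xmax, dtype=float), x.shape)
    span = xmax - xmin
    if np.any(span <= 0):
        raise ValueError("population coding needs xmax > xmin per feature")
    g = np.arange(1, cfg.G + 1)
    mu = xmin[:, None] + (2 * g[None, :] - 3) / 2 * (span[:, None] / (cfg.G - 2))
    sigma = span[:, None] / (cfg.gamma * (cfg.G - 2))
    phi = np.exp(-((x[:, None] - mu) ** 2) / (2 * sigma ** 2))
    t = np.clip(cfg.T * (1.0 - phi), 0.0, cfg.T)
    return SpikeVector.all_fired(t.ravel())


def encode_labels(y: int, J: int, cfg: CodingConfig) -> ExpectedSpikes:
    """Class ``y`` gets the early target time, every other class the late one."""
    if not 0 <= y < J:
        raise ValueError(f"label {y} outside 0..{J - 1}")
    t = np.full(J, cfg.t_late, dtype=float)
    t[y] = cfg.t_early
    return ExpectedSpikes(times=t)


def add_bias(x: np.ndarray) -> np.ndarray:
    """Append the constant bias input 1 as feature N+1."""
    x = np.asarray(x, dtype=float).ravel()
    return np.concatenate([x, [1.0]])
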