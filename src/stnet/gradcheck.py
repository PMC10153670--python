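"""Finite-difference verification of the analytic SpikeProp gradients.

For randomized small networks, every weight coordinate's analytic gradient
(the weight update divided by ``-eta``) is compared against a central
finite difference of the loss computed by full forward re-simulation on a
fine time grid.  Firing times are grid-quantized by default, which makes
finite differences degenerate, so the check runs with interpolated
threshold crossings (``SimulationConfig(refine=True)``).

Coordinates adjacent to a threshold-crossing discontinuity — where the
perturbed forward pass changes which neurons fire or which coding entries
clamp — are excluded: there the loss is genuinely non-differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import learning as L
from .coding import add_bias, encode_labels
from .networks import build_cstnet, build_pstnet, cstnet_forward, pstnet_forward
from .srm import SimulationConfig, SpikeVector, SRMLayer

__all__ = ["GradCheckResult", "gradient_check_cstnet", "gradient_check_pstnet"]

_H = 1e-4
_DT = 1e-3


@dataclass
class GradCheckResult:
    """Relative errors |analytic - fd| / |fd| over all testable coordinates."""

    errors: list = field(default_factory=list)
    n_networks: int = 0
    n_excluded: int = 0

    @property
    def median(self) -> float:
        return float(np.median(self.errors))

    @property
    def max(self) -> float:
        return float(np.max(self.errors))


def _collect(arrs_grads, state_and_loss, result: GradCheckResult,
             h: float = _H) -> None:
    """Compare analytic gradients with central differences coordinate-wise.

    ``state_and_loss()`` runs a full forward pass and returns
    ``(pattern, loss)`` where ``pattern`` captures the discrete firing /
    clamping state; coordinates whose perturbation flips the pattern are
    excluded (loss discontinuity), as are coordinates where both values
    vanish (no information).
    """
    p0, _ = state_and_loss()
    for arr, g in arrs_grads:
        for idx in np.ndindex(arr.shape):
            orig = arr[idx]
            arr[idx] = orig + h
            pa, ea = state_and_loss()
            arr[idx] = orig - h
            pb, eb = state_and_loss()
            arr[idx] = orig
            if pa != p0 or pb != p0:
                result.n_excluded += 1
                continue
            fd = (ea - eb) / (2.0 * h)
            if abs(fd) < 1e-10 and abs(g[idx]) < 1e-10:
                continue
            result.errors.append(abs(g[idx] - fd) / max(abs(fd), 1e-10))


def gradient_check_cstnet(n_networks: int = 20, seed: int = 0, *,
                          n_features: int = 3, q_hidden: int = 4,
                          n_classes: int = 2, k_synapses: int = 3,
                          dt: float = _DT) -> GradCheckResult:
    """Verify the C-STNet output-layer and sigmoid-layer gradients.

    Draws random networks and inputs until ``n_networks`` with all output
    neurons firing have been checked (the analytic rule for a silent output
    is a heuristic, not a derivative).
    """
    master = np.random.default_rng(seed)
    sim = SimulationConfig(dt=dt, refine=True)
    lcfg = L.LearningConfig(eta=0.03, denom_floor=1e-9)
    res = GradCheckResult()
    while res.n_networks < n_networks:
        rng = np.random.default_rng(master.integers(2 ** 31))
        m = build_cstnet(n_features, n_classes, q_hidden, k_synapses,
                         sim=sim, rng=rng)
        x = rng.uniform(0.2, 0.8, n_features)
        y_enc = encode_labels(int(rng.integers(n_classes)), n_classes,
                              m.coding)

        def state_and_loss():
            R, cs, out = cstnet_forward(x, m)
            return ((tuple(out.fired), tuple(cs.clamped)),
                    L.loss(out, y_enc))

        R, cs, out = cstnet_forward(x, m)
        if not out.fired.all():
            continue
        deltas = L.output_delta(out, y_enc, cs, m.out, lcfg)
        g_v = -L.output_weight_update(deltas, cs, out, m.out,
                                      lcfg.eta) / lcfg.eta
        gt = L.hidden_time_gradient(deltas, out, cs, m.out)
        g_w = -L.cstnet_ann_update(add_bias(x), R, gt, cs, lcfg.eta,
                                   m.coding.beta) / lcfg.eta
        _collect([(m.out.weights, g_v), (m.ann.weights, g_w)],
                 state_and_loss, res)
        res.n_networks += 1
    return res


def gradient_check_pstnet(n_networks: int = 20, seed: int = 0, *,
                          n_features: int = 4, G: int = 4, p_hidden: int = 3,
                          q_hidden: int = 3, n_classes: int = 2,
                          k_synapses: int = 3,
                          dt: float = _DT) -> GradCheckResult:
    """Verify all three P-STNet gradient groups (v, b, w).

    Networks whose output neurons do not all fire are redrawn; hidden
    neurons may be silent (their incoming coordinates contribute only when
    the finite difference is nonzero, which the exclusion rules handle).
    """
    from .coding import CodingConfig

    master = np.random.default_rng(seed)
    sim = SimulationConfig(dt=dt, refine=True)
    coding = CodingConfig(G=G, t_late=10.0)
    lcfg = L.LearningConfig(eta=0.03, denom_floor=1e-9)
    res = GradCheckResult()
    while res.n_networks < n_networks:
        rng = np.random.default_rng(master.integers(2 ** 31))
        m = build_pstnet(n_features, n_classes, p_hidden, q_hidden,
                         k_synapses, sim=sim, coding=coding, rng=rng)
        x = rng.uniform(0.2, 0.8, n_features)
        y_enc = encode_labels(int(rng.integers(n_classes)), n_classes,
                              m.coding)

        def state_and_loss():
            inp, hid, R, cs, out = pstnet_forward(x, m)
            return ((tuple(out.fired), tuple(hid.fired), tuple(cs.clamped)),
                    L.loss(out, y_enc))

        inp, hid, R, cs, out = pstnet_forward(x, m)
        if not out.fired.all():
            continue
        P = m.P
        deltas = L.output_delta(out, y_enc, cs, m.out, lcfg)
        g_v = -L.output_weight_update(deltas, cs, out, m.out,
                                      lcfg.eta) / lcfg.eta
        upper_rows = SRMLayer(weights=m.out.weights[:P],
                              delays=m.out.delays, kernel=m.out.kernel)
        g_b = -L.pstnet_upper_update(inp, hid, deltas, upper_rows, m.upper,
                                     out, lcfg, lcfg.eta) / lcfg.eta
        lower_rows = SRMLayer(weights=m.out.weights[P:],
                              delays=m.out.delays, kernel=m.out.kernel)
        low = SpikeVector(times=cs.times[P:], fired=cs.fired[P:],
                          clamped=cs.clamped[P:])
        gt = L.hidden_time_gradient(deltas, out, low, lower_rows)
        g_w = -L.cstnet_ann_update(add_bias(x), R, gt, low, lcfg.eta,
                                   m.coding.beta) / lcfg.eta
        _collect([(m.out.weights, g_v), (m.upper.weights, g_b),
                  (m.ann.weights, g_w)], state_and_loss, res)
        res.n_networks += 1
    return res
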