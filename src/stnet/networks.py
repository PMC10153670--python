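"""The two hybrid architectures and their joint training loop.

C-STNet stacks a sigmoid layer in front of a spiking output layer; the
reciprocal coding layer splices the analog activations into spike times.
P-STNet runs two parallel paths — a spiking hidden layer over
population/linear-encoded inputs (the "temporal" stream) and a sigmoid
layer over the raw features (the "spatial" stream) — and concatenates both
in the coding layer before a spiking output layer.  Both are trained
sample-by-sample with joint SpikeProp / gradient descent; classification is
by the earliest-firing output neuron.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .ann import SigmoidLayer, ann_forward
from .coding import (CodingConfig, add_bias, encode_labels,
                     linear_delay_encode, population_encode,
                     reciprocal_encode)
from .learning import (LearningConfig, GradientSet, loss, output_delta,
                       output_weight_update, hidden_time_gradient,
                       cstnet_ann_update, pstnet_upper_update)
from .srm import (KernelConfig, SimulationConfig, SpikeVector, SRMLayer,
                  first_crossing)

__all__ = [
    "CSTNetModel",
    "PSTNetModel",
    "TrainState",
    "TrainHistory",
    "build_cstnet",
    "build_pstnet",
    "cstnet_forward",
    "pstnet_forward",
    "forward",
    "predict",
    "predict_batch",
    "train",
    "accuracy",
    "save_model",
    "load_model",
]

CHECKPOINT_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# models


@dataclass
class CSTNetModel:
    """Concatenated hybrid: (N+1) sigmoid inputs -> Q -> coding -> J spikes."""

    ann: SigmoidLayer
    coding: CodingConfig
    out: SRMLayer
    sim: SimulationConfig

    def __post_init__(self) -> None:
        if self.ann.n_out != self.out.n_pre:
            raise ValueError("coding layer width must equal the ANN output "
                             "and the spiking layer input")

    @property
    def architecture(self) -> str:
        return f"{self.ann.n_in}:{self.ann.n_out}:{self.out.n_post}"


@dataclass
class PSTNetModel:
    """Parallel hybrid: spiking and sigmoid paths spliced in the coding layer.

    The output layer's presynaptic order is upper path first (P hidden
    spiking neurons), lower path second (Q coded sigmoid activations).
    ``encoding`` selects the upper-path input coding: "population" or
    "linear"; extrema of the (normalized) features are stored for it.
    """

    upper: SRMLayer
    ann: SigmoidLayer
    coding: CodingConfig
    out: SRMLayer
    sim: SimulationConfig
    encoding: str = "population"
    xmin: np.ndarray | float = 0.0
    xmax: np.ndarray | float = 1.0

    def __post_init__(self) -> None:
        if self.encoding not in ("population", "linear"):
            raise ValueError("encoding must be 'population' or 'linear'")
        if self.upper.n_post + self.ann.n_out != self.out.n_pre:
            raise ValueError("output layer input must equal P + Q")

    @property
    def P(self) -> int:
        return self.upper.n_post

    @property
    def Q(self) -> int:
        return self.ann.n_out

    @property
    def architecture(self) -> str:
        return (f"({self.upper.n_pre}+{self.ann.n_in}):"
                f"({self.P}+{self.Q}):{self.out.n_post}")


# ---------------------------------------------------------------------------
# initialization


def _init_srm(rng: np.random.Generator, n_pre: int, n_post: int, K: int,
              kernel_cfg: KernelConfig, sim: SimulationConfig) -> SRMLayer:
    """Uniform positive weights, rescaled so every neuron fires initially.

    Weights are drawn uniform on (0, 1) and each postsynaptic neuron's
    incoming weights are rescaled so that its peak potential in response to
    a reference volley (every presynaptic neuron spiking at t = 0) is
    ``2 * theta``.  Real input spikes arrive later and their kernels are
    truncated by the window end, so the realised peaks straddle the
    threshold from above — a silent initial network cannot learn under
    SpikeProp, so firing at initialization is essential.
    """
    from .srm import kernel as _kernel
    delays = np.arange(1, K + 1, dtype=float)
    w = rng.uniform(0.0, 1.0, size=(n_pre, n_post, K))
    # reference response of each postsynaptic neuron to a t=0 volley
    resp = _kernel(sim.grid()[None, :] - delays[:, None], kernel_cfg)  # (K, G)
    peak = np.einsum("ijk,kg->jg", w, resp).max(axis=1)  # (n_post,)
    w *= (2.0 * sim.theta / peak)[None, :, None]
    return SRMLayer(weights=w, delays=delays, kernel=kernel_cfg)


def _init_ann(rng: np.random.Generator, n_in: int, n_out: int) -> SigmoidLayer:
    """Glorot-uniform sigmoid weights."""
    lim = np.sqrt(6.0 / (n_in + n_out))
    return SigmoidLayer(weights=rng.uniform(-lim, lim, size=(n_in, n_out)))


def build_cstnet(n_features: int, n_classes: int, q_hidden: int,
                 k_synapses: int = 6, *,
                 sim: SimulationConfig = SimulationConfig(),
                 kernel: KernelConfig = KernelConfig(),
                 coding: CodingConfig | None = None,
                 rng: np.random.Generator | int | None = None) -> CSTNetModel:
    """Assemble a (N+1):Q:J C-STNet with calibrated random weights."""
    rng = np.random.default_rng(rng)
    coding = coding or CodingConfig(T=sim.T, t_late=sim.T)
    return CSTNetModel(
        ann=_init_ann(rng, n_features + 1, q_hidden),
        coding=coding,
        out=_init_srm(rng, q_hidden, n_classes, k_synapses, kernel, sim),
        sim=sim,
    )


def build_pstnet(n_features: int, n_classes: int, p_hidden: int,
                 q_hidden: int | None = None, k_synapses: int = 6, *,
                 encoding: str = "population",
                 sim: SimulationConfig = SimulationConfig(),
                 kernel: KernelConfig = KernelConfig(),
                 coding: CodingConfig | None = None,
                 xmin=0.0, xmax=1.0,
                 rng: np.random.Generator | int | None = None) -> PSTNetModel:
    """Assemble a P-STNet; by default P = Q and population input coding."""
    rng = np.random.default_rng(rng)
    q_hidden = p_hidden if q_hidden is None else q_hidden
    coding = coding or CodingConfig(T=sim.T, t_late=sim.T)
    m = n_features * coding.G if encoding == "population" else n_features
    return PSTNetModel(
        upper=_init_srm(rng, m, p_hidden, k_synapses, kernel, sim),
        ann=_init_ann(rng, n_features + 1, q_hidden),
        coding=coding,
        out=_init_srm(rng, p_hidden + q_hidden, n_classes, k_synapses,
                      kernel, sim),
        sim=sim,
        encoding=encoding,
        xmin=xmin,
        xmax=xmax,
    )


# ---------------------------------------------------------------------------
# forward passes


def cstnet_forward(x: np.ndarray, model: CSTNetModel):
    """Sigmoid -> reciprocal coding -> spiking output.

    Returns ``(R, coding_spikes, output_spikes)``; the intermediates are
    what the backward pass consumes.
    """
    xb = add_bias(x)
    R = ann_forward(xb, model.ann)
    coding_spikes = reciprocal_encode(R, model.coding)
    out = first_crossing(coding_spikes, model.out, model.sim)
    return R, coding_spikes, out


def _encode_upper(x: np.ndarray, model: PSTNetModel) -> SpikeVector:
    if model.encoding == "population":
        return population_encode(x, model.coding, model.xmin, model.xmax)
    return linear_delay_encode(x, model.xmin, model.xmax, model.coding.T)


def pstnet_forward(x: np.ndarray, model: PSTNetModel):
    """Both paths, spliced in the coding layer, then the spiking output.

    Returns ``(input_spikes, hidden_spikes, R, coding_spikes, output_spikes)``
    where ``coding_spikes`` is the upper-then-lower concatenation feeding the
    output layer.
    """
    input_spikes = _encode_upper(x, model)
    hidden = first_crossing(input_spikes, model.upper, model.sim)
    xb = add_bias(x)
    R = ann_forward(xb, model.ann)
    lower = reciprocal_encode(R, model.coding)
    coding_spikes = SpikeVector(
        times=np.concatenate([hidden.times, lower.times]),
        fired=np.concatenate([hidden.fired, lower.fired]),
        clamped=np.concatenate([np.zeros(model.P, dtype=bool),
                                lower.clamped]),
    )
    out = first_crossing(coding_spikes, model.out, model.sim)
    return input_spikes, hidden, R, coding_spikes, out


def forward(x: np.ndarray, model) -> SpikeVector:
    """Output spike vector of either architecture for one sample."""
    if isinstance(model, CSTNetModel):
        return cstnet_forward(x, model)[2]
    return pstnet_forward(x, model)[4]


# ---------------------------------------------------------------------------
# prediction


def predict(output: SpikeVector) -> int:
    """Earliest-firing output neuron wins.

    Ties are broken by the larger peak membrane potential, then by the
    lower index; if no neuron fired, the one with the largest peak
    potential over the window is chosen.
    """
    fired = output.fired
    peaks = output.peaks if output.peaks is not None \
        else np.zeros_like(output.times)
    if not fired.any():
        return int(np.argmax(peaks))
    times = np.where(fired, output.times, np.inf)
    tmin = times.min()
    tied = np.nonzero(times == tmin)[0]
    if tied.size == 1:
        return int(tied[0])
    return int(tied[np.argmax(peaks[tied])])


def predict_batch(X: np.ndarray, model) -> np.ndarray:
    return np.array([predict(forward(x, model)) for x in X], dtype=int)


def accuracy(X: np.ndarray, y: np.ndarray, model) -> float:
    """Fraction of samples whose earliest output spike matches the label."""
    return float(np.mean(predict_batch(X, model) == np.asarray(y)))


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainState:
    """Stopping rule: run while epoch < max_epoch and MSE > min_mse."""

    max_epoch: int = 100
    min_mse: float = 0.0
    shuffle: bool = True
    seed: int | None = None


@dataclass
class TrainHistory:
    """Per-epoch mean squared spike-time error and training accuracy."""

    mse: list = field(default_factory=list)
    accuracy: list = field(default_factory=list)

    @property
    def epochs(self) -> int:
        return len(self.mse)


def _update_cstnet(x, y_enc, model: CSTNetModel, lcfg: LearningConfig,
                   eta: float) -> float:
    R, coding_spikes, out = cstnet_forward(x, model)
    e = loss(out, y_enc)
    deltas = output_delta(out, y_enc, coding_spikes, model.out, lcfg)
    d_v = output_weight_update(deltas, coding_spikes, out, model.out, eta)
    grad_t = hidden_time_gradient(deltas, out, coding_spikes, model.out)
    d_w = cstnet_ann_update(add_bias(x), R, grad_t, coding_spikes, eta,
                            model.coding.beta)
    model.out.weights += d_v
    model.ann.weights += d_w
    return e


def _update_pstnet(x, y_enc, model: PSTNetModel, lcfg: LearningConfig,
                   eta: float) -> float:
    input_spikes, hidden, R, coding_spikes, out = pstnet_forward(x, model)
    e = loss(out, y_enc)
    deltas = output_delta(out, y_enc, coding_spikes, model.out, lcfg)
    d_v = output_weight_update(deltas, coding_spikes, out, model.out, eta)
    # upper path: chain through the hidden spiking layer
    upper_rows = SRMLayer(weights=model.out.weights[:model.P],
                          delays=model.out.delays, kernel=model.out.kernel)
    d_b = pstnet_upper_update(input_spikes, hidden, deltas, upper_rows,
                              model.upper, out, lcfg, eta)
    # lower path: chain through the reciprocal coding into the sigmoid layer
    lower_rows = SRMLayer(weights=model.out.weights[model.P:],
                          delays=model.out.delays, kernel=model.out.kernel)
    lower_spikes = SpikeVector(times=coding_spikes.times[model.P:],
                               fired=coding_spikes.fired[model.P:],
                               clamped=coding_spikes.clamped[model.P:])
    grad_t = hidden_time_gradient(deltas, out, lower_spikes, lower_rows)
    d_w = cstnet_ann_update(add_bias(x), R, grad_t, lower_spikes, eta,
                            model.coding.beta)
    model.out.weights += d_v
    model.upper.weights += d_b
    model.ann.weights += d_w
    # wake up silent hidden neurons: no SpikeProp gradient reaches them,
    # so boost their incoming weights until they fire again
    if not hidden.fired.all():
        model.upper.weights[:, ~hidden.fired, :] *= lcfg.silent_boost
    return e


def train(model, X: np.ndarray, y: np.ndarray,
          lcfg: LearningConfig = LearningConfig(),
          state: TrainState = TrainState()) -> TrainHistory:
    """Joint SpikeProp / gradient-descent training (online updates).

    Samples are presented one at a time; each presentation runs a full
    forward pass and applies the weight increments immediately.  The
    presentation order is reshuffled every epoch (seedable; switch off for
    strict order replication).  MSE is the mean over samples of the summed
    squared spike-time error, and training stops when it reaches
    ``state.min_mse`` or after ``state.max_epoch`` epochs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    J = model.out.n_post
    encoded = [encode_labels(int(c), J, model.coding) for c in y]
    rng = np.random.default_rng(state.seed)
    step = _update_cstnet if isinstance(model, CSTNetModel) else _update_pstnet
    hist = TrainHistory()
    epoch = 0
    mse = np.inf
    while epoch < state.max_epoch and mse > state.min_mse:
        eta = lcfg.rate_at(epoch)
        order = rng.permutation(len(X)) if state.shuffle else np.arange(len(X))
        sq_err = 0.0
        for i in order:
            e = step(X[i], encoded[i], model, lcfg, eta)
            if not np.isfinite(e):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, sample {i}")
            sq_err += 2.0 * e  # summed squared error of this sample
        mse = sq_err / len(X)
        hist.mse.append(mse)
        hist.accuracy.append(accuracy(X, y, model))
        epoch += 1
    return hist


# ---------------------------------------------------------------------------
# checkpoints


def _sim_dict(sim: SimulationConfig) -> dict:
    return {"T": sim.T, "theta": sim.theta, "dt": sim.dt,
            "refine": sim.refine}


def save_model(model, path) -> None:
    """Serialize a model to a versioned JSON checkpoint (round-trip exact)."""
    kind = "cstnet" if isinstance(model, CSTNetModel) else "pstnet"
    doc = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "kind": kind,
        "sim": _sim_dict(model.sim),
        "kernel": {"tau": model.out.kernel.tau},
        "coding": asdict(model.coding),
        "out_weights": model.out.weights.tolist(),
        "out_delays": model.out.delays.tolist(),
        "ann_weights": model.ann.weights.tolist(),
    }
    if kind == "pstnet":
        doc.update({
            "upper_weights": model.upper.weights.tolist(),
            "upper_delays": model.upper.delays.tolist(),
            "encoding": model.encoding,
            "xmin": np.asarray(model.xmin, dtype=float).tolist(),
            "xmax": np.asarray(model.xmax, dtype=float).tolist(),
        })
    Path(path).write_text(json.dumps(doc))


def load_model(path):
    """Load a checkpoint written by :func:`save_model`."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != CHECKPOINT_FORMAT_VERSION:
        raise ValueError(f"unsupported checkpoint version "
                         f"{doc.get('format_version')!r}")
    sim = SimulationConfig(**doc["sim"])
    kernel_cfg = KernelConfig(**doc["kernel"])
    coding = CodingConfig(**doc["coding"])
    out = SRMLayer(weights=np.array(doc["out_weights"]),
                   delays=np.array(doc["out_delays"]), kernel=kernel_cfg)
    ann = SigmoidLayer(weights=np.array(doc["ann_weights"]))
    if doc["kind"] == "cstnet":
        return CSTNetModel(ann=ann, coding=coding, out=out, sim=sim)
    upper = SRMLayer(weights=np.array(doc["upper_weights"]),
                     delays=np.array(doc["upper_delays"]), kernel=kernel_cfg)
    return PSTNetModel(upper=upper, ann=ann, coding=coding, out=out, sim=sim,
                       encoding=doc["encoding"],
                       xmin=np.array(doc["xmin"]), xmax=np.array(doc["xmax"]))
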