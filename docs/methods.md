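# Methods

## Neuron models

**SRM neuron.** Each connection between a presynaptic neuron `q` and a
postsynaptic neuron `j` carries `K` synapses with distinct delays
`d^k = k` (time units, configurable). The membrane potential is the
weighted sum of kernel responses

    u_j(t) = Σ_q Σ_k v_qj^k · ε(t − t_q − d^k),
    ε(s) = (s/τ) e^{1 − s/τ} for s > 0, 0 otherwise,

with `τ = 7` by default, so each PSP rises to a unit peak `τ` time units
after it starts and decays slowly. A neuron fires at most one spike, at the
first time `u_j ≥ θ` (`θ = 1`) within the window `[0, T]` (`T = 10`);
neurons that never cross carry the clamped time `T` downstream with a
`fired = False` flag.

**Sigmoid neuron.** The spatial half is a dense layer of logistic units
over the features plus a constant bias input of 1 appended as feature
`N+1`. One sigmoid hidden layer is used throughout; the coding layers
between the halves hold no trainable parameters.

## Time discretization

Potentials are simulated on a uniform grid with step `dt = 0.01`; the
reported firing time is the first grid point at or above threshold, with no
interpolation — simple, reproducible, and refinable by shrinking `dt`.
`SimulationConfig(refine=True)` optionally interpolates the crossing
linearly between the bracketing grid points. This matters only where
firing times must be a smooth function of the weights: a dt-quantized time
makes central finite differences degenerate (the difference of a quantized
quantity at `h = 1e-4` is a multiple of `dt/2h`), so the gradient
verification runs with refinement on and `dt = 1e-3`. Training uses the
plain grid times.

## Codings

* **Reciprocal coding** `t_q = β/R_q` (`β = 1`) converts sigmoid
  activations to spike times; times beyond `T` are clamped to `T` and
  flagged. The clamp is flat, so the backward factor through a clamped
  entry is zero; `R_q` is floored at `1e-3` inside the `−β/R_q²` backward
  factor to avoid overflow.
* **Linear time-delay coding** `t = (x_max − x)/(x_max − x_min) · T` maps a
  feature range affinely onto the window (large values early). Used for the
  P-STNet upper path when `N·G` would be impractically wide (the default
  switch point is `N·G > 256`, i.e. population coding is the default for
  small tabular data).
* **Gaussian population coding** spreads each feature over `G ≥ 3`
  overlapping receptive fields with centers
  `μ_g = I_min + (2g−3)/2 · (I_max−I_min)/(G−2)` and width
  `σ = (I_max−I_min)/(γ(G−2))`, `γ = 1.5` — the conventional SpikeProp
  receptive-field layout. The response `φ = exp(−(x−μ)²/2σ²)` maps to the
  spike time `t = T(1−φ)`, so a feature sitting exactly on a center fires
  immediately. The activation→time map and the field constants are
  package choices (only the field count `G` has an established
  convention); all are configurable.
* **Label coding**: the correct class gets the early target time
  `t_early = 3`, every other class `t_late = T`. The values are
  configurable; 3 leaves the correct neuron room to fire strictly earlier
  than the window end while staying reachable given synaptic delays up to
  `K`.

## Learning rules

Output-layer SpikeProp: `δ_j = (t_j^d − t_j) / (∂u_j/∂t)(t_j)` and
`Δv_qj^k = −η δ_j ε(t_j − t_q − d^k)`. The chain continues into the
sigmoid layer via `∂E/∂t_q = Σ_j δ_j Σ_k v_qj^k (−ε'(t_j − t_q − d^k))`
and `∂t_q/∂w_nq = (−β/R_q²) R_q(1−R_q) x_n`, and into the P-STNet upper
hidden layer via the standard hidden-layer SpikeProp quotient (the output
deltas chained through the PSPs the hidden spike feeds, divided by the
slope of the hidden neuron's own potential at its firing time).

Updates are applied per sample in a presentation order reshuffled every
epoch (seedable; `shuffle=False` restores strict order replication). The
learning rate is `η = 0.03` fixed by default, with an optional
multiplicative per-epoch decay. Training stops when the per-epoch MSE
(mean over samples of the summed squared spike-time error) reaches
`min_mse`, or after `max_epoch` epochs.

### Degenerate cases and stabilizations

SpikeProp's delta denominators vanish at near-tangential threshold
crossings, and several states carry no gradient at all. The package
handles each explicitly:

* **Shallow crossings** (fired neurons): `|∂u/∂t|` is floored at
  `denom_floor = 0.1`, sign preserved — the standard SpikeProp
  stabilization.
* **Silent output neurons**: a neuron that never crossed has no crossing
  slope; its raw slope at the clamped time `T` is often *negative* (a
  decaying potential), and a sign-preserving floor there drives the
  neuron's weights toward −∞ — we observed exactly this death spiral.
  Instead silent outputs use a positive reference slope
  (`unfired_denom = 1.0`, i.e. θ per time unit), so the update always
  pushes the neuron toward firing with a moderate magnitude. The tiny
  `denom_floor` must not be used here: `|δ| ≈ 70` kicks saturate the
  upstream sigmoid layer into the coding clamp, which then freezes it.
* **Silent hidden spiking neurons** (P-STNet upper path): no gradient
  reaches them, so their incoming increments are zero; each silent
  encounter additionally multiplies the neuron's incoming weights by
  `silent_boost = 1.05` (classic SpikeProp boosting). Without boosting, an
  upper path that starts silent stays dead for an entire run.
* **Clamped coding entries**: zero backward factor (the clamp is flat),
  avoiding biased updates from saturated sigmoid units.
* **Ties and all-silent outputs at prediction time**: earliest spike wins;
  ties break by the larger peak membrane potential over the window, then
  the lower index; if nothing fired, the largest peak wins. This keeps
  prediction a deterministic total order.

### Initialization

Spiking weights are drawn uniform on (0, 1) and rescaled per postsynaptic
neuron so its peak response to a reference volley (all presynaptic spikes
at `t = 0`) equals `2θ`. Real inputs arrive later and their kernels are
truncated by the window end, so realised peaks straddle `θ` from above and
most neurons fire from the start — a silent initial network cannot learn
under SpikeProp. (A simpler calibration against the window-averaged kernel
response proved insufficient: population-coded inputs arrive spread over
the window and left entire hidden layers silent.) Sigmoid weights are
Glorot-uniform. Both draws are seedable.

## Gradient verification

`stnet.gradcheck` compares every weight coordinate's analytic gradient
(the update divided by `−η`) against a central finite difference
(`h = 1e-4`) of the loss under full forward re-simulation at `dt = 1e-3`
with refined crossings. Coordinates whose perturbation changes the
discrete firing/clamping pattern are excluded — the loss is genuinely
discontinuous there — as are coordinates where both values vanish.
Networks with silent output neurons are redrawn, because the silent-output
rule is a recovery heuristic, not a derivative. Median relative errors on
20 random networks per architecture are ~1e-4.

## Synthetic data

`make_synthetic` generates three deterministic families: isotropic
Gaussian **blobs** at random centers with enforced pairwise separation
(default 5× the noise sd — "moderately separated": nearly but not
perfectly learnable after fold splitting), a 2-feature **xor**
checkerboard, and concentric **rings**. The learning demonstrations use
3-class blobs with `N = 4`, 50 samples per class, noise sd 1. These
fixtures emulate low-dimensional tabular classification with balanced
classes and isotropic noise; they do not exercise feature correlation,
class imbalance, missing data at scale, or high dimensionality, so passing
them shows the training machinery works, not that benchmark accuracies on
real datasets are reproduced (those require the external datasets).

## Evaluation protocol

Repeated stratified k-fold cross-validation (5×5 by default; stratification
falls back to plain folds with a warning when a class is smaller than the
fold count), accuracies reported in percent as mean (std) over
repeats×folds, plus mean epochs to stopping. The generalization gap is
training minus testing accuracy in percentage points. Cross-dataset
comparison uses competition ranking of test accuracies (ties share the
minimum rank) averaged over datasets; applied to the stored published
benchmark table this reproduces the published average ranks exactly.
Large datasets with predefined train/test splits are evaluated by repeated
holdout rather than folding (via the `train`/`evaluate` commands).

## Problem sizes

The bundled demonstrations and checks use desk-scale problems chosen to
exercise every code path: gradient verification on 20 networks per
architecture (C: N=3, Q=4, J=2, K=3; P: N=4, G=4, P=Q=3, J=2), and
cross-validation on 150-sample blob datasets with Q=8 (C-STNet) or
P=Q=4, G=4 (P-STNet), K=6, `η = 0.03`, at most 100 epochs with a
`min_mse = 0.5` stopping target (a fitted sample leaves well under 0.5
summed squared error, so the target marks convergence rather than
truncation).

## Known limitations

Single-spike neurons only (no refractoriness or multi-spike decoding); no
momentum/Adam or minibatching (plain online gradient descent by design);
grid-based simulation rather than event-driven exact crossing detection;
the checkpoint format stores dense weights as JSON, which is exact but not
compact; CV repeats are independent trainings, so wall time scales with
repeats×folds.
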