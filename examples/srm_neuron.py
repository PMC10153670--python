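"""A single spike-response-model neuron, step by step.

Builds one spiking neuron with a single delayed synapse, shows the PSP
kernel shape, the membrane potential it produces, and the resulting
threshold-crossing (firing) time.
"""

import numpy as np

import stnet as st

tau = st.KernelConfig(tau=7.0)
print("PSP kernel eps(s) = (s/tau) exp(1 - s/tau), tau = 7")
for s in (0.0, 3.5, 7.0, 14.0):
    print(f"  eps({s:4.1f}) = {st.kernel(s, tau):.4f}")
print("-> zero before the spike arrives, peak value 1 at s = tau.\n")

# one presynaptic neuron spiking at t=3, one synapse with weight 2, delay 1
layer = st.SRMLayer(weights=np.array([[[2.0]]]), delays=np.array([1.0]),
                    kernel=tau)
inputs = st.SpikeVector.all_fired([3.0])
sim = st.SimulationConfig(T=10.0, theta=1.0, dt=0.01)

for t in (4.0, 5.0, 6.0, 10.0):
    u = st.membrane_potential(t, inputs, layer, j=0)
    print(f"membrane potential u({t:4.1f}) = {u:.4f}")

out = st.first_crossing(inputs, layer, sim)
print(f"\nthreshold theta = {sim.theta}: neuron fires at t = {out.times[0]:.2f}"
      f" (fired = {bool(out.fired[0])})")
print("The PSP starts at t = 3 + 1 = 4 (spike time + synaptic delay) and the")
print("potential first reaches the threshold about 1.6 time units later.")
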