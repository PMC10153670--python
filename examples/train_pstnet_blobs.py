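"""Train the parallel hybrid (P-STNet) on synthetic Gaussian blobs.

Two streams run side by side: a spiking hidden layer over Gaussian
population-coded inputs (temporal stream) and a sigmoid layer over the raw
features (spatial stream).  Their spike times are spliced in the coding
layer and classified by a final spiking layer.
"""

import stnet as st

ds = st.minmax_normalize(st.make_synthetic(
    "blobs", n_per_class=50, n_features=4, n_classes=3, noise=1.0, seed=1))

model = st.build_pstnet(ds.n_features, ds.n_classes, p_hidden=4, q_hidden=4,
                        k_synapses=6,
                        coding=st.CodingConfig(G=4, t_late=10.0), rng=1)
print(f"architecture {model.architecture}")
print("(population-coded inputs + raw+bias : spiking P + sigmoid Q : "
      "spiking outputs)\n")

hist = st.train(model, ds.X, ds.y, st.LearningConfig(eta=0.03),
                st.TrainState(max_epoch=100, min_mse=0.5, seed=1))
for e, (mse, acc) in enumerate(zip(hist.mse, hist.accuracy), start=1):
    print(f"epoch {e:3d}  MSE {mse:6.2f}  train accuracy {acc:.3f}")

inp, hid, R, cs, out = st.pstnet_forward(ds.X[0], model)
print(f"\nsample 0:")
print(f"  upper-path hidden spike times {hid.times.round(2)}")
print(f"  lower-path coding spike times {cs.times[model.P:].round(2)}")
print(f"  output spike times {out.times.round(2)} "
      f"-> predicted class {st.predict(out)} (true {ds.y[0]})")
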