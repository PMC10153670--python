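"""Repeated stratified 5-fold cross-validation of both hybrids.

Reports mean (std) training and testing accuracy in percent over all
folds, plus the mean number of epochs to the MSE stopping target.
"""

import stnet as st

ds = st.minmax_normalize(st.make_synthetic(
    "blobs", n_per_class=50, n_features=4, n_classes=3, noise=1.0, seed=1))

builders = {
    "C-STNet": lambda n, j, rng: st.build_cstnet(n, j, 8, 6, rng=rng),
    "P-STNet": lambda n, j, rng: st.build_pstnet(
        n, j, 4, 4, 6, coding=st.CodingConfig(G=4, t_late=10.0), rng=rng),
}

for name, build in builders.items():
    res = st.cross_validate(build, ds, st.CVConfig(folds=5, repeats=1,
                                                   seed=1),
                            st.LearningConfig(eta=0.03),
                            st.TrainState(max_epoch=100, min_mse=0.5))
    gap = st.generalization_gap(res.train_acc, res.test_acc)
    print(f"{name}: train {res.train_acc:.1f} ({res.train_std:.1f})  "
          f"test {res.test_acc:.1f} ({res.test_std:.1f})  "
          f"gap {gap:.1f} pp  mean epochs {res.mean_epochs:.1f}")
print("\nEach fold trains a fresh network on 4/5 of the data and tests on")
print("the held-out 1/5; the gap is train minus test accuracy.")
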