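"""Leader-follower graphs over discriminative pairs, per group.

For each selected channel pair, every subject votes with the sign of its
mean normalized lead-matrix entry; the majority direction becomes a
directed edge weighted by the vote proportion.  Nodes are layered so
activity flows downward.  Comparing groups shows where the ordering is
consistent, where it is variable, and which pairs flip direction.
"""

import numpy as np

from cyclicity import CohortSpec, cohort_features, gen_cohort
from cyclicity.features import CohortFeatures
from cyclicity.graphs import consistency_graph, flipped_edges
from cyclicity.selection import monte_carlo_stability, select_stable

spec = CohortSpec(
    n_group_a=12, n_group_b=12, n_channels=12, n_samples=200, n_periods=5,
    ordering_jitter_a=0.05, ordering_jitter_b=1.2, subject_jitter=0.2,
    contrast_channels=(0, 1), seed=6,
)
features = cohort_features(gen_cohort(spec))
ranking = monte_carlo_stability(features, n_trials=300, top_k=20, seed=0)
pairs = select_stable(ranking, n_select=8)

graphs = {}
for group in ("control", "patient"):
    mask = (features.meta["group"] == group).to_numpy()
    sub = CohortFeatures(
        features.meta[mask].reset_index(drop=True), features.X[mask], features.pair_index
    )
    graphs[group] = consistency_graph(sub, pairs)
    weights = [d["weight"] for _, _, d in graphs[group].graph.edges(data=True)]
    print(f"{group}: mean direction consistency "
          f"{np.mean(weights):.2f} over {len(weights)} edges; "
          f"layers {graphs[group].layers}")

flips = flipped_edges(graphs["control"], graphs["patient"])
print("pairs flipping leader-follower direction between groups:",
      [f"{a}-{b}" for a, b in flips] or "none")
# Higher consistency in the low-jitter group means its subjects agree on
# who leads whom; flips mark pairs whose ordering reverses between groups.
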