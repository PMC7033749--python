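"""Simulate one clustered mixture-2PL dataset from the factorial design.

Builds the E5010 cell (equal mixing, 50 clusters of 10 examinees, 10 items,
30% class-variant items), draws generating item parameters, and simulates
responses with recorded true latent memberships.
"""

import numpy as np

from mlmirt import Condition, default_structure, generate_dataset, make_item_params

condition = Condition(n_items=10, mixing="equal", pct_variant=30,
                      n_clusters=50, cluster_size=10)
params = make_item_params(condition.n_items, condition.pct_variant, delta=1.0, seed=11)
structure = default_structure(condition.mixing)
data = generate_dataset(condition, params, structure, seed=7)

print(f"condition {condition.label}: {data.n_persons} examinees x {data.n_items} items "
      f"in {data.n_clusters} clusters")
print(f"class-variant items: {np.flatnonzero(~params.class_invariant_items()) + 1} "
      f"(class-2 threshold shifted by +/-1 logit)")
shares = [float(np.mean(data.true_within_class == g)) for g in (1, 2)]
print(f"empirical within-class shares: {shares[0]:.3f}/{shares[1]:.3f} "
      f"(generating marginal mixing: 0.5/0.5)")
print(f"overall proportion correct: {data.responses.mean():.3f}")
# The within-class shares should sit near the generating mixing proportions;
# deviations reflect finite-sample noise at N = 500.
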