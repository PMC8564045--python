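"""From a feature table to one network per sample, and its 48 statistics.

Every unordered feature pair gets a fitted edge model; a sample's network
is the complete weighted graph of those models evaluated at its values.
Vertex strengths (weighted degrees) and 48 descriptive statistics of eight
topological characteristics summarize each network.
"""

import numpy as np

import parenclitic as pc

spec = pc.SphereSpec(model_kind="ideal", dim=6,
                     n_case_train=30, n_control_train=30,
                     n_case_test=8, n_control_test=8, seed=11)
ds = pc.sample_ideal_sphere(spec)

models = pc.fit_pair_models(ds.table.train(), "wSA", seed=0)
print(f"fitted {len(models.models)} pair models "
      f"(= C({ds.table.n_features}, 2))")

# one sample's network
row = ds.table.features.iloc[0]
net = pc.build_sample_network(models, row)
print(f"network: {net.n_nodes} nodes, weights in "
      f"[{net.weights.min():.3f}, {net.weights.max():.3f}]")
print("vertex strengths:", np.round(pc.strengths(net), 3))

vec = pc.characteristic_feature_vector(net)
print(f"\ncharacteristic feature vector: {len(vec)} entries, e.g.")
print(vec[["strength_mean", "closeness_mean", "edge_weights_max",
           "page_rank_sd"]].round(4).to_string())

# strengths for the whole table at once; mean strength tracks the radius
S = pc.strength_matrix(models, ds.table)
mean_strength = S.X.mean(axis=1)
for label, name in ((0, "controls"), (1, "cases")):
    m = mean_strength[ds.table.labels == label].mean()
    print(f"mean vertex strength, {name}: {m:.2f}")
# cases sit far from the control region in most planes, so their edges
# (case probabilities) and hence strengths are systematically larger
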