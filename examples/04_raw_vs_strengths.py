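"""Do strength-based classifiers beat raw-data classifiers when n << p?

A 60-dimensional sphere with only 15 TRAIN samples per class: classifiers
on the raw coordinates can overfit badly, while boosted trees on wSA vertex
strengths exploit the per-plane SVM ensemble.  Directed AUC locks the score
orientation on TRAIN, so TEST AUC below 0.5 indicates inverted overfitting.
"""

import parenclitic as pc

spec = pc.SphereSpec(model_kind="ideal", dim=60,
                     n_case_train=15, n_control_train=15,
                     n_case_test=4, n_control_test=4, seed=5)
ds = pc.sample_ideal_sphere(spec)

models = pc.fit_pair_models(ds.table.train(), "wSA", seed=5)
strengths = pc.strength_matrix(models, ds.table)

result = pc.compare_raw_vs_strengths(ds.table, strengths, seed=5)
print(result.to_string(index=False))
# 3 classifiers x 2 representations, all on the identical TRAIN/TEST split

best_gain = pc.best_result_difference(result)
print(f"\nbest-strengths minus best-raw TEST AUC: {best_gain:+.3f}")
print("small-n/large-p regime here:",
      pc.is_small_sample_regime(train_size=30, dim=60))
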