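"""Generate the three sphere benchmarks and inspect their geometry.

Points in the unit N-ball are labelled by their radius: controls live in
[0.01, 0.5], cases in [0.5, 1.0].  The noisy variant appends 50 uniform
noise columns; the broken variant replaces half the coordinates with noise
while keeping the original radius as the (now imperfect) ground truth.
"""

import numpy as np

import parenclitic as pc

spec = pc.SphereSpec(model_kind="ideal", dim=10,
                     n_case_train=115, n_control_train=115,
                     n_case_test=29, n_control_test=29, seed=42)
ideal = pc.sample_ideal_sphere(spec)
print(f"ideal sphere: {len(ideal.table)} samples x {ideal.table.n_features} features")

norms = np.linalg.norm(ideal.table.X, axis=1)
print(f"max |stored radius - row norm| = {np.abs(norms - ideal.radius).max():.2e}")
# the stored radius IS the Euclidean norm for the ideal model

noisy = pc.add_noise_features(ideal, k=50)
broken = pc.break_sphere(ideal)
print(f"noisy:  {noisy.table.n_features} features "
      f"({len(noisy.signal_columns)} signal + {len(noisy.noise_columns)} noise)")
print(f"broken: {broken.table.n_features} features "
      f"({len(broken.signal_columns)} signal + {len(broken.noise_columns)} noise)")
print("radius preserved after degradation:",
      np.array_equal(ideal.radius, broken.radius))

grid = pc.generate_grid("ideal", base_seed=0)
print(f"\nfull design grid: {len(grid)} datasets "
      f"(dims {sorted({s.dim for s in grid})})")
# 288 = 8 dimensions x 6 case-TRAIN counts x 6 control-TRAIN counts;
# TEST counts are 25% of TRAIN per class.
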