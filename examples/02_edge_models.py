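"""The three pairwise edge models on one feature plane.

Each model turns a sample's position in a 2-feature plane into an edge
weight measuring deviation from normality (wLRPA, wKDEPA, fitted on
controls only) or probability of being a case (wSA, fitted on both classes).
"""

import numpy as np

import parenclitic as pc

rng = np.random.default_rng(7)

# controls follow y = 2x + noise; one clearly deviant query point
controls = np.column_stack([rng.normal(size=200)] * 2)
controls[:, 1] = 2 * controls[:, 0] + rng.normal(0, 0.3, 200)

lin = pc.fit_linear_edge(controls)
print(f"wLRPA: slope={lin.slope:.3f} intercept={lin.intercept:.3f} "
      f"resid_sd={lin.resid_sd:.3f}")
on_line = pc.linear_edge_weight(lin, 1.0, lin.slope * 1.0 + lin.intercept)
deviant = pc.linear_edge_weight(lin, 1.0, 5.0)
print(f"  weight on the regression line: {on_line:.3f} (no deviation)")
print(f"  weight at (1, 5):              {deviant:.3f} residual sd units away")

kde = pc.fit_kde_edge(controls)
print(f"\nwKDEPA: grid mass = {kde.total_mass:.4f} (should be ~1)")
w_mode = pc.kde_edge_weight(kde, 0.0, 0.0)
w_far = pc.kde_edge_weight(kde, 4.0, -4.0)
print(f"  weight near the density mode: {w_mode:.3f} "
      f"(fraction of mass in denser regions)")
print(f"  weight far from the controls: {w_far:.3f} (saturates at 1)")

# wSA sees both classes: cases shifted off the control cloud
cases = controls + rng.normal(2.0, 0.3, size=controls.shape)
pts = np.vstack([controls, cases])
labels = np.r_[np.zeros(200), np.ones(200)].astype(int)
svm = pc.fit_svm_edge(pts, labels, seed=0)
print(f"\nwSA: P(case) at a control point = "
      f"{pc.svm_edge_weight(svm, 0.0, 0.0):.3f}")
print(f"     P(case) at a case point    = "
      f"{pc.svm_edge_weight(svm, 2.0, 2.0):.3f}")
# edge weights are calibrated class probabilities, always in [0, 1]
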