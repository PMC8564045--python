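# Methods

This note documents the models implemented in `parenclitic`, the choices
made where the method family leaves details open, and what the synthetic
benchmark does and does not establish.

## Per-sample networks

Given a TRAIN fold of a samples × features table, one 2-D reference model is
fitted per unordered feature pair; a sample's network is the complete graph
over features whose edge (i, j) carries that model's score at the sample's
values. Edges are never dropped: a weighted edge exists for every sample
and every pair, including degenerate ones (below).

### wLRPA — regression-residual z-score

Fitted on TRAIN **controls only**. The regression direction is fixed by
column order: the higher-indexed feature is regressed on the lower-indexed
one (OLS). The weight is |(r − r̄)/s_r| where r is the sample's residual and
r̄, s_r are the mean and *sample* standard deviation (n−1) of the control
residuals — the spread of the observed control deviations, not the
regression standard error. Weights are unbounded above. If the control
residual spread is below 1e−12 (e.g. a constant response column) the model
is kept but returns weight 0 with a `DegeneracyWarning`, consistent with the
sanitization convention; a pair whose predictor has zero spread cannot be
fitted at all and is replaced by a constant-zero placeholder recorded in the
model set's metadata. A symmetrized variant (mean of the two directions) is
not provided; the fixed direction keeps results deterministic and
documented.

### wKDEPA — highest-density-region mass

Also fitted on TRAIN controls only. Density is a Gaussian *product* kernel
with Scott's rule per axis (σ̂ · n^(−1/6) for two dimensions), evaluated on
a 101 × 101 grid spanning the control range padded by 3 bandwidths per axis
(grid size and padding are arguments of `fit_kde_edge`). The weight of a
query is the normalised mass of all grid cells **strictly** denser than the
query's bilinearly interpolated density: 0 exactly at the grid's densest
cell, increasing as the query moves into the tails. Queries outside the
grid saturate at weight 1. This saturation replaces the unbounded distance
continuation used by some earlier KDE-based pipelines: it keeps all wKDEPA
weights in [0, 1] and matches the probabilistic reading "mass of the region
more normal than this point". The padding guarantees ≥ 99.7% of the kernel
mass lies on the grid, so saturation only affects genuinely extreme points.

If U is a draw from the fitted density itself, its HDR mass is Uniform(0,1)
by construction; `KdeEdgeModel.sample` draws from the fitted mixture so this
calibration is directly testable (mean ≈ 0.5, KS-uniform). Draws from the
*underlying* distribution are systematically mis-calibrated by the kernel
smoothing (the KDE is an over-smoothed version of it), which is a property
of KDE itself, not of the HDR transform.

### wSA — synolytic SVM probability

Fitted on TRAIN **controls and cases**. Inputs are standardized with TRAIN
mean/sd per axis; an RBF-kernel SVM (C = 1, gamma = "scale") with Platt
probability calibration (the classifier's built-in seeded 5-fold internal
CV) supplies P(case | x, y) as the edge weight. Determinism: each pair gets
its own seed derived from the model-set seed and the pair index via a
counter-keyed `SeedSequence`, so fitting is reproducible and independent of
evaluation order.

## Characteristics and the 48-vector

Shortest-path characteristics treat weights as **distances** (natural for
wLRPA/wKDEPA, where weight = deviation from normality): closeness is
1/Σ_j d(i, j) over Dijkstra distances, betweenness and edge betweenness are
unnormalized shortest-path counts. Spectral/flow characteristics treat
weights as **connection strengths**: page rank (damping 0.85, tolerance
1e−12), eigenvector centrality (principal eigenvector of the weight matrix)
and authority score (principal singular direction; identical to eigenvector
centrality up to sign for symmetric matrices — retained for completeness of
the characteristic list). Both spectral vectors are scaled to maximum 1
with the sign fixed by making the largest-magnitude component positive; a
numerically zero leading eigenvalue yields the zero vector. Strength is the
row sum; edge weights are the upper triangle in (i < j) order.

Zero-weight edges are legitimate zero-length paths; the complete-graph
topology keeps everything reachable. Values that still come out as
NA/±Inf (e.g. closeness on an all-zero network) are replaced by 0 before
summarizing — by design this can erase class differences in a
characteristic, but never affects strengths, which are finite sums. The
summary statistics are zeros (count of |x| < 1e−12), min, max, mean, sample
sd (0 for length-1 vectors), and coefvar = sd/mean (0/0 sanitized to 0),
in that order, over the eight characteristics in the order listed above:
48 named entries, always finite.

## Sphere benchmark

The generator emulates a classification problem whose latent structure is
fully known: samples are R·u with u uniform on the unit (N−1)-sphere
(normalized Gaussians) and R uniform on the class band — controls
[0.01, 0.5], cases [0.5, 1.0], so the label is exactly the radius
thresholded at 0.5. Radius-uniform sampling is the default because the
radius is the quantity the correlation study reads out; uniform-in-volume
is available via `radial_law="uniform_volume"`. Noisy spheres append 50
i.i.d. Uniform(−1, 1) columns; broken spheres keep the first ⌈N/2⌉
coordinates and replace the rest with Uniform(−1, 1) (the ceiling rule
preserves at least half the signal for odd N; the *last* columns are
replaced, deterministically). The stored radius is never recalculated after
degradation — in the degraded models it is deliberately an imperfect label
of position.

The design grid is the full product of dimensions
{2, 3, 10, 30, 60, 90, 120, 150} and per-class TRAIN counts
{15, 65, …, 265} (288 datasets per variant); TEST counts are
round-half-up of 25% of the TRAIN counts. Per-dataset seeds are
`(base·1009 + index) mod 2³¹`.

What passing the sphere suites shows: that the pipeline recovers a smooth
latent deviation coordinate and resists overfitting when n ≪ p **for data
whose classes are radially separated in every 2-D projection**. What it
does not show: performance on data with correlated features, heavy tails,
batch structure, or class geometries invisible in 2-D projections (a
checkerboard-like arrangement defeats all pairwise models by construction).
Real-table operators (mean imputation, zero-variance removal, label
binarization, the balanced 40+40 resampling design with 20/20 TRAIN/TEST
per class) are provided, but no real datasets ship with the package — only
the 16 benchmark dataset shells (feature dimension and class sizes) used by
the design-count checks.

## Evaluation harness

Directed AUC: rank-based (midrank ties); the orientation that makes TRAIN
AUC ≥ 0.5 is locked and applied to TEST, so TEST AUC < 0.5 signals an
inverted (overfit) decision rule rather than being silently flipped.
The three reference classifiers are pipelines with internal TRAIN
standardization and stratified 5-fold CV-AUC selection over small grids:
elastic-net logistic (l1_ratio {0.1, 0.5, 0.9} × 10 C values, saga),
single-hidden-layer perceptron (lbfgs; {1, 3, 5} hidden units × weight
decay {0, 0.01, 0.1}), and gradient-boosted trees (depth {1, 2, 3} ×
{50, 100, 150} rounds, learning rate 0.3). The grids are deliberately
small and documented rather than exhaustive; CV-AUC selection is the
contract. Paired Wilcoxon: two-sided signed-rank, zeros dropped, exact
null for ≤ 25 non-zero pairs, otherwise normal approximation with
continuity correction; identical vectors return p = 1 with a warning.
The small-n/large-p indicator is round-half-up of ln(TRAIN size /
dimension) ≤ 0; with the 40-sample TRAIN folds of the resampling design it
selects the 7 dataset shells of dimension ≥ 33.

## Study sizes

The bundled studies (`parenclitic.studies`) regenerate data, refit all pair
models and recompute statistics per repetition. The radius-recovery study
uses 10-dim ideal spheres at 115/115 TRAIN, 29/29 TEST (20 seeds in the
test suite; 10 in the acceptance script). The small-sample study uses
120-dim spheres at 15/15 TRAIN, 4/4 TEST — C(120, 2) = 7140 SVM fits per
repetition — with 10 seeds in the test suite and 6 in the acceptance
script; medians over seeds are the reported quantities. These sizes keep a
full from-scratch rerun to minutes on one CPU while leaving the medians
stable across base seeds.

## Known limitations

- Pairwise planes only: feature triples/quadruples and per-edge model
  choice are out of scope.
- No edge pruning or network simplification; exported graphs are complete.
- The authority score duplicates eigenvector centrality on undirected
  networks (kept so the characteristic set stays the canonical eight).
- wKDEPA inherits KDE's boundary and bandwidth sensitivity; only Scott's
  rule is built in.
- Binarized (thresholded) networks are supported only through
  `binarize_weight`; the analysis pipeline is weighted throughout.
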