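"""Evaluation protocol: directed AUC, classifier harness, paired comparisons.

The central question the harness answers is whether classifiers trained on
vertex-strength matrices beat the same classifiers trained on the raw
feature matrix, especially in the small-n / large-p regime.  AUC direction
(cases-high vs controls-high) is locked on the TRAIN fold and applied to
TEST, so TEST AUC below 0.5 is possible and meaningful.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import InvalidLabelsError, SchemaError
from .spheres import round_half_up
from .table import TEST, TRAIN, FeatureTable

CLASSIFIER_KINDS = (
    "elastic_net_logistic",
    "single_hidden_layer_net",
    "gradient_boosted_trees",
)

#: Feature dimensions and class sizes of the 16 public benchmark datasets
#: used as the real-data design (name, n_features, n_cases, n_controls).
#: Only these shell parameters enter the package: the resampling design and
#: the small-p selection rule operate on dimensions and class counts alone.
REAL_DATASET_SHELLS = (
    ("banknote", 4, 610, 762),
    ("transfusion", 4, 178, 570),
    ("vertebral_2c", 6, 210, 100),
    ("breast_cancer_wisconsin", 10, 241, 458),
    ("ilpd", 10, 167, 416),
    ("planning_relax", 12, 52, 130),
    ("climate_crashes", 18, 494, 46),
    ("diabetic_retinopathy", 19, 611, 540),
    ("spect", 22, 212, 55),
    ("ionosphere", 33, 126, 225),
    ("qsar", 41, 356, 699),
    ("spectf", 44, 212, 55),
    ("sonar", 60, 97, 111),
    ("cortex", 77, 510, 570),
    ("urban", 147, 122, 553),
    ("arrhythmia", 260, 245, 207),
)


# ---------------------------------------------------------------------------
# directed AUC
# ---------------------------------------------------------------------------

@dataclass
class DirectedAucResult:
    """TRAIN/TEST AUC with the score orientation locked on TRAIN."""

    auc_train: float
    auc_test: float
    direction: str  # "controls_lt_cases" or "controls_gt_cases"


def directed_auc(train_scores, train_labels, test_scores,
                 test_labels) -> DirectedAucResult:
    """Rank-based AUC with TRAIN-locked direction (midrank tie handling).

    The orientation giving TRAIN AUC >= 0.5 is chosen on TRAIN and applied
    unchanged to TEST, so the TEST value can drop below 0.5.
    """
    train_labels = np.asarray(train_labels, dtype=int)
    test_labels = np.asarray(test_labels, dtype=int)
    if len(set(train_labels)) < 2:
        raise InvalidLabelsError("TRAIN labels must contain both classes")
    auc_train = roc_auc_score(train_labels, np.asarray(train_scores, dtype=float))
    if len(set(test_labels)) < 2:
        auc_test = np.nan
    else:
        auc_test = roc_auc_score(test_labels, np.asarray(test_scores, dtype=float))
    if auc_train >= 0.5:
        return DirectedAucResult(float(auc_train), float(auc_test),
                                 "controls_lt_cases")
    return DirectedAucResult(float(1 - auc_train), float(1 - auc_test),
                             "controls_gt_cases")


def univariate_logistic_auc(feature_train, labels_train, feature_test,
                            labels_test) -> DirectedAucResult:
    """Directed AUC of a one-variable logistic regression (glm analogue)."""
    x_tr = np.asarray(feature_train, dtype=float).reshape(-1, 1)
    x_te = np.asarray(feature_test, dtype=float).reshape(-1, 1)
    if x_tr.std() < 1e-12:
        warnings.warn("zero-variance feature: AUC defaults to 0.5", UserWarning,
                      stacklevel=2)
        return DirectedAucResult(0.5, 0.5, "controls_lt_cases")
    # standardize for solver stability; affine maps leave ranks unchanged
    mu, sd = x_tr.mean(), x_tr.std()
    model = LogisticRegression(C=np.inf, max_iter=1000)
    model.fit((x_tr - mu) / sd, np.asarray(labels_train, dtype=int))
    p_tr = model.predict_proba((x_tr - mu) / sd)[:, 1]
    p_te = model.predict_proba((x_te - mu) / sd)[:, 1]
    return directed_auc(p_tr, labels_train, p_te, labels_test)


# ---------------------------------------------------------------------------
# classifier harness
# ---------------------------------------------------------------------------

def _parameter_grid(kind: str, seed: int):
    if kind == "elastic_net_logistic":
        est = LogisticRegression(solver="saga", max_iter=5000)
        grid = {"clf__l1_ratio": [0.1, 0.5, 0.9],
                "clf__C": np.logspace(-3, 3, 10)}
    elif kind == "single_hidden_layer_net":
        est = MLPClassifier(solver="lbfgs", max_iter=2000, random_state=seed)
        grid = {"clf__hidden_layer_sizes": [(1,), (3,), (5,)],
                "clf__alpha": [0.0, 0.01, 0.1]}
    elif kind == "gradient_boosted_trees":
        from xgboost import XGBClassifier
        est = XGBClassifier(learning_rate=0.3, eval_metric="logloss",
                            n_jobs=1, verbosity=0, tree_method="hist",
                            random_state=seed)
        grid = {"clf__max_depth": [1, 2, 3],
                "clf__n_estimators": [50, 100, 150]}
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    return est, grid


def fit_classifier(kind: str, X_train, y_train, cv_folds: int = 5,
                   seed: int = 0):
    """Fit one of the three reference classifiers with CV-AUC model selection.

    Features are centred and scaled inside the pipeline using TRAIN
    statistics only; hyperparameters come from a small documented grid
    selected by stratified ``cv_folds``-fold cross-validated AUC.
    """
    y_train = np.asarray(y_train, dtype=int)
    if len(set(y_train)) < 2:
        raise InvalidLabelsError("training labels must contain both classes")
    est, grid = _parameter_grid(kind, seed)
    pipe = Pipeline([("scale", StandardScaler()), ("clf", est)])
    n_min = min(np.bincount(y_train))
    cv = StratifiedKFold(n_splits=min(cv_folds, n_min), shuffle=True,
                         random_state=seed)
    search = GridSearchCV(pipe, grid, scoring="roc_auc", cv=cv, n_jobs=1,
                          refit=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(np.asarray(X_train, dtype=float), y_train)
    return search


def classifier_scores(model, X) -> np.ndarray:
    """Case-probability scores of a fitted harness model."""
    return model.predict_proba(np.asarray(X, dtype=float))[:, 1]


# ---------------------------------------------------------------------------
# raw vs strengths comparison
# ---------------------------------------------------------------------------

def _check_aligned(a: FeatureTable, b: FeatureTable) -> None:
    if (list(a.sample_ids) != list(b.sample_ids)
            or list(a.folds) != list(b.folds)
            or list(a.labels) != list(b.labels)):
        raise SchemaError("raw and strength tables must share samples, labels "
                          "and folds exactly")


def compare_raw_vs_strengths(table: FeatureTable, strength_table: FeatureTable,
                             classifier_kinds=CLASSIFIER_KINDS,
                             seed: int = 0) -> pd.DataFrame:
    """Directed TEST AUC of every classifier on both representations.

    Both tables must carry identical sample ids, labels and folds, so every
    (classifier, representation) cell is evaluated on exactly the same
    split — the paired design the significance test relies on.
    """
    _check_aligned(table, strength_table)
    rows = []
    for rep_name, rep in (("raw", table), ("strengths", strength_table)):
        tr, te = rep.train(), rep.test()
        for kind in classifier_kinds:
            model = fit_classifier(kind, tr.X, tr.labels, seed=seed)
            res = directed_auc(classifier_scores(model, tr.X), tr.labels,
                               classifier_scores(model, te.X), te.labels)
            rows.append({"classifier": kind, "representation": rep_name,
                         "auc_train": res.auc_train, "auc_test": res.auc_test,
                         "direction": res.direction})
    return pd.DataFrame(rows)


def best_result_difference(comparison: pd.DataFrame) -> float:
    """Max TEST AUC over classifiers on strengths minus the same on raw."""
    best = comparison.groupby("representation")["auc_test"].max()
    return float(best["strengths"] - best["raw"])


def paired_wilcoxon(auc_a, auc_b) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value on AUC vectors.

    Zero differences are dropped (classical convention); the exact null
    distribution is used for n <= 25 remaining pairs, otherwise the normal
    approximation with continuity correction.  Identical vectors are a
    degenerate case and return p = 1 with a warning.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        warnings.warn("all paired differences are zero; p-value degenerate",
                      UserWarning, stacklevel=2)
        return 1.0
    method = "exact" if len(nonzero) <= 25 else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                         method=method, correction=(method == "approx"))
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# radius-correlation study
# ---------------------------------------------------------------------------

def radius_correlations(char_table: pd.DataFrame, radii) -> pd.Series:
    """|Pearson r| of each characteristic statistic against sample radius.

    Zero-variance statistics (undefined correlation) sanitize to 0.
    """
    radii = np.asarray(radii, dtype=float)
    stat_cols = [c for c in char_table.columns
                 if c not in ("sample_id", "label", "fold")]
    if len(char_table) != len(radii):
        raise ValueError("characteristic rows and radii must align")
    if len(radii) < 3:
        raise ValueError("need at least 3 samples")
    if not np.isfinite(radii).all():
        raise ValueError("radii must be finite")
    out = {}
    for col in stat_cols:
        v = char_table[col].to_numpy(dtype=float)
        if v.std() < 1e-12 or radii.std() < 1e-12:
            out[col] = 0.0
        else:
            out[col] = float(abs(stats.pearsonr(v, radii)[0]))
    return pd.Series(out)


# ---------------------------------------------------------------------------
# real-data design operators
# ---------------------------------------------------------------------------

def make_real_subsets(table: FeatureTable, n_rep: int = 20,
                      seed: int = 0) -> list[FeatureTable]:
    """The balanced resampling design: n_rep subsets of 80 samples each.

    Every subset holds 40 cases and 40 controls drawn without replacement,
    split at random into 20 TRAIN / 20 TEST per class.
    """
    case_idx = np.flatnonzero(table.labels == 1)
    control_idx = np.flatnonzero(table.labels == 0)
    if len(case_idx) < 40 or len(control_idx) < 40:
        raise InvalidLabelsError("need at least 40 samples per class")
    rng = np.random.default_rng(seed)
    subsets = []
    for _ in range(n_rep):
        rows, folds = [], []
        for idx in (case_idx, control_idx):
            chosen = rng.choice(idx, size=40, replace=False)
            chosen = rng.permutation(chosen)
            rows.append(chosen)
            folds += [TRAIN] * 20 + [TEST] * 20
        order = np.concatenate(rows)
        sub = table.subset(order)
        sub.folds = np.array(folds, dtype=object)
        subsets.append(sub)
    return subsets


def preprocess_table(df: pd.DataFrame, case_label=None, label_map=None,
                     label_column: str = "label",
                     id_column: str | None = None) -> FeatureTable:
    """Generic ingestion of a raw CSV table into a FeatureTable.

    Missing feature values are imputed with the column mean; all-missing
    columns are dropped with a warning, as are zero-variance columns.
    Labels binarize either through ``case_label`` (that value -> 1, all
    others -> 0) or an explicit ``label_map``; any pre-existing fold labels
    are discarded (folds are reassigned by the resampling design).
    """
    df = df.copy()
    if label_column not in df.columns:
        raise SchemaError(f"label column {label_column!r} missing")
    raw_labels = df.pop(label_column)
    if label_map is not None:
        unmapped = set(raw_labels) - set(label_map)
        if unmapped:
            raise SchemaError(f"unmappable label values: {sorted(unmapped)}")
        labels = raw_labels.map(label_map).to_numpy(dtype=int)
    elif case_label is not None:
        labels = (raw_labels == case_label).astype(int).to_numpy()
    else:
        labels = raw_labels.to_numpy(dtype=int)
    sample_ids = None
    if id_column is not None and id_column in df.columns:
        sample_ids = df.pop(id_column).astype(str).to_numpy()
    df = df.drop(columns=[c for c in ("fold", "sample_id") if c in df.columns])

    features = df.apply(pd.to_numeric, errors="coerce")
    all_missing = [c for c in features.columns if features[c].isna().all()]
    if all_missing:
        warnings.warn(f"dropping all-missing columns: {all_missing}",
                      UserWarning, stacklevel=2)
        features = features.drop(columns=all_missing)
    features = features.fillna(features.mean())
    constant = [c for c in features.columns if features[c].std(ddof=0) < 1e-12]
    if constant:
        warnings.warn(f"dropping zero-variance columns: {constant}",
                      UserWarning, stacklevel=2)
        features = features.drop(columns=constant)
    folds = np.array([TRAIN] * len(features), dtype=object)
    return FeatureTable(features=features, labels=labels, folds=folds,
                        sample_ids=sample_ids)


def is_small_sample_regime(train_size: int, dim: int) -> bool:
    """round(ln(train_size / dim)) <= 0: the regime where strength-based
    models are expected to beat raw-data models (round = half-up)."""
    return round_half_up(math.log(train_size / dim)) <= 0


def small_p_dataset_names(train_size: int = 40) -> list[str]:
    """Benchmark shells in the small-n/large-p regime for a given TRAIN size."""
    return [name for name, dim, _, _ in REAL_DATASET_SHELLS
            if is_small_sample_regime(train_size, dim)]
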