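"""Reproducible benchmark studies on the sphere models.

These bundle the two headline experiments so they can be re-run from tests,
scripts or a shell with one call each:

* :func:`radius_recovery_study` — does the mean vertex strength of a
  synolytic (wSA) network recover the hidden radius of an ideal sphere, and
  how well does it separate the classes on its own?
* :func:`small_sample_study` — in the small-n / large-p regime (TRAIN size
  far below the dimension), do boosted trees on wSA vertex strengths beat
  raw-data classifiers?

Each repetition regenerates the dataset with its own derived seed, refits
every pair model and recomputes all statistics from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import evaluation, networks, spheres


def _rep_seed(base_seed: int, rep: int) -> int:
    return int(np.random.SeedSequence([base_seed, rep]).generate_state(1)[0]
               % 2**31)


def radius_recovery_study(n_seeds: int = 20, dim: int = 10,
                          n_case_train: int = 115, n_control_train: int = 115,
                          base_seed: int = 0,
                          include_boosted_trees: bool = True) -> pd.DataFrame:
    """wSA strength-based radius recovery on ideal spheres, one row per seed.

    Columns: ``abs_corr_strength_mean`` (|Pearson r| between the network
    ``strength_mean`` statistic and the radius over TEST samples),
    ``univariate_auc`` (directed TEST AUC of a one-variable logistic model on
    ``strength_mean``) and, optionally, ``xgb_strengths_auc`` (directed TEST
    AUC of gradient-boosted trees on the full vertex-strength matrix).
    """
    rows = []
    for rep in range(n_seeds):
        seed = _rep_seed(base_seed, rep)
        spec = spheres.SphereSpec(
            model_kind="ideal", dim=dim,
            n_case_train=n_case_train, n_control_train=n_control_train,
            n_case_test=spheres.round_half_up(0.25 * n_case_train),
            n_control_test=spheres.round_half_up(0.25 * n_control_train),
            seed=seed)
        ds = spheres.sample_ideal_sphere(spec)
        table = ds.table
        models = networks.fit_pair_models(table.train(), "wSA", seed=seed)

        strengths = networks.strength_matrix(models, table)
        test_mask = table.folds == "TEST"
        strength_mean = strengths.X.mean(axis=1)

        corr = float(abs(np.corrcoef(strength_mean[test_mask],
                                     ds.radius[test_mask])[0, 1]))
        uni = evaluation.univariate_logistic_auc(
            strength_mean[~test_mask], table.labels[~test_mask],
            strength_mean[test_mask], table.labels[test_mask])
        row = {"seed": seed, "abs_corr_strength_mean": corr,
               "univariate_auc": uni.auc_test}

        if include_boosted_trees:
            tr, te = strengths.train(), strengths.test()
            model = evaluation.fit_classifier("gradient_boosted_trees",
                                              tr.X, tr.labels, seed=seed)
            res = evaluation.directed_auc(
                evaluation.classifier_scores(model, tr.X), tr.labels,
                evaluation.classifier_scores(model, te.X), te.labels)
            row["xgb_strengths_auc"] = res.auc_test
        rows.append(row)
    return pd.DataFrame(rows)


def small_sample_study(n_seeds: int = 10, dim: int = 120,
                       n_case_train: int = 15, n_control_train: int = 15,
                       base_seed: int = 0) -> pd.DataFrame:
    """Raw-data classifiers vs boosted trees on wSA strengths, 15/15 TRAIN.

    One row per seed with directed TEST AUCs: ``xgb_strengths`` (gradient
    boosted trees on the vertex-strength matrix) and ``glmnet_raw`` /
    ``nnet_raw`` / ``xgb_raw`` (the three reference classifiers on the raw
    coordinates).
    """
    rows = []
    for rep in range(n_seeds):
        seed = _rep_seed(base_seed, rep)
        spec = spheres.SphereSpec(
            model_kind="ideal", dim=dim,
            n_case_train=n_case_train, n_control_train=n_control_train,
            n_case_test=spheres.round_half_up(0.25 * n_case_train),
            n_control_test=spheres.round_half_up(0.25 * n_control_train),
            seed=seed)
        table = spheres.sample_ideal_sphere(spec).table
        models = networks.fit_pair_models(table.train(), "wSA", seed=seed)
        strengths = networks.strength_matrix(models, table)

        def test_auc(kind, rep_table):
            tr, te = rep_table.train(), rep_table.test()
            model = evaluation.fit_classifier(kind, tr.X, tr.labels, seed=seed)
            return evaluation.directed_auc(
                evaluation.classifier_scores(model, tr.X), tr.labels,
                evaluation.classifier_scores(model, te.X), te.labels).auc_test

        rows.append({
            "seed": seed,
            "xgb_strengths": test_auc("gradient_boosted_trees", strengths),
            "glmnet_raw": test_auc("elastic_net_logistic", table),
            "nnet_raw": test_auc("single_hidden_layer_net", table),
            "xgb_raw": test_auc("gradient_boosted_trees", table),
        })
    return pd.DataFrame(rows)
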