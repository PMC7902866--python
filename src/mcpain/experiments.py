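"""Reproducible validation experiments on synthetic cohorts.

These drivers regenerate cohorts from scratch and run the full pipeline
(voxel draws -> KDE densities -> MC networks -> nested feature selection
under leave-one-out CV), so they measure what a user of the package would
measure. They back both the test suite and the acceptance script.

Problem sizes: parameter recovery uses the package's reference recovery
setting (60 participants, 20 ROIs = 190 MC edges, 10 planted edges, planted
linear model explaining ~70% of threshold variance); null calibration uses
40 participants x 12 ROIs, where a pure-noise run is informative but cheap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import (
    compare_correlations,
    compare_error_sets,
    evaluate_predictions,
)
from .mc import cohort_mc_features
from .parcellation import toy_parcellation
from .samples import compute_gmv
from .selection import select_features
from .simulate import CohortSpec, generate_cohort, planted_matching

__all__ = ["recovery_experiment", "null_calibration", "null_test_rejection_rates"]


def _derived_seed(base: int, k: int) -> int:
    return int((base * 100_003 + 7919 * k + 1) % (2**31 - 1))


def recovery_experiment(
    base_seed: int,
    n_seeds: int = 10,
    n_participants: int = 60,
    n_rois: int = 20,
    n_planted: int = 10,
    target_r2: float = 0.7,
    n_voxels: int = 1500,
) -> pd.DataFrame:
    """Planted-signal recovery across replicate cohorts.

    For each seed: generate a cohort whose laser thresholds are a sparse
    linear function of true MC edges, run nested-mode selection + LOO-CV
    prediction from (a) empirical MC features and (b) regional GMV (which
    carries no planted signal by construction), and record the Pearson r,
    MAE of both feature sets, and the recall of planted edges in the
    consensus selected set.
    """
    parc = toy_parcellation(n_rois)
    rows = []
    for k in range(n_seeds):
        seed = _derived_seed(base_seed, k)
        spec = CohortSpec(
            n_participants=n_participants,
            n_rois=n_rois,
            n_voxels=n_voxels,
            planted_edges=planted_matching(n_rois, n_planted),
            target_r2=target_r2,
            seed=seed,
        )
        samples, phenotypes, truth = generate_cohort(spec, parc)
        mc = cohort_mc_features(samples, parc)
        gmv = compute_gmv(samples, parc)
        y = phenotypes["laser_threshold_J"].to_numpy()

        sel_mc = select_features(
            mc.to_numpy(),
            y,
            mode="nested",
            schedule=(100, 10, 1),
            feature_names=list(mc.columns),
            seed=_derived_seed(base_seed, 1000 + k),
        )
        rep_mc = evaluate_predictions(sel_mc.predictions, y)
        sel_gmv = select_features(
            gmv.to_numpy(),
            y,
            mode="nested",
            schedule=(10, 1),
            feature_names=list(gmv.columns),
            seed=_derived_seed(base_seed, 2000 + k),
        )
        rep_gmv = evaluate_predictions(sel_gmv.predictions, y)
        planted = set(truth.planted_pair_names)
        recall = len(planted & set(sel_mc.selected_names))
        rows.append(
            {
                "seed": seed,
                "pearson_r_mc": rep_mc.pearson_r,
                "mae_mc": rep_mc.mae,
                "pearson_r_gmv": rep_gmv.pearson_r,
                "mae_gmv": rep_gmv.mae,
                "planted_recall": recall,
                "n_planted": n_planted,
                "consensus_size": len(sel_mc.selected),
            }
        )
    return pd.DataFrame(rows)


def null_calibration(
    base_seed: int,
    n_seeds: int = 20,
    n_participants: int = 40,
    n_rois: int = 12,
    n_voxels: int = 800,
) -> pd.DataFrame:
    """Nested-mode LOO correlation on cohorts with pure-noise thresholds."""
    parc = toy_parcellation(n_rois)
    rows = []
    for k in range(n_seeds):
        seed = _derived_seed(base_seed, 5000 + k)
        spec = CohortSpec(
            n_participants=n_participants,
            n_rois=n_rois,
            n_voxels=n_voxels,
            planted_edges=None,
            noise_sd=1.0,
            seed=seed,
        )
        samples, phenotypes, _ = generate_cohort(spec, parc)
        mc = cohort_mc_features(samples, parc)
        y = phenotypes["laser_threshold_J"].to_numpy()
        sel = select_features(
            mc.to_numpy(),
            y,
            mode="nested",
            schedule=(10, 1),
            seed=_derived_seed(base_seed, 6000 + k),
        )
        rows.append({"seed": seed, "pearson_r": evaluate_predictions(sel.predictions, y).pearson_r})
    return pd.DataFrame(rows)


def null_test_rejection_rates(
    base_seed: int,
    n_replicates: int = 200,
    n: int = 60,
    n_boot: int = 500,
    alpha: float = 0.05,
) -> dict:
    """False-positive rates of the two model-comparison tests under the null.

    Each replicate draws two error samples from one distribution (rank-sum
    test) and two independent noise predictors for one response (bootstrap
    correlation-difference test); rates are the fraction of replicates with
    p < alpha.
    """
    ranksum_rejects = 0
    bootstrap_rejects = 0
    for k in range(n_replicates):
        rng = np.random.default_rng(_derived_seed(base_seed, 9000 + k))
        a = np.abs(rng.normal(size=n))
        b = np.abs(rng.normal(size=n))
        if compare_error_sets(a, b).p_value < alpha:
            ranksum_rejects += 1
        y = rng.normal(size=n)
        pa, pb = rng.normal(size=n), rng.normal(size=n)
        res = compare_correlations(
            pa, pb, y, n_boot=n_boot, seed=_derived_seed(base_seed, 12_000 + k)
        )
        if res.p_value < alpha:
            bootstrap_rejects += 1
    return {
        "ranksum_rejection_rate": ranksum_rejects / n_replicates,
        "bootstrap_rejection_rate": bootstrap_rejects / n_replicates,
        "n_replicates": n_replicates,
    }
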