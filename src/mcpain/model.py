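"""High-level prediction model: features -> LOO-CV pain-threshold prediction.

`MCPredictionModel` bundles a feature matrix (MC edges, regional GMV, or
their concatenation) with one threshold type, runs coefficient-ranked
feature selection under leave-one-out cross-validation, and returns an
`MCPredictionResults` carrying per-participant predictions, the error and
correlation metrics, the selected features, and a `summary()` table.

    model = MCPredictionModel.from_cohort(samples, phenotypes, parc,
                                          feature_set="mc", threshold="laser")
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .evaluation import EvaluationReport, compute_pain_scores, evaluate_predictions
from .mc import cohort_mc_features
from .parcellation import Parcellation
from .samples import ROISampleSet, compute_gmv
from .selection import GMV_SCHEDULE, MC_SCHEDULE, SelectionResult, select_features

THRESHOLD_COLUMNS = {
    "laser": "laser_threshold_J",
    "cold": "cold_threshold_s",
    "score": "pain_sensitivity_score",
}


def feature_table(
    samples: ROISampleSet,
    parc: Parcellation,
    feature_set: str,
    mc_table: pd.DataFrame | None = None,
    gmv_mode: str = "sum",
    voxel_volume: float = 1.0,
) -> pd.DataFrame:
    """Assemble the participants x features table for one feature set.

    ``mc_table`` may carry precomputed MC features (participants x pairs) to
    avoid re-running the KDE stage.
    """
    if feature_set not in ("mc", "gmv", "gmv_mc"):
        raise InvalidParameterError(
            f"feature_set must be one of mc/gmv/gmv_mc, got {feature_set!r}"
        )
    parts: list[pd.DataFrame] = []
    if feature_set in ("gmv", "gmv_mc"):
        parts.append(compute_gmv(samples, parc, voxel_volume=voxel_volume, mode=gmv_mode))
    if feature_set in ("mc", "gmv_mc"):
        if mc_table is None:
            mc_table = cohort_mc_features(samples, parc)
        parts.append(mc_table)
    if len(parts) == 1:
        return parts[0]
    return pd.concat(parts, axis=1)


class MCPredictionModel:
    """Pain-threshold prediction from morphometric features under LOO-CV.

    Parameters
    ----------
    endog : array-like (N,)
        Threshold values (one type).
    exog : DataFrame or array (N, K)
        Feature table; DataFrame columns become feature names.
    mode : {"nested", "group_level"}
        Feature-selection mode (see :mod:`mcpain.selection`).
    schedule : tuple of int
        Coarse-to-fine search intervals; default (100, 10, 1) for >=100
        features, (10, 1) otherwise.
    """

    def __init__(
        self,
        endog,
        exog,
        participant_ids=None,
        feature_names=None,
        mode: str = "nested",
        schedule=None,
        error_metric: str = "mae",
        pls_options: dict | None = None,
        inner_cv: int = 5,
        inner_repeats: int = 2,
        seed: int = 0,
        feature_set: str = "",
        threshold_type: str = "",
    ):
        if isinstance(exog, pd.DataFrame):
            if feature_names is None:
                feature_names = [str(c) for c in exog.columns]
            if participant_ids is None:
                participant_ids = [str(i) for i in exog.index]
            exog = exog.to_numpy(dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        self.endog = np.asarray(endog, dtype=float).ravel()
        if self.exog.shape[0] != self.endog.shape[0]:
            raise InvalidParameterError("endog/exog row mismatch")
        self.feature_names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{j}" for j in range(self.exog.shape[1])]
        )
        self.participant_ids = (
            list(participant_ids)
            if participant_ids is not None
            else [str(i) for i in range(len(self.endog))]
        )
        if schedule is None:
            schedule = MC_SCHEDULE if self.exog.shape[1] >= 100 else GMV_SCHEDULE
        self.mode = mode
        self.schedule = tuple(schedule)
        self.error_metric = error_metric
        self.pls_options = dict(pls_options or {})
        self.inner_cv = inner_cv
        self.inner_repeats = inner_repeats
        self.seed = seed
        self.feature_set = feature_set
        self.threshold_type = threshold_type

    @classmethod
    def from_cohort(
        cls,
        samples: ROISampleSet,
        phenotypes: pd.DataFrame,
        parc: Parcellation,
        feature_set: str = "mc",
        threshold: str = "laser",
        mc_table: pd.DataFrame | None = None,
        **kwargs,
    ) -> "MCPredictionModel":
        """Build from a sample set + phenotype table, aligning participants."""
        if threshold not in THRESHOLD_COLUMNS:
            raise InvalidParameterError(
                f"threshold must be one of {sorted(THRESHOLD_COLUMNS)}"
            )
        X = feature_table(samples, parc, feature_set, mc_table=mc_table)
        pheno = phenotypes.set_index("participant_id")
        if threshold == "score":
            scored = compute_pain_scores(phenotypes)
            pheno = scored.set_index("participant_id")
        missing = [p for p in X.index if p not in pheno.index]
        if missing:
            raise InvalidParameterError(f"phenotypes missing participants {missing}")
        y = pheno.loc[X.index, THRESHOLD_COLUMNS[threshold]].to_numpy(float)
        return cls(
            y, X, feature_set=feature_set, threshold_type=threshold, **kwargs
        )

    def fit(self) -> "MCPredictionResults":
        selection = select_features(
            self.exog,
            self.endog,
            mode=self.mode,
            schedule=self.schedule,
            error_metric=self.error_metric,
            feature_names=self.feature_names,
            pls_options=self.pls_options,
            inner_cv=self.inner_cv,
            inner_repeats=self.inner_repeats,
            seed=self.seed,
        )
        report = evaluate_predictions(
            selection.predictions,
            self.endog,
            participant_ids=self.participant_ids,
            feature_set=self.feature_set,
            threshold_type=self.threshold_type,
        )
        return MCPredictionResults(self, selection, report)


class MCPredictionResults:
    """LOO-CV predictions, metrics and selected features of a fitted model."""

    def __init__(
        self,
        model: MCPredictionModel,
        selection: SelectionResult,
        report: EvaluationReport,
    ):
        self.model = model
        self.selection = selection
        self.report = report

    # metric passthroughs
    @property
    def predictions(self) -> np.ndarray:
        return self.report.y_pred

    @property
    def mae(self) -> float:
        return self.report.mae

    @property
    def mrae(self) -> float | None:
        return self.report.mrae

    @property
    def pearson_r(self) -> float:
        return self.report.pearson_r

    @property
    def selected_features(self) -> list[str] | None:
        return self.selection.selected_names

    def summary(self) -> str:
        sel = self.selection
        lines = [
            "Morphological-Connectivity Pain Prediction (LOO-CV)",
            "=" * 58,
            f"Feature set:        {self.model.feature_set or '(custom)'}"
            f"  ({self.model.exog.shape[1]} features)",
            f"Threshold type:     {self.model.threshold_type or '(custom)'}",
            f"Participants (N):   {self.report.n}",
            f"Selection mode:     {sel.mode}",
            f"Search schedule:    {self.model.schedule}",
        ]
        if sel.mode == "group_level":
            lines.append(f"Selected m*:        {sel.m_star}")
        else:
            lines.append(
                f"Consensus features: {len(sel.selected)}"
                f" (median per-fold m = {int(np.median(sel.per_fold_m))})"
            )
        mrae_txt = "n/a (zero true values)" if self.mrae is None else f"{self.mrae:.4f}"
        lines += [
            "-" * 58,
            f"MAE:                {self.mae:.4f}",
            f"MRAE:               {mrae_txt}",
            f"Pearson r:          {self.pearson_r:.4f}",
        ]
        return "\n".join(lines)

    def plot_predictions(self, ax=None):
        """Predicted-vs-true scatter with the identity line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        y, yh = self.report.y_true, self.report.y_pred
        ax.scatter(y, yh, s=18, alpha=0.7, edgecolor="none")
        lims = [min(y.min(), yh.min()), max(y.max(), yh.max())]
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel("measured threshold")
        ax.set_ylabel("predicted threshold")
        ax.set_title(
            f"{self.model.feature_set} / {self.model.threshold_type}  "
            f"r={self.pearson_r:.2f}"
        )
        return ax

    def to_dict(self) -> dict:
        out = self.report.to_dict()
        out["selection"] = self.selection.to_dict()
        out["mode"] = self.selection.mode
        return out
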