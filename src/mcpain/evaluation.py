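"""Cross-validated evaluation, metrics and model comparisons.

Prediction accuracy is summarised by the mean absolute error
MAE = (1/N) sum |y_hat_i - y_i|, the mean relative absolute error
MRAE = (1/N) sum |(y_hat_i - y_i) / y_i|, and the Pearson correlation
between predicted and true thresholds; error sets of two feature sets are
compared by a two-sided Wilcoxon rank-sum (Mann-Whitney) test, correlation
coefficients by a participant bootstrap. Selected MC edges are summarised by
hemisphere-lobe pair counts, and MC features can be cross-correlated with
regional GMV with Benjamini-Hochberg control.

The composite pain sensitivity score is the per-participant arithmetic mean
of the min-max normalised laser and cold thresholds (range 0-1; higher score
means lower pain sensitivity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError
from .mc import PAIR_SEP
from .parcellation import Parcellation
from .pls import fit_simpls

__all__ = [
    "compute_pain_scores",
    "loocv",
    "mae",
    "mrae",
    "pearson_r",
    "EvaluationReport",
    "evaluate_predictions",
    "ComparisonResult",
    "compare_error_sets",
    "compare_correlations",
    "LobePairSummary",
    "lobe_pair_counts",
    "mc_gmv_correlation",
]


# ------------------------------------------------------------ pain scores ---

def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise InvalidParameterError("constant threshold column: normalization undefined")
    return (v - lo) / (hi - lo)


def compute_pain_scores(
    phenotypes: pd.DataFrame, normalization: str = "minmax"
) -> pd.DataFrame:
    """Min-max normalise both thresholds and average them into a 0-1 score.

    Expects columns ``participant_id``, ``laser_threshold_J``,
    ``cold_threshold_s``. A z-score normalization is available behind the
    ``normalization`` flag (the score is then not range-bounded).
    """
    required = {"participant_id", "laser_threshold_J", "cold_threshold_s"}
    if not required.issubset(phenotypes.columns):
        raise InvalidParameterError(f"phenotype table needs columns {sorted(required)}")
    if len(phenotypes) < 2:
        raise InvalidParameterError("need at least 2 participants")
    out = phenotypes.copy().reset_index(drop=True)
    laser = out["laser_threshold_J"].to_numpy(float)
    cold = out["cold_threshold_s"].to_numpy(float)
    if normalization == "minmax":
        nl, nc = _minmax(laser), _minmax(cold)
    elif normalization == "zscore":
        nl = (laser - laser.mean()) / laser.std(ddof=1)
        nc = (cold - cold.mean()) / cold.std(ddof=1)
    else:
        raise InvalidParameterError(f"unknown normalization {normalization!r}")
    out["laser_normalized"] = nl
    out["cold_normalized"] = nc
    out["pain_sensitivity_score"] = (nl + nc) / 2.0
    return out


# ------------------------------------------------------------------ LOOCV ---

def loocv(
    X,
    y,
    pls_options: dict | None = None,
    feature_subset=None,
    return_alphas: bool = False,
):
    """Leave-one-individual-out cross-validated predictions.

    Fold i trains a SIMPLS model on all participants but i and predicts i;
    predictions are returned aligned to the input row order. With
    ``return_alphas`` the per-fold coefficient vectors are returned as well
    (the input to group-level feature selection).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if feature_subset is not None:
        X = X[:, np.asarray(feature_subset, dtype=int)]
    n = len(y)
    if n < 3:
        raise InvalidParameterError("need at least 3 participants for LOOCV")
    pls_options = dict(pls_options or {})
    preds = np.empty(n)
    alphas = np.empty((n, X.shape[1]))
    for i in range(n):
        tr = np.ones(n, bool)
        tr[i] = False
        try:
            res = fit_simpls(y[tr], X[tr], pls_options)
        except Exception as exc:  # re-raise with fold context
            raise type(exc)(f"fold {i}: {exc}") from exc
        preds[i] = res.predict(X[i : i + 1])[0]
        alphas[i] = res.params
    if return_alphas:
        return preds, alphas
    return preds


# ---------------------------------------------------------------- metrics ---

def _check_lengths(y_hat, y):
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if y_hat.shape != y.shape:
        raise InvalidParameterError("prediction/truth length mismatch")
    return y_hat, y


def mae(y_hat, y):
    """Mean absolute error and the per-participant absolute errors."""
    y_hat, y = _check_lengths(y_hat, y)
    errs = np.abs(y_hat - y)
    return float(errs.mean()), errs


def mrae(y_hat, y):
    """Mean relative absolute error; refuses zero true values."""
    y_hat, y = _check_lengths(y_hat, y)
    if np.any(y == 0):
        raise InvalidParameterError(
            "mrae undefined for zero true values (near-zero targets inflate it)"
        )
    errs = np.abs((y_hat - y) / y)
    return float(errs.mean()), errs


def pearson_r(y_hat, y) -> float:
    y_hat, y = _check_lengths(y_hat, y)
    return float(stats.pearsonr(y_hat, y).statistic)


@dataclass
class EvaluationReport:
    """Per-participant predictions and summary metrics for one model run."""

    feature_set: str
    threshold_type: str
    participant_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    mae: float
    mrae: float | None
    pearson_r: float
    abs_errors: np.ndarray
    rel_errors: np.ndarray | None

    @property
    def n(self) -> int:
        return len(self.participant_ids)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "participant_id": self.participant_ids,
                "y_true": self.y_true,
                "y_pred": self.y_pred,
                "abs_error": self.abs_errors,
            }
        )
        if self.rel_errors is not None:
            out["rel_error"] = self.rel_errors
        return out

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "threshold_type": self.threshold_type,
            "n": self.n,
            "mae": self.mae,
            "mrae": self.mrae,
            "pearson_r": self.pearson_r,
        }


def evaluate_predictions(
    y_pred,
    y_true,
    participant_ids=None,
    feature_set: str = "",
    threshold_type: str = "",
) -> EvaluationReport:
    """Assemble an :class:`EvaluationReport` from aligned predictions."""
    y_pred, y_true = _check_lengths(y_pred, y_true)
    if participant_ids is None:
        participant_ids = [str(i) for i in range(len(y_true))]
    m, abs_errors = mae(y_pred, y_true)
    try:
        mr, rel_errors = mrae(y_pred, y_true)
    except InvalidParameterError:
        mr, rel_errors = None, None
    return EvaluationReport(
        feature_set=feature_set,
        threshold_type=threshold_type,
        participant_ids=list(participant_ids),
        y_true=y_true,
        y_pred=y_pred,
        mae=m,
        mrae=mr,
        pearson_r=pearson_r(y_pred, y_true),
        abs_errors=abs_errors,
        rel_errors=rel_errors,
    )


# ------------------------------------------------------------ comparisons ---

@dataclass(frozen=True)
class ComparisonResult:
    pair: tuple[str, str]
    statistic: float
    p_value: float
    comparison: str  # "errors" | "correlations"
    method: str


def compare_error_sets(
    abs_errors_a, abs_errors_b, labels=("A", "B")
) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum test on two per-participant error samples.

    Uses the Mann-Whitney U with normal approximation and tie correction.
    """
    a = np.asarray(abs_errors_a, dtype=float).ravel()
    b = np.asarray(abs_errors_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("empty error sample")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return ComparisonResult(
        pair=tuple(labels),
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        comparison="errors",
        method="wilcoxon_rank_sum_asymptotic",
    )


def compare_correlations(
    pred_a,
    pred_b,
    y,
    n_boot: int = 2000,
    seed: int = 0,
    labels=("A", "B"),
) -> ComparisonResult:
    """Participant bootstrap of the difference r(pred_a, y) - r(pred_b, y).

    Two-sided percentile p: twice the smaller tail probability of the
    bootstrap difference distribution around zero.
    """
    if n_boot <= 0:
        raise InvalidParameterError("n_boot must be positive")
    pa, y = _check_lengths(pred_a, y)
    pb, _ = _check_lengths(pred_b, y)
    if np.std(y) == 0:
        raise InvalidParameterError("degenerate (constant) y")
    n = len(y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    ya = pa[idx]
    yb = pb[idx]
    yy = y[idx]

    def _rowwise_r(u, v):
        uc = u - u.mean(axis=1, keepdims=True)
        vc = v - v.mean(axis=1, keepdims=True)
        denom = np.sqrt((uc**2).sum(axis=1) * (vc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (uc * vc).sum(axis=1) / denom
        return r

    d = _rowwise_r(ya, yy) - _rowwise_r(yb, yy)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise InvalidParameterError("all bootstrap replicates degenerate")
    p_low = np.mean(d <= 0)
    p_high = np.mean(d >= 0)
    p = min(1.0, 2.0 * min(p_low, p_high))
    observed = pearson_r(pa, y) - pearson_r(pb, y)
    return ComparisonResult(
        pair=tuple(labels),
        statistic=float(observed),
        p_value=float(p),
        comparison="correlations",
        method=f"participant_bootstrap_B{n_boot}",
    )


def dependent_correlation_test(pred_a, pred_b, y) -> ComparisonResult:
    """Steiger-style z-test for two dependent correlations sharing y.

    Alternative to the bootstrap; uses the back-transformed Fisher z with the
    Williams modification.
    """
    pa, y = _check_lengths(pred_a, y)
    pb, _ = _check_lengths(pred_b, y)
    n = len(y)
    r1 = pearson_r(pa, y)
    r2 = pearson_r(pb, y)
    r12 = pearson_r(pa, pb)
    det = 1 - r1**2 - r2**2 - r12**2 + 2 * r1 * r2 * r12
    rbar2 = ((r1 + r2) / 2) ** 2
    denom = 2 * det * (n - 1) / (n - 3) + rbar2 * (1 - r12) ** 3
    t = (r1 - r2) * np.sqrt((n - 1) * (1 + r12) / denom)
    p = 2 * stats.t.sf(abs(t), df=n - 3)
    return ComparisonResult(
        pair=("A", "B"),
        statistic=float(t),
        p_value=float(p),
        comparison="correlations",
        method="williams_t",
    )


# ------------------------------------------------------ lobe-pair summary ---

@dataclass
class LobePairSummary:
    """Counts of selected MC edges per unordered hemisphere-lobe pair."""

    counts: dict[tuple[str, str], int]
    top_k: list[tuple[tuple[str, str], int]]
    total: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"lobe_a": a, "lobe_b": b, "count": c}
            for (a, b), c in sorted(self.counts.items(), key=lambda kv: -kv[1])
        ]
        return pd.DataFrame(rows)

    def common_pairs(self, other: "LobePairSummary") -> set[tuple[str, str]]:
        return set(self.counts) & set(other.counts)

    def unique_pairs(self, other: "LobePairSummary") -> set[tuple[str, str]]:
        return set(self.counts) - set(other.counts)


def lobe_pair_counts(
    selected_pair_names,
    parc: Parcellation,
    top_k: int = 5,
) -> LobePairSummary:
    """Count selected MC edges per unordered hemisphere-lobe pair.

    ``selected_pair_names`` are MC feature names (``"ROI_i-ROI_j"``). The
    top-k list includes ties at the k-th count.
    """
    counts: dict[tuple[str, str], int] = {}
    for name in selected_pair_names:
        parts = name.split(PAIR_SEP)
        if len(parts) != 2:
            raise InvalidParameterError(f"not an MC pair feature name: {name!r}")
        la = parc.hemisphere_lobe(parts[0])
        lb = parc.hemisphere_lobe(parts[1])
        key = tuple(sorted((la, lb)))
        counts[key] = counts.get(key, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > top_k:
        cutoff = ranked[top_k - 1][1]
        top = [kv for kv in ranked if kv[1] >= cutoff]
    else:
        top = ranked
    return LobePairSummary(counts=counts, top_k=top, total=sum(counts.values()))


# --------------------------------------------------- MC-GMV correlation ----

def mc_gmv_correlation(
    mc_features: pd.DataFrame, gmv: pd.DataFrame, q: float = 0.05
) -> pd.DataFrame:
    """Pearson correlation of every (MC feature, GMV feature) pair.

    Returns a long DataFrame with r, the p-value and a Benjamini-Hochberg
    significance flag at level ``q``. Constant features yield NaN r and are
    flagged undefined rather than aborting.
    """
    from statsmodels.stats.multitest import multipletests

    if not mc_features.index.equals(gmv.index):
        if set(mc_features.index) != set(gmv.index):
            raise InvalidParameterError("participant sets differ between tables")
        gmv = gmv.loc[mc_features.index]
    n = len(mc_features)
    A = mc_features.to_numpy(float)
    B = gmv.to_numpy(float)
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    sa = np.sqrt((A0**2).sum(axis=0))
    sb = np.sqrt((B0**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (A0.T @ B0) / np.outer(sa, sb)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    flat_r = r.ravel()
    flat_p = p.ravel()
    defined = np.isfinite(flat_r)
    sig = np.zeros(flat_r.size, dtype=bool)
    if defined.any():
        sig[defined] = multipletests(flat_p[defined], alpha=q, method="fdr_bh")[0]
    mc_names = np.repeat(mc_features.columns.to_numpy(), len(gmv.columns))
    gmv_names = np.tile(gmv.columns.to_numpy(), len(mc_features.columns))
    return pd.DataFrame(
        {
            "mc_feature": mc_names,
            "gmv_feature": gmv_names,
            "r": flat_r,
            "p": flat_p,
            "significant": sig,
            "undefined": ~defined,
        }
    )
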