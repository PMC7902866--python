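"""Coefficient-ranked feature selection with a coarse-to-fine subset search.

Features are ranked by the magnitude of their PLSR coefficients; the subset
size minimising a cross-validated error is found by evaluating candidate
sizes on a shrinking grid of search intervals (e.g. 100, 10, 1 for the 4005
MC edges; 10, 1 for the 90 GMV features): the coarse stage scans
m = 1, 1+s, 1+2s, ... up to K, each finer stage scans +/- the previous
interval around the running best.

Two selection modes ship:

``group_level``
    The fold-averaged procedure: run full leave-one-out with all features,
    average the per-fold coefficient vectors, rank once, and search subset
    sizes with the error of a fresh leave-one-out run on each candidate
    subset. One subset is chosen for the whole cohort. Because the subset is
    chosen using every participant's fold, the reported error is optimistic.

``nested``
    The unbiased estimate: within each training fold, rank features on that
    fold only and search the subset size against an inner cross-validation
    confined to the training data; the held-out participant is predicted
    with the fold's own subset. Reported per-fold subsets plus their
    consensus (features chosen in at least half the folds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .pls import fit_simpls

#: Default search schedules by feature-set size regime.
MC_SCHEDULE = (100, 10, 1)
GMV_SCHEDULE = (10, 1)


@dataclass(frozen=True)
class CoefficientRanking:
    """Feature indices sorted by descending |coefficient|.

    Ties are broken by ascending feature index (stable argsort on -|coef|).
    """

    order: np.ndarray
    coefficients: np.ndarray
    tie_rule: str = "ascending_index"

    def top(self, m: int) -> np.ndarray:
        return self.order[:m]


@dataclass
class SearchTrace:
    """Every (subset size, cv error) the search evaluated, plus stage bests."""

    evaluated: dict[int, float] = field(default_factory=dict)
    stage_bests: list[tuple[int, int]] = field(default_factory=list)  # (interval, m)
    m_star: int | None = None
    error_metric: str = "mae"

    def as_records(self) -> list[dict]:
        return [
            {"m": m, "error": e} for m, e in sorted(self.evaluated.items())
        ]


@dataclass
class SelectionResult:
    """Chosen subset (group level) or per-fold subsets and consensus (nested)."""

    mode: str
    m_star: int | None
    selected: np.ndarray
    feature_names: list[str] | None
    trace: SearchTrace | None
    ranking: CoefficientRanking | None = None
    per_fold_selected: list[np.ndarray] | None = None
    per_fold_m: list[int] | None = None
    predictions: np.ndarray | None = None

    @property
    def selected_names(self) -> list[str] | None:
        if self.feature_names is None:
            return None
        return [self.feature_names[j] for j in self.selected]

    def to_dict(self) -> dict:
        out = {
            "mode": self.mode,
            "m_star": self.m_star,
            "selected": [int(j) for j in self.selected],
            "selected_names": self.selected_names,
        }
        if self.trace is not None:
            out["trace"] = {
                "evaluated": self.trace.as_records(),
                "stage_bests": [
                    {"interval": s, "m": m} for s, m in self.trace.stage_bests
                ],
                "error_metric": self.trace.error_metric,
            }
        if self.per_fold_m is not None:
            out["per_fold_m"] = self.per_fold_m
        return out


def average_fold_coefficients(per_fold_alphas) -> np.ndarray:
    """Element-wise arithmetic mean of per-fold coefficient vectors."""
    alphas = [np.asarray(a, dtype=float).ravel() for a in per_fold_alphas]
    if not alphas:
        raise InvalidParameterError("no coefficient vectors to average")
    k = alphas[0].size
    if any(a.size != k for a in alphas):
        raise InvalidParameterError("coefficient vectors differ in length")
    return np.mean(alphas, axis=0)


def rank_features(alpha) -> CoefficientRanking:
    """Rank features by descending |coefficient|, ties by ascending index."""
    a = np.asarray(alpha, dtype=float).ravel()
    if not np.all(np.isfinite(a)):
        raise InvalidParameterError("non-finite coefficient in ranking")
    order = np.argsort(-np.abs(a), kind="stable")
    return CoefficientRanking(order=order, coefficients=a)


def _stage_candidates(lo: int, hi: int, step: int) -> list[int]:
    return list(range(lo, hi + 1, step))


def coarse_to_fine_search(
    n_features: int,
    schedule,
    evaluator,
    error_metric: str = "mae",
) -> SearchTrace:
    """Find the error-minimising subset size by interval-refined search.

    Parameters
    ----------
    n_features
        Total number of ranked features K; candidate sizes stay in [1, K].
    schedule
        Strictly decreasing search intervals ending at 1,
        e.g. ``(100, 10, 1)``.
    evaluator
        Callable ``m -> cross-validated error`` for the top-m subset.

    The first stage scans ``m = 1, 1+s, 1+2s, ... <= K``; each later stage
    scans ``[best - prev_s, best + prev_s]`` clipped to [1, K] at the finer
    interval. Evaluations are cached across stages; ties go to the smallest m.
    """
    schedule = tuple(int(s) for s in schedule)
    if not schedule or schedule[-1] != 1:
        raise InvalidParameterError("schedule must end at interval 1")
    if any(s2 >= s1 for s1, s2 in zip(schedule, schedule[1:])):
        raise InvalidParameterError("schedule must be strictly decreasing")
    if any(s < 1 for s in schedule):
        raise InvalidParameterError("schedule intervals must be >= 1")

    trace = SearchTrace(error_metric=error_metric)

    def evaluate(m: int) -> float:
        if m not in trace.evaluated:
            trace.evaluated[m] = float(evaluator(m))
        return trace.evaluated[m]

    lo, hi = 1, n_features
    best_m: int | None = None
    prev_step: int | None = None
    for step in schedule:
        if prev_step is not None:
            lo = max(1, best_m - prev_step)
            hi = min(n_features, best_m + prev_step)
        candidates = _stage_candidates(lo, hi, step)
        if not candidates:
            raise InvalidParameterError("empty candidate set in search stage")
        errs = [(evaluate(m), m) for m in candidates]
        best_m = min(errs)[1]  # ties -> smallest m
        trace.stage_bests.append((step, best_m))
        prev_step = step
    # global best over everything evaluated, ties -> smallest m
    trace.m_star = min((e, m) for m, e in trace.evaluated.items())[1]
    return trace


def _loo_alphas_and_predictions(X, y, pls_options):
    """Leave-one-out fits: per-fold coefficient vectors and predictions."""
    n = len(y)
    alphas = np.empty((n, X.shape[1]))
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        res = fit_simpls(y[tr], X[tr], pls_options)
        alphas[i] = res.params
        preds[i] = res.predict(X[i : i + 1])[0]
    return alphas, preds


def _cv_error(X, y, pls_options, error_metric, folds):
    """Cross-validated error of a SIMPLS fit over the given folds."""
    preds = np.empty(len(y))
    for te in folds:
        tr = np.ones(len(y), bool)
        tr[te] = False
        res = fit_simpls(y[tr], X[tr], pls_options)
        preds[te] = res.predict(X[te])
    return _metric(preds, y, error_metric)


def _metric(y_hat, y, name):
    err = np.abs(y_hat - y)
    if name == "mae":
        return float(err.mean())
    if name == "mrae":
        if np.any(y == 0):
            raise InvalidParameterError("mrae undefined for zero true values")
        return float((err / np.abs(y)).mean())
    if name == "one_minus_r":
        return 1.0 - float(np.corrcoef(y_hat, y)[0, 1])
    raise InvalidParameterError(f"unknown error metric {name!r}")


def _loo_folds(n):
    return [np.array([i]) for i in range(n)]


def _kfold_folds(n, k, rng):
    perm = rng.permutation(n)
    return [perm[i::k] for i in range(min(k, n))]


def select_features(
    X,
    y,
    mode: str = "group_level",
    schedule=MC_SCHEDULE,
    error_metric: str = "mae",
    feature_names=None,
    pls_options: dict | None = None,
    inner_cv: int = 5,
    inner_repeats: int = 2,
    consensus_threshold: float = 0.5,
    seed: int = 0,
) -> SelectionResult:
    """Coefficient-ranked subset selection under leave-one-out CV.

    See the module docstring for the two modes. ``pls_options`` are passed to
    :meth:`SIMPLS.fit` for every internal fit (so the latent-component count
    is re-selected for every candidate subset by default).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    pls_options = dict(pls_options or {})
    rng = np.random.default_rng(seed)

    if mode == "group_level":
        alphas, _ = _loo_alphas_and_predictions(X, y, pls_options)
        ranking = rank_features(average_fold_coefficients(alphas))
        loo = _loo_folds(n)
        pred_cache: dict[int, np.ndarray] = {}

        def evaluator(m: int) -> float:
            cols = ranking.top(m)
            preds = np.empty(n)
            for te in loo:
                tr = np.ones(n, bool)
                tr[te] = False
                res = fit_simpls(y[tr], X[np.ix_(tr, cols)], pls_options)
                preds[te] = res.predict(X[np.ix_(te, cols)])
            pred_cache[m] = preds
            return _metric(preds, y, error_metric)

        trace = coarse_to_fine_search(k, schedule, evaluator, error_metric)
        m_star = trace.m_star
        return SelectionResult(
            mode=mode,
            m_star=m_star,
            selected=ranking.top(m_star),
            feature_names=list(feature_names) if feature_names is not None else None,
            trace=trace,
            ranking=ranking,
            predictions=pred_cache[m_star],
        )

    if mode == "nested":
        preds = np.empty(n)
        per_fold_selected: list[np.ndarray] = []
        per_fold_m: list[int] = []
        votes = np.zeros(k)
        for i in range(n):
            tr = np.ones(n, bool)
            tr[i] = False
            X_tr, y_tr = X[tr], y[tr]
            fit_full = fit_simpls(y_tr, X_tr, pls_options)
            ranking = rank_features(fit_full.params)
            if inner_cv is None or inner_cv >= n - 1:
                fold_sets = [_loo_folds(n - 1)]
            else:
                fold_sets = [
                    _kfold_folds(n - 1, inner_cv, rng) for _ in range(inner_repeats)
                ]

            def evaluator(m: int) -> float:
                cols = ranking.top(m)
                return float(
                    np.mean(
                        [
                            _cv_error(X_tr[:, cols], y_tr, pls_options, error_metric, fs)
                            for fs in fold_sets
                        ]
                    )
                )

            trace = coarse_to_fine_search(k, schedule, evaluator, error_metric)
            cols = ranking.top(trace.m_star)
            res = fit_simpls(y_tr, X_tr[:, cols], pls_options)
            preds[i] = res.predict(X[i : i + 1, cols])[0]
            per_fold_selected.append(cols)
            per_fold_m.append(trace.m_star)
            votes[cols] += 1
        consensus = np.flatnonzero(votes >= consensus_threshold * n)
        return SelectionResult(
            mode=mode,
            m_star=None,
            selected=consensus,
            feature_names=list(feature_names) if feature_names is not None else None,
            trace=None,
            per_fold_selected=per_fold_selected,
            per_fold_m=per_fold_m,
            predictions=preds,
        )

    raise InvalidParameterError(f"mode must be 'group_level' or 'nested', got {mode!r}")
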