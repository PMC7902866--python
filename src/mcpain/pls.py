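"""Partial least squares regression via the SIMPLS algorithm.

The prediction model is y = X a + E with a single response: y is the N-vector
of one pain-threshold type, X the N x K feature matrix (regional GMV, MC
edges, or their concatenation), and a the K-vector of PLSR coefficients.
Coefficients are computed by de Jong's SIMPLS: successive weight vectors are
extracted from the (deflated) cross-covariance X'y, with deflation performed
by projecting X'y off the orthonormalised x-loading basis. Components are
nested, so a single fit at L_max components yields the coefficient vector for
every smaller component count — used both for component selection by training
R^2 and to keep cross-validated subset searches cheap.

Columns of X and y are mean-centered (not variance-scaled) by default; a
``standardize`` flag exists for mixed-scale feature sets such as GMV+MC
concatenations. The sign of each weight vector is fixed (first nonzero
element positive) so that per-fold coefficient vectors can be averaged
meaningfully.

Usage follows the statsmodels convention::

    res = SIMPLS(y, X).fit(n_components=3)
    res.params, res.intercept, res.predict(X_new), res.summary()
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

#: Default cap on latent components when none is requested.
DEFAULT_MAX_COMPONENTS = 10

#: Default training-R^2 target for component selection.
DEFAULT_R2_TARGET = 0.95

#: Default minimum R^2 increment in elbow mode.
DEFAULT_ELBOW_THRESHOLD = 0.01


def _simpls_core(X0: np.ndarray, y0: np.ndarray, n_components: int):
    """Centered-data SIMPLS. Returns (weights R, loadings P, y-loadings q).

    May return fewer than ``n_components`` components if the cross-covariance
    is numerically exhausted (rank-deficient X or fully explained y).
    """
    n, k = X0.shape
    R = np.zeros((k, n_components))
    P = np.zeros((k, n_components))
    q = np.zeros(n_components)
    V = np.zeros((k, n_components))  # orthonormal basis of x-loadings
    s = X0.T @ y0  # deflated cross-covariance
    s_scale = np.linalg.norm(s)
    n_done = 0
    for a in range(n_components):
        if np.linalg.norm(s) <= 1e-12 * max(s_scale, 1.0):
            break
        r = s.copy()
        t = X0 @ r
        norm_t = np.linalg.norm(t)
        if norm_t <= 1e-12:
            break
        t /= norm_t
        r /= norm_t
        # sign convention: first nonzero weight element positive
        nz = np.flatnonzero(np.abs(r) > 1e-12 * np.abs(r).max())
        if nz.size and r[nz[0]] < 0:
            r, t = -r, -t
        p = X0.T @ t
        R[:, a] = r
        P[:, a] = p
        q[a] = float(y0 @ t)
        v = p.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p)
        nv = np.linalg.norm(v)
        if nv <= 1e-12:
            break
        v /= nv
        V[:, a] = v
        s = s - v * (v @ s)
        n_done = a + 1
    return R[:, :n_done], P[:, :n_done], q[:n_done]


class SIMPLS:
    """PLS1 regression model (SIMPLS algorithm), statsmodels-style.

    Parameters
    ----------
    endog : array-like, shape (N,)
        Response (one pain-threshold type).
    exog : array-like or DataFrame, shape (N, K)
        Feature matrix; a DataFrame supplies feature names.
    feature_names : sequence of str, optional
        Overrides DataFrame column names.
    standardize : bool
        Scale columns to unit variance after centering (default False).
    """

    def __init__(self, endog, exog, feature_names=None, standardize=False):
        if isinstance(exog, pd.DataFrame):
            if feature_names is None:
                feature_names = [str(c) for c in exog.columns]
            exog = exog.to_numpy(dtype=float)
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(endog, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise InvalidParameterError(
                f"endog length {y.shape[0]} != exog rows {X.shape[0]}"
            )
        if X.shape[0] < 3:
            raise InvalidParameterError("need at least 3 observations")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise InvalidParameterError("non-finite values in endog/exog")
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(X.shape[1])]
        if len(feature_names) != X.shape[1]:
            raise InvalidParameterError("feature_names length mismatch")
        self.endog = y
        self.exog = X
        self.feature_names = list(feature_names)
        self.standardize = bool(standardize)
        self.nobs, self.k_features = X.shape

    @property
    def max_allowed_components(self) -> int:
        return min(self.k_features, self.nobs - 1)

    def fit(
        self,
        n_components: int | None = None,
        max_components: int | None = None,
        criterion: str = "r2_target",
        r2_target: float = DEFAULT_R2_TARGET,
        elbow_threshold: float = DEFAULT_ELBOW_THRESHOLD,
    ) -> "SIMPLSResults":
        """Fit the model.

        With ``n_components`` given, fits exactly that many latent components.
        Otherwise fits up to ``max_components`` (default
        min(K, N-1, 10)) and selects the count from the training-R^2
        sequence: ``criterion="r2_target"`` takes the smallest L whose
        R^2(L) reaches ``r2_target``; ``criterion="elbow"`` takes the last L
        before the first R^2 increment below ``elbow_threshold``.
        """
        cap = self.max_allowed_components
        if n_components is not None:
            if not 1 <= n_components <= cap:
                raise InvalidParameterError(
                    f"n_components must be in [1, {cap}], got {n_components}"
                )
            L_fit = n_components
        else:
            if max_components is None:
                max_components = min(cap, DEFAULT_MAX_COMPONENTS)
            if not 1 <= max_components <= cap:
                raise InvalidParameterError(
                    f"max_components must be in [1, {cap}], got {max_components}"
                )
            L_fit = max_components
        y = self.endog
        y_mean = y.mean()
        y0 = y - y_mean
        ssy = float(y0 @ y0)
        if ssy <= 0:
            raise InvalidParameterError("zero-variance endog")
        x_mean = self.exog.mean(axis=0)
        X0 = self.exog - x_mean
        if self.standardize:
            x_scale = X0.std(axis=0, ddof=1)
            x_scale[x_scale == 0] = 1.0
        else:
            x_scale = np.ones(self.k_features)
        X0 = X0 / x_scale

        R, P, q = _simpls_core(X0, y0, L_fit)
        n_eff = q.size
        if n_eff == 0:
            raise InvalidParameterError("no usable latent component (degenerate X)")
        # nested coefficient path on the centered/scaled data
        coef_path = np.cumsum(R * q[None, :], axis=1)
        r2_path = np.cumsum(q**2) / ssy

        if n_components is not None:
            L = min(n_components, n_eff)
        elif criterion == "r2_target":
            reached = np.flatnonzero(r2_path >= r2_target)
            L = int(reached[0]) + 1 if reached.size else n_eff
        elif criterion == "elbow":
            incr = np.diff(r2_path, prepend=0.0)
            small = np.flatnonzero(incr[1:] < elbow_threshold)  # index of L-1
            L = int(small[0]) + 1 if small.size else n_eff
        else:
            raise InvalidParameterError(
                f"criterion must be 'r2_target' or 'elbow', got {criterion!r}"
            )
        params = coef_path[:, L - 1] / x_scale
        intercept = float(y_mean - x_mean @ params)
        return SIMPLSResults(
            model=self,
            params=params,
            intercept=intercept,
            n_components=L,
            x_mean=x_mean,
            y_mean=float(y_mean),
            x_scale=x_scale,
            weights=R,
            loadings=P,
            y_loadings=q,
            coef_path=coef_path / x_scale[:, None],
            r2_path=r2_path,
        )


class SIMPLSResults:
    """Fitted SIMPLS model: coefficients, centering constants, diagnostics."""

    def __init__(
        self,
        model,
        params,
        intercept,
        n_components,
        x_mean,
        y_mean,
        x_scale,
        weights,
        loadings,
        y_loadings,
        coef_path,
        r2_path,
    ):
        self.model = model
        self.params = params
        self.intercept = intercept
        self.n_components = n_components
        self.x_mean = x_mean
        self.y_mean = y_mean
        self.x_scale = x_scale
        self.weights = weights
        self.loadings = loadings
        self.y_loadings = y_loadings
        self.coef_path = coef_path
        self.r2_path = r2_path

    def predict(self, exog=None, n_components: int | None = None) -> np.ndarray:
        """Predict: y_hat = (X_new - x_mean) @ params + y_mean."""
        if exog is None:
            X = self.model.exog
        else:
            if isinstance(exog, pd.DataFrame):
                exog = exog.to_numpy(dtype=float)
            X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[1] != self.model.k_features:
            raise InvalidParameterError(
                f"exog has {X.shape[1]} columns, expected {self.model.k_features}"
            )
        if n_components is None:
            params = self.params
        else:
            if not 1 <= n_components <= self.coef_path.shape[1]:
                raise InvalidParameterError("n_components outside fitted path")
            params = self.coef_path[:, n_components - 1]
        return (X - self.x_mean) @ params + self.y_mean

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict()

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    @property
    def rsquared(self) -> float:
        return float(self.r2_path[self.n_components - 1])

    def summary(self) -> str:
        lines = [
            "SIMPLS Partial Least Squares Regression",
            "=" * 55,
            f"No. observations:      {self.model.nobs}",
            f"No. features (K):      {self.model.k_features}",
            f"Latent components (L): {self.n_components}",
            f"Training R-squared:    {self.rsquared:.4f}",
            f"Intercept:             {self.intercept:.6g}",
            "-" * 55,
            "Largest |coefficient| features:",
        ]
        order = np.argsort(-np.abs(self.params))[:10]
        for j in order:
            lines.append(f"  {self.model.feature_names[j]:<35s} {self.params[j]: .4e}")
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize the fitted model to a single NPZ archive."""
        np.savez(
            path,
            params=self.params,
            intercept=self.intercept,
            n_components=self.n_components,
            x_mean=self.x_mean,
            y_mean=self.y_mean,
            x_scale=self.x_scale,
            feature_names=np.array(self.model.feature_names, dtype=object),
        )


def fit_simpls(endog, exog, options: dict | None = None) -> "SIMPLSResults":
    """Fit helper: ``options`` are :meth:`SIMPLS.fit` kwargs, plus an optional
    ``standardize`` key routed to the model constructor."""
    opts = dict(options or {})
    standardize = opts.pop("standardize", False)
    model = SIMPLS(endog, exog, standardize=standardize)
    # a requested component cap is clamped to what the data allow, so one
    # setting can serve subsets of any width during feature selection
    if opts.get("max_components") is not None:
        opts["max_components"] = min(opts["max_components"], model.max_allowed_components)
    if opts.get("n_components") is not None:
        opts["n_components"] = min(opts["n_components"], model.max_allowed_components)
    return model.fit(**opts)


def select_n_components(
    endog,
    exog,
    max_components: int | None = None,
    criterion: str = "r2_target",
    r2_target: float = DEFAULT_R2_TARGET,
    elbow_threshold: float = DEFAULT_ELBOW_THRESHOLD,
) -> int:
    """Latent-component count by the training coefficient of determination.

    Convenience wrapper: fits once at the component cap and reads the count
    off the nested R^2 sequence (non-decreasing in L).
    """
    res = SIMPLS(endog, exog).fit(
        max_components=max_components,
        criterion=criterion,
        r2_target=r2_target,
        elbow_threshold=elbow_threshold,
    )
    return res.n_components
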