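"""Statistical inference: CCA with a max-statistic permutation test, and
stepwise prognostic regression on rank-inverse-normal transformed outcomes.

Canonical correlation analysis (CCA) finds paired linear combinations
(canonical variates) of two standardized variable sets with maximal
correlation. Significance uses a randomization test: patient rows of one set
are shuffled, the CCA refit, and the *largest* canonical correlation recorded
each time; comparing every observed pair against this max-statistic null
controls for the selection of the best pair. The p-value is the plain
proportion of null maxima exceeding the observed correlation (strict
inequality), matching the source procedure rather than the (b+1)/(P+1)
convention.

Prognostic models are built by stepwise linear regression (forward entry at
p <= 0.05 on the partial F test, backward removal at p >= 0.10) after the
ordinal outcome is normalized with the rank-based inverse Gaussian transform
(Blom offset 3/8).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CCAResult",
    "PermutationResult",
    "StepwiseResult",
    "fit_cca",
    "permutation_test_cca",
    "variate_loadings",
    "rank_inverse_normal",
    "stepwise_regression",
    "r2_change",
]


# ---------------------------------------------------------------------------
# CCA
# ---------------------------------------------------------------------------


@dataclass
class CCAResult:
    canonical_correlations: np.ndarray  # descending, in [0, 1]
    x_weights: np.ndarray  # (p, k) on standardized variables
    y_weights: np.ndarray  # (q, k)
    x_variates: np.ndarray  # (n, k), unit variance
    y_variates: np.ndarray  # (n, k)
    x_names: list[str]
    y_names: list[str]
    p_values: np.ndarray | None = None

    @property
    def n_pairs(self) -> int:
        return self.canonical_correlations.size


def _as_matrix(data, prefix: str) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), [str(c) for c in data.columns]
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"{prefix}{i}" for i in range(arr.shape[1])]


def _standardize_checked(arr: np.ndarray, names: list[str]) -> np.ndarray:
    sd = arr.std(axis=0, ddof=1)
    constant = [names[i] for i in np.flatnonzero(sd == 0)]
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    return (arr - arr.mean(axis=0)) / sd


def _qr_checked(z: np.ndarray, names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    Q, R = np.linalg.qr(z)
    diag = np.abs(np.diag(R))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        collinear = [names[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"rank-deficient design; collinear column(s): {collinear}")
    return Q, R


def fit_cca(x_set, y_set) -> CCAResult:
    """Canonical correlation analysis on standardized variable sets.

    Solved via QR + SVD: with ``Z_x = Q_x R_x`` and ``Z_y = Q_y R_y``, the
    singular values of ``Q_x' Q_y`` are the canonical correlations and the
    transformed singular vectors give the weights.
    """
    X, x_names = _as_matrix(x_set, "x")
    Y, y_names = _as_matrix(y_set, "y")
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("x_set and y_set must have the same number of rows")
    if n <= max(X.shape[1], Y.shape[1]) + 1:
        raise ValueError("need n > max(p, q) + 1 subjects")
    Zx = _standardize_checked(X, x_names)
    Zy = _standardize_checked(Y, y_names)
    Qx, Rx = _qr_checked(Zx, x_names)
    Qy, Ry = _qr_checked(Zy, y_names)
    U, s, Vt = np.linalg.svd(Qx.T @ Qy)
    k = min(X.shape[1], Y.shape[1])
    s = np.clip(s[:k], 0.0, 1.0)
    scale = np.sqrt(n - 1)
    x_weights = np.linalg.solve(Rx, U[:, :k]) * scale
    y_weights = np.linalg.solve(Ry, Vt.T[:, :k]) * scale
    return CCAResult(
        canonical_correlations=s,
        x_weights=x_weights,
        y_weights=y_weights,
        x_variates=Qx @ U[:, :k] * scale,
        y_variates=Qy @ Vt.T[:, :k] * scale,
        x_names=x_names,
        y_names=y_names,
    )


@dataclass
class PermutationResult:
    p_values: np.ndarray
    observed: np.ndarray
    null_max: np.ndarray


def permutation_test_cca(
    x_set, y_set, n_perm: int = 2000, seed: int = 0
) -> PermutationResult:
    """Max-statistic randomization test for all canonical variate pairs.

    Rows of ``x_set`` are shuffled relative to ``y_set``; each shuffle's
    largest canonical correlation forms the null. ``p_i`` is the proportion
    of null maxima strictly greater than observed ``r_i``.
    """
    res = fit_cca(x_set, y_set)
    X, x_names = _as_matrix(x_set, "x")
    Y, y_names = _as_matrix(y_set, "y")
    Qx, _ = _qr_checked(_standardize_checked(X, x_names), x_names)
    Qy, _ = _qr_checked(_standardize_checked(Y, y_names), y_names)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(Qx.shape[0])
        # QR of row-permuted Z is (P Q) R, so permuting Q's rows suffices
        null_max[b] = np.linalg.svd(Qx[perm].T @ Qy, compute_uv=False)[0]
    observed = res.canonical_correlations
    p_values = (null_max[None, :] > observed[:, None]).mean(axis=1)
    return PermutationResult(
        p_values=p_values, observed=observed, null_max=null_max
    )


def variate_loadings(res: CCAResult, x_set, y_set) -> pd.DataFrame:
    """Correlations of each original variable with the opposite set's first
    canonical variate (Pearson r with two-tailed p)."""
    X, _ = _as_matrix(x_set, "x")
    Y, _ = _as_matrix(y_set, "y")
    rows = []
    for j, name in enumerate(res.x_names):
        r, p = stats.pearsonr(X[:, j], res.y_variates[:, 0])
        rows.append(("x", name, r, p))
    for j, name in enumerate(res.y_names):
        r, p = stats.pearsonr(Y[:, j], res.x_variates[:, 0])
        rows.append(("y", name, r, p))
    return pd.DataFrame(rows, columns=["set", "variable", "loading", "p_value"])


# ---------------------------------------------------------------------------
# Rank-based inverse Gaussian transform
# ---------------------------------------------------------------------------


def rank_inverse_normal(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Blom-type rank-based inverse normal transform.

    ``z_i = Phi^-1((r_i - c) / (n - 2c + 1))`` with tied ranks averaged and
    offset ``c = 3/8`` by default.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if np.isnan(v).any():
        raise ValueError("missing values are not allowed")
    if np.ptp(v) == 0:
        raise ValueError("all values equal; no ordering information to transform")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - offset) / (v.size - 2 * offset + 1))


# ---------------------------------------------------------------------------
# Stepwise regression
# ---------------------------------------------------------------------------


@dataclass
class StepwiseResult:
    selected: list[str]  # in entry order
    betas: dict[str, float]  # standardized coefficients
    raw_coefs: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    df: tuple[int, int]
    steps: list[dict]
    dropped_ids: list
    n_used: int
    empty: bool
    _y: np.ndarray = field(repr=False, default=None)
    _X: pd.DataFrame = field(repr=False, default=None)


def _ols_pvalues(y: np.ndarray, X: pd.DataFrame, cols: list[str]):
    design = sm.add_constant(X[cols].to_numpy(), has_constant="add")
    fit = sm.OLS(y, design).fit()
    return fit, dict(zip(cols, fit.pvalues[1:]))


def stepwise_regression(
    y,
    candidates: pd.DataFrame,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
) -> StepwiseResult:
    """Forward-entry / backward-removal stepwise linear regression.

    Each round adds the candidate with the smallest partial-F p-value if it
    is <= ``entry_p``, then removes any retained predictor whose p-value has
    risen to >= ``removal_p``; iteration stops at a fixed point. Betas are
    standardized (fit on z-scored outcome and predictors); raw coefficients
    are also reported. Rows with missing values are dropped listwise first.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=candidates.index)
    mask = ~(y.isna() | candidates.isna().any(axis=1))
    dropped = list(candidates.index[~mask])
    yv = y[mask].to_numpy()
    X = candidates[mask].astype(float)
    n = yv.size
    if n < 4:
        raise ValueError("too few complete cases for regression")
    constant_cols = [c for c in X.columns if X[c].nunique() <= 1]
    X = X.drop(columns=constant_cols)

    selected: list[str] = []
    steps: list[dict] = [
        {"action": "exclude_constant", "predictor": c} for c in constant_cols
    ]
    for _ in range(2 * len(candidates.columns) + 10):
        changed = False
        # forward: only while a residual degree of freedom would remain
        remaining = (
            [c for c in X.columns if c not in selected]
            if n - len(selected) - 2 >= 1
            else []
        )
        best_p, best_c = np.inf, None
        for c in remaining:
            _, pvals = _ols_pvalues(yv, X, selected + [c])
            if pvals[c] < best_p:
                best_p, best_c = pvals[c], c
        if best_c is not None and best_p <= entry_p:
            selected.append(best_c)
            steps.append({"action": "enter", "predictor": best_c, "p": float(best_p)})
            changed = True
        # backward
        while len(selected) > 0:
            _, pvals = _ols_pvalues(yv, X, selected)
            worst = max(selected, key=lambda c: pvals[c])
            if pvals[worst] >= removal_p:
                selected.remove(worst)
                steps.append(
                    {"action": "remove", "predictor": worst, "p": float(pvals[worst])}
                )
                changed = True
            else:
                break
        if not changed:
            break

    empty = len(selected) == 0
    if empty:
        return StepwiseResult(
            selected=[], betas={}, raw_coefs={}, p_values={},
            r_squared=0.0, adj_r_squared=0.0, f_statistic=np.nan,
            df=(0, n - 1), steps=steps, dropped_ids=dropped, n_used=n,
            empty=True, _y=yv, _X=X,
        )

    fit, pvals = _ols_pvalues(yv, X, selected)
    zy = (yv - yv.mean()) / yv.std(ddof=1)
    zX = (X[selected] - X[selected].mean()) / X[selected].std(ddof=1)
    zfit = sm.OLS(zy, sm.add_constant(zX.to_numpy(), has_constant="add")).fit()
    k = len(selected)
    return StepwiseResult(
        selected=selected,
        betas=dict(zip(selected, zfit.params[1:])),
        raw_coefs=dict(zip(selected, fit.params[1:])),
        p_values={c: float(pvals[c]) for c in selected},
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        df=(k, n - k - 1),
        steps=steps,
        dropped_ids=dropped,
        n_used=n,
        empty=False,
        _y=yv,
        _X=X,
    )


def r2_change(full: StepwiseResult, reduced: list[str]) -> float:
    """R-squared difference between the full stepwise model and a nested
    reduced model fit on the identical case set."""
    if not set(reduced) <= set(full.selected):
        raise ValueError(
            f"reduced set {reduced} is not nested in the full model {full.selected}"
        )
    if sorted(reduced) == sorted(full.selected):
        return 0.0
    if not reduced:
        return float(full.r_squared)
    fit, _ = _ols_pvalues(full._y, full._X, list(reduced))
    return float(full.r_squared - fit.rsquared)
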