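"""Quantile-heterogeneity analysis of the vulnerability index.

Quantile fits minimise the check loss exactly via the dual linear program
(HiGHS); standard errors and cross-quantile covariances come from a paired
(row-resampling) bootstrap so that joint and pairwise Wald tests across
quantiles share one resampling pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linprog

__all__ = [
    "VifReport",
    "QuantileFitResult",
    "OlsFitResult",
    "CrossQuantileTest",
    "SubgroupComparison",
    "design",
    "compute_vif",
    "fit_quantile",
    "fit_ols",
    "cross_quantile_tests",
    "classify_pattern",
    "subgroup_equality",
    "fit_interactions",
    "full_quantile_sweep",
    "check_loss",
]


def design(
    table: pd.DataFrame, columns: Sequence[str], intercept: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Build a design matrix from named columns, optionally prepending 1s."""
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    X = table.loc[:, list(columns)].to_numpy(dtype=float)
    names = list(columns)
    if intercept:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["const"] + names
    return X, names


def _rank_check(X: np.ndarray, names: Sequence[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        bad = [names[i] for i in np.flatnonzero(np.abs(vt[-1]) > 1e-8)]
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear columns: {bad}")


# ---------------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------------

@dataclass
class VifReport:
    names: list[str]
    vif: np.ndarray
    max_vif: float
    collinear: bool
    threshold: float = 10.0


def compute_vif(X: pd.DataFrame | np.ndarray, threshold: float = 10.0) -> VifReport:
    """VIF_j = 1 / (1 - R^2_j) from regressing column j on the others.

    An intercept is always included in the auxiliary regressions.  Perfect
    collinearity yields an infinite VIF and sets the flag rather than raising.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(M.shape[1])]
    if M.shape[1] < 2:
        raise ValueError("VIF needs at least two covariates")
    if np.any(np.ptp(M, axis=0) == 0):
        const = [names[j] for j in np.flatnonzero(np.ptp(M, axis=0) == 0)]
        raise ValueError(f"constant columns not allowed in VIF screen: {const}")
    n, p = M.shape
    vifs = np.empty(p)
    for j in range(p):
        y = M[:, j]
        Z = np.column_stack([np.ones(n), np.delete(M, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ coef
        tss = np.sum((y - y.mean()) ** 2)
        rss = np.sum(resid**2)
        r2 = 1.0 - rss / tss
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    vmax = float(np.max(vifs))
    return VifReport(
        names=names,
        vif=vifs,
        max_vif=vmax,
        collinear=bool(vmax > threshold),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Quantile regression (exact LP)
# ---------------------------------------------------------------------------

def check_loss(u: np.ndarray, tau: float) -> float:
    """Total check (pinball) loss: sum of u * (tau - 1{u < 0})."""
    u = np.asarray(u, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


def _solve_quantile(X: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    """Exact check-loss minimiser via the dual LP.

    max y'd  s.t.  X'd = 0,  tau-1 <= d_i <= tau ;  the coefficient vector is
    (minus) the marginals of the equality constraints at the optimum.
    """
    n, p = X.shape
    res = linprog(
        -y,
        A_eq=X.T,
        b_eq=np.zeros(p),
        bounds=[(tau - 1.0, tau)] * n,
        method="highs",
        options={"presolve": False},  # tiny LPs; presolve is pure overhead
    )
    if not res.success:  # pragma: no cover - HiGHS is robust on full-rank designs
        raise RuntimeError(f"quantile LP failed at tau={tau}: {res.message}")
    return -np.asarray(res.eqlin.marginals, dtype=float)


@dataclass
class QuantileFitResult:
    tau: float
    params: np.ndarray
    bse: np.ndarray
    objective: float
    n: int
    names: list[str]
    residuals: np.ndarray

    @property
    def pvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.params / self.bse
        return 2 * stats.norm.sf(np.abs(z))


def fit_quantile(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    tau: float,
    bootstrap_reps: int = 500,
    seed: int | None = None,
    names: Sequence[str] | None = None,
) -> QuantileFitResult:
    """Quantile regression at ``tau`` with paired-bootstrap standard errors.

    Pass ``bootstrap_reps=0`` to skip the bootstrap (SEs become NaN).
    """
    if not 0 < tau < 1:
        raise ValueError(f"tau must lie in (0,1), got {tau}")
    if isinstance(X, pd.DataFrame):
        names = names or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    _rank_check(X, names)
    beta = _solve_quantile(X, y, tau)
    resid = y - X @ beta
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty((bootstrap_reps, p))
        for b in range(bootstrap_reps):
            idx = rng.integers(0, n, n)
            boot[b] = _solve_quantile(X[idx], y[idx], tau)
        bse = boot.std(axis=0, ddof=1)
    else:
        bse = np.full(p, np.nan)
    return QuantileFitResult(
        tau=tau,
        params=beta,
        bse=bse,
        objective=check_loss(resid, tau),
        n=n,
        names=list(names),
        residuals=resid,
    )


@dataclass
class OlsFitResult:
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    n: int
    names: list[str]
    residuals: np.ndarray


def fit_ols(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    names: Sequence[str] | None = None,
) -> OlsFitResult:
    import statsmodels.api as sm

    if isinstance(X, pd.DataFrame):
        names = names or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    _rank_check(X, names)
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return OlsFitResult(
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        pvalues=np.asarray(res.pvalues),
        n=int(res.nobs),
        names=list(names),
        residuals=np.asarray(res.resid),
    )


# ---------------------------------------------------------------------------
# Cross-quantile Wald tests and shape classification
# ---------------------------------------------------------------------------

def classify_pattern(
    c25: float,
    c50: float,
    c75: float,
    sig_25_50: bool,
    sig_50_75: bool,
    rule: str = "strict",
) -> str:
    """Shape label for a coefficient triple across the three quantiles.

    Strict rule: the middle coefficient must be the strict max (inverted V)
    or strict min (V) with both pairwise differences significant; a strict
    monotone ordering with both differences significant is "monotone"; any
    tie or failed condition falls through to "flat/other".  The lenient rule
    drops the significance requirements and classifies on ordering alone.
    """
    if rule not in ("strict", "lenient"):
        raise ValueError(f"unknown pattern rule {rule!r}")
    for c in (c25, c50, c75):
        if not np.isfinite(c):
            raise ValueError("pattern classification needs finite coefficients")
    both = (sig_25_50 and sig_50_75) or rule == "lenient"
    if c50 > max(c25, c75) and both:
        return "Inverted V-shaped"
    if c50 < min(c25, c75) and both:
        return "V-shaped"
    if (c25 < c50 < c75 or c25 > c50 > c75) and both:
        return "monotone"
    return "flat/other"


@dataclass
class CrossQuantileTest:
    variable: str
    taus: tuple[float, ...]
    coefficients: np.ndarray
    joint_stat: float
    joint_pvalue: float
    joint_df: int
    diff_25_50: float
    se_25_50: float
    p_25_50: float
    diff_50_75: float
    se_50_75: float
    p_50_75: float
    pattern: str


def _fit_all_taus(X: np.ndarray, y: np.ndarray, taus: Sequence[float]) -> np.ndarray:
    return np.column_stack([_solve_quantile(X, y, t) for t in taus])


def cross_quantile_tests(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    taus: Sequence[float] = (0.25, 0.50, 0.75),
    bootstrap_reps: int = 500,
    seed: int | None = None,
    names: Sequence[str] | None = None,
    alpha: float = 0.05,
    pattern_rule: str = "strict",
    skip_const: bool = True,
) -> list[CrossQuantileTest]:
    """Joint and pairwise Wald tests of coefficient equality across quantiles.

    All quantiles are refit on every bootstrap resample, giving the joint
    covariance of the stacked coefficient vectors in one pass; the joint test
    per variable has len(taus)-1 degrees of freedom.
    """
    if len(taus) != 3:
        raise ValueError("cross-quantile tests expect exactly three quantiles")
    if isinstance(X, pd.DataFrame):
        names = names or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    _rank_check(X, names)

    full = _fit_all_taus(X, y, taus)  # p x 3
    rng = np.random.default_rng(seed)
    boot = np.empty((bootstrap_reps, p, 3))
    for b in range(bootstrap_reps):
        idx = rng.integers(0, n, n)
        boot[b] = _fit_all_taus(X[idx], y[idx], taus)

    D = np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
    out: list[CrossQuantileTest] = []
    for j, name in enumerate(names):
        if skip_const and name == "const":
            continue
        c = full[j]  # 3-vector
        V = np.cov(boot[:, j, :].T)  # 3x3 bootstrap covariance
        d = D @ c
        Vd = D @ V @ D.T
        # eigen-thresholded inverse: a (near-)singular bootstrap covariance
        # falls back to a pseudo-inverse over the informative directions
        evals, evecs = np.linalg.eigh(Vd)
        tol = 1e-10 * max(1.0, float(evals.max(initial=0.0)))
        keep = evals > tol
        if not keep.all():
            warnings.warn(
                f"singular bootstrap covariance for {name}; using pseudo-inverse",
                RuntimeWarning,
                stacklevel=2,
            )
        if keep.any():
            proj = evecs[:, keep].T @ d
            W = float(proj @ (proj / evals[keep]))
        else:
            W = 0.0
        W = max(W, 0.0)
        se1 = float(np.sqrt(max(Vd[0, 0], 0.0)))
        se2 = float(np.sqrt(max(Vd[1, 1], 0.0)))
        p1 = 2 * stats.norm.sf(abs(d[0]) / se1) if se1 > 0 else (1.0 if d[0] == 0 else 0.0)
        p2 = 2 * stats.norm.sf(abs(d[1]) / se2) if se2 > 0 else (1.0 if d[1] == 0 else 0.0)
        out.append(
            CrossQuantileTest(
                variable=name,
                taus=tuple(taus),
                coefficients=c.copy(),
                joint_stat=W,
                joint_pvalue=float(stats.chi2.sf(W, 2)) if np.isfinite(W) else np.nan,
                joint_df=2,
                diff_25_50=float(d[0]),
                se_25_50=se1,
                p_25_50=float(p1),
                diff_50_75=float(d[1]),
                se_50_75=se2,
                p_50_75=float(p2),
                pattern=classify_pattern(
                    c[0], c[1], c[2], p1 < alpha, p2 < alpha, rule=pattern_rule
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Subgroup and interaction analyses
# ---------------------------------------------------------------------------

@dataclass
class SubgroupComparison:
    group_column: str
    group_values: tuple
    n_per_group: tuple[int, int]
    names: list[str]
    params: dict
    bse: dict
    equality_stat: np.ndarray
    equality_pvalue: np.ndarray


def subgroup_equality(
    table: pd.DataFrame,
    group_column: str,
    y_column: str,
    x_columns: Sequence[str],
    estimator: str = "ols",
    tau: float = 0.5,
    bootstrap_reps: int = 200,
    seed: int | None = None,
    min_group_size: int = 30,
) -> SubgroupComparison:
    """Fit the model per group and test per-variable coefficient equality.

    The equality statistic is (b_A - b_B)^2 / (SE_A^2 + SE_B^2), referred to
    chi-square with 1 degree of freedom.
    """
    g = table[group_column]
    levels = sorted(pd.unique(g.dropna()))
    if len(levels) != 2:
        raise ValueError(
            f"group column {group_column!r} must be binary, found levels {levels}"
        )
    fits = {}
    sizes = []
    for lev in levels:
        sub = table.loc[g == lev]
        if len(sub) < min_group_size:
            raise ValueError(
                f"group {group_column}=={lev} has only {len(sub)} rows "
                f"(minimum {min_group_size})"
            )
        sizes.append(len(sub))
        X, names = design(sub, x_columns)
        yv = sub[y_column].to_numpy(dtype=float)
        if estimator == "ols":
            fits[lev] = fit_ols(X, yv, names=names)
        elif estimator == "quantile":
            fits[lev] = fit_quantile(
                X, yv, tau, bootstrap_reps=bootstrap_reps, seed=seed, names=names
            )
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
    a, b = levels
    diff = fits[a].params - fits[b].params
    var = fits[a].bse ** 2 + fits[b].bse ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(var > 0, diff**2 / var, 0.0)
    return SubgroupComparison(
        group_column=group_column,
        group_values=tuple(levels),
        n_per_group=(sizes[0], sizes[1]),
        names=fits[a].names,
        params={lev: fits[lev].params for lev in levels},
        bse={lev: fits[lev].bse for lev in levels},
        equality_stat=stat,
        equality_pvalue=stats.chi2.sf(stat, 1),
    )


def fit_interactions(
    table: pd.DataFrame,
    y_column: str,
    x_columns: Sequence[str],
    interaction_pairs: Sequence[tuple[str, str]],
) -> OlsFitResult:
    """OLS with product terms appended for each named pair."""
    X, names = design(table, x_columns)
    cols = [X]
    for u, v in interaction_pairs:
        for c in (u, v):
            if c not in table.columns:
                raise KeyError(f"interaction column {c!r} not in table")
        prod = (table[u].to_numpy(dtype=float) * table[v].to_numpy(dtype=float))
        term = f"{u}:{v}"
        if np.ptp(prod) == 0:
            raise np.linalg.LinAlgError(
                f"interaction term {term} is constant (all {prod[0]}); "
                "design would be rank deficient"
            )
        cols.append(prod[:, None])
        names.append(term)
    Xfull = np.hstack(cols)
    return fit_ols(Xfull, table[y_column].to_numpy(dtype=float), names=names)


def full_quantile_sweep(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    tau_grid: Sequence[float] | None = None,
    bootstrap_reps: int = 100,
    seed: int | None = None,
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tidy table (variable, tau, coefficient, se) over a quantile grid."""
    if tau_grid is None:
        tau_grid = np.round(np.arange(0.05, 0.951, 0.05), 2)
    rows = []
    rng = np.random.default_rng(seed)
    for tau in tau_grid:
        sub = rng.integers(0, 2**31 - 1) if bootstrap_reps > 0 else None
        fit = fit_quantile(
            X, y, float(tau), bootstrap_reps=bootstrap_reps, seed=sub, names=names
        )
        for nm, b, s in zip(fit.names, fit.params, fit.bse):
            rows.append({"variable": nm, "tau": float(tau), "coefficient": b, "se": s})
    return pd.DataFrame(rows)
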