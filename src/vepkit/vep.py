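"""Vulnerability-as-expected-poverty estimation via three-stage FGLS.

The measurement pipeline is: (1) OLS of log income on household
characteristics, (2) OLS of the squared residuals on the variance design to
approximate the conditional variance, (3) weighted re-estimation of both
equations, and (4) the vulnerability index as the normal probability that
future log income falls below the log poverty line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SampleSizeSpec",
    "IncomeModelSpec",
    "FglsFit",
    "MeanVariance",
    "VulnerabilityResult",
    "VulnerabilityDistribution",
    "compute_min_sample_size",
    "fit_income_fgls",
    "predict_mean_variance",
    "vulnerability_index",
    "classify_households",
    "classify_and_summarize",
    "relative_poverty_line",
    "tabulate",
    "round_half_up",
]

VARIANCE_FLOOR = 1e-6


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of the reported tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Sample size
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs of the prevalence-estimation sample-size formula.

    ``u_alpha`` defaults to the two-tailed standard-normal critical value for
    ``alpha`` but may be pinned explicitly (e.g. 1.96).
    """

    pi: float
    delta: float
    alpha: float = 0.05
    u_alpha: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0,1), got {self.alpha}")
        if not 0 < self.pi < 1:
            raise ValueError(f"pi must lie in (0,1), got {self.pi}")
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")

    @property
    def critical_value(self) -> float:
        if self.u_alpha is not None:
            return self.u_alpha
        return float(stats.norm.ppf(1 - self.alpha / 2))


def compute_min_sample_size(spec: SampleSizeSpec) -> int:
    """Minimum n = ceil(u^2 * pi * (1 - pi) / delta^2)."""
    u = spec.critical_value
    return math.ceil(u * u * spec.pi * (1 - spec.pi) / spec.delta**2)


# ---------------------------------------------------------------------------
# FGLS income model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IncomeModelSpec:
    """Column selection for the income mean and variance equations."""

    mean_covariates: tuple[str, ...]
    variance_covariates: tuple[str, ...] | None = None
    include_intercept: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_covariates", tuple(self.mean_covariates))
        if self.variance_covariates is not None:
            object.__setattr__(
                self, "variance_covariates", tuple(self.variance_covariates)
            )
        for names in (self.mean_covariates, self.var_names):
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate covariate names in {names}")

    @property
    def var_names(self) -> tuple[str, ...]:
        return (
            self.variance_covariates
            if self.variance_covariates is not None
            else self.mean_covariates
        )

    def design(self, table: pd.DataFrame, which: str = "mean") -> np.ndarray:
        names = self.mean_covariates if which == "mean" else self.var_names
        missing = [c for c in names if c not in table.columns]
        if missing:
            raise KeyError(f"covariates not in table: {missing}")
        X = table.loc[:, list(names)].to_numpy(dtype=float)
        if self.include_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        return X

    def coef_names(self, which: str = "mean") -> tuple[str, ...]:
        names = self.mean_covariates if which == "mean" else self.var_names
        return (("const",) if self.include_intercept else ()) + tuple(names)


@dataclass
class FglsFit:
    spec: IncomeModelSpec
    beta_hat: np.ndarray
    theta_hat: np.ndarray
    stage1_beta_ols: np.ndarray
    stage1_residuals: np.ndarray
    stage2_theta_ols: np.ndarray
    stage2_residual: np.ndarray
    n: int
    floored_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    eps: float = VARIANCE_FLOOR


@dataclass
class MeanVariance:
    mu: np.ndarray
    sigma2: np.ndarray
    floored: np.ndarray


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the columns loading on the near-null singular vector
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        bad = np.abs(vt[-1]) > 1e-8
        cols = [names[i] for i in np.flatnonzero(bad)]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {cols}"
        )


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    if w is None:
        return np.linalg.lstsq(X, y, rcond=None)[0]
    sw = np.sqrt(w)
    return np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)[0]


def fit_income_fgls(
    table: pd.DataFrame,
    spec: IncomeModelSpec,
    income_col: str = "income",
    log_income: bool = True,
    eps: float = VARIANCE_FLOOR,
    stage3_weight: str = "floor",
) -> FglsFit:
    """Three-stage FGLS of log income.

    Stages: OLS mean fit, OLS of squared residuals on the variance design,
    WLS re-fit of the variance equation with weights ``1/max(h, eps)`` (or
    ``1/|h|`` / ``1/h^2`` via ``stage3_weight``), then WLS of log income with
    weights from the fitted variances.  Rows whose fitted variance fell below
    ``eps`` are recorded in ``floored_rows``.
    """
    y_raw = table[income_col].to_numpy(dtype=float)
    if log_income:
        if np.any(y_raw <= 0) or not np.all(np.isfinite(y_raw)):
            bad = np.flatnonzero(~(y_raw > 0) | ~np.isfinite(y_raw))
            raise ValueError(
                f"income must be strictly positive and finite to take logs; "
                f"offending rows {bad[:10].tolist()} — drop them or supply "
                f"pre-logged income with log_income=False"
            )
        lny = np.log(y_raw)
    else:
        lny = y_raw

    Xm = spec.design(table, "mean")
    Xv = spec.design(table, "variance")
    _check_full_rank(Xm, spec.coef_names("mean"))
    _check_full_rank(Xv, spec.coef_names("variance"))
    n, p = Xm.shape
    if n <= max(p, Xv.shape[1]):
        raise ValueError(f"n={n} too small for {p} coefficients")

    # stage 1: OLS mean
    beta_ols = _wls(Xm, lny)
    e = lny - Xm @ beta_ols
    e2 = e * e

    # stage 2: OLS of squared residuals
    theta_ols = _wls(Xv, e2)
    h = Xv @ theta_ols
    if stage3_weight == "floor":
        w2 = 1.0 / np.maximum(h, eps)
    elif stage3_weight == "abs":
        w2 = 1.0 / np.maximum(np.abs(h), eps)
    elif stage3_weight == "square":
        w2 = 1.0 / np.maximum(h * h, eps * eps)
    else:
        raise ValueError(f"unknown stage3_weight {stage3_weight!r}")

    # stage 3: WLS variance equation -> FGLS theta
    theta_hat = _wls(Xv, e2, w2)
    sigma2 = Xv @ theta_hat
    floored = np.flatnonzero(sigma2 < eps)
    sigma2 = np.maximum(sigma2, eps)

    # stage 4: WLS mean equation -> FGLS beta
    beta_hat = _wls(Xm, lny, 1.0 / sigma2)

    return FglsFit(
        spec=spec,
        beta_hat=beta_hat,
        theta_hat=theta_hat,
        stage1_beta_ols=beta_ols,
        stage1_residuals=e,
        stage2_theta_ols=theta_ols,
        stage2_residual=e2 - h,
        n=n,
        floored_rows=floored,
        eps=eps,
    )


def predict_mean_variance(fit: FglsFit, table: pd.DataFrame) -> MeanVariance:
    """Expected value and variance of log income for new rows.

    Fitted variances below the floor are clipped and flagged.
    """
    Xm = fit.spec.design(table, "mean")
    Xv = fit.spec.design(table, "variance")
    if Xm.shape[1] != len(fit.beta_hat) or Xv.shape[1] != len(fit.theta_hat):
        raise ValueError("design width does not match fitted coefficients")
    mu = Xm @ fit.beta_hat
    raw = Xv @ fit.theta_hat
    floored = raw < fit.eps
    return MeanVariance(mu=mu, sigma2=np.maximum(raw, fit.eps), floored=floored)


# ---------------------------------------------------------------------------
# Vulnerability index
# ---------------------------------------------------------------------------

def vulnerability_index(
    mu: np.ndarray, sigma2: np.ndarray, poverty_line: float
) -> np.ndarray:
    """P(log income <= log line) = Phi((ln(line) - mu) / sqrt(sigma2))."""
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if poverty_line <= 0:
        raise ValueError(f"poverty line must be positive, got {poverty_line}")
    if np.any(sigma2 <= 0):
        raise ValueError("sigma2 must be strictly positive")
    return stats.norm.cdf((np.log(poverty_line) - mu) / np.sqrt(sigma2))


@dataclass
class VulnerabilityResult:
    index: np.ndarray
    vulnerable: np.ndarray
    threshold: float
    poverty_line: float

    @property
    def log_line(self) -> float:
        return math.log(self.poverty_line)


def classify_households(
    index: np.ndarray, poverty_line: float, threshold: float = 0.5
) -> VulnerabilityResult:
    index = np.asarray(index, dtype=float)
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    return VulnerabilityResult(
        index=index,
        vulnerable=index >= threshold,
        threshold=threshold,
        poverty_line=poverty_line,
    )


@dataclass
class VulnerabilityDistribution:
    bin_edges: np.ndarray
    counts: np.ndarray
    percents: np.ndarray
    bin_means: np.ndarray
    bin_sds: np.ndarray
    headcount_ge_threshold: int
    headcount_percent: float
    threshold: float
    n: int


def classify_and_summarize(
    v: np.ndarray,
    threshold: float = 0.5,
    bin_edges: Sequence[float] = (0.0, 0.25, 0.50, 0.75, 1.0),
) -> VulnerabilityDistribution:
    """Bin the index (left-closed bins, last bin closed) and count v >= threshold."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("empty vulnerability vector")
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError("vulnerability index must lie in [0,1]")
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    nbins = len(edges) - 1
    # np.digitize gives left-closed bins; fold the top edge into the last bin
    which = np.digitize(v, edges[1:-1], right=False)
    which[v >= edges[-1]] = nbins - 1
    counts = np.bincount(which, minlength=nbins)
    n = v.size
    percents = np.array([round_half_up(100.0 * c / n, 2) for c in counts])
    means = np.full(nbins, np.nan)
    sds = np.full(nbins, np.nan)
    for b in range(nbins):
        vals = v[which == b]
        if vals.size:
            means[b] = vals.mean()
            sds[b] = vals.std(ddof=1) if vals.size > 1 else 0.0
    head = int(np.sum(v >= threshold))
    return VulnerabilityDistribution(
        bin_edges=edges,
        counts=counts,
        percents=percents,
        bin_means=means,
        bin_sds=sds,
        headcount_ge_threshold=head,
        headcount_percent=round_half_up(100.0 * head / n, 2),
        threshold=threshold,
        n=n,
    )


def relative_poverty_line(
    per_capita_disposable_income: float,
    fraction: float = 0.60,
    rounding: str = "none",
) -> float:
    """Relative poverty line as a fraction of per-capita disposable income.

    ``rounding`` ∈ {"none", "nearest", "floor", "ceil"} controls optional
    rounding to whole currency units.
    """
    if per_capita_disposable_income <= 0:
        raise ValueError("per-capita income must be positive")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must lie in (0,1], got {fraction}")
    line = fraction * per_capita_disposable_income
    if rounding == "none":
        return line
    if rounding == "nearest":
        return float(round_half_up(line, 0))
    if rounding == "floor":
        return float(math.floor(line))
    if rounding == "ceil":
        return float(math.ceil(line))
    raise ValueError(f"unknown rounding mode {rounding!r}")


def tabulate(column: Sequence) -> pd.DataFrame:
    """Counts and percents (2 dp, half-up) per level, in stable sorted order."""
    s = pd.Series(column)
    if s.empty:
        raise ValueError("empty column")
    counts = s.value_counts(sort=False)
    counts = counts.sort_index()
    n = int(counts.sum())
    out = pd.DataFrame(
        {
            "level": counts.index.to_numpy(),
            "count": counts.to_numpy(),
            "percent": [round_half_up(100.0 * c / n, 2) for c in counts],
        }
    )
    return out
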