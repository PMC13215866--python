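"""Seeded synthetic household-survey generator.

The generator mirrors the statistical structure the downstream analyses
assume: log income normal with conditional mean X·beta and conditional
variance X·theta, capital-driven binary utilization variables via a logistic
link, and a recursive dependency chain among the capital constructs
(human -> physical -> social).  Every variable block draws from its own
deterministic substream of the master seed, so adding a variable never
perturbs the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .vep import vulnerability_index

__all__ = [
    "MarginalSpec",
    "SyntheticConfig",
    "GeneratedSurvey",
    "default_config",
    "generate_covariates",
    "generate_income",
    "generate_survey",
    "simulate_dag",
]


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent, order-insensitive substream keyed by (seed, name)."""
    digest = hashlib.blake2b(name.encode(), digest_size=8).digest()
    return np.random.default_rng([seed & 0xFFFFFFFF, int.from_bytes(digest, "big")])


@dataclass(frozen=True)
class MarginalSpec:
    """Marginal distribution of one covariate.

    kind: "bernoulli" (p), "categorical" (values, probs), "poisson" (lam),
    "normal" (mu, sigma, optional low truncation), "uniform" (low, high).
    ``parent`` names a construct whose standardized score shifts this
    variable through a Gaussian copula with the given ``loading``.
    """

    name: str
    kind: str
    params: dict
    parent: str | None = None
    loading: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("bernoulli", "categorical", "poisson", "normal", "uniform"):
            raise ValueError(f"unknown marginal kind {self.kind!r} for {self.name!r}")
        if not -1.0 < self.loading < 1.0:
            raise ValueError(f"loading for {self.name!r} must lie in (-1,1)")

    def ppf(self, u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        if self.kind == "bernoulli":
            prob = p["p"]
            if not 0 <= prob <= 1:
                raise ValueError(f"bernoulli p for {self.name!r} out of [0,1]")
            return (u > 1 - prob).astype(float)
        if self.kind == "categorical":
            values = np.asarray(p["values"], dtype=float)
            probs = np.asarray(p["probs"], dtype=float)
            if abs(probs.sum() - 1) > 1e-9 or np.any(probs < 0):
                raise ValueError(f"invalid categorical probs for {self.name!r}")
            edges = np.cumsum(probs)
            return values[np.searchsorted(edges, u, side="right").clip(0, len(values) - 1)]
        if self.kind == "poisson":
            return stats.poisson.ppf(u, p["lam"])
        if self.kind == "normal":
            x = stats.norm.ppf(u, loc=p["mu"], scale=p["sigma"])
            if "low" in p:
                x = np.maximum(x, p["low"])
            return x
        if self.kind == "uniform":
            return p["low"] + u * (p["high"] - p["low"])
        raise AssertionError


def _table2_defaults() -> list[MarginalSpec]:
    """Marginals loosely calibrated to the published sample description;
    every entry is overridable through SyntheticConfig.covariate_spec."""
    return [
        # human capital block
        MarginalSpec("educational_level", "categorical",
                     {"values": [1, 2, 3, 4], "probs": [0.16, 0.52, 0.27, 0.05]}),
        MarginalSpec("health_status", "bernoulli", {"p": 0.6927}),
        MarginalSpec("labor_force", "poisson", {"lam": 2.39}, parent="human", loading=0.35),
        MarginalSpec("migrant_workers", "poisson", {"lam": 0.37}, parent="human", loading=0.30),
        # physical capital block (driven by the physical latent)
        MarginalSpec("agricultural_machines", "poisson", {"lam": 0.42}, parent="physical", loading=0.40),
        MarginalSpec("durable_products", "poisson", {"lam": 10.03}, parent="physical", loading=0.50),
        MarginalSpec("building_material", "bernoulli", {"p": 0.0075}, parent="physical", loading=0.20),
        MarginalSpec("drinking_water", "bernoulli", {"p": 0.9549}, parent="physical", loading=0.30),
        MarginalSpec("latrines", "bernoulli", {"p": 0.0885}, parent="physical", loading=0.40),
        MarginalSpec("cultivated_area", "normal", {"mu": 22.79, "sigma": 20.0, "low": 0.0},
                     parent="physical", loading=0.25),
        MarginalSpec("kitchen_separation", "bernoulli", {"p": 0.7497}, parent="physical", loading=0.35),
        # social capital block (driven by the social latent)
        MarginalSpec("cash_gift", "normal", {"mu": 6.44, "sigma": 3.38, "low": 0.0},
                     parent="social", loading=0.60),
        # income-equation covariates (user-definable demographic block)
        MarginalSpec("household_size", "poisson", {"lam": 2.46}),
        MarginalSpec("dependency_ratio", "uniform", {"low": 0.0, "high": 1.0}),
        MarginalSpec("medical_insurance", "bernoulli", {"p": 0.95}),
        MarginalSpec("medical_debt", "bernoulli", {"p": 0.20}),
    ]


_HUMAN_INDICATORS = ("educational_level", "labor_force", "migrant_workers")
_UTILIZATION_VARS = {
    "outpatient": 0.1229,
    "inpatient": 0.3592,
    "physical_examination": 0.7122,
    "self_treatment": 0.1034,
}


@dataclass(frozen=True)
class SyntheticConfig:
    n_households: int
    seed: int
    beta_true: tuple[float, ...]
    theta_true: tuple[float, ...]
    mean_covariates: tuple[str, ...]
    variance_covariates: tuple[str, ...]
    covariate_spec: tuple[MarginalSpec, ...] = field(
        default_factory=lambda: tuple(_table2_defaults())
    )
    structural_paths: dict = field(
        default_factory=lambda: {
            ("human", "physical"): 0.5,
            ("physical", "social"): 0.45,
            ("human", "utilization"): -0.3,
        }
    )
    utilization_targets: dict = field(default_factory=lambda: dict(_UTILIZATION_VARS))
    farming_share: float = 0.7335
    poverty_line: float = 9202.0
    max_resample_attempts: int = 50

    def __post_init__(self) -> None:
        if self.n_households <= 0:
            raise ValueError("n_households must be positive")
        if not 0 < self.farming_share < 1:
            raise ValueError(f"farming_share must lie in (0,1), got {self.farming_share}")
        if self.poverty_line <= 0:
            raise ValueError("poverty_line must be positive")
        names = [m.name for m in self.covariate_spec]
        if len(set(names)) != len(names):
            raise ValueError("duplicate covariate names in covariate_spec")
        for group, coefs in (
            (self.mean_covariates, self.beta_true),
            (self.variance_covariates, self.theta_true),
        ):
            if len(coefs) != len(group) + 1:
                raise ValueError(
                    f"coefficient vector of length {len(coefs)} does not match "
                    f"intercept + {len(group)} covariates"
                )
        known = set(names)
        for c in tuple(self.mean_covariates) + tuple(self.variance_covariates):
            if c not in known:
                raise ValueError(f"model covariate {c!r} not in covariate_spec")


def default_config(n_households: int = 4371, seed: int = 0, **overrides) -> SyntheticConfig:
    """Config whose mean/variance designs use the demographic block; theta is
    non-negative so the variance X·theta is positive for all rows."""
    base = dict(
        n_households=n_households,
        seed=seed,
        mean_covariates=(
            "household_size",
            "dependency_ratio",
            "health_status",
            "medical_insurance",
            "medical_debt",
        ),
        variance_covariates=(
            "household_size",
            "dependency_ratio",
            "health_status",
            "medical_insurance",
            "medical_debt",
        ),
        beta_true=(9.35, 0.06, -0.45, -0.22, 0.10, -0.25),
        theta_true=(0.35, 0.01, 0.08, 0.10, 0.02, 0.08),
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@dataclass
class GeneratedSurvey:
    table: pd.DataFrame
    truth: SyntheticConfig
    true_vulnerability: np.ndarray


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _draw_block(
    config: SyntheticConfig, n: int, salt: str = ""
) -> tuple[pd.DataFrame, dict]:
    """Draw all covariates plus latent construct scores for n households."""
    seed = config.seed
    cols: dict[str, np.ndarray] = {}
    # construct latents in dependency order: human <- indicators; then chained
    # physical and social latents with the configured standardized coefficients
    latents: dict[str, np.ndarray] = {}

    by_parent: dict[str | None, list[MarginalSpec]] = {}
    for m in config.covariate_spec:
        by_parent.setdefault(m.parent, []).append(m)

    def draw(m: MarginalSpec) -> np.ndarray:
        rng = _substream(seed, f"cov:{m.name}{salt}")
        if m.parent is None or m.loading == 0.0:
            u = rng.uniform(size=n)
        else:
            z = rng.standard_normal(n)
            lat = m.loading * latents[m.parent] + np.sqrt(1 - m.loading**2) * z
            u = stats.norm.cdf(lat)
        return m.ppf(u, rng)

    for m in by_parent.get(None, []):
        cols[m.name] = draw(m)

    # human latent: standardized composite of its indicator z-scores
    hz = [
        _standardize(cols[v]) for v in _HUMAN_INDICATORS if v in cols
    ]
    if "health_status" in cols:
        hz.append(-_standardize(cols["health_status"]))
    latents["human"] = _standardize(np.mean(hz, axis=0)) if hz else np.zeros(n)

    for construct, key in (("physical", ("human", "physical")),
                           ("social", ("physical", "social"))):
        coef = float(config.structural_paths.get(key, 0.0))
        if not -1.0 < coef < 1.0:
            raise ValueError(f"structural coefficient {key} must lie in (-1,1)")
        rng = _substream(seed, f"latent:{construct}{salt}")
        parent = latents[key[0]]
        latents[construct] = coef * parent + np.sqrt(1 - coef**2) * rng.standard_normal(n)

    for parent in ("human", "physical", "social"):
        for m in by_parent.get(parent, []):
            cols[m.name] = draw(m)
    unknown = set(by_parent) - {None, "human", "physical", "social"}
    if unknown:
        raise ValueError(f"unknown parent constructs in covariate_spec: {sorted(unknown)}")

    return pd.DataFrame(cols), latents


def _variance_design(config: SyntheticConfig, table: pd.DataFrame) -> np.ndarray:
    X = table.loc[:, list(config.variance_covariates)].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(X)), X])


def generate_covariates(config: SyntheticConfig) -> pd.DataFrame:
    """Covariate table with X·theta_true > 0 verified row-wise.

    Rows violating variance positivity are redrawn (bounded attempts); a
    config under which feasibility cannot be reached raises ValueError.
    """
    table, _ = _draw_block(config, config.n_households)
    theta = np.asarray(config.theta_true)
    for attempt in range(config.max_resample_attempts):
        bad = _variance_design(config, table) @ theta <= 0
        if not bad.any():
            table.index = pd.RangeIndex(len(table))
            return table
        redraw, _ = _draw_block(config, int(bad.sum()), salt=f":retry{attempt}")
        table.loc[bad, :] = redraw.to_numpy()
    raise ValueError(
        f"variance specification infeasible: {int(bad.sum())} rows still have "
        f"X·theta <= 0 after {config.max_resample_attempts} resampling attempts"
    )


def generate_income(
    X: np.ndarray, beta: np.ndarray, theta: np.ndarray, seed: int
) -> np.ndarray:
    """Log income: lnY_i ~ Normal(X_i·beta, X_i·theta). X includes the intercept."""
    X = np.asarray(X, dtype=float)
    mu = X @ np.asarray(beta, dtype=float)
    var = X @ np.asarray(theta, dtype=float)
    if np.any(var <= 0):
        row = int(np.argmax(var <= 0))
        raise ValueError(
            f"non-positive income variance at row {row}: X·theta = {var[row]:.6g}"
        )
    rng = _substream(seed, "income")
    return mu + np.sqrt(var) * rng.standard_normal(len(mu))


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def generate_survey(config: SyntheticConfig) -> GeneratedSurvey:
    """Full survey: covariates, income, utilization, farming flag, and the
    per-household true crossing probability from the generative parameters."""
    table, latents = _draw_block(config, config.n_households)
    theta = np.asarray(config.theta_true)
    # feasibility pass identical to generate_covariates
    for attempt in range(config.max_resample_attempts):
        bad = _variance_design(config, table) @ theta <= 0
        if not bad.any():
            break
        redraw, relat = _draw_block(config, int(bad.sum()), salt=f":retry{attempt}")
        table.loc[bad, :] = redraw.to_numpy()
        for k in latents:
            latents[k][np.asarray(bad)] = relat[k]
    else:
        raise ValueError(
            "variance specification infeasible after "
            f"{config.max_resample_attempts} resampling attempts"
        )
    table.index = pd.RangeIndex(len(table))
    n = len(table)
    seed = config.seed

    Xm = np.column_stack(
        [np.ones(n), table.loc[:, list(config.mean_covariates)].to_numpy(dtype=float)]
    )
    Xv = _variance_design(config, table)
    # mean and variance designs may differ, so draw from both explicitly
    # (same substream as generate_income for reproducibility)
    mu = Xm @ np.asarray(config.beta_true)
    var = Xv @ theta
    if np.any(var <= 0):
        row = int(np.argmax(var <= 0))
        raise ValueError(f"non-positive income variance at row {row}")
    rng = _substream(seed, "income")
    lny = mu + np.sqrt(var) * rng.standard_normal(n)
    table["ln_income"] = lny
    table["income"] = np.exp(lny)

    # utilization binaries: logistic link on the human composite
    coef_hu = float(config.structural_paths.get(("human", "utilization"), 0.0))
    human = latents["human"]
    for name, target in config.utilization_targets.items():
        rng_u = _substream(seed, f"util:{name}")
        p = 1.0 / (1.0 + np.exp(-(_logit(target) + coef_hu * human)))
        table[name] = (rng_u.uniform(size=n) < p).astype(float)
    # out-of-pocket logged expenses: positive draws for users, 0 otherwise
    for name, user_col, mu_e, sd_e in (
        ("outpatient_oop", "outpatient", 6.8, 1.0),
        ("inpatient_oop", "inpatient", 8.1, 1.1),
    ):
        if user_col in table.columns:
            rng_e = _substream(seed, f"oop:{name}")
            amt = np.abs(rng_e.normal(mu_e, sd_e, size=n))
            table[name] = table[user_col].to_numpy() * amt

    rng_f = _substream(seed, "farming")
    table["farming"] = (rng_f.uniform(size=n) < config.farming_share).astype(float)

    true_v = vulnerability_index(mu, var, config.poverty_line)
    table["true_vulnerability"] = true_v
    return GeneratedSurvey(table=table, truth=config, true_vulnerability=true_v)


def simulate_dag(
    coefficients: dict,
    n: int,
    seed: int,
    order: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Standardized draws from a linear recursive system with the given
    standardized edge coefficients ((src, dst) -> value).

    Residual variances are set so every variable has unit population variance;
    an edge set implying variance > 1 for some node raises ValueError.
    """
    import networkx as nx

    g = nx.DiGraph()
    for (src, dst), w in coefficients.items():
        g.add_edge(src, dst, weight=float(w))
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("coefficient edge set contains a cycle")
    if order is None:
        order = tuple(nx.topological_sort(g))
    elif set(order) != set(g.nodes):
        for node in order:
            g.add_node(node)

    idx = {c: i for i, c in enumerate(order)}
    k = len(order)
    cov = np.zeros((k, k))
    data = np.zeros((n, k))
    for node in nx.topological_sort(g):
        i = idx[node]
        parents = [(idx[p], g[p][node]["weight"]) for p in g.predecessors(node)]
        rng = _substream(seed, f"dag:{node}")
        if not parents:
            data[:, i] = rng.standard_normal(n)
            cov[i, i] = 1.0
            continue
        mean = np.zeros(n)
        var_pred = 0.0
        for (pi, w) in parents:
            mean += w * data[:, pi]
        for (pi, wi) in parents:
            for (pj, wj) in parents:
                var_pred += wi * wj * cov[pi, pj]
        psi = 1.0 - var_pred
        if psi < 0:
            raise ValueError(
                f"coefficients into {node!r} imply variance {var_pred:.4f} > 1"
            )
        data[:, i] = mean + np.sqrt(psi) * rng.standard_normal(n)
        for other, j in idx.items():
            if other == node:
                continue
            cov[i, j] = cov[j, i] = sum(w * cov[pi, j] for pi, w in parents)
        cov[i, i] = 1.0
    return pd.DataFrame(data, columns=list(order))
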