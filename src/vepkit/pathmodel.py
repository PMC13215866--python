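"""Recursive construct-level path analysis with effect decomposition.

Constructs are unit-weighted composites of sign-aligned z-scored indicators.
Each endogenous construct is regressed on its parents (the exact ML solution
for a recursive system with uncorrelated errors on standardized data); total
effects come from the (I - B)^-1 identity, and covariance-based fit indices
compare the implied and sample covariance of the composites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConstructSpec",
    "PathDiagram",
    "PathFit",
    "EffectTable",
    "FitIndexReport",
    "default_construct_spec",
    "default_diagram",
    "build_composites",
    "fit_path_model",
    "decompose_effects",
    "implied_covariance",
    "fit_indices",
    "significance_report",
    "enumerate_path_effects",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstructSpec:
    """Mapping construct name -> ordered (indicator, sign) pairs, sign in {+1,-1}."""

    constructs: dict

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cname, indicators in self.constructs.items():
            for ind, sign in indicators:
                if sign not in (1, -1):
                    raise ValueError(f"sign for {ind!r} must be +1 or -1, got {sign}")
                if ind in seen:
                    raise ValueError(
                        f"indicator {ind!r} assigned to both {seen[ind]!r} and {cname!r}"
                    )
                seen[ind] = cname

    @property
    def names(self) -> list[str]:
        return list(self.constructs)


def default_construct_spec(modified: bool = True) -> ConstructSpec:
    """Default construct blocks over the survey indicator set.

    ``modified=True`` (default) drops the outpatient out-of-pocket and
    physical-examination indicators from the utilization block; the full
    initial block is available with ``modified=False``.
    """
    utilization = [
        ("outpatient", 1),
        ("outpatient_oop", 1),
        ("inpatient", 1),
        ("inpatient_oop", 1),
        ("physical_examination", 1),
        ("self_treatment", 1),
    ]
    if modified:
        utilization = [
            (ind, s)
            for ind, s in utilization
            if ind not in ("outpatient_oop", "physical_examination")
        ]
    return ConstructSpec(
        constructs={
            "human": [
                ("educational_level", 1),
                ("health_status", -1),  # 1 = chronic illness/disability present
                ("labor_force", 1),
                ("migrant_workers", 1),
            ],
            "physical": [
                ("agricultural_machines", 1),
                ("durable_products", 1),
                ("building_material", 1),
                ("drinking_water", 1),
                ("latrines", 1),
                ("cultivated_area", 1),
                ("kitchen_separation", 1),
            ],
            "social": [("cash_gift", 1)],
            "utilization": utilization,
        }
    )


@dataclass(frozen=True)
class PathDiagram:
    """Ordered construct list plus a directed acyclic edge set."""

    constructs: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "constructs", tuple(self.constructs))
        object.__setattr__(self, "edges", tuple(tuple(e) for e in self.edges))
        known = set(self.constructs)
        for src, dst in self.edges:
            if src not in known or dst not in known:
                raise ValueError(f"edge {src}->{dst} references undeclared construct")
        g = nx.DiGraph(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"diagram contains a cycle: {cycle}")

    def parents(self, node: str) -> list[str]:
        return [s for s, d in self.edges if d == node]

    @property
    def endogenous(self) -> list[str]:
        return [c for c in self.constructs if self.parents(c)]

    @property
    def exogenous(self) -> list[str]:
        return [c for c in self.constructs if not self.parents(c)]


def default_diagram() -> PathDiagram:
    return PathDiagram(
        constructs=("human", "physical", "social", "utilization", "vulnerability"),
        edges=(
            ("human", "physical"),
            ("human", "utilization"),
            ("human", "vulnerability"),
            ("physical", "social"),
            ("physical", "vulnerability"),
            ("social", "vulnerability"),
            ("utilization", "vulnerability"),
        ),
    )


# ---------------------------------------------------------------------------
# Composites
# ---------------------------------------------------------------------------

def build_composites(table: pd.DataFrame, spec: ConstructSpec) -> pd.DataFrame:
    """One standardized score per construct: mean of sign-aligned z-scores,
    re-standardized to unit variance."""
    out = {}
    for cname, indicators in spec.constructs.items():
        zs = []
        for ind, sign in indicators:
            if ind not in table.columns:
                raise KeyError(f"indicator {ind!r} (construct {cname!r}) not in table")
            x = table[ind].to_numpy(dtype=float)
            sd = x.std(ddof=1)
            if sd == 0 or not np.isfinite(sd):
                raise ValueError(f"indicator {ind!r} is constant; cannot z-score")
            zs.append(sign * (x - x.mean()) / sd)
        comp = np.mean(zs, axis=0)
        csd = comp.std(ddof=1)
        if csd == 0:
            raise ValueError(f"composite {cname!r} is constant")
        out[cname] = (comp - comp.mean()) / csd
    return pd.DataFrame(out, index=table.index)


# ---------------------------------------------------------------------------
# Path fit
# ---------------------------------------------------------------------------

@dataclass
class PathFit:
    diagram: PathDiagram
    coefficients: dict          # (src, dst) -> standardized coefficient
    se: dict                    # (src, dst) -> bootstrap SE
    critical_ratio: dict
    pvalues: dict
    residual_variance: dict     # endogenous construct -> psi
    exogenous_variance: dict
    sample_cov: pd.DataFrame
    n: int
    coefficient_cap: float = 1.0
    capped_edges: list = field(default_factory=list)

    def b_matrix(self) -> np.ndarray:
        """B[i, j] = coefficient of edge construct_j -> construct_i."""
        order = self.diagram.constructs
        k = len(order)
        B = np.zeros((k, k))
        pos = {c: i for i, c in enumerate(order)}
        for (src, dst), val in self.coefficients.items():
            B[pos[dst], pos[src]] = val
        return B


def _edge_coefs(comp: np.ndarray, cols: dict, diagram: PathDiagram) -> dict:
    coefs = {}
    for node in diagram.endogenous:
        pars = diagram.parents(node)
        Z = np.column_stack(
            [np.ones(comp.shape[0])] + [comp[:, cols[p]] for p in pars]
        )
        beta = np.linalg.lstsq(Z, comp[:, cols[node]], rcond=None)[0]
        for j, p in enumerate(pars):
            coefs[(p, node)] = float(beta[j + 1])
    return coefs


def fit_path_model(
    composites: pd.DataFrame,
    diagram: PathDiagram,
    bootstrap_reps: int = 500,
    seed: int | None = None,
    coefficient_cap: float = 1.0,
) -> PathFit:
    """Estimate every structural equation by least squares on its parents.

    Standard errors are from a paired bootstrap over households; critical
    ratios are estimate/SE with two-sided normal p-values.  Standardized
    coefficients beyond ``coefficient_cap`` in magnitude are flagged (a known
    composite-model artifact), not truncated.
    """
    missing = [c for c in diagram.constructs if c not in composites.columns]
    if missing:
        raise KeyError(f"constructs missing from composite table: {missing}")
    comp = composites.loc[:, list(diagram.constructs)].to_numpy(dtype=float)
    n = comp.shape[0]
    cols = {c: i for i, c in enumerate(diagram.constructs)}
    for node in diagram.endogenous:
        pars = diagram.parents(node)
        Z = np.column_stack([comp[:, cols[p]] for p in pars])
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise np.linalg.LinAlgError(
                f"collinear parents for construct {node!r}: {pars}"
            )

    coefs = _edge_coefs(comp, cols, diagram)

    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        draws = {e: np.empty(bootstrap_reps) for e in coefs}
        for b in range(bootstrap_reps):
            idx = rng.integers(0, n, n)
            bc = _edge_coefs(comp[idx], cols, diagram)
            for e, v in bc.items():
                draws[e][b] = v
        se = {e: float(draws[e].std(ddof=1)) for e in coefs}
    else:
        se = {e: np.nan for e in coefs}

    cr, pv = {}, {}
    for e, b in coefs.items():
        s = se[e]
        cr[e] = b / s if s and np.isfinite(s) and s > 0 else np.nan
        pv[e] = 2 * stats.norm.sf(abs(cr[e])) if np.isfinite(cr[e]) else np.nan

    resid_var = {}
    for node in diagram.endogenous:
        pars = diagram.parents(node)
        pred = sum(coefs[(p, node)] * comp[:, cols[p]] for p in pars)
        r = comp[:, cols[node]] - pred
        resid_var[node] = float(max(np.mean((r - r.mean()) ** 2), 0.0))
    exo_var = {
        node: float(np.var(comp[:, cols[node]]))
        for node in diagram.exogenous
    }

    capped = [e for e, b in coefs.items() if abs(b) > coefficient_cap]
    S = pd.DataFrame(
        np.cov(comp.T, ddof=1),
        index=list(diagram.constructs),
        columns=list(diagram.constructs),
    )
    return PathFit(
        diagram=diagram,
        coefficients=coefs,
        se=se,
        critical_ratio=cr,
        pvalues=pv,
        residual_variance=resid_var,
        exogenous_variance=exo_var,
        sample_cov=S,
        n=n,
        coefficient_cap=coefficient_cap,
        capped_edges=capped,
    )


def path_fit_from_coefficients(
    diagram: PathDiagram, coefficients: dict, n: int = 0
) -> PathFit:
    """Assemble a PathFit from externally supplied standardized coefficients
    (no data needed) — for desk decomposition of published tables."""
    for e in coefficients:
        if tuple(e) not in diagram.edges:
            raise ValueError(f"coefficient supplied for non-edge {e}")
    missing = [e for e in diagram.edges if e not in coefficients]
    if missing:
        raise ValueError(f"missing coefficients for edges {missing}")
    k = len(diagram.constructs)
    return PathFit(
        diagram=diagram,
        coefficients={tuple(e): float(v) for e, v in coefficients.items()},
        se={tuple(e): np.nan for e in coefficients},
        critical_ratio={tuple(e): np.nan for e in coefficients},
        pvalues={tuple(e): np.nan for e in coefficients},
        residual_variance={c: np.nan for c in diagram.endogenous},
        exogenous_variance={c: 1.0 for c in diagram.exogenous},
        sample_cov=pd.DataFrame(
            np.eye(k), index=list(diagram.constructs), columns=list(diagram.constructs)
        ),
        n=n,
    )


# ---------------------------------------------------------------------------
# Effect decomposition
# ---------------------------------------------------------------------------

@dataclass
class EffectTable:
    table: pd.DataFrame  # source, target, direct, indirect, total (+ 3dp twins)

    def effect(self, source: str, target: str, kind: str = "total") -> float:
        row = self.table[
            (self.table.source == source) & (self.table.target == target)
        ]
        if row.empty:
            return 0.0
        return float(row.iloc[0][kind])


def decompose_effects(fit: PathFit, diagram: PathDiagram | None = None) -> EffectTable:
    """Direct/indirect/total standardized effects for every ordered pair.

    With B the direct-coefficient matrix, total = (I - B)^-1 - I and
    indirect = total - direct; the identity total = direct + indirect is
    exact by construction.
    """
    diagram = diagram or fit.diagram
    order = diagram.constructs
    k = len(order)
    B = fit.b_matrix()
    eye = np.eye(k)
    M = eye - B
    if abs(np.linalg.det(M)) < 1e-12:  # unreachable for acyclic B; guarded anyway
        raise np.linalg.LinAlgError("I - B is singular")
    T = np.linalg.inv(M) - eye
    ind = T - B
    rows = []
    for j, src in enumerate(order):
        for i, dst in enumerate(order):
            if i == j:
                continue
            d, indir, tot = B[i, j], ind[i, j], T[i, j]
            if d == 0 and indir == 0:
                continue
            rows.append(
                {
                    "source": src,
                    "target": dst,
                    "direct": d,
                    "indirect": indir,
                    "total": tot,
                    "direct_3dp": round(d, 3),
                    "indirect_3dp": round(indir, 3),
                    "total_3dp": round(tot, 3),
                }
            )
    columns = ["source", "target", "direct", "indirect", "total",
               "direct_3dp", "indirect_3dp", "total_3dp"]
    return EffectTable(table=pd.DataFrame(rows, columns=columns))


def enumerate_path_effects(diagram: PathDiagram, coefficients: dict) -> dict:
    """Independent oracle: total effect per pair by explicit enumeration of all
    directed paths, summing products of edge coefficients along each path."""
    g = nx.DiGraph()
    g.add_nodes_from(diagram.constructs)
    for (src, dst), w in coefficients.items():
        g.add_edge(src, dst, weight=w)
    totals: dict[tuple[str, str], float] = {}
    for src in diagram.constructs:
        for dst in diagram.constructs:
            if src == dst:
                continue
            tot = 0.0
            for path in nx.all_simple_paths(g, src, dst):
                prod = 1.0
                for a, b in zip(path[:-1], path[1:]):
                    prod *= g[a][b]["weight"]
                tot += prod
            if tot != 0.0 or g.has_edge(src, dst):
                totals[(src, dst)] = tot
    return totals


# ---------------------------------------------------------------------------
# Implied covariance and fit indices
# ---------------------------------------------------------------------------

def implied_covariance(fit: PathFit, diagram: PathDiagram | None = None) -> pd.DataFrame:
    """Model-implied construct covariance: (I-B)^-1 Psi (I-B)^-T with Psi the
    diagonal of exogenous variances and residual variances."""
    diagram = diagram or fit.diagram
    order = diagram.constructs
    B = fit.b_matrix()
    psi = np.zeros(len(order))
    for i, c in enumerate(order):
        psi[i] = (
            fit.residual_variance[c]
            if c in fit.residual_variance
            else fit.exogenous_variance[c]
        )
    M = np.linalg.inv(np.eye(len(order)) - B)
    Sigma = M @ np.diag(psi) @ M.T
    return pd.DataFrame(Sigma, index=list(order), columns=list(order))


@dataclass
class FitIndexReport:
    chi_square: float
    df: int
    chi_square_baseline: float
    df_baseline: int
    GFI: float
    AGFI: float
    PGFI: float
    IFI: float
    CFI: float
    SRMR: float
    RMSEA: float
    n: int


def model_degrees_of_freedom(diagram: PathDiagram) -> int:
    """p(p+1)/2 distinct moments minus free parameters (edges + p variances)."""
    p = len(diagram.constructs)
    return p * (p + 1) // 2 - (len(diagram.edges) + p)


def fit_indices(
    S: pd.DataFrame | np.ndarray,
    Sigma: pd.DataFrame | np.ndarray,
    df_model: int,
    n: int,
    df_baseline: int | None = None,
) -> FitIndexReport:
    """Covariance-based fit indices from the ML discrepancy.

    chi2 = (n-1)[ln|Sigma| + tr(S Sigma^-1) - ln|S| - p]; the baseline is the
    independence (diagonal) model.  SRMR is the RMS of correlation-metric
    residuals over the lower triangle including the diagonal.
    """
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    p = S.shape[0]
    if S.shape != Sigma.shape or S.shape[0] != S.shape[1]:
        raise ValueError("S and Sigma must be square with equal dimension")
    for name, M in (("S", S), ("Sigma", Sigma)):
        if np.any(np.linalg.eigvalsh((M + M.T) / 2) <= 0):
            raise np.linalg.LinAlgError(f"{name} is not positive definite")
    if df_baseline is None:
        df_baseline = p * (p - 1) // 2

    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    SigInvS = np.linalg.solve(Sigma, S)
    chi2 = (n - 1) * (logdet_m + np.trace(SigInvS) - logdet_s - p)
    chi2 = float(max(chi2, 0.0))

    # independence model: Sigma_b = diag(S)
    chi2_b = float((n - 1) * (np.sum(np.log(np.diag(S))) - logdet_s))
    chi2_b = max(chi2_b, 0.0)

    R = SigInvS - np.eye(p)
    gfi = float(1.0 - np.trace(R @ R) / np.trace(SigInvS @ SigInvS))
    agfi = (
        float(1.0 - (p * (p + 1)) / (2.0 * df_model) * (1.0 - gfi))
        if df_model > 0
        else np.nan
    )
    pgfi = float(2.0 * df_model / (p * (p + 1)) * gfi)
    ifi = (
        float((chi2_b - chi2) / (chi2_b - df_model))
        if chi2_b != df_model
        else np.nan
    )
    denom = max(chi2_b - df_baseline, chi2 - df_model, 0.0)
    cfi = float(1.0 - max(chi2 - df_model, 0.0) / denom) if denom > 0 else 1.0

    d = np.sqrt(np.diag(S))
    std_resid = (S - Sigma) / np.outer(d, d)
    tri = std_resid[np.tril_indices(p)]
    srmr = float(np.sqrt(np.mean(tri**2)))
    rmsea = (
        float(np.sqrt(max(chi2 - df_model, 0.0) / (df_model * (n - 1))))
        if df_model > 0
        else 0.0
    )
    return FitIndexReport(
        chi_square=chi2,
        df=df_model,
        chi_square_baseline=chi2_b,
        df_baseline=df_baseline,
        GFI=gfi,
        AGFI=agfi,
        PGFI=pgfi,
        IFI=ifi,
        CFI=min(max(cfi, 0.0), 1.0),
        SRMR=srmr,
        RMSEA=rmsea,
        n=n,
    )


def significance_report(fit: PathFit) -> dict:
    """Two-level star convention per edge: '**' if p<0.001, '*' if p<0.05."""
    out = {}
    for e, p in fit.pvalues.items():
        if not np.isfinite(p):
            out[e] = ""
        elif p < 0.001:
            out[e] = "**"
        elif p < 0.05:
            out[e] = "*"
        else:
            out[e] = ""
    return out
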