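"""Survey I/O, pipeline configuration, and end-to-end orchestration."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import pathmodel, quantiles, synthetic, vep

logger = logging.getLogger("vepkit")

__all__ = [
    "read_survey",
    "write_survey",
    "PipelineConfig",
    "StageError",
    "run_pipeline",
]

# CSV dialect is pinned: UTF-8, comma separator, "." decimal, header row.
_CSV_KW = dict(encoding="utf-8", sep=",")


def read_survey(path: str | Path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a household table; drop rows with missing values in schema columns.

    ``schema`` maps column name -> kind in {"binary", "count", "continuous"}.
    Type violations raise with the offending row and column named.
    """
    path = Path(path)
    table = pd.read_csv(path, **_CSV_KW)
    if schema:
        unknown = [c for c in schema if c not in table.columns]
        if unknown:
            raise KeyError(f"schema columns missing from {path.name}: {unknown}")
        before = len(table)
        table = table.dropna(subset=list(schema))
        dropped = before - len(table)
        if dropped:
            logger.info("read_survey: excluded %d incomplete rows of %d", dropped, before)
        for col, kind in schema.items():
            vals = table[col].to_numpy()
            if kind == "binary":
                bad = ~np.isin(vals, (0, 1))
            elif kind == "count":
                arr = vals.astype(float)
                bad = (arr < 0) | (arr != np.floor(arr)) | ~np.isfinite(arr)
            elif kind == "continuous":
                bad = ~np.isfinite(vals.astype(float))
            else:
                raise ValueError(f"unknown schema kind {kind!r} for column {col!r}")
            if bad.any():
                row = table.index[np.argmax(bad)]
                raise ValueError(
                    f"column {col!r} violates kind {kind!r} at row {row}: "
                    f"value {table.loc[row, col]!r}"
                )
    return table.reset_index(drop=True)


def write_survey(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, **_CSV_KW)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Exactly one of ``input_csv`` / ``synthetic`` must be set.
    """

    output_dir: str
    master_seed: int = 0
    input_csv: str | None = None
    synthetic: synthetic.SyntheticConfig | None = None
    schema: dict | None = None
    income_model: vep.IncomeModelSpec | None = None
    poverty_line: float = 9202.0
    threshold: float = 0.5
    quantile_covariates: tuple[str, ...] | None = None
    taus: tuple[float, ...] = (0.25, 0.50, 0.75)
    bootstrap_reps: int = 200
    group_column: str | None = "farming"
    run_quantiles: bool = True
    run_paths: bool = True
    construct_spec: pathmodel.ConstructSpec | None = None
    diagram: pathmodel.PathDiagram | None = None

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_csv or synthetic must be set")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        if "synthetic" in kw and kw["synthetic"] is not None:
            syn = dict(kw["synthetic"])
            if "covariate_spec" in syn:
                syn["covariate_spec"] = tuple(
                    synthetic.MarginalSpec(**m) for m in syn["covariate_spec"]
                )
            for key in ("mean_covariates", "variance_covariates", "beta_true", "theta_true"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            if "structural_paths" in syn:
                syn["structural_paths"] = {
                    tuple(k.split("->")): v for k, v in syn["structural_paths"].items()
                }
            if set(syn) >= {"beta_true", "theta_true", "mean_covariates", "variance_covariates"}:
                kw["synthetic"] = synthetic.SyntheticConfig(**syn)
            else:
                kw["synthetic"] = synthetic.default_config(**syn)
        if "income_model" in kw and kw["income_model"] is not None:
            kw["income_model"] = vep.IncomeModelSpec(**kw["income_model"])
        if "construct_spec" in kw and kw["construct_spec"] is not None:
            kw["construct_spec"] = pathmodel.ConstructSpec(
                constructs={
                    c: [tuple(i) for i in inds]
                    for c, inds in kw["construct_spec"].items()
                }
            )
        if "diagram" in kw and kw["diagram"] is not None:
            kw["diagram"] = pathmodel.PathDiagram(
                constructs=tuple(kw["diagram"]["constructs"]),
                edges=tuple(tuple(e) for e in kw["diagram"]["edges"]),
            )
        for key in ("quantile_covariates", "taus"):
            if key in kw and kw[key] is not None:
                kw[key] = tuple(kw[key])
        return cls(**kw)


def _stage_seed(master_seed: int, stage: str) -> int:
    import hashlib

    h = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {
            ("->".join(k) if isinstance(k, tuple) else str(k)): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every enabled stage and write artifacts under output_dir.

    Returns the machine-readable run report (also written as report.json).
    A stage failure raises StageError after writing a partial manifest.
    """
    import platform

    import scipy
    import statsmodels

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": {"master_seed": config.master_seed, "poverty_line": config.poverty_line,
                   "threshold": config.threshold, "taus": list(config.taus),
                   "bootstrap_reps": config.bootstrap_reps},
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "stages": {},
    }

    def fail(stage: str, exc: Exception):
        report["stages"][stage] = {"error": str(exc)}
        (out / "report.json").write_text(
            json.dumps(_jsonable(report), indent=2), encoding="utf-8"
        )
        raise StageError(stage, exc)

    # --- data stage -------------------------------------------------------
    try:
        if config.synthetic is not None:
            survey = synthetic.generate_survey(config.synthetic)
            table = survey.table
        else:
            table = read_survey(config.input_csv, config.schema)
        write_survey(table, out / "survey.csv")
        report["stages"]["data"] = {"n_households": len(table)}
    except StageError:
        raise
    except Exception as exc:
        fail("data", exc)

    # --- VEP-FGLS stage ---------------------------------------------------
    try:
        spec = config.income_model
        if spec is None and config.synthetic is not None:
            spec = vep.IncomeModelSpec(
                mean_covariates=config.synthetic.mean_covariates,
                variance_covariates=config.synthetic.variance_covariates,
            )
        if spec is None:
            raise ValueError("income_model must be provided for CSV input")
        fit = vep.fit_income_fgls(table, spec)
        mv = vep.predict_mean_variance(fit, table)
        v = vep.vulnerability_index(mv.mu, mv.sigma2, config.poverty_line)
        result = vep.classify_households(v, config.poverty_line, config.threshold)
        dist = vep.classify_and_summarize(v, config.threshold)
        table = table.assign(vulnerability=v, vulnerable=result.vulnerable.astype(int))
        table.to_csv(out / "vulnerability.csv", index=False, **_CSV_KW)
        report["stages"]["vep"] = {
            "beta_hat": fit.beta_hat,
            "theta_hat": fit.theta_hat,
            "floored_rows": len(fit.floored_rows),
            "distribution": {
                "bin_edges": dist.bin_edges,
                "counts": dist.counts,
                "percents": dist.percents,
                "bin_means": dist.bin_means,
                "bin_sds": dist.bin_sds,
                "headcount_ge_threshold": dist.headcount_ge_threshold,
                "headcount_percent": dist.headcount_percent,
            },
        }
        logger.info("vep: %d rows floored, headcount %.2f%%",
                    len(fit.floored_rows), dist.headcount_percent)
    except StageError:
        raise
    except Exception as exc:
        fail("vep", exc)

    # --- quantile stage ---------------------------------------------------
    if config.run_quantiles:
        try:
            xcols = config.quantile_covariates
            if xcols is None:
                xcols = tuple(
                    c for c in table.columns
                    if c not in ("income", "ln_income", "true_vulnerability",
                                 "vulnerability", "vulnerable")
                    and pd.api.types.is_numeric_dtype(table[c])
                    and table[c].nunique() > 1
                )
            X, names = quantiles.design(table, xcols)
            y = table["vulnerability"].to_numpy()
            seed_q = _stage_seed(config.master_seed, "quantiles")
            vif = quantiles.compute_vif(table.loc[:, list(xcols)])
            ols = quantiles.fit_ols(X, y, names=names)
            tests = quantiles.cross_quantile_tests(
                X, y, taus=config.taus, bootstrap_reps=config.bootstrap_reps,
                seed=seed_q, names=names,
            )
            qtable = pd.DataFrame(
                [
                    {
                        "variable": t.variable,
                        **{f"q{int(tau*100)}": c for tau, c in zip(t.taus, t.coefficients)},
                        "joint_stat": t.joint_stat,
                        "joint_pvalue": t.joint_pvalue,
                        "diff_25_50": t.diff_25_50,
                        "p_25_50": t.p_25_50,
                        "diff_50_75": t.diff_50_75,
                        "p_50_75": t.p_50_75,
                        "pattern": t.pattern,
                    }
                    for t in tests
                ]
            )
            qtable.to_csv(out / "cross_quantile_tests.csv", index=False, **_CSV_KW)
            stage: dict = {
                "vif": {"names": vif.names, "vif": vif.vif, "max_vif": vif.max_vif,
                        "collinear": vif.collinear},
                "ols": {"names": ols.names, "params": ols.params, "bse": ols.bse},
                "cross_quantile": qtable,
            }
            if config.group_column and config.group_column in table.columns:
                sub = quantiles.subgroup_equality(
                    table, config.group_column, "vulnerability", xcols,
                )
                stage["subgroup"] = {
                    "group_column": sub.group_column,
                    "n_per_group": sub.n_per_group,
                    "names": sub.names,
                    "equality_stat": sub.equality_stat,
                    "equality_pvalue": sub.equality_pvalue,
                }
                inter = quantiles.fit_interactions(
                    table, "vulnerability",
                    tuple(xcols) + (config.group_column,),
                    [(xcols[0], config.group_column)],
                )
                stage["interaction"] = {"names": inter.names, "params": inter.params,
                                        "bse": inter.bse, "pvalues": inter.pvalues}
            report["stages"]["quantiles"] = stage
        except StageError:
            raise
        except Exception as exc:
            fail("quantiles", exc)

    # --- path stage -------------------------------------------------------
    if config.run_paths:
        try:
            cspec = config.construct_spec or pathmodel.default_construct_spec()
            diagram = config.diagram or pathmodel.default_diagram()
            comp = pathmodel.build_composites(table, cspec)
            if "vulnerability" in diagram.constructs:
                vv = table["vulnerability"].to_numpy(dtype=float)
                comp["vulnerability"] = (vv - vv.mean()) / vv.std(ddof=1)
            pfit = pathmodel.fit_path_model(
                comp, diagram,
                bootstrap_reps=config.bootstrap_reps,
                seed=_stage_seed(config.master_seed, "paths"),
            )
            effects = pathmodel.decompose_effects(pfit)
            sigma = pathmodel.implied_covariance(pfit)
            indices = pathmodel.fit_indices(
                pfit.sample_cov, sigma,
                df_model=pathmodel.model_degrees_of_freedom(diagram),
                n=pfit.n,
            )
            effects.table.to_csv(out / "effects.csv", index=False, **_CSV_KW)
            report["stages"]["paths"] = {
                "coefficients": pfit.coefficients,
                "se": pfit.se,
                "critical_ratio": pfit.critical_ratio,
                "pvalues": pfit.pvalues,
                "stars": pathmodel.significance_report(pfit),
                "effects": effects.table,
                "fit_indices": {
                    k: getattr(indices, k)
                    for k in ("chi_square", "df", "GFI", "AGFI", "PGFI",
                              "IFI", "CFI", "SRMR", "RMSEA")
                },
            }
        except StageError:
            raise
        except Exception as exc:
            fail("paths", exc)

    (out / "report.json").write_text(
        json.dumps(_jsonable(report), indent=2, sort_keys=True), encoding="utf-8"
    )
    return report
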