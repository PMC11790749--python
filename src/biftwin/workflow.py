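"""End-to-end orchestration: covariate residualization, one-twin selection,
listwise deletion, and the full analysis pipeline producing report files
shaped like the published tables (loadings/indices, fit comparison, effect
estimates, per-source indices)."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import COVARIATE_NAMES, BifactorStructure, TwinPairDataset, validate_dataset
from .fit_eval import fit_statistics, lrt, twin_bifactor_indices
from .psychometrics import fit_dsl_bifactor, general_factor_indices, loading_summary
from .twin_sem import (
    ModelSpec,
    aggregate_standardized_effects,
    fit_independence,
    fit_model,
    fit_saturated,
)

__all__ = [
    "RunConfig",
    "residualize",
    "select_one_per_pair",
    "listwise_delete",
    "run_pipeline",
]

log = logging.getLogger("biftwin")

_COMPONENT_SETS = {"ace": frozenset("ACE"), "ae": frozenset("AE"),
                   "ce": frozenset("CE"), "e": frozenset("E")}


@dataclass
class RunConfig:
    input_path: str
    seed: int
    out_dir: str = "reports"
    covariates: tuple[str, ...] = COVARIATE_NAMES
    analyses: tuple[str, ...] = ("psychometrics", "cp", "ip", "comparison", "indices")
    components: tuple[str, ...] = ("ace", "ae", "ce", "e")
    bootstrap_B: int = 0
    n_starts: int = 3
    unique_ace: bool = True

    def __post_init__(self) -> None:
        if not self.analyses:
            raise ValueError("analysis list must be non-empty")
        unknown = set(self.analyses) - {"psychometrics", "cp", "ip", "comparison", "indices"}
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def residualize(data: TwinPairDataset,
                covariates: tuple[str, ...] = COVARIATE_NAMES) -> TwinPairDataset:
    """Replace item scores by OLS residuals on the covariates.

    Regressions are fit per item at the individual level, pooling both
    co-twins (non-independence only affects standard errors, which are not
    used).  Cohort enters as categorical dummies, age and sex as-is.
    Missing items stay missing; constant covariates are dropped with a
    warning.
    """
    n_pairs, _, n_items = data.items.shape
    X_items = data.items.reshape(2 * n_pairs, n_items)
    covs = data.covariates.reshape(2 * n_pairs, len(COVARIATE_NAMES))
    cols = [np.ones(2 * n_pairs)]
    for name in covariates:
        k = COVARIATE_NAMES.index(name)
        v = covs[:, k]
        finite = v[np.isfinite(v)]
        if finite.size and np.all(finite == finite[0]):
            log.warning("covariate %r is constant; dropped", name)
            continue
        if name == "cohort":
            vals = np.unique(finite)
            for lev in vals[1:]:
                cols.append((v == lev).astype(float))
        else:
            cols.append(v)
    D = np.column_stack(cols)
    resid = X_items.copy()
    for j in range(n_items):
        y = X_items[:, j]
        ok = np.isfinite(y) & np.isfinite(D).all(axis=1)
        if ok.sum() <= D.shape[1]:
            continue
        beta, *_ = np.linalg.lstsq(D[ok], y[ok], rcond=None)
        resid[ok, j] = y[ok] - D[ok] @ beta
    out = TwinPairDataset(
        pair_ids=data.pair_ids.copy(),
        zygosity=data.zygosity.copy(),
        items=resid.reshape(n_pairs, 2, n_items),
        covariates=data.covariates.copy(),
    )
    return out


def select_one_per_pair(data: TwinPairDataset, seed: int) -> pd.DataFrame:
    """One randomly selected co-twin per pair (seeded fair coin).

    Returns an individual-level table with pair id, selected member (1/2),
    covariates and item scores.
    """
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, 2, size=data.n_pairs)
    rows = data.items[np.arange(data.n_pairs), pick]
    covs = data.covariates[np.arange(data.n_pairs), pick]
    df = pd.DataFrame(rows, columns=[f"i{i + 1:02d}" for i in range(data.n_items)])
    df.insert(0, "pair_id", data.pair_ids)
    df.insert(1, "member", pick + 1)
    for k, name in enumerate(COVARIATE_NAMES):
        df.insert(2 + k, name, covs[:, k])
    return df


def listwise_delete(table: pd.DataFrame) -> pd.DataFrame:
    """Drop rows with any missing item score; logs the retained fraction."""
    item_cols = [c for c in table.columns if c.startswith("i") and c[1:].isdigit()]
    kept = table.dropna(subset=item_cols)
    if len(kept) == 0:
        raise ValueError("listwise deletion removed every row")
    log.info("listwise deletion retained %d/%d rows (%.1f%%)",
             len(kept), len(table), 100.0 * len(kept) / len(table))
    return kept.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _provenance(config: RunConfig) -> dict:
    h = hashlib.sha256(Path(config.input_path).read_bytes()).hexdigest()
    return {"input": config.input_path, "input_sha256": h,
            "seed": config.seed, "version": __version__,
            "config": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in vars(config).items()}}


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_psychometrics(data: TwinPairDataset, structure: BifactorStructure,
                      seed: int) -> dict:
    """Psychometric branch: select one twin, listwise delete, estimate the
    bifactor pattern and its general-factor indices."""
    table = listwise_delete(select_one_per_pair(data, seed))
    item_cols = [f"i{i + 1:02d}" for i in range(structure.n_items)]
    X = table[item_cols].to_numpy(dtype=float)
    R = np.corrcoef(X, rowvar=False)
    L = fit_dsl_bifactor(R, structure)
    report = general_factor_indices(L, label="phenotypic general factor")
    summary = loading_summary(L)
    return {
        "n_individuals": len(table),
        "loadings": {
            "items": list(structure.item_labels),
            "columns": ["general", *structure.group_names],
            "dense": L.dense,
            "values": L.values,
        },
        "indices": report.to_dict(),
        "summary": summary,
    }


def run_pipeline(config: RunConfig, structure: BifactorStructure) -> dict:
    """Execute the configured analyses and write JSON + TSV reports.

    Returns a dict of report payloads keyed by report name; files are
    written under ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = TwinPairDataset.from_csv(config.input_path)
    problems = validate_dataset(data, structure)
    if problems:
        raise ValueError("invalid dataset: " + "; ".join(problems[:5]))
    prov = _provenance(config)
    reports: dict[str, dict] = {}

    log.info("residualizing covariates %s", config.covariates)
    resid = residualize(data, config.covariates)

    if "psychometrics" in config.analyses:
        log.info("psychometric branch")
        rep = run_psychometrics(resid, structure, config.seed)
        rep["provenance"] = prov
        reports["psychometrics"] = rep
        _write_json(out_dir / "psychometrics.json", rep)
        pd.DataFrame(np.asarray(rep["loadings"]["dense"]),
                     index=rep["loadings"]["items"],
                     columns=rep["loadings"]["columns"]).to_csv(
            out_dir / "loadings.tsv", sep="\t")

    fits: dict[str, dict] = {}
    saturated = independence = None
    families = [f for f in ("cp", "ip") if f in config.analyses]
    if families or "comparison" in config.analyses:
        saturated = fit_saturated(resid)
        independence = fit_independence(resid)
    for family in families:
        for comp in config.components:
            spec = ModelSpec(family=family.upper(),
                             components=_COMPONENT_SETS[comp],
                             structure=structure, unique_ace=config.unique_ace)
            log.info("fitting %s %s", family.upper(), comp.upper())
            fit = fit_model(resid, spec, n_starts=config.n_starts, seed=config.seed)
            stats = fit_statistics(fit, saturated, independence)
            fits[f"{family}_{comp}"] = {"fit": fit, "stats": stats}

    if fits:
        rep = {"provenance": prov, "models": {}}
        for name, d in fits.items():
            fam = name.split("_")[0]
            full = fits.get(f"{fam}_ace")
            entry = {"stats": d["stats"].to_dict(),
                     "converged": d["fit"].converged,
                     "aggregated_effects": aggregate_standardized_effects(d["fit"])}
            if full is not None and full is not d:
                entry["lrt_vs_ace"] = lrt(full["fit"], d["fit"]).to_dict()
            rep["models"][name] = entry
        reports["comparison"] = rep
        _write_json(out_dir / "comparison.json", rep)
        rows = []
        for name, entry in rep["models"].items():
            st = entry["stats"]
            rows.append({"model": name, "rmsea": st["rmsea"], "cfi": st["cfi"],
                         "minus2LL": st["minus2LL"], "aic": st["aic"],
                         "bic": st["bic"],
                         "lrt_p": entry.get("lrt_vs_ace", {}).get("p_value")})
        pd.DataFrame(rows).to_csv(out_dir / "comparison.tsv", sep="\t", index=False)

    if "indices" in config.analyses and "ip_ace" in fits:
        per_source = twin_bifactor_indices(fits["ip_ace"]["fit"])
        rep = {"provenance": prov,
               "sources": {c: r.to_dict() for c, r in per_source.items()}}
        reports["indices"] = rep
        _write_json(out_dir / "indices.json", rep)

    if config.bootstrap_B >= 2 and "ip_ace" in fits:
        from .fit_eval import bootstrap_ci

        def source_totals(fit):
            means = fit.standardized.mean(axis=0)
            return {f"{src}_total": float(means[src].sum())
                    for src in ("A", "C", "E")}

        log.info("bootstrapping IP ACE source totals, B=%d", config.bootstrap_B)
        boot = bootstrap_ci(
            resid, fits["ip_ace"]["fit"].spec, B=config.bootstrap_B,
            seed=config.seed, statistic=source_totals,
            point_fit=fits["ip_ace"]["fit"])
        rep = {"provenance": prov, "point": boot["point"],
               "intervals": boot["intervals"], "B": boot["B"],
               "n_failed": boot["n_failed"], "flagged": boot["flagged"]}
        reports["bootstrap"] = rep
        _write_json(out_dir / "bootstrap.json", rep)

    return reports
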