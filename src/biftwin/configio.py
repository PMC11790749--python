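"""YAML/JSON configuration and result (de)serialization.

Builds structures and parameter sets from plain dict specs (scalars are
broadcast over items/factors), and round-trips fitted results through JSON
so the CLI verbs can be chained.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .core import BifactorStructure, CPParameterSet, IPParameterSet, LoadingMatrix
from .datasets import conners_structure
from .simulate import SimulationConfig
from .twin_sem import FitResult, ModelSpec
from .workflow import RunConfig

__all__ = [
    "structure_from_dict",
    "params_from_dict",
    "simconfig_from_yaml",
    "runconfig_from_yaml",
    "fit_result_to_dict",
    "fit_result_from_dict",
]


def structure_from_dict(d: dict | None) -> BifactorStructure:
    """Structure from ``{"groups": {name: n_items, ...}}``; default is the
    packaged 20-item two-group layout."""
    if not d:
        return conners_structure()
    groups = d["groups"]
    names = tuple(groups)
    group_of: list[int] = []
    for g, count in enumerate(groups.values()):
        group_of.extend([g] * int(count))
    return BifactorStructure(group_of=tuple(group_of), group_names=names,
                             item_labels=tuple(d.get("item_labels", ())))


def _broadcast(value, n: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"expected scalar or length-{n} list, got shape {arr.shape}")
    return arr


def _loading_matrix(spec, structure: BifactorStructure) -> LoadingMatrix:
    n = structure.n_items
    if isinstance(spec, dict) and "general" in spec:
        gen = _broadcast(spec["general"], n)
        grp = _broadcast(spec.get("group", 0.0), n)
        lam = np.zeros((n, structure.n_factors))
        lam[:, 0] = gen
        lam[np.arange(n), 1 + np.asarray(structure.group_of)] = grp
        return LoadingMatrix(lam, structure)
    return LoadingMatrix(np.asarray(spec, dtype=float), structure)


def _triples(spec, n_rows: int, normalize: bool) -> np.ndarray:
    arr = np.asarray(spec, dtype=float)
    if arr.ndim == 1:
        if arr.shape != (3,):
            raise ValueError("ACE path spec must be a triple [a, c, e]")
        arr = np.tile(arr, (n_rows, 1))
    if arr.shape != (n_rows, 3):
        raise ValueError(f"expected {n_rows} x 3 path matrix")
    if normalize:
        norms = np.sqrt((arr**2).sum(axis=1))
        arr = arr / norms[:, None]
    return arr


def params_from_dict(d: dict, structure: BifactorStructure | None = None):
    """Build a CP or IP parameter set from a plain dict.

    CP: ``{"family": "cp", "loadings": {...}, "factor_ace": [a, c, e],
    "unique_ace": [a, c, e]}`` — factor triples are normalized to unit
    factor variance.  IP: ``{"family": "ip", "loadings": {"A": {...},
    "C": {...}, "E": {...}}, "unique_ace": [...]}``.  Loading specs are
    either ``{"general": x, "group": y}`` shorthands or full matrices.
    """
    structure = structure or structure_from_dict(d.get("structure"))
    family = d["family"].lower()
    if family == "cp":
        return CPParameterSet(
            lambda_p=_loading_matrix(d["loadings"], structure),
            factor_paths=_triples(d["factor_ace"], structure.n_factors, normalize=True),
            unique_paths=_triples(d["unique_ace"], structure.n_items, normalize=False),
        )
    if family == "ip":
        zero = np.zeros((structure.n_items, structure.n_factors))
        mats = {}
        for c in ("A", "C", "E"):
            spec = d["loadings"].get(c)
            mats[c] = (_loading_matrix(spec, structure) if spec is not None
                       else LoadingMatrix(zero, structure))
        return IPParameterSet(
            lambda_A=mats["A"], lambda_C=mats["C"], lambda_E=mats["E"],
            unique_paths=_triples(d["unique_ace"], structure.n_items, normalize=False),
        )
    raise ValueError(f"unknown family {family!r}")


def simconfig_from_yaml(path: str | Path) -> tuple[SimulationConfig, BifactorStructure]:
    d = yaml.safe_load(Path(path).read_text())
    structure = structure_from_dict(d.get("structure"))
    params = params_from_dict(d["params"], structure)
    cfg = SimulationConfig(
        n_MZ=int(d["n_MZ"]),
        n_DZ=int(d["n_DZ"]),
        params=params,
        missing_rate=float(d.get("missing_rate", 0.0)),
        mask_whole_twin=bool(d.get("mask_whole_twin", False)),
        ordinalize=bool(d.get("ordinalize", False)),
        thresholds=tuple(d["thresholds"]) if d.get("thresholds") else None,
        seed=int(d.get("seed", 0)),
    )
    return cfg, structure


def runconfig_from_yaml(path: str | Path) -> tuple[RunConfig, BifactorStructure]:
    d = yaml.safe_load(Path(path).read_text())
    structure = structure_from_dict(d.pop("structure", None))
    cfg = RunConfig(
        input_path=d["input"],
        seed=int(d["seed"]),
        out_dir=d.get("out_dir", "reports"),
        covariates=tuple(d.get("covariates", ("age", "sex", "cohort"))),
        analyses=tuple(d.get("analyses", ("psychometrics", "cp", "ip",
                                          "comparison", "indices"))),
        components=tuple(d.get("components", ("ace", "ae", "ce", "e"))),
        bootstrap_B=int(d.get("bootstrap_B", 0)),
        n_starts=int(d.get("n_starts", 3)),
        unique_ace=bool(d.get("unique_ace", True)),
    )
    return cfg, structure


# ---------------------------------------------------------------------------
# FitResult round-trip
# ---------------------------------------------------------------------------

def fit_result_to_dict(fit: FitResult, stats=None) -> dict:
    spec = fit.spec
    out = {
        "family": spec.family if spec else None,
        "components": sorted(spec.components) if spec else None,
        "unique_ace": spec.unique_ace if spec else None,
        "structure": {
            "group_of": list(spec.structure.group_of),
            "group_names": list(spec.structure.group_names),
            "item_labels": list(spec.structure.item_labels),
        } if spec else None,
        "minus2LL": fit.minus2LL,
        "n_free_params": fit.n_free_params,
        "n_pairs_used": fit.n_pairs_used,
        "converged": fit.converged,
        "optimizer_status": fit.optimizer_status,
    }
    p = fit.params
    if isinstance(p, CPParameterSet):
        out["params"] = {"lambda_p": p.lambda_p.values.tolist(),
                         "factor_paths": p.factor_paths.tolist(),
                         "unique_paths": p.unique_paths.tolist()}
    elif isinstance(p, IPParameterSet):
        out["params"] = {"lambda_A": p.lambda_A.values.tolist(),
                         "lambda_C": p.lambda_C.values.tolist(),
                         "lambda_E": p.lambda_E.values.tolist(),
                         "unique_paths": p.unique_paths.tolist()}
    if fit.standardized is not None:
        out["standardized"] = {
            "columns": [list(c) for c in fit.standardized.columns],
            "items": list(fit.standardized.index),
            "values": fit.standardized.to_numpy().tolist(),
        }
    if stats is not None:
        out["stats"] = stats.to_dict()
    return out


def fit_result_from_dict(d: dict) -> FitResult:
    import pandas as pd

    sd = d["structure"]
    structure = BifactorStructure(group_of=tuple(sd["group_of"]),
                                 group_names=tuple(sd["group_names"]),
                                 item_labels=tuple(sd["item_labels"]))
    spec = ModelSpec(family=d["family"], components=frozenset(d["components"]),
                     structure=structure, unique_ace=bool(d["unique_ace"]))
    pd_ = d["params"]
    if spec.family == "CP":
        params = CPParameterSet(
            lambda_p=LoadingMatrix(np.asarray(pd_["lambda_p"]), structure),
            factor_paths=np.asarray(pd_["factor_paths"]),
            unique_paths=np.asarray(pd_["unique_paths"]),
        )
    else:
        params = IPParameterSet(
            lambda_A=LoadingMatrix(np.asarray(pd_["lambda_A"]), structure),
            lambda_C=LoadingMatrix(np.asarray(pd_["lambda_C"]), structure),
            lambda_E=LoadingMatrix(np.asarray(pd_["lambda_E"]), structure),
            unique_paths=np.asarray(pd_["unique_paths"]),
        )
    std = None
    if "standardized" in d:
        s = d["standardized"]
        std = pd.DataFrame(
            np.asarray(s["values"]),
            index=pd.Index(s["items"], name="item"),
            columns=pd.MultiIndex.from_tuples([tuple(c) for c in s["columns"]],
                                              names=["source", "level"]),
        )
    return FitResult(spec=spec, params=params, minus2LL=float(d["minus2LL"]),
                     n_free_params=int(d["n_free_params"]),
                     n_pairs_used=int(d["n_pairs_used"]),
                     converged=bool(d["converged"]), _standardized=std,
                     optimizer_status=d.get("optimizer_status", ""))


def load_fit_json(path: str | Path) -> tuple[FitResult, dict | None]:
    d = json.loads(Path(path).read_text())
    return fit_result_from_dict(d), d.get("stats")
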