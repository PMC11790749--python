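"""Packaged reference data: the published 20-item bifactor loading pattern
for the Conners-style scale and the published ACE effect estimates."""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .core import BifactorStructure, LoadingMatrix

__all__ = [
    "conners_structure",
    "load_published_loadings",
    "load_published_cp_estimates",
    "load_published_ip_estimates",
]


def _data_path(name: str):
    return resources.files("biftwin.data").joinpath(name)


def conners_structure() -> BifactorStructure:
    """Default 20-item structure: 11 inattention + 9 hyperactivity items."""
    df = pd.read_csv(_data_path("conners_bifactor_loadings.csv"))
    group_names = ("inattention", "hyperactivity")
    group_of = tuple(group_names.index(s) for s in df["subscale"])
    return BifactorStructure(
        group_of=group_of,
        group_names=group_names,
        item_labels=tuple(df["label"]),
    )


def load_published_loadings() -> LoadingMatrix:
    """Published standardized bifactor loadings of the 20-item scale.

    The dense pattern (including small cross-loadings) is retained on the
    ``dense`` attribute; ``values`` has the structural zeros imposed.
    """
    df = pd.read_csv(_data_path("conners_bifactor_loadings.csv"))
    dense = df[["general", "inattention", "hyperactivity"]].to_numpy(dtype=float)
    return LoadingMatrix.from_dense(dense, conners_structure())


def load_published_cp_estimates() -> pd.DataFrame:
    """Standardized factor-level ACE estimates of the common pathway model.

    Rows: general, inattention, hyperactivity.  The C column is empty (the
    best-fitting model dropped shared-environment effects).
    """
    return pd.read_csv(_data_path("published_cp_estimates.csv"), index_col="factor")


def load_published_ip_estimates() -> pd.DataFrame:
    """Mean squared standardized effects from the independent pathway model.

    Rows: general, inattention, hyperactivity, unique; columns A, C, E.
    """
    return pd.read_csv(_data_path("published_ip_estimates.csv"), index_col="level")
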