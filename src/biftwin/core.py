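"""Core domain types for bifactor twin modeling.

Defines the bifactor item/group structure, the twin-pair dataset with its
wide-CSV dialect, loading matrices with structural zeros, and the parameter
sets of the two twin-model families (common pathway and independent
pathway).  Missing item scores are represented internally as NaN and as
empty cells in CSV files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BifactorStructure",
    "TwinPairDataset",
    "LoadingMatrix",
    "CPParameterSet",
    "IPParameterSet",
    "ExpectedCovariances",
    "validate_dataset",
]

ZYGOSITIES = ("MZ", "DZ")
COVARIATE_NAMES = ("age", "sex", "cohort")


# ---------------------------------------------------------------------------
# Bifactor structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BifactorStructure:
    """Item-to-group assignment defining a general + group factor pattern.

    Parameters
    ----------
    group_of
        For each of the ``n_items`` items, the 0-based index of the group
        factor the item belongs to.  Groups must be contiguous integers
        ``0..m-1`` and every group needs at least two items.
    group_names
        Labels for the ``m`` group factors.
    item_labels
        Optional labels for the items (defaults to ``item01..itemNN``).
    """

    group_of: tuple[int, ...]
    group_names: tuple[str, ...]
    item_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        n = len(self.group_of)
        m = len(self.group_names)
        if n == 0 or m == 0:
            raise ValueError("structure needs at least one item and one group")
        counts = np.bincount(np.asarray(self.group_of, dtype=int), minlength=m)
        if len(counts) > m:
            raise ValueError("group_of refers to a group index >= number of groups")
        if (counts < 2).any():
            bad = [self.group_names[g] for g in np.where(counts < 2)[0]]
            raise ValueError(f"every group needs >= 2 items; too small: {bad}")
        if not self.item_labels:
            labels = tuple(f"item{i + 1:02d}" for i in range(n))
            object.__setattr__(self, "item_labels", labels)
        elif len(self.item_labels) != n:
            raise ValueError("item_labels length must equal number of items")

    @property
    def n_items(self) -> int:
        return len(self.group_of)

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    @property
    def n_factors(self) -> int:
        """General factor plus group factors."""
        return 1 + self.n_groups

    def items_in_group(self, g: int) -> np.ndarray:
        return np.where(np.asarray(self.group_of) == g)[0]

    def loading_mask(self) -> np.ndarray:
        """Boolean n_items x (1 + m) mask of permitted loadings.

        Column 0 (general) is free for every item; column g+1 is free only
        for items assigned to group g.
        """
        mask = np.zeros((self.n_items, self.n_factors), dtype=bool)
        mask[:, 0] = True
        for i, g in enumerate(self.group_of):
            mask[i, g + 1] = True
        return mask


# ---------------------------------------------------------------------------
# Twin-pair dataset
# ---------------------------------------------------------------------------

@dataclass
class TwinPairDataset:
    """MZ/DZ twin pairs with per-twin item responses and covariates.

    Attributes
    ----------
    pair_ids
        Length ``n_pairs`` identifiers, unique.
    zygosity
        Length ``n_pairs`` array of ``"MZ"``/``"DZ"`` codes.
    items
        Array of shape ``(n_pairs, 2, n_items)``; NaN marks a missing score.
    covariates
        Array of shape ``(n_pairs, 2, 3)`` holding age, sex, cohort per twin;
        NaN marks a missing covariate.
    """

    pair_ids: np.ndarray
    zygosity: np.ndarray
    items: np.ndarray
    covariates: np.ndarray

    def __post_init__(self) -> None:
        self.pair_ids = np.asarray(self.pair_ids)
        self.zygosity = np.asarray(self.zygosity, dtype=object)
        self.items = np.asarray(self.items, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.items.ndim != 3 or self.items.shape[1] != 2:
            raise ValueError("items must have shape (n_pairs, 2, n_items)")
        if self.covariates.shape[:2] != self.items.shape[:2]:
            raise ValueError("covariates must align with items on (n_pairs, 2)")

    @property
    def n_pairs(self) -> int:
        return self.items.shape[0]

    @property
    def n_items(self) -> int:
        return self.items.shape[2]

    def zygosity_mask(self, zyg: str) -> np.ndarray:
        return np.asarray([z == zyg for z in self.zygosity])

    def subset(self, index: np.ndarray | Sequence[int]) -> "TwinPairDataset":
        idx = np.asarray(index)
        return TwinPairDataset(
            pair_ids=self.pair_ids[idx],
            zygosity=self.zygosity[idx],
            items=self.items[idx],
            covariates=self.covariates[idx],
        )

    def pair_vectors(self) -> np.ndarray:
        """Stacked per-pair vectors ``[twin1 items | twin2 items]`` (n_pairs, 2n)."""
        return self.items.reshape(self.n_pairs, 2 * self.n_items)

    # -- CSV dialect --------------------------------------------------------
    # Wide format, one row per pair:
    #   pair_id, zygosity, age1, sex1, cohort1, age2, sex2, cohort2,
    #   i01_t1..iNN_t1, i01_t2..iNN_t2
    def to_frame(self) -> pd.DataFrame:
        n = self.n_items
        cols: dict[str, object] = {
            "pair_id": self.pair_ids,
            "zygosity": self.zygosity,
        }
        for t in (0, 1):
            for k, name in enumerate(COVARIATE_NAMES):
                cols[f"{name}{t + 1}"] = self.covariates[:, t, k]
        for t in (0, 1):
            for i in range(n):
                cols[f"i{i + 1:02d}_t{t + 1}"] = self.items[:, t, i]
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TwinPairDataset":
        item_cols_t1 = sorted(c for c in df.columns if c.startswith("i") and c.endswith("_t1"))
        n = len(item_cols_t1)
        items = np.full((len(df), 2, n), np.nan)
        covs = np.full((len(df), 2, len(COVARIATE_NAMES)), np.nan)
        for t in (0, 1):
            for i in range(n):
                items[:, t, i] = pd.to_numeric(df[f"i{i + 1:02d}_t{t + 1}"], errors="coerce")
            for k, name in enumerate(COVARIATE_NAMES):
                col = f"{name}{t + 1}"
                if col in df.columns:
                    covs[:, t, k] = pd.to_numeric(df[col], errors="coerce")
        return cls(
            pair_ids=df["pair_id"].to_numpy(),
            zygosity=df["zygosity"].to_numpy(dtype=object),
            items=items,
            covariates=covs,
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "TwinPairDataset":
        return cls.from_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Loading matrices and parameter sets
# ---------------------------------------------------------------------------

@dataclass
class LoadingMatrix:
    """n_items x (1 + m) loading matrix with structural zeros.

    Column 0 loads the general factor; column ``g + 1`` the group factor
    ``g``.  Entries outside the permitted pattern must be exactly zero.  A
    pre-zeroing dense variant (e.g. the full estimated pattern including
    cross-loadings) may be attached as ``dense``.
    """

    values: np.ndarray
    structure: BifactorStructure
    dense: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        s = self.structure
        if self.values.shape != (s.n_items, s.n_factors):
            raise ValueError(
                f"loading matrix must be {s.n_items} x {s.n_factors}, "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("loadings must be finite")
        mask = s.loading_mask()
        if np.any(self.values[~mask] != 0.0):
            raise ValueError("structural zeros violated outside the bifactor pattern")
        if self.dense is not None:
            self.dense = np.asarray(self.dense, dtype=float)
            if self.dense.shape != self.values.shape:
                raise ValueError("dense variant must match loading matrix shape")

    @classmethod
    def from_dense(cls, dense: np.ndarray, structure: BifactorStructure) -> "LoadingMatrix":
        """Impose structural zeros on a dense pattern, keeping the original."""
        dense = np.asarray(dense, dtype=float)
        values = np.where(structure.loading_mask(), dense, 0.0)
        return cls(values=values, structure=structure, dense=dense)

    @property
    def general(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def groups(self) -> np.ndarray:
        return self.values[:, 1:]


def _check_paths(arr: np.ndarray, shape: tuple[int, ...], what: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.shape != shape:
        raise ValueError(f"{what} must have shape {shape}, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{what} must be finite")
    return arr


@dataclass
class CPParameterSet:
    """Common pathway parameters: phenotypic loadings plus ACE paths.

    ``factor_paths[f] = (a, c, e)`` decomposes latent factor ``f`` (general
    first, then groups) and must satisfy ``a^2 + c^2 + e^2 = 1`` so every
    factor has unit variance.  ``unique_paths[i] = (a_u, c_u, e_u)`` are the
    item-level residual paths.
    """

    lambda_p: LoadingMatrix
    factor_paths: np.ndarray
    unique_paths: np.ndarray

    def __post_init__(self) -> None:
        s = self.structure
        self.factor_paths = _check_paths(self.factor_paths, (s.n_factors, 3), "factor_paths")
        self.unique_paths = _check_paths(self.unique_paths, (s.n_items, 3), "unique_paths")

    @property
    def structure(self) -> BifactorStructure:
        return self.lambda_p.structure

    def check_standardized(self, tol: float = 1e-6) -> None:
        ss = (self.factor_paths**2).sum(axis=1)
        if np.any(np.abs(ss - 1.0) > tol):
            raise ValueError(f"factor a^2+c^2+e^2 must be 1, got {ss}")


@dataclass
class IPParameterSet:
    """Independent pathway parameters: one loading matrix per variance source."""

    lambda_A: LoadingMatrix
    lambda_C: LoadingMatrix
    lambda_E: LoadingMatrix
    unique_paths: np.ndarray

    def __post_init__(self) -> None:
        s = self.structure
        for lm in (self.lambda_C, self.lambda_E):
            if lm.structure is not s and lm.structure != s:
                raise ValueError("all three loading matrices must share one structure")
        self.unique_paths = _check_paths(self.unique_paths, (s.n_items, 3), "unique_paths")

    @property
    def structure(self) -> BifactorStructure:
        return self.lambda_A.structure

    def source(self, which: str) -> LoadingMatrix:
        return {"A": self.lambda_A, "C": self.lambda_C, "E": self.lambda_E}[which]


@dataclass
class ExpectedCovariances:
    """Model-implied per-zygosity covariance matrices, twin1 block first."""

    sigma_MZ: np.ndarray
    sigma_DZ: np.ndarray

    def __post_init__(self) -> None:
        for name in ("sigma_MZ", "sigma_DZ"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] % 2:
                raise ValueError(f"{name} must be square 2n x 2n")
            setattr(self, name, m)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_dataset(data: TwinPairDataset, structure: BifactorStructure,
                     raw_scores: bool = True) -> list[str]:
    """Report structural violations of a dataset against a bifactor structure.

    Returns a list of human-readable violations; the list is empty iff the
    dataset is valid.  With ``raw_scores=True``, present item values must lie
    in {0, 1, 2, 3}; residualized data should be checked with
    ``raw_scores=False``.
    """
    report: list[str] = []
    ids, counts = np.unique(data.pair_ids, return_counts=True)
    for pid in ids[counts > 1]:
        report.append(f"duplicate pair_id: {pid!r}")
    for pid, z in zip(data.pair_ids, data.zygosity):
        if z not in ZYGOSITIES:
            report.append(f"pair {pid!r}: invalid zygosity code {z!r}")
    if data.n_items != structure.n_items:
        report.append(
            f"item vectors have length {data.n_items}, structure expects "
            f"{structure.n_items}"
        )
    if raw_scores:
        vals = data.items
        bad = np.isfinite(vals) & ~np.isin(vals, (0.0, 1.0, 2.0, 3.0))
        for p in np.unique(np.where(bad)[0]):
            report.append(f"pair {data.pair_ids[p]!r}: raw item score outside 0-3")
    return report
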