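"""Phenotypic bifactor workflow.

Direct Schmid-Leiman estimation of a general + group loading pattern from a
correlation matrix, the general-factor reliability indices (omega
hierarchical, H-index, explained common variance), loading-adequacy
summaries, and scale-level reliability (alpha / omega total).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._factor import (
    extract_paf,
    one_factor_loadings,
    procrustes_rotate,
    rotate_quartimin,
    rotate_to_pattern,
)
from .core import BifactorStructure, LoadingMatrix

__all__ = [
    "IndexReport",
    "fit_dsl_bifactor",
    "omega_hierarchical",
    "h_index",
    "ecv",
    "general_factor_indices",
    "loading_summary",
    "scale_reliability",
]

OMEGA_H_CUTOFF = 0.5
H_CUTOFF = 0.7


@dataclass
class IndexReport:
    """General-factor reliability indices with the conventional cutoffs."""

    omega_h: float
    h_index: float
    ecv: float
    label: str = ""
    omega_h_cutoff: float = OMEGA_H_CUTOFF
    h_cutoff: float = H_CUTOFF
    omega_h_pass: bool = field(init=False)
    h_pass: bool = field(init=False)

    def __post_init__(self) -> None:
        for name in ("omega_h", "h_index", "ecv"):
            v = getattr(self, name)
            if not (-1e-9 <= v <= 1.0 + 1e-9):
                raise ValueError(f"{name} = {v} outside [0, 1]")
        self.omega_h_pass = self.omega_h > self.omega_h_cutoff
        self.h_pass = self.h_index > self.h_cutoff

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "omega_h": self.omega_h,
            "h_index": self.h_index,
            "ecv": self.ecv,
            "omega_h_cutoff": self.omega_h_cutoff,
            "h_cutoff": self.h_cutoff,
            "omega_h_pass": self.omega_h_pass,
            "h_pass": self.h_pass,
        }


def _as_loading_array(L) -> np.ndarray:
    """Dense pattern if available, else the structural-zero values."""
    if isinstance(L, LoadingMatrix):
        return L.dense if L.dense is not None else L.values
    return np.asarray(L, dtype=float)


# ---------------------------------------------------------------------------
# Direct Schmid-Leiman
# ---------------------------------------------------------------------------

def _anchored_factors(R: np.ndarray, h2: np.ndarray, k: int) -> np.ndarray:
    """k principal factors with the communalities fixed at ``h2``."""
    Rr = R.copy()
    np.fill_diagonal(Rr, np.clip(h2, 0.0, 0.98))
    vals, vecs = np.linalg.eigh(Rr)
    order = np.argsort(vals)[::-1][:k]
    return vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))


def _target_rotated_factors(R: np.ndarray, target: np.ndarray,
                            k: int) -> np.ndarray:
    """Extract k factors anchored at the target's communalities, then
    procrustes-rotate them onto the target."""
    L = _anchored_factors(R, (target**2).sum(axis=1), k)
    return procrustes_rotate(L, target)


def _pattern_refine(R: np.ndarray, L: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """One re-anchored pass of partially specified target rotation."""
    from scipy.linalg import orthogonal_procrustes

    A = _anchored_factors(R, (L**2).sum(axis=1), L.shape[1])
    T0, _ = orthogonal_procrustes(A, np.where(mask, L, 0.0))
    return rotate_to_pattern(A, mask, T0=T0)


def fit_dsl_bifactor(R: np.ndarray, structure: BifactorStructure) -> LoadingMatrix:
    """Estimate an orthogonal bifactor pattern by Direct Schmid-Leiman.

    Route: (i) extract ``m`` factors and rotate obliquely (quartimin) to get
    pattern ``P`` and factor correlation ``Phi``; (ii) one-factor solution
    on ``Phi`` gives second-order loadings ``gamma``; (iii) build the classic
    Schmid-Leiman target ``[P gamma, P diag(sqrt(1 - gamma^2))]``; (iv)
    extract ``m + 1`` unrotated factors and procrustes-rotate them onto the
    target.  Columns are sign-flipped to nonnegative sums; the returned
    matrix has structural zeros imposed with the dense pattern attached.

    Raises
    ------
    ValueError
        If ``R`` is not a valid correlation matrix (symmetric, unit
        diagonal, positive semi-definite).
    """
    R = np.asarray(R, dtype=float)
    n, m = structure.n_items, structure.n_groups
    if R.shape != (n, n):
        raise ValueError(f"R must be {n} x {n}")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise ValueError("R must have unit diagonal")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be symmetric")
    if np.linalg.eigvalsh(R).min() < -1e-8:
        raise ValueError("R must be positive semi-definite")

    # (i) oblique m-factor solution
    P, phi = rotate_quartimin(extract_paf(R, m))
    # flip factors so loading sums are nonnegative; phi flips accordingly
    signs = np.where(P.sum(axis=0) >= 0, 1.0, -1.0)
    P = P * signs
    phi = phi * np.outer(signs, signs)
    # align factor order with the structure's groups (quartimin order is
    # arbitrary, and the later pattern rotation relies on the group mask)
    order = _match_columns_to_groups(P, structure)
    P = P[:, order]
    phi = phi[np.ix_(order, order)]

    # (ii) second-order loadings from the factor correlations
    gamma = one_factor_loadings(phi)
    gamma = np.clip(np.abs(gamma), 0.0, 0.999)

    # (iii) classic Schmid-Leiman target
    target = np.column_stack([P @ gamma, P * np.sqrt(1.0 - gamma**2)])

    # (iv) m+1 factors rotated onto the target.  Communalities are anchored
    # at the target's row sums (one-shot eigendecomposition): iterating them
    # freely lets the weak extra dimension collapse onto single items in
    # finite samples.  A partially specified target rotation then drives
    # off-pattern loadings toward zero, which removes the bias of the SL
    # target under loading heterogeneity; if that rotation degenerates by
    # emptying a group column (it can, when the data carry genuine
    # cross-loadings), the procrustes solution is kept instead.
    mask = structure.loading_mask()
    L0 = _target_rotated_factors(R, target, m + 1)
    L = L0
    n_collapsed = 0
    for _ in range(30):
        L_new = _pattern_refine(R, L, mask)
        # a persistent emptying of a group column marks degeneration (data
        # with genuine cross-loadings); a single transient dip is fine
        n_collapsed = n_collapsed + 1 if _group_collapse(L_new, L0, structure) else 0
        if n_collapsed >= 3:
            L = L0
            break
        done = np.max(np.abs(L_new - L)) < 1e-7
        L = L_new
        if done:
            break
    if _group_collapse(L, L0, structure):
        L = L0
    L = L * np.where(L.sum(axis=0) >= 0, 1.0, -1.0)
    return LoadingMatrix.from_dense(L, structure)


def _group_collapse(L: np.ndarray, L0: np.ndarray,
                    structure: BifactorStructure) -> bool:
    """True if any group column lost most of its within-group mass."""
    for g in range(structure.n_groups):
        idx = structure.items_in_group(g)
        before = float(np.sum(L0[idx, 1 + g] ** 2))
        after = float(np.sum(L[idx, 1 + g] ** 2))
        if before > 1e-6 and after < 0.5 * before:
            return True
    return False


def _match_columns_to_groups(P: np.ndarray, structure: BifactorStructure) -> np.ndarray:
    """Greedy assignment of pattern columns to groups by absolute mass."""
    m = structure.n_groups
    order = np.empty(m, dtype=int)
    taken: set[int] = set()
    for g in range(m):
        mass = np.array([
            np.sum(np.abs(P[structure.items_in_group(g), c]))
            if c not in taken else -np.inf
            for c in range(m)
        ])
        order[g] = int(np.argmax(mass))
        taken.add(order[g])
    return order


# ---------------------------------------------------------------------------
# Reliability indices
# ---------------------------------------------------------------------------

def omega_hierarchical(L, uniquenesses: np.ndarray,
                       extra_common: np.ndarray | None = None) -> float:
    """Omega hierarchical of the general factor.

    ``(sum g)^2 / [(sum g)^2 + sum_k (column-sum_k)^2 + sum(uniqueness)]``
    where ``g`` is the general column and ``k`` runs over the group columns.
    ``extra_common`` adds further common-variance terms to the denominator
    (used for model-implied composites where other variance sources exist).
    """
    arr = _as_loading_array(L)
    u = np.asarray(uniquenesses, dtype=float)
    if u.shape != (arr.shape[0],):
        raise ValueError("uniquenesses must have one entry per item")
    if np.any(u < 0):
        raise ValueError("uniquenesses must be nonnegative")
    num = arr[:, 0].sum() ** 2
    den = num + np.sum(arr[:, 1:].sum(axis=0) ** 2) + u.sum()
    if extra_common is not None:
        den += float(np.sum(extra_common))
    return float(num / den)


def h_index(general_loadings: np.ndarray) -> float:
    """Hancock-Mueller construct reliability: ``S / (1 + S)`` with
    ``S = sum lambda_i^2 / (1 - lambda_i^2)``."""
    lam = np.asarray(general_loadings, dtype=float)
    if np.any(np.abs(lam) >= 1.0):
        raise ValueError("all |loadings| must be < 1")
    S = float(np.sum(lam**2 / (1.0 - lam**2)))
    return S / (1.0 + S)


def ecv(L) -> float:
    """Explained common variance of the general factor."""
    arr = _as_loading_array(L)
    ss = (arr**2).sum(axis=0)
    total = ss.sum()
    if total == 0:
        raise ValueError("all-zero loading matrix")
    return float(ss[0] / total)


def general_factor_indices(L, uniquenesses: np.ndarray | None = None,
                           label: str = "") -> IndexReport:
    """Bundle omega_h, H and ECV for one loading matrix.

    With ``uniquenesses=None`` they default to ``1 - sum_k lambda_ik^2``
    (unit standardized item variance).
    """
    arr = _as_loading_array(L)
    if uniquenesses is None:
        uniquenesses = np.clip(1.0 - (arr**2).sum(axis=1), 0.0, None)
    return IndexReport(
        omega_h=omega_hierarchical(arr, uniquenesses),
        h_index=h_index(np.clip(arr[:, 0], -0.999999, 0.999999)),
        ecv=ecv(arr),
        label=label,
    )


# ---------------------------------------------------------------------------
# Loading adequacy / dominance summary
# ---------------------------------------------------------------------------

def loading_summary(L: LoadingMatrix, threshold: float = 0.4) -> dict:
    """Adequacy and dominance summary of a bifactor loading matrix.

    Returns the items whose general loading falls below ``threshold``, the
    count/share of items whose general loading strictly exceeds every group
    loading, and (from the dense pre-zeroing pattern) whether each item
    loads its intended group more strongly than the other groups.
    """
    s = L.structure
    dense = _as_loading_array(L)
    general = dense[:, 0]
    below = [s.item_labels[i] for i in range(s.n_items) if general[i] < threshold]
    dominant = general > dense[:, 1:].max(axis=1)
    own_group_ok = []
    for i, g in enumerate(s.group_of):
        own = abs(dense[i, 1 + g])
        others = [abs(dense[i, 1 + k]) for k in range(s.n_groups) if k != g]
        own_group_ok.append(bool(own > max(others)) if others else True)
    return {
        "threshold": threshold,
        "items_below_threshold": below,
        "n_below_threshold": len(below),
        "n_general_dominant": int(dominant.sum()),
        "pct_general_dominant": 100.0 * dominant.mean(),
        "own_group_dominant": own_group_ok,
        "all_items_load_intended_group": all(own_group_ok),
    }


# ---------------------------------------------------------------------------
# Scale-level reliability
# ---------------------------------------------------------------------------

def scale_reliability(item_scores) -> dict:
    """Cronbach's alpha and one-factor omega total for an items table.

    ``item_scores`` is an (observations x items) array or DataFrame; rows
    with any missing value are dropped (listwise).
    """
    X = np.asarray(pd.DataFrame(item_scores).dropna(), dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValueError("need at least 2 items")
    if n < 3:
        raise ValueError("need at least 3 complete rows")
    var_items = X.var(axis=0, ddof=1)
    if np.any(var_items == 0):
        raise ValueError("zero-variance item")
    var_total = X.sum(axis=1).var(ddof=1)
    alpha = k / (k - 1) * (1.0 - var_items.sum() / var_total)
    R = np.corrcoef(X, rowvar=False)
    lam = extract_paf(R, 1)[:, 0]
    lam = lam * np.sign(lam.sum() or 1.0)
    omega_total = lam.sum() ** 2 / (lam.sum() ** 2 + np.sum(1.0 - lam**2))
    return {"alpha": float(alpha), "omega_total": float(omega_total)}
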