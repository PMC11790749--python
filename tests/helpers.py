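"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np

from biftwin import BifactorStructure, CPParameterSet, IPParameterSet, LoadingMatrix

R_ADD = {"MZ": 1.0, "DZ": 0.5}


def small_structure() -> BifactorStructure:
    return BifactorStructure(group_of=(0, 0, 1, 1), group_names=("g1", "g2"))


def bifactor_loadings(structure, general, group):
    """Loading matrix with constant general/group loadings."""
    n = structure.n_items
    lam = np.zeros((n, structure.n_factors))
    lam[:, 0] = general
    lam[np.arange(n), 1 + np.asarray(structure.group_of)] = group
    return LoadingMatrix(lam, structure)


def make_cp(structure, general=0.65, group=0.45, factor_ace=(0.5, 0.0, 0.5),
            unique_ace=(0.0, 0.0, 0.35)):
    """CP parameter set; factor_ace/unique_ace given as variance shares."""
    fp = np.tile(np.sqrt(np.asarray(factor_ace, dtype=float)),
                 (structure.n_factors, 1))
    fp = fp / np.sqrt((fp**2).sum(axis=1))[:, None]
    up = np.tile(np.sqrt(np.asarray(unique_ace, dtype=float)),
                 (structure.n_items, 1))
    return CPParameterSet(bifactor_loadings(structure, general, group), fp, up)


def make_ip(structure, loads=None, unique_ace=(0.2, 0.1, 0.6)):
    """IP parameter set from per-source (general, group) loading pairs."""
    if loads is None:
        loads = {"A": (0.30, 0.20), "C": (0.15, 0.10), "E": (0.45, 0.35)}
    mats = {c: bifactor_loadings(structure, *loads.get(c, (0.0, 0.0)))
            for c in ("A", "C", "E")}
    up = np.tile(np.sqrt(np.asarray(unique_ace, dtype=float)),
                 (structure.n_items, 1))
    return IPParameterSet(mats["A"], mats["C"], mats["E"], up)


def random_cp(structure, rng):
    n, nf = structure.n_items, structure.n_factors
    lam = np.where(structure.loading_mask(),
                   rng.uniform(0.2, 0.7, (n, nf)), 0.0)
    fp = rng.uniform(0.2, 1.0, (nf, 3))
    fp = fp / np.sqrt((fp**2).sum(axis=1))[:, None]
    up = rng.uniform(0.1, 0.6, (n, 3))
    return CPParameterSet(LoadingMatrix(lam, structure), fp, up)


def random_ip(structure, rng):
    n, nf = structure.n_items, structure.n_factors
    mask = structure.loading_mask()
    mats = [LoadingMatrix(np.where(mask, rng.uniform(0.1, 0.5, (n, nf)), 0.0),
                          structure) for _ in range(3)]
    up = rng.uniform(0.1, 0.6, (n, 3))
    return IPParameterSet(*mats, unique_paths=up)


# ---------------------------------------------------------------------------
# Path-tracing oracle: build the joint latent vector for both co-twins,
# assign latent-latent covariances by the twin rules, and map to items.
# Deliberately a different route than the closed-form block expressions.
# ---------------------------------------------------------------------------

def path_tracing_cov(params, zygosity: str) -> np.ndarray:
    r = R_ADD[zygosity]
    s = params.structure
    n, nf = s.n_items, s.n_factors
    latents = []  # (twin, kind, source, index)
    for t in (0, 1):
        for src in ("A", "C", "E"):
            for f in range(nf):
                latents.append((t, "factor", src, f))
            for i in range(n):
                latents.append((t, "unique", src, i))
    L = len(latents)
    S = np.zeros((L, L))
    cross = {"A": r, "C": 1.0, "E": 0.0}
    for a in range(L):
        ta, ka, sa, ia = latents[a]
        for b in range(L):
            tb, kb, sb, ib = latents[b]
            if (ka, sa, ia) != (kb, sb, ib):
                continue
            S[a, b] = 1.0 if ta == tb else cross[sa]

    M = np.zeros((2 * n, L))
    col = {"A": 0, "C": 1, "E": 2}
    for a, (t, kind, src, idx) in enumerate(latents):
        for i in range(n):
            row = t * n + i
            if kind == "unique":
                if idx == i:
                    M[row, a] = params.unique_paths[i, col[src]]
            elif isinstance(params, CPParameterSet):
                # item <- factor path * loading
                M[row, a] = (params.lambda_p.values[i, idx]
                             * params.factor_paths[idx, col[src]])
            else:
                M[row, a] = params.source(src).values[i, idx]
    return M @ S @ M.T


def exact_sample_cov(n_rows: int, cov: np.ndarray, rng) -> np.ndarray:
    """Data matrix whose sample covariance (ddof=1) equals ``cov`` exactly."""
    k = cov.shape[0]
    X = rng.standard_normal((n_rows, k))
    X = X - X.mean(axis=0)
    S = X.T @ X / (n_rows - 1)
    whiten = np.linalg.inv(np.linalg.cholesky(S))
    return X @ whiten.T @ np.linalg.cholesky(cov).T
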