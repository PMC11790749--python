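"""Minimal factor-analysis primitives used by the psychometric workflow.

Iterated principal-axis extraction, quartimin (oblimin, gamma = 0) rotation
via gradient projection, and orthogonal procrustes target rotation.  Kept
deliberately small: only what the bifactor estimation route needs.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import orthogonal_procrustes

__all__ = ["extract_paf", "rotate_quartimin", "procrustes_rotate", "one_factor_loadings"]


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations as starting communalities."""
    try:
        Rinv = np.linalg.inv(R)
        smc = 1.0 - 1.0 / np.diag(Rinv)
        return np.clip(smc, 0.0, 0.999)
    except np.linalg.LinAlgError:
        return np.full(R.shape[0], 0.5)


def extract_paf(R: np.ndarray, n_factors: int, max_iter: int = 2000,
                tol: float = 1e-6) -> np.ndarray:
    """Iterated principal-axis factoring of a correlation matrix.

    Returns the unrotated n x k loading matrix.  Raises if the communality
    iteration fails to converge (a small residual drift near a Heywood case
    is tolerated).
    """
    R = np.asarray(R, dtype=float)
    n = R.shape[0]
    if R.shape != (n, n):
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be symmetric")
    h2 = _smc(R)
    L = np.zeros((n, n_factors))
    delta = np.inf
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        vals, vecs = np.linalg.eigh(Rr)
        order = np.argsort(vals)[::-1][:n_factors]
        lam = np.clip(vals[order], 0.0, None)
        L = vecs[:, order] * np.sqrt(lam)
        h2_new = np.clip((L**2).sum(axis=1), 0.0, 0.9999)
        delta = np.max(np.abs(h2_new - h2))
        if delta < tol:
            return L
        h2 = h2_new
    if delta < 1e-4:
        return L
    raise RuntimeError("principal-axis extraction did not converge")


def _quartimin(L: np.ndarray) -> tuple[float, np.ndarray]:
    """Quartimin criterion and its gradient with respect to the pattern."""
    L2 = L**2
    N = 1.0 - np.eye(L.shape[1])
    f = float(np.sum(L2 * (L2 @ N)) / 4.0)
    G = L * (L2 @ N)
    return f, G


def rotate_quartimin(A: np.ndarray, max_iter: int = 2000,
                     tol: float = 1e-7) -> tuple[np.ndarray, np.ndarray]:
    """Oblique quartimin rotation by gradient projection.

    Parameters
    ----------
    A
        Unrotated loading matrix (n x k).

    Returns
    -------
    pattern, phi
        Rotated pattern matrix and factor correlation matrix.
    """
    A = np.asarray(A, dtype=float)
    k = A.shape[1]
    if k == 1 or np.max(np.abs(A)) < 1e-8:
        return A.copy(), np.eye(k)
    T = np.eye(k)
    al = 1.0
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin(L)
    G = -(L.T @ Gq @ Ti).T
    for _ in range(max_iter):
        Gp = G - T * np.sum(T * G, axis=0)
        s = np.linalg.norm(Gp)
        if s < tol:
            break
        al = 2.0 * al
        for _ in range(60):
            X = T - al * Gp
            X = X / np.sqrt(np.sum(X**2, axis=0))
            Ti = np.linalg.inv(X)
            L = A @ Ti.T
            ft, Gq = _quartimin(L)
            if ft < f - 0.5 * s**2 * al:
                break
            al = al / 2.0
        T = X
        f = ft
        G = -(L.T @ Gq @ Ti).T
    phi = T.T @ T
    return L, phi


def procrustes_rotate(A: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Orthogonally rotate loadings ``A`` toward ``target`` (least squares)."""
    Q, _ = orthogonal_procrustes(A, target)
    return A @ Q


def rotate_to_pattern(A: np.ndarray, mask: np.ndarray, T0: np.ndarray | None = None,
                      max_iter: int = 300, tol: float = 1e-9) -> np.ndarray:
    """Orthogonal rotation minimizing the squared loadings outside ``mask``.

    Partially specified target rotation: ``f(T) = sum offmask((A T)^2)``.
    ``T0`` seeds the rotation (e.g. a procrustes solution); iterates stay on
    the orthogonal group via polar retraction.
    """
    A = np.asarray(A, dtype=float)
    off = ~np.asarray(mask, dtype=bool)
    T = np.eye(A.shape[1]) if T0 is None else T0.copy()
    L = A @ T
    f = float(np.sum(L[off] ** 2))
    al = 1.0
    for _ in range(max_iter):
        Gq = 2.0 * np.where(off, L, 0.0)
        G = A.T @ Gq
        M = T.T @ G
        Gp = G - T @ (M + M.T) / 2.0
        s = np.linalg.norm(Gp)
        if s < tol:
            break
        al = 2.0 * al
        for _ in range(60):
            U, _, Vt = np.linalg.svd(T - al * Gp)
            X = U @ Vt
            Lx = A @ X
            fx = float(np.sum(Lx[off] ** 2))
            if fx < f - 0.5 * s**2 * al:
                break
            al = al / 2.0
        T, L, f = X, Lx, fx
    return L


def one_factor_loadings(R: np.ndarray) -> np.ndarray:
    """Single-factor principal-axis loadings (e.g. on a factor correlation)."""
    return extract_paf(R, 1)[:, 0]
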