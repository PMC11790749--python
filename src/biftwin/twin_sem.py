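"""Bifactor twin structural equation models.

Builds model-implied per-zygosity covariance matrices for the common
pathway (CP) and independent pathway (IP) families, evaluates the full
information maximum likelihood (FIML) -2 log-likelihood over twin pairs
with arbitrary missingness, and fits ACE/AE/CE/E variants by gradient-based
optimization.

The additive-genetic cross-twin correlation is 1 for MZ and 0.5 for DZ
pairs; shared-environment components correlate 1 and non-shared components
0 across co-twins.  Item scores are treated as continuous multivariate
normal with means fixed at zero (covariate-residualized data).

Likelihood evaluation groups pairs by missingness pattern, so complete data
automatically reduce to a sufficient-statistics computation.  Gradients of
the likelihood with respect to all structural parameters are analytic,
obtained by accumulating d(-2LL)/dSigma per pattern and chaining through
the covariance structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, lapack  # cho_* used by EM

from .core import (
    BifactorStructure,
    CPParameterSet,
    ExpectedCovariances,
    IPParameterSet,
    LoadingMatrix,
    TwinPairDataset,
)

__all__ = [
    "ModelSpec",
    "FitResult",
    "expected_cov_cp",
    "expected_cov_ip",
    "expected_covariances",
    "fiml_minus2ll",
    "fit_model",
    "fit_saturated",
    "fit_independence",
    "standardized_effects",
    "aggregate_standardized_effects",
    "shares_within_source",
]

R_ADDITIVE = {"MZ": 1.0, "DZ": 0.5}
_COMP_COL = {"A": 0, "C": 1, "E": 2}
E_U_FLOOR = 1e-4


# ---------------------------------------------------------------------------
# Specs and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Which model family and which variance components to estimate.

    ``components`` must contain ``"E"``; dropping A and/or C yields the
    nested AE/CE/E variants.  For the CP family, ``unique_ace`` selects
    whether item residuals get their own A/C/E decomposition (default) or
    non-shared residuals only.
    """

    family: Literal["CP", "IP"]
    components: frozenset[str]
    structure: BifactorStructure
    unique_ace: bool = True

    def __post_init__(self) -> None:
        comps = frozenset(self.components)
        if not comps <= {"A", "C", "E"}:
            raise ValueError("components must be a subset of {A, C, E}")
        if "E" not in comps:
            raise ValueError("E must always be present")
        if self.family not in ("CP", "IP"):
            raise ValueError("family must be 'CP' or 'IP'")
        object.__setattr__(self, "components", comps)

    @property
    def comp_tuple(self) -> tuple[str, ...]:
        return tuple(c for c in ("A", "C", "E") if c in self.components)

    @property
    def unique_comps(self) -> tuple[str, ...]:
        if self.family == "IP" or self.unique_ace:
            return self.comp_tuple
        return ("E",)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return (self.family == other.family
                and self.structure == other.structure
                and self.unique_ace == other.unique_ace
                and self.components <= other.components)


@dataclass
class FitResult:
    spec: ModelSpec | None
    params: CPParameterSet | IPParameterSet | None
    minus2LL: float
    n_free_params: int
    n_pairs_used: int
    converged: bool
    theta: np.ndarray | None = None
    optimizer_status: str = ""
    start_values: list[float] = field(default_factory=list)
    _standardized: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def standardized(self) -> pd.DataFrame | None:
        """Per-item squared standardized effects (computed on first access)."""
        if self._standardized is None and self.params is not None:
            self._standardized = standardized_effects(self.params)
        return self._standardized


# ---------------------------------------------------------------------------
# Model-implied covariance builders
# ---------------------------------------------------------------------------

def _assemble(W: np.ndarray, B: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    S = np.empty((2 * n, 2 * n))
    S[:n, :n] = W
    S[n:, n:] = W
    S[:n, n:] = B
    S[n:, :n] = B.T
    return S


def expected_cov_cp(params: CPParameterSet, zygosity: str) -> np.ndarray:
    """2n x 2n model-implied covariance of a CP model for one zygosity.

    Within-twin block ``Lam Lam' + diag(a_u^2 + c_u^2 + e_u^2)``; cross-twin
    block ``Lam diag(r a_F^2 + c_F^2) Lam' + diag(r a_u^2 + c_u^2)`` with
    ``r`` the additive-genetic cross-twin correlation.
    """
    params.check_standardized(tol=1e-4)
    r = R_ADDITIVE[zygosity]
    lam = params.lambda_p.values
    a_F, c_F, _ = params.factor_paths.T
    a_u, c_u, e_u = params.unique_paths.T
    W = lam @ lam.T + np.diag(a_u**2 + c_u**2 + e_u**2)
    K = r * a_F**2 + c_F**2
    B = (lam * K) @ lam.T + np.diag(r * a_u**2 + c_u**2)
    return _assemble(W, B)


def expected_cov_ip(params: IPParameterSet, zygosity: str) -> np.ndarray:
    """2n x 2n model-implied covariance of an IP model for one zygosity."""
    r = R_ADDITIVE[zygosity]
    lamA = params.lambda_A.values
    lamC = params.lambda_C.values
    lamE = params.lambda_E.values
    a_u, c_u, e_u = params.unique_paths.T
    W = (lamA @ lamA.T + lamC @ lamC.T + lamE @ lamE.T
         + np.diag(a_u**2 + c_u**2 + e_u**2))
    B = r * (lamA @ lamA.T) + lamC @ lamC.T + np.diag(r * a_u**2 + c_u**2)
    return _assemble(W, B)


def expected_covariances(params: CPParameterSet | IPParameterSet) -> ExpectedCovariances:
    f = expected_cov_cp if isinstance(params, CPParameterSet) else expected_cov_ip
    return ExpectedCovariances(sigma_MZ=f(params, "MZ"), sigma_DZ=f(params, "DZ"))


# ---------------------------------------------------------------------------
# FIML over missingness patterns
# ---------------------------------------------------------------------------

@dataclass
class _Pattern:
    obs: np.ndarray          # observed column indices
    n: int                   # rows with this pattern
    M: np.ndarray            # sum of outer products of (x_obs - mu_obs)
    pair_ids: list           # for error reporting
    grid: tuple = None       # cached np.ix_(obs, obs)
    complete: bool = False   # pattern observes every variable

    def __post_init__(self) -> None:
        self.grid = np.ix_(self.obs, self.obs)


def _build_patterns(X: np.ndarray, means: np.ndarray,
                    pair_ids: Sequence) -> list[_Pattern]:
    obs_mask = np.isfinite(X)
    patterns: dict[bytes, list[int]] = {}
    for i, row in enumerate(obs_mask):
        patterns.setdefault(row.tobytes(), []).append(i)
    out: list[_Pattern] = []
    for key, rows in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        obs = np.where(mask)[0]
        if obs.size == 0:
            continue  # fully missing pair contributes nothing
        Xg = X[np.ix_(rows, obs)] - means[obs]
        out.append(_Pattern(obs=obs, n=len(rows), M=Xg.T @ Xg,
                            pair_ids=[pair_ids[i] for i in rows],
                            complete=obs.size == X.shape[1]))
    return out


class _FIMLData:
    """Per-zygosity pattern summaries reused across likelihood evaluations."""

    def __init__(self, data: TwinPairDataset, means: np.ndarray | None = None):
        p = 2 * data.n_items
        self.p = p
        self.means = np.zeros(p) if means is None else np.asarray(means, dtype=float)
        if self.means.shape != (p,):
            raise ValueError(f"means must have length {p}")
        X = data.pair_vectors()
        self.patterns: dict[str, list[_Pattern]] = {}
        self.n_pairs_used = 0
        for z in ("MZ", "DZ"):
            mask = data.zygosity_mask(z)
            pats = _build_patterns(X[mask], self.means,
                                   list(data.pair_ids[mask]))
            self.patterns[z] = pats
            self.n_pairs_used += sum(pt.n for pt in pats)

    def minus2ll_and_G(self, sigma: dict[str, np.ndarray],
                       want_grad: bool = True):
        """-2LL and, optionally, d(-2LL)/dSigma_z accumulated per zygosity."""
        total = 0.0
        G = {z: np.zeros((self.p, self.p)) for z in ("MZ", "DZ")} if want_grad else None
        log2pi = np.log(2.0 * np.pi)
        for z in ("MZ", "DZ"):
            S_full = sigma[z]
            for pt in self.patterns[z]:
                sub = S_full if pt.complete else S_full[pt.grid]
                c, info = lapack.dpotrf(sub, lower=1)
                if info != 0:
                    raise np.linalg.LinAlgError(
                        f"singular observed covariance for pairs {pt.pair_ids[:3]}..."
                    )
                logdet = 2.0 * np.sum(np.log(np.diag(c)))
                inv_, info = lapack.dpotri(c, lower=1)
                Sinv = inv_ + np.tril(inv_, -1).T
                total += (pt.n * (pt.obs.size * log2pi + logdet)
                          + np.sum(Sinv * pt.M))
                if want_grad:
                    Sinv_M = Sinv @ pt.M
                    Gp = pt.n * Sinv - Sinv_M @ Sinv
                    if pt.complete:
                        G[z] += Gp
                    else:
                        G[z][pt.grid] += Gp
        return total, G


def fiml_minus2ll(data: TwinPairDataset, sigma_MZ: np.ndarray,
                  sigma_DZ: np.ndarray, means: np.ndarray | None = None) -> float:
    """FIML -2 log-likelihood of twin-pair data under given covariances.

    Each pair contributes -2 log of the multivariate-normal density of its
    observed sub-vector under its zygosity's covariance; fully missing pairs
    contribute zero.  ``means`` defaults to zero (residualized scores).
    """
    fd = _FIMLData(data, means)
    val, _ = fd.minus2ll_and_G({"MZ": np.asarray(sigma_MZ, dtype=float),
                                "DZ": np.asarray(sigma_DZ, dtype=float)},
                               want_grad=False)
    return float(val)


# ---------------------------------------------------------------------------
# Parameter codecs: theta vector <-> parameter set, Sigma and gradient
# ---------------------------------------------------------------------------

def _normalize_rows(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.sqrt((theta**2).sum(axis=1))
    norms = np.maximum(norms, 1e-12)
    return theta / norms[:, None], norms


class _Codec:
    """Maps a free-parameter vector to covariance matrices and back-chains
    d(-2LL)/dSigma to the free parameters."""

    spec: ModelSpec

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        s = spec.structure
        self.n = s.n_items
        self.nf = s.n_factors
        self.group_col = np.asarray(s.group_of)          # group index per item
        self.comps = spec.comp_tuple
        self.ucomps = spec.unique_comps
        self.mask = s.loading_mask()

    # -- loading helpers: each item has one general + one group entry -------
    def _lam_from(self, gen: np.ndarray, grp: np.ndarray) -> np.ndarray:
        lam = np.zeros((self.n, self.nf))
        lam[:, 0] = gen
        lam[np.arange(self.n), 1 + self.group_col] = grp
        return lam

    def _lam_grad_to(self, glam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return glam[:, 0], glam[np.arange(self.n), 1 + self.group_col]

    def _unpack_unique(self, u_raw: np.ndarray) -> np.ndarray:
        up = np.zeros((self.n, 3))
        for j, cmp in enumerate(self.ucomps):
            up[:, _COMP_COL[cmp]] = u_raw[:, j]
        return up

    def unique_bounds(self) -> list[tuple[float, float]]:
        b = []
        for cmp in self.ucomps:
            lo = E_U_FLOOR if cmp == "E" else 0.0
            b.extend([(lo, 3.0)] * self.n)
        return b

    def penalty(self, theta: np.ndarray):
        """Optional smooth penalty pinning redundant directions (none)."""
        return 0.0, np.zeros_like(theta)


class _CPCodec(_Codec):
    """theta = [lam_gen(n), lam_grp(n), factor raw paths (nf x k, normalized
    per factor to enforce a^2+c^2+e^2=1), unique paths (n x ku)]."""

    def __init__(self, spec: ModelSpec):
        super().__init__(spec)
        self.k = len(self.comps)
        self.ku = len(self.ucomps)
        self.n_theta = 2 * self.n + self.nf * self.k + self.n * self.ku
        # one redundant direction per factor from the normalization
        self.n_free = 2 * self.n + self.nf * (self.k - 1) + self.n * self.ku

    def split(self, theta):
        n, nf = self.n, self.nf
        gen = theta[:n]
        grp = theta[n:2 * n]
        f_raw = theta[2 * n:2 * n + nf * self.k].reshape(nf, self.k)
        u_raw = theta[2 * n + nf * self.k:].reshape(self.ku, n).T
        return gen, grp, f_raw, u_raw

    def to_params(self, theta: np.ndarray) -> CPParameterSet:
        gen, grp, f_raw, u_raw = self.split(theta)
        fp_norm, _ = _normalize_rows(f_raw)
        fp = np.zeros((self.nf, 3))
        for j, cmp in enumerate(self.comps):
            fp[:, _COMP_COL[cmp]] = fp_norm[:, j]
        return CPParameterSet(
            lambda_p=LoadingMatrix(self._lam_from(gen, grp), self.spec.structure),
            factor_paths=fp,
            unique_paths=self._unpack_unique(u_raw),
        )

    def sigma_and_grad(self, theta: np.ndarray):
        gen, grp, f_raw, u_raw = self.split(theta)
        lam = self._lam_from(gen, grp)
        fp_norm, f_norms = _normalize_rows(f_raw)
        a_F = np.zeros(self.nf)
        c_F = np.zeros(self.nf)
        for j, cmp in enumerate(self.comps):
            if cmp == "A":
                a_F = fp_norm[:, j]
            elif cmp == "C":
                c_F = fp_norm[:, j]
        up = self._unpack_unique(u_raw)
        a_u, c_u, e_u = up.T

        W = lam @ lam.T + np.diag(a_u**2 + c_u**2 + e_u**2)
        sigma = {}
        K = {}
        for z, r in R_ADDITIVE.items():
            K[z] = r * a_F**2 + c_F**2
            B = (lam * K[z]) @ lam.T + np.diag(r * a_u**2 + c_u**2)
            sigma[z] = _assemble(W, B)

        def backprop(G: dict[str, np.ndarray]) -> np.ndarray:
            n = self.n
            H_W = np.zeros((n, n))
            grad_lam = np.zeros_like(lam)
            grad_K = {z: np.zeros(self.nf) for z in R_ADDITIVE}
            h_B_diag = {}
            for z in R_ADDITIVE:
                Gz = G[z]
                H_W += Gz[:n, :n] + Gz[n:, n:]
                H_B = Gz[:n, n:] + Gz[n:, :n].T
                H_Bs = H_B + H_B.T
                grad_lam += H_Bs @ (lam * K[z])
                grad_K[z] = np.einsum("if,ij,jf->f", lam, H_Bs, lam) / 2.0
                h_B_diag[z] = np.diag(H_B)
            H_Ws = H_W + H_W.T
            grad_lam += H_Ws @ lam
            g_gen, g_grp = self._lam_grad_to(grad_lam)

            # factor paths through the normalization map u = theta/|theta|
            grad_u_norm = np.zeros((self.nf, self.k))
            for j, cmp in enumerate(self.comps):
                if cmp == "A":
                    for z, r in R_ADDITIVE.items():
                        grad_u_norm[:, j] += grad_K[z] * 2.0 * r * a_F
                elif cmp == "C":
                    for z in R_ADDITIVE:
                        grad_u_norm[:, j] += grad_K[z] * 2.0 * c_F
            inner = (grad_u_norm * fp_norm).sum(axis=1)
            g_fraw = (grad_u_norm - inner[:, None] * fp_norm) / f_norms[:, None]

            # unique paths: d(-2LL)/d diag(W) and d diag(B_z)
            hw = np.diag(H_W)
            g_u = np.zeros((self.n, self.ku))
            for j, cmp in enumerate(self.ucomps):
                if cmp == "A":
                    g = 2.0 * hw * a_u
                    for z, r in R_ADDITIVE.items():
                        g += 2.0 * r * h_B_diag[z] * a_u
                elif cmp == "C":
                    g = 2.0 * hw * c_u
                    for z in R_ADDITIVE:
                        g += 2.0 * h_B_diag[z] * c_u
                else:
                    g = 2.0 * hw * e_u
                g_u[:, j] = g
            return np.concatenate([g_gen, g_grp, g_fraw.ravel(), g_u.T.ravel()])

        return sigma, backprop

    def bounds(self) -> list[tuple[float, float]]:
        b = [(-3.0, 3.0)] * (2 * self.n)
        b += [(-3.0, 3.0)] * (self.nf * self.k)
        b += self.unique_bounds()
        return b

    def penalty(self, theta: np.ndarray):
        """Pin the scale of the raw factor-path vectors at 1.

        The likelihood depends only on their direction (paths are
        normalized), so this removes a flat ray without moving the optimum.
        """
        off = 2 * self.n
        f_raw = theta[off:off + self.nf * self.k].reshape(self.nf, self.k)
        norms = np.maximum(np.sqrt((f_raw**2).sum(axis=1)), 1e-12)
        w = 10.0
        val = w * np.sum((norms - 1.0) ** 2)
        g_f = 2.0 * w * (norms - 1.0)[:, None] * f_raw / norms[:, None]
        grad = np.zeros_like(theta)
        grad[off:off + self.nf * self.k] = g_f.ravel()
        return float(val), grad

    def start_theta(self, lam_start: np.ndarray, resid_var: np.ndarray) -> np.ndarray:
        gen = lam_start[:, 0]
        grp = lam_start[np.arange(self.n), 1 + self.group_col]
        f_raw = np.full((self.nf, self.k), 1.0 / np.sqrt(self.k))
        u = np.sqrt(np.maximum(resid_var, 0.05) / self.ku)
        u_raw = np.tile(u, (self.ku, 1))
        return np.concatenate([gen, grp, f_raw.ravel(), u_raw.ravel()])


class _IPCodec(_Codec):
    """theta = per included source [lam_gen(n), lam_grp(n)], then unique."""

    def __init__(self, spec: ModelSpec):
        super().__init__(spec)
        self.ku = len(self.ucomps)
        self.n_theta = len(self.comps) * 2 * self.n + self.n * self.ku
        self.n_free = self.n_theta

    def split(self, theta):
        n = self.n
        lams = {}
        off = 0
        for cmp in self.comps:
            lams[cmp] = (theta[off:off + n], theta[off + n:off + 2 * n])
            off += 2 * n
        u_raw = theta[off:].reshape(self.ku, n).T
        return lams, u_raw

    def _lam_mats(self, theta):
        lams, u_raw = self.split(theta)
        mats = {}
        for cmp in ("A", "C", "E"):
            if cmp in lams:
                mats[cmp] = self._lam_from(*lams[cmp])
            else:
                mats[cmp] = np.zeros((self.n, self.nf))
        return mats, self._unpack_unique(u_raw)

    def to_params(self, theta: np.ndarray) -> IPParameterSet:
        mats, up = self._lam_mats(theta)
        s = self.spec.structure
        return IPParameterSet(
            lambda_A=LoadingMatrix(mats["A"], s),
            lambda_C=LoadingMatrix(mats["C"], s),
            lambda_E=LoadingMatrix(mats["E"], s),
            unique_paths=up,
        )

    def sigma_and_grad(self, theta: np.ndarray):
        mats, up = self._lam_mats(theta)
        a_u, c_u, e_u = up.T
        lamA, lamC, lamE = mats["A"], mats["C"], mats["E"]
        W = (lamA @ lamA.T + lamC @ lamC.T + lamE @ lamE.T
             + np.diag(a_u**2 + c_u**2 + e_u**2))
        sigma = {}
        for z, r in R_ADDITIVE.items():
            B = r * (lamA @ lamA.T) + lamC @ lamC.T + np.diag(r * a_u**2 + c_u**2)
            sigma[z] = _assemble(W, B)

        def backprop(G: dict[str, np.ndarray]) -> np.ndarray:
            n = self.n
            H_W = np.zeros((n, n))
            H_Bs = {}
            for z in R_ADDITIVE:
                Gz = G[z]
                H_W += Gz[:n, :n] + Gz[n:, n:]
                H_B = Gz[:n, n:] + Gz[n:, :n].T
                H_Bs[z] = H_B + H_B.T
            H_Ws = H_W + H_W.T
            pieces = []
            for cmp in self.comps:
                glam = H_Ws @ mats[cmp]
                if cmp == "A":
                    for z, r in R_ADDITIVE.items():
                        glam = glam + r * (H_Bs[z] @ lamA)
                elif cmp == "C":
                    for z in R_ADDITIVE:
                        glam = glam + H_Bs[z] @ lamC
                g_gen, g_grp = self._lam_grad_to(glam)
                pieces.extend([g_gen, g_grp])
            hw = np.diag(H_W)
            hb_diag = {z: np.diag(G[z][:n, n:] + G[z][n:, :n].T) for z in R_ADDITIVE}
            g_u = np.zeros((n, self.ku))
            for j, cmp in enumerate(self.ucomps):
                if cmp == "A":
                    g = 2.0 * hw * a_u
                    for z, r in R_ADDITIVE.items():
                        g += 2.0 * r * hb_diag[z] * a_u
                elif cmp == "C":
                    g = 2.0 * hw * c_u
                    for z in R_ADDITIVE:
                        g += 2.0 * hb_diag[z] * c_u
                else:
                    g = 2.0 * hw * e_u
                g_u[:, j] = g
            pieces.append(g_u.T.ravel())
            return np.concatenate(pieces)

        return sigma, backprop

    def bounds(self) -> list[tuple[float, float]]:
        return ([(-3.0, 3.0)] * (len(self.comps) * 2 * self.n)
                + self.unique_bounds())

    def start_theta(self, lam_start: np.ndarray, resid_var: np.ndarray) -> np.ndarray:
        gen = lam_start[:, 0]
        grp = lam_start[np.arange(self.n), 1 + self.group_col]
        share = 1.0 / np.sqrt(len(self.comps))
        pieces = []
        for _ in self.comps:
            pieces.extend([gen * share, grp * share])
        u = np.sqrt(np.maximum(resid_var, 0.05) / self.ku)
        pieces.append(np.tile(u, (self.ku, 1)).ravel())
        return np.concatenate(pieces)


def _codec_for(spec: ModelSpec) -> _Codec:
    return _CPCodec(spec) if spec.family == "CP" else _IPCodec(spec)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _start_loadings(data: TwinPairDataset, structure: BifactorStructure):
    """Heuristic starts: bifactor pattern of the pooled individual-level
    correlation matrix, with a flat fallback if estimation fails."""
    from .psychometrics import fit_dsl_bifactor

    X = data.items.reshape(-1, data.n_items)
    X = X[np.isfinite(X).all(axis=1)]
    try:
        if X.shape[0] < 5 * data.n_items:
            raise ValueError("too few complete rows for a correlation start")
        R = np.corrcoef(X, rowvar=False)
        sd = X.std(axis=0, ddof=1)
        lm = fit_dsl_bifactor(R, structure)
        lam = lm.values * sd[:, None]
        resid = np.maximum(X.var(axis=0, ddof=1) - (lam**2).sum(axis=1), 0.05)
        return lam, resid
    except Exception:
        lam = np.where(structure.loading_mask(), 0.4, 0.0)
        return lam, np.full(structure.n_items, 0.5)


def fit_model(data: TwinPairDataset, spec: ModelSpec,
              start: CPParameterSet | IPParameterSet | np.ndarray | None = None,
              n_starts: int = 5, jitter: float = 0.05,
              optimizer: str = "L-BFGS-B", maxiter: int = 3000,
              tol: float = 1e-8, seed: int = 0) -> FitResult:
    """Fit a bifactor twin model by FIML.

    Multi-start gradient-based minimization of the FIML -2LL; the best
    converged start is kept.  ``start`` may be a parameter set (or raw theta
    vector); otherwise starts are derived from a phenotypic bifactor
    solution on the pooled data.  Loading-column signs are fixed to
    nonnegative sums afterwards (the likelihood is sign-invariant).
    """
    codec = _codec_for(spec)
    fd = _FIMLData(data)
    if fd.n_pairs_used == 0:
        raise ValueError("no pairs with observed data")

    if isinstance(start, np.ndarray):
        theta0 = np.asarray(start, dtype=float)
    elif start is not None:
        theta0 = _theta_from_params(codec, start)
    else:
        lam0, resid0 = _start_loadings(data, spec.structure)
        theta0 = codec.start_theta(lam0, resid0)
    if theta0.shape != (codec.n_theta,):
        raise ValueError(f"start vector must have length {codec.n_theta}")

    bounds = codec.bounds()
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def objective(theta):
        sigma, backprop = codec.sigma_and_grad(theta)
        try:
            val, G = fd.minus2ll_and_G(sigma)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros_like(theta)
        pv, pg = codec.penalty(theta)
        return val + pv, backprop(G) + pg

    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(1, n_starts)):
        th = theta0 if s == 0 else np.clip(
            theta0 + jitter * rng.standard_normal(theta0.size), lo, hi)
        res = optimize.minimize(objective, np.clip(th, lo, hi), jac=True,
                                method=optimizer, bounds=bounds,
                                options={"maxiter": maxiter, "ftol": tol,
                                         "gtol": 1e-6} if optimizer == "L-BFGS-B"
                                else {"maxiter": maxiter, "ftol": tol})
        if best is None or res.fun < best.fun:
            best = res

    theta_hat = _fix_signs(codec, best.x)
    params = codec.to_params(theta_hat)
    # report the likelihood without the (vanishing) pinning penalty
    sigma_hat, _ = codec.sigma_and_grad(theta_hat)
    m2ll, _ = fd.minus2ll_and_G(sigma_hat, want_grad=False)
    fit = FitResult(
        spec=spec,
        params=params,
        minus2LL=float(m2ll),
        n_free_params=codec.n_free,
        n_pairs_used=fd.n_pairs_used,
        converged=bool(best.success),
        theta=theta_hat,
        optimizer_status=str(best.message),
    )
    if not best.success:
        warnings.warn(f"optimizer did not report convergence: {best.message}")
    return fit


def _theta_from_params(codec: _Codec,
                       params: CPParameterSet | IPParameterSet) -> np.ndarray:
    n = codec.n
    gc = codec.group_col
    if isinstance(codec, _CPCodec):
        if not isinstance(params, CPParameterSet):
            raise TypeError("CP spec needs a CPParameterSet start")
        lam = params.lambda_p.values
        f_raw = np.column_stack([params.factor_paths[:, _COMP_COL[c]]
                                 for c in codec.comps])
        u_raw = np.column_stack([np.abs(params.unique_paths[:, _COMP_COL[c]])
                                 for c in codec.ucomps])
        return np.concatenate([lam[:, 0], lam[np.arange(n), 1 + gc],
                               f_raw.ravel(), u_raw.T.ravel()])
    if not isinstance(params, IPParameterSet):
        raise TypeError("IP spec needs an IPParameterSet start")
    pieces = []
    for cmp in codec.comps:
        lam = params.source(cmp).values
        pieces.extend([lam[:, 0], lam[np.arange(n), 1 + gc]])
    u_raw = np.column_stack([np.abs(params.unique_paths[:, _COMP_COL[c]])
                             for c in codec.ucomps])
    pieces.append(u_raw.T.ravel())
    return np.concatenate(pieces)


def _fix_signs(codec: _Codec, theta: np.ndarray) -> np.ndarray:
    """Flip loading columns to nonnegative sums (likelihood invariant)."""
    theta = theta.copy()
    n = codec.n
    gc = codec.group_col
    n_lam_blocks = 1 if isinstance(codec, _CPCodec) else len(codec.comps)
    for b in range(n_lam_blocks):
        off = b * 2 * n
        gen = theta[off:off + n]
        if gen.sum() < 0:
            theta[off:off + n] = -gen
        grp = theta[off + n:off + 2 * n]
        for g in range(codec.nf - 1):
            sel = gc == g
            if grp[sel].sum() < 0:
                grp[sel] = -grp[sel]
        theta[off + n:off + 2 * n] = grp
    return theta


# ---------------------------------------------------------------------------
# Saturated and independence reference models
# ---------------------------------------------------------------------------

def _em_covariance(pats: list[_Pattern], p: int, max_iter: int = 500,
                   tol: float = 1e-7) -> np.ndarray:
    """EM estimate of an unstructured covariance (zero means) from one
    zygosity's pattern summaries, handling missingness."""
    # init from per-variable observed mean squares
    diag = np.zeros(p)
    cnt = np.zeros(p)
    for pt in pats:
        diag[pt.obs] += np.diag(pt.M)
        cnt[pt.obs] += pt.n
    diag = np.where(cnt > 0, diag / np.maximum(cnt, 1), 1.0)
    sigma = np.diag(np.maximum(diag, 1e-6))
    n_total = sum(pt.n for pt in pats)
    for _ in range(max_iter):
        T = np.zeros((p, p))
        for pt in pats:
            o = pt.obs
            mis = np.setdiff1d(np.arange(p), o)
            Soo = sigma[np.ix_(o, o)]
            c, low = cho_factor(Soo, check_finite=False)
            T[np.ix_(o, o)] += pt.M
            if mis.size:
                Smo = sigma[np.ix_(mis, o)]
                B = cho_solve((c, low), Smo.T, check_finite=False).T  # Smo Soo^-1
                BM = B @ pt.M
                T[np.ix_(mis, o)] += BM
                T[np.ix_(o, mis)] += BM.T
                cond = sigma[np.ix_(mis, mis)] - B @ Smo.T
                T[np.ix_(mis, mis)] += BM @ B.T + pt.n * cond
        new = T / n_total
        delta = np.max(np.abs(new - sigma))
        sigma = new
        if delta < tol:
            break
    return sigma


def fit_saturated(data: TwinPairDataset) -> FitResult:
    """Unstructured covariance per zygosity (means fixed at zero).

    Closed form with complete data; EM for the FIML estimate otherwise.
    """
    fd = _FIMLData(data)
    p = fd.p
    sigma = {}
    for z in ("MZ", "DZ"):
        pats = fd.patterns[z]
        n_z = sum(pt.n for pt in pats)
        if n_z == 0:
            sigma[z] = np.eye(p)
            continue
        if len(pats) == 1 and pats[0].obs.size == p:
            sigma[z] = pats[0].M / pats[0].n
        else:
            sigma[z] = _em_covariance(pats, p)
    m2ll, _ = fd.minus2ll_and_G(sigma, want_grad=False)
    return FitResult(spec=None, params=None, minus2LL=float(m2ll),
                     n_free_params=2 * p * (p + 1) // 2,
                     n_pairs_used=fd.n_pairs_used, converged=True,
                     optimizer_status="saturated")


def fit_independence(data: TwinPairDataset) -> FitResult:
    """Diagonal covariance per zygosity, zero cross-twin covariance."""
    fd = _FIMLData(data)
    p = fd.p
    sigma = {}
    for z in ("MZ", "DZ"):
        ssq = np.zeros(p)
        cnt = np.zeros(p)
        for pt in fd.patterns[z]:
            ssq[pt.obs] += np.diag(pt.M)
            cnt[pt.obs] += pt.n
        v = np.where(cnt > 0, ssq / np.maximum(cnt, 1), 1.0)
        sigma[z] = np.diag(np.maximum(v, 1e-12))
    m2ll, _ = fd.minus2ll_and_G(sigma, want_grad=False)
    return FitResult(spec=None, params=None, minus2LL=float(m2ll),
                     n_free_params=2 * p, n_pairs_used=fd.n_pairs_used,
                     converged=True, optimizer_status="independence")


# ---------------------------------------------------------------------------
# Standardized effects
# ---------------------------------------------------------------------------

def standardized_effects(params: CPParameterSet | IPParameterSet) -> pd.DataFrame:
    """Per-item squared standardized effects by source (A/C/E) and level.

    Levels are ``general``, one per group factor, and ``unique``; each
    item's row sums to 1 (squared paths divided by the model-implied item
    variance).
    """
    s = params.structure
    levels = ["general", *s.group_names, "unique"]
    cols = pd.MultiIndex.from_product([("A", "C", "E"), levels],
                                      names=["source", "level"])
    out = np.zeros((s.n_items, len(cols)))
    up2 = params.unique_paths**2
    if isinstance(params, CPParameterSet):
        lam2 = params.lambda_p.values**2
        fp2 = params.factor_paths**2
        v = lam2.sum(axis=1) + up2.sum(axis=1)
        for si, src in enumerate(("A", "C", "E")):
            for f in range(s.n_factors):
                out[:, si * len(levels) + f] = lam2[:, f] * fp2[f, si] / v
            out[:, si * len(levels) + len(levels) - 1] = up2[:, si] / v
    else:
        lam2 = {c: params.source(c).values**2 for c in ("A", "C", "E")}
        v = sum(m.sum(axis=1) for m in lam2.values()) + up2.sum(axis=1)
        for si, src in enumerate(("A", "C", "E")):
            for f in range(s.n_factors):
                out[:, si * len(levels) + f] = lam2[src][:, f] / v
            out[:, si * len(levels) + len(levels) - 1] = up2[:, si] / v
    return pd.DataFrame(out, columns=cols,
                        index=pd.Index(s.item_labels, name="item"))


def shares_within_source(means: Sequence[float]) -> np.ndarray:
    """Normalize level means (general, groups..., unique) to shares."""
    m = np.asarray(means, dtype=float)
    total = m.sum()
    if total <= 0:
        raise ValueError("source total must be positive")
    return m / total


def aggregate_standardized_effects(fit: FitResult | pd.DataFrame) -> dict:
    """Mean squared standardized effects across items, by source and level,
    plus each level's share of its source total."""
    table = fit.standardized if isinstance(fit, FitResult) else fit
    if table is None:
        raise ValueError("fit carries no standardized table")
    means = table.mean(axis=0)
    out: dict = {}
    for src in ("A", "C", "E"):
        m = means[src]
        total = float(m.sum())
        shares = (m / total) if total > 0 else m * 0.0
        out[src] = {
            "means": {lvl: float(v) for lvl, v in m.items()},
            "total": total,
            "shares": {lvl: float(v) for lvl, v in shares.items()},
        }
    return out
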