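"""Model comparison and uncertainty: RMSEA/CFI/AIC/BIC, likelihood-ratio
tests, stratified pair bootstrap, and general-factor indices of the fitted
source-specific loading matrices of an independent pathway model."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import TwinPairDataset
from .psychometrics import IndexReport, ecv, h_index, omega_hierarchical
from .twin_sem import FitResult, IPParameterSet, ModelSpec, fit_model

__all__ = [
    "FitStatistics",
    "LRTResult",
    "fit_statistics",
    "lrt",
    "bootstrap_ci",
    "twin_bifactor_indices",
]


@dataclass
class FitStatistics:
    minus2LL: float
    aic: float
    bic: float
    rmsea: float
    cfi: float
    df: int
    chi2_vs_saturated: float
    n_free_params: int
    n: int

    def __post_init__(self) -> None:
        if abs(self.aic - (self.minus2LL + 2 * self.n_free_params)) > 1e-8:
            raise ValueError("AIC identity violated")
        if abs(self.bic - (self.minus2LL + self.n_free_params * np.log(self.n))) > 1e-8:
            raise ValueError("BIC identity violated")

    def to_dict(self) -> dict:
        return {
            "minus2LL": self.minus2LL, "aic": self.aic, "bic": self.bic,
            "rmsea": self.rmsea, "cfi": self.cfi, "df": self.df,
            "chi2_vs_saturated": self.chi2_vs_saturated,
            "n_free_params": self.n_free_params, "n": self.n,
        }


@dataclass
class LRTResult:
    delta_chi2: float
    delta_df: int
    p_value: float

    def to_dict(self) -> dict:
        return {"delta_chi2": self.delta_chi2, "delta_df": self.delta_df,
                "p_value": self.p_value}


def fit_statistics(fit: FitResult, saturated_fit: FitResult,
                   independence_fit: FitResult, N: int | None = None) -> FitStatistics:
    """Five fit statistics of a model against saturated/independence fits.

    ``chi2 = -2LL_model - (-2LL_saturated)`` with ``df = k_sat - k_model``;
    ``RMSEA = sqrt(max(0, chi2 - df) / (df (N - 1)))``; CFI relative to the
    independence baseline, clipped to [0, 1].  ``N`` defaults to the number
    of twin pairs used (the pair is the sampling unit); pass the number of
    individuals to use that convention instead.
    """
    if N is None:
        N = fit.n_pairs_used
    chi2_m = max(0.0, fit.minus2LL - saturated_fit.minus2LL)
    df_m = saturated_fit.n_free_params - fit.n_free_params
    if df_m <= 0:
        raise ValueError("model has no fewer parameters than the saturated model")
    chi2_b = max(0.0, independence_fit.minus2LL - saturated_fit.minus2LL)
    df_b = saturated_fit.n_free_params - independence_fit.n_free_params
    rmsea = float(np.sqrt(max(0.0, chi2_m - df_m) / (df_m * (N - 1))))
    denom = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(0.0, chi2_m - df_m) / denom
    cfi = float(np.clip(cfi, 0.0, 1.0))
    k = fit.n_free_params
    return FitStatistics(
        minus2LL=fit.minus2LL,
        aic=fit.minus2LL + 2 * k,
        bic=fit.minus2LL + k * float(np.log(N)),
        rmsea=rmsea,
        cfi=cfi,
        df=df_m,
        chi2_vs_saturated=chi2_m,
        n_free_params=k,
        n=N,
    )


def lrt(full: FitResult, nested: FitResult) -> LRTResult:
    """Likelihood-ratio test of a nested model against its full version.

    Boundary components are tested with the ordinary chi-square reference
    (no mixture correction).
    """
    if full.spec is not None and nested.spec is not None:
        if not nested.spec.is_nested_in(full.spec):
            raise ValueError("models are not nested")
    delta_df = full.n_free_params - nested.n_free_params
    if delta_df < 0:
        raise ValueError("nested model has more free parameters than the full model")
    delta_chi2 = max(0.0, nested.minus2LL - full.minus2LL)
    p = 1.0 if delta_df == 0 else float(stats.chi2.sf(delta_chi2, delta_df))
    return LRTResult(delta_chi2=float(delta_chi2), delta_df=int(delta_df), p_value=p)


def bootstrap_ci(data: TwinPairDataset, spec: ModelSpec, B: int, seed: int,
                 statistic, level: float = 0.95, point_fit: FitResult | None = None,
                 **fit_kwargs) -> dict:
    """Percentile bootstrap intervals for model statistics.

    Pairs are resampled with replacement within zygosity strata; each
    replicate is refit starting from the point estimate.  ``statistic`` maps
    a :class:`FitResult` to a dict of floats.  Non-converged replicates are
    dropped (the result is flagged when more than 5% drop).
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    fit_kwargs.setdefault("n_starts", 1)
    if point_fit is None:
        point_fit = fit_model(data, spec, seed=seed, **fit_kwargs)
    point_stats = statistic(point_fit)
    idx_mz = np.where(data.zygosity_mask("MZ"))[0]
    idx_dz = np.where(data.zygosity_mask("DZ"))[0]
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {k: [] for k in point_stats}
    n_failed = 0
    for _ in range(B):
        take = np.concatenate([
            rng.choice(idx_mz, size=idx_mz.size, replace=True),
            rng.choice(idx_dz, size=idx_dz.size, replace=True),
        ])
        boot = data.subset(take)
        # duplicate pair ids are fine here; resampled rows are new units
        boot.pair_ids = np.array([f"b{i}" for i in range(len(take))], dtype=object)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = fit_model(boot, spec, start=point_fit.theta, **fit_kwargs)
        except (np.linalg.LinAlgError, ValueError):
            n_failed += 1
            continue
        if not rep.converged:
            n_failed += 1
            continue
        for k, v in statistic(rep).items():
            draws[k].append(v)
    alpha = (1.0 - level) / 2.0
    out = {
        "point": point_stats,
        "intervals": {},
        "B": B,
        "n_failed": n_failed,
        "flagged": n_failed > 0.05 * B,
    }
    if n_failed > 0.05 * B:
        warnings.warn(f"{n_failed}/{B} bootstrap replicates failed to converge")
    for k, vals in draws.items():
        arr = np.asarray(vals)
        out["intervals"][k] = (
            float(np.percentile(arr, 100 * alpha)),
            float(np.percentile(arr, 100 * (1 - alpha))),
        ) if arr.size else (np.nan, np.nan)
    return out


def twin_bifactor_indices(fit: FitResult) -> dict[str, IndexReport]:
    """General-factor indices (omega_h, H, ECV) per variance source.

    Only defined for independent pathway fits: each source's loadings are
    standardized by the model-implied item standard deviations; omega_h uses
    the full model-implied composite variance in its denominator (all
    sources' common terms plus all unique variances), while H and ECV are
    evaluated on the source's own standardized matrix.
    """
    params = fit.params
    if not isinstance(params, IPParameterSet):
        raise ValueError("per-source indices are only defined for IP-family fits")
    lam = {c: params.source(c).values for c in ("A", "C", "E")}
    up2 = params.unique_paths**2
    v = sum((m**2).sum(axis=1) for m in lam.values()) + up2.sum(axis=1)
    sd = np.sqrt(v)
    std = {c: lam[c] / sd[:, None] for c in lam}
    u_std = up2.sum(axis=1) / v
    colsumsq = {c: np.sum(std[c].sum(axis=0) ** 2) for c in std}
    out = {}
    for c in ("A", "C", "E"):
        extra = sum(colsumsq[o] for o in std if o != c)
        gen = np.clip(std[c][:, 0], -0.999999, 0.999999)
        out[c] = IndexReport(
            omega_h=omega_hierarchical(std[c], u_std, extra_common=extra),
            h_index=h_index(gen),
            ecv=ecv(std[c]),
            label=f"{c} general factor",
        )
    return out
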