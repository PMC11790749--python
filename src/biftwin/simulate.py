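"""Twin-pair data simulator for bifactor ACE models.

Generates MZ/DZ pairs from a common pathway or independent pathway
parameter set: additive-genetic components correlate 1 (MZ) or 0.5 (DZ)
across co-twins, shared-environment components are identical within a pair,
and non-shared components are independent — at both the factor/source level
and the item-unique level.  Optional ordinalization to 0-3 scores and MCAR
masking.  Each pair draws from its own spawned random stream, so enlarging
the sample leaves earlier pairs unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BifactorStructure, CPParameterSet, IPParameterSet, TwinPairDataset

__all__ = ["SimulationConfig", "simulate_twins", "DEFAULT_THRESHOLDS"]

# Cuts on the latent standard-normal scale giving a right-skewed 0-3 score
# distribution (population mean total for 20 items near 13.5 of 60).
DEFAULT_THRESHOLDS = (0.0, 1.0, 2.0)

_R_ADDITIVE = {"MZ": 1.0, "DZ": 0.5}


@dataclass
class SimulationConfig:
    n_MZ: int
    n_DZ: int
    params: CPParameterSet | IPParameterSet
    missing_rate: float = 0.0
    mask_whole_twin: bool = False
    ordinalize: bool = False
    thresholds: tuple[float, float, float] | None = None
    seed: int = 0
    covariate_effects: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_MZ < 0 or self.n_DZ < 0:
            raise ValueError("pair counts must be nonnegative")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.thresholds is not None:
            t = tuple(float(x) for x in self.thresholds)
            if len(t) != 3 or not (t[0] < t[1] < t[2]):
                raise ValueError("thresholds must be 3 strictly increasing cuts")
            self.thresholds = t


def _shared_pair(rng: np.random.Generator, size: int, r: float) -> np.ndarray:
    """Draw (2, size) standard-normal with cross-twin correlation r."""
    common = rng.standard_normal(size)
    indiv = rng.standard_normal((2, size))
    return np.sqrt(r) * common + np.sqrt(1.0 - r) * indiv


def _pair_items_cp(rng: np.random.Generator, params: CPParameterSet, r: float) -> np.ndarray:
    lam = params.lambda_p.values
    a_F, c_F, e_F = params.factor_paths.T
    a_u, c_u, e_u = params.unique_paths.T
    nf, n = lam.shape[1], lam.shape[0]
    A_f = _shared_pair(rng, nf, r)
    C_f = np.broadcast_to(rng.standard_normal(nf), (2, nf))
    E_f = rng.standard_normal((2, nf))
    F = a_F * A_f + c_F * C_f + e_F * E_f
    A_u = _shared_pair(rng, n, r)
    C_u = np.broadcast_to(rng.standard_normal(n), (2, n))
    E_u = rng.standard_normal((2, n))
    return F @ lam.T + a_u * A_u + c_u * C_u + e_u * E_u


def _pair_items_ip(rng: np.random.Generator, params: IPParameterSet, r: float) -> np.ndarray:
    lamA, lamC, lamE = (params.lambda_A.values, params.lambda_C.values,
                        params.lambda_E.values)
    a_u, c_u, e_u = params.unique_paths.T
    nf, n = lamA.shape[1], lamA.shape[0]
    A_f = _shared_pair(rng, nf, r)
    C_f = np.broadcast_to(rng.standard_normal(nf), (2, nf))
    E_f = rng.standard_normal((2, nf))
    A_u = _shared_pair(rng, n, r)
    C_u = np.broadcast_to(rng.standard_normal(n), (2, n))
    E_u = rng.standard_normal((2, n))
    return (A_f @ lamA.T + C_f @ lamC.T + E_f @ lamE.T
            + a_u * A_u + c_u * C_u + e_u * E_u)


def simulate_twins(config: SimulationConfig,
                   structure: BifactorStructure | None = None) -> TwinPairDataset:
    """Generate a :class:`TwinPairDataset` from a parameter set.

    Covariates (age, sex, cohort) are drawn per twin pair; by default they
    do not influence item scores, but linear per-item effects can be added
    via ``config.covariate_effects`` (keys ``age``/``sex``/``cohort``,
    values length-n coefficient vectors) to exercise residualization.
    """
    params = config.params
    if structure is None:
        structure = params.structure
    elif structure != params.structure:
        raise ValueError("structure does not match the parameter set")
    is_cp = isinstance(params, CPParameterSet)
    if is_cp:
        params.check_standardized(tol=1e-6)

    n_pairs = config.n_MZ + config.n_DZ
    n = structure.n_items
    zyg = np.array(["MZ"] * config.n_MZ + ["DZ"] * config.n_DZ, dtype=object)
    items = np.empty((n_pairs, 2, n))
    covs = np.empty((n_pairs, 2, 3))

    streams = np.random.SeedSequence(config.seed).spawn(n_pairs)
    for p in range(n_pairs):
        rng = np.random.default_rng(streams[p])
        r = _R_ADDITIVE[zyg[p]]
        x = (_pair_items_cp(rng, params, r) if is_cp
             else _pair_items_ip(rng, params, r))
        # shared covariates: same age/cohort per pair, sex per twin
        age = 21.0 + 2.0 * rng.random()
        cohort = float(rng.integers(0, 3))
        sex = rng.integers(0, 2, size=2).astype(float)
        covs[p, :, 0] = age
        covs[p, :, 1] = sex
        covs[p, :, 2] = cohort
        for name, col in (("age", 0), ("sex", 1), ("cohort", 2)):
            beta = config.covariate_effects.get(name)
            if beta is not None:
                x = x + covs[p, :, col][:, None] * np.asarray(beta)

        if config.ordinalize:
            cuts = np.asarray(config.thresholds or DEFAULT_THRESHOLDS)
            x = np.searchsorted(cuts, x).astype(float)

        if config.missing_rate > 0:
            if config.mask_whole_twin:
                mask = np.repeat(rng.random(2) < config.missing_rate, n).reshape(2, n)
            else:
                mask = rng.random((2, n)) < config.missing_rate
            x = np.where(mask, np.nan, x)
        items[p] = x

    return TwinPairDataset(
        pair_ids=np.array([f"p{p + 1:06d}" for p in range(n_pairs)], dtype=object),
        zygosity=zyg,
        items=items,
        covariates=covs,
    )
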