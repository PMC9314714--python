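"""Confounded logistic data-generating models for simulation studies.

The exposure follows a logistic model in the instruments and a shared
standard-normal confounder ``U``:

    logit P(X=1 | Z=z, U=u) = gamma0 + sum_i gamma_i z_i + gammaU u

and the binary outcome follows

    logit P(Y=1 | X=x, Z=z, U=u) = beta0 + betaX x + betaZ z + betaU u,

with ``betaZ = 0`` under a valid instrument (exclusion restriction) and
``betaZ != 0`` modelling pleiotropy.  Genotypes take values 0/1/2 with the
balanced default ``P(Z=0)=P(Z=2)=0.25, P(Z=1)=0.5``.  From these models the
module derives the population marginals ``P(X=1|Z_j=z)``, ``P(Y=1|Z_j=z)``
(exact Gauss-Hermite quadrature for a single instrument, seeded Monte Carlo
when other instruments must be marginalized out), the true ATE, the
strength curve ``ST(gamma1)`` and its inverse, the smallest instrument
effect that makes a bound informative, the multi-instrument scenario
builders, the pleiotropy sensitivity grid, and a continuous-exposure model
with median dichotomization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .bounds import instrument_strength, iv_inequality_check, two_sample_bounds
from .tables import MarginalTable

__all__ = [
    "DEFAULT_GENOTYPE_DIST",
    "ExposureModel",
    "OutcomeModel",
    "ContinuousExposureModel",
    "exposure_prob",
    "model_marginals",
    "all_instrument_marginals",
    "ate",
    "st_to_gamma1",
    "smallest_gamma_excluding_zero",
    "scenario_gammas",
    "pleiotropy_grid",
    "dichotomized_experiment",
]

logger = logging.getLogger(__name__)

#: Balanced genotype distribution for z in {0, 1, 2} (allele frequency 1/2
#: under Hardy-Weinberg equilibrium), the default in all illustrations.
DEFAULT_GENOTYPE_DIST = np.array([0.25, 0.5, 0.25])

# 64-node Gauss-Hermite rule; for the expit integrand against a standard
# normal the quadrature error is far below 1e-12.
_GH_X, _GH_W = np.polynomial.hermite.hermgauss(64)
_GH_NODES = np.sqrt(2.0) * _GH_X
_GH_WEIGHTS = _GH_W / np.sqrt(np.pi)


def _gauss_std_normal(f):
    """E[f(U)] for U ~ N(0,1); f must accept an array of nodes."""
    return f(_GH_NODES) @ _GH_WEIGHTS


@dataclass(frozen=True)
class ExposureModel:
    """Logistic exposure model coefficients (confounder is standard normal)."""

    gamma0: float
    gammas: np.ndarray
    gammaU: float

    def __post_init__(self):
        g = np.atleast_1d(np.asarray(self.gammas, dtype=float))
        if g.size == 0 or not np.all(np.isfinite(g)):
            raise ValueError("gammas must be a non-empty finite vector")
        if not (np.isfinite(self.gamma0) and np.isfinite(self.gammaU)):
            raise ValueError("coefficients must be finite")
        g.setflags(write=False)
        object.__setattr__(self, "gammas", g)

    @property
    def n_instruments(self) -> int:
        return self.gammas.size


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic outcome model; ``betaZ != 0`` encodes a pleiotropic path."""

    beta0: float
    betaX: float
    betaU: float
    betaZ: float = 0.0

    def __post_init__(self):
        vals = (self.beta0, self.betaX, self.betaU, self.betaZ)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("coefficients must be finite")


@dataclass(frozen=True)
class ContinuousExposureModel:
    """Linear model for a continuous exposure, later median-dichotomized.

    ``X~ = gamma0 + gamma1 Z + gammaU U + eps`` with ``U, eps ~ N(0,1)``;
    the analysis exposure is ``X = 1[X~ >= median(X~)]``.
    """

    gamma1: float
    gammaU: float
    gamma0: float = 0.0


def exposure_prob(model: ExposureModel, z) -> float:
    """``P(X=1 | Z=z)``, integrating the confounder out by quadrature."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if z.size != model.n_instruments:
        raise ValueError(
            f"z has {z.size} entries but the model has "
            f"{model.n_instruments} instruments"
        )
    lin = model.gamma0 + float(model.gammas @ z)
    if model.gammaU == 0.0:
        return float(expit(lin))
    return float(_gauss_std_normal(lambda u: expit(lin + model.gammaU * u)))


def ate(om: OutcomeModel, p_z=None) -> float:
    """True average treatment effect ``E[Y1 - Y0]`` implied by the model.

    Integrates the risk difference over the confounder; with a pleiotropic
    direct effect (``betaZ != 0``) the potential outcomes depend on the
    instrument too, so the genotype distribution ``p_z`` is averaged over
    as well and must be supplied.
    """
    if om.betaZ != 0.0:
        if p_z is None:
            raise ValueError("p_z is required when betaZ != 0")
        p_z = np.asarray(p_z, dtype=float)
        levels = np.arange(p_z.size)
        total = 0.0
        for z, w in zip(levels, p_z):
            total += w * _gauss_std_normal(
                lambda u: expit(om.beta0 + om.betaX + om.betaZ * z + om.betaU * u)
                - expit(om.beta0 + om.betaZ * z + om.betaU * u)
            )
        return float(total)
    return float(
        _gauss_std_normal(
            lambda u: expit(om.beta0 + om.betaX + om.betaU * u)
            - expit(om.beta0 + om.betaU * u)
        )
    )


def _marginals_single(em: ExposureModel, om: OutcomeModel, n_levels: int = 3):
    """Exact quadrature marginals for a single-instrument model."""
    g1 = float(em.gammas[0])
    p_x = np.empty(n_levels)
    p_y = np.empty(n_levels)
    for z in range(n_levels):
        lin_x = em.gamma0 + g1 * z

        def integrand_x(u):
            return expit(lin_x + em.gammaU * u)

        def integrand_y(u):
            px_u = expit(lin_x + em.gammaU * u)
            base = om.beta0 + om.betaZ * z + om.betaU * u
            return expit(base + om.betaX) * px_u + expit(base) * (1.0 - px_u)

        p_x[z] = _gauss_std_normal(integrand_x)
        p_y[z] = _gauss_std_normal(integrand_y)
    return MarginalTable(p_x=p_x, p_y=p_y)


def model_marginals(
    em: ExposureModel,
    om: OutcomeModel,
    instrument_index: int = 0,
    p_z=None,
    mc_n: int | None = None,
    seed: int | None = None,
) -> MarginalTable:
    """Population ``P(X=1|Z_j=z)``, ``P(Y=1|Z_j=z)`` for one instrument.

    With a single instrument the confounder integral is evaluated exactly
    by Gauss-Hermite quadrature.  With several mutually independent
    instruments (each distributed ``p_z``) the others are marginalized out
    by Monte Carlo with ``mc_n`` draws (default 10^6) and the given seed;
    common random numbers are shared across the three conditioning levels.
    """
    p = em.n_instruments
    if not 0 <= instrument_index < p:
        raise ValueError("instrument_index out of range")
    if p_z is None:
        p_z = DEFAULT_GENOTYPE_DIST
    p_z = np.asarray(p_z, dtype=float)
    n_levels = p_z.size
    if p == 1:
        return _marginals_single(em, om, n_levels)
    if mc_n is None:
        mc_n = 1_000_000
    if mc_n < 10_000:
        logger.warning("mc_n=%d is small; Monte Carlo marginals will be noisy", mc_n)
    rng = np.random.default_rng(seed)
    j = instrument_index
    others = np.delete(np.arange(p), j)
    z_other = rng.choice(n_levels, size=(mc_n, others.size), p=p_z)
    u = rng.standard_normal(mc_n)
    partial = z_other @ em.gammas[others] + em.gammaU * u
    gj = em.gammas[j]
    p_x = np.empty(n_levels)
    p_y = np.empty(n_levels)
    for z in range(n_levels):
        px_u = expit(em.gamma0 + partial + gj * z)
        base = om.beta0 + om.betaZ * z + om.betaU * u
        py_u = expit(base + om.betaX) * px_u + expit(base) * (1.0 - px_u)
        p_x[z] = px_u.mean()
        p_y[z] = py_u.mean()
    return MarginalTable(p_x=p_x, p_y=p_y)


def all_instrument_marginals(
    em: ExposureModel,
    om: OutcomeModel,
    p_z=None,
    mc_n: int = 1_000_000,
    seed: int | None = None,
) -> list[MarginalTable]:
    """Marginal tables for every instrument of a multi-instrument model.

    One shared set of Monte Carlo draws of ``(Z, U)`` serves all
    instruments: conditioning instrument ``j`` on level ``z`` only swaps the
    ``gamma_j Z_j`` term of the precomputed linear predictor, so the cost is
    linear in ``p`` rather than quadratic.  Common random numbers across
    levels make the per-instrument strength estimates smooth.
    """
    p = em.n_instruments
    if p == 1:
        return [_marginals_single(em, om)]
    if p_z is None:
        p_z = DEFAULT_GENOTYPE_DIST
    p_z = np.asarray(p_z, dtype=float)
    n_levels = p_z.size
    if mc_n < 10_000:
        logger.warning("mc_n=%d is small; Monte Carlo marginals will be noisy", mc_n)
    rng = np.random.default_rng(seed)
    z_mat = np.searchsorted(np.cumsum(p_z), rng.uniform(size=(mc_n, p)),
                            side="right").astype(np.int8)
    u = rng.standard_normal(mc_n)
    lin = em.gamma0 + z_mat @ em.gammas + em.gammaU * u
    # outcome pieces depend on (z, u) only, not on which instrument j
    e1 = [expit(om.beta0 + om.betaX + om.betaZ * z + om.betaU * u)
          for z in range(n_levels)]
    e0 = [expit(om.beta0 + om.betaZ * z + om.betaU * u)
          for z in range(n_levels)]
    out = []
    for j in range(p):
        base = lin - em.gammas[j] * z_mat[:, j]
        p_x = np.empty(n_levels)
        p_y = np.empty(n_levels)
        for z in range(n_levels):
            px_u = expit(base + em.gammas[j] * z)
            p_x[z] = px_u.mean()
            p_y[z] = (e1[z] * px_u + e0[z] * (1.0 - px_u)).mean()
        out.append(MarginalTable(p_x=p_x, p_y=p_y))
    return out


def _st_of_gamma1(gamma1: float, gammaU: float, n_levels: int = 3) -> float:
    em = ExposureModel(gamma0=-gamma1, gammas=np.array([gamma1]), gammaU=gammaU)
    probs = [exposure_prob(em, [z]) for z in range(n_levels)]
    return instrument_strength(probs)


def st_to_gamma1(
    target_st: float, gammaU: float, bracket: tuple[float, float] = (1e-9, 50.0)
) -> float:
    """Instrument coefficient ``gamma1`` achieving strength ``ST = target``.

    Uses the centering convention ``gamma0 = -gamma1`` (the instrument has
    mean genotype 1 under the balanced distribution, so the linear predictor
    is centred).  ``ST(gamma1)`` is continuous and strictly increasing for
    ``gamma1 > 0``, so bracketed root finding applies.
    """
    if not 0.0 < target_st < 1.0:
        raise ValueError("target strength must lie strictly between 0 and 1")
    lo, hi = bracket
    f = lambda g: _st_of_gamma1(g, gammaU) - target_st
    if f(hi) < 0:
        raise ValueError(
            f"target ST={target_st} not reachable with gamma1 <= {hi}"
        )
    return float(brentq(f, lo, hi, xtol=1e-10))


def smallest_gamma_excluding_zero(
    om: OutcomeModel,
    gammaU: float,
    gamma_max: float = 8.0,
    grid_size: int = 33,
    tol: float = 1e-4,
) -> float | None:
    """Smallest ``gamma1 > 0`` whose two-sample bound excludes zero.

    Scans a grid on ``(0, gamma_max]`` for the first instrument coefficient
    (with ``gamma0 = -gamma1``) whose closed-form two-sample bound excludes
    0 while still covering the model's true ATE, then refines by bisection
    to ``tol``.  Returns ``None`` when no grid point qualifies — e.g. under
    a null exposure effect, where valid bounds always cover the ATE of 0.
    """
    true_ate = ate(om, DEFAULT_GENOTYPE_DIST if om.betaZ != 0.0 else None)
    sign = np.sign(om.betaX)

    def qualifies(g1: float) -> bool:
        em = ExposureModel(gamma0=-g1, gammas=np.array([g1]), gammaU=gammaU)
        b = two_sample_bounds(model_marginals(em, om))
        if b.crossed or not b.contains(true_ate, tol=1e-9):
            return False
        if sign > 0:
            return b.lower > 0
        if sign < 0:
            return b.upper < 0
        return False

    grid = np.linspace(0.0, gamma_max, grid_size)[1:]
    hit = None
    for g in grid:
        if qualifies(g):
            hit = g
            break
    if hit is None:
        return None
    lo = hit - (grid[1] - grid[0])
    hi = hit
    if lo <= 0 or qualifies(lo):
        return float(hi if lo <= 0 else lo)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if qualifies(mid):
            hi = mid
        else:
            lo = mid
    return float(hi)


def scenario_gammas(scenario: int, p: int) -> np.ndarray:
    """Instrument-effect vectors for the four multi-instrument scenarios.

    1. many weak instruments: evenly spaced on [0, 0.2];
    2. many strong instruments: evenly spaced on [1, 4];
    3. many very weak plus one medium: p-1 values on [0, 0.01], last 0.2;
    4. many medium plus one strong: p-1 values on [1, 1.2], last 4.
    """
    if p < 2:
        raise ValueError("scenarios need at least two instruments")
    if scenario == 1:
        return np.linspace(0.0, 0.2, p)
    if scenario == 2:
        return np.linspace(1.0, 4.0, p)
    if scenario == 3:
        return np.append(np.linspace(0.0, 0.01, p - 1), 0.2)
    if scenario == 4:
        return np.append(np.linspace(1.0, 1.2, p - 1), 4.0)
    raise ValueError(f"unknown scenario {scenario!r}; valid: 1, 2, 3, 4")


#: Coefficient grid for the pleiotropy sensitivity study.
PLEIOTROPY_GRID = {
    "betaX": (-2.0, -1.0, 0.0, 1.0, 2.0),
    "betaZ": (-0.5, -0.25, -0.1, 0.0, 0.1, 0.25, 0.5),
    "gamma1": (-0.5, -0.25, -0.1, 0.0, 0.1, 0.25, 0.5),
}


def pleiotropy_grid(grid: dict | None = None, gammaU: float = 1.0,
                    betaU: float = 1.0) -> list[dict]:
    """Bounds under exclusion-restriction violations over a coefficient grid.

    For every cell of ``betaX x betaZ x gamma1`` (defaults as in
    :data:`PLEIOTROPY_GRID`, with ``beta0 = -betaX/2``, ``gamma0 = -gamma1``
    and unit confounding) the single-instrument marginals are computed under
    the pleiotropic outcome model, and the two-sample bounds, IV-inequality
    flag and true-ATE coverage are recorded.
    """
    if grid is None:
        grid = PLEIOTROPY_GRID
    rows = []
    for betaX in grid["betaX"]:
        for betaZ in grid["betaZ"]:
            for gamma1 in grid["gamma1"]:
                em = ExposureModel(
                    gamma0=-gamma1, gammas=np.array([gamma1]), gammaU=gammaU
                )
                om = OutcomeModel(
                    beta0=-betaX / 2.0, betaX=betaX, betaU=betaU, betaZ=betaZ
                )
                m = model_marginals(em, om)
                b = two_sample_bounds(m)
                true_ate = ate(om, DEFAULT_GENOTYPE_DIST)
                rows.append({
                    "betaX": betaX,
                    "betaZ": betaZ,
                    "gamma1": gamma1,
                    "st": instrument_strength(m.p_x),
                    "marginals": m,
                    "bounds": b,
                    "ate": true_ate,
                    "iv_pass": iv_inequality_check(m).passed,
                    "covers_ate": b.contains(true_ate, tol=1e-9),
                })
    return rows


@dataclass(frozen=True)
class SignReport:
    """Direction inferred from a dichotomized-exposure bound."""

    inferred_sign: int  # -1, 0 (bounds cover zero), +1
    true_sign: int
    consistent: bool


def dichotomized_experiment(
    cm: ContinuousExposureModel,
    om: OutcomeModel,
    n: int = 10_000_000,
    seed: int | None = None,
    p_z=None,
):
    """Two-sample bounds after median-dichotomizing a continuous exposure.

    Simulates ``(Z, U, eps) -> X~ -> X = 1[X~ >= median] -> Y`` with the
    outcome driven by the *continuous* exposure
    (``logit P(Y=1|X~, U) = beta0 + betaX X~ + betaZ Z + betaU U``),
    estimates the conditional marginals by plug-in frequencies, and returns
    ``(MarginalTable, AteBounds, SignReport)``.  Under a monotone exposure
    effect, a bound that excludes zero can only do so on the side of
    ``sign(betaX)``.
    """
    if n < 1000:
        raise ValueError("n too small for stable plug-in frequencies")
    if p_z is None:
        p_z = DEFAULT_GENOTYPE_DIST
    p_z = np.asarray(p_z, dtype=float)
    rng = np.random.default_rng(seed)
    z = rng.choice(p_z.size, size=n, p=p_z)
    u = rng.standard_normal(n)
    x_cont = cm.gamma0 + cm.gamma1 * z + cm.gammaU * u + rng.standard_normal(n)
    x = x_cont >= np.median(x_cont)
    if x.all() or not x.any():
        raise ValueError("degenerate dichotomization: exposure is constant")
    y = rng.uniform(size=n) < expit(
        om.beta0 + om.betaX * x_cont + om.betaZ * z + om.betaU * u
    )
    p_x = np.array([x[z == lev].mean() for lev in range(p_z.size)])
    p_y = np.array([y[z == lev].mean() for lev in range(p_z.size)])
    m = MarginalTable(p_x=p_x, p_y=p_y)
    b = two_sample_bounds(m)
    if b.covers_zero or b.crossed:
        inferred = 0
    else:
        inferred = 1 if b.lower > 0 else -1
    true_sign = int(np.sign(om.betaX))
    report = SignReport(
        inferred_sign=inferred,
        true_sign=true_sign,
        consistent=(inferred == 0 or inferred == true_sign),
    )
    return m, b, report
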