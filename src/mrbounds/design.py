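"""What could a one-sample design have shown? Covariance-sampling framework.

A two-sample study observes only the marginals ``P(X=1|Z=z)`` and
``P(Y=1|Z=z)``; the conditional joint needed for the (tighter) one-sample
bounds differs from the product of marginals by the single unidentified
number ``Cov(X, Y | Z=z)`` per level:

    P(X=x, Y=y|Z=z) = P(X=x|Z=z) P(Y=y|Z=z) + (2*I[x=y] - 1) Cov(X,Y|Z=z)

Cell validity confines each covariance to a closed interval, and the
observable one-sample IV inequalities confine every pairwise difference
``Cov(z) - Cov(z')`` to another interval.  Sampling covariance triples
uniformly from this feasible polytope, reconstructing joints and running
the one-sample sharp-bound LP on each yields the distribution of one-sample
bounds that *could* have been obtained — and in particular how often they
would exclude zero, a proxy for how much information the two-sample design
forfeits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bounds import _ordered_pairs, iv_inequality_check
from .lp import lp_sharp_bounds
from .tables import AteBounds, JointTable, MarginalTable

__all__ = [
    "CovTriple",
    "PlausibilitySummary",
    "cov_feasible_interval",
    "pairwise_cov_constraint",
    "sample_cov_triples",
    "joint_from_cov",
    "plausible_one_sample_bounds",
    "multi_instrument_plausibility",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CovTriple:
    """One ``Cov(X, Y|Z=z)`` value per instrument level."""

    cov: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.cov, dtype=float)
        if c.ndim != 1:
            raise ValueError("cov must be a vector")
        if np.any(np.abs(c) > 1.0):
            raise ValueError("covariances of binary variables lie in [-1, 1]")
        c.setflags(write=False)
        object.__setattr__(self, "cov", c)


@dataclass(frozen=True)
class PlausibilitySummary:
    """Summary of sampled plausible one-sample bounds.

    ``frac_excluding_zero = frac_above_zero + frac_below_zero`` counts the
    sampled one-sample bounds lying entirely above or entirely below zero,
    relative to the LP-feasible draws (``n_samples``); ``n_infeasible``
    counts sampled joints rejected by the one-sample LP.
    """

    n_samples: int
    frac_excluding_zero: float
    frac_above_zero: float
    frac_below_zero: float
    bounds: list = field(repr=False)
    n_infeasible: int = 0
    scheme: str = "rejection"
    seed: int | None = None


def _margins(m: MarginalTable, z: int):
    p1 = m.p_x[z]
    q1 = m.p_y[z]
    return p1, 1.0 - p1, q1, 1.0 - q1


def cov_feasible_interval(m: MarginalTable, z: int) -> tuple[float, float]:
    """Range of ``Cov(X, Y|Z=z)`` keeping all four joint cells in [0, 1]."""
    p1, p0, q1, q0 = _margins(m, z)
    lo = max(-p1 * q1, -p0 * q0, p1 * q0 - 1.0, p0 * q1 - 1.0)
    hi = min(1.0 - p1 * q1, 1.0 - p0 * q0, p1 * q0, p0 * q1)
    return lo, hi


def pairwise_cov_constraint(m: MarginalTable, z: int, z2: int) -> tuple[float, float]:
    """Feasible range of ``Cov(X,Y|Z=z) - Cov(X,Y|Z=z2)``.

    These are the one-sample IV inequalities — for each exposure arm the
    joint cells at different levels must be mutually consistent, e.g.
    ``P(X=1,Y=0|Z=z) + P(X=1,Y=1|Z=z2) <= 1`` — rewritten as constraints on
    the covariance difference.
    """
    if z == z2:
        raise ValueError("levels must differ")
    p1, p0, q1, q0 = _margins(m, z)
    r1, r0, s1, s0 = _margins(m, z2)
    lo = max(
        -p0 * q0 - r0 * s1,
        p1 * q0 + r1 * s1 - 1.0,
        r0 * s0 + p0 * q1 - 1.0,
        -r1 * s0 - p1 * q1,
    )
    hi = min(
        1.0 - p0 * q0 - r0 * s1,
        p1 * q0 + r1 * s1,
        r0 * s0 + p0 * q1,
        1.0 - r1 * s0 - p1 * q1,
    )
    return lo, hi


def joint_from_cov(m: MarginalTable, c: CovTriple) -> JointTable:
    """Reconstruct ``P(X=x,Y=y|Z=z)`` from marginals and covariances."""
    cov = c.cov
    if cov.size != m.n_levels:
        raise ValueError("need one covariance per instrument level")
    px, py = m.p_x, m.p_y
    cells = np.empty((2, 2, m.n_levels))
    cells[1, 1] = px * py + cov
    cells[0, 0] = (1 - px) * (1 - py) + cov
    cells[1, 0] = px * (1 - py) - cov
    cells[0, 1] = (1 - px) * py - cov
    if np.any(cells < -1e-10) or np.any(cells > 1 + 1e-10):
        raise ValueError("covariance triple is infeasible for these marginals")
    return JointTable(cells=np.clip(cells, 0.0, 1.0))


def _pair_matrices(m: MarginalTable):
    """Constraint system A @ cov in [lo, hi] for all ordered level pairs."""
    pairs = _ordered_pairs(m.n_levels)
    a = np.zeros((len(pairs), m.n_levels))
    lo = np.empty(len(pairs))
    hi = np.empty(len(pairs))
    for row, (i, j) in enumerate(pairs):
        a[row, i], a[row, j] = 1.0, -1.0
        lo[row], hi[row] = pairwise_cov_constraint(m, i, j)
    return a, lo, hi


def _require_feasible(m: MarginalTable):
    report = iv_inequality_check(m)
    if not report.passed:
        raise ValueError(
            "marginals violate the IV inequalities "
            f"(min slack {report.min_slack:.3g}); covariance sampling "
            "requires IV-consistent marginals"
        )


def sample_cov_triples(
    m: MarginalTable,
    n: int,
    seed: int | None = None,
    scheme: str = "rejection",
) -> list[CovTriple]:
    """Draw covariance triples from the feasible region.

    ``rejection`` draws each component uniformly on its per-level interval
    and rejects violations of the pairwise constraints — uniform over the
    feasible polytope, the flat-prior reading.  ``sequential`` draws level 0
    on its interval, then truncates each subsequent level to the range the
    pairwise constraints allow given the earlier draws (not uniform over
    the polytope, but never rejects a partial draw unless the truncated
    range is empty).
    """
    if scheme not in ("rejection", "sequential"):
        raise ValueError("scheme must be 'rejection' or 'sequential'")
    _require_feasible(m)
    rng = np.random.default_rng(seed)
    k = m.n_levels
    intervals = np.array([cov_feasible_interval(m, z) for z in range(k)])
    widths = intervals[:, 1] - intervals[:, 0]
    a, plo, phi = _pair_matrices(m)
    if np.any(plo > phi + 1e-12):
        bad = int(np.argmax(plo - phi))
        raise ValueError(
            f"empty feasible region: pairwise covariance constraint {bad} "
            f"has lower {plo[bad]:.4g} > upper {phi[bad]:.4g}"
        )
    out = np.empty((n, k))
    if scheme == "rejection":
        filled = 0
        max_rounds = 2000
        for _ in range(max_rounds):
            todo = n - filled
            if todo == 0:
                break
            batch = max(4 * todo, 256)
            draws = intervals[:, 0] + widths * rng.uniform(size=(batch, k))
            diffs = draws @ a.T
            keep = np.all((diffs >= plo - 1e-12) & (diffs <= phi + 1e-12), axis=1)
            kept = draws[keep][:todo]
            out[filled:filled + kept.shape[0]] = kept
            filled += kept.shape[0]
        else:
            raise ValueError(
                "rejection sampling failed: feasible region has negligible "
                "volume for these marginals"
            )
    else:
        for row in range(n):
            for _ in range(1000):
                triple = np.empty(k)
                ok = True
                for z in range(k):
                    lo, hi = intervals[z]
                    for prev in range(z):
                        d_lo, d_hi = pairwise_cov_constraint(m, z, prev)
                        lo = max(lo, triple[prev] + d_lo)
                        hi = min(hi, triple[prev] + d_hi)
                        d_lo, d_hi = pairwise_cov_constraint(m, prev, z)
                        lo = max(lo, triple[prev] - d_hi)
                        hi = min(hi, triple[prev] - d_lo)
                    if lo > hi:
                        ok = False
                        break
                    triple[z] = rng.uniform(lo, hi)
                if ok:
                    out[row] = triple
                    break
            else:
                raise ValueError("sequential sampling failed to complete a triple")
    return [CovTriple(cov=row) for row in out]


def _summarize(bounds_list, n_infeasible, scheme, seed) -> PlausibilitySummary:
    if not bounds_list:
        raise ValueError("every sampled joint was infeasible for the one-sample LP")
    n = len(bounds_list)
    # midpoint sign settles the (rare) crossed intersection intervals
    above = sum(
        1 for b in bounds_list if not b.covers_zero and b.lower + b.upper > 0
    )
    below = sum(
        1 for b in bounds_list if not b.covers_zero and b.lower + b.upper <= 0
    )
    return PlausibilitySummary(
        n_samples=n,
        frac_excluding_zero=(above + below) / n,
        frac_above_zero=above / n,
        frac_below_zero=below / n,
        bounds=bounds_list,
        n_infeasible=n_infeasible,
        scheme=scheme,
        seed=seed,
    )


def plausible_one_sample_bounds(
    m: MarginalTable,
    n: int = 500,
    seed: int | None = None,
    scheme: str = "rejection",
) -> PlausibilitySummary:
    """Distribution of one-sample bounds compatible with observed marginals.

    Samples ``n`` covariance triples, reconstructs the implied joints and
    computes one-sample sharp LP bounds for each.  Joints the LP rejects
    (possible in principle, since cell validity plus the pairwise
    constraints need not exhaust the IV constraints) are dropped from the
    denominator and counted in ``n_infeasible``.
    """
    triples = sample_cov_triples(m, n, seed=seed, scheme=scheme)
    bounds_list = []
    n_infeasible = 0
    for t in triples:
        res = lp_sharp_bounds(joint_from_cov(m, t), design="one")
        if res is None:
            n_infeasible += 1
        else:
            bounds_list.append(res)
    if n_infeasible:
        logger.warning("%d of %d sampled joints were LP-infeasible", n_infeasible, n)
    return _summarize(bounds_list, n_infeasible, scheme, seed)


def multi_instrument_plausibility(
    ms: list[MarginalTable],
    n: int = 500,
    seed: int | None = None,
    scheme: str = "rejection",
) -> PlausibilitySummary:
    """Plausible *intersection* bounds across several instruments.

    Per draw, one covariance triple is sampled independently for each
    instrument (derived per-instrument seed streams), each instrument's
    one-sample bound is computed, and the bounds are intersected.  Draws
    where any instrument's joint is LP-infeasible are dropped.
    """
    if not ms:
        raise ValueError("need at least one instrument")
    streams = np.random.SeedSequence(seed).spawn(len(ms))
    per_instrument = [
        sample_cov_triples(m, n, seed=stream, scheme=scheme)
        for m, stream in zip(ms, streams)
    ]
    bounds_list = []
    n_infeasible = 0
    for draw in range(n):
        per_draw = []
        for m, triples in zip(ms, per_instrument):
            res = lp_sharp_bounds(joint_from_cov(m, triples[draw]), design="one")
            if res is None:
                per_draw = None
                break
            per_draw.append(res)
        if per_draw is None:
            n_infeasible += 1
            continue
        lower = max(b.lower for b in per_draw)
        upper = min(b.upper for b in per_draw)
        bounds_list.append(AteBounds(lower=lower, upper=upper))
    if n_infeasible:
        logger.warning("%d of %d draws had an LP-infeasible joint", n_infeasible, n)
    return _summarize(bounds_list, n_infeasible, scheme, seed)
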