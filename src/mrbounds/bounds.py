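"""Closed-form two-sample ATE bounds, IV inequalities and instrument strength.

Under the core IV assumptions (relevance, independence from confounders,
exclusion restriction, conditional ignorability given the confounder) and a
two-sample design — where ``P(X=1|Z=z)`` comes from one study and
``P(Y=1|Z=z)`` from another — the average treatment effect
``ATE = P(Y1=1) - P(Y0=1)`` is partially identified.  This module evaluates
the sharp closed-form bounds for instruments with two or three levels, the
observable falsification ("IV") inequalities, the instrument-strength
statistic ``ST`` and the ``2 - 2*ST`` length bound, plus interval
aggregation across instruments.

The closed forms are linear min/max expressions in the twelve observed
probabilities; everything here is vectorized so that millions of tables can
be screened at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .tables import AteBounds, MarginalTable, StrengthReport

__all__ = [
    "instrument_strength",
    "concentration_parameter",
    "strength_report",
    "two_sample_bounds",
    "two_sample_bounds_arrays",
    "iv_inequality_check",
    "iv_min_slack_arrays",
    "IvInequalityReport",
    "max_length_bound",
    "max_length_at_strength",
    "intersect_bounds",
    "union_bounds",
    "is_nested",
]


def instrument_strength(p_x) -> float:
    """Instrument strength ``ST = max_{z != z'} |P(X=1|Z=z) - P(X=1|Z=z')|``.

    For a binary instrument this reduces to the usual Balke-Pearl strength
    ``|P(X=1|Z=1) - P(X=1|Z=0)|``.
    """
    arr = np.asarray(p_x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("instrument strength needs at least two levels")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(arr.max() - arr.min())


def concentration_parameter(st: float, sum_z2: float, sigma2: float) -> float:
    """Concentration parameter ``mu^2 = ST^2/4 * sum(z_i^2) / sigma^2``.

    Relates the nonparametric strength ``ST`` to the model-based strength
    measure used in linear IV (roughly proportional to the first-stage F
    statistic), for fixed observed instrument values ``z_i`` and first-stage
    error variance ``sigma^2``.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if sum_z2 < 0:
        raise ValueError("sum_z2 must be nonnegative")
    return st * st / 4.0 * sum_z2 / sigma2


def strength_report(p_x, z_values=None, sigma2: float | None = None) -> StrengthReport:
    """Bundle ``ST`` with the model-based concentration parameter.

    ``z_values`` are the observed instrument values (e.g. the genotype
    column); with ``sigma2``, the first-stage error variance, the report
    also carries ``mu2 = ST^2/4 * sum(z_i^2) / sigma2``.
    """
    st = instrument_strength(p_x)
    if z_values is None or sigma2 is None:
        return StrengthReport(st=st)
    sum_z2 = float(np.square(np.asarray(z_values, dtype=float)).sum())
    return StrengthReport(
        st=st,
        sum_z2=sum_z2,
        sigma2=sigma2,
        mu2=concentration_parameter(st, sum_z2, sigma2),
    )


def max_length_bound(st: float) -> float:
    """Sharp upper bound ``2 - 2*ST`` on the two-sample bound length."""
    if not 0.0 <= st <= 1.0:
        raise ValueError("st must lie in [0, 1]")
    return 2.0 - 2.0 * st


def _ordered_pairs(k: int):
    return [(i, j) for i in range(k) for j in range(k) if i != j]


def two_sample_bounds_arrays(p_x: np.ndarray, p_y: np.ndarray):
    """Vectorized closed-form two-sample bounds.

    Parameters
    ----------
    p_x, p_y : ndarray, shape (..., n_levels)
        Conditional probabilities, ``n_levels`` in {2, 3}.

    Returns
    -------
    lower, upper : ndarray with shape ``p_x.shape[:-1]``

    The lower bound is the maximum of five families of linear expressions
    (three ranging over ordered level pairs, two over single levels), the
    upper bound the minimum of the five mirrored families.  Crossed results
    (``upper < lower``) are returned as computed.
    """
    px = np.asarray(p_x, dtype=float)
    py = np.asarray(p_y, dtype=float)
    k = px.shape[-1]
    if k not in (2, 3):
        raise ValueError(
            "closed-form bounds cover 2- and 3-level instruments; "
            "use lp_sharp_bounds for 4 levels"
        )
    pairs = _ordered_pairs(k)
    lo_terms = []
    up_terms = []
    for i, j in pairs:
        pxi, pxj = px[..., i], px[..., j]
        pyi, pyj = py[..., i], py[..., j]
        lo_terms.append(pyi - 2.0 * pyj - 2.0 * pxj)
        lo_terms.append(pyi + pxi - pyj - pxj - 1.0)
        lo_terms.append(2.0 * pyi + 2.0 * pxi - pyj - 3.0)
        up_terms.append(pyi - 2.0 * pyj + 2.0 * pxj + 1.0)
        up_terms.append(2.0 * pyi - 2.0 * pxi - pyj + 2.0)
        up_terms.append(pyi - pxi + pxj - pyj + 1.0)
    for z in range(k):
        lo_terms.append(-py[..., z] - px[..., z])
        lo_terms.append(py[..., z] + px[..., z] - 2.0)
        up_terms.append(px[..., z] - py[..., z] + 1.0)
        up_terms.append(py[..., z] - px[..., z] + 1.0)
    lower = np.max(np.stack(lo_terms, axis=0), axis=0)
    upper = np.min(np.stack(up_terms, axis=0), axis=0)
    return lower, upper


def two_sample_bounds(m: MarginalTable) -> AteBounds:
    """Sharp closed-form two-sample ATE bounds for a single marginal table.

    Raises for 4-level instruments, where no closed form is implemented;
    the linear-programming route (:func:`mrbounds.lp.lp_sharp_bounds`)
    covers that case.
    """
    lower, upper = two_sample_bounds_arrays(m.p_x[None, :], m.p_y[None, :])
    return AteBounds(lower=float(lower[0]), upper=float(upper[0]))


@dataclass(frozen=True)
class IvInequalityReport:
    """Slack values of the observable IV falsification inequalities.

    Each slack must be nonnegative for the data to be consistent with the
    IV assumptions.  ``pairwise_1``/``pairwise_2`` are the two nontrivial
    families evaluated over all ordered level pairs; ``range_*`` are the
    probability-range constraints.
    """

    pairwise_1: np.ndarray
    pairwise_2: np.ndarray
    range_slacks: np.ndarray
    tol: float = 1e-10

    @property
    def min_slack(self) -> float:
        return float(
            min(self.pairwise_1.min(), self.pairwise_2.min(), self.range_slacks.min())
        )

    @property
    def passed(self) -> bool:
        return self.min_slack >= -self.tol


def iv_min_slack_arrays(p_x: np.ndarray, p_y: np.ndarray) -> np.ndarray:
    """Minimum IV-inequality slack, vectorized over leading axes."""
    px = np.asarray(p_x, dtype=float)
    py = np.asarray(p_y, dtype=float)
    k = px.shape[-1]
    terms = []
    for i, j in _ordered_pairs(k):
        terms.append(py[..., i] - px[..., i] - py[..., j] - px[..., j] + 2.0)
        terms.append(py[..., i] + px[..., i] - py[..., j] + px[..., j])
    terms.append(np.min(px, axis=-1))
    terms.append(np.min(py, axis=-1))
    terms.append(np.min(1.0 - px, axis=-1))
    terms.append(np.min(1.0 - py, axis=-1))
    return np.min(np.stack(terms, axis=0), axis=0)


def iv_inequality_check(m: MarginalTable, tol: float = 1e-10) -> IvInequalityReport:
    """Evaluate the observable IV falsification inequalities.

    For a three-level instrument there are 12 nontrivial constraints (two
    families over six ordered pairs) plus the probability-range constraints.
    A negative slack falsifies the joint IV assumptions for this instrument.
    """
    px, py = m.p_x, m.p_y
    pairs = _ordered_pairs(m.n_levels)
    fam1 = np.array([py[i] - px[i] - py[j] - px[j] + 2.0 for i, j in pairs])
    fam2 = np.array([py[i] + px[i] - py[j] + px[j] for i, j in pairs])
    ranges = np.concatenate([px, py, 1.0 - px, 1.0 - py])
    return IvInequalityReport(
        pairwise_1=fam1, pairwise_2=fam2, range_slacks=ranges, tol=tol
    )


def max_length_at_strength(st: float) -> float:
    """Maximum two-sample bound length over tables with strength ``ST = st``.

    Maximizes ``upper - lower`` of the closed-form bounds over all marginal
    tables with three instrument levels that satisfy the IV inequalities and
    have exactly the requested strength.  Because the bound families and the
    IV inequalities are linear in the probabilities, and level permutations
    leave the bounds invariant (so ``P(X=1|Z=z)`` may be taken increasing in
    ``z`` with range ``st``), the search is an exact linear program:
    auxiliary scalars ``l <= lower-family`` ... ``u >= ...`` pin the
    envelope, and ``u - l`` is maximized.
    """
    if not 0.0 <= st <= 1.0:
        raise ValueError("st must lie in [0, 1]")
    # Variables v = (a, s, py0, py1, py2, l, u), with P(X=1|Z) = (a, a+s,
    # a+st) so that the strength is exactly `st` for any 0 <= s <= st.
    # Linear expressions are (coef_vector, constant) pairs over v.
    n = 7
    IDX_L, IDX_U = 5, 6

    def px(z):
        vec = np.zeros(n)
        vec[0] = 1.0
        if z == 1:
            vec[1] = 1.0
        return vec, (st if z == 2 else 0.0)

    def py(z):
        vec = np.zeros(n)
        vec[2 + z] = 1.0
        return vec, 0.0

    def combine(*terms, const=0.0):
        vec = np.zeros(n)
        c0 = const
        for coef, (tvec, tconst) in terms:
            vec += coef * tvec
            c0 += coef * tconst
        return vec, c0

    a_ub, b_ub = [], []

    def leq(vec, const, rhs=0.0):  # vec . v + const <= rhs
        a_ub.append(vec)
        b_ub.append(rhs - const)

    lower_fams, upper_fams, iv_fams = [], [], []
    for i, j in _ordered_pairs(3):
        lower_fams += [
            combine((1, py(i)), (-2, py(j)), (-2, px(j))),
            combine((1, py(i)), (1, px(i)), (-1, py(j)), (-1, px(j)), const=-1.0),
            combine((2, py(i)), (2, px(i)), (-1, py(j)), const=-3.0),
        ]
        upper_fams += [
            combine((1, py(i)), (-2, py(j)), (2, px(j)), const=1.0),
            combine((2, py(i)), (-2, px(i)), (-1, py(j)), const=2.0),
            combine((1, py(i)), (-1, px(i)), (1, px(j)), (-1, py(j)), const=1.0),
        ]
        iv_fams += [
            combine((1, py(i)), (-1, px(i)), (-1, py(j)), (-1, px(j)), const=2.0),
            combine((1, py(i)), (1, px(i)), (-1, py(j)), (1, px(j))),
        ]
    for z in range(3):
        lower_fams += [
            combine((-1, py(z)), (-1, px(z))),
            combine((1, py(z)), (1, px(z)), const=-2.0),
        ]
        upper_fams += [
            combine((1, px(z)), (-1, py(z)), const=1.0),
            combine((1, py(z)), (-1, px(z)), const=1.0),
        ]
    for vec, const in lower_fams:  # family - l <= 0
        row = vec.copy()
        row[IDX_L] -= 1.0
        leq(row, const)
    for vec, const in upper_fams:  # u - family <= 0
        row = -vec
        row[IDX_U] += 1.0
        leq(row, -const)
    for vec, const in iv_fams:  # family >= 0
        leq(-vec, -const)
    obj = np.zeros(n)
    obj[IDX_L], obj[IDX_U] = 1.0, -1.0  # minimize l - u
    var_bounds = [
        (0.0, 1.0 - st),
        (0.0, st),
        (0.0, 1.0), (0.0, 1.0), (0.0, 1.0),
        (-1.0, 1.0), (-1.0, 1.0),
    ]
    res = linprog(
        obj, A_ub=np.array(a_ub), b_ub=np.array(b_ub), bounds=var_bounds,
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"length maximization failed: {res.message}")
    return float(-res.fun)


def _check_nonempty(bounds_list):
    if not bounds_list:
        raise ValueError("need at least one bound")


def intersect_bounds(bounds_list) -> AteBounds:
    """Intersection of per-instrument bounds: valid if every instrument is.

    ``lower = max`` of lowers, ``upper = min`` of uppers; a crossed result
    means the instruments are mutually inconsistent.
    """
    bounds_list = list(bounds_list)
    _check_nonempty(bounds_list)
    return AteBounds(
        lower=max(b.lower for b in bounds_list),
        upper=min(b.upper for b in bounds_list),
    )


def union_bounds(bounds_list) -> AteBounds:
    """Union (interval hull) of per-instrument bounds.

    Covers the true ATE as long as at least one instrument is valid.
    """
    bounds_list = list(bounds_list)
    _check_nonempty(bounds_list)
    return AteBounds(
        lower=min(b.lower for b in bounds_list),
        upper=max(b.upper for b in bounds_list),
    )


def is_nested(bounds_list, tol: float = 1e-10) -> bool:
    """True if the intervals form a chain under inclusion.

    Sorted from longest to shortest, each interval must contain the next.
    With nested per-instrument bounds, the intersection bound is simply the
    strongest instrument's bound.
    """
    bounds_list = sorted(bounds_list, key=lambda b: -b.length)
    _check_nonempty(bounds_list)
    for outer, inner in zip(bounds_list, bounds_list[1:]):
        if inner.lower < outer.lower - tol or inner.upper > outer.upper + tol:
            return False
    return True
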