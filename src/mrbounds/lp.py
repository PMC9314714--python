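"""Linear-programming sharp ATE bounds for one- and two-sample designs.

The sharp identification interval for the ATE under the IV assumptions is
the range of ``P(Y1=1) - P(Y0=1)`` over all latent response-type
distributions (:class:`~mrbounds.tables.ResponseDistribution`) consistent
with the observed data.  The latent law assigns mass to
``(y0, y1, x | z)``; independence of the instrument from the confounder
forces the ``(y0, y1)`` marginal to be identical across instrument levels,
and the data enter as matching constraints:

* one-sample: the implied ``P(X=x, Y=y | Z=z)`` must equal the observed
  joint cells;
* two-sample: only the implied ``P(X=1|Z=z)`` and ``P(Y=1|Z=z)`` must match
  the observed marginals.

Minimizing and maximizing the ATE over this polytope gives sharp bounds for
any number of instrument levels (2-4 here).  An infeasible program means
the observed data are incompatible with the IV assumptions — the LP
analogue of "crossed" closed-form bounds, and a strictly stronger
falsification check than the printed IV inequalities for 3-level
instruments.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import linprog

from .tables import AteBounds, JointTable, MarginalTable

__all__ = ["lp_sharp_bounds"]

# variable layout: m(r) for the 4 response types r=(y0,y1), then
# q_z(r, x) for each level z (8 per level), index r*2 + x.
_R_TYPES = [(y0, y1) for y0 in (0, 1) for y1 in (0, 1)]


@lru_cache(maxsize=None)
def _lp_matrices(n_levels: int, design: str):
    n_var = 4 + 8 * n_levels

    def q_idx(z, r, x):
        return 4 + 8 * z + 2 * r + x

    rows = []

    def row(entries):
        r = np.zeros(n_var)
        for idx, coef in entries:
            r[idx] += coef
        rows.append(r)

    # normalization of the type marginal
    row([(r, 1.0) for r in range(4)])
    # per level: sum_x q_z(r, x) = m(r)
    for z in range(n_levels):
        for r in range(4):
            row([(q_idx(z, r, 0), 1.0), (q_idx(z, r, 1), 1.0), (r, -1.0)])
    # data-matching constraints; the b vector is filled per call
    n_fixed = len(rows)
    if design == "one":
        # P(X=x, Y=y|Z=z): observed outcome is the potential outcome y_x
        for z in range(n_levels):
            for x in (0, 1):
                for y in (0, 1):
                    row([
                        (q_idx(z, r, x), 1.0)
                        for r, (y0, y1) in enumerate(_R_TYPES)
                        if (y1 if x else y0) == y
                    ])
    elif design == "two":
        for z in range(n_levels):
            row([(q_idx(z, r, 1), 1.0) for r in range(4)])  # P(X=1|Z=z)
        for z in range(n_levels):
            row([
                (q_idx(z, r, x), 1.0)
                for r, (y0, y1) in enumerate(_R_TYPES)
                for x in (0, 1)
                if (y1 if x else y0) == 1
            ])  # P(Y=1|Z=z)
    else:
        raise ValueError("design must be 'one' or 'two'")
    a_eq = np.array(rows)
    b_fixed = np.zeros(n_fixed)
    b_fixed[0] = 1.0
    # objective: ATE = m(0,1) - m(1,0); types ordered (0,0),(0,1),(1,0),(1,1)
    c = np.zeros(n_var)
    c[1], c[2] = 1.0, -1.0
    return a_eq, b_fixed, c


def _data_vector(data, design: str):
    if design == "one":
        if not isinstance(data, JointTable):
            raise TypeError("one-sample bounds require a JointTable")
        k = data.n_levels
        b = np.empty(4 * k)
        pos = 0
        for z in range(k):
            for x in (0, 1):
                for y in (0, 1):
                    b[pos] = data.cells[x, y, z]
                    pos += 1
        return b, k
    if isinstance(data, JointTable):
        data = data.marginals()
    if not isinstance(data, MarginalTable):
        raise TypeError("two-sample bounds require a MarginalTable or JointTable")
    return np.concatenate([data.p_x, data.p_y]), data.n_levels


def lp_sharp_bounds(data, design: str = "two") -> AteBounds | None:
    """Sharp ATE bounds by linear programming.

    Parameters
    ----------
    data : MarginalTable or JointTable
        The observed conditional distribution.  A ``JointTable`` passed with
        ``design="two"`` is reduced to its marginals.
    design : {"one", "two"}
        Whether the joint ``(X, Y)`` law per level is observed ("one") or
        only the two marginals ("two").

    Returns
    -------
    AteBounds or None
        ``None`` means the program is infeasible: the data are incompatible
        with the IV assumptions (no latent response-type distribution can
        reproduce them), which subsumes every observable falsification
        inequality.
    """
    b_data, k = _data_vector(data, design)
    a_eq, b_fixed, c = _lp_matrices(k, design)
    b_eq = np.concatenate([b_fixed, b_data])
    var_bounds = (0.0, 1.0)
    endpoints = []
    for sign in (1.0, -1.0):
        res = linprog(sign * c, A_eq=a_eq, b_eq=b_eq, bounds=var_bounds,
                      method="highs")
        if res.status == 2:  # infeasible
            return None
        if not res.success:
            raise RuntimeError(f"LP solver failure: {res.message}")
        endpoints.append(sign * res.fun)
    lower, upper = endpoints
    return AteBounds(lower=float(np.clip(lower, -1, 1)),
                     upper=float(np.clip(upper, -1, 1)))
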