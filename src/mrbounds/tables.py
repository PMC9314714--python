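"""Core data containers for bound-based instrumental-variable analysis.

The two-sample observable is a :class:`MarginalTable` holding the exposure
and outcome probabilities conditional on each instrument level,
``P(X=1|Z=z)`` and ``P(Y=1|Z=z)``.  The one-sample observable is a
:class:`JointTable` holding the full conditional joint ``P(X=x,Y=y|Z=z)``.
Either determines an identification interval for the average treatment
effect, represented by :class:`AteBounds`.  :class:`ResponseDistribution`
holds a latent distribution over potential-outcome response types and the
exposure, the object the sharp-bound linear programs optimize over.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MarginalTable",
    "JointTable",
    "AteBounds",
    "ResponseDistribution",
    "StrengthReport",
]

_PROB_TOL = 1e-9


def _as_prob_vector(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    if np.any(arr < -_PROB_TOL) or np.any(arr > 1 + _PROB_TOL):
        raise ValueError(f"{name} entries must lie in [0, 1], got {arr}")
    return np.clip(arr, 0.0, 1.0)


@dataclass(frozen=True)
class MarginalTable:
    """Conditional exposure/outcome probabilities per instrument level.

    Parameters
    ----------
    p_x : array-like
        ``P(X=1|Z=z)`` for ``z = 0 .. n_levels-1``.
    p_y : array-like
        ``P(Y=1|Z=z)`` for ``z = 0 .. n_levels-1``.

    Instruments with 2, 3 (the SNP genotype case) or 4 categories are
    supported.
    """

    p_x: np.ndarray
    p_y: np.ndarray

    def __post_init__(self):
        px = _as_prob_vector(self.p_x, "p_x")
        py = _as_prob_vector(self.p_y, "p_y")
        if px.shape != py.shape:
            raise ValueError("p_x and p_y must have the same length")
        if not 2 <= px.size <= 4:
            raise ValueError("instrument must have 2, 3 or 4 levels")
        px.setflags(write=False)
        py.setflags(write=False)
        object.__setattr__(self, "p_x", px)
        object.__setattr__(self, "p_y", py)

    @property
    def n_levels(self) -> int:
        return self.p_x.size


@dataclass(frozen=True)
class JointTable:
    """Conditional joint distribution ``P(X=x, Y=y | Z=z)``.

    ``cells`` has shape ``(2, 2, n_levels)`` indexed ``[x, y, z]`` and each
    ``z``-slice sums to one.
    """

    cells: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.cells, dtype=float)
        if c.ndim != 3 or c.shape[:2] != (2, 2):
            raise ValueError(f"cells must have shape (2, 2, n_levels), got {c.shape}")
        if not 2 <= c.shape[2] <= 4:
            raise ValueError("instrument must have 2, 3 or 4 levels")
        if np.any(c < -1e-10):
            raise ValueError("joint cells must be nonnegative")
        sums = c.sum(axis=(0, 1))
        if np.any(np.abs(sums - 1.0) > 1e-8):
            raise ValueError(f"each z-slice must sum to 1, got sums {sums}")
        c = np.clip(c, 0.0, 1.0)
        c.setflags(write=False)
        object.__setattr__(self, "cells", c)

    @property
    def n_levels(self) -> int:
        return self.cells.shape[2]

    def marginals(self) -> MarginalTable:
        """The two-sample observable implied by this joint distribution."""
        p_x = self.cells[1].sum(axis=0)
        p_y = self.cells[:, 1].sum(axis=0)
        return MarginalTable(p_x=p_x, p_y=p_y)

    def conditional_cov(self) -> np.ndarray:
        """``Cov(X, Y | Z=z)`` per level, recovered from the joint cells."""
        m = self.marginals()
        return self.cells[1, 1] - m.p_x * m.p_y


@dataclass(frozen=True)
class AteBounds:
    """An identification interval for the average treatment effect.

    ``upper < lower`` ("crossed" bounds) is reported as-is rather than
    clamped: it signals that the observed probabilities are incompatible
    with the instrumental-variable assumptions, which is diagnostic
    information in its own right.
    """

    lower: float
    upper: float

    def __post_init__(self):
        for name, v in (("lower", self.lower), ("upper", self.upper)):
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
            if not -1 - _PROB_TOL <= v <= 1 + _PROB_TOL:
                raise ValueError(f"{name} must lie in [-1, 1], got {v}")

    @property
    def length(self) -> float:
        """Interval length; negative exactly when the bounds cross."""
        return self.upper - self.lower

    @property
    def crossed(self) -> bool:
        return self.upper < self.lower

    @property
    def covers_zero(self) -> bool:
        return self.lower <= 0.0 <= self.upper

    def contains(self, value: float, tol: float = 0.0) -> bool:
        return self.lower - tol <= value <= self.upper + tol

    def __iter__(self):
        yield self.lower
        yield self.upper


@dataclass(frozen=True)
class StrengthReport:
    """Instrument-strength summary.

    ``st`` is the maximum pairwise difference of exposure probabilities
    across instrument levels.  When the observed instrument values and the
    first-stage error variance are supplied, ``mu2`` is the model-based
    concentration parameter ``st^2/4 * sum(z_i^2) / sigma2``, roughly
    proportional to the first-stage F statistic in linear IV models.
    """

    st: float
    mu2: float | None = None
    sigma2: float | None = None
    sum_z2: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.st <= 1.0 + _PROB_TOL:
            raise ValueError(f"st must lie in [0, 1], got {self.st}")
        if self.mu2 is not None and self.mu2 < 0:
            raise ValueError("mu2 must be nonnegative")


@dataclass(frozen=True)
class ResponseDistribution:
    """Distribution over potential-outcome response types and exposure.

    ``weights`` has shape ``(2, 2, 2, n_levels)`` indexed ``[y0, y1, x, z]``
    with ``weights[..., z]`` a probability distribution for each ``z``.
    ``(y0, y1)`` is the response type: the outcome the unit would show under
    exposure 0 and exposure 1 (exclusion restriction: the instrument enters
    the outcome only through the exposure).  Instrument independence forces
    the ``(y0, y1)``-marginal to be identical across ``z``, which is
    validated here.
    """

    weights: np.ndarray
    rtol: float = field(default=1e-8, compare=False)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 4 or w.shape[:3] != (2, 2, 2):
            raise ValueError(f"weights must have shape (2,2,2,n_levels), got {w.shape}")
        if np.any(w < -1e-12):
            raise ValueError("weights must be nonnegative")
        sums = w.sum(axis=(0, 1, 2))
        if np.any(np.abs(sums - 1.0) > 1e-8):
            raise ValueError("weights must sum to 1 for each z")
        type_marg = w.sum(axis=2)  # (2, 2, n_levels)
        spread = type_marg.max(axis=2) - type_marg.min(axis=2)
        if np.any(spread > self.rtol):
            raise ValueError(
                "the (Y0, Y1) marginal must not depend on z "
                f"(max discrepancy {spread.max():.3g})"
            )
        w = np.clip(w, 0.0, 1.0)
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @property
    def n_levels(self) -> int:
        return self.weights.shape[3]

    def type_marginal(self) -> np.ndarray:
        """``P(Y0=y0, Y1=y1)``, shape (2, 2)."""
        return self.weights.sum(axis=2).mean(axis=2)

    def ate(self) -> float:
        m = self.type_marginal()
        return float(m[0, 1] - m[1, 0])

    def joint_table(self) -> JointTable:
        """Observable ``P(X=x, Y=y|Z=z)`` implied by the latent law."""
        w = self.weights
        k = self.n_levels
        cells = np.empty((2, 2, k))
        # X = x realized => observed Y equals the potential outcome y_x
        cells[0, 0] = w[0, :, 0].sum(axis=0)  # x=0, y0=0
        cells[0, 1] = w[1, :, 0].sum(axis=0)  # x=0, y0=1
        cells[1, 0] = w[:, 0, 1].sum(axis=0)  # x=1, y1=0
        cells[1, 1] = w[:, 1, 1].sum(axis=0)  # x=1, y1=1
        return JointTable(cells=cells)

    def marginal_table(self) -> MarginalTable:
        return self.joint_table().marginals()
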