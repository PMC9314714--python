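"""From GWAS summary statistics to the conditional probabilities bounds need.

GWAS report, per SNP, a marginal log odds ratio for the exposure
(``gamma_hat``) and for the outcome (``Gamma_hat``) plus the effect-allele
frequency.  Together with the scalar exposure and outcome prevalences these
pin down per-genotype probabilities through a marginal logistic model: the
intercept ``gamma_0`` solves

    P(X=1) = sum_z expit(gamma_0 + gamma_hat * z) P(Z=z)

(and analogously for the outcome), after which
``P(X=1|Z=z) = expit(gamma_0 + gamma_hat * z)``.  The genotype distribution
defaults to Hardy-Weinberg equilibrium at the reported allele frequency.
The marginal log-OR is used directly as the per-genotype slope — adequate
when instruments are mutually independent and effects are small, the
typical GWAS regime — with no attenuation correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .tables import MarginalTable

__all__ = [
    "GwasRecord",
    "hwe_genotype_dist",
    "solve_intercept",
    "marginals_from_summary",
    "read_summary_table",
    "summary_to_marginals",
]


@dataclass(frozen=True)
class GwasRecord:
    """Per-SNP summary statistics plus study prevalences."""

    id: str
    gamma_hat: float  # exposure log-OR per effect allele
    big_gamma_hat: float  # outcome log-OR per effect allele
    eaf: float  # effect-allele frequency
    prev_x: float  # exposure prevalence P(X=1)
    prev_y: float  # outcome prevalence P(Y=1)

    def __post_init__(self):
        if not (np.isfinite(self.gamma_hat) and np.isfinite(self.big_gamma_hat)):
            raise ValueError("log odds ratios must be finite")
        for name, v in (("eaf", self.eaf), ("prev_x", self.prev_x),
                        ("prev_y", self.prev_y)):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")


def hwe_genotype_dist(eaf: float) -> np.ndarray:
    """Genotype distribution ``((1-f)^2, 2f(1-f), f^2)`` under HWE."""
    if not 0.0 < eaf < 1.0:
        raise ValueError("allele frequency must lie strictly in (0, 1)")
    f = eaf
    return np.array([(1 - f) ** 2, 2 * f * (1 - f), f * f])


def solve_intercept(log_or: float, p_z, prevalence: float) -> float:
    """Intercept making the genotype-averaged probability hit the prevalence.

    Solves ``sum_z expit(c + log_or * z) p_z(z) = prevalence`` for ``c``.
    The left side is strictly increasing in ``c``, so the root is unique;
    it is bracketed (expit is bounded, so shifting ``c`` by more than the
    total genotype effect plus a logit margin guarantees a sign change) and
    found by Brent's method.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly in (0, 1)")
    p_z = np.asarray(p_z, dtype=float)
    if np.any(p_z < 0) or abs(p_z.sum() - 1.0) > 1e-9:
        raise ValueError("p_z must be a probability distribution")
    levels = np.arange(p_z.size)

    def f(c):
        return float(expit(c + log_or * levels) @ p_z) - prevalence

    span = abs(log_or) * (p_z.size - 1)
    lo = logit(prevalence) - span - 10.0
    hi = logit(prevalence) + span + 10.0
    return float(brentq(f, lo, hi, xtol=1e-13))


def marginals_from_summary(r: GwasRecord, p_z=None) -> MarginalTable:
    """Reconstruct ``P(X=1|Z=z)``, ``P(Y=1|Z=z)`` from one SNP's summary.

    If ``p_z`` is not given it is derived from the allele frequency under
    Hardy-Weinberg equilibrium.  The reconstructed marginals always average
    back to the input prevalences under ``p_z``.
    """
    if p_z is None:
        p_z = hwe_genotype_dist(r.eaf)
    p_z = np.asarray(p_z, dtype=float)
    levels = np.arange(p_z.size)
    g0 = solve_intercept(r.gamma_hat, p_z, r.prev_x)
    big_g0 = solve_intercept(r.big_gamma_hat, p_z, r.prev_y)
    return MarginalTable(
        p_x=expit(g0 + r.gamma_hat * levels),
        p_y=expit(big_g0 + r.big_gamma_hat * levels),
    )


_COLUMN_ALIASES = {
    "snp": "id",
    "rsid": "id",
    "beta.exposure": "beta_exposure",
    "beta.outcome": "beta_outcome",
    "eaf.exposure": "eaf",
    "effect_allele_freq": "eaf",
}


def read_summary_table(
    path,
    prev_x: float | None = None,
    prev_y: float | None = None,
) -> list[GwasRecord]:
    """Read a per-SNP summary-statistics TSV.

    Expected columns: ``id, beta_exposure, beta_outcome, eaf`` and either
    ``prev_x``/``prev_y`` columns or the scalar overrides.  A few common
    alternative headers are accepted (see module source).
    """
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={c: _COLUMN_ALIASES.get(c.lower(), c.lower())
                            for c in df.columns})
    required = ["id", "beta_exposure", "beta_outcome", "eaf"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"summary table is missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(GwasRecord(
            id=str(row["id"]),
            gamma_hat=float(row["beta_exposure"]),
            big_gamma_hat=float(row["beta_outcome"]),
            eaf=float(row["eaf"]),
            prev_x=float(prev_x if prev_x is not None else row["prev_x"]),
            prev_y=float(prev_y if prev_y is not None else row["prev_y"]),
        ))
    return records


def summary_to_marginals(records: list[GwasRecord]) -> pd.DataFrame:
    """Bounds-ready marginal table, one row per SNP."""
    rows = []
    for r in records:
        m = marginals_from_summary(r)
        rows.append({
            "id": r.id,
            "px0": m.p_x[0], "px1": m.p_x[1], "px2": m.p_x[2],
            "py0": m.p_y[0], "py1": m.p_y[1], "py2": m.p_y[2],
        })
    return pd.DataFrame(rows)
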