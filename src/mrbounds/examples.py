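"""Worked-example marginal tables.

Nine hypothetical two-sample marginal tables (rows A-C, columns 1-3)
spanning qualitatively different behaviours of the design-comparison
procedure: A/C are centred near zero (with wide and narrow two-sample
bounds respectively), B is centred well above zero.  All nine satisfy the
IV inequalities.  They serve as standard inputs for examples and
regression tests.
"""

from __future__ import annotations

from .tables import MarginalTable

__all__ = ["WORKED_EXAMPLES", "worked_example"]

_RAW = {
    "A1": ((0.125, 0.399, 0.080), (0.699, 0.840, 0.742)),
    "A2": ((0.244, 0.275, 0.185), (0.238, 0.089, 0.146)),
    "A3": ((0.603, 0.469, 0.310), (0.638, 0.346, 0.719)),
    "B1": ((0.886, 0.968, 0.874), (0.805, 0.822, 0.951)),
    "B2": ((0.139, 0.441, 0.334), (0.179, 0.359, 0.559)),
    "B3": ((0.901, 0.909, 0.935), (0.821, 0.810, 0.905)),
    "C1": ((0.175, 0.079, 0.365), (0.599, 0.358, 0.087)),
    "C2": ((0.493, 0.911, 0.085), (0.360, 0.480, 0.441)),
    "C3": ((0.434, 0.045, 0.733), (0.747, 0.370, 0.169)),
}

WORKED_EXAMPLES: dict[str, MarginalTable] = {
    key: MarginalTable(p_x=px, p_y=py) for key, (px, py) in _RAW.items()
}


def worked_example(key: str) -> MarginalTable:
    """Fetch one of the nine worked-example tables by key (e.g. ``"A2"``)."""
    try:
        return WORKED_EXAMPLES[key]
    except KeyError:
        raise KeyError(
            f"unknown example {key!r}; valid keys: {sorted(WORKED_EXAMPLES)}"
        ) from None
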