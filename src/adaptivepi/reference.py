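"""Canonical parameter sets and published reference values.

The baseline operating point of the adaptive PI system is

    b = 0.3, s = 0.25, l = 0.7, c = 2, with r(0) = 11, d(0) = 0.01,

and three single-parameter variants (s -> 1.5, b -> 0.6, c -> 4) probe how
the equilibria and eigenvalues respond.  ``REFERENCE_SCENARIOS`` freezes the
reference equilibrium coordinates and eigenvalues for these four sets, all
rounded to three decimals; the reproduction driver recomputes every entry
from the closed forms and compares at that rounding.
"""

from __future__ import annotations

from .models import AdaptivePIParams

__all__ = [
    "BASELINE_PARAMS",
    "R0",
    "D0",
    "R_FINAL",
    "D_FINAL",
    "REFERENCE_SCENARIOS",
]

BASELINE_PARAMS = AdaptivePIParams(b=0.3, s=0.25, l=0.7, c=2.0)

#: initial and final levels of the canonical step schedule
R0 = 11.0
D0 = 0.01
R_FINAL = 13.75
D_FINAL = 5.0

#: reference values at 3-decimal rounding for the four canonical parameter
#: sets: equilibrium coordinates, the real eigenvalue pair at E1 and the
#: complex pair (real, imag) at E2
REFERENCE_SCENARIOS = [
    {
        "name": "baseline",
        "overrides": {},
        "E1_y": -0.033,
        "E2_y": 11.000,
        "E2_z": 4.012,
        "lambda_E1": (0.300, -22.067),
        "lambda_E2": (-0.351, 2.549),
    },
    {
        "name": "s_x6",
        "overrides": {"s": 1.5},
        "E1_y": -0.033,
        "E2_y": 11.000,
        "E2_z": 0.669,
        "lambda_E1": (0.300, -22.067),
        "lambda_E2": (-0.351, 2.549),
    },
    {
        "name": "b_x2",
        "overrides": {"b": 0.6},
        "E1_y": -0.017,
        "E2_y": 11.000,
        "E2_z": 8.012,
        "lambda_E1": (0.600, -22.033),
        "lambda_E2": (-0.701, 3.568),
    },
    {
        "name": "c_x2",
        "overrides": {"c": 4.0},
        "E1_y": -0.033,
        "E2_y": 11.000,
        "E2_z": 4.012,
        "lambda_E1": (0.300, -44.133),
        "lambda_E2": (-0.351, 3.622),
    },
]
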