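"""Closed-form equilibria and local stability of the adaptive PI system.

With constant reference ``r`` and disturbance ``d`` the system

    dy/dt = b*y + d + s*z*(l*r - y)
    dz/dt = -c*z*(r - y)

has exactly two equilibria:

    E1 = (-d/b, 0)                      (off state, biologically infeasible)
    E2 = (r, (d + b*r) / (s*r*(1 - l))) (tracking state, y = r)

The Jacobian is

    J(y, z) = [[b - s*z,  s*(l*r - y)],
               [c*z,      -c*(r - y)]]

At E1 it is triangular with eigenvalues (b, -c*(d + b*r)/b) — a saddle for
all positive parameters.  At E2 the eigenvalues are the roots of
``lambda^2 - tau*lambda + delta`` with

    tau   = (d + b*l*r) / (r*(l - 1))      (trace, negative when 0 < l < 1)
    delta = c*(d + b*r)                    (determinant, always positive)

so E2 is locally stable (focus or node) throughout the admissible regime.
Notably neither tau nor delta contains ``s``: the gain scale moves the
equilibrium gain state ``z2`` but not the local dynamics of the output.
"""

from __future__ import annotations

import cmath
import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import AdaptivePIParams, StateVector

__all__ = [
    "StabilityClass",
    "Equilibrium",
    "equilibrium_points",
    "jacobian",
    "eigenvalues_E1",
    "eigenvalues_E2",
    "classify_stability",
    "equilibria_table",
]

#: absolute tolerance on the discriminant tau^2 - 4*delta for calling a
#: repeated (degenerate) root
DISCRIMINANT_TOL = 1e-12


class StabilityClass(str, enum.Enum):
    SADDLE = "saddle"
    STABLE_FOCUS = "stable_focus"
    STABLE_NODE = "stable_node"
    DEGENERATE_NODE = "degenerate_node"
    UNSTABLE = "unstable"


@dataclass(frozen=True)
class Equilibrium:
    """An equilibrium point with its local linearization summary."""

    point: StateVector
    eigenvalues: tuple
    tau: float
    delta: float
    stability_class: StabilityClass

    @property
    def y(self) -> float:
        return self.point[0]

    @property
    def z(self) -> float:
        return self.point[1]


def _sorted_pair(l1: complex, l2: complex) -> tuple:
    """Deterministic eigenvalue ordering: imag part descending, then real."""
    return tuple(sorted((complex(l1), complex(l2)), key=lambda v: (-v.imag, -v.real)))


def _classify(tau: float, delta: float, tol: float = DISCRIMINANT_TOL) -> StabilityClass:
    disc = tau * tau - 4.0 * delta
    if delta < 0:
        return StabilityClass.SADDLE
    if abs(disc) <= tol:
        return StabilityClass.DEGENERATE_NODE if tau < 0 else StabilityClass.UNSTABLE
    if disc < 0:
        return StabilityClass.STABLE_FOCUS if tau < 0 else StabilityClass.UNSTABLE
    return StabilityClass.STABLE_NODE if tau < 0 else StabilityClass.UNSTABLE


def classify_stability(eq: Equilibrium) -> StabilityClass:
    """Stability class from the trace/determinant of an equilibrium."""
    return _classify(eq.tau, eq.delta)


def jacobian(params: AdaptivePIParams, state, r: float) -> np.ndarray:
    """Jacobian of the adaptive PI right-hand side at ``state`` (y, z)."""
    y, z = np.asarray(state, dtype=float)
    b, s, l, c = params.b, params.s, params.l, params.c
    return np.array(
        [
            [b - s * z, s * (l * r - y)],
            [c * z, -c * (r - y)],
        ]
    )


def eigenvalues_E1(params: AdaptivePIParams, r: float, d: float) -> tuple:
    """Eigenvalues at the off state E1: ``(b, -c*(d + b*r)/b)``.

    The Jacobian is lower-triangular there (``z = 0`` kills the lower-left
    entry), so the eigenvalues sit on the diagonal.  One is ``b > 0`` and the
    other negative: E1 is always a saddle.
    """
    if params.b == 0:
        raise ValueError("b must be nonzero")
    l2 = -params.c * (d + params.b * r) / params.b
    return _sorted_pair(complex(params.b), complex(l2))


def eigenvalues_E2(params: AdaptivePIParams, r: float, d: float) -> tuple:
    """Eigenvalues at the tracking state E2, from the trace/determinant.

    Roots of ``lambda^2 - tau*lambda + delta``; independent of ``s``.
    """
    tau, delta = _tau_delta(params, r, d)
    disc = tau * tau - 4.0 * delta
    root = cmath.sqrt(disc)
    if abs(disc) <= DISCRIMINANT_TOL:
        root = 0.0
    return _sorted_pair((tau + root) / 2.0, (tau - root) / 2.0)


def _tau_delta(params: AdaptivePIParams, r: float, d: float) -> tuple:
    if params.l == 1:
        raise ValueError("l = 1 is degenerate: the tracking equilibrium escapes to infinity")
    tau = (d + params.b * params.l * r) / (r * (params.l - 1.0))
    delta = params.c * (d + params.b * r)
    return tau, delta


def equilibrium_points(params: AdaptivePIParams, r: float, d: float) -> tuple:
    """Both equilibria of the adaptive PI system under constant ``(r, d)``.

    Returns ``(E1, E2)`` with eigenvalues, trace, determinant and stability
    class attached.  Raises for ``l = 1``, where ``z2`` diverges.
    """
    if r <= 0 or d <= 0:
        raise ValueError("r and d must be positive")
    if params.l == 1:
        raise ValueError("l = 1 is degenerate: the tracking equilibrium escapes to infinity")
    b, s, l, c = params.b, params.s, params.l, params.c
    labels = ("y", "z")

    e1_point = StateVector((-d / b, 0.0), labels)
    e1_eigs = eigenvalues_E1(params, r, d)
    tau1 = float(sum(v.real for v in e1_eigs))
    delta1 = float((e1_eigs[0] * e1_eigs[1]).real)
    e1 = Equilibrium(e1_point, e1_eigs, tau1, delta1, _classify(tau1, delta1))

    z2 = (d + b * r) / (s * r * (1.0 - l))
    e2_point = StateVector((r, z2), labels)
    tau2, delta2 = _tau_delta(params, r, d)
    e2_eigs = eigenvalues_E2(params, r, d)
    e2 = Equilibrium(e2_point, e2_eigs, tau2, delta2, _classify(tau2, delta2))
    return e1, e2


def equilibria_table(params: AdaptivePIParams, r: float, d: float) -> pd.DataFrame:
    """One-row-per-equilibrium summary table (for reports and the CLI)."""
    rows = []
    for name, eq in zip(("E1", "E2"), equilibrium_points(params, r, d)):
        l1, l2 = eq.eigenvalues
        rows.append(
            {
                "equilibrium": name,
                "y": eq.y,
                "z": eq.z,
                "tau": eq.tau,
                "delta": eq.delta,
                "lambda1_re": l1.real,
                "lambda1_im": l1.imag,
                "lambda2_re": l2.real,
                "lambda2_im": l2.imag,
                "stability": eq.stability_class.value,
            }
        )
    return pd.DataFrame(rows)
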