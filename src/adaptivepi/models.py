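"""Right-hand sides and parameter sets of the feedback circuit models.

Three nested models are implemented:

* a three-state hormonal circuit in which a regulated variable ``y`` controls
  the functional mass ``z`` of a tissue secreting a hormone ``x``
  (:func:`karin_rhs`),
* its two-state simplification with a single multiplicative feedback state
  (:func:`simplified_rhs`),
* a two-state adaptive proportional-integral (PI) feedback system built
  around an open-loop exponential-growth plant (:func:`adaptive_pi_rhs`).

The adaptive PI system is the core object of the package.  Its states are the
output ``y`` and the adapting state ``z``; the product ``s*z(t)`` acts as a
time-varying (adaptive) PI gain driving ``y`` towards the reference ``r(t)``
in spite of the disturbance ``d(t)``:

    dy/dt = b*y + d(t) + s*z*(l*r(t) - y)
    dz/dt = -c*z*(r(t) - y)

State ordering is fixed once and for all as ``(y, z)`` for the two-state
models and ``(y, x, z)`` for the three-state circuit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import Callable, Sequence

import numpy as np
import yaml

__all__ = [
    "KarinParams",
    "SimplifiedParams",
    "AdaptivePIParams",
    "StateVector",
    "STATE_LABELS",
    "MODEL_DIM",
    "as_signal",
    "karin_rhs",
    "simplified_rhs",
    "adaptive_pi_rhs",
    "rhs_for",
    "save_params",
    "load_params",
]

#: state labels per model id, in the fixed integration order
STATE_LABELS = {
    "karin": ("y", "x", "z"),
    "simplified": ("y", "z"),
    "adaptive_pi": ("y", "z"),
}

MODEL_DIM = {name: len(labels) for name, labels in STATE_LABELS.items()}


def as_signal(value) -> Callable[[float], float]:
    """Wrap a constant into a callable of time; pass callables through.

    All model inputs (reference, disturbance, drive) share the callable
    interface so that constant and time-varying signals are interchangeable.
    """
    if callable(value):
        return value
    v = float(value)
    return lambda t: v


def _check_dim(state, n: int, model: str) -> np.ndarray:
    arr = np.asarray(state, dtype=float)
    if arr.shape != (n,):
        raise ValueError(
            f"{model} model expects a state of length {n}, got shape {arr.shape}"
        )
    return arr


@dataclass(frozen=True)
class KarinParams:
    """Parameters of the three-state hormonal circuit.

    ``s`` and ``p`` are the feedback gains of the hormone ``x`` and of the
    functional mass ``z``; ``u0`` is the basal input and ``y0`` the output
    set-point that the circuit regulates ``y`` towards.
    """

    s: float
    p: float
    u0: float = 0.0
    y0: float = 1.0

    def __post_init__(self):
        if self.s <= 0 or self.p <= 0 or self.y0 <= 0:
            raise ValueError("s, p and y0 must be strictly positive")
        if self.u0 < 0:
            raise ValueError("u0 must be non-negative")


@dataclass(frozen=True)
class SimplifiedParams:
    """Parameters of the two-state simplified circuit."""

    s: float
    u0: float = 0.0
    y0: float = 1.0

    def __post_init__(self):
        if self.s <= 0 or self.y0 <= 0:
            raise ValueError("s and y0 must be strictly positive")
        if self.u0 < 0:
            raise ValueError("u0 must be non-negative")


@dataclass(frozen=True)
class AdaptivePIParams:
    """Parameters of the adaptive PI feedback system.

    b : open-loop growth rate of the plant ``dy/dt = b*y``.
    s : scale of the adaptive gain ``s*z(t)``.
    l : scaling of the reference inside the proportional error term
        ``l*r(t) - y``; the stable operating regime requires ``0 < l < 1``
        (``l >= 1`` is admitted for model evaluation but warned about,
        because the tracking equilibrium then loses stability or blows up).
    c : adaptation rate of the gain state ``z``.
    """

    b: float
    s: float
    l: float
    c: float

    def __post_init__(self):
        if self.b <= 0 or self.s <= 0 or self.c <= 0:
            raise ValueError("b, s and c must be strictly positive")
        if self.l <= 0:
            raise ValueError("l must be strictly positive")
        if self.l >= 1:
            warnings.warn(
                "l >= 1 leaves the stable tracking regime (0 < l < 1); "
                "equilibrium analysis may be degenerate",
                stacklevel=2,
            )

    def replace(self, **kwargs) -> "AdaptivePIParams":
        """Return a copy with some fields overridden."""
        vals = {f.name: getattr(self, f.name) for f in fields(self)}
        vals.update(kwargs)
        return AdaptivePIParams(**vals)


@dataclass(frozen=True)
class StateVector:
    """An ordered, labelled point in state space."""

    coordinates: tuple
    labels: tuple

    def __post_init__(self):
        if len(self.coordinates) != len(self.labels):
            raise ValueError("coordinates and labels must have equal length")
        object.__setattr__(self, "coordinates", tuple(float(v) for v in self.coordinates))
        object.__setattr__(self, "labels", tuple(self.labels))

    def __array__(self, dtype=None, copy=None):
        return np.array(self.coordinates, dtype=dtype or float)

    def __len__(self):
        return len(self.coordinates)

    def __getitem__(self, i):
        return self.coordinates[i]

    @property
    def all_positive(self) -> bool:
        """Whether the point lies in the biologically feasible orthant."""
        return all(v > 0 for v in self.coordinates)

    def asdict(self) -> dict:
        return dict(zip(self.labels, self.coordinates))


def karin_rhs(t: float, state, params: KarinParams, u=0.0) -> np.ndarray:
    """Time derivative of the three-state hormonal circuit at ``(t, state)``.

    States are ``(y, x, z)``; ``u`` is the external drive added to the basal
    input ``u0``.  The adapting state obeys ``dz/dt = z*(y - y0)``, so both
    ``z = 0`` and ``y = y0`` annihilate its derivative.
    """
    y, x, z = _check_dim(state, 3, "karin")
    u_t = as_signal(u)(t)
    return np.array(
        [
            params.u0 + u_t - params.s * x * y,
            params.p * z * y - x,
            z * (y - params.y0),
        ]
    )


def simplified_rhs(t: float, state, params: SimplifiedParams, u=0.0) -> np.ndarray:
    """Time derivative of the two-state simplified circuit at ``(t, state)``.

    States are ``(y, z)``.  Substituting ``z_tilde = s*z`` removes the gain
    ``s`` from the equations entirely, which is the root of the output's
    invariance to ``s``.
    """
    y, z = _check_dim(state, 2, "simplified")
    u_t = as_signal(u)(t)
    return np.array(
        [
            params.u0 + u_t - params.s * z * y,
            z * (y - params.y0),
        ]
    )


def adaptive_pi_rhs(t: float, state, params: AdaptivePIParams, r=1.0, d=0.0) -> np.ndarray:
    """Time derivative of the adaptive PI feedback system at ``(t, state)``.

    States are ``(y, z)``; ``r`` and ``d`` are the reference and disturbance
    inputs (constants or callables of time).
    """
    y, z = _check_dim(state, 2, "adaptive_pi")
    r_t = as_signal(r)(t)
    d_t = as_signal(d)(t)
    return np.array(
        [
            params.b * y + d_t + params.s * z * (params.l * r_t - y),
            -params.c * z * (r_t - y),
        ]
    )


def rhs_for(model: str):
    """Return the RHS function for a model id."""
    try:
        return {
            "karin": karin_rhs,
            "simplified": simplified_rhs,
            "adaptive_pi": adaptive_pi_rhs,
        }[model]
    except KeyError:
        raise ValueError(f"unknown model id {model!r}; expected one of {sorted(MODEL_DIM)}")


_PARAM_CLASSES = {
    "karin": KarinParams,
    "simplified": SimplifiedParams,
    "adaptive_pi": AdaptivePIParams,
}


def save_params(params, path) -> None:
    """Serialize a parameter set to a YAML file (keys are the field names)."""
    model = next(m for m, cls in _PARAM_CLASSES.items() if isinstance(params, cls))
    data = {"model": model}
    data.update({f.name: float(getattr(params, f.name)) for f in fields(params)})
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_params(path):
    """Load a parameter set from a YAML file written by :func:`save_params`."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "model" not in data:
        raise ValueError(f"{path}: expected a mapping with a 'model' key")
    model = data.pop("model")
    if model not in _PARAM_CLASSES:
        raise ValueError(f"{path}: unknown model id {model!r}")
    cls = _PARAM_CLASSES[model]
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}")
    return cls(**data)
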