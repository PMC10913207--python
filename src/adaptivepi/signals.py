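"""Seeded piecewise-constant input signals with optional held Gaussian noise.

The experiments drive the adaptive PI system with step-like reference and
disturbance schedules.  A :class:`PiecewiseSignal` holds a list of intervals,
one base level per interval, and a per-interval noise standard deviation.
Noise draws are standard normal, scaled by the interval's sd, refreshed every
``sample_step`` time units and held constant in between (zero-order hold), so
the signal — and hence the ODE right-hand side — stays piecewise constant.
All draws are frozen at construction from the seed: evaluating the same
signal twice, or two signals built with the same seed and schedule, gives
bit-identical values.  That is what lets paired simulation runs share one
noise realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ConstantSignal", "PiecewiseSignal", "make_step_schedule"]

#: smallest admissible signal value; draws below it are truncated so that the
#: positivity assumption on r(t) (and d(t)) survives the added noise
POSITIVITY_FLOOR = 1e-6


class ConstantSignal:
    """A constant signal with an unbounded time domain."""

    piecewise_constant = True

    def __init__(self, value: float):
        self.value = float(value)

    def __call__(self, t: float) -> float:
        return self.value

    def discontinuities(self, t0: float, t1: float) -> np.ndarray:
        return np.empty(0)

    def __repr__(self):
        return f"ConstantSignal({self.value})"


@dataclass
class PiecewiseSignal:
    """Piecewise-constant signal with frozen, seeded zero-order-hold noise.

    Parameters
    ----------
    breakpoints : increasing sequence of times delimiting the intervals.
    base_values : one base level per interval (``len(breakpoints) - 1``).
    noise_sd : per-interval noise standard deviation (scalar broadcast).
    seed : seed of the noise stream.
    sample_step : noise refresh period; draws are held between refreshes.
    floor : lower truncation applied after adding noise.

    Intervals are half-open ``[b_i, b_{i+1})`` with the final interval closed,
    so the value *at* a breakpoint is the one of the interval that starts
    there.  Evaluation outside ``[breakpoints[0], breakpoints[-1]]`` raises.
    """

    breakpoints: np.ndarray
    base_values: np.ndarray
    noise_sd: np.ndarray = 0.0
    seed: int = 0
    sample_step: float = 1.0
    floor: float = POSITIVITY_FLOOR
    piecewise_constant: bool = field(default=True, repr=False)

    def __post_init__(self):
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.base_values = np.asarray(self.base_values, dtype=float)
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), self.base_values.shape
        ).copy()
        if self.breakpoints.ndim != 1 or len(self.breakpoints) < 2:
            raise ValueError("need at least two breakpoints")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if len(self.base_values) != len(self.breakpoints) - 1:
            raise ValueError("need exactly one base value per interval")
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be non-negative")
        if self.sample_step <= 0:
            raise ValueError("sample_step must be positive")
        # freeze the full noise stream now: one draw per sample step over the
        # whole domain, indexed by floor((t - t0)/sample_step)
        span = self.breakpoints[-1] - self.breakpoints[0]
        n_draws = int(np.ceil(span / self.sample_step)) + 1
        rng = np.random.default_rng(self.seed)
        self._draws = rng.standard_normal(n_draws)

    @property
    def domain(self) -> tuple:
        return float(self.breakpoints[0]), float(self.breakpoints[-1])

    def _interval_index(self, t: float) -> int:
        t0, t1 = self.domain
        if not (t0 <= t <= t1):
            raise ValueError(f"t={t} outside signal domain [{t0}, {t1}]")
        idx = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        return min(max(idx, 0), len(self.base_values) - 1)

    def __call__(self, t: float) -> float:
        i = self._interval_index(t)
        value = self.base_values[i]
        sd = self.noise_sd[i]
        if sd > 0:
            t0 = self.breakpoints[0]
            k = min(int((t - t0) // self.sample_step), len(self._draws) - 1)
            value = value + sd * self._draws[k]
        return float(max(value, self.floor))

    def discontinuities(self, t0: float, t1: float) -> np.ndarray:
        """Times in ``(t0, t1)`` where the signal may jump.

        Breakpoints always qualify; noise refresh times qualify only inside
        noisy intervals.  Integrators restart at these times so that adaptive
        steppers never smooth across a jump.
        """
        times = [self.breakpoints[(t0 < self.breakpoints) & (self.breakpoints < t1)]]
        d0 = self.breakpoints[0]
        for i, sd in enumerate(self.noise_sd):
            if sd <= 0:
                continue
            a, b = self.breakpoints[i], self.breakpoints[i + 1]
            lo, hi = max(a, t0), min(b, t1)
            if lo >= hi:
                continue
            k0 = int(np.ceil((lo - d0) / self.sample_step))
            refreshes = d0 + self.sample_step * np.arange(k0, int((hi - d0) // self.sample_step) + 1)
            times.append(refreshes[(t0 < refreshes) & (refreshes < t1)])
        return np.unique(np.concatenate(times)) if times else np.empty(0)

    def sample(self, step: float = 0.1) -> pd.DataFrame:
        """Evaluate on a regular grid; returns columns ``time``, ``value``."""
        t0, t1 = self.domain
        times = np.arange(t0, t1 + 0.5 * step, step)
        times[-1] = min(times[-1], t1)
        return pd.DataFrame({"time": times, "value": [self(t) for t in times]})

    def to_csv(self, path, step: float = 0.1) -> None:
        self.sample(step).to_csv(path, index=False, float_format="%.10g")


def make_step_schedule(
    r0: float = 11.0,
    d0: float = 0.01,
    r_final: float = 13.75,
    d_final: float = 5.0,
    seed: int = 0,
    noise_sd: float = 1.0,
    sample_step: float = 1.0,
) -> tuple:
    """Build the canonical step-like reference/disturbance pair ``(r, d)``.

    Six intervals over ``[0, 400]``:

    ========== ============================ ============================
    interval   reference r(t)               disturbance d(t)
    ========== ============================ ============================
    [0, 50)    constant ``r0``              constant ``d0``
    [50, 150)  steps to 16, noisy           constant ``d0``
    [150, 200) constant 16                  constant ``d0``
    [200, 300) constant 16                  steps to ``d_final``, noisy
    [300, 350) steps to ``r_final``, noisy  ``d_final``, noisy
    [350, 400] constant ``r_final``         constant ``d_final``
    ========== ============================ ============================

    Noise (standard normal scaled by ``noise_sd``, held for ``sample_step``)
    is applied only during the "varying" intervals; constant intervals are
    exactly flat.  The two signals use noise streams derived from ``seed``
    so that a single seed pins the whole experiment.
    """
    if r0 <= 0 or d0 <= 0:
        raise ValueError("r0 and d0 must be positive")
    breaks = np.array([0.0, 50.0, 150.0, 200.0, 300.0, 350.0, 400.0])
    r_mid = 16.0
    r_sig = PiecewiseSignal(
        breakpoints=breaks,
        base_values=[r0, r_mid, r_mid, r_mid, r_final, r_final],
        noise_sd=[0.0, noise_sd, 0.0, 0.0, noise_sd, 0.0],
        seed=seed,
        sample_step=sample_step,
    )
    # independent stream for the disturbance, still a pure function of `seed`
    d_sig = PiecewiseSignal(
        breakpoints=breaks,
        base_values=[d0, d0, d0, d_final, d_final, d_final],
        noise_sd=[0.0, 0.0, 0.0, noise_sd, noise_sd, 0.0],
        seed=seed + 1_000_003,
        sample_step=sample_step,
    )
    return r_sig, d_sig
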