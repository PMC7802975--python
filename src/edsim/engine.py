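"""Generic discrete-time stock-and-flow machinery.

The building blocks here are deliberately small: Euler integration of stocks
with negative-stock protection, fixed-duration pipeline delays, triangular
service-time sampling, and strict-priority capacity allocation.  Everything
operates on per-minute rates; with a 1-minute step a "rate" and a "quantity
per step" coincide numerically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationClock",
    "TriangularSpec",
    "DelayLine",
    "RandomStream",
    "integrate_step",
    "delay_push_pop",
    "sample_duration",
    "priority_allocate",
    "limit_outflows",
]


@dataclass(frozen=True)
class SimulationClock:
    """Discrete simulation time base, in minutes from midnight.

    ``horizon`` must be an integer multiple of ``dt``.  The default covers a
    single 24-hour day at 1-minute resolution.
    """

    t0: float = 0.0
    horizon: float = 1440.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n = self.horizon / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("horizon must be an integer multiple of dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon / self.dt))

    def times(self) -> np.ndarray:
        """Step start times t0, t0+dt, ..., t0+horizon-dt."""
        return self.t0 + self.dt * np.arange(self.n_steps)


@dataclass(frozen=True)
class TriangularSpec:
    """Triangular service-time distribution, corners in minutes.

    The analytic mean is ``(low + mode + high) / 3``; deterministic runs use
    it directly, stochastic runs draw from the distribution.
    """

    low: float
    mode: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.mode <= self.high):
            raise ValueError(
                f"invalid triangular corners ({self.low}, {self.mode}, {self.high}): "
                "need low <= mode <= high"
            )
        if self.low < 0:
            raise ValueError("service times cannot be negative")

    @property
    def mean(self) -> float:
        return (self.low + self.mode + self.high) / 3.0

    def scaled(self, factor: float) -> "TriangularSpec":
        """All three corners multiplied by ``factor`` (policy levers use this)."""
        return TriangularSpec(self.low * factor, self.mode * factor, self.high * factor)


class RandomStream:
    """Seeded random source; identical seeds give identical trajectories."""

    def __init__(self, seed: int):
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)

    def spawn(self, offset: int) -> "RandomStream":
        """Independent child stream, reproducibly derived from this seed."""
        return RandomStream((self.seed * 1_000_003 + offset) % (2**31 - 1))


class DelayLine:
    """Fixed-duration pipeline: whatever enters at t leaves at t + duration.

    Entries are bucketed on the step grid.  A fractional duration splits the
    entering mass between the two bracketing step boundaries so the mean
    transit time equals the duration exactly (an integer-multiple duration
    releases in one lump); mass is always conserved.  ``content`` is the
    in-transit total.
    """

    def __init__(self, duration: float, dt: float = 1.0):
        if duration < 0:
            raise ValueError("delay duration must be >= 0")
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.duration = float(duration)
        self.dt = float(dt)
        self._buffer: dict[int, float] = {}
        self.content = 0.0

    def _step_index(self, t: float) -> int:
        return int(math.ceil(t / self.dt - 1e-9))

    def push(self, quantity: float, t: float) -> None:
        if quantity < 0:
            raise ValueError(f"negative inflow {quantity} pushed into delay line")
        if quantity == 0:
            return
        exit_exact = (t + self.duration) / self.dt
        lo = int(math.floor(exit_exact + 1e-9))
        frac = exit_exact - lo
        if frac <= 1e-9:  # exit lands on a step boundary
            self._buffer[lo] = self._buffer.get(lo, 0.0) + quantity
        else:
            self._buffer[lo] = self._buffer.get(lo, 0.0) + quantity * (1.0 - frac)
            self._buffer[lo + 1] = self._buffer.get(lo + 1, 0.0) + quantity * frac
        self.content += quantity

    def pop(self, t: float) -> float:
        """Everything whose exit time has been reached by step time ``t``."""
        now = self._step_index(t)
        due = [k for k in self._buffer if k <= now]
        out = 0.0
        for k in due:
            out += self._buffer.pop(k)
        self.content -= out
        return out


def delay_push_pop(line: DelayLine, inflow: float, t: float) -> float:
    """Push this step's inflow, then collect whatever is due at ``t``.

    With duration 0 the inflow passes straight through.
    """
    line.push(inflow, t)
    return line.pop(t)


def integrate_step(
    stocks: dict[str, float],
    net_flows: dict[str, float],
    dt: float,
) -> dict[str, float]:
    """One Euler step: stock' = stock + net_rate * dt, floored at zero.

    A net outflow that would overdraw a stock within the step is clipped to
    exactly empty it (and logged); the model's MIN/MAX guards make this rare,
    but simultaneous competing outflows can overshoot in discrete time.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    out = dict(stocks)
    for name, rate in net_flows.items():
        if not np.isfinite(rate):
            raise ValueError(f"non-finite net flow for stock '{name}': {rate}")
        new = out.get(name, 0.0) + rate * dt
        if new < 0:
            logger.warning("clipped stock '%s' at zero (would be %.3g)", name, new)
            new = 0.0
        out[name] = new
    return out


def limit_outflows(stock: float, outflows: np.ndarray, dt: float) -> np.ndarray:
    """Scale competing outflow rates so they cannot overdraw ``stock`` in one step.

    All outflows are reduced by a common factor (proportional clipping) when
    their combined withdrawal exceeds the stock.
    """
    outflows = np.asarray(outflows, dtype=float)
    total = outflows.sum() * dt
    if total <= stock or total <= 0:
        return outflows
    logger.debug("proportional outflow clipping: demand %.4g > stock %.4g", total, stock)
    return outflows * (stock / total)


def sample_duration(
    spec: TriangularSpec,
    stream: RandomStream | None = None,
    mode: str = "deterministic",
) -> float:
    """A stage duration in minutes: the analytic mean, or one triangular draw."""
    if mode == "deterministic":
        return spec.mean
    if mode == "stochastic":
        if stream is None:
            raise ValueError("stochastic sampling requires a RandomStream")
        if spec.low == spec.high:  # degenerate triangle
            return spec.low
        return float(stream.rng.triangular(spec.low, spec.mode, spec.high))
    raise ValueError(f"unknown sampling mode {mode!r}")


def priority_allocate(available: float, demands) -> np.ndarray:
    """Strict-priority allocation of a scarce capacity.

    The highest priority takes ``min(available, demand)``; each subsequent
    priority takes the minimum of its demand and the remaining capacity.
    Fractional allocations are the norm (continuous stock-and-flow
    semantics).  Never exceeds capacity or any demand.
    """
    if available < 0:
        raise ValueError("available capacity must be >= 0")
    demands = np.asarray(demands, dtype=float)
    if (demands < 0).any():
        raise ValueError("demands must be >= 0")
    alloc = np.zeros_like(demands)
    residual = float(available)
    for i, d in enumerate(demands):
        a = min(residual, d)
        alloc[i] = a
        residual -= a
        if residual <= 0:
            break
    return alloc
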