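"""Behaviour-validation statistics: MAPE and the Theil inequality decomposition.

The Theil decomposition splits the mean squared error between a simulated
and an observed series into a bias share U_M, an unequal-variance share U_S,
and a covariation share U_C that always sum to one:

    MSE = (m_s - m_o)^2 + (s_s - s_o)^2 + 2 (1 - r) s_s s_o

with population standard deviations and the Pearson correlation r.  A large
U_C with small U_M and U_S indicates unsystematic, point-by-point error
around a well-tracked trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SeriesPair", "TheilDecomposition", "PerfectFitError", "mape", "theil"]


class PerfectFitError(ValueError):
    """The series are identical: MSE is zero and the decomposition undefined."""


@dataclass(frozen=True)
class SeriesPair:
    """An aligned simulated/observed series pair of equal length >= 2."""

    simulated: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.simulated, dtype=float)
        o = np.asarray(self.observed, dtype=float)
        object.__setattr__(self, "simulated", s)
        object.__setattr__(self, "observed", o)
        if s.ndim != 1 or o.ndim != 1:
            raise ValueError("series must be one-dimensional")
        if len(s) != len(o):
            raise ValueError(f"length mismatch: {len(s)} vs {len(o)}")
        if len(s) < 2:
            raise ValueError("need at least 2 points")
        if not (np.isfinite(s).all() and np.isfinite(o).all()):
            raise ValueError("series must be finite")


@dataclass(frozen=True)
class TheilDecomposition:
    """Shares of MSE: bias U_M, unequal variance U_S, covariation U_C."""

    U_M: float
    U_S: float
    U_C: float

    @property
    def total(self) -> float:
        return self.U_M + self.U_S + self.U_C


def mape(pair: SeriesPair) -> float:
    """Mean absolute percentage error, in percent.

    Plain unweighted form: 100 * mean(|sim - obs| / |obs|).  Fails loudly on
    zero observed values.
    """
    zeros = np.flatnonzero(pair.observed == 0)
    if zeros.size:
        raise ValueError(
            f"MAPE undefined: observed value is 0 at index {zeros[0]}"
        )
    return 100.0 * float(
        np.mean(np.abs(pair.simulated - pair.observed) / np.abs(pair.observed))
    )


def theil(pair: SeriesPair) -> TheilDecomposition:
    """Theil inequality decomposition of the mean squared error.

    Raises :class:`PerfectFitError` when the series coincide (MSE = 0).
    """
    s, o = pair.simulated, pair.observed
    mse = float(np.mean((s - o) ** 2))
    if mse == 0.0:
        raise PerfectFitError("perfect fit: MSE is zero, decomposition undefined")
    sd_s = float(np.std(s))
    sd_o = float(np.std(o))
    u_m = (s.mean() - o.mean()) ** 2 / mse
    u_s = (sd_s - sd_o) ** 2 / mse
    if sd_s == 0.0 or sd_o == 0.0:
        u_c = 1.0 - u_m - u_s  # no covariation term when a series is constant
    else:
        r = float(np.corrcoef(s, o)[0, 1])
        u_c = 2.0 * (1.0 - r) * sd_s * sd_o / mse
    return TheilDecomposition(float(u_m), float(u_s), float(u_c))
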