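"""Synthetic exogenous demand for the ED simulator.

The hospital's recorded arrival series is confidential, so demand is
synthesized: a bimodal "peak day" profile (late-morning and early-evening
humps, ~350 visits/day, the workload the study system was stress-tested at),
a "quiet day" of the same shape at ~250 visits/day, and a constant
low-rate "uncongested" regime under which no queue ever forms given default
capacities.  Walk-ins pass through registration and triage; ambulance
arrivals (priority 1 and 2 only) enter critical care directly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from edsim.engine import RandomStream

__all__ = [
    "ArrivalProfile",
    "ArrivalSeries",
    "TriageFractions",
    "build_profile",
    "realize_arrivals",
    "default_triage_fractions",
    "implied_venue_shares",
    "PRIORITIES",
    "DEFAULT_WALKIN_PRIORITY_MIX",
    "DEFAULT_AMBULANCE_SHARE",
]

PRIORITIES = ("P1", "P2", "P3", "P4")

# Walk-in acuity mix and the ambulance share of total attendances are not
# public; these values are assumptions chosen so that the implied venue split
# matches the reported 39% critical / 55% ambulatory / 6% isolation.
DEFAULT_WALKIN_PRIORITY_MIX = np.array([0.02, 0.37, 0.51, 0.10])
DEFAULT_AMBULANCE_SHARE = 0.10
AMBULANCE_P1_SHARE = 0.30  # of ambulance arrivals; remainder are P2

VENUE_SHARE_TARGETS = {"critical": 0.39, "ambulatory": 0.55, "isolation": 0.06}

MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class ArrivalProfile:
    """Hourly demand profile for one day.

    ``hourly_walkin``: 24 walk-in rates (patients/hour).
    ``hourly_ambulance``: 24x2 ambulance rates for priorities P1, P2.
    ``priority_mix_walkin``: fractions over P1..P4, summing to 1.
    """

    hourly_walkin: np.ndarray
    hourly_ambulance: np.ndarray
    priority_mix_walkin: np.ndarray = field(
        default_factory=lambda: DEFAULT_WALKIN_PRIORITY_MIX.copy()
    )

    def __post_init__(self) -> None:
        w = np.asarray(self.hourly_walkin, dtype=float)
        a = np.asarray(self.hourly_ambulance, dtype=float)
        m = np.asarray(self.priority_mix_walkin, dtype=float)
        object.__setattr__(self, "hourly_walkin", w)
        object.__setattr__(self, "hourly_ambulance", a)
        object.__setattr__(self, "priority_mix_walkin", m)
        if w.shape != (24,):
            raise ValueError("hourly_walkin must have 24 entries")
        if a.shape != (24, 2):
            raise ValueError("hourly_ambulance must be 24x2 (P1, P2)")
        if (w < 0).any() or (a < 0).any() or (m < 0).any():
            raise ValueError("arrival rates and mix fractions must be >= 0")
        if m.shape != (4,) or abs(m.sum() - 1.0) > 1e-9:
            raise ValueError("priority_mix_walkin must be 4 fractions summing to 1")

    @property
    def daily_total(self) -> float:
        return float(self.hourly_walkin.sum() + self.hourly_ambulance.sum())


@dataclass(frozen=True)
class ArrivalSeries:
    """Per-minute arrival rates over one day (1440 samples).

    In rate mode the integral over the day equals ``total_expected``; in
    count mode entries are Poisson realizations with that expectation.
    """

    walkin: np.ndarray
    ambulance: np.ndarray  # 1440 x 2 (P1, P2)
    priority_mix_walkin: np.ndarray
    total_expected: float

    def __post_init__(self) -> None:
        if self.walkin.shape != (MINUTES_PER_DAY,):
            raise ValueError("walkin must have 1440 per-minute entries")
        if self.ambulance.shape != (MINUTES_PER_DAY, 2):
            raise ValueError("ambulance must be 1440x2")
        if (self.walkin < 0).any() or (self.ambulance < 0).any():
            raise ValueError("arrival rates must be >= 0")

    @property
    def daily_total(self) -> float:
        return float(self.walkin.sum() + self.ambulance.sum())

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "minute": np.arange(MINUTES_PER_DAY),
                "walkin_rate": self.walkin,
                "amb_P1": self.ambulance[:, 0],
                "amb_P2": self.ambulance[:, 1],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, priority_mix_walkin=None) -> "ArrivalSeries":
        df = pd.read_csv(path)
        walkin = df["walkin_rate"].to_numpy(dtype=float)
        amb = df[["amb_P1", "amb_P2"]].to_numpy(dtype=float)
        mix = (
            np.asarray(priority_mix_walkin, dtype=float)
            if priority_mix_walkin is not None
            else DEFAULT_WALKIN_PRIORITY_MIX.copy()
        )
        return cls(walkin, amb, mix, total_expected=float(walkin.sum() + amb.sum()))


@dataclass(frozen=True)
class TriageFractions:
    """Per-priority routing at triage: critical / ambulatory / isolation.

    Rows are (fcca_j, fab_j, fis_j) over j = P1..P4.  ``gp_divert`` is the
    fraction of each priority decanted to a co-located GP clinic before the
    venue split (zero under business as usual); each row satisfies
    fcca + fab + fis = 1 - gp_divert.
    """

    fcca: np.ndarray
    fab: np.ndarray
    fis: np.ndarray
    gp_divert: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def __post_init__(self) -> None:
        for name in ("fcca", "fab", "fis", "gp_divert"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != (4,):
                raise ValueError(f"{name} must have one entry per priority P1..P4")
            if (v < 0).any() or (v > 1).any():
                raise ValueError(f"{name} fractions must lie in [0, 1]")
        total = self.fcca + self.fab + self.fis + self.gp_divert
        if np.abs(total - 1.0).max() > 1e-9:
            raise ValueError("per-priority fractions must sum to 1")
        if self.fcca[2] != 0 or self.fcca[3] != 0:
            raise ValueError("P3/P4 patients never route to critical care")


def build_profile(scenario: str, total: float | None = None) -> ArrivalProfile:
    """Construct a named demand scenario.

    ``peak``: bimodal day totalling ~350 attendances; ``quiet``: the same
    shape scaled to ~250; ``uncongested``: constant 2 walk-ins/hour, no
    ambulances, guaranteeing zero queueing at default capacities.
    """
    hours = np.arange(24) + 0.5
    if scenario == "uncongested":
        rate = (48.0 if total is None else total) / 24.0
        return ArrivalProfile(np.full(24, rate), np.zeros((24, 2)))
    if scenario in ("peak", "quiet"):
        daily = total if total is not None else (350.0 if scenario == "peak" else 250.0)
        # Two Gaussian humps (late morning, early evening) on a low overnight
        # baseline, renormalized to the daily total; shape only, values are
        # not drawn from any recorded series.  The humps are pronounced so
        # the peak day genuinely stresses default capacities (the regime the
        # study system was analysed in).
        shape = (
            0.25
            + 2.0 * np.exp(-0.5 * ((hours - 11.0) / 1.8) ** 2)
            + 1.6 * np.exp(-0.5 * ((hours - 19.0) / 1.8) ** 2)
        )
        shape = shape / shape.sum()
        amb_total = daily * DEFAULT_AMBULANCE_SHARE
        walkin = shape * (daily - amb_total)
        amb = np.outer(
            shape * amb_total, [AMBULANCE_P1_SHARE, 1.0 - AMBULANCE_P1_SHARE]
        )
        return ArrivalProfile(walkin, amb)
    raise ValueError(
        f"unknown scenario {scenario!r}; choose one of "
        "'peak', 'quiet', 'uncongested' (or build a custom ArrivalProfile)"
    )


def realize_arrivals(
    profile: ArrivalProfile,
    mode: str = "rate",
    stream: RandomStream | None = None,
) -> ArrivalSeries:
    """Expand an hourly profile to per-minute arrivals.

    ``rate`` mode spreads each hourly rate uniformly over its 60 minutes
    (deterministic, integral-preserving); ``count`` mode draws independent
    Poisson counts per minute with those means.
    """
    per_min_w = np.repeat(profile.hourly_walkin / 60.0, 60)
    per_min_a = np.repeat(profile.hourly_ambulance / 60.0, 60, axis=0)
    expected = profile.daily_total
    if mode == "rate":
        pass
    elif mode == "count":
        if stream is None:
            raise ValueError("count mode requires a RandomStream")
        per_min_w = stream.rng.poisson(per_min_w).astype(float)
        per_min_a = stream.rng.poisson(per_min_a).astype(float)
    else:
        raise ValueError(f"unknown arrival mode {mode!r}")
    return ArrivalSeries(per_min_w, per_min_a, profile.priority_mix_walkin.copy(), expected)


def default_triage_fractions(
    priority_mix: np.ndarray | None = None,
    ambulance_share: float = DEFAULT_AMBULANCE_SHARE,
) -> TriageFractions:
    """Routing fractions consistent with the reported venue split.

    Across all attendances (ambulances included, which enter critical care
    directly) the implied venue shares are 39% critical, 55% ambulatory and
    6% isolation.  A fixed fever fraction of every priority routes to
    isolation; non-fever P1 and non-ambulant P2 go to critical care; the
    ambulant remainder of P2 and all P3/P4 go to ambulatory care.
    """
    mix = (
        np.asarray(priority_mix, dtype=float)
        if priority_mix is not None
        else DEFAULT_WALKIN_PRIORITY_MIX.copy()
    )
    walk = 1.0 - ambulance_share
    iso_w = VENUE_SHARE_TARGETS["isolation"] / walk
    cca_w = (VENUE_SHARE_TARGETS["critical"] - ambulance_share) / walk
    fis = np.full(4, iso_w)
    fcca = np.zeros(4)
    fcca[0] = 1.0 - iso_w  # every non-fever P1 is critical
    need = cca_w - mix[0] * fcca[0]
    if not (0.0 <= need <= mix[1] * (1.0 - iso_w)):
        raise ValueError("priority mix cannot reproduce the target venue shares")
    fcca[1] = need / mix[1]
    fab = 1.0 - fis - fcca
    return TriageFractions(fcca, fab, fis)


def implied_venue_shares(
    fractions: TriageFractions,
    priority_mix: np.ndarray | None = None,
    ambulance_share: float = DEFAULT_AMBULANCE_SHARE,
) -> dict[str, float]:
    """Marginal venue shares over all attendances implied by the routing."""
    mix = (
        np.asarray(priority_mix, dtype=float)
        if priority_mix is not None
        else DEFAULT_WALKIN_PRIORITY_MIX.copy()
    )
    walk = 1.0 - ambulance_share
    return {
        "critical": ambulance_share + walk * float(mix @ fractions.fcca),
        "ambulatory": walk * float(mix @ fractions.fab),
        "isolation": walk * float(mix @ fractions.fis),
        "diverted": walk * float(mix @ fractions.gp_divert),
    }
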