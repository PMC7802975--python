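"""The coupled ED model: registration/triage, critical care, ambulatory care,
observation ward & discharge, and isolation care.

The model is a deterministic (or per-run stochastic) stock-and-flow system
advanced in 1-minute Euler steps.  Each care venue has a consultation queue
served by a strict-priority allocation of its doctors, a consultation
pipeline (fixed service duration), and venue-specific downstream routing:

* critical care (P1/P2 only, plus direct ambulance arrivals): after
  consultation a fraction goes straight to the observation ward, a fraction
  home, and the rest through laboratory & investigation, after which
  patients go to the ward, home, or — if no bed is free — are observed in
  the waiting area;
* ambulatory care (P1-P4): every consultation is followed by laboratory &
  investigation, then ward / home / waiting-area observation;
* isolation care (fever patients of any priority) has its own observation
  ward and pharmacy.

Observation beds are granted in strict order: critical post-consult P1, P2;
critical post-lab P1, P2; ambulatory post-lab P1..P4.  Stage durations are
triangular; a deterministic run uses the analytic means, a stochastic run
draws each duration once per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from edsim.arrivals import ArrivalSeries, TriageFractions, default_triage_fractions
from edsim.engine import (
    DelayLine,
    RandomStream,
    SimulationClock,
    TriangularSpec,
    delay_push_pop,
    limit_outflows,
    priority_allocate,
    sample_duration,
)

__all__ = ["ParameterSet", "Trajectory", "EDSimulator", "default_parameters"]

# keys of the triangular stage-time parameters, in sampling order (the order
# fixes the draw sequence of a stochastic replicate)
DURATION_KEYS = (
    "RT", "TT", "CT_cc", "CT_ab", "CT_is",
    "LIT", "wt", "ot", "otis", "ppt", "ttba",
)


@dataclass(frozen=True)
class ParameterSet:
    """All stage-time distributions, routing fractions and capacities.

    Stage times (triangular, minutes):

    RT / TT        registration / triage
    CT_cc/ab/is    consultation per venue
    LIT            laboratory & investigation turnaround (shared by critical
                   and ambulatory care)
    wt             observation in the waiting area (no ward bed free)
    ot             observation-ward dwell until the admit/discharge decision
    otis           isolation-ward observation dwell
    ppt            pharmacy & payment
    ttba           time to make a vacated bed available

    Fractions: fb (critical consult -> ward), fh (critical consult -> home,
    of those not warded), fob/foba (post-lab -> ward, critical/ambulatory),
    fdd/famb (per-minute admission hazard from waiting-area observation,
    critical/ambulatory), fis_obs (isolation consult -> isolation ward),
    fah (isolation ward -> hospital), df (main ward -> discharge).

    Capacities: NP/NPAB/NPIS doctors per venue, bc observation beds; ppd,
    dpp, ppb, AT are unit-bookkeeping ratios, all 1 by default.
    """

    RT: TriangularSpec
    TT: TriangularSpec
    CT_cc: TriangularSpec
    CT_ab: TriangularSpec
    CT_is: TriangularSpec
    LIT: TriangularSpec
    wt: TriangularSpec
    ot: TriangularSpec
    otis: TriangularSpec
    ppt: TriangularSpec
    ttba: TriangularSpec
    NP: float = 3.0
    NPAB: float = 4.0
    NPIS: float = 2.0
    bc: float = 25.0
    ppd: float = 1.0
    dpp: float = 1.0
    ppb: float = 1.0
    AT: float = 1.0
    fb: float = 0.30
    fh: float = 0.40
    fob: float = 0.50
    foba: float = 0.30
    fdd: float = 0.005
    famb: float = 0.005
    fis_obs: float = 0.50
    fah: float = 0.30
    df: float = 0.70

    def __post_init__(self) -> None:
        for name in ("fb", "fh", "fob", "foba", "fis_obs", "fah", "df"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"fraction {name}={v} outside [0, 1]")
        for name in ("NP", "NPAB", "NPIS", "bc", "fdd", "famb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def realize_durations(
        self, mode: str = "deterministic", stream: RandomStream | None = None
    ) -> dict[str, float]:
        """One duration per stage: triangular means, or one draw per stage."""
        return {
            key: sample_duration(getattr(self, key), stream, mode)
            for key in DURATION_KEYS
        }


def default_parameters() -> ParameterSet:
    """Default parameterization of the study ED.

    Stage-time triangulars are the published estimates; doctor and bed
    capacities and the routing fractions are assumptions (the originals are
    confidential) chosen to give a plausibly congested peak day.
    """
    return ParameterSet(
        RT=TriangularSpec(3, 5, 7),
        TT=TriangularSpec(4, 5, 7),
        CT_cc=TriangularSpec(10, 15, 20),
        CT_ab=TriangularSpec(10, 15.5, 20),
        CT_is=TriangularSpec(20, 30, 45),
        LIT=TriangularSpec(35, 45, 60),
        wt=TriangularSpec(30, 60, 90),
        ot=TriangularSpec(100, 120, 150),
        otis=TriangularSpec(30, 60, 90),
        ppt=TriangularSpec(10, 15, 30),
        ttba=TriangularSpec(10, 15, 25),
    )


@dataclass
class Trajectory:
    """Recorded per-minute state of one simulated day."""

    t: np.ndarray
    series: dict[str, np.ndarray]
    durations: dict[str, float]
    dt: float
    params: ParameterSet
    fractions: TriageFractions
    census_start: float = 0.0  # in-system patients when recording began

    def __getitem__(self, key: str) -> np.ndarray:
        return self.series[key]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: t_min, stock_name, value."""
        frames = [
            pd.DataFrame({"t_min": self.t, "stock_name": name, "value": arr})
            for name, arr in self.series.items()
        ]
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class EDSimulator:
    """Run the full coupled ED model over one day.

    Parameters
    ----------
    params, fractions : model configuration (see :class:`ParameterSet`).
    arrivals : per-minute exogenous demand.
    clock : time base; must cover the arrival series.
    mode : 'deterministic' (triangular means) or 'stochastic' (one draw per
        stage per run, Poisson arrival counts are the caller's choice when
        realizing the series).
    stream : random source for stochastic duration draws.
    initial_state : optional overrides for initial stock values, keyed by
        stock-group name (e.g. ``{"C": [0, 3], "OW": [1, 1, 0, 0]}``).
    warmup_days : replay the arrival day this many times before the
        recorded day, so the reported day starts from the replayed state
        rather than an empty ED at midnight.
    """

    def __init__(
        self,
        params: ParameterSet | None = None,
        fractions: TriageFractions | None = None,
        arrivals: ArrivalSeries | None = None,
        clock: SimulationClock | None = None,
        mode: str = "deterministic",
        stream: RandomStream | None = None,
        initial_state: dict | None = None,
        warmup_days: int = 0,
    ):
        self.params = params or default_parameters()
        self.fractions = fractions or default_triage_fractions()
        self.arrivals = arrivals
        self.clock = clock or SimulationClock()
        if mode not in ("deterministic", "stochastic"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.stream = stream
        self.initial_state = initial_state or {}
        if warmup_days < 0:
            raise ValueError("warmup_days must be >= 0")
        self.warmup_days = int(warmup_days)

    # ------------------------------------------------------------------ run

    def run(self) -> Trajectory:
        p = self.params
        fr = self.fractions
        clock = self.clock
        dt = clock.dt
        n = clock.n_steps
        times = clock.times()
        dur = p.realize_durations(self.mode, self.stream)

        if self.arrivals is None:
            raise ValueError("an ArrivalSeries is required to run the model")
        if len(self.arrivals.walkin) < n:
            raise ValueError("arrival series shorter than the simulation horizon")
        mix = self.arrivals.priority_mix_walkin

        # --- state ------------------------------------------------------
        P = float(np.sum(self.initial_state.get("P", 0.0)))
        B = float(np.sum(self.initial_state.get("B", 0.0)))

        def init(name, size):
            v = np.zeros(size)
            if name in self.initial_state:
                v[:] = np.asarray(self.initial_state[name], dtype=float)
            return v

        C = init("C", 2)          # critical: waiting for consultation (P1, P2)
        EP = init("EP", 2)        # critical: in consultation
        PLI = init("PLI", 2)      # critical: in laboratory & investigation
        POW = init("POW", 2)      # critical: observed in waiting area
        PCC = float(np.sum(self.initial_state.get("PCC", 0.0)))

        CAB = init("CAB", 4)
        EPAB = init("EPAB", 4)
        PHIAB = init("PHIAB", 4)
        POWAB = init("POWAB", 4)
        PCAB = float(np.sum(self.initial_state.get("PCAB", 0.0)))

        OW = init("OW", 4)        # main observation ward, by priority
        PHAB = init("PHAB", 4)    # main pharmacy & payment

        CIS = init("CIS", 4)
        EPIS = init("EPIS", 4)
        OWIS = init("OWIS", 4)
        PHIS = init("PHIS", 4)
        PCIS = float(np.sum(self.initial_state.get("PCIS", 0.0)))

        reg_line = DelayLine(dur["RT"], dt)
        triage_line = DelayLine(dur["TT"], dt)
        cc_consult = [DelayLine(dur["CT_cc"], dt) for _ in range(2)]
        cc_lab = [DelayLine(dur["LIT"], dt) for _ in range(2)]
        ab_consult = [DelayLine(dur["CT_ab"], dt) for _ in range(4)]
        ab_lab = [DelayLine(dur["LIT"], dt) for _ in range(4)]
        is_consult = [DelayLine(dur["CT_is"], dt) for _ in range(4)]

        # Pipeline-mirrored stocks (P, B, PLI, PHIAB, EP*) live inside delay
        # lines; a nonzero initial value is primed into its line so the
        # patients re-emerge after one transit time instead of stranding.
        t_start = times[0]
        reg_line.push(P, t_start)
        triage_line.push(B, t_start)
        for j in range(2):
            cc_lab[j].push(PLI[j], t_start)
            cc_consult[j].push(EP[j], t_start)
        for j in range(4):
            ab_lab[j].push(PHIAB[j], t_start)
            ab_consult[j].push(EPAB[j], t_start)
            is_consult[j].push(EPIS[j], t_start)
        PCC = max(PCC, EP.sum())
        PCAB = max(PCAB, EPAB.sum())
        PCIS = max(PCIS, EPIS.sum())

        arrivals_cum = 0.0
        home_cum = 0.0
        admit_cum = 0.0
        diverted_cum = 0.0

        rec_names = (
            "cc_queue", "cc_queue_in", "cc_starts",
            "ab_queue", "ab_queue_in", "ab_starts",
            "is_queue", "is_queue_in", "is_starts",
            "P", "B", "PCC", "PCAB", "PCIS",
            "EP", "PLI", "POW", "EPAB", "PHIAB", "POWAB",
            "OW", "PHAB", "EPIS", "OWIS", "PHIS",
            "census", "avb",
            "arrivals_cum", "home_cum", "admit_cum", "diverted_cum",
        )
        rec = {name: np.zeros(n) for name in rec_names}

        bed_cap = p.bc * p.ppb

        def census_now() -> float:
            return (
                P + B
                + C.sum() + EP.sum() + PLI.sum() + POW.sum()
                + CAB.sum() + EPAB.sum() + PHIAB.sum() + POWAB.sum()
                + OW.sum() + PHAB.sum()
                + CIS.sum() + EPIS.sum() + OWIS.sum() + PHIS.sum()
            )

        n_total = n * (self.warmup_days + 1)
        rec_offset = self.warmup_days * n
        census_start = census_now()

        for k in range(n_total):
            t = self.clock.t0 + k * dt  # monotone across warm-up days
            if k == rec_offset and k > 0:
                # recording starts: restart the day's conservation ledger
                arrivals_cum = home_cum = admit_cum = diverted_cum = 0.0
                census_start = census_now()
            # --- exogenous demand (the arrival day replays in warm-up)
            a_total = float(self.arrivals.walkin[k % n])
            nab = self.arrivals.ambulance[k % n]  # (P1, P2)

            # --- registration & triage (pure pipeline delays) --------
            reg_line.push(a_total * dt, t)
            g = reg_line.pop(t) / dt
            triage_line.push(g * dt, t)
            gd = triage_line.pop(t) / dt
            out_j = gd * mix
            cca = out_j[:2] * fr.fcca[:2]
            ab = out_j * fr.fab
            is_ = out_j * fr.fis
            divert = out_j * fr.gp_divert
            P += (a_total - g) * dt
            B += (g - gd) * dt

            # --- observation-ward availability (start-of-step) -------
            avb = max(0.0, bed_cap - OW.sum()) / dur["ttba"]
            beds_left = avb

            # --- critical care ----------------------------------------
            # completions first: a doctor freed this minute can start a new
            # consultation within the same minute
            cc_done = np.array([cc_consult[j].pop(t) for j in range(2)]) / dt
            q_in_cc = cca + nab
            demand_cc = (C / dt + q_in_cc) * p.dpp / p.AT
            pa = max(0.0, p.NP - PCC + cc_done.sum() * dt)
            nc = priority_allocate(pa / p.AT, demand_cc)
            cs = nc * p.ppd
            for j in range(2):
                cc_consult[j].push(nc[j] * dt, t)
            comp = cc_done * p.ppd
            cpo = comp * p.fb
            co = priority_allocate(beds_left, cpo)
            beds_left -= co.sum()
            ch = (comp - co) * p.fh
            cl = comp - co - ch
            al = np.array(
                [delay_push_pop(cc_lab[j], cl[j] * dt, t) for j in range(2)]
            ) / dt
            lo = priority_allocate(beds_left, al * p.fob)
            beds_left -= lo.sum()
            ld = al * (1.0 - p.fob)
            lw = np.maximum(0.0, al * p.fob - lo)
            dw = POW / dur["wt"]
            cad = POW * p.fdd
            for j in range(2):
                dw[j], cad[j] = limit_outflows(POW[j], [dw[j], cad[j]], dt)

            # --- ambulatory care --------------------------------------
            ccab_done = np.array([ab_consult[j].pop(t) for j in range(4)]) / dt
            demand_ab = (CAB / dt + ab) * p.dpp / p.AT
            pa_ab = max(0.0, p.NPAB - PCAB + ccab_done.sum() * dt)
            ncab = priority_allocate(pa_ab / p.AT, demand_ab)
            csab = ncab * p.ppd
            for j in range(4):
                ab_consult[j].push(ncab[j] * dt, t)
            clab = ccab_done * p.ppd  # every consultation proceeds to lab
            ala = np.array(
                [delay_push_pop(ab_lab[j], clab[j] * dt, t) for j in range(4)]
            ) / dt
            ao = priority_allocate(beds_left, ala * p.foba)
            beds_left -= ao.sum()
            ldab = ala * (1.0 - p.foba)
            lwab = np.maximum(0.0, ala * p.foba - ao)
            dwab = POWAB / dur["wt"]
            aab = POWAB * p.famb
            for j in range(4):
                dwab[j], aab[j] = limit_outflows(POWAB[j], [dwab[j], aab[j]], dt)

            # --- observation ward & discharge -------------------------
            ow_in = np.zeros(4)
            ow_in[:2] += co + lo
            ow_in += ao
            aobw = OW / dur["ot"]
            do = aobw * p.df
            ah = aobw - do
            ph_in = ldab + dwab + do
            ph_in[:2] += ld + dw + ch
            hab = PHAB / dur["ppt"]

            # --- isolation care ---------------------------------------
            ccis_done = np.array([is_consult[j].pop(t) for j in range(4)]) / dt
            demand_is = (CIS / dt + is_) * p.dpp / p.AT
            pa_is = max(0.0, p.NPIS - PCIS + ccis_done.sum() * dt)
            ncis = priority_allocate(pa_is / p.AT, demand_is)
            csis = ncis * p.ppd
            for j in range(4):
                is_consult[j].push(ncis[j] * dt, t)
            comp_is = ccis_done * p.ppd
            cois = comp_is * p.fis_obs
            cpis = comp_is * (1.0 - p.fis_obs)
            owd = OWIS / dur["otis"]
            ahis = owd * p.fah
            oph = owd - ahis
            his = PHIS / dur["ppt"]

            # --- state update (Euler) ---------------------------------
            C += (q_in_cc - cs) * dt
            PCC += (nc.sum() - cc_done.sum()) * dt
            EP += (cs - comp) * dt
            PLI += (cl - al) * dt
            POW += (lw - dw - cad) * dt
            CAB += (ab - csab) * dt
            PCAB += (ncab.sum() - ccab_done.sum()) * dt
            EPAB += (csab - clab) * dt
            PHIAB += (clab - ala) * dt
            POWAB += (lwab - dwab - aab) * dt
            OW += (ow_in - aobw) * dt
            PHAB += (ph_in - hab) * dt
            CIS += (is_ - csis) * dt
            PCIS += (ncis.sum() - ccis_done.sum()) * dt
            EPIS += (csis - comp_is) * dt
            OWIS += (cois - owd) * dt
            PHIS += (oph + cpis - his) * dt

            for arr in (C, EP, PLI, POW, CAB, EPAB, PHIAB, POWAB, OW, PHAB,
                        CIS, EPIS, OWIS, PHIS):
                np.clip(arr, 0.0, None, out=arr)

            arrivals_cum += (a_total + nab.sum()) * dt
            home_cum += (hab.sum() + his.sum()) * dt
            admit_cum += (cad.sum() + ah.sum() + aab.sum() + ahis.sum()) * dt
            diverted_cum += divert.sum() * dt

            kr = k - rec_offset
            if kr >= 0:
                rec["cc_queue"][kr] = C.sum()
                rec["cc_queue_in"][kr] = q_in_cc.sum()
                rec["cc_starts"][kr] = cs.sum()
                rec["ab_queue"][kr] = CAB.sum()
                rec["ab_queue_in"][kr] = ab.sum()
                rec["ab_starts"][kr] = csab.sum()
                rec["is_queue"][kr] = CIS.sum()
                rec["is_queue_in"][kr] = is_.sum()
                rec["is_starts"][kr] = csis.sum()
                rec["P"][kr] = P
                rec["B"][kr] = B
                rec["PCC"][kr] = PCC
                rec["PCAB"][kr] = PCAB
                rec["PCIS"][kr] = PCIS
                rec["EP"][kr] = EP.sum()
                rec["PLI"][kr] = PLI.sum()
                rec["POW"][kr] = POW.sum()
                rec["EPAB"][kr] = EPAB.sum()
                rec["PHIAB"][kr] = PHIAB.sum()
                rec["POWAB"][kr] = POWAB.sum()
                rec["OW"][kr] = OW.sum()
                rec["PHAB"][kr] = PHAB.sum()
                rec["EPIS"][kr] = EPIS.sum()
                rec["OWIS"][kr] = OWIS.sum()
                rec["PHIS"][kr] = PHIS.sum()
                rec["census"][kr] = census_now()
                rec["avb"][kr] = avb
                rec["arrivals_cum"][kr] = arrivals_cum
                rec["home_cum"][kr] = home_cum
                rec["admit_cum"][kr] = admit_cum
                rec["diverted_cum"][kr] = diverted_cum

            if PCC > p.NP + 1e-9 or PCAB > p.NPAB + 1e-9 or PCIS > p.NPIS + 1e-9:
                raise RuntimeError(
                    f"doctors consulting exceed allocation at t={t:.0f}"
                )
            if OW.sum() > bed_cap + 1e-9:
                raise RuntimeError(
                    f"observation-ward occupancy {OW.sum():.3f} exceeds "
                    f"capacity {bed_cap:.3f} at t={t:.0f}"
                )

        return Trajectory(
            t=times, series=rec, durations=dur, dt=dt,
            params=p, fractions=fr, census_start=census_start,
        )
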