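"""Tests for the policy harness and ALOS metrics."""

from dataclasses import replace

import math

import numpy as np
import pytest

from edsim.arrivals import ArrivalSeries, DEFAULT_WALKIN_PRIORITY_MIX
from edsim.experiments import (
    PATHWAYS,
    PHASE_WINDOWS,
    ALOSTable,
    PolicySpec,
    apply_policy,
    compute_pathway_alos,
    run_experiment,
    sweep,
    tracer_pathway_alos,
)
from edsim.model import EDSimulator, default_parameters


def make_series(walkin):
    w = np.full(1440, walkin) if np.isscalar(walkin) else np.asarray(walkin, float)
    return ArrivalSeries(
        w, np.zeros((1440, 2)), DEFAULT_WALKIN_PRIORITY_MIX.copy(), float(w.sum())
    )


class TestPolicySpec:
    def test_bau_is_identity(self, params, fractions):
        p2, f2 = apply_policy(params, fractions, PolicySpec.bau())
        assert p2 is params and f2 is fractions

    def test_decant_scales_p3_p4_only(self, params, fractions):
        _, f2 = apply_policy(params, fractions, PolicySpec.colocation(0.3))
        np.testing.assert_allclose(f2.fab[2:], fractions.fab[2:] * 0.7)
        np.testing.assert_allclose(f2.fab[:2], fractions.fab[:2])
        np.testing.assert_allclose(f2.gp_divert[2:], 0.3, atol=1e-12)
        np.testing.assert_allclose(f2.gp_divert[:2], 0.0, atol=1e-12)

    def test_doctor_scale_multiplies_allocations(self, params, fractions):
        p2, _ = apply_policy(params, fractions, PolicySpec.doctors(0.3))
        assert p2.NP == pytest.approx(params.NP * 1.3)
        assert p2.NPAB == pytest.approx(params.NPAB * 1.3)
        assert p2.NPIS == pytest.approx(params.NPIS * 1.3)

    def test_waittime_scales_all_corners(self, params, fractions):
        p2, _ = apply_policy(params, fractions, PolicySpec.waittime(0.2))
        for key in ("LIT", "wt", "ot", "otis"):
            orig, new = getattr(params, key), getattr(p2, key)
            assert (new.low, new.mode, new.high) == pytest.approx(
                (orig.low * 0.8, orig.mode * 0.8, orig.high * 0.8)
            )
        assert p2.RT == params.RT  # untouched

    def test_out_of_range_intensity_warns(self):
        with pytest.warns(UserWarning):
            PolicySpec.waittime(0.5)


@pytest.fixture(scope="module")
def bau():
    return run_experiment(PolicySpec.bau(), "uncongested", mode="deterministic")


@pytest.fixture(scope="module")
def sweep_result():
    return sweep("peak", intensities=(0.1, 0.3), policies=("colocation", "waittime"))


class TestUncongestedALOS:
    """Phase-1 cells in the uncongested regime are sums of stage means."""

    @pytest.mark.parametrize(
        "venue,pathway,expected",
        [
            ("critical", 1, 25.0),
            ("critical", 2, 72.0),
            ("critical", 3, 149.0),
            ("critical", 4, 195.0),
            ("ambulatory", 1, 72.0),
            ("ambulatory", 2, 196.0),
            ("isolation", 1, 42.0),
            ("isolation", 2, 101.0),
        ],
    )
    def test_bau_phase1_cells(self, bau, venue, pathway, expected):
        assert bau.cell(venue, pathway, 1) == pytest.approx(expected, rel=0.02)

    def test_phase_invariance_when_uncongested(self, bau):
        for (v, pw) in PATHWAYS:
            cells = [bau.cell(v, pw, ph) for ph in (1, 2, 3)]
            assert max(cells) - min(cells) < 1e-9

    def test_doubling_capacity_changes_nothing_when_slack(self, params, fractions):
        base = run_experiment(PolicySpec.bau(), "uncongested", params, fractions)
        big = replace(params, NP=params.NP * 2, NPAB=params.NPAB * 2,
                      NPIS=params.NPIS * 2, bc=params.bc * 2)
        doubled = run_experiment(PolicySpec.bau(), "uncongested", big, fractions)
        np.testing.assert_allclose(
            doubled.data.alos_min.to_numpy(), base.data.alos_min.to_numpy()
        )


class TestWaittimePolicy:
    def test_policy3_30pct_phase1_cells(self):
        table = run_experiment(PolicySpec.waittime(0.3), "uncongested")
        assert table.cell("critical", 4, 1) == pytest.approx(144.0, rel=0.05)
        assert table.cell("ambulatory", 2, 1) == pytest.approx(145.0, rel=0.05)

    def test_reduction_matches_analytic_scaling(self, params):
        # uncongested: the ALOS drop equals r x (sum of reduced stage means)
        r = 0.2
        bau = run_experiment(PolicySpec.bau(), "uncongested")
        pol = run_experiment(PolicySpec.waittime(r), "uncongested")
        expected_drop = r * (params.LIT.mean + params.ot.mean)
        got = bau.cell("critical", 4, 1) - pol.cell("critical", 4, 1)
        assert got == pytest.approx(expected_drop, rel=0.02)


class TestColocation:
    def test_critical_cells_invariant_at_every_decant_level(self):
        bau = run_experiment(PolicySpec.bau(), "peak")
        ref = bau.data[bau.data.venue == "critical"].alos_min.to_numpy()
        for d in (0.1, 0.2, 0.3):
            t = run_experiment(PolicySpec.colocation(d), "peak")
            got = t.data[t.data.venue == "critical"].alos_min.to_numpy()
            np.testing.assert_array_equal(got, ref)

    def test_relieves_ambulatory_congestion(self):
        bau = run_experiment(PolicySpec.bau(), "peak")
        dec = run_experiment(PolicySpec.colocation(0.3), "peak")
        assert dec.cell("ambulatory", 1, 2) < bau.cell("ambulatory", 1, 2)


class TestMonotonicity:
    def test_alos_nonincreasing_in_doctor_scale(self):
        prev = None
        for s in (0.0, 0.1, 0.2, 0.3):
            t = run_experiment(PolicySpec.doctors(s) if s else PolicySpec.bau(), "peak")
            vals = t.data.alos_min.to_numpy()
            if prev is not None:
                assert (vals <= prev + 1e-9).all()
            prev = vals

    def test_alos_nonincreasing_in_waittime_reduction(self):
        prev = None
        for r in (0.0, 0.1, 0.2, 0.3):
            t = run_experiment(PolicySpec.waittime(r) if r else PolicySpec.bau(), "peak")
            vals = t.data.alos_min.to_numpy()
            if prev is not None:
                assert (vals <= prev + 1e-9).all()
            prev = vals


class TestALOSEstimator:
    def test_saturated_stage_flagged_infinite(self, fractions):
        # no ambulatory doctors but steady inflow: standing queue, no starts
        p = replace(default_parameters(), NPAB=0.0)
        traj = EDSimulator(params=p, fractions=fractions,
                           arrivals=make_series(1.0)).run()
        assert math.isinf(compute_pathway_alos(traj, "ambulatory", 1, 2))

    def test_little_vs_fifo_tracer_under_congestion(self, peak_series):
        # two independent wait estimators agree on a congested day
        traj = EDSimulator(arrivals=peak_series).run()
        for venue in ("critical", "ambulatory"):
            for ph in (1, 2, 3):
                little = compute_pathway_alos(traj, venue, 1, ph)
                tracer = tracer_pathway_alos(traj, venue, 1, ph)
                assert little == pytest.approx(tracer, rel=0.05)

    def test_overload_wait_matches_fluid_queue_oracle(self, fractions):
        # single overloaded stage: constant inflow lambda > capacity mu for
        # the whole day; the fluid-limit wait of a patient arriving at time
        # t is q(t)/mu with q(t) = (lambda - mu) * t
        p = replace(default_parameters(), NPAB=1.0)
        lam_total = 0.2  # walk-ins/min
        traj = EDSimulator(params=p, fractions=fractions,
                           arrivals=make_series(lam_total)).run()
        lam = lam_total * float(DEFAULT_WALKIN_PRIORITY_MIX @ fractions.fab)
        mu = 1.0 / p.CT_ab.mean  # one doctor
        base = p.RT.mean + p.TT.mean
        start, end = 480.0, 960.0
        t_mid = (start + end) / 2 + base
        expected_wait = (lam - mu) * t_mid / mu
        got = compute_pathway_alos(traj, "ambulatory", 1, 2)
        got_wait = got - base - p.CT_ab.mean - p.LIT.mean
        assert got_wait == pytest.approx(expected_wait, rel=0.05)

    def test_unknown_pathway_rejected(self, uncongested_series):
        traj = EDSimulator(arrivals=uncongested_series).run()
        with pytest.raises(ValueError):
            compute_pathway_alos(traj, "critical", 9, 1)


class TestStochasticReplicates:
    def test_replicate_mean_near_deterministic(self):
        det = run_experiment(PolicySpec.bau(), "uncongested", mode="deterministic")
        sto = run_experiment(
            PolicySpec.bau(), "uncongested", mode="stochastic", replicates=10, seed=5
        )
        for (v, pw) in PATHWAYS:
            assert sto.cell(v, pw, 1) == pytest.approx(det.cell(v, pw, 1), rel=0.05)
        assert sto.replicates == 10
        assert (sto.data.alos_sd > 0).any()


class TestSweep:
    def test_shape(self, sweep_result):
        # bau + 2 policies x 2 intensities, 8 pathways x 3 phases each
        assert len(sweep_result) == (1 + 4) * len(PATHWAYS) * len(PHASE_WINDOWS)

    def test_bau_pct_change_zero(self, sweep_result):
        bau_rows = sweep_result[sweep_result.policy == "bau"]
        np.testing.assert_allclose(bau_rows.pct_change_vs_bau, 0.0, atol=1e-12)

    def test_pct_change_arithmetic(self, sweep_result):
        # spot-check: pct = (bau - policy) / bau * 100
        result = sweep_result
        row = result[(result.policy == "waittime") & (result.intensity == 0.3)
                     & (result.venue == "critical") & (result.pathway == 4)
                     & (result.phase == 1)].iloc[0]
        base = result[(result.policy == "bau") & (result.venue == "critical")
                      & (result.pathway == 4) & (result.phase == 1)].iloc[0]
        expected = (base.alos_min - row.alos_min) / base.alos_min * 100
        assert row.pct_change_vs_bau == pytest.approx(expected)
        # the reference arithmetic: a (166, 125) pair is a 24.7% reduction
        assert (166 - 125) / 166 * 100 == pytest.approx(24.7, abs=0.05)


class TestALOSTableInterface:
    def test_cell_lookup_and_pivot(self):
        t = run_experiment(PolicySpec.bau(), "uncongested")
        assert t.cell("critical", 1, "ph1") == t.cell("critical", 1, 1)
        piv = t.pivot()
        assert piv.shape == (len(PATHWAYS), 3)
        with pytest.raises(KeyError):
            t.cell("critical", 7, 1)

    def test_csv_export(self, tmp_path):
        import pandas as pd

        t = run_experiment(PolicySpec.bau(), "uncongested")
        path = tmp_path / "alos.csv"
        t.to_csv(path)
        back = pd.read_csv(path)
        assert {"policy", "venue", "pathway", "phase", "alos_min"} <= set(back.columns)
        assert len(back) == len(PATHWAYS) * 3
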