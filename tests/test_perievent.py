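"""Peri-event windows, spline bands, bootstrap CI and the scramble null."""

import numpy as np
import pandas as pd
import pytest

from vocloco import perievent as pe
from vocloco.splines import fit_spline

from conftest import make_arousal_sessions


def _events(onsets, durs):
    onsets = np.asarray(onsets, float)
    return pd.DataFrame({"onset_s": onsets, "offset_s": onsets + np.asarray(durs, float)})


class TestExtractWindows:
    def test_window_arithmetic(self):
        sig = np.arange(600.0)
        tr = pe.extract_windows(sig, _events([30.0], [2.0]), "locomotor")
        on = tr["onset"][0]
        assert on.rel_t[0] == -20 and on.rel_t[-1] == 5
        # onset trace covers absolute [10, 35] s
        assert on.values[0] == sig[10] and on.values[-1] == sig[35]

    def test_edge_clipping_pads_nan(self):
        sig = np.arange(600.0)
        on = pe.extract_windows(sig, _events([5.0], [1.0]), "locomotor")["onset"][0]
        assert np.isnan(on.values[on.rel_t < -5]).all()
        assert np.isfinite(on.values[on.rel_t >= -5]).all()

    def test_zero_events_empty(self):
        tr = pe.extract_windows(np.zeros(100), _events([], []), "heartrate")
        assert tr["onset"] == [] and tr["offset"] == []

    def test_heartrate_window_bounds(self):
        tr = pe.extract_windows(np.zeros(100), _events([50.0], [1.0]), "heartrate")
        assert (tr["onset"][0].rel_t[0], tr["onset"][0].rel_t[-1]) == (-10, 5)
        assert (tr["offset"][0].rel_t[0], tr["offset"][0].rel_t[-1]) == (-5, 10)


class TestStitch:
    def test_constant_signal_continuous_at_join(self):
        sig = np.full(200, 3.3)
        tr = pe.extract_windows(sig, _events([100.0], [1.0]), "locomotor")
        st = pe.stitch_call_axis(tr["onset"], tr["offset"])[0]
        assert np.allclose(st.values[np.isfinite(st.values)], 3.3)

    def test_step_at_onset(self):
        sig = np.zeros(200)
        sig[100:] = 1.0
        tr = pe.extract_windows(sig, _events([100.0], [2.0]), "locomotor")
        st = pe.stitch_call_axis(tr["onset"], tr["offset"])[0]
        assert np.nanmean(st.values[st.rel_t < 0]) < 0.1
        assert np.nanmean(st.values[st.rel_t > 0]) > 0.9

    def test_stitched_halves_equal_anchored_means(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(0, 1, 400)
        ev = _events([100.0, 200.0, 300.0], [2.0, 3.0, 1.0])
        tr = pe.extract_windows(sig, ev, "locomotor")
        st = pe.stitch_call_axis(tr["onset"], tr["offset"])
        pre = np.mean([t.values[t.rel_t < 0].mean() for t in st])
        pre_anchor = np.mean([t.values[t.rel_t < 0].mean() for t in tr["onset"]])
        post = np.mean([t.values[t.rel_t > 0].mean() for t in st])
        post_anchor = np.mean([t.values[t.rel_t > 0].mean() for t in tr["offset"]])
        assert pre == pytest.approx(pre_anchor)
        assert post == pytest.approx(post_anchor)

    def test_unpaired_traces_rejected(self):
        with pytest.raises(ValueError):
            pe.stitch_call_axis([], [pe.PeriEventTrace(0, "offset",
                                                       np.arange(3.0), np.zeros(3))])


class TestPopulationSpline:
    def test_identical_sessions_reproduce_shared_curve(self):
        rel = np.arange(-10.0, 6.0)
        vals = np.sin(rel / 4.0)
        s = fit_spline(rel, vals, 1.0)
        pop = pe.population_spline([s] * 5, rel, p=0.3)
        # smoothing pulls slightly toward a line; identical inputs should
        # still agree closely with the shared curve
        assert np.abs(pop(rel) - vals).max() < 0.05

    def test_single_session_close_to_resmoothed(self):
        rng = np.random.default_rng(1)
        rel = np.arange(-10.0, 6.0)
        s = fit_spline(rel, rng.normal(0, 1, len(rel)), 0.1)
        pop = pe.population_spline([s], rel, p=0.3)
        direct = fit_spline(rel, s(rel), 0.3)
        assert np.allclose(pop(rel), direct(rel), atol=1e-9)


class TestBootstrapCI:
    def _traces(self, n_sessions=3, n_traces=8, noise=1.0, seed=0):
        rng = np.random.default_rng(seed)
        rel = np.arange(-10.0, 6.0)
        out = []
        for s in range(n_sessions):
            out.append([pe.PeriEventTrace(i, "onset", rel,
                                          50 + noise * rng.normal(0, 1, len(rel)))
                        for i in range(n_traces)])
        return out, rel

    def test_zero_variance_band_collapses_to_observed(self):
        traces, rel = self._traces(noise=0.0)
        lo, hi = pe.bootstrap_ci(traces, rel, n_rep=50, seed=3)
        assert np.allclose(lo, hi)
        assert np.allclose(lo, 50.0, atol=1e-9)

    def test_same_seed_reproducible(self):
        traces, rel = self._traces(seed=5)
        b1 = pe.bootstrap_ci(traces, rel, n_rep=100, seed=9)
        b2 = pe.bootstrap_ci(traces, rel, n_rep=100, seed=9)
        assert np.array_equal(b1[0], b2[0]) and np.array_equal(b1[1], b2[1])

    def test_band_width_shrinks_with_session_count(self):
        t1, rel = self._traces(n_sessions=4, seed=1)
        t2, _ = self._traces(n_sessions=16, seed=2)
        lo1, hi1 = pe.bootstrap_ci(t1, rel, n_rep=400, seed=0)
        lo2, hi2 = pe.bootstrap_ci(t2, rel, n_rep=400, seed=0)
        ratio = np.mean(hi2 - lo2) / np.mean(hi1 - lo1)
        assert ratio == pytest.approx(0.5, abs=0.125)


class TestScrambleEvents:
    def test_preserves_counts_and_lengths(self):
        rng = np.random.default_rng(0)
        on = np.sort(rng.uniform(0, 500, 20))
        off = on + rng.uniform(1, 4, 20)
        pon, poff = pe.scramble_events(on, off, 600.0, rng)
        assert len(pon) == 20
        assert np.allclose(np.sort(poff - pon), np.sort(off - on))
        assert (np.diff(pon) >= 0).all()
        assert poff[-1] <= 600.0 + 1e-9

    def test_single_event_two_layouts(self):
        rng = np.random.default_rng(1)
        layouts = set()
        for _ in range(50):
            pon, poff = pe.scramble_events([10.0], [12.0], 60.0, rng)
            layouts.add(round(float(pon[0]), 6))
        # one event, one leading gap: the only layout keeps the original gap
        assert len(layouts) == 1
        assert layouts == {10.0}


class TestScrambleNull:
    def test_uncoupled_signal_mostly_inside(self):
        sessions = make_arousal_sessions(seed=100, n_sessions=5)
        band = pe.perievent_band(sessions, kind="heartrate", anchor="onset",
                                 n_rep=200, seed=7)
        inside = (band.exceed == "inside").mean()
        assert inside >= 0.75  # single study; the 200-study average is ~95%

    def test_constructed_coupling_flagged_above_at_zero(self):
        sessions = make_arousal_sessions(seed=200, n_sessions=6, effect=15.0)
        band = pe.perievent_band(sessions, kind="heartrate", anchor="onset",
                                 n_rep=200, seed=8)
        near0 = (band.grid >= -2) & (band.grid <= 2)
        assert (band.exceed[near0] == "above").any()

    def test_seed_reproducible(self):
        sessions = make_arousal_sessions(seed=300)
        b1 = pe.scramble_null(sessions, "heartrate", "onset", n_rep=50, seed=4)
        b2 = pe.scramble_null(sessions, "heartrate", "onset", n_rep=50, seed=4)
        assert np.array_equal(b1[0], b2[0])


class TestExceedance:
    def test_midline_all_inside(self):
        obs = np.zeros(10)
        flags, runs = pe.exceedance(obs, obs - 1, obs + 1)
        assert (flags == "inside").all() and runs == []

    def test_constructed_above_run(self):
        grid = np.arange(-10, 6)
        hi = np.zeros(len(grid))
        obs = np.where((grid >= -8) & (grid <= 0), 0.1, -0.5)
        flags, runs = pe.exceedance(obs, hi - 1, hi)
        assert len(runs) == 1
        assert runs[0]["flag"] == "above"
        assert grid[runs[0]["start"]] == -8 and grid[runs[0]["end"]] == 0

    def test_matches_naive_pointwise_oracle(self):
        rng = np.random.default_rng(2)
        obs = rng.normal(0, 1, 50)
        lo, hi = -0.5 * np.ones(50), 0.5 * np.ones(50)
        flags, _ = pe.exceedance(obs, lo, hi)
        naive = ["above" if o > h else "below" if o < l else "inside"
                 for o, l, h in zip(obs, lo, hi)]
        assert list(flags) == naive

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pe.exceedance(np.zeros(5), np.zeros(4), np.zeros(5))


class TestDevelopmentalCurve:
    def test_constant_signal_flat_curve(self):
        sessions = []
        for pnd in (5, 15, 25, 35, 45):
            sig = np.full(120, 42.0)
            sessions.append(pe.SessionSignal(
                sig, _events([20.0, 60.0, 90.0], [2.0, 2.0, 2.0]),
                120.0, pnd=pnd))
        band = pe.developmental_curve(sessions, n_rep=50, seed=0)
        assert np.allclose(band.observed, 42.0, atol=1e-6)

    def test_configured_increase_recovered_in_slope_sign(self):
        rng = np.random.default_rng(3)
        sessions = []
        for pnd in range(1, 42, 2):
            sig = 40 + 0.5 * pnd + rng.normal(0, 3, 180)
            on = np.sort(rng.uniform(5, 170, 8))
            sessions.append(pe.SessionSignal(
                sig, _events(on, np.full(8, 2.0)), 180.0, pnd=pnd))
        band = pe.developmental_curve(sessions, n_rep=50, seed=1)
        assert band.observed[-1] > band.observed[0]

    def test_no_eligible_sessions_explicit_status(self):
        band = pe.developmental_curve([], n_rep=10, seed=0)
        assert band.status == "no eligible sessions"
        assert band.observed.size == 0
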