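"""DF maps, phase, PS detection/linking, mother-rotor classification."""

import numpy as np
import pytest

from atriasim import fixtures as fx
from atriasim import wavedynamics as wd
from atriasim.propagation import SimulationResult
from atriasim.wavedynamics import (
    MotherRotorCriterion,
    PhaseField,
    PSEvent,
    PSTrajectory,
    classify_mother_rotor,
    compute_df_map,
    compute_phase,
    detect_ps,
    detect_ps_movie,
    link_trajectories,
    minimal_enclosing_circle,
    top_df_region,
)


def _movie(signals, dt_ms=10.0):
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    times = np.arange(x.shape[1]) * dt_ms
    return SimulationResult(times=times, vm=x)


class TestDominantFrequency:
    def test_pure_tone(self):
        t = np.arange(0, 6000, 10) / 1000.0
        res = _movie(30.0 * np.sin(2 * np.pi * 6.0 * t))
        df = compute_df_map(res)
        assert df.df_hz[0] == pytest.approx(6.0, abs=1.0 / 6.0)

    def test_larger_amplitude_wins(self):
        t = np.arange(0, 6000, 10) / 1000.0
        sig = 10.0 * np.sin(2 * np.pi * 4.0 * t) + 20.0 * np.sin(2 * np.pi * 8.0 * t)
        df = compute_df_map(_movie(sig))
        assert df.df_hz[0] == pytest.approx(8.0, abs=1.0 / 6.0)

    def test_constant_trace_flagged_undefined(self):
        res = _movie(np.full(600, -80.0))
        df = compute_df_map(res)
        assert np.isnan(df.df_hz[0])

    def test_window_too_short_rejected(self):
        res = _movie(np.sin(np.arange(50)))
        with pytest.raises(ValueError, match="1 s"):
            compute_df_map(res)

    def test_argmax_matches_bruteforce_periodogram(self, rng):
        """DF equals an independent per-node scan of the tapered periodogram."""
        t = np.arange(0, 6000, 10) / 1000.0
        freqs = rng.uniform(2.0, 15.0, size=8)
        sig = np.array([
            25.0 * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            + 5.0 * rng.normal(size=t.size)
            for f in freqs
        ])
        res = _movie(sig)
        df = compute_df_map(res)
        win = np.hanning(t.size)
        for node in range(len(freqs)):
            x = sig[node] - sig[node].mean()
            best_f, best_p = None, -1.0
            for k, f in enumerate(np.fft.rfftfreq(t.size, d=0.01)):
                if not 1.0 <= f <= 20.0:
                    continue
                p = np.abs(np.fft.rfft(x * win)[k]) ** 2
                if p > best_p:
                    best_p, best_f = p, f
            assert df.df_hz[node] == pytest.approx(best_f, abs=1e-9)


class TestTopDFRegion:
    def _map(self, values):
        v = np.asarray(values, dtype=float)
        return wd.DFMap(df_hz=v, peak_power=np.ones_like(v), window_s=6.0,
                        band_hz=(1, 20))

    def test_exact_count_for_distinct_values(self):
        dfmap = self._map(np.arange(100.0) / 10.0 + 1.0)
        top, peak = top_df_region(dfmap, 0.05)
        assert len(top) == 5
        assert peak == 99

    def test_all_ties_return_everything_with_warning(self):
        dfmap = self._map(np.full(50, 7.0))
        with pytest.warns(UserWarning, match="tie|whole map|equal"):
            top, _ = top_df_region(dfmap, 0.05)
        assert len(top) == 50

    def test_fraction_one_returns_all(self):
        dfmap = self._map(np.arange(30.0) + 1.0)
        top, _ = top_df_region(dfmap, 1.0)
        assert len(top) == 30

    def test_invalid_fraction_rejected(self):
        dfmap = self._map(np.arange(30.0) + 1.0)
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                top_df_region(dfmap, bad)


class TestPhase:
    def test_sinusoid_advances_2pi_per_period(self):
        t = np.arange(0, 2000, 10) / 1000.0
        res = _movie(30.0 * np.sin(2 * np.pi * 5.0 * t))
        ph = compute_phase(res)
        un = np.unwrap(ph.phase[0])
        # interior advance over exactly 5 periods (1 s), edges excluded
        k = np.searchsorted(ph.times, [500.0, 1500.0])
        advance = un[k[1]] - un[k[0]]
        assert advance == pytest.approx(2 * np.pi * 5.0, rel=0.05)

    def test_amplitude_scaling_leaves_phase_unchanged(self):
        t = np.arange(0, 2000, 10) / 1000.0
        base = 10.0 * np.sin(2 * np.pi * 5.0 * t) + 3.0 * np.sin(2 * np.pi * 10.0 * t)
        a = compute_phase(_movie(base))
        b = compute_phase(_movie(5.0 * base))
        assert np.allclose(a.phase, b.phase, atol=1e-9)

    def test_constant_node_flagged_undefined(self):
        res = _movie(np.full(400, -80.0))
        ph = compute_phase(res)
        assert not ph.defined[0]


class TestDetectPS:
    def test_vortex_field_yields_single_ps(self, sheet_coarse):
        x0, y0 = 15.2, 15.1
        th = np.arctan2(sheet_coarse.nodes[:, 1] - y0, sheet_coarse.nodes[:, 0] - x0)
        ph = PhaseField(times=np.array([0.0]), phase=th[:, None],
                        defined=np.ones(sheet_coarse.n_nodes, bool))
        events = detect_ps(ph, sheet_coarse, 0)
        assert len(events) == 1
        assert events[0].chirality == 1
        assert np.linalg.norm(events[0].location[:2] - [x0, y0]) < 1.0

    def test_uniform_phase_has_no_ps(self, sheet_coarse):
        ph = PhaseField(times=np.array([0.0]),
                        phase=np.full((sheet_coarse.n_nodes, 1), 0.3),
                        defined=np.ones(sheet_coarse.n_nodes, bool))
        assert detect_ps(ph, sheet_coarse, 0) == []

    def test_topological_charge_vanishes_on_closed_surface(self, sphere_mesh):
        th = np.arctan2(sphere_mesh.nodes[:, 1], sphere_mesh.nodes[:, 0])
        ph = PhaseField(times=np.array([0.0]), phase=th[:, None],
                        defined=np.ones(sphere_mesh.n_nodes, bool))
        events = detect_ps(ph, sphere_mesh, 0)
        assert len(events) >= 2
        assert sum(e.chirality for e in events) == 0

    def test_spiral_tip_tracked_within_one_edge(self, sheet_coarse, spiral_movie):
        movie, tips = spiral_movie
        ph = compute_phase(movie)
        edge = sheet_coarse.statistics().mean_spacing_um / 1000.0
        checked = 0
        for k in range(5, ph.times.size - 5):
            events = detect_ps(ph, sheet_coarse, k)
            if not events:
                continue
            err = min(
                np.linalg.norm(e.location[:2] - tips[k, :2]) for e in events
            )
            assert err < edge
            checked += 1
        assert checked > 100

    def test_chirality_flips_with_rotation_direction(self, sheet_coarse):
        for ch in (1, -1):
            movie, _ = fx.make_spiral_movie(
                sheet_coarse, duration_ms=400.0, chirality=ch
            )
            ph = compute_phase(movie)
            events = detect_ps(ph, sheet_coarse, 20)
            assert events and all(e.chirality == ch for e in events)


def _ev(t, xyz, ch=1, face=0):
    return PSEvent(time_ms=float(t), face=face,
                   location=np.asarray(xyz, dtype=float), chirality=ch)


class TestLinking:
    def test_stationary_ps_forms_one_trajectory(self):
        frames = [[_ev(10.0 * k, [5.0, 5.0, 0.0])] for k in range(10)]
        trajs, _ = link_trajectories(frames)
        assert len(trajs) == 1
        assert trajs[0].lifespan_ms == 90.0

    def test_distant_simultaneous_ps_stay_separate(self):
        frames = [
            [_ev(10.0 * k, [0.0, 0.0, 0.0]), _ev(10.0 * k, [20.0, 0.0, 0.0])]
            for k in range(5)
        ]
        trajs, _ = link_trajectories(frames, max_step_mm=5.0)
        assert len(trajs) == 2

    def test_slow_drift_is_linked(self):
        frames = [[_ev(10.0 * k, [0.5 * k, 0.0, 0.0])] for k in range(20)]
        trajs, _ = link_trajectories(frames, max_step_mm=5.0)
        assert len(trajs) == 1
        assert trajs[0].max_tip_displacement() == pytest.approx(9.5)

    def test_chirality_never_mixes(self):
        frames = [[_ev(10.0 * k, [0.0, 0.0, 0.0], ch=1 if k % 2 else -1)]
                  for k in range(6)]
        trajs, _ = link_trajectories(frames)
        assert all(len({e.chirality for e in t.events}) == 1 for t in trajs)

    def test_regional_counts(self, sheet_coarse):
        labeled = fx.make_labeled_regions(sheet_coarse, 4, seed=0)
        frames = [[_ev(10.0 * k, labeled.nodes[10])] for k in range(5)]
        _, counts = link_trajectories(frames, labeled)
        lab = int(labeled.region[10])
        assert counts["events"][lab] == 5
        assert counts["trajectories"][lab] == 1


class TestMotherRotor:
    def _stationary(self, lifespan_ms, n=60, meander_mm=0.0):
        ts = np.linspace(0.0, lifespan_ms, n)
        ang = np.linspace(0.0, 6 * np.pi, n)
        return PSTrajectory(events=[
            _ev(t, [0.5 * meander_mm * np.cos(a), 0.5 * meander_mm * np.sin(a), 0.0])
            for t, a in zip(ts, ang)
        ])

    def test_stationary_long_lived_rotor_qualifies(self):
        crit = MotherRotorCriterion(wavelength_mm=80.0)
        assert classify_mother_rotor(self._stationary(6000.0), crit)

    def test_wide_meander_disqualifies(self):
        crit = MotherRotorCriterion(wavelength_mm=80.0)
        traj = self._stationary(6000.0, meander_mm=60.0)
        assert traj.confinement_diameter() == pytest.approx(60.0, rel=0.05)
        assert not classify_mother_rotor(traj, crit)

    def test_short_lifespan_disqualifies(self):
        crit = MotherRotorCriterion(wavelength_mm=80.0)
        assert not classify_mother_rotor(self._stationary(3000.0), crit)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            classify_mother_rotor(PSTrajectory(events=[]),
                                  MotherRotorCriterion(wavelength_mm=80.0))

    def test_criterion_from_planar_wave(self):
        crit = MotherRotorCriterion.from_planar_wave(0.5, 600.0)
        assert crit.wavelength_mm == 300.0
        assert crit.confinement_diameter_mm == 150.0


class TestMinimalEnclosingCircle:
    def test_known_circle(self):
        pts = np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        center, r = minimal_enclosing_circle(pts)
        assert r == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(center, 0.0, atol=1e-9)

    def test_collinear_points(self):
        pts = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        _, r = minimal_enclosing_circle(pts)
        assert r == pytest.approx(2.5, abs=1e-9)

    def test_single_point(self):
        _, r = minimal_enclosing_circle(np.array([[3.0, 4.0, 5.0]]))
        assert r == 0.0

    def test_contains_all_points(self, rng):
        pts = np.column_stack([rng.normal(size=(40, 2)), np.zeros(40)])
        center, r = minimal_enclosing_circle(pts)
        d = np.linalg.norm(pts - center, axis=1)
        assert d.max() <= r + 1e-9
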