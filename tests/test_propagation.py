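"""Monodomain solver: operator assembly, wave propagation, protocols."""

import numpy as np
import pytest

from atriasim import fixtures as fx
from atriasim import geometry as geo
from atriasim import ionic
from atriasim import propagation as prop
from atriasim.geometry import AtrialMesh, assign_fiber_field, generate_sheet_mesh
from atriasim.propagation import (
    ConductivitySet,
    LATMap,
    PacingProtocol,
    build_diffusion,
    detect_induction,
    disk_site,
    extract_lat,
    make_ramp_protocol,
    measure_cv,
    node_scaling,
    run_monodomain,
    tune_diffusion,
)

AF = ionic.af_remodeling_profile()


@pytest.fixture(scope="module")
def strip_mesh():
    """15 x 6 mm sheet at 500 µm with longitudinal fibers (~700 nodes)."""
    m = generate_sheet_mesh(15.0, 6.0, 500.0)
    return assign_fiber_field(m, "uniform", direction=[1.0, 0.0, 0.0])


@pytest.fixture(scope="module")
def strip_fine():
    """Same strip at the reference 235 µm density (~2000 nodes)."""
    m = generate_sheet_mesh(15.0, 6.0, 235.0)
    return assign_fiber_field(m, "uniform", direction=[1.0, 0.0, 0.0])


def _edge_protocol(mesh, amplitude=prop.TISSUE_STIM_AMPLITUDE):
    site = np.nonzero(mesh.nodes[:, 0] < 1.0)[0]
    return PacingProtocol(site_nodes=site, events=[(1.0, 2.0, amplitude)])


class TestConductivitySet:
    def test_defaults_are_the_published_values(self):
        c = ConductivitySet()
        assert (c.sigma_l_normal, c.sigma_l_fibrotic) == (0.1264, 0.0546)
        assert (c.sigma_t_normal, c.sigma_t_fibrotic) == (0.0252, 0.0068)

    def test_anisotropy_ordering_enforced(self):
        with pytest.raises(ValueError):
            ConductivitySet(sigma_l_normal=0.01, sigma_t_normal=0.02)

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            ConductivitySet(sigma_t_fibrotic=0.0)


class TestDiffusionOperator:
    def test_uniform_field_maps_to_zero(self, strip_mesh):
        op = build_diffusion(strip_mesh, ConductivitySet(), (2.0, 4.0))
        u = np.full(strip_mesh.n_nodes, -81.18)
        assert np.abs(op.apply(u)).max() < 1e-10

    def test_stiffness_symmetric_with_zero_row_sums(self, strip_mesh):
        op = build_diffusion(strip_mesh, ConductivitySet(), (2.0, 4.0))
        k = op.stiffness
        assert np.abs((k - k.T).data).max() < 1e-12 if (k - k.T).nnz else True
        assert np.abs(np.asarray(k.sum(axis=1))).max() < 1e-12

    def test_total_diffusion_current_conserved(self, strip_mesh, rng):
        op = build_diffusion(strip_mesh, ConductivitySet(), (2.0, 4.0))
        u = rng.normal(size=strip_mesh.n_nodes) * 50.0
        # mass-weighted total of the diffusion update = -sum(K u) = 0
        total = np.sum(op.apply(u) / op.inv_mass)
        assert abs(total) < 1e-8 * np.abs(u).sum()

    def test_isotropic_operator_ignores_fiber_rotation(self, sheet_small):
        iso = ConductivitySet(
            sigma_l_normal=0.05, sigma_t_normal=0.05,
            sigma_l_fibrotic=0.02, sigma_t_fibrotic=0.02,
        )
        a = build_diffusion(
            assign_fiber_field(sheet_small, "uniform", direction=[1, 0, 0]),
            iso, (3.0, 3.0),
        )
        b = build_diffusion(
            assign_fiber_field(sheet_small, "uniform", direction=[0.3, 1.0, 0]),
            iso, (3.0, 3.0),
        )
        assert np.allclose(a.stiffness.toarray(), b.stiffness.toarray(), atol=1e-10)

    def test_matches_hand_assembled_stiffness(self):
        """Two right triangles on the unit square, isotropic D = 1."""
        mesh = AtrialMesh(
            nodes=np.array(
                [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [1.0, 1.0, 0.0]]
            ),
            triangles=np.array([[0, 1, 2], [1, 3, 2]]),
            fiber=np.tile([1.0, 0.0, 0.0], (4, 1)),
        )
        iso = ConductivitySet(
            sigma_l_normal=1.0, sigma_t_normal=1.0,
            sigma_l_fibrotic=1.0, sigma_t_fibrotic=1.0,
        )
        op = build_diffusion(mesh, iso, (1.0, 1.0))
        # per-triangle stiffness of a unit right triangle with D = 1:
        # K = 1/2 * [[2, -1, -1], [-1, 1, 0], [-1, 0, 1]] at the right-angle
        # vertex ordering; assemble both triangles by hand
        expected = np.zeros((4, 4))
        k_local = 0.5 * np.array([[2.0, -1.0, -1.0], [-1.0, 1.0, 0.0], [-1.0, 0.0, 1.0]])
        for tri, right in (((0, 1, 2), 0), ((3, 2, 1), 0)):
            order = (tri[right], *[v for i, v in enumerate(tri) if i != right])
            for a, ia in zip(order, range(3)):
                for b, ib in zip(order, range(3)):
                    expected[a, b] += k_local[ia, ib]
        assert np.allclose(op.stiffness.toarray(), expected, atol=1e-12)

    def test_missing_fibers_rejected(self, sheet_small):
        bare = sheet_small.copy()
        bare.fiber = None
        with pytest.raises(ValueError, match="fiber"):
            build_diffusion(bare, ConductivitySet(), (1.0, 1.0))


class TestMonodomainRuns:
    def test_unstimulated_tissue_stays_at_rest(self, strip_mesh):
        op = build_diffusion(strip_mesh, ConductivitySet(), (2.0, 4.0))
        proto = PacingProtocol(site_nodes=np.array([0]), events=[])
        res = run_monodomain(strip_mesh, op, ionic.neutral_profile(), proto,
                             duration=1000.0, output_interval=10.0)
        assert np.abs(res.vm - res.vm[:, :1]).max() < 1.0

    def test_planar_wave_lat_is_linear_in_distance(self, strip_mesh):
        op = build_diffusion(strip_mesh, ConductivitySet(), (2.0, 2.0))
        res = run_monodomain(
            strip_mesh, op, AF, _edge_protocol(strip_mesh), duration=60.0,
            output_interval=0.5,
        )
        lat = extract_lat(res, event_time=1.0)
        x = strip_mesh.nodes[:, 0]
        sel = (x > 3.0) & (x < 13.0) & lat.activated
        r = np.corrcoef(x[sel], lat.lat[sel])[0, 1]
        assert r ** 2 > 0.99

    def test_bitwise_deterministic(self, strip_mesh):
        op = build_diffusion(strip_mesh, ConductivitySet(), (2.0, 2.0))
        a = run_monodomain(strip_mesh, op, AF, _edge_protocol(strip_mesh),
                           duration=20.0, output_interval=1.0)
        b = run_monodomain(strip_mesh, op, AF, _edge_protocol(strip_mesh),
                           duration=20.0, output_interval=1.0)
        assert np.array_equal(a.vm, b.vm)

    def test_cv_scales_as_sqrt_diffusion(self, strip_fine):
        """Across a 4x range of kappa the planar CV tracks √kappa.

        Measured at the reference 235 µm density, where the wavefront is
        well resolved; on coarser meshes discrete propagation slows the
        low-diffusion end below the continuum law.
        """
        pa, pb = prop._centerline_probes(strip_fine, 4.0, 11.0)
        cv2 = prop._planar_cv(strip_fine, ConductivitySet(), (2.0, 2.0),
                              pa, pb, AF, duration=80.0)
        cv8 = prop._planar_cv(strip_fine, ConductivitySet(), (8.0, 8.0),
                              pa, pb, AF, duration=80.0)
        assert cv8 / cv2 == pytest.approx(2.0, rel=0.05)

    def test_cv_converges_under_mesh_refinement(self, strip_fine):
        """Halving the 235 µm spacing changes planar CV by < 3 %."""
        fine2 = assign_fiber_field(
            generate_sheet_mesh(15.0, 6.0, 117.5), "uniform",
            direction=[1.0, 0.0, 0.0],
        )
        cv_ref = prop._planar_cv(
            strip_fine, ConductivitySet(), (2.0, 2.0),
            *prop._centerline_probes(strip_fine, 4.0, 11.0), AF, duration=80.0,
        )
        cv_half = prop._planar_cv(
            fine2, ConductivitySet(), (2.0, 2.0),
            *prop._centerline_probes(fine2, 4.0, 11.0), AF, duration=80.0,
        )
        assert abs(cv_half - cv_ref) / cv_ref < 0.03

    def test_fibrosis_slows_conduction_in_both_directions(self, strip_mesh):
        pa, pb = prop._centerline_probes(strip_mesh, 4.0, 11.0)
        fibrotic = strip_mesh.copy()
        fibrotic.fibrosis[:] = True
        for direction in ([1.0, 0.0, 0.0], [0.0, 1.0, 0.0]):
            healthy_m = assign_fiber_field(strip_mesh, "uniform", direction=direction)
            fib_m = assign_fiber_field(fibrotic, "uniform", direction=direction)
            fib_m.fibrosis[:] = True
            cv_h = prop._planar_cv(healthy_m, ConductivitySet(), (2.0, 2.0),
                                   pa, pb, AF, duration=120.0)
            cv_f = prop._planar_cv(fib_m, ConductivitySet(), (2.0, 2.0),
                                   pa, pb, AF, duration=120.0)
            assert cv_f < cv_h

    def test_subthreshold_stimulus_has_no_capture(self, strip_mesh):
        op = build_diffusion(strip_mesh, ConductivitySet(), (2.0, 2.0))
        res = run_monodomain(
            strip_mesh, op, AF, _edge_protocol(strip_mesh, amplitude=-100.0),
            duration=30.0, output_interval=1.0,
        )
        with pytest.raises(ValueError, match="capture"):
            extract_lat(res, event_time=1.0)

    def test_wrong_operator_or_scaling_rejected(self, strip_mesh, sheet_small):
        op_other = build_diffusion(
            assign_fiber_field(sheet_small, "uniform", direction=[1, 0, 0]),
            ConductivitySet(), (1.0, 1.0),
        )
        with pytest.raises(ValueError, match="different mesh"):
            run_monodomain(strip_mesh, op_other, AF,
                           _edge_protocol(strip_mesh), duration=10.0)

    def test_result_roundtrips_through_hdf5(self, strip_mesh, tmp_path):
        op = build_diffusion(strip_mesh, ConductivitySet(), (2.0, 2.0))
        res = run_monodomain(strip_mesh, op, AF, _edge_protocol(strip_mesh),
                             duration=10.0, output_interval=1.0)
        path = str(tmp_path / "movie.h5")
        res.save(path, mesh=strip_mesh)
        back = prop.SimulationResult.load(path)
        assert np.array_equal(back.vm, res.vm)
        assert np.array_equal(back.times, res.times)


class TestLATAndCV:
    def _latmap(self, mesh, speed):
        lat = mesh.nodes[:, 0] / speed
        return LATMap(lat=lat, activated=np.ones(mesh.n_nodes, bool),
                      eas_node=int(np.argmin(lat)))

    def test_cv_arithmetic(self, sheet_small):
        # distance 10 mm in 20 ms -> 0.5 m/s
        latmap = self._latmap(sheet_small, 0.5)
        i1 = int(np.argmin(np.linalg.norm(sheet_small.nodes - [10, 0, 0], axis=1)))
        cv, mean = measure_cv(latmap, sheet_small, latmap.eas_node, [i1])
        assert mean == pytest.approx(0.5, rel=0.05)

    def test_target_equal_to_eas_rejected(self, sheet_small):
        latmap = self._latmap(sheet_small, 0.5)
        with pytest.raises(ValueError, match="non-positive"):
            measure_cv(latmap, sheet_small, latmap.eas_node, [latmap.eas_node])

    def test_stimulus_node_is_earliest(self, strip_mesh):
        op = build_diffusion(strip_mesh, ConductivitySet(), (2.0, 2.0))
        res = run_monodomain(strip_mesh, op, AF, _edge_protocol(strip_mesh),
                             duration=40.0, output_interval=0.5)
        lat = extract_lat(res, event_time=1.0)
        assert strip_mesh.nodes[lat.eas_node, 0] < 1.5


class TestTuning:
    def test_recovers_unit_scale_as_fixed_point(self, strip_mesh):
        cond = ConductivitySet()
        kappa = (2.0, 2.0)
        site = np.nonzero(strip_mesh.nodes[:, 0] < 1.0)[0]
        x = strip_mesh.nodes[:, 0]
        targets = np.array([
            int(np.argmin(np.abs(x - d) + np.abs(strip_mesh.nodes[:, 1] - 3.0)))
            for d in (6.0, 9.0, 12.0)
        ])
        op = build_diffusion(strip_mesh, cond, kappa)
        proto = PacingProtocol(site_nodes=site,
                               events=[(1.0, 2.0, prop.TISSUE_STIM_AMPLITUDE)])
        res = run_monodomain(strip_mesh, op, AF, proto, duration=80.0,
                             output_interval=0.5, stop_when_activated=targets)
        lat = extract_lat(res, event_time=1.0)
        clinical = lat.lat[targets] - np.nanmin(lat.lat)
        scale, residuals = tune_diffusion(
            strip_mesh, cond, kappa, AF, site, targets, clinical,
        )
        assert scale == pytest.approx(1.0, abs=0.02)
        assert np.abs(residuals).max() < 5.0

    def test_degenerate_clinical_times_rejected(self, strip_mesh):
        with pytest.raises(ValueError, match="positive mean"):
            tune_diffusion(
                strip_mesh, ConductivitySet(), (2.0, 2.0), AF,
                np.array([0]), np.array([5, 6]), np.array([0.0, 0.0]),
            )


class TestRampProtocol:
    def test_default_matches_published_duration(self):
        p = make_ramp_protocol(np.array([0]))
        assert p.total_duration == 6530.0
        onsets = np.array([t for t, _, _ in p.events])
        assert np.all(np.diff(onsets) > 0)
        assert onsets[0] == 0.0
        # the ramp walks from 200 ms down to 120 ms cycle length
        cls = np.diff(onsets)
        assert cls[0] == 200.0
        assert cls[-1] == 120.0
        # pacing fills the stated overall duration
        assert onsets[-1] + 120.0 <= 6530.0 + 1e-9
        assert 6530.0 - (onsets[-1] + 120.0) < 120.0

    def test_constant_cl_beat_count(self):
        p = make_ramp_protocol(np.array([0]), cl_start=200.0, cl_end=199.0,
                               total_ms=1000.0, cl_step=1.0, beats_per_step=5)
        assert len(p.events) == 5

    def test_inverted_ramp_rejected(self):
        with pytest.raises(ValueError):
            make_ramp_protocol(np.array([0]), cl_start=120.0, cl_end=200.0)

    def test_infeasible_total_rejected(self):
        with pytest.raises(ValueError):
            make_ramp_protocol(np.array([0]), total_ms=100.0)


class TestInductionDetection:
    def _protocol(self, end_ms):
        return PacingProtocol(
            site_nodes=np.array([0]), events=[(end_ms - 2.0, 2.0, -4000.0)]
        )

    def test_quiescent_tissue_not_induced(self, sheet_small):
        times = np.arange(0.0, 6501.0, 10.0)
        vm = np.full((sheet_small.n_nodes, times.size), -81.0, dtype=np.float32)
        res = prop.SimulationResult(times=times, vm=vm)
        induced, _ = detect_induction(res, self._protocol(400.0))
        assert not induced

    def test_sustained_spiral_is_induced(self, sheet_coarse):
        movie, _ = fx.make_spiral_movie(sheet_coarse, duration_ms=6600.0,
                                        output_interval_ms=10.0)
        induced, window = detect_induction(movie, self._protocol(400.0))
        assert induced
        assert window == (400.0, 6400.0)

    def test_short_movie_rejected(self, sheet_small):
        times = np.arange(0.0, 2001.0, 10.0)
        vm = np.full((sheet_small.n_nodes, times.size), -81.0, dtype=np.float32)
        res = prop.SimulationResult(times=times, vm=vm)
        with pytest.raises(ValueError, match="needs"):
            detect_induction(res, self._protocol(400.0))
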