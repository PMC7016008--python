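"""Electro-anatomical maps: alignment, IDW, fibrosis model, statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atriasim import emap as em
from atriasim.emap import (
    ElectroAnatomicalMap,
    FibrosisModel,
    NodeField,
    assign_fibrosis,
    fibrosis_probability,
    generate_synthetic_emap,
    idw_interpolate,
    map_agreement,
    read_emap,
    rigid_align,
    write_emap,
)


def _flat_map(points, voltages, lats=None):
    pts = np.asarray(points, dtype=float)
    if lats is None:
        lats = np.zeros(len(pts))
    return ElectroAnatomicalMap(
        points=pts, bipolar_voltage=np.asarray(voltages, dtype=float),
        lat=np.asarray(lats, dtype=float),
    )


class TestFibrosisProbability:
    @pytest.mark.parametrize(
        "x,expected",
        [
            (0.0, 0.998),     # cubic's constant term, percent scale
            (0.5, 0.3055),    # direct evaluation of the cubic
            (-0.1, 1.0),      # piecewise: negative voltage
            (5.0, 0.0),       # above the 1.74 mV cutoff
        ],
    )
    def test_reference_values(self, x, expected):
        assert fibrosis_probability(x) == pytest.approx(expected, abs=1e-6)

    def test_continuity_at_cutoff(self):
        assert abs(fibrosis_probability(1.74)) < 0.01
        assert abs(fibrosis_probability(1.74) - fibrosis_probability(1.7401)) < 0.01

    @given(st.floats(min_value=0.0, max_value=3.0))
    @settings(deadline=None, max_examples=50)
    def test_bounded(self, x):
        p = fibrosis_probability(x)
        assert 0.0 <= p <= 1.0

    def test_monotone_non_increasing(self):
        grid = np.linspace(-0.5, 3.0, 400)
        p = fibrosis_probability(grid)
        assert np.all(np.diff(p) <= 1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            fibrosis_probability(np.nan)


class TestIDW:
    def test_constant_map_everywhere(self, sheet_small):
        pts = sheet_small.nodes[::7] + [0.1, 0.05, 0.0]
        f = idw_interpolate(
            _flat_map(pts, np.full(len(pts), 1.8)), sheet_small
        )
        assert np.allclose(f.values[f.covered], 1.8)

    def test_exact_hit_returns_sample(self, sheet_small):
        node = sheet_small.nodes[11]
        m = _flat_map([node, node + [3.0, 0, 0]], [1.8, 0.4])
        f = idw_interpolate(m, sheet_small)
        assert f.values[11] == pytest.approx(1.8, abs=1e-12)

    def test_equidistant_samples_average(self):
        from atriasim.geometry import AtrialMesh

        mesh = AtrialMesh(
            nodes=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.5, 1.0, 0.0]]),
            triangles=np.array([[0, 1, 2]]),
        )
        m = _flat_map([[-2.0, 0, 0], [2.0, 0, 0]], [1.0, 3.0])
        f = idw_interpolate(m, mesh)
        assert f.values[0] == pytest.approx(2.0, rel=1e-9)  # node at origin

    def test_output_bounded_by_samples(self, sheet_small, rng):
        pts = sheet_small.nodes[rng.choice(sheet_small.n_nodes, 40, replace=False)]
        v = rng.uniform(0.1, 3.5, 40)
        f = idw_interpolate(_flat_map(pts, v), sheet_small)
        assert np.nanmin(f.values) >= v.min() - 1e-9
        assert np.nanmax(f.values) <= v.max() + 1e-9

    def test_uncovered_nodes_flagged(self, sheet_small):
        m = _flat_map([[0.0, 0.0, 0.0]], [1.0])
        f = idw_interpolate(m, sheet_small, radius_mm=2.0)
        far = np.linalg.norm(sheet_small.nodes, axis=1) > 2.0
        assert not f.covered[far].any()
        assert np.isnan(f.values[far]).all()

    def test_bad_radius_rejected(self, sheet_small):
        with pytest.raises(ValueError):
            idw_interpolate(_flat_map([[0, 0, 0]], [1.0]), sheet_small, radius_mm=0.0)


class TestRigidAlign:
    def test_identity_landmarks(self):
        m = _flat_map(np.random.default_rng(0).random((20, 3)) * 10, np.ones(20))
        aligned, res = rigid_align(m, m.points[:4], m.points[:4])
        assert res < 1e-9
        assert np.allclose(aligned.points, m.points)

    def test_recovers_known_transform(self, rng):
        pts = rng.random((30, 3)) * 20.0
        th = np.radians(30.0)
        rot = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        moved = pts @ rot.T + [3.0, -2.0, 5.0]
        m = _flat_map(moved, np.ones(30))
        aligned, res = rigid_align(m, moved[:5], pts[:5])
        assert res < 1e-6
        assert np.abs(aligned.points - pts).max() < 1e-6

    def test_two_landmarks_rejected(self):
        m = _flat_map([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [1, 1, 1])
        with pytest.raises(ValueError):
            rigid_align(m, m.points[:2], m.points[:2])

    def test_collinear_landmarks_rejected(self):
        m = _flat_map([[0, 0, 0], [1, 0, 0], [2, 0, 0]], [1, 1, 1])
        with pytest.raises(ValueError, match="collinear"):
            rigid_align(m, m.points, m.points)


class TestAssignFibrosis:
    def _uniform_field(self, mesh, value):
        return NodeField(
            values=np.full(mesh.n_nodes, value),
            covered=np.ones(mesh.n_nodes, dtype=bool),
        )

    def test_healthy_voltage_gives_no_fibrosis(self, sheet_small):
        out, frac = assign_fibrosis(sheet_small, self._uniform_field(sheet_small, 5.0))
        assert frac == 0.0
        assert not out.fibrosis.any()

    def test_fraction_matches_probability(self, sheet_coarse):
        # binomial concentration at three voltages; ~3000 nodes per draw
        for voltage in (0.2, 0.5, 1.0):
            p = fibrosis_probability(voltage)
            out, frac = assign_fibrosis(
                sheet_coarse, self._uniform_field(sheet_coarse, voltage),
                FibrosisModel(rng_seed=7),
            )
            se = np.sqrt(p * (1 - p) / sheet_coarse.n_nodes)
            assert abs(frac - p) < 3.0 * se + 1e-9

    def test_reproducible_for_fixed_seed(self, sheet_small):
        f = self._uniform_field(sheet_small, 0.8)
        a, _ = assign_fibrosis(sheet_small, f, FibrosisModel(rng_seed=3))
        b, _ = assign_fibrosis(sheet_small, f, FibrosisModel(rng_seed=3))
        assert np.array_equal(a.fibrosis, b.fibrosis)


class TestMapAgreement:
    def _field(self, values):
        v = np.asarray(values, dtype=float)
        return NodeField(values=v, covered=np.ones(v.size, dtype=bool))

    def test_identity(self):
        a = self._field([1.0, 2.0, 3.0, 4.0])
        out = map_agreement(a, a)
        assert out["overall"]["pearson_r"] == pytest.approx(1.0)
        assert out["overall"]["rmse"] == 0.0

    def test_anticorrelation(self):
        a = self._field([1.0, 2.0, 3.0])
        b = self._field([-1.0, -2.0, -3.0])
        assert map_agreement(a, b)["overall"]["pearson_r"] == pytest.approx(-1.0)

    def test_hand_computed_rmse(self):
        a = self._field([1.0, 2.0, 3.0])
        b = self._field([1.0, 2.0, 4.0])
        out = map_agreement(a, b)["overall"]
        assert out["rmse"] == pytest.approx(1.0 / np.sqrt(3.0))
        assert out["percent_rmse"] == pytest.approx(100.0 * out["rmse"] / 2.0)

    def test_sparse_region_skipped_with_warning(self):
        a = self._field(np.arange(10.0))
        regions = np.array([1] * 9 + [2])
        with pytest.warns(UserWarning, match="region 2"):
            out = map_agreement(a, a, regions)
        assert 1 in out and 2 not in out


class TestSyntheticEmap:
    def test_zero_noise_recovery(self, sheet_coarse):
        m, v_truth, _ = generate_synthetic_emap(
            sheet_coarse, n_points=600, seed=3,
            voltage_noise_sd=0.0, lat_noise_sd=0.0, jitter_mm=0.0,
        )
        f = idw_interpolate(m, sheet_coarse)
        r = np.corrcoef(f.values[f.covered], v_truth.values[f.covered])[0, 1]
        assert r > 0.95

    def test_voltage_truth_spans_clinical_range(self, sheet_coarse):
        _, v_truth, _ = generate_synthetic_emap(sheet_coarse, seed=5)
        assert v_truth.values.min() == pytest.approx(0.1, abs=0.01)
        assert v_truth.values.max() == pytest.approx(3.5, abs=0.01)

    def test_lat_truth_spreads_from_eas(self, sheet_coarse):
        _, _, lat_truth = generate_synthetic_emap(
            sheet_coarse, seed=5, eas_node=0, conduction_speed_m_s=0.7
        )
        assert lat_truth.values[0] == 0.0
        assert np.all(lat_truth.values >= 0.0)

    def test_same_seed_is_bit_identical(self, sheet_small):
        a, _, _ = generate_synthetic_emap(sheet_small, n_points=50, seed=11)
        b, _, _ = generate_synthetic_emap(sheet_small, n_points=50, seed=11)
        assert np.array_equal(a.points, b.points)
        assert np.array_equal(a.bipolar_voltage, b.bipolar_voltage)

    def test_oversampling_rejected(self, sheet_small):
        with pytest.raises(ValueError):
            generate_synthetic_emap(sheet_small, n_points=10 ** 6)


class TestEmapIO:
    def test_roundtrip(self, sheet_small, tmp_path):
        m, _, _ = generate_synthetic_emap(sheet_small, n_points=40, seed=2)
        path = str(tmp_path / "map.tsv")
        write_emap(m, path)
        back = read_emap(path)
        assert np.allclose(back.points, m.points, atol=1e-6)
        assert np.allclose(back.bipolar_voltage, m.bipolar_voltage, atol=1e-6)
        assert np.allclose(back.lat, m.lat, atol=1e-6)

    def test_malformed_row_reported_with_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "x_mm\ty_mm\tz_mm\tvoltage_mV\tlat_ms\n"
            "0\t0\t0\t1.0\t2.0\n"
            "0\t0\toops\t1.0\t2.0\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            read_emap(str(path))

    def test_wrong_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("a\tb\tc\td\te\n0\t0\t0\t0\t0\n")
        with pytest.raises(ValueError, match="header"):
            read_emap(str(path))
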