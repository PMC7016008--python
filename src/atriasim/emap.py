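"""Electro-anatomical maps: alignment, interpolation, fibrosis, statistics.

A clinical electro-anatomical map is a sparse cloud of catheter samples —
3-D position, bipolar peak-to-peak voltage (mV) and local activation time
(ms) — acquired over the atrial endocardium during pacing.  This module

* aligns such a map to a model surface by a rigid landmark transform,
* spreads the sparse samples onto mesh nodes by inverse-distance
  weighting (IDW) within a 10 mm radius,
* converts bipolar voltage to a probability of fibrosis through the
  piecewise cubic

  .. math::

     P = \\begin{cases} 1 & X < 0\\\\
         (-40.0X^3 + 155X^2 - 206X + 99.8)/100 & 0 \\le X \\le 1.74\\\\
         0 & X > 1.74 \\end{cases}

  (the polynomial is expressed in percent; 1.74 mV is the voltage above
  which tissue is taken as electrically healthy),
* samples a per-node fibrosis status by comparing that probability with a
  uniform random draw, and
* computes the voltage/activation agreement statistics (Pearson r, RMSE,
  %RMSE) used to compare clinical and simulated maps per region.

A deterministic synthetic-map generator emulates an acquisition of >500
points with a spatially smooth voltage field spanning ~0.1–3.5 mV and an
activation field spreading from one earliest-activation site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .geometry import AtrialMesh, geodesic_distance

__all__ = [
    "ElectroAnatomicalMap",
    "NodeField",
    "FibrosisModel",
    "read_emap",
    "write_emap",
    "rigid_align",
    "idw_interpolate",
    "fibrosis_probability",
    "assign_fibrosis",
    "map_agreement",
    "generate_synthetic_emap",
    "UNCOVERED_VOLTAGE_MV",
]

# Voltage assumed at nodes with no map sample within the IDW radius:
# healthy (above the fibrosis cutoff), and excluded from agreement stats.
UNCOVERED_VOLTAGE_MV = 5.0


@dataclass
class ElectroAnatomicalMap:
    """Sparse point samples of bipolar voltage and activation time."""

    points: np.ndarray            # (n, 3) mm
    bipolar_voltage: np.ndarray   # (n,) mV
    lat: np.ndarray               # (n,) ms
    pacing_cycle_length: float = 500.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.bipolar_voltage = np.asarray(self.bipolar_voltage, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        n = len(self.points)
        if n < 1:
            raise ValueError("map needs at least one point")
        if self.bipolar_voltage.shape != (n,) or self.lat.shape != (n,):
            raise ValueError("voltage/lat length must match point count")
        if np.any(self.bipolar_voltage < 0):
            raise ValueError("bipolar voltages must be >= 0")
        if not np.all(np.isfinite(self.lat)):
            raise ValueError("activation times must be finite")

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class NodeField:
    """A scalar per mesh node plus a coverage mask.

    ``values`` are NaN exactly where ``covered`` is False (no map sample
    within the interpolation radius).
    """

    values: np.ndarray
    covered: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.covered = np.asarray(self.covered, dtype=bool)
        if self.values.shape != self.covered.shape:
            raise ValueError("values/covered shape mismatch")
        if not np.all(np.isfinite(self.values[self.covered])):
            raise ValueError("covered nodes must carry finite values")

    def filled(self, fill_value: float) -> np.ndarray:
        return np.where(self.covered, self.values, fill_value)


@dataclass
class FibrosisModel:
    """Voltage-to-fibrosis mapping parameters.

    ``coefficients`` are the cubic's coefficients on the percent scale,
    highest power first; ``threshold_mv`` is the voltage above which the
    probability is zero.
    """

    threshold_mv: float = 1.74
    coefficients: tuple = (-40.0, 155.0, -206.0, 99.8)
    rng_seed: int = 0


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

_COLUMNS = ("x_mm", "y_mm", "z_mm", "voltage_mV", "lat_ms")


def write_emap(emap: ElectroAnatomicalMap, path: str) -> None:
    """Write the map as tab-separated text with a header row."""
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for p, v, t in zip(emap.points, emap.bipolar_voltage, emap.lat):
            fh.write(f"{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\t{v:.6f}\t{t:.6f}\n")


def read_emap(path: str, pacing_cycle_length: float = 500.0) -> ElectroAnatomicalMap:
    """Read a map written by :func:`write_emap`.

    Malformed rows are rejected with their 1-based line numbers.
    """
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = tuple(header.split("\t"))
        if cols != _COLUMNS:
            raise ValueError(
                f"unexpected header {cols!r}; expected {_COLUMNS!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(
                    f"line {lineno}: expected 5 fields, found {len(parts)}"
                )
            try:
                rows.append([float(x) for x in parts])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric field") from exc
    if not rows:
        raise ValueError("map file contains no data rows")
    arr = np.asarray(rows)
    return ElectroAnatomicalMap(
        points=arr[:, :3],
        bipolar_voltage=arr[:, 3],
        lat=arr[:, 4],
        pacing_cycle_length=pacing_cycle_length,
    )


# ---------------------------------------------------------------------------
# Rigid alignment
# ---------------------------------------------------------------------------

def rigid_align(
    emap: ElectroAnatomicalMap,
    map_landmarks: np.ndarray,
    mesh_landmarks: np.ndarray,
) -> tuple[ElectroAnatomicalMap, float]:
    """Least-squares rigid (rotation + translation) alignment.

    The transform mapping ``map_landmarks`` onto ``mesh_landmarks`` is
    estimated by the Kabsch / orthogonal-Procrustes solution and applied
    to every map point.  Returns the transformed map and the RMS landmark
    residual in mm.  At least 3 non-collinear landmark pairs are required.
    """
    a = np.asarray(map_landmarks, dtype=float).reshape(-1, 3)
    b = np.asarray(mesh_landmarks, dtype=float).reshape(-1, 3)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need >= 3 landmark pairs of matching length")
    ac, bc = a - a.mean(axis=0), b - b.mean(axis=0)
    # collinearity: rank of the centered landmark cloud
    if np.linalg.matrix_rank(ac, tol=1e-9 * max(1.0, np.abs(ac).max())) < 2:
        raise ValueError("landmarks are collinear; alignment is underdetermined")
    h = ac.T @ bc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = b.mean(axis=0) - rot @ a.mean(axis=0)
    residual = float(
        np.sqrt(np.mean(np.sum((a @ rot.T + trans - b) ** 2, axis=1)))
    )
    aligned = ElectroAnatomicalMap(
        points=emap.points @ rot.T + trans,
        bipolar_voltage=emap.bipolar_voltage.copy(),
        lat=emap.lat.copy(),
        pacing_cycle_length=emap.pacing_cycle_length,
    )
    return aligned, residual


# ---------------------------------------------------------------------------
# IDW interpolation
# ---------------------------------------------------------------------------

def idw_interpolate(
    emap: ElectroAnatomicalMap,
    mesh: AtrialMesh,
    which: str = "voltage",
    radius_mm: float = 10.0,
    power: float = 2.0,
    exact_hit_eps: float = 1e-6,
) -> NodeField:
    """Inverse-distance-weighted interpolation of map samples onto nodes.

    For each mesh node, samples within ``radius_mm`` contribute with
    weight 1/d^power; a node within ``exact_hit_eps`` mm of a sample takes
    that sample's value exactly.  Nodes with no sample in radius are
    flagged uncovered (value NaN).
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    if emap.n_points == 0:
        raise ValueError("empty map")
    if which == "voltage":
        sample_values = emap.bipolar_voltage
    elif which == "lat":
        sample_values = emap.lat
    else:
        raise ValueError("which must be 'voltage' or 'lat'")

    tree = cKDTree(emap.points)
    neighbors = tree.query_ball_point(mesh.nodes, r=radius_mm)
    n = mesh.n_nodes
    values = np.full(n, np.nan)
    covered = np.zeros(n, dtype=bool)
    for i, idx in enumerate(neighbors):
        if not idx:
            continue
        idx = np.asarray(idx)
        d = np.linalg.norm(emap.points[idx] - mesh.nodes[i], axis=1)
        hit = d < exact_hit_eps
        if hit.any():
            values[i] = sample_values[idx[hit][0]]
        else:
            w = 1.0 / d ** power
            values[i] = float(np.sum(w * sample_values[idx]) / np.sum(w))
        covered[i] = True
    return NodeField(values=values, covered=covered)


# ---------------------------------------------------------------------------
# Fibrosis probability and assignment
# ---------------------------------------------------------------------------

def fibrosis_probability(
    x, model: FibrosisModel | None = None
):
    """Probability of fibrosis given bipolar voltage (mV), in [0, 1].

    Scalar in, scalar out; array in, array out.  The cubic is evaluated on
    the percent scale and divided by 100, clamped to [0, 1]; voltages below
    0 map to 1 and above the threshold to 0.
    """
    if model is None:
        model = FibrosisModel()
    xv = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(xv)):
        raise ValueError("voltage must be finite")
    poly = np.polyval(model.coefficients, xv) / 100.0
    p = np.clip(poly, 0.0, 1.0)
    p = np.where(xv < 0.0, 1.0, p)
    p = np.where(xv > model.threshold_mv, 0.0, p)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(p)
    return p


def assign_fibrosis(
    mesh: AtrialMesh,
    voltage_field: NodeField,
    model: FibrosisModel | None = None,
) -> tuple[AtrialMesh, float]:
    """Bernoulli fibrosis assignment from an interpolated voltage field.

    Each node's fibrosis probability is compared against an independent
    uniform draw from a generator seeded by ``model.rng_seed``; nodes with
    the draw below the probability are flagged fibrotic.  Uncovered nodes
    are treated as healthy (assigned ``UNCOVERED_VOLTAGE_MV``).  Returns
    the flagged mesh copy and the global fibrotic fraction.
    """
    if model is None:
        model = FibrosisModel()
    v = voltage_field.filled(UNCOVERED_VOLTAGE_MV)
    if v.shape != (mesh.n_nodes,):
        raise ValueError("voltage field does not match the mesh")
    p = fibrosis_probability(v, model)
    rng = np.random.default_rng(model.rng_seed)
    draws = rng.random(mesh.n_nodes)
    out = mesh.copy()
    out.fibrosis = draws < p
    return out, float(out.fibrosis.mean())


# ---------------------------------------------------------------------------
# Map agreement statistics
# ---------------------------------------------------------------------------

def _agreement_stats(a: np.ndarray, b: np.ndarray) -> dict:
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    denom = float(np.mean(np.abs(a)))
    pct = float(100.0 * rmse / denom) if denom > 0 else float("nan")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        r = float("nan")
        p = float("nan")
    else:
        r, p = pearsonr(a, b)
    return {
        "pearson_r": float(r),
        "p_value": float(p),
        "rmse": rmse,
        "percent_rmse": pct,
        "n": int(len(a)),
    }


def map_agreement(
    a: NodeField, b: NodeField, regions: np.ndarray | None = None
) -> dict:
    """Pearson r / RMSE / %RMSE between two node fields.

    Only nodes covered in both fields enter.  ``regions`` (per-node integer
    labels; 0 = unlabeled) adds one entry per label next to ``"overall"``.
    %RMSE is normalized by the mean |value| of the first (reference) field
    within the region.  Regions with fewer than 2 covered nodes are skipped
    with a warning.
    """
    if a.values.shape != b.values.shape:
        raise ValueError("fields live on different meshes")
    both = a.covered & b.covered
    if both.sum() < 2:
        raise ValueError("fewer than 2 jointly covered nodes")
    out = {"overall": _agreement_stats(a.values[both], b.values[both])}
    if regions is not None:
        regions = np.asarray(regions)
        for label in np.unique(regions[regions > 0]):
            sel = both & (regions == label)
            if sel.sum() < 2:
                warnings.warn(
                    f"region {label}: fewer than 2 covered nodes; skipped",
                    stacklevel=2,
                )
                continue
            out[int(label)] = _agreement_stats(a.values[sel], b.values[sel])
    return out


# ---------------------------------------------------------------------------
# Synthetic acquisition
# ---------------------------------------------------------------------------

def _smooth_voltage_truth(
    mesh: AtrialMesh, rng: np.random.Generator,
    v_range: tuple[float, float], n_bumps: int = 6,
) -> np.ndarray:
    """Spatially smooth voltage truth spanning ``v_range`` (mV).

    A sum of random Gaussian bumps over the bounding box, rescaled to the
    requested range — smooth at the ~5 mm scale like clinical voltage maps.
    """
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    span = np.linalg.norm(hi - lo)
    f = np.zeros(mesh.n_nodes)
    for _ in range(n_bumps):
        c = lo + rng.random(3) * (hi - lo)
        s = (0.15 + 0.25 * rng.random()) * span
        amp = rng.uniform(-1.0, 1.0)
        d2 = np.sum((mesh.nodes - c) ** 2, axis=1)
        f += amp * np.exp(-d2 / (2.0 * s * s))
    fmin, fmax = f.min(), f.max()
    if fmax - fmin < 1e-12:
        return np.full(mesh.n_nodes, 0.5 * (v_range[0] + v_range[1]))
    return v_range[0] + (f - fmin) / (fmax - fmin) * (v_range[1] - v_range[0])


def generate_synthetic_emap(
    mesh: AtrialMesh,
    n_points: int = 600,
    seed: int = 0,
    eas_node: int | None = None,
    conduction_speed_m_s: float = 0.7,
    voltage_range_mv: tuple[float, float] = (0.1, 3.5),
    voltage_noise_sd: float = 0.05,
    lat_noise_sd: float = 1.0,
    jitter_mm: float = 0.5,
    pacing_cycle_length: float = 500.0,
):
    """Emulate a catheter acquisition of a sparse electro-anatomical map.

    Ground truth: a smooth voltage field spanning ``voltage_range_mv`` and
    an activation field equal to the geodesic distance from ``eas_node``
    divided by ``conduction_speed_m_s``.  ``n_points`` nodes are sampled
    without replacement, displaced by up to ``jitter_mm`` along the surface
    normal, and Gaussian measurement noise is added.  Returns
    ``(emap, truth_voltage, truth_lat)`` with the truths as fully covered
    :class:`NodeField` objects for recovery tests.
    """
    if n_points > mesh.n_nodes:
        raise ValueError("cannot sample more points than mesh nodes")
    rng = np.random.default_rng(seed)
    if eas_node is None:
        eas_node = int(np.argmin(np.linalg.norm(mesh.nodes - mesh.nodes.min(axis=0), axis=1)))

    v_truth = _smooth_voltage_truth(mesh, rng, voltage_range_mv)
    dist = geodesic_distance(mesh, eas_node)   # mm
    lat_truth = dist / conduction_speed_m_s    # mm / (mm/ms) = ms

    idx = rng.choice(mesh.n_nodes, size=n_points, replace=False)
    normals = mesh.node_normals()
    offsets = rng.uniform(-jitter_mm, jitter_mm, size=n_points)
    pts = mesh.nodes[idx] + offsets[:, None] * normals[idx]
    volt = np.clip(
        v_truth[idx] + rng.normal(0.0, voltage_noise_sd, n_points), 0.0, None
    )
    lat = lat_truth[idx] + rng.normal(0.0, lat_noise_sd, n_points)

    emap = ElectroAnatomicalMap(
        points=pts,
        bipolar_voltage=volt,
        lat=lat,
        pacing_cycle_length=pacing_cycle_length,
    )
    full = np.ones(mesh.n_nodes, dtype=bool)
    return (
        emap,
        NodeField(values=v_truth, covered=full),
        NodeField(values=lat_truth, covered=full),
    )
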