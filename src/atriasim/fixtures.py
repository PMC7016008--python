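"""Deterministic synthetic-data factory for analysis-stage testing.

The wave-dynamics and electrogram stages operate on membrane-potential
movies.  Generating those movies kinematically — a stereotyped action
potential translated as a plane wave, or wrapped around a (possibly
drifting) spiral core — exercises the analysis chain with exact ground
truth and without the cost of the reaction–diffusion solver.  Every
fixture is a pure function of its parameters and seed.

The AP template is a piecewise waveform (1-ms linear upstroke from
−80 mV to +20 mV, exponential repolarization parameterized by APD90); it
is not an ionic-model output and is only meant to carry realistic timing
and amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .geometry import AtrialMesh, _geodesic_graph
from .propagation import SimulationResult

__all__ = [
    "FixtureSpec",
    "ap_template",
    "make_plane_wave_movie",
    "make_spiral_movie",
    "make_roving_spiral_movie",
    "make_labeled_regions",
    "make_fixture",
]

V_REST = -80.0
V_PEAK = 20.0
UPSTROKE_MS = 1.0


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of one synthetic fixture.

    ``kind`` selects the factory; ``params`` are its keyword arguments;
    the same (kind, params, seed) always produces a bit-identical
    fixture.
    """

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def manifest(self) -> dict:
        return {"kind": self.kind, "seed": self.seed, **self.params}


def ap_template(t_since_activation_ms, apd90_ms: float = 180.0):
    """Stereotyped action potential value(s) at times after activation.

    Linear 1-ms upstroke to +20 mV, then exponential decay toward rest
    with the time constant chosen so 90 % of the amplitude is recovered
    ``apd90_ms`` after activation.  Negative times return rest.
    """
    t = np.asarray(t_since_activation_ms, dtype=float)
    tau = (apd90_ms - UPSTROKE_MS) / np.log(10.0)
    amp = V_PEAK - V_REST
    up = V_REST + amp * np.clip(t / UPSTROKE_MS, 0.0, 1.0)
    down = V_REST + amp * np.exp(-(t - UPSTROKE_MS) / tau)
    out = np.where(t < UPSTROKE_MS, up, down)
    out = np.where(t < 0.0, V_REST, out)
    if np.ndim(t_since_activation_ms) == 0:
        return float(out)
    return out


def make_plane_wave_movie(
    mesh: AtrialMesh,
    direction=(1.0, 0.0, 0.0),
    speed_m_s: float = 0.5,
    cl_ms: float = 600.0,
    duration_ms: float = 2000.0,
    output_interval_ms: float = 1.0,
    apd90_ms: float = 180.0,
) -> SimulationResult:
    """Plane wave of stereotyped APs sweeping the mesh at a set speed.

    Activation times are exactly linear in the coordinate along
    ``direction`` (LAT = x/speed; mm / (mm/ms)), repeating every
    ``cl_ms``; extracting LAT or CV from the movie recovers the inputs.
    """
    if speed_m_s <= 0 or cl_ms <= 0:
        raise ValueError("speed and cycle length must be positive")
    if duration_ms <= 0:
        raise ValueError("movie duration must be positive")
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    x = mesh.nodes @ d
    lat = (x - x.min()) / speed_m_s  # ms

    times = np.arange(0.0, duration_ms + 1e-9, output_interval_ms)
    # time since the most recent activation of each node at each frame
    rel = times[None, :] - lat[:, None]
    rel_mod = np.where(rel >= 0, rel % cl_ms, rel)
    vm = ap_template(rel_mod, apd90_ms).astype(np.float32)
    return SimulationResult(
        times=times, vm=vm,
        metadata={"fixture": "plane_wave", "speed_m_s": speed_m_s, "cl_ms": cl_ms},
    )


def _spiral_vm(
    nodes: np.ndarray,
    core_xy: np.ndarray,
    t_ms: float,
    omega_rad_ms: float,
    pitch_mm: float,
    apd90_ms: float,
    chirality: int,
) -> np.ndarray:
    """Archimedean-spiral phase mapped through the AP template."""
    dx = nodes[:, 0] - core_xy[0]
    dy = nodes[:, 1] - core_xy[1]
    r = np.hypot(dx, dy)
    az = np.arctan2(dy, dx)
    phase = omega_rad_ms * t_ms + chirality * az - 2.0 * np.pi * r / pitch_mm
    frac = (phase / (2.0 * np.pi)) % 1.0
    cl = 2.0 * np.pi / omega_rad_ms
    return ap_template(frac * cl, apd90_ms)


def make_spiral_movie(
    mesh: AtrialMesh,
    core=(15.0, 15.0),
    rotation_period_ms: float = 150.0,
    drift_velocity_mm_s=(0.0, 0.0),
    duration_ms: float = 2000.0,
    output_interval_ms: float = 10.0,
    pitch_mm: float = 60.0,
    apd90_ms: float = 120.0,
    chirality: int = 1,
) -> tuple[SimulationResult, np.ndarray]:
    """Rigidly rotating (optionally drifting) spiral-wave movie.

    Returns the movie and the ground-truth tip path (frame × 3, mm).
    ``chirality`` +1 gives counter-clockwise rotation in the x–y plane.
    """
    if duration_ms <= 0:
        raise ValueError("movie duration must be positive")
    omega = 2.0 * np.pi / rotation_period_ms
    drift = np.asarray(drift_velocity_mm_s, dtype=float) / 1000.0  # mm/ms
    times = np.arange(0.0, duration_ms + 1e-9, output_interval_ms)
    core0 = np.asarray(core, dtype=float)

    vm = np.empty((mesh.n_nodes, times.size), dtype=np.float32)
    tips = np.zeros((times.size, 3))
    for k, t in enumerate(times):
        c = core0 + drift * t
        vm[:, k] = _spiral_vm(
            mesh.nodes, c, t, omega, pitch_mm, apd90_ms, chirality
        )
        tips[k, :2] = c
    return (
        SimulationResult(
            times=times, vm=vm,
            metadata={"fixture": "spiral", "period_ms": rotation_period_ms},
        ),
        tips,
    )


def make_roving_spiral_movie(
    mesh: AtrialMesh,
    core_nodes,
    segment_ms: float = 600.0,
    rotation_period_ms: float = 150.0,
    output_interval_ms: float = 10.0,
    pitch_mm: float = 60.0,
    apd90_ms: float = 120.0,
) -> tuple[SimulationResult, np.ndarray]:
    """Spiral activity whose core relocates between successive segments.

    Emulates the clinical observation that rotor sites cluster in
    particular substrate: callers choose where the cores sit (for
    example, sampled preferentially from fibrotic areas) and each core
    anchors the spiral for one ``segment_ms`` segment.  Returns the
    movie and the per-frame true core position.
    """
    core_nodes = np.atleast_1d(np.asarray(core_nodes, dtype=int))
    if core_nodes.size == 0:
        raise ValueError("need at least one core node")
    omega = 2.0 * np.pi / rotation_period_ms
    times = np.arange(
        0.0, segment_ms * core_nodes.size + 1e-9, output_interval_ms
    )
    vm = np.empty((mesh.n_nodes, times.size), dtype=np.float32)
    tips = np.zeros((times.size, 3))
    for k, t in enumerate(times):
        seg = min(int(t // segment_ms), core_nodes.size - 1)
        c = mesh.nodes[core_nodes[seg], :2]
        vm[:, k] = _spiral_vm(mesh.nodes, c, t, omega, pitch_mm, apd90_ms, 1)
        tips[k, :2] = c
    return (
        SimulationResult(
            times=times, vm=vm,
            metadata={"fixture": "roving_spiral", "segment_ms": segment_ms},
        ),
        tips,
    )


def make_labeled_regions(mesh: AtrialMesh, n_regions: int = 10, seed: int = 0) -> AtrialMesh:
    """Partition the surface into contiguous, roughly equal-area regions.

    Region seeds are placed by farthest-point sampling on the surface
    graph and nodes take the label of the geodesically nearest seed
    (a geodesic Voronoi partition, hence each region is connected).
    Labels run 1..n_regions with no gaps or overlaps.
    """
    if n_regions < 1:
        raise ValueError("need at least one region")
    if n_regions > mesh.n_nodes:
        raise ValueError("more regions than mesh nodes")
    out = mesh.copy()
    if n_regions == 1:
        out.region = np.ones(mesh.n_nodes, dtype=np.int64)
        return out
    g = _geodesic_graph(mesh)
    rng = np.random.default_rng(seed)
    seeds = [int(rng.integers(mesh.n_nodes))]
    dist = dijkstra(g, directed=False, indices=seeds[0])
    for _ in range(n_regions - 1):
        nxt = int(np.argmax(dist))
        seeds.append(nxt)
        dist = np.minimum(dist, dijkstra(g, directed=False, indices=nxt))
    # Lloyd relaxation: move each seed to its cell's centroid-nearest node,
    # re-partition; evens out the cell areas
    labels = None
    for _ in range(6):
        all_d = dijkstra(g, directed=False, indices=seeds)
        labels = np.argmin(all_d, axis=0)
        new_seeds = []
        for k in range(n_regions):
            cell = np.nonzero(labels == k)[0]
            if cell.size == 0:
                new_seeds.append(seeds[k])
                continue
            centroid = mesh.nodes[cell].mean(axis=0)
            new_seeds.append(
                int(cell[np.argmin(np.sum((mesh.nodes[cell] - centroid) ** 2, axis=1))])
            )
        if new_seeds == seeds:
            break
        seeds = new_seeds
    out.region = np.asarray(labels + 1, dtype=np.int64)
    return out


_FACTORIES = {
    "plane-wave": make_plane_wave_movie,
    "spiral": make_spiral_movie,
    "roving-spiral": make_roving_spiral_movie,
}


def make_fixture(spec: FixtureSpec, mesh: AtrialMesh | None = None):
    """Build the fixture described by ``spec``.

    Mesh-producing kinds (``sheet``, ``sphere``, ``labeled-sheet``,
    ``emap``) need no input mesh; movie kinds require one.
    """
    from .emap import generate_synthetic_emap
    from .geometry import generate_sheet_mesh, generate_sphere_mesh

    if spec.kind == "sheet":
        return generate_sheet_mesh(**spec.params)
    if spec.kind == "sphere":
        return generate_sphere_mesh(**spec.params)
    if spec.kind == "labeled-sheet":
        p = dict(spec.params)
        n_regions = p.pop("n_regions", 10)
        return make_labeled_regions(
            generate_sheet_mesh(**p), n_regions=n_regions, seed=spec.seed
        )
    if spec.kind == "emap":
        if mesh is None:
            raise ValueError("emap fixture needs a mesh")
        return generate_synthetic_emap(mesh, seed=spec.seed, **spec.params)
    if spec.kind in _FACTORIES:
        if mesh is None:
            raise ValueError(f"{spec.kind} fixture needs a mesh")
        return _FACTORIES[spec.kind](mesh, **spec.params)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
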