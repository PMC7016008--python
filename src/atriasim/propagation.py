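"""Monodomain reaction–diffusion on the atrial surface.

Tissue propagation couples the CRN membrane model at every mesh node with
an anisotropic diffusion of membrane potential along the surface:

.. math:: \\partial_t v = -I_{ion}(v, s)/C_m + \\nabla\\cdot(D\\,\\nabla v)

with a per-element conductivity tensor
``D = kappa_L σ_L f fᵀ + kappa_T σ_T (P − f fᵀ)`` (``f`` the element fiber
direction, ``P`` the projection onto the element plane, σ the longitudinal
or transverse conductivity of the element's tissue class).  The published
conductivities (S/m) underdetermine a surface diffusion coefficient
(mm²/ms): no surface-to-volume ratio is given and the printed CV
anisotropy (0.707/0.486 ≈ 1.45) differs from the continuum prediction of
the conductivity ratio (≈ 2.24).  The conduction velocities are therefore
treated as the authoritative observables: :func:`calibrate_conduction`
fixes the two unit-conversion scales ``kappa_L``, ``kappa_T`` so planar
CV along and across fibers matches 0.707 and 0.486 m/s on a reference
sheet, and per-patient tuning (:func:`tune_diffusion`) then rescales both
at the same rate against clinical conduction times.

Discretization: linear-triangle stiffness assembly with a lumped mass
matrix; operator splitting per step (reaction via the Rush–Larsen CRN
stepper, diffusion explicit, sub-cycled to its stability limit); global
time step adaptive between 0.01 ms (during upstrokes) and 0.1 ms.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import ionic
from .geometry import AtrialMesh, geodesic_distance
from .ionic import (
    DT_MAX,
    DT_MIN,
    N_STATE,
    UPSTROKE_DVDT,
    IonChannelScaling,
    NumericalBlowupError,
    af_remodeling_profile,
    fibrosis_remodeling_profile,
    resting_state,
    rl_step,
)

__all__ = [
    "ConductivitySet",
    "DiffusionOperator",
    "PacingProtocol",
    "SimulationResult",
    "LATMap",
    "CV_TARGET_LONGITUDINAL",
    "CV_TARGET_TRANSVERSE",
    "build_diffusion",
    "node_scaling",
    "run_monodomain",
    "extract_lat",
    "measure_cv",
    "calibrate_conduction",
    "tune_diffusion",
    "make_ramp_protocol",
    "disk_site",
    "detect_induction",
    "TISSUE_STIM_AMPLITUDE",
    "LAT_THRESHOLD_MV",
]

# Clinically tuned planar conduction-velocity targets (m/s) for
# AF-remodeled, non-fibrotic tissue.
CV_TARGET_LONGITUDINAL = 0.707
CV_TARGET_TRANSVERSE = 0.486

# Upstroke marker for activation-time extraction.
LAT_THRESHOLD_MV = -40.0

# Tissue pacing needs roughly twice the single-cell stimulus because the
# stimulated disk also charges its neighbors through diffusion.
TISSUE_STIM_AMPLITUDE = -4000.0  # pA


@dataclass(frozen=True)
class ConductivitySet:
    """Longitudinal/transverse conductivities by tissue class, S/m."""

    sigma_l_normal: float = 0.1264
    sigma_l_fibrotic: float = 0.0546
    sigma_t_normal: float = 0.0252
    sigma_t_fibrotic: float = 0.0068

    def __post_init__(self) -> None:
        vals = (
            self.sigma_l_normal, self.sigma_l_fibrotic,
            self.sigma_t_normal, self.sigma_t_fibrotic,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("conductivities must be positive")
        if (
            self.sigma_l_normal < self.sigma_t_normal
            or self.sigma_l_fibrotic < self.sigma_t_fibrotic
        ):
            raise ValueError("longitudinal conductivity must be >= transverse")


@dataclass
class DiffusionOperator:
    """Assembled surface-diffusion operator.

    ``stiffness`` is the symmetric FEM stiffness matrix (row sums zero);
    the action of the diffusion term on a nodal field ``u`` is
    ``-inv_mass * (stiffness @ u)`` (mm²/ms · mV/mm² → mV/ms).  Boundary
    behavior is natural zero flux.
    """

    stiffness: sp.csr_matrix
    inv_mass: np.ndarray
    kappa_l: float
    kappa_t: float
    dt_stable: float

    def apply(self, u: np.ndarray) -> np.ndarray:
        """Diffusion rate of change of ``u`` (mV/ms per node)."""
        return -self.inv_mass * (self.stiffness @ u)


def build_diffusion(
    mesh: AtrialMesh,
    conductivities: ConductivitySet,
    calibration: tuple[float, float],
) -> DiffusionOperator:
    """Assemble the fiber-anisotropic diffusion operator.

    Element tensors use the element's majority-vote fibrosis class and the
    mean of its node fiber vectors projected into the element plane;
    ``calibration = (kappa_L, kappa_T)`` converts conductivity (S/m) into
    surface diffusion (mm²/ms).
    """
    if mesh.fiber is None:
        raise ValueError("mesh has no fiber field; assign fibers first")
    kappa_l, kappa_t = calibration
    if kappa_l <= 0 or kappa_t <= 0:
        raise ValueError("calibration scales must be positive")

    tris = mesh.triangles
    p = mesh.nodes[tris]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    nrm = np.cross(e1, e2)
    a2 = np.linalg.norm(nrm, axis=1)
    if np.any(a2 <= 0):
        raise ValueError("degenerate (zero-area) triangle in mesh")
    nhat = nrm / a2[:, None]
    area = 0.5 * a2

    # element fiber: mean of node fibers projected to the element plane
    f_el = mesh.fiber[tris].mean(axis=1)
    f_el -= np.sum(f_el * nhat, axis=1, keepdims=True) * nhat
    f_norm = np.linalg.norm(f_el, axis=1)
    f_norm[f_norm < 1e-12] = 1.0
    f_el /= f_norm[:, None]

    fib_el = mesh.fibrosis[tris].sum(axis=1) >= 2  # majority vote
    sig_l = np.where(
        fib_el, conductivities.sigma_l_fibrotic, conductivities.sigma_l_normal
    )
    sig_t = np.where(
        fib_el, conductivities.sigma_t_fibrotic, conductivities.sigma_t_normal
    )
    d_l = kappa_l * sig_l
    d_t = kappa_t * sig_t

    # D = d_l f f^T + d_t (P - f f^T),  P = I - n n^T
    eye = np.eye(3)
    ffT = np.einsum("ei,ej->eij", f_el, f_el)
    proj = eye[None] - np.einsum("ei,ej->eij", nhat, nhat)
    d_tensor = d_l[:, None, None] * ffT + d_t[:, None, None] * (proj - ffT)

    # gradients of the linear shape functions: grad phi_i = (nhat x e_i)/(2A)
    edges_opp = np.stack([p[:, 2] - p[:, 1], p[:, 0] - p[:, 2], p[:, 1] - p[:, 0]], axis=1)
    grads = np.cross(nhat[:, None, :], edges_opp) / a2[:, None, None]

    # K_ij = area * grad_i . D . grad_j
    dg = np.einsum("eab,ejb->eja", d_tensor, grads)
    k_el = np.einsum("eia,eja->eij", grads, dg) * area[:, None, None]

    n = mesh.n_nodes
    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    stiff = sp.coo_matrix((k_el.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    mass = mesh.node_areas()
    inv_mass = 1.0 / mass

    # explicit-Euler stability bound via Gershgorin on M^-1 K
    row_abs = np.asarray(np.abs(stiff).sum(axis=1)).ravel()
    lam_max = float(np.max(inv_mass * row_abs))
    dt_stable = 2.0 / lam_max if lam_max > 0 else DT_MAX

    return DiffusionOperator(
        stiffness=stiff,
        inv_mass=inv_mass,
        kappa_l=float(kappa_l),
        kappa_t=float(kappa_t),
        dt_stable=dt_stable,
    )


def node_scaling(
    mesh: AtrialMesh, base: IonChannelScaling | None = None
) -> np.ndarray:
    """Per-node channel-scaling matrix (n, 6) honoring fibrosis flags.

    Every node carries ``base`` (default: the AF remodeling profile);
    fibrotic nodes are additionally fibrosis-remodeled.
    """
    if base is None:
        base = af_remodeling_profile()
    fibrotic = fibrosis_remodeling_profile(base)
    scal = np.tile(base.as_array(), (mesh.n_nodes, 1))
    scal[mesh.fibrosis] = fibrotic.as_array()
    return scal


# ---------------------------------------------------------------------------
# Pacing protocols
# ---------------------------------------------------------------------------

@dataclass
class PacingProtocol:
    """Stimulus site (node set) and rectangular stimulus events."""

    site_nodes: np.ndarray
    events: list           # of (time ms, duration ms, amplitude pA)
    label: str = ""
    total_duration: float | None = None

    def __post_init__(self) -> None:
        self.site_nodes = np.asarray(self.site_nodes, dtype=np.int64)
        self.events = sorted(
            [(float(t), float(d), float(a)) for t, d, a in self.events]
        )
        if self.events and self.events[0][0] < 0:
            raise ValueError("event times must be non-negative")

    @property
    def last_event_end(self) -> float:
        if not self.events:
            return 0.0
        return max(t + d for t, d, _ in self.events)

    @classmethod
    def s1(
        cls,
        site_nodes,
        n_beats: int,
        cycle_length: float,
        start: float = 1.0,
        amplitude: float = TISSUE_STIM_AMPLITUDE,
        duration: float = ionic.STIM_DURATION,
    ) -> "PacingProtocol":
        events = [
            (start + i * cycle_length, duration, amplitude)
            for i in range(n_beats)
        ]
        return cls(site_nodes=site_nodes, events=events, label=f"S1-{cycle_length:g}")


def disk_site(mesh: AtrialMesh, center_node: int, radius_mm: float = 1.0) -> np.ndarray:
    """Node indices within a Euclidean disk around ``center_node``."""
    d = np.linalg.norm(mesh.nodes - mesh.nodes[center_node], axis=1)
    return np.nonzero(d <= radius_mm)[0]


def make_ramp_protocol(
    site_nodes,
    cl_start: float = 200.0,
    cl_end: float = 120.0,
    total_ms: float = 6530.0,
    cl_step: float = 10.0,
    beats_per_step: int = 4,
    amplitude: float = TISSUE_STIM_AMPLITUDE,
    stim_duration: float = ionic.STIM_DURATION,
) -> PacingProtocol:
    """Ramp pacing: cycle length stepped down from ``cl_start`` to ``cl_end``.

    ``beats_per_step`` beats are delivered at each cycle length from
    ``cl_start`` down to ``cl_end`` in decrements of ``cl_step``; once the
    ramp reaches ``cl_end``, pacing continues at ``cl_end`` and the
    remainder is absorbed in this final step so the protocol's overall
    duration equals ``total_ms``.
    """
    if not (cl_start > cl_end > 0):
        raise ValueError("require cl_start > cl_end > 0")
    if total_ms < cl_start:
        raise ValueError("total duration cannot fit a single beat")
    events = []
    t = 0.0
    cl = cl_start
    beats_at_cl = 0
    while t + cl <= total_ms + 1e-9:
        events.append((t, stim_duration, amplitude))
        t += cl
        beats_at_cl += 1
        if beats_at_cl >= beats_per_step and cl > cl_end:
            cl = max(cl - cl_step, cl_end)
            beats_at_cl = 0
    if not events:
        raise ValueError("ramp schedule produced no beats")
    return PacingProtocol(
        site_nodes=site_nodes,
        events=events,
        label=f"ramp-{cl_start:g}-{cl_end:g}",
        total_duration=float(total_ms),
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Membrane-potential movie (node × frame) with protocol metadata."""

    times: np.ndarray      # (t,) ms
    vm: np.ndarray         # (n, t) mV
    protocol: PacingProtocol | None = None
    metadata: dict = field(default_factory=dict)
    final_states: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vm = np.asarray(self.vm)
        if self.vm.shape[1] != self.times.size:
            raise ValueError("vm frame count does not match times")

    @property
    def n_nodes(self) -> int:
        return self.vm.shape[0]

    @property
    def output_interval(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0

    def save(self, path: str, mesh: AtrialMesh | None = None) -> None:
        """Write to a chunked HDF5 container with provenance attributes."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("times", data=self.times)
            fh.create_dataset(
                "vm", data=self.vm, chunks=True, compression="gzip", compression_opts=1
            )
            fh.attrs["units_times"] = "ms"
            fh.attrs["units_vm"] = "mV"
            if mesh is not None:
                checksum = hashlib.sha256(
                    mesh.nodes.tobytes() + mesh.triangles.tobytes()
                ).hexdigest()
                fh.attrs["mesh_sha256"] = checksum
            for k, v in self.metadata.items():
                try:
                    fh.attrs[f"meta_{k}"] = v
                except TypeError:
                    fh.attrs[f"meta_{k}"] = str(v)
            if self.protocol is not None:
                fh.create_dataset("protocol_events", data=np.asarray(self.protocol.events))
                fh.create_dataset("protocol_site", data=self.protocol.site_nodes)

    @classmethod
    def load(cls, path: str) -> "SimulationResult":
        import h5py

        with h5py.File(path, "r") as fh:
            times = fh["times"][...]
            vm = fh["vm"][...]
            protocol = None
            if "protocol_events" in fh:
                ev = fh["protocol_events"][...]
                protocol = PacingProtocol(
                    site_nodes=fh["protocol_site"][...],
                    events=[tuple(row) for row in ev],
                )
            meta = {
                k[5:]: v for k, v in fh.attrs.items() if k.startswith("meta_")
            }
        return cls(times=times, vm=vm, protocol=protocol, metadata=meta)


def run_monodomain(
    mesh: AtrialMesh,
    operator: DiffusionOperator,
    scaling: np.ndarray | IonChannelScaling,
    protocol: PacingProtocol,
    duration: float,
    output_interval: float = 1.0,
    dt: float | None = None,
    initial_states: np.ndarray | None = None,
    stop_when_activated: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate the monodomain model and record a vm movie.

    ``scaling`` is either one profile for every node or a per-node (n, 6)
    matrix (see :func:`node_scaling`).  The global step follows the
    adaptive rule (0.01 ms while any node's |dvm/dt| exceeds 1 mV/ms, else
    0.1 ms), never straddles a stimulus edge, and the explicit diffusion
    update is sub-cycled to its stability limit.  ``stop_when_activated``
    (node indices) truncates the run once all listed nodes have crossed
    the activation threshold — used by the calibration loops.  The run is
    deterministic: identical inputs give identical movies.
    """
    n = mesh.n_nodes
    if operator.stiffness.shape != (n, n):
        raise ValueError("operator was built on a different mesh")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt is not None and not (DT_MIN - 1e-12 <= dt <= DT_MAX + 1e-12):
        raise ValueError(f"dt must lie in [{DT_MIN}, {DT_MAX}] ms")
    if isinstance(scaling, IonChannelScaling):
        scal = np.tile(scaling.as_array(), (n, 1))
    else:
        scal = np.ascontiguousarray(scaling, dtype=float)
        if scal.shape != (n, 6):
            raise ValueError("per-node scaling must be (n, 6)")

    if initial_states is None:
        states = np.tile(resting_state(), (n, 1))
    else:
        states = np.array(initial_states, dtype=float)
        if states.shape != (n, N_STATE):
            raise ValueError("initial states must be (n, 21)")

    events = protocol.events
    edge_times = np.unique(
        np.concatenate([[t for t, _, _ in events], [t + d for t, d, _ in events]])
    ) if events else np.empty(0)
    edge_times = edge_times[(edge_times > 0) & (edge_times < duration)]

    n_out = int(np.floor(duration / output_interval + 1e-9)) + 1
    out_t = np.arange(n_out) * output_interval
    movie = np.empty((n, n_out), dtype=np.float32)
    movie[:, 0] = states[:, 0]

    istim = np.zeros(n)
    site = protocol.site_nodes
    dt_diff = operator.dt_stable * 0.8  # safety margin on the explicit bound

    watch = None
    if stop_when_activated is not None:
        watch = np.asarray(stop_when_activated, dtype=int)
        watch_done = np.zeros(len(watch), dtype=bool)

    t = 0.0
    k_out = 1
    e_idx = 0
    last_dvdt = np.inf  # start fine in case the protocol fires at t=0
    stopped_at = None
    while t < duration - 1e-9:
        dt_cur = dt if dt is not None else (
            DT_MIN if last_dvdt > UPSTROKE_DVDT else DT_MAX
        )
        step = dt_cur
        while e_idx < edge_times.size and edge_times[e_idx] <= t + 1e-9:
            e_idx += 1
        if e_idx < edge_times.size:
            step = min(step, edge_times[e_idx] - t)
        if k_out < n_out:
            step = min(step, out_t[k_out] - t)
        step = min(step, duration - t)

        istim[:] = 0.0
        for t0, d0, a0 in events:
            if t0 > t + 1e-9:
                break
            if t0 <= t + 1e-9 < t0 + d0 - 1e-9:
                istim[site] = a0

        # operator splitting: reaction then sub-cycled explicit diffusion
        last_dvdt = rl_step(states, scal, istim, step)
        vm = states[:, 0]
        n_sub = max(1, int(np.ceil(step / dt_diff)))
        h = step / n_sub
        for _ in range(n_sub):
            vm += h * operator.apply(vm)
        states[:, 0] = vm
        t += step

        vmax = np.max(np.abs(vm))
        if not np.isfinite(vmax) or vmax > 200.0:
            node = int(np.argmax(np.abs(vm)))
            raise NumericalBlowupError(
                f"instability at t = {t:.3f} ms, node {node}"
            )
        if k_out < n_out and t >= out_t[k_out] - 1e-9:
            movie[:, k_out] = vm
            k_out += 1
        if watch is not None:
            watch_done |= vm[watch] > LAT_THRESHOLD_MV
            if watch_done.all():
                stopped_at = t
                break

    times_out = out_t[:k_out]
    vm_out = movie[:, :k_out]
    if stopped_at is not None and stopped_at > times_out[-1] + 1e-9:
        # keep the truncating frame so threshold crossings at the watched
        # nodes are always bracketed by recorded frames
        times_out = np.append(times_out, stopped_at)
        vm_out = np.hstack([vm_out, states[:, 0:1].astype(np.float32)])
    return SimulationResult(
        times=times_out,
        vm=vm_out,
        protocol=protocol,
        metadata={
            "duration_requested": duration,
            "stopped_at": -1.0 if stopped_at is None else stopped_at,
            "kappa_l": operator.kappa_l,
            "kappa_t": operator.kappa_t,
        },
        final_states=states,
    )


# ---------------------------------------------------------------------------
# Activation times and conduction velocity
# ---------------------------------------------------------------------------

@dataclass
class LATMap:
    """Per-node activation time relative to a stimulus event."""

    lat: np.ndarray          # ms; NaN where never activated
    activated: np.ndarray    # bool
    eas_node: int

    def __post_init__(self) -> None:
        if self.activated.any():
            lat_act = self.lat[self.activated]
            if not np.isclose(self.lat[self.eas_node], np.nanmin(lat_act)):
                raise ValueError("EAS must carry the minimum activation time")


def extract_lat(
    result: SimulationResult,
    event_time: float = 0.0,
    threshold_mv: float = LAT_THRESHOLD_MV,
) -> LATMap:
    """First positive-slope crossing of the threshold after ``event_time``.

    Crossing instants are linearly interpolated between output frames;
    nodes that never activate are NaN.  Raises if no node activates.
    """
    t = result.times
    if event_time > t[-1]:
        raise ValueError("event time beyond the recorded movie")
    k0 = int(np.searchsorted(t, event_time))
    vm = result.vm[:, k0:]
    tt = t[k0:]
    below = vm[:, :-1] <= threshold_mv
    above = vm[:, 1:] > threshold_mv
    crossing = below & above
    any_cross = crossing.any(axis=1)
    if not any_cross.any():
        raise ValueError("no node activated after the event (no capture)")
    first = np.argmax(crossing, axis=1)
    lat = np.full(result.n_nodes, np.nan)
    idx = np.nonzero(any_cross)[0]
    k = first[idx]
    v0 = vm[idx, k].astype(float)
    v1 = vm[idx, k + 1].astype(float)
    frac = (threshold_mv - v0) / (v1 - v0)
    lat[idx] = tt[k] + frac * (tt[k + 1] - tt[k]) - event_time
    eas = int(idx[np.argmin(lat[idx])])
    return LATMap(lat=lat, activated=any_cross, eas_node=eas)


def measure_cv(
    latmap: LATMap,
    mesh: AtrialMesh,
    eas_node: int | None = None,
    target_nodes=None,
) -> tuple[np.ndarray, float]:
    """Conduction velocity (m/s) from EAS to each target.

    CV_i = geodesic distance(EAS, target_i) / (LAT_i − LAT_EAS);
    mm/ms ≡ m/s.  Raises for targets with non-positive time differences.
    """
    if eas_node is None:
        eas_node = latmap.eas_node
    targets = np.atleast_1d(np.asarray(target_nodes, dtype=int))
    if np.any(~latmap.activated[targets]):
        bad = targets[~latmap.activated[targets]].tolist()
        raise ValueError(f"targets never activated: {bad}")
    dts = latmap.lat[targets] - latmap.lat[eas_node]
    if np.any(dts <= 0):
        bad = targets[dts <= 0].tolist()
        raise ValueError(f"non-positive activation delay for targets {bad}")
    dist = geodesic_distance(mesh, eas_node, targets)
    cv = dist / dts
    return cv, float(cv.mean())


# ---------------------------------------------------------------------------
# Calibration and patient-level tuning
# ---------------------------------------------------------------------------

def _planar_cv(
    mesh: AtrialMesh,
    conductivities: ConductivitySet,
    kappa: tuple[float, float],
    probe_a: int,
    probe_b: int,
    scaling: IonChannelScaling,
    duration: float,
) -> float:
    """Planar-wave CV (m/s) between two probes on a sheet.

    One short edge (x < 1 mm) is stimulated; CV is the probe separation
    along x divided by the LAT difference.
    """
    op = build_diffusion(mesh, conductivities, kappa)
    site = np.nonzero(mesh.nodes[:, 0] < 1.0)[0]
    proto = PacingProtocol(site_nodes=site, events=[(1.0, 2.0, TISSUE_STIM_AMPLITUDE)])
    res = run_monodomain(
        mesh, op, scaling, proto, duration=duration,
        output_interval=0.5, stop_when_activated=np.array([probe_a, probe_b]),
    )
    lat = extract_lat(res, event_time=1.0)
    d = abs(mesh.nodes[probe_b, 0] - mesh.nodes[probe_a, 0])
    dt_ab = lat.lat[probe_b] - lat.lat[probe_a]
    if not np.isfinite(dt_ab) or dt_ab <= 0:
        raise RuntimeError("probe activation order inconsistent with a planar wave")
    return float(d / dt_ab)


def _centerline_probes(mesh: AtrialMesh, x_a: float, x_b: float) -> tuple[int, int]:
    mid_y = 0.5 * (mesh.nodes[:, 1].min() + mesh.nodes[:, 1].max())
    def nearest(x):
        return int(np.argmin(
            (mesh.nodes[:, 0] - x) ** 2 + (mesh.nodes[:, 1] - mid_y) ** 2
        ))
    return nearest(x_a), nearest(x_b)


def calibrate_conduction(
    conductivities: ConductivitySet | None = None,
    spacing_um: float = 235.0,
    sheet_mm: tuple[float, float] = (30.0, 10.0),
    cv_targets: tuple[float, float] = (CV_TARGET_LONGITUDINAL, CV_TARGET_TRANSVERSE),
    scaling: IonChannelScaling | None = None,
    rel_tol: float = 0.01,
    max_iter: int = 12,
    probe_x_mm: tuple[float, float] = (10.0, 20.0),
    run_duration: float = 120.0,
) -> tuple[float, float]:
    """Fix the conductivity→diffusion scales against the target CVs.

    Two planar-wave experiments on a ``sheet_mm`` sheet meshed at
    ``spacing_um`` — fibers along the propagation axis for ``kappa_L``,
    across it for ``kappa_T`` — are iterated with the continuum scaling
    law CV ∝ √kappa until the simulated CV matches its target within
    ``rel_tol``.  Tissue is AF-remodeled and non-fibrotic.  Returns
    ``(kappa_L, kappa_T)``, to be frozen for all subsequent runs.
    """
    from .geometry import assign_fiber_field, generate_sheet_mesh

    if conductivities is None:
        conductivities = ConductivitySet()
    if scaling is None:
        scaling = af_remodeling_profile()

    base = generate_sheet_mesh(sheet_mm[0], sheet_mm[1], spacing_um)
    probe_a, probe_b = _centerline_probes(base, *probe_x_mm)
    mesh_l = assign_fiber_field(base, "uniform", direction=[1.0, 0.0, 0.0])
    mesh_t = assign_fiber_field(base, "uniform", direction=[0.0, 1.0, 0.0])

    kappas = []
    for mesh, target, sigma, which in (
        (mesh_l, cv_targets[0], conductivities.sigma_l_normal, "L"),
        (mesh_t, cv_targets[1], conductivities.sigma_t_normal, "T"),
    ):
        # initial guess from the continuum law CV ≈ c·√D with c ≈ 1.45
        # (m/s at D = 1 mm²/ms) for AF-remodeled CRN tissue at this spacing
        kappa = (target / 1.45) ** 2 / sigma
        cv = np.nan
        for _ in range(max_iter):
            # only the conductivity along the propagation axis matters on
            # each sheet, so one shared kappa per experiment suffices
            cv = _planar_cv(
                mesh, conductivities, (kappa, kappa), probe_a, probe_b,
                scaling, duration=run_duration,
            )
            if abs(cv - target) <= rel_tol * target:
                break
            kappa *= (target / cv) ** 2
        else:
            raise RuntimeError(
                f"calibration did not converge for direction {which}: "
                f"reached CV {cv:.3f} m/s vs target {target} m/s"
            )
        kappas.append(kappa)
    return float(kappas[0]), float(kappas[1])


def tune_diffusion(
    mesh: AtrialMesh,
    conductivities: ConductivitySet,
    calibration: tuple[float, float],
    scaling: np.ndarray | IonChannelScaling,
    protocol_site: np.ndarray,
    target_nodes: np.ndarray,
    clinical_times_ms: np.ndarray,
    run_duration: float = 120.0,
    rel_tol: float = 0.02,
    max_iter: int = 30,
) -> tuple[float, np.ndarray]:
    """Patient-level conduction tuning: one global diffusion scale.

    Both kappa scales are multiplied by the same factor (longitudinal and
    transverse diffusion adjusted at the same rate) until the mean virtual
    conduction time from the pacing site to ``target_nodes`` matches the
    mean of ``clinical_times_ms`` within ``rel_tol``.  Conduction time
    T ∝ 1/√scale guides the update.  Returns the scale and the per-target
    residuals (virtual − clinical, ms) at convergence.
    """
    clinical = np.asarray(clinical_times_ms, dtype=float)
    targets = np.asarray(target_nodes, dtype=int)
    if clinical.shape != targets.shape:
        raise ValueError("one clinical time per target is required")
    mean_cli = clinical.mean()
    if mean_cli <= 0:
        raise ValueError("clinical conduction times must have positive mean")

    kappa_l, kappa_t = calibration
    proto = PacingProtocol(
        site_nodes=protocol_site, events=[(1.0, 2.0, TISSUE_STIM_AMPLITUDE)]
    )
    scale = 1.0
    last_virtual = None
    for it in range(max_iter):
        op = build_diffusion(
            mesh, conductivities, (kappa_l * scale, kappa_t * scale)
        )
        res = run_monodomain(
            mesh, op, scaling, proto, duration=run_duration,
            output_interval=0.5, stop_when_activated=targets,
        )
        lat = extract_lat(res, event_time=1.0)
        virtual = lat.lat[targets] - np.nanmin(lat.lat)
        if np.any(~np.isfinite(virtual)):
            raise RuntimeError("a target did not activate during tuning")
        last_virtual = virtual
        mean_vir = virtual.mean()
        if abs(mean_vir - mean_cli) <= rel_tol * mean_cli:
            return float(scale), virtual - clinical
        scale *= (mean_vir / mean_cli) ** 2
    raise RuntimeError(
        f"tuning did not converge in {max_iter} iterations; "
        f"best scale {scale:.4f}, virtual mean {last_virtual.mean():.2f} ms "
        f"vs clinical {mean_cli:.2f} ms"
    )


# ---------------------------------------------------------------------------
# AF induction
# ---------------------------------------------------------------------------

def detect_induction(
    result: SimulationResult,
    protocol: PacingProtocol,
    window_s: float = 6.0,
    max_silent_gap_ms: float = 500.0,
    threshold_mv: float = LAT_THRESHOLD_MV,
) -> tuple[bool, tuple[float, float]]:
    """Decide whether pacing induced sustained activity (virtual AF).

    Induced iff, over the full ``window_s`` after the last stimulus, some
    node crosses the activation threshold upward with no electrically
    silent gap longer than ``max_silent_gap_ms``.  Returns the verdict and
    the analysis window (start, end) in ms.
    """
    t_start = protocol.last_event_end
    t_end = t_start + window_s * 1000.0
    if result.times[-1] < t_end - 1e-6:
        raise ValueError(
            f"movie ends at {result.times[-1]:.0f} ms; induction analysis "
            f"needs {t_end:.0f} ms"
        )
    sel = (result.times >= t_start) & (result.times <= t_end)
    tt = result.times[sel]
    vm = result.vm[:, sel]
    up = (vm[:, :-1] <= threshold_mv) & (vm[:, 1:] > threshold_mv)
    frame_active = up.any(axis=0)
    active_times = tt[1:][frame_active]
    if active_times.size == 0:
        return False, (t_start, t_end)
    gaps = np.diff(np.concatenate([[t_start], active_times, [t_end]]))
    return bool(np.max(gaps) <= max_silent_gap_ms), (t_start, t_end)
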