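"""AF wave-dynamics analysis: dominant frequency, phase singularities, rotors.

During simulated fibrillation each node's action-potential signal is
analyzed over a 6-s window:

* **Dominant frequency (DF)** — the frequency of highest power in the
  node's periodogram (de-meaned, Hann-tapered FFT), restricted to a
  physiologic band (default 1–20 Hz).  The map's peak point and the
  top-5 % DF region summarize where the fastest activity lives.
* **Phase** — the analytic-signal (Hilbert) phase of the de-meaned
  potential; one full cycle advances the phase by 2π.
* **Phase singularities (PS)** — points where the phase is undefined,
  detected per mesh face by the winding number of the phase around the
  oriented face cycle: a ±2π winding marks a rotor tip of the matching
  chirality at the face centroid.
* **Trajectories** — PS events linked frame-to-frame by greedy nearest
  neighbor under a step bound and equal chirality.
* **Mother rotor** — a trajectory that lives longer than 5 s while its
  tip stays within a circle of diameter half the cardiac wavelength
  (wavelength = planar CV at 600-ms pacing × 600 ms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .geometry import AtrialMesh
from .propagation import SimulationResult

__all__ = [
    "DFMap",
    "PhaseField",
    "PSEvent",
    "PSTrajectory",
    "MotherRotorCriterion",
    "compute_df_map",
    "top_df_region",
    "compute_phase",
    "detect_ps",
    "detect_ps_movie",
    "link_trajectories",
    "classify_mother_rotor",
    "minimal_enclosing_circle",
]

DF_BAND_HZ = (1.0, 20.0)
SILENT_PTP_MV = 1.0     # below this peak-to-peak swing a node is silent


# ---------------------------------------------------------------------------
# Dominant frequency
# ---------------------------------------------------------------------------

@dataclass
class DFMap:
    """Per-node dominant frequency (Hz) and its peak spectral power."""

    df_hz: np.ndarray          # NaN where undefined (silent node)
    peak_power: np.ndarray
    window_s: float
    band_hz: tuple

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.df_hz)


def compute_df_map(
    result: SimulationResult,
    window_ms: tuple[float, float] | None = None,
    band_hz: tuple[float, float] = DF_BAND_HZ,
) -> DFMap:
    """Dominant frequency of every node's action-potential signal.

    ``window_ms`` selects the analysis interval (default: the trailing
    6 s of the movie).  Each node is de-meaned, Hann-tapered and Fourier
    transformed; the DF is the in-band frequency of highest power.
    Nodes with no appreciable signal are flagged NaN.
    """
    t = result.times
    if window_ms is None:
        window_ms = (max(t[0], t[-1] - 6000.0), t[-1])
    t0, t1 = window_ms
    if t1 - t0 < 1000.0:
        raise ValueError("DF analysis window must be at least 1 s")
    dt = result.output_interval
    if dt <= 0 or dt > 10.0:
        raise ValueError("DF analysis needs sampling interval <= 10 ms")
    sel = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
    x = result.vm[:, sel].astype(float)
    n_t = x.shape[1]
    fs = 1000.0 / dt

    x = x - x.mean(axis=1, keepdims=True)
    ptp = x.max(axis=1) - x.min(axis=1)
    taper = np.hanning(n_t)
    spec = np.abs(np.fft.rfft(x * taper, axis=1)) ** 2
    freqs = np.fft.rfftfreq(n_t, d=1.0 / fs)

    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not in_band.any():
        raise ValueError("frequency band contains no FFT bins for this window")
    band_freqs = freqs[in_band]
    band_spec = spec[:, in_band]
    k = np.argmax(band_spec, axis=1)
    df = band_freqs[k]
    power = band_spec[np.arange(len(k)), k]

    silent = ptp < SILENT_PTP_MV
    df = np.where(silent, np.nan, df)
    power = np.where(silent, np.nan, power)
    return DFMap(
        df_hz=df, peak_power=power, window_s=(t1 - t0) / 1000.0, band_hz=tuple(band_hz)
    )


def top_df_region(
    dfmap: DFMap, fraction: float = 0.05
) -> tuple[np.ndarray, int]:
    """Nodes at or above the (1 − fraction) DF quantile, plus the peak node.

    Ties at the quantile are all included (with a warning if the whole map
    is tied); the peak node is the maximum-DF node, ties broken by peak
    spectral power.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    defined = np.nonzero(dfmap.defined)[0]
    if defined.size < 20:
        raise ValueError("DF map defined on fewer than 20 nodes")
    df = dfmap.df_hz[defined]
    thr = np.quantile(df, 1.0 - fraction)
    top = defined[df >= thr]
    if np.ptp(df) == 0:
        warnings.warn("all DF values equal; top-DF region is the whole map",
                      stacklevel=2)
    best = df.max()
    cand = defined[df == best]
    peak_node = int(cand[np.argmax(dfmap.peak_power[cand])])
    return top, peak_node


# ---------------------------------------------------------------------------
# Phase
# ---------------------------------------------------------------------------

@dataclass
class PhaseField:
    """Instantaneous phase per node and frame, radians in (−π, π]."""

    times: np.ndarray          # (t,) ms
    phase: np.ndarray          # (n, t)
    defined: np.ndarray        # (n,) bool — False for silent nodes


def compute_phase(
    result: SimulationResult,
    window_ms: tuple[float, float] | None = None,
) -> PhaseField:
    """Analytic-signal phase of the de-meaned membrane potential.

    Scale-invariant by construction (the Hilbert transform is linear and
    the phase discards amplitude).  Silent nodes — peak-to-peak swing
    below ~1 mV — are flagged undefined.
    """
    t = result.times
    if window_ms is None:
        window_ms = (t[0], t[-1])
    t0, t1 = window_ms
    sel = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
    if sel.sum() < 4:
        raise ValueError("phase window covers fewer than 4 frames")
    x = result.vm[:, sel].astype(float)
    x = x - x.mean(axis=1, keepdims=True)
    defined = (x.max(axis=1) - x.min(axis=1)) >= SILENT_PTP_MV
    analytic = hilbert(x, axis=1)
    return PhaseField(times=t[sel], phase=np.angle(analytic), defined=defined)


# ---------------------------------------------------------------------------
# Phase singularities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSEvent:
    """One detected rotor tip: time, mesh face, location, chirality ±1."""

    time_ms: float
    face: int
    location: np.ndarray
    chirality: int


@dataclass
class PSTrajectory:
    """Time-linked chain of PS events of one chirality."""

    events: list

    def __post_init__(self) -> None:
        times = [e.time_ms for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time_ms for e in self.events])

    @property
    def points(self) -> np.ndarray:
        return np.array([e.location for e in self.events])

    @property
    def chirality(self) -> int:
        return self.events[0].chirality

    @property
    def lifespan_ms(self) -> float:
        return float(self.times[-1] - self.times[0])

    def max_tip_displacement(self) -> float:
        p = self.points
        return float(np.max(np.linalg.norm(p - p[0], axis=1)))

    def confinement_diameter(self) -> float:
        """Diameter of the minimal enclosing circle of the tip path, mm."""
        _, radius = minimal_enclosing_circle(self.points)
        return 2.0 * radius


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def detect_ps(
    phase: PhaseField, mesh: AtrialMesh, frame: int
) -> list[PSEvent]:
    """Phase singularities in one frame by face winding number.

    The wrapped phase differences around each oriented triangle sum to 0
    for a smooth field and to ±2π around a singularity ("the phase is
    undefined" at the enclosed point); such faces yield a PS at their
    centroid with the winding sign as chirality.  Faces touching
    undefined-phase nodes are skipped.
    """
    th = phase.phase[:, frame]
    tris = mesh.triangles
    ok = phase.defined[tris].all(axis=1)
    d1 = _wrap(th[tris[:, 1]] - th[tris[:, 0]])
    d2 = _wrap(th[tris[:, 2]] - th[tris[:, 1]])
    d3 = _wrap(th[tris[:, 0]] - th[tris[:, 2]])
    winding = d1 + d2 + d3
    hits = np.nonzero(ok & (np.abs(winding) > np.pi))[0]
    t_ms = float(phase.times[frame])
    events = []
    for f in hits:
        centroid = mesh.nodes[tris[f]].mean(axis=0)
        events.append(
            PSEvent(
                time_ms=t_ms,
                face=int(f),
                location=centroid,
                chirality=int(np.sign(winding[f])),
            )
        )
    return events


def detect_ps_movie(phase: PhaseField, mesh: AtrialMesh) -> list[list[PSEvent]]:
    """PS events for every frame of the phase field."""
    return [detect_ps(phase, mesh, k) for k in range(phase.times.size)]


# ---------------------------------------------------------------------------
# Trajectory linking
# ---------------------------------------------------------------------------

def link_trajectories(
    events_per_frame: list,
    mesh: AtrialMesh | None = None,
    max_step_mm: float = 5.0,
) -> tuple[list, dict]:
    """Greedy nearest-neighbor linking of PS events across frames.

    An event continues the trajectory whose last tip is nearest, provided
    the step is within ``max_step_mm`` and the chirality matches;
    otherwise it starts a new trajectory.  Returns the trajectories and,
    when ``mesh`` carries region labels, per-region PS counts — both raw
    events and trajectories (a trajectory counts in the region of its
    mean tip position).
    """
    open_trajs: list[list] = []
    closed: list[list] = []
    for events in events_per_frame:
        used = [False] * len(open_trajs)
        new_trajs: list[list] = []
        assigned = []
        # match each event to the nearest compatible open trajectory
        for ev in sorted(events, key=lambda e: (e.chirality, tuple(e.location))):
            best_j, best_d = -1, np.inf
            for j, tr in enumerate(open_trajs):
                if used[j] or tr[-1].chirality != ev.chirality:
                    continue
                d = float(np.linalg.norm(tr[-1].location - ev.location))
                if d < best_d:
                    best_j, best_d = j, d
            if best_j >= 0 and best_d <= max_step_mm:
                used[best_j] = True
                assigned.append((best_j, ev))
            else:
                new_trajs.append([ev])
        survivors = []
        for j, tr in enumerate(open_trajs):
            if used[j]:
                survivors.append(tr)
            else:
                closed.append(tr)
        for j, ev in assigned:
            open_trajs[j].append(ev)
        open_trajs = survivors + new_trajs
    closed.extend(open_trajs)
    trajectories = [PSTrajectory(events=tr) for tr in closed if tr]

    counts: dict = {}
    if mesh is not None and mesh.region is not None:
        ev_counts: dict[int, int] = {}
        tr_counts: dict[int, int] = {}
        for events in events_per_frame:
            for ev in events:
                label = _region_of(mesh, ev.location)
                ev_counts[label] = ev_counts.get(label, 0) + 1
        for tr in trajectories:
            label = _region_of(mesh, tr.points.mean(axis=0))
            tr_counts[label] = tr_counts.get(label, 0) + 1
        counts = {"events": ev_counts, "trajectories": tr_counts}
    return trajectories, counts


def _region_of(mesh: AtrialMesh, point: np.ndarray) -> int:
    node = int(np.argmin(np.sum((mesh.nodes - point) ** 2, axis=1)))
    return int(mesh.region[node])


# ---------------------------------------------------------------------------
# Mother-rotor classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotherRotorCriterion:
    """Spatial-confinement + longevity definition of a driving rotor.

    ``wavelength_mm`` is the cardiac wavelength measured from a planar
    wave paced at 600-ms cycle length (CV × 600 ms); a rotor qualifies if
    it outlives ``min_lifespan_ms`` while its tip remains inside a circle
    of diameter ``wavelength_mm / 2``.
    """

    wavelength_mm: float
    min_lifespan_ms: float = 5000.0

    def __post_init__(self) -> None:
        if self.wavelength_mm <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def confinement_diameter_mm(self) -> float:
        return self.wavelength_mm / 2.0

    @classmethod
    def from_planar_wave(
        cls, cv_m_s: float, cycle_length_ms: float = 600.0, **kw
    ) -> "MotherRotorCriterion":
        return cls(wavelength_mm=cv_m_s * cycle_length_ms, **kw)


def classify_mother_rotor(
    traj: PSTrajectory, criterion: MotherRotorCriterion
) -> bool:
    """True iff the trajectory satisfies the mother-rotor definition."""
    if not traj.events:
        raise ValueError("empty trajectory")
    if traj.lifespan_ms <= criterion.min_lifespan_ms:
        return False
    return traj.confinement_diameter() <= criterion.confinement_diameter_mm


# ---------------------------------------------------------------------------
# Minimal enclosing circle (exact, Welzl)
# ---------------------------------------------------------------------------

def minimal_enclosing_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact smallest enclosing circle of 3-D points lying near a plane.

    Points are projected onto their best-fit (PCA) plane and Welzl's
    algorithm is run in 2-D; returns the center (3-D, on the plane) and
    radius in mm.  For a single point the radius is 0.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 1:
        return pts[0].copy(), 0.0
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    basis = vt[:2]
    p2 = centered @ basis.T

    c2, r = _welzl(list(map(tuple, p2)))
    center3 = centroid + np.asarray(c2) @ basis
    return center3, float(r)


def _circle_from(a, b, c=None):
    ax, ay = a
    bx, by = b
    if c is None:
        cx, cy = (ax + bx) / 2.0, (ay + by) / 2.0
        return (cx, cy), np.hypot(ax - cx, ay - cy)
    cx2, cy2 = c
    d = 2.0 * (ax * (by - cy2) + bx * (cy2 - ay) + cx2 * (ay - by))
    if abs(d) < 1e-14:
        # collinear: take the widest pair
        pairs = [(a, b), (a, c), (b, c)]
        circles = [_circle_from(p, q) for p, q in pairs]
        return max(circles, key=lambda cr: cr[1])
    ux = (
        (ax ** 2 + ay ** 2) * (by - cy2)
        + (bx ** 2 + by ** 2) * (cy2 - ay)
        + (cx2 ** 2 + cy2 ** 2) * (ay - by)
    ) / d
    uy = (
        (ax ** 2 + ay ** 2) * (cx2 - bx)
        + (bx ** 2 + by ** 2) * (ax - cx2)
        + (cx2 ** 2 + cy2 ** 2) * (bx - ax)
    ) / d
    return (ux, uy), np.hypot(ax - ux, ay - uy)


def _in_circle(p, circle, eps=1e-9):
    (cx, cy), r = circle
    return np.hypot(p[0] - cx, p[1] - cy) <= r + eps


def _welzl(points):
    """Iterative move-to-front Welzl; deterministic (no shuffling)."""
    circle = ((points[0][0], points[0][1]), 0.0)
    for i, p in enumerate(points):
        if _in_circle(p, circle):
            continue
        circle = ((p[0], p[1]), 0.0)
        for j in range(i):
            q = points[j]
            if _in_circle(q, circle):
                continue
            circle = _circle_from(p, q)
            for k in range(j):
                s = points[k]
                if _in_circle(s, circle):
                    continue
                circle = _circle_from(p, q, s)
    return circle
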