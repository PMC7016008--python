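"""Forward extracellular electrograms from a membrane-potential movie.

The unipolar potential at an electrode r′ follows the volume-conductor
current-source formulation

.. math::

   \\phi_e(r') = -\\frac{1}{4\\pi}\\frac{\\sigma_i}{\\sigma_e}
       \\int \\nabla V_m(r)\\cdot\\nabla\\!\\left[\\frac{1}{|r'-r|}\\right] dv

discretized per surface triangle: ``∇V_m`` is the exact gradient of the
linear interpolant over the element, the kernel is evaluated at the
element centroid, and ``dv`` is element area times a nominal wall
thickness (the surface model is a monolayer; thickness only scales the
amplitude uniformly and leaves morphology untouched).  A bipolar
electrogram is the difference of two unipolar electrograms 1 mm apart,
as recorded by a mapping catheter.

Morphology agreement between two electrograms is the mean inner product
of the unit-normalized signals (cosine similarity, optionally averaged
over beat segments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import AtrialMesh
from .propagation import SimulationResult

__all__ = [
    "ElectrogramModel",
    "Electrogram",
    "SimilarityInput",
    "unipolar_egm",
    "bipolar_egm",
    "morphology_similarity",
    "segment_beats",
]


@dataclass(frozen=True)
class ElectrogramModel:
    """Volume-conductor parameters for the forward computation.

    Only the conductivity ratio σ_i/σ_e affects the signal up to scale.
    ``clearance_mm`` keeps electrodes away from the singular kernel.
    """

    sigma_i: float = 0.4
    sigma_e: float = 1.0
    thickness_mm: float = 2.0
    clearance_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma_i <= 0 or self.sigma_e <= 0:
            raise ValueError("conductivities must be positive")
        if self.thickness_mm <= 0:
            raise ValueError("wall thickness must be positive")


@dataclass
class Electrogram:
    """Sampled extracellular signal at one electrode (or pole pair)."""

    times: np.ndarray
    values: np.ndarray
    electrode: np.ndarray | tuple

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times/values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite electrogram values")


@dataclass
class SimilarityInput:
    """A clinical/reference and a virtual signal on a common time grid."""

    egm_reference: np.ndarray
    egm_virtual: np.ndarray

    def __post_init__(self) -> None:
        self.egm_reference = np.asarray(self.egm_reference, dtype=float)
        self.egm_virtual = np.asarray(self.egm_virtual, dtype=float)
        if self.egm_reference.shape != self.egm_virtual.shape:
            raise ValueError("signals must share one time grid")
        if self.egm_reference.size < 2:
            raise ValueError("signals need at least 2 samples")


def _node_weights(
    mesh: AtrialMesh, electrode: np.ndarray, model: ElectrogramModel
) -> np.ndarray:
    """Per-node weight vector w such that φ_e(t) = w · vm(t).

    Collapses the per-element sum ∇V_m·∇(1/R)·dv into node space using the
    linearity of the element gradient in nodal values.
    """
    r_p = np.asarray(electrode, dtype=float)
    tris = mesh.triangles
    p = mesh.nodes[tris]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    nrm = np.cross(e1, e2)
    a2 = np.linalg.norm(nrm, axis=1)
    nhat = nrm / a2[:, None]
    area = 0.5 * a2
    centroids = p.mean(axis=1)

    sep = r_p[None, :] - centroids
    dist = np.linalg.norm(sep, axis=1)
    if dist.min() < model.clearance_mm:
        raise ValueError(
            f"electrode is {dist.min():.2f} mm from the surface; "
            f"minimum clearance is {model.clearance_mm} mm"
        )
    # ∇_r (1/|r'−r|) evaluated at the element centroid
    kernel = sep / dist[:, None] ** 3

    edges_opp = np.stack(
        [p[:, 2] - p[:, 1], p[:, 0] - p[:, 2], p[:, 1] - p[:, 0]], axis=1
    )
    grads = np.cross(nhat[:, None, :], edges_opp) / a2[:, None, None]

    dv = area * model.thickness_mm
    coeff = -(model.sigma_i / model.sigma_e) / (4.0 * np.pi)
    w_el = coeff * dv[:, None] * np.einsum("eja,ea->ej", grads, kernel)

    w = np.zeros(mesh.n_nodes)
    for k in range(3):
        np.add.at(w, tris[:, k], w_el[:, k])
    return w


def unipolar_egm(
    result: SimulationResult,
    mesh: AtrialMesh,
    electrode,
    model: ElectrogramModel | None = None,
) -> Electrogram:
    """Unipolar extracellular electrogram at a point off the surface."""
    if model is None:
        model = ElectrogramModel()
    w = _node_weights(mesh, electrode, model)
    values = w @ result.vm.astype(float)
    return Electrogram(
        times=result.times.copy(), values=values, electrode=np.asarray(electrode)
    )


def bipolar_egm(
    result: SimulationResult,
    mesh: AtrialMesh,
    center,
    orientation,
    spacing_mm: float = 1.0,
    model: ElectrogramModel | None = None,
) -> Electrogram:
    """Bipolar electrogram: two unipolar poles ``spacing_mm`` apart.

    The poles sit at center ± spacing/2 along ``orientation``; the signal
    is their difference (distal minus proximal).
    """
    if model is None:
        model = ElectrogramModel()
    c = np.asarray(center, dtype=float)
    o = np.asarray(orientation, dtype=float)
    norm = np.linalg.norm(o)
    if norm == 0:
        raise ValueError("orientation must be non-zero")
    o = o / norm
    pole_a = c + 0.5 * spacing_mm * o
    pole_b = c - 0.5 * spacing_mm * o
    ega = unipolar_egm(result, mesh, pole_a, model)
    egb = unipolar_egm(result, mesh, pole_b, model)
    return Electrogram(
        times=result.times.copy(),
        values=ega.values - egb.values,
        electrode=(pole_a, pole_b),
    )


# ---------------------------------------------------------------------------
# Morphology similarity
# ---------------------------------------------------------------------------

def segment_beats(
    values: np.ndarray, times: np.ndarray, min_separation_ms: float = 100.0
) -> list[slice]:
    """Split a signal into beat segments between detected activations.

    Activations are prominent absolute-amplitude peaks separated by at
    least ``min_separation_ms``; segments span from each activation to
    the next (trailing partial beat included).
    """
    from scipy.signal import find_peaks

    x = np.abs(np.asarray(values, dtype=float))
    if x.size < 3:
        return [slice(0, x.size)]
    dt = float(times[1] - times[0])
    dist = max(1, int(min_separation_ms / dt))
    peaks, _ = find_peaks(x, height=0.5 * x.max(), distance=dist)
    if len(peaks) < 2:
        return [slice(0, x.size)]
    bounds = [0] + [int((a + b) // 2) for a, b in zip(peaks[:-1], peaks[1:])] + [x.size]
    return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b - a >= 2]


def morphology_similarity(
    a: SimilarityInput | np.ndarray,
    b: np.ndarray | None = None,
    segments: list | None = None,
    resample_to: int = 64,
) -> float:
    """Mean inner product of unit-normalized electrogram signals, in [−1, 1].

    With no ``segments`` the plain cosine similarity of the two whole
    signals is returned; with segments (index slices on the common grid)
    each pair of segments is resampled to a common length, normalized and
    compared, and the per-segment cosines are averaged.
    """
    if isinstance(a, SimilarityInput):
        x, y = a.egm_reference, a.egm_virtual
    else:
        if b is None:
            raise ValueError("two signals are required")
        x = np.asarray(a, dtype=float)
        y = np.asarray(b, dtype=float)
        if x.shape != y.shape or x.size < 2:
            raise ValueError("signals must share a common grid of >= 2 samples")

    def cosine(u: np.ndarray, v: np.ndarray) -> float:
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            raise ValueError("zero-norm signal in similarity computation")
        return float(np.dot(u / nu, v / nv))

    if not segments:
        return cosine(x, y)
    vals = []
    for seg in segments:
        xs, ys = x[seg], y[seg]
        if xs.size < 2:
            continue
        grid = np.linspace(0.0, 1.0, resample_to)
        src = np.linspace(0.0, 1.0, xs.size)
        vals.append(cosine(np.interp(grid, src, xs), np.interp(grid, src, ys)))
    if not vals:
        raise ValueError("no usable segments")
    return float(np.mean(vals))
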