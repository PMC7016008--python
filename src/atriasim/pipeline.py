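"""End-to-end study orchestration: map in, wave-dynamics report out.

``run_study`` mirrors the clinical modeling workflow on synthetic (or
file-based) inputs: interpolate the electro-anatomical map onto the mesh,
assign fibrosis from voltage, orient fibers from the activation gradient,
calibrate/tune conduction, provoke AF by ramp pacing, and — when
sustained activity results — analyze dominant frequency and phase
singularities over a 6-s window.  Every stage is logged with its
duration, every random draw flows from the seeds in the configuration,
and the report carries enough provenance (config hash, seeds, package
version) to regenerate it bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field, fields

import numpy as np

from .emap import (
    ElectroAnatomicalMap,
    FibrosisModel,
    assign_fibrosis,
    generate_synthetic_emap,
    idw_interpolate,
    read_emap,
)
from .fixtures import make_labeled_regions
from .geometry import AtrialMesh, assign_fiber_field, generate_sheet_mesh, load_mesh, save_mesh
from .propagation import (
    ConductivitySet,
    calibrate_conduction,
    build_diffusion,
    detect_induction,
    disk_site,
    extract_lat,
    make_ramp_protocol,
    node_scaling,
    run_monodomain,
    tune_diffusion,
    CV_TARGET_LONGITUDINAL,
)
from .wavedynamics import (
    MotherRotorCriterion,
    classify_mother_rotor,
    compute_df_map,
    compute_phase,
    detect_ps_movie,
    link_trajectories,
    top_df_region,
)

__all__ = ["RunConfig", "WaveDynamicsReport", "run_study"]

logger = logging.getLogger("atriasim")


@dataclass
class RunConfig:
    """Flat, fully serializable study configuration.

    Physical defaults follow the published model conditions (conductivity
    set, 10-mm interpolation radius, ramp pacing 200→120 ms over
    6,530 ms, 6-s analysis window, 1–20 Hz DF band) so any of them can be
    overridden from the config file.
    """

    # mesh: either a file path or sheet-fixture dimensions
    mesh_path: str | None = None
    mesh_width_mm: float = 30.0
    mesh_height_mm: float = 10.0
    mesh_spacing_um: float = 235.0
    n_regions: int = 10

    # electro-anatomical map: path or synthetic acquisition
    emap_path: str | None = None
    emap_n_points: int = 600
    emap_voltage_noise_sd: float = 0.05
    emap_lat_noise_sd: float = 1.0

    # interpolation / fibrosis
    idw_radius_mm: float = 10.0
    idw_power: float = 2.0
    fibrosis_threshold_mv: float = 1.74

    # conduction
    sigma_l_normal: float = 0.1264
    sigma_l_fibrotic: float = 0.0546
    sigma_t_normal: float = 0.0252
    sigma_t_fibrotic: float = 0.0068
    kappa_l: float | None = None     # None -> run calibrate_conduction
    kappa_t: float | None = None
    tune_to_map: bool = True
    n_cv_targets: int = 5

    # pacing
    ramp_cl_start_ms: float = 200.0
    ramp_cl_end_ms: float = 120.0
    ramp_total_ms: float = 6530.0
    pacing_site_radius_mm: float = 1.0

    # analysis
    post_pacing_window_s: float = 6.0
    df_band_hz: tuple = (1.0, 20.0)
    top_df_fraction: float = 0.05
    ps_max_step_mm: float = 5.0
    output_interval_ms: float = 5.0

    # bookkeeping
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Read a TOML config; unknown keys are rejected."""
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        flat: dict = {}
        for key, val in raw.items():
            if isinstance(val, dict):
                flat.update(val)
            else:
                flat[key] = val
        known = {f.name for f in fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "df_band_hz" in flat:
            flat["df_band_hz"] = tuple(flat["df_band_hz"])
        return cls(**flat)

    def conductivities(self) -> ConductivitySet:
        return ConductivitySet(
            sigma_l_normal=self.sigma_l_normal,
            sigma_l_fibrotic=self.sigma_l_fibrotic,
            sigma_t_normal=self.sigma_t_normal,
            sigma_t_fibrotic=self.sigma_t_fibrotic,
        )

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class WaveDynamicsReport:
    """Machine-readable summary of one study run."""

    fibrosis_fraction_pct: float
    induced: bool
    tuning_scale: float
    df_peak_hz: float | None = None
    df_peak_node: int | None = None
    top_df_node_count: int | None = None
    ps_event_count: int | None = None
    ps_trajectory_count: int | None = None
    mother_rotor_count: int | None = None
    per_region: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "report.json"), "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)
        with open(os.path.join(directory, "report.txt"), "w") as fh:
            fh.write(self.pretty())

    def pretty(self) -> str:
        lines = [
            "wave-dynamics report",
            f"  fibrosis fraction : {self.fibrosis_fraction_pct:.1f} %",
            f"  AF induced        : {self.induced}",
            f"  conduction scale  : {self.tuning_scale:.3f}",
        ]
        if self.induced and self.df_peak_hz is not None:
            lines += [
                f"  peak DF           : {self.df_peak_hz:.2f} Hz at node {self.df_peak_node}",
                f"  top-5% DF nodes   : {self.top_df_node_count}",
                f"  PS events         : {self.ps_event_count}",
                f"  PS trajectories   : {self.ps_trajectory_count}",
                f"  mother rotors     : {self.mother_rotor_count}",
            ]
        lines.append(f"  config digest     : {self.provenance.get('config_digest')}")
        return "\n".join(lines) + "\n"


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            dt = time.perf_counter() - self.t0
            logger.info("stage=%s duration_s=%.2f", name, dt)
            return False

    return _Timer()


def run_study(config: RunConfig) -> WaveDynamicsReport:
    """Execute the full modeling pipeline described by ``config``."""
    rng_seed = int(config.seed)

    with _stage("mesh"):
        if config.mesh_path:
            mesh = load_mesh(config.mesh_path)
        else:
            mesh = generate_sheet_mesh(
                config.mesh_width_mm, config.mesh_height_mm, config.mesh_spacing_um
            )
        mesh = make_labeled_regions(mesh, config.n_regions, seed=rng_seed)

    with _stage("emap"):
        if config.emap_path:
            emap = read_emap(config.emap_path)
        else:
            emap, _, _ = generate_synthetic_emap(
                mesh,
                n_points=min(config.emap_n_points, mesh.n_nodes),
                seed=rng_seed,
                voltage_noise_sd=config.emap_voltage_noise_sd,
                lat_noise_sd=config.emap_lat_noise_sd,
            )

    with _stage("interpolation"):
        v_field = idw_interpolate(
            emap, mesh, "voltage",
            radius_mm=config.idw_radius_mm, power=config.idw_power,
        )
        lat_field = idw_interpolate(
            emap, mesh, "lat",
            radius_mm=config.idw_radius_mm, power=config.idw_power,
        )

    with _stage("fibrosis"):
        model = FibrosisModel(
            threshold_mv=config.fibrosis_threshold_mv, rng_seed=rng_seed + 1
        )
        mesh, fib_fraction = assign_fibrosis(mesh, v_field, model)

    with _stage("fibers"):
        lat_filled = lat_field.filled(float(np.nanmax(lat_field.values)))
        mesh = assign_fiber_field(mesh, "from_lat_gradient", lat=lat_filled)

    cond = config.conductivities()
    with _stage("calibration"):
        if config.kappa_l is None or config.kappa_t is None:
            kappa_l, kappa_t = calibrate_conduction(cond)
        else:
            kappa_l, kappa_t = float(config.kappa_l), float(config.kappa_t)

    with _stage("tuning"):
        covered = np.nonzero(lat_field.covered)[0]
        eas_node = int(covered[np.argmin(lat_field.values[covered])])
        site = disk_site(mesh, eas_node, config.pacing_site_radius_mm)
        scale = 1.0
        if config.tune_to_map:
            # clinical conduction times: interpolated LAT at spread targets
            lat_cov = lat_field.values[covered]
            qs = np.linspace(0.5, 0.95, config.n_cv_targets)
            targets = covered[
                np.argmin(
                    np.abs(lat_cov[:, None] - np.quantile(lat_cov, qs)[None, :]),
                    axis=0,
                )
            ]
            clinical = lat_field.values[targets] - lat_field.values[eas_node]
            scal = node_scaling(mesh)
            scale, _ = tune_diffusion(
                mesh, cond, (kappa_l, kappa_t), scal, site,
                targets, clinical,
            )
        kappa_l *= scale
        kappa_t *= scale

    with _stage("induction"):
        op = build_diffusion(mesh, cond, (kappa_l, kappa_t))
        scal = node_scaling(mesh)
        protocol = make_ramp_protocol(
            site,
            cl_start=config.ramp_cl_start_ms,
            cl_end=config.ramp_cl_end_ms,
            total_ms=config.ramp_total_ms,
        )
        duration = protocol.total_duration + config.post_pacing_window_s * 1000.0
        result = run_monodomain(
            mesh, op, scal, protocol, duration=duration,
            output_interval=config.output_interval_ms,
        )
        induced, window = detect_induction(
            result, protocol, window_s=config.post_pacing_window_s
        )

    report = WaveDynamicsReport(
        fibrosis_fraction_pct=100.0 * fib_fraction,
        induced=induced,
        tuning_scale=scale,
        provenance={
            "config_digest": config.digest(),
            "seed": rng_seed,
            "kappa_l": kappa_l,
            "kappa_t": kappa_t,
            "n_nodes": mesh.n_nodes,
            "eas_node": eas_node,
        },
    )

    if induced:
        with _stage("wave_dynamics"):
            dfmap = compute_df_map(result, window_ms=window, band_hz=config.df_band_hz)
            top, peak = top_df_region(dfmap, config.top_df_fraction)
            phase = compute_phase(result, window_ms=window)
            events = detect_ps_movie(phase, mesh)
            trajs, counts = link_trajectories(
                events, mesh, max_step_mm=config.ps_max_step_mm
            )
            criterion = MotherRotorCriterion.from_planar_wave(
                CV_TARGET_LONGITUDINAL * scale
            )
            mothers = sum(
                classify_mother_rotor(tr, criterion) for tr in trajs
            )
            report.df_peak_hz = float(dfmap.df_hz[peak])
            report.df_peak_node = int(peak)
            report.top_df_node_count = int(len(top))
            report.ps_event_count = int(sum(len(e) for e in events))
            report.ps_trajectory_count = int(len(trajs))
            report.mother_rotor_count = int(mothers)
            report.per_region = {
                "fibrosis_fraction": {
                    int(r): float(mesh.fibrosis[mesh.region == r].mean())
                    for r in np.unique(mesh.region[mesh.region > 0])
                },
                "ps_counts": counts,
            }

    if config.output_dir:
        with _stage("artifacts"):
            os.makedirs(config.output_dir, exist_ok=True)
            report.save(config.output_dir)
            save_mesh(mesh, os.path.join(config.output_dir, "model.vtk"))
            result.save(os.path.join(config.output_dir, "movie.h5"), mesh=mesh)
            with open(os.path.join(config.output_dir, "manifest.json"), "w") as fh:
                json.dump(
                    {"config": asdict(config), "report_digest": report.digest()},
                    fh, indent=2, default=str,
                )
    return report
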