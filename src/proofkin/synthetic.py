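"""Synthetic data generation with explicit ground truth.

Every input the analysis pipeline consumes can be generated here from known
parameters: single-cell measurement tables (occupancy, enforced binding
half-life, DAG level), in-vitro dissociation traces, stochastic binding-event
streams realizing the proofreading chain, and multi-channel image time courses
for the quantification pipeline.  A single root seed fully determines all
output; per-generator child streams are derived from fixed stream offsets so
the generators are independent of each other.

The generative model mirrors the experimental design: on each imaging day
several supported-lipid-bilayer datasets are prepared at different ligand
densities, and ~30 cells per dataset are each driven with one blue-light
intensity from a fixed program.  The light intensity sets the enforced binding
half-life through the photokinetic model; occupancy follows the binding
equilibrium ``kon*rho / (kon*rho + koff)``; DAG follows the saturable
proofreading response.  Cell-to-cell variability is multiplicative lognormal
on occupancy and DAG, measurement noise is additive Gaussian on DAG, and each
day carries its own arbitrary-unit scale on occupancy (emulating day-to-day
optical-path changes, which is why fits are grouped by day).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .photokinetics import LN2, PhotoKineticParams, default_photokinetics, predict_kobs
from .proofreading import dag_response

__all__ = [
    "SimulationConfig",
    "GillespieRates",
    "BindingEventRecord",
    "ImageTimecourse",
    "generate_cell_table",
    "generate_dissociation_trace",
    "simulate_binding_events",
    "generate_image_timecourse",
]

# fixed child-stream offsets: rng = default_rng([offset, seed])
_STREAM_CELL_TABLE = 1
_STREAM_TRACE = 2
_STREAM_EVENTS = 3
_STREAM_IMAGE = 4


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth for the synthetic study.

    Defaults describe one realistic study: 3 imaging days, 4 ligand densities
    per day spanning the sensitive range (~40-1200 molecules/um^2), 30 cells
    per dataset, and an 8-intensity blue-light program producing roughly
    log-spaced enforced half-lives between 10 s (dark) and ~0.56 s (16
    uW/cm^2).
    """

    seed: int = 0
    n_days: int = 3
    datasets_per_day: int = 4
    cells_per_dataset: int = 30
    lov2_densities: tuple[float, ...] = (40.0, 150.0, 450.0, 1200.0)
    light_intensities: tuple[float, ...] = (0.0, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 16.0)
    photokinetics: PhotoKineticParams = field(default_factory=default_photokinetics)
    kon_rho_scale: float = 2e-4  # s^-1 effective binding propensity per (molec/um^2)
    receptor_total: float = 150_000.0
    true_n: float = 2.7
    true_K: float = 1e6  # units of R * tau^n
    true_beta: float = 5.0
    true_A: float = 100.0
    cell_noise_cv: float = 0.25
    meas_noise_sd: float = 2.0  # 2% of true_A
    day_scale_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.datasets_per_day < 1 or self.cells_per_dataset < 1:
            raise ValueError("counts must be >= 1")
        if not self.lov2_densities or not self.light_intensities:
            raise ValueError("density and intensity lists must be non-empty")
        if any(d <= 0 for d in self.lov2_densities):
            raise ValueError("ligand densities must be positive")
        if any(i < 0 for i in self.light_intensities):
            raise ValueError("light intensities must be non-negative")
        for name in ("kon_rho_scale", "receptor_total", "true_K", "true_A"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("true_n", "true_beta", "cell_noise_cv", "meas_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.day_scale_range
        if not (0 < lo <= hi):
            raise ValueError("day_scale_range must be positive with low <= high")

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GillespieRates:
    """Rates of the binding / proofreading event simulation."""

    kon: float
    koff: float
    kp: float
    n_steps: int

    def __post_init__(self) -> None:
        if not (self.kon > 0 and self.koff > 0 and self.kp > 0):
            raise ValueError("kon, koff, kp must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")


@dataclass(frozen=True)
class BindingEventRecord:
    """One ligand binding event of the proofreading chain."""

    event_id: int
    bound_duration: float
    max_state_reached: int
    completed: bool


@dataclass
class ImageTimecourse:
    """Channel-aligned synthetic image stacks with their ground truth.

    ``channels`` maps 'RICM' / 'TIRF488' / 'TIRF561' to (T, H, W) stacks;
    ``dye_reference`` holds one flat-field reference frame per channel.
    ``ground_truth`` records the rendered occupancy and DAG values so the
    quantification pipeline can be validated against them.
    """

    channels: dict[str, np.ndarray]
    timestamps: np.ndarray
    camera_offset: float
    dye_reference: dict[str, np.ndarray]
    ground_truth: dict | None = None


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 lognormal multipliers with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def generate_cell_table(config: SimulationConfig) -> pd.DataFrame:
    """Generate a single-cell measurement table from the ground truth.

    Each row is one cell: identifiers, applied light intensity, enforced
    half-life, measured occupancy (a.u.) and measured DAG (a.u.).  The same
    config (including seed) always yields a byte-identical table.
    """
    rng = np.random.default_rng([_STREAM_CELL_TABLE, config.seed])

    # precompute half-lives of the light program, validating each intensity
    tau_by_intensity = {}
    for nu in config.light_intensities:
        kobs = predict_kobs(config.photokinetics, nu)
        tau = LN2 / kobs
        if not tau > 0:
            raise ValueError(f"light program yields non-positive half-life at intensity {nu}")
        tau_by_intensity[nu] = tau

    rows = []
    n_int = len(config.light_intensities)
    for day in range(config.n_days):
        lo, hi = config.day_scale_range
        day_scale = rng.uniform(lo, hi)
        for ds in range(config.datasets_per_day):
            rho = config.lov2_densities[ds % len(config.lov2_densities)]
            kon_rho = config.kon_rho_scale * rho
            n_cells = config.cells_per_dataset
            r_noise = _lognormal_factors(rng, config.cell_noise_cv, n_cells)
            d_noise = _lognormal_factors(rng, config.cell_noise_cv, n_cells)
            add_noise = (
                rng.normal(0.0, config.meas_noise_sd, n_cells)
                if config.meas_noise_sd > 0
                else np.zeros(n_cells)
            )
            for c in range(n_cells):
                nu = config.light_intensities[c % n_int]
                tau = tau_by_intensity[nu]
                koff = LN2 / tau
                fraction = kon_rho / (kon_rho + koff)
                occupancy = config.receptor_total * fraction * day_scale * r_noise[c]
                dag = dag_response(
                    occupancy, tau, config.true_n, config.true_K, config.true_beta, config.true_A
                )
                dag = dag * d_noise[c] + add_noise[c]
                rows.append(
                    {
                        "day_id": f"day{day:02d}",
                        "dataset_id": f"day{day:02d}_rho{rho:g}",
                        "cell_id": f"day{day:02d}_ds{ds}_c{c:03d}",
                        "light_intensity": nu,
                        "half_life_s": tau,
                        "occupancy_au": occupancy,
                        "dag_au": dag,
                        "adhesion_antibody": True,
                    }
                )
    return pd.DataFrame(rows)


def generate_dissociation_trace(
    params: PhotoKineticParams,
    intensity: float,
    duration: float = 30.0,
    dt: float = 0.2,
    noise_sd: float = 0.0,
    seed: int = 0,
    y0: float = 100.0,
    y_plateau: float = 0.0,
    pre_onset_time: float = 2.0,
):
    """Simulate an in-vitro ligand dissociation trace at one light intensity.

    The LED turns on at ``pre_onset_time``; before that the fluorescence sits
    at ``y0``, after it decays as ``y_plateau + (y0 - y_plateau) *
    exp(-k_obs * (t - t_onset))`` with ``k_obs`` from the photokinetic model.
    The default frame interval is 0.2 s.
    """
    from .photokinetics import DissociationTrace  # local to avoid cycle at import time

    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if dt >= duration:
        raise ValueError(f"dt ({dt}) must be smaller than duration ({duration})")
    kobs = predict_kobs(params, intensity)
    times = np.arange(0.0, duration + 0.5 * dt, dt)
    onset = int(np.searchsorted(times, pre_onset_time))
    onset = min(onset, times.size - 1)
    y = np.full(times.shape, float(y0))
    post = times >= times[onset]
    y[post] = y_plateau + (y0 - y_plateau) * np.exp(-kobs * (times[post] - times[onset]))
    if noise_sd > 0:
        rng = np.random.default_rng([_STREAM_TRACE, seed])
        y = y + rng.normal(0.0, noise_sd, y.shape)
    return DissociationTrace(
        times=times, fluorescence=y, illumination_onset_index=onset, intensity=float(intensity)
    )


def simulate_binding_events(
    rates: GillespieRates, n_events: int, seed: int = 0
) -> list[BindingEventRecord]:
    """Stochastically realize binding events of the proofreading chain.

    Each event starts at state 0 on ligand binding.  At each state the forward
    transition (rate ``kp``) races dissociation (rate ``koff``) via competing
    exponentials; the event completes if state ``n_steps`` is reached before
    unbinding.  The empirical completion frequency is an unbiased estimator of
    ``alpha**n`` with ``alpha = kp / (kp + koff)``.
    """
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    rng = np.random.default_rng([_STREAM_EVENTS, seed])
    n, kp, koff = rates.n_steps, rates.kp, rates.koff
    alpha = kp / (kp + koff)
    ktot = kp + koff

    if n == 0:
        completed = np.ones(n_events, dtype=bool)
        max_state = np.zeros(n_events, dtype=int)
        stages = np.zeros(n_events, dtype=int)
    else:
        forward = rng.random((n_events, n)) < alpha
        completed = forward.all(axis=1)
        # index of the first failed transition = state at which the ligand fell off
        first_fail = np.argmin(forward, axis=1)
        max_state = np.where(completed, n, first_fail)
        # stages spent racing: one Exp(kp+koff) wait per transition attempted
        stages = np.where(completed, n, first_fail + 1)

    durations = np.zeros(n_events)
    has_stages = stages > 0
    if has_stages.any():
        durations[has_stages] = rng.gamma(shape=stages[has_stages], scale=1.0 / ktot)
    # a completed receptor stays bound until plain dissociation
    if completed.any():
        durations[completed] += rng.exponential(1.0 / koff, int(completed.sum()))
    durations = np.maximum(durations, np.finfo(float).tiny)

    return [
        BindingEventRecord(
            event_id=i,
            bound_duration=float(durations[i]),
            max_state_reached=int(max_state[i]),
            completed=bool(completed[i]),
        )
        for i in range(n_events)
    ]


def events_to_frame(events: list[BindingEventRecord]) -> pd.DataFrame:
    """Tabulate binding-event records (e.g. for CSV export)."""
    return pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "bound_duration": [e.bound_duration for e in events],
            "max_state_reached": [e.max_state_reached for e in events],
            "completed": [e.completed for e in events],
        }
    )


def generate_image_timecourse(
    config: SimulationConfig,
    frame_shape: tuple[int, int] = (64, 64),
    seed: int = 0,
    n_frames: int = 6,
    disk_radius: int = 15,
    enrichment: float = 8.0,
    dag_level: float = 10.0,
    pp2_level: float = 30.0,
    ligand_background: float = 100.0,
    laser_series: np.ndarray | None = None,
    vignette_strength: float = 0.3,
    poisson_noise: bool = False,
    frame_interval_s: float = 10.0,
) -> ImageTimecourse:
    """Render a synthetic three-channel image time course of one cell.

    RICM shows a dark disk (the cell footprint) on a bright background;
    TIRF488 shows the free-ligand background plus ``enrichment`` (the
    ground-truth occupancy, a.u.) inside the footprint, modulated per frame by
    ``laser_series``; TIRF561 shows ``pp2_level + dag_level`` inside the
    footprint.  All channels share a radial flat-field vignette and a constant
    camera offset, both provided as dye-reference frames so the quantification
    pipeline can undo them.
    """
    h, w = frame_shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    if disk_radius >= min(cy, cx):
        raise ValueError(
            f"disk radius {disk_radius} does not fit in frame {frame_shape} with a ribbon margin"
        )
    if laser_series is None:
        laser_series = np.ones(n_frames)
    laser_series = np.asarray(laser_series, dtype=float)
    if laser_series.size != n_frames:
        raise ValueError("laser_series length must equal n_frames")

    yy, xx = np.mgrid[0:h, 0:w]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    inside = r2 <= disk_radius**2
    rmax2 = cy**2 + cx**2
    vignette = 1.0 - vignette_strength * (r2 / rmax2)
    offset = 100.0

    ricm_ideal = np.where(inside, 800.0, 2000.0)
    t488_ideal = ligand_background + np.where(inside, enrichment, 0.0)
    t561_ideal = np.where(inside, pp2_level + dag_level, 20.0)

    def render(ideal: np.ndarray, gain: float = 1.0) -> np.ndarray:
        return gain * ideal * vignette + offset

    rng = np.random.default_rng([_STREAM_IMAGE, seed])
    stacks = {"RICM": [], "TIRF488": [], "TIRF561": []}
    for i in range(n_frames):
        stacks["RICM"].append(render(ricm_ideal))
        stacks["TIRF488"].append(render(t488_ideal, gain=laser_series[i]))
        stacks["TIRF561"].append(render(t561_ideal))
    channels = {k: np.stack(v) for k, v in stacks.items()}
    if poisson_noise:
        for k in channels:
            channels[k] = rng.poisson(np.maximum(channels[k], 0.0)).astype(float)

    # unit-mean dye signal: flat-field correction then restores the ideal scale
    dye = {k: vignette + offset for k in channels}
    gt = {
        "occupancy": enrichment * float(np.mean(laser_series)),
        "enrichment": enrichment,
        "dag": dag_level,
        "pp2_baseline": pp2_level,
        "laser_series": laser_series.tolist(),
        "disk_radius": disk_radius,
        "mask_area": float(inside.sum()),
    }
    return ImageTimecourse(
        channels=channels,
        timestamps=np.arange(n_frames, dtype=float) * frame_interval_s,
        camera_offset=offset,
        dye_reference=dye,
        ground_truth=gt,
    )
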