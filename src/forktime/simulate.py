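"""Ground-truthed synthetic data for every stage of the pipeline.

The live-cell assay watches two operator-array foci per cell whose
integrated intensity doubles when the array is replicated.  No raw movies
are deposited with such experiments, so this module generates inputs with
the statistical structure the analysis assumes, together with their ground
truth:

* per-cell replication kinetics — cell-to-cell fork-speed variability
  (log-normal), origin firing-time spread, and an optional G4 obstacle that
  pauses the fork in the *folded* subpopulation of cells only (two-state
  obstacle: a cell whose G4 happens to be unfolded replicates at wild-type
  speed);
* per-cell two-channel intensity traces — step-doubling logistic rise with
  finite rise time, mono-exponential photobleaching, Gaussian noise;
* full 3D two-channel movies — Gaussian PSF spots on a uniform background
  with Poisson shot noise, Gaussian read noise and slow cell drift;
* two-state G4 melting curves and primer-extension gel lane time courses.

Default acquisition follows the study conditions: 1-min frame interval,
two channels, 12 z-sections 0.7 µm apart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import erf, expit

from .biochem import GelLaneProfile, MeltingCurve, theta_two_state
from .foci import CHANNELS, CellTrace
from .geometry import LocusLayout, nominal_layout

__all__ = [
    "ScenarioConfig",
    "CellGroundTruth",
    "AcquisitionConfig",
    "MovieStack",
    "sample_cell_kinetics",
    "expected_delta_t",
    "render_trace",
    "render_movie",
    "simulate_melting_curve",
    "simulate_gel_timecourse",
    "GelGeometry",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """One strain/condition of the replication assay.

    ``fork_speed_mean``/``fork_speed_cv`` parameterize a log-normal fork
    speed per cell (kb/min; 1.5 kb/min is a typical budding-yeast fork).
    A cell carries a folded obstacle with probability ``folded_fraction``;
    folded cells incur a pause drawn from Exponential(``pause_mean``)
    minutes (or exactly ``pause_mean`` with ``pause_model="fixed"``).
    Origin firing times are Normal(``firing_time_mean``,
    ``firing_time_sd``), truncated at zero.
    """

    label: str = "wt"
    fork_speed_mean: float = 1.5
    fork_speed_cv: float = 0.2
    pause_mean: float = 0.0
    folded_fraction: float = 0.0
    n_cells: int = 25
    seed: int | None = None
    firing_time_mean: float = 20.0
    firing_time_sd: float = 5.0
    pause_model: str = "exponential"

    def __post_init__(self) -> None:
        if self.fork_speed_mean <= 0:
            raise ValueError("fork_speed_mean must be > 0")
        if self.fork_speed_cv < 0:
            raise ValueError("fork_speed_cv must be >= 0")
        if self.pause_mean < 0:
            raise ValueError("pause_mean must be >= 0")
        if not 0.0 <= self.folded_fraction <= 1.0:
            raise ValueError("folded_fraction must be in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.pause_model not in ("exponential", "fixed"):
            raise ValueError("pause_model must be 'exponential' or 'fixed'")


@dataclass
class CellGroundTruth:
    """True replication times of the two arrays in one cell (minutes)."""

    cell_id: str
    t_rep_array1: float
    t_rep_array2: float
    delta_t_true: float
    paused: bool
    fork_speed: float
    pause: float = 0.0


def _lognormal_speeds(rng, mean: float, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def sample_cell_kinetics(
    layout: LocusLayout,
    scenario: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> list[CellGroundTruth]:
    """Draw per-cell ground-truth replication kinetics for a scenario.

    Per cell: fork speed v ~ log-normal(mean, CV); array 1 replicates at
    firing time + (origin-to-array-1 distance)/v; the inter-array transit is
    mid_to_mid/v plus, in folded cells (probability ``folded_fraction``,
    only when the layout has an obstacle), a pause.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    n = scenario.n_cells
    v = _lognormal_speeds(rng, scenario.fork_speed_mean, scenario.fork_speed_cv, n)
    firing = np.maximum(rng.normal(scenario.firing_time_mean, scenario.firing_time_sd, n), 0.0)
    has_obstacle = layout.obstacle_pos is not None
    folded = (rng.random(n) < scenario.folded_fraction) & has_obstacle
    if scenario.pause_model == "fixed":
        pauses = np.where(folded, scenario.pause_mean, 0.0)
    else:
        draws = rng.exponential(scenario.pause_mean, n) if scenario.pause_mean > 0 else np.zeros(n)
        pauses = np.where(folded, draws, 0.0)
    d0 = max(layout.origin_to_array1_mid_kb, 0.0)
    mid = layout.mid_to_mid_kb
    out = []
    for i in range(n):
        t1 = firing[i] + d0 / v[i]
        dt = mid / v[i] + pauses[i]
        out.append(
            CellGroundTruth(
                cell_id=f"cell_{i:03d}",
                t_rep_array1=float(t1),
                t_rep_array2=float(t1 + dt),
                delta_t_true=float(dt),
                paused=bool(folded[i]),
                fork_speed=float(v[i]),
                pause=float(pauses[i]),
            )
        )
    return out


def expected_delta_t(layout: LocusLayout, scenario: ScenarioConfig) -> float:
    """Closed-form E[delta_t] for a scenario.

    For v log-normal with mean m and coefficient of variation c,
    E[1/v] = (1 + c^2)/m, so
    E[delta_t] = mid_to_mid * (1 + c^2)/m + folded_fraction * pause_mean.
    (The pause term holds for both pause models.)
    """
    m, c = scenario.fork_speed_mean, scenario.fork_speed_cv
    base = layout.mid_to_mid_kb * (1.0 + c * c) / m
    pause = scenario.folded_fraction * scenario.pause_mean
    if layout.obstacle_pos is None:
        pause = 0.0
    return base + pause


# ---------------------------------------------------------------------------
# acquisition / traces


@dataclass(frozen=True)
class AcquisitionConfig:
    """Imaging parameters.  Defaults follow the study's acquisition:
    1-min intervals, 12 z-sections 0.7 µm apart; the remaining optical
    parameters are typical for a spinning-disk confocal with a 63x/1.4
    objective and an EM-CCD."""

    n_frames: int = 180
    frame_interval: float = 1.0  # min
    n_z: int = 12
    z_step: float = 0.7  # µm
    ny: int = 128
    nx: int = 128
    pixel_size: float = 0.15  # µm
    psf_sigma_xy: float = 0.15  # µm
    psf_sigma_z: float = 0.35  # µm
    background_level: float = 100.0  # photons / voxel
    read_noise_sd: float = 5.0  # photons
    bleach_rate: float = 0.002  # 1/min
    spot_amplitude: float = 2000.0  # integrated photons pre-replication
    rise_time: float = 6.7  # min for the doubling step (~array_len / fork speed)
    drift_sigma: float = 0.01  # µm random-walk step per frame per axis

    def __post_init__(self) -> None:
        for name in ("n_frames", "n_z", "ny", "nx"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frame_interval", "z_step", "pixel_size", "psf_sigma_xy", "psf_sigma_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if min(self.background_level, self.read_noise_sd, self.bleach_rate,
               self.spot_amplitude, self.rise_time, self.drift_sigma) < 0:
            raise ValueError("noise/amplitude parameters must be >= 0")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def _step_intensity(t, t_rep, baseline, bleach_rate, rise_time):
    """Bleach-modulated doubling step: exp(-kt) [B + B logistic((t-t_rep)/tau)].

    tau = rise_time/4 so the logistic covers ~90% of its rise within
    rise_time around the midpoint.
    """
    tau = max(rise_time / 4.0, 1e-9)
    step = baseline + baseline * expit((t - t_rep) / tau)
    return np.exp(-bleach_rate * t) * step


def render_trace(
    gt: CellGroundTruth,
    acq: AcquisitionConfig,
    *,
    rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
    baselines: tuple[float, float] | None = None,
) -> CellTrace:
    """Render the two-channel integrated-intensity trace of one cell.

    Channel intensities follow the doubling-step model — per channel c,
    I_c(t) = exp(-bleach_rate t) [B_c + A_c logistic((t - t_rep_c)/tau)]
    with A_c = B_c (replication doubles the operator copy number) and
    tau = rise_time/4 — plus i.i.d. Gaussian noise of sd ``noise_sd``
    (default: ``acq.read_noise_sd``).  Green reports array 1, red array 2.
    """
    if noise_sd is None:
        noise_sd = acq.read_noise_sd
    if baselines is None:
        baselines = (acq.spot_amplitude, acq.spot_amplitude)
    t = acq.times
    t_reps = (gt.t_rep_array1, gt.t_rep_array2)
    chans = []
    for b, t_rep in zip(baselines, t_reps):
        y = _step_intensity(t, t_rep, b, acq.bleach_rate, acq.rise_time)
        if noise_sd > 0:
            if rng is None:
                rng = np.random.default_rng()
            y = y + rng.normal(0.0, noise_sd, size=t.shape)
        chans.append(y)
    return CellTrace(
        cell_id=gt.cell_id,
        times=t,
        intensity_green=chans[0],
        intensity_red=chans[1],
        provenance="simulated",
    )


# ---------------------------------------------------------------------------
# movies


@dataclass
class MovieStack:
    """A simulated movie with axes (t, channel, z, y, x) plus its metadata."""

    data: np.ndarray
    config: AcquisitionConfig

    def __post_init__(self) -> None:
        c = self.config
        expect = (c.n_frames, len(CHANNELS), c.n_z, c.ny, c.nx)
        if self.data.shape != expect:
            raise ValueError(f"movie shape {self.data.shape} != metadata {expect}")
        if self.data.min() < 0:
            raise ValueError("intensities must be >= 0")


def _axis_weights(n: int, center: float, sigma: float, halfwidth: int):
    """Gaussian mass per voxel along one axis (CDF differences -> the sum
    over all voxels equals 1 up to tail truncation, independent of sigma)."""
    lo = max(0, int(math.floor(center)) - halfwidth)
    hi = min(n, int(math.ceil(center)) + halfwidth + 1)
    if hi <= lo:
        return lo, hi, np.zeros(0)
    edges = np.arange(lo, hi + 1) - 0.5
    cdf = 0.5 * (1.0 + erf((edges - center) / (math.sqrt(2.0) * sigma)))
    return lo, hi, np.diff(cdf)


def _add_spot(frame: np.ndarray, center, sigmas, amplitude: float) -> None:
    hw = [int(math.ceil(4 * s)) + 1 for s in sigmas]
    ws = []
    los = []
    for ax in range(3):
        lo, hi, w = _axis_weights(frame.shape[ax], center[ax], sigmas[ax], hw[ax])
        if w.size == 0:
            return
        ws.append(w)
        los.append(lo)
    kernel = amplitude * ws[0][:, None, None] * ws[1][None, :, None] * ws[2][None, None, :]
    frame[
        los[0] : los[0] + ws[0].size,
        los[1] : los[1] + ws[1].size,
        los[2] : los[2] + ws[2].size,
    ] += kernel


def _default_positions(n_cells: int, acq: AcquisitionConfig, rng) -> np.ndarray:
    """Jittered grid of cell positions (y, x in pixels) with edge margins."""
    margin = 12
    side = max(1, math.ceil(math.sqrt(n_cells)))
    ys = np.linspace(margin, acq.ny - margin, side)
    xs = np.linspace(margin, acq.nx - margin, side)
    grid = np.array([(y, x) for y in ys for x in xs])[:n_cells]
    return grid + rng.uniform(-2, 2, size=grid.shape)


def render_movie(
    gts: list[CellGroundTruth],
    layout: LocusLayout,
    acq: AcquisitionConfig,
    *,
    rng: np.random.Generator | None = None,
    positions: np.ndarray | None = None,
    noise: bool = True,
) -> tuple[MovieStack, pd.DataFrame]:
    """Render a two-channel 3D movie of focus spots plus the ground-truth table.

    Each cell contributes one spot per channel: a 3D Gaussian with the PSF
    sigmas whose *integrated* amplitude follows the doubling-step time
    course of :func:`render_trace` (green = array 1, red = array 2).  The
    red spot sits ~0.5 µm from the green one (the two loci are 20–30 kb
    apart on the same chromosome); both drift together as a small random
    walk.  The field has a uniform background; with ``noise=True`` each
    voxel gets Poisson shot noise plus Gaussian read noise (clipped at 0).

    Returns the movie (float32, axes t, channel, z, y, x) and a tidy table
    of true spot positions and expected amplitudes per frame.
    """
    if rng is None:
        rng = np.random.default_rng()
    n_cells = len(gts)
    if positions is None:
        positions = _default_positions(n_cells, acq, rng)
    positions = np.asarray(positions, dtype=float)
    if positions.shape != (n_cells, 2):
        raise ValueError("positions must be (n_cells, 2) [y, x] pixels")
    pad = 6
    if n_cells and (
        positions.min() < pad
        or positions[:, 0].max() > acq.ny - pad
        or positions[:, 1].max() > acq.nx - pad
    ):
        raise ValueError("spot positions outside the usable field")

    sig_vox = (acq.psf_sigma_z / acq.z_step,
               acq.psf_sigma_xy / acq.pixel_size,
               acq.psf_sigma_xy / acq.pixel_size)
    zc = (acq.n_z - 1) / 2.0
    # per-cell channel offset: red locus ~0.5 µm away in a random direction
    sep_px = 0.5 / acq.pixel_size
    angles = rng.uniform(0, 2 * np.pi, n_cells)
    offsets = np.stack([sep_px * np.sin(angles), sep_px * np.cos(angles)], axis=1)
    z0 = zc + rng.uniform(-1.0, 1.0, n_cells)
    # shared drift random walk per cell (µm -> pixels/z-steps per axis)
    steps = rng.normal(0.0, acq.drift_sigma, size=(acq.n_frames, n_cells, 3))
    drift = np.cumsum(steps, axis=0)
    drift[..., 0] /= acq.z_step
    drift[..., 1] /= acq.pixel_size
    drift[..., 2] /= acq.pixel_size

    t = acq.times
    amp = np.empty((n_cells, 2, acq.n_frames))
    for i, gt in enumerate(gts):
        amp[i, 0] = _step_intensity(t, gt.t_rep_array1, acq.spot_amplitude,
                                    acq.bleach_rate, acq.rise_time)
        amp[i, 1] = _step_intensity(t, gt.t_rep_array2, acq.spot_amplitude,
                                    acq.bleach_rate, acq.rise_time)

    data = np.empty((acq.n_frames, 2, acq.n_z, acq.ny, acq.nx), dtype=np.float32)
    records = []
    for f in range(acq.n_frames):
        for c, chan in enumerate(CHANNELS):
            frame = np.full((acq.n_z, acq.ny, acq.nx), acq.background_level, dtype=np.float64)
            for i, gt in enumerate(gts):
                cy = positions[i, 0] + (offsets[i, 0] if c == 1 else 0.0) + drift[f, i, 1]
                cx = positions[i, 1] + (offsets[i, 1] if c == 1 else 0.0) + drift[f, i, 2]
                czv = z0[i] + drift[f, i, 0]
                _add_spot(frame, (czv, cy, cx), sig_vox, amp[i, c, f])
                records.append(
                    (gt.cell_id, f, chan, czv, cy, cx, amp[i, c, f])
                )
            if noise:
                frame = rng.poisson(frame).astype(np.float64)
                if acq.read_noise_sd > 0:
                    frame += rng.normal(0.0, acq.read_noise_sd, size=frame.shape)
                np.clip(frame, 0, None, out=frame)
            data[f, c] = frame.astype(np.float32)
    truth = pd.DataFrame.from_records(
        records, columns=["cell_id", "frame", "channel", "z", "y", "x", "amplitude"]
    )
    return MovieStack(data=data, config=acq), truth


# ---------------------------------------------------------------------------
# melting curves and gels


def default_melt_temps(start: float = 15.0, stop: float = 95.0, step: float = 2.0) -> np.ndarray:
    """Default melting-temperature grid: 2 degC increments from 15 degC."""
    return np.arange(start, stop + step / 2, step)


def simulate_melting_curve(
    tm_c: float,
    dh_kcal: float,
    temps_c: np.ndarray | None = None,
    *,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    label: str = "",
) -> MeltingCurve:
    """Two-state melting curve: y(T) = theta(T) + Gaussian noise.

    ``dh_kcal`` is the unfolding enthalpy (> 0 by convention, giving a
    signal that decreases with temperature and crosses 0.5 at Tm).
    """
    if dh_kcal <= 0:
        raise ValueError("dh_kcal must be > 0 (unfolding enthalpy convention)")
    if temps_c is None:
        temps_c = default_melt_temps()
    temps_c = np.asarray(temps_c, dtype=float)
    if np.any(np.diff(temps_c) <= 0):
        raise ValueError("temps must be strictly increasing")
    y = theta_two_state(temps_c, tm_c, dh_kcal)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return MeltingCurve(temps=temps_c, signal=y, label=label)


@dataclass(frozen=True)
class GelGeometry:
    """Band layout of a simulated denaturing-gel lane (positions in mm)."""

    n_points: int = 400
    length: float = 100.0
    full_length_center: float = 20.0
    stall_center: float = 50.0
    primer_center: float = 80.0
    band_sigma: float = 2.0
    window_halfwidth: float = 8.0
    total_area: float = 1000.0
    primer_fraction: float = 0.1  # unextended primer share of lane signal
    baseline: float = 2.0

    def windows(self) -> dict[str, tuple[float, float]]:
        w = self.window_halfwidth
        return {
            "full_length": (self.full_length_center - w, self.full_length_center + w),
            "stall": (self.stall_center - w, self.stall_center + w),
            "primer": (self.primer_center - w, self.primer_center + w),
        }


def simulate_gel_timecourse(
    k_synth: float,
    times: np.ndarray,
    geometry: GelGeometry | None = None,
    *,
    f_max: float = 1.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[GelLaneProfile], pd.DataFrame]:
    """Simulate lanes of a primer-extension time course.

    Full-length fraction f(t) = f_max (1 - exp(-k_synth t)); the extended
    signal splits between a stall band (1 - f) and a full-length band (f),
    with a constant unextended-primer band, a flat baseline and optional
    Gaussian noise.  Returns the lanes and a ground-truth table of f(t).
    """
    if k_synth < 0:
        raise ValueError("k_synth must be >= 0")
    if geometry is None:
        geometry = GelGeometry()
    times = np.asarray(times, dtype=float)
    x = np.linspace(0.0, geometry.length, geometry.n_points)
    wins = geometry.windows()
    ext_area = geometry.total_area * (1.0 - geometry.primer_fraction)
    primer_area = geometry.total_area * geometry.primer_fraction

    def gauss(center, area):
        return area * np.exp(-0.5 * ((x - center) / geometry.band_sigma) ** 2) / (
            geometry.band_sigma * math.sqrt(2 * math.pi)
        )

    lanes, rows = [], []
    for t in times:
        f = f_max * (1.0 - math.exp(-k_synth * t)) if k_synth > 0 else 0.0
        y = (
            geometry.baseline
            + gauss(geometry.full_length_center, ext_area * f)
            + gauss(geometry.stall_center, ext_area * (1.0 - f))
            + gauss(geometry.primer_center, primer_area)
        )
        if noise_sd > 0:
            if rng is None:
                rng = np.random.default_rng()
            y = y + rng.normal(0.0, noise_sd, size=y.shape)
        lanes.append(
            GelLaneProfile(positions=x, intensity=y, band_windows=dict(wins),
                           label=f"t={t:g}min")
        )
        rows.append((float(t), f))
    truth = pd.DataFrame(rows, columns=["time_min", "full_length_fraction"])
    return lanes, truth


# ---------------------------------------------------------------------------
# study-condition scenario catalog


def scenario_catalog(seed: int | None = None) -> dict[str, tuple[LocusLayout, ScenarioConfig]]:
    """Emulations of the imaged strains (cohort sizes as reported).

    Pauses are set so the expected fold-slowdowns match the reported
    contrasts: no slowdown for WT strains and the mutated-G4 control,
    ~1.5-fold for the single strong G4 without the helicase, ~2-fold for
    the tandem G4s without the helicase.  Folded fractions below 1 encode
    the two-state obstacle (unfolded cells replicate at WT speed).
    """
    wt_layout = nominal_layout()
    g4 = nominal_layout(obstacle=True)
    base = ScenarioConfig(seed=seed)
    base_dt = expected_delta_t(wt_layout, base)

    def paused(label, ratio, folded, n):
        pause = (ratio - 1.0) * base_dt / folded
        return (
            g4,
            replace(base, label=label, pause_mean=pause, folded_fraction=folded, n_cells=n),
        )

    return {
        "wt_no_insert": (wt_layout, replace(base, label="wt_no_insert", n_cells=45)),
        "wt_g4AB": (g4, replace(base, label="wt_g4AB", n_cells=22)),
        "pif1d_g4A": paused("pif1d_g4A", 1.1, 0.6, 31),
        "pif1d_g4B": paused("pif1d_g4B", 1.5, 0.7, 25),
        "pif1d_g4AB": paused("pif1d_g4AB", 2.0, 0.8, 26),
        "pif1d_mutG4AB": (g4, replace(base, label="pif1d_mutG4AB", n_cells=25)),
    }
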