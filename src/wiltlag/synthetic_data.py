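"""Synthetic greenhouse plant-day generator with a known water-transport delay.

Everything downstream of the sensors is testable against this module: it
produces minute-resolution environment traces (PPFD, temperature, RH, VPD),
a closed-loop stem-diameter trace whose irrigation is issued by the RSR
threshold controller, a latent leaf-water signal that is a pure-delay,
first-order-smoothed copy of stem water status, and either rendered 144x144
plant image sequences or precomputed optical-flow fields.

The water-transport model is a discrete-time reservoir chain::

    soil --uptake--> stem water W --delay D, low-pass tau--> leaf water L

Transpiration E(t) drains stem water in proportion to normalised light and to
VPD clipped at a plateau (stomatal closure at high VPD).  Uptake refills the
stem from the soil reservoir in proportion to the current deficit; irrigation
events (issued when the relative stem ratio falls below ``t_rsr``) top up the
soil.  Stem diameter is baseline + slow growth + ``shrink_gain`` x water
status + sensor noise, and leaf-tip wilt displacement (in pixels) is a
monotone non-increasing function of leaf water.  The injected transport delay
``transport_delay_D`` is the ground truth the lag analysis must recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import time

import numpy as np
import pandas as pd

from .stem_processing import CONTROL_CUTOFF, RsrControllerState, detect_sunrise
from .wilt_quantification import FlowField, FlowSequence, ImageSequence

__all__ = [
    "ScenarioConfig",
    "vpd_from_t_rh",
    "generate_environment",
    "simulate_plant",
    "generate_dataset",
    "render_frames",
    "synth_flow_fields",
    "leaf_tip_positions",
    "write_dataset",
]

MINUTES_PER_DAY = 1440

# --- internal plant-physiology constants (per-minute discrete dynamics) ----
TRANSPIRATION_GAIN = 0.01   # water units lost per minute at full light, VPD >= plateau
UPTAKE_RATE = 0.5           # fraction of the current deficit replenished per minute
INITIAL_SOIL = 0.1          # pre-dawn soil reserve (reservoir units)

# --- renderer geometry (144 x 144 scene) -----------------------------------
FRAME_SIZE = 144
SUPERSAMPLE = 2
SOIL_TOP_ROW = 96
STEM_COL = 71
STEM_WIDTH = 3
STEM_TOP, STEM_BOTTOM = 44, 128
LEAF_LENGTH = 30.0
LEAF_HALF_WIDTH = 5.0
LEAF_BASE_DROOP = 6.0
#: (anchor_row, side) pairs; side -1 = leaf extends left, +1 = right
LEAF_ANCHORS = ((52, -1), (62, +1), (74, -1), (86, +1))

SKY_RGB = (170, 170, 180)    # ExG numerator 2G-R-B = -10  (never plant)
SOIL_RGB = (110, 75, 40)     # ExG numerator 0
CLOUD_RGB = (225, 225, 225)  # achromatic: ExG numerator 0
PLANT_RGB = (40, 160, 40)    # ExG numerator +240


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic experiment.

    Defaults emulate a spring greenhouse tomato under deficit irrigation:
    2-minute stem-to-leaf water-transport delay, fast leaf equilibration,
    RSR threshold 0.9975, scattered-light PPFD peaking at 80 umol s^-1 m^-2.
    """

    seed: int = 0
    n_days: int = 1
    weather: str = "sunny"            # sunny | cloudy | mixed
    ppfd_amplitude: float = 80.0      # umol s^-1 m^-2 clear-sky peak (scattered)
    cloud_strength: float = 0.6       # dimensionless in [0, 1]
    transport_delay_D: int = 2        # minutes, stem -> leaf
    leaf_time_constant_tau: float = 1.0  # minutes, first-order leaf smoothing
    coupling_gamma: float = 1.0       # stem -> leaf wilt gain (dimensionless)
    stem_baseline: float = 10.0       # mm
    growth_rate: float = 0.05         # mm / day
    shrink_gain: float = 0.5          # mm per unit water deficit
    irrigation_volume: float = 0.05   # soil-reservoir units per event
    t_rsr: float = 0.9975             # RSR irrigation threshold
    sensor_noise_sd: float = 2.0      # per-channel image noise SD (0-255 scale)
    stem_noise_sd: float = 0.001      # mm
    flow_noise_sd: float = 0.2        # px, iid noise on synthetic flow fields
    vpd_plateau: float = 4.0          # kPa, transpiration saturates above this
    wilt_gain: float = 40.0           # px of leaf-tip droop per unit leaf deficit
    day_start: time = time(6, 0)      # sunrise edge of the solar arc
    day_end: time = time(18, 30)      # sunset edge
    image_start: time = time(9, 0)    # camera window (inclusive)
    image_end: time = time(17, 0)
    start_date: str = "2018-04-06"

    def __post_init__(self):
        if self.transport_delay_D < 0:
            raise ValueError("transport_delay_D must be >= 0")
        if self.leaf_time_constant_tau <= 0:
            raise ValueError("leaf_time_constant_tau must be > 0")
        if self.ppfd_amplitude < 0:
            raise ValueError("ppfd_amplitude must be >= 0")
        if not (0 < self.t_rsr <= 1):
            raise ValueError("t_rsr must be in (0, 1]")
        if not (0 <= self.cloud_strength <= 1):
            raise ValueError("cloud_strength must be in [0, 1]")
        if self.coupling_gamma < 0:
            raise ValueError("coupling_gamma must be >= 0")
        if self.weather not in ("sunny", "cloudy", "mixed"):
            raise ValueError("weather must be sunny, cloudy or mixed")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")


def _rng(config: ScenarioConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams per component
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def vpd_from_t_rh(temperature, rh):
    """Vapor-pressure deficit (kPa) from temperature (degC) and RH (%).

    Tetens saturation vapor pressure: es = 0.6108 exp(17.27 T / (T + 237.3));
    vpd = es (1 - rh/100).
    """
    t_arr = np.asarray(temperature, dtype=float)
    rh_arr = np.asarray(rh, dtype=float)
    if np.any((rh_arr < 0) | (rh_arr > 100)):
        raise ValueError("rh must be within [0, 100] %")
    if np.any((t_arr < -20) | (t_arr > 60)):
        raise ValueError("temperature must be within [-20, 60] degC")
    es = 0.6108 * np.exp(17.27 * t_arr / (t_arr + 237.3))
    vpd = es * (1.0 - rh_arr / 100.0)
    if np.isscalar(temperature) and np.isscalar(rh):
        return float(vpd)
    return vpd


def _minutes_of_day(index: pd.DatetimeIndex) -> np.ndarray:
    return index.hour.values * 60 + index.minute.values


def _time_minutes(t: time) -> int:
    return t.hour * 60 + t.minute


def _day_strengths(config: ScenarioConfig) -> np.ndarray:
    """Per-day cloud attenuation strength according to the weather regime."""
    if config.weather == "sunny":
        return np.zeros(config.n_days)
    if config.weather == "cloudy":
        return np.full(config.n_days, config.cloud_strength)
    rng = _rng(config, 1)
    return rng.uniform(0.0, config.cloud_strength, size=config.n_days)


def generate_environment(config: ScenarioConfig) -> pd.DataFrame:
    """Minute-grid environment series over ``n_days``.

    PPFD follows a clear-sky half-sine arc between ``day_start`` and
    ``day_end`` attenuated by a clipped AR(1) cloud process; temperature is a
    diurnal sinusoid (peak 14:00) with amplitude damped on cloudy days; RH is
    anti-phased; VPD follows from the Tetens relation.  Identical configs give
    bit-identical output.
    """
    index = pd.date_range(
        config.start_date, periods=config.n_days * MINUTES_PER_DAY, freq="min"
    )
    mod = _minutes_of_day(index).astype(float)
    t_sr, t_ss = float(_time_minutes(config.day_start)), float(_time_minutes(config.day_end))
    solar = np.maximum(0.0, np.sin(np.pi * (mod - t_sr) / (t_ss - t_sr)))
    solar[(mod < t_sr) | (mod > t_ss)] = 0.0

    rng = _rng(config, 2)
    strengths = np.repeat(_day_strengths(config), MINUTES_PER_DAY)
    rho = 0.98
    z = np.empty(len(index))
    z[0] = rng.standard_normal()
    eps = rng.standard_normal(len(index) - 1) * math.sqrt(1 - rho**2)
    for i in range(1, len(index)):
        z[i] = rho * z[i - 1] + eps[i - 1]
    cloud = np.clip(1.0 - strengths * (0.55 + 0.3 * z), 0.05, 1.0)

    ppfd = config.ppfd_amplitude * solar * cloud

    day_mean_attn = cloud.reshape(config.n_days, MINUTES_PER_DAY).mean(axis=1)
    damp = np.repeat(0.4 + 0.6 * day_mean_attn, MINUTES_PER_DAY)
    phase = np.sin(2 * np.pi * (mod / 60.0 - 8.0) / 24.0)
    temperature = 19.0 + 7.0 * damp * phase
    rh = np.clip(75.0 - 20.0 * damp * phase, 5.0, 100.0)
    vpd = vpd_from_t_rh(temperature, rh)

    env = pd.DataFrame(
        {"ppfd": ppfd, "temperature": temperature, "rh": rh, "vpd": vpd}, index=index
    )
    env.index.name = "timestamp"
    return env


def _check_minute_grid(index: pd.DatetimeIndex) -> None:
    if len(index) < 2:
        raise ValueError("environment series too short")
    steps = np.diff(index.values).astype("timedelta64[s]").astype(int)
    if np.any(steps != 60):
        raise ValueError("environment grid has gaps; a full minute grid is required")


def simulate_plant(config: ScenarioConfig, env: pd.DataFrame):
    """Closed-loop plant simulation on the environment's minute grid.

    Returns ``(stem, truth, irrigation)`` where ``stem`` is the noisy diameter
    series (mm), ``truth`` a DataFrame with columns ``stem_water, leaf_water,
    soil_reservoir, wilt_displacement`` plus ``attrs['true_delay']``, and
    ``irrigation`` the controller-issued event log (timestamp, volume_ml,
    pre_rsr).
    """
    _check_minute_grid(env.index)
    index = env.index
    n = len(index)
    ppfd = env["ppfd"].to_numpy()
    vpd = env["vpd"].to_numpy()
    ppfd_norm = ppfd / config.ppfd_amplitude if config.ppfd_amplitude > 0 else np.zeros(n)
    e_rate = TRANSPIRATION_GAIN * ppfd_norm * np.minimum(vpd, config.vpd_plateau) / config.vpd_plateau

    sunrise_by_date = {
        date: detect_sunrise(day["ppfd"]) for date, day in env.groupby(env.index.date)
    }

    noise = _rng(config, 3).standard_normal(n) * config.stem_noise_sd
    alpha = 1.0 / max(config.leaf_time_constant_tau, 1.0)
    delay = int(config.transport_delay_D)

    controller = RsrControllerState(t_rsr=config.t_rsr)
    w_hist = np.empty(n)
    leaf = np.empty(n)
    soil = np.empty(n)
    stem = np.empty(n)
    events = []

    w_cur, s_cur, l_prev = 0.0, INITIAL_SOIL, 0.0
    minutes_of_day = _minutes_of_day(index)
    cutoff_min = _time_minutes(CONTROL_CUTOFF)
    for i, ts in enumerate(index):
        uptake = min(s_cur, UPTAKE_RATE * max(0.0, -w_cur))
        s_cur -= uptake
        w_cur += uptake - e_rate[i]
        w_hist[i] = w_cur

        w_delayed = w_hist[max(0, i - delay)] if i >= delay else w_hist[0]
        l_cur = (1.0 - alpha) * l_prev + alpha * w_delayed
        leaf[i] = l_cur
        l_prev = l_cur

        stem[i] = (
            config.stem_baseline
            + config.growth_rate * (i / MINUTES_PER_DAY)
            + config.shrink_gain * w_cur
            + noise[i]
        )

        sunrise = sunrise_by_date.get(ts.date())
        active = (
            sunrise is not None and ts >= sunrise and minutes_of_day[i] < cutoff_min
        )
        pre, _post, fired = controller.step(stem[i], active)
        if fired:
            s_cur += config.irrigation_volume
            events.append((ts, 15.0, pre))
        soil[i] = s_cur

    stem_series = pd.Series(stem, index=index, name="diameter_mm")
    truth = pd.DataFrame(
        {
            "stem_water": w_hist,
            "leaf_water": leaf,
            "soil_reservoir": soil,
            "wilt_displacement": config.wilt_gain
            * config.coupling_gamma
            * np.maximum(0.0, -leaf),
        },
        index=index,
    )
    truth.attrs["true_delay"] = delay
    irrigation = pd.DataFrame(events, columns=["timestamp", "volume_ml", "pre_rsr"])
    return stem_series, truth, irrigation


# --------------------------------------------------------------------------
# rendering


def leaf_tip_positions(displacement: float) -> list[tuple[float, float]]:
    """(row, col) of each leaf tip for a given wilt displacement (pixels).

    Each leaf rotates downward about its stem anchor keeping its length
    constant; the tip row is anchor_row + base droop + displacement (capped
    just short of vertical).
    """
    tips = []
    for anchor_row, side in LEAF_ANCHORS:
        drop = min(LEAF_BASE_DROOP + displacement, LEAF_LENGTH - 2.0)
        extent = math.sqrt(LEAF_LENGTH**2 - drop**2)
        tips.append((anchor_row + drop, STEM_COL + STEM_WIDTH / 2 + side * extent))
    return tips


def _plant_coverage(displacement: float) -> np.ndarray:
    """Fractional plant coverage per 144-grid pixel via 2x supersampling."""
    s = SUPERSAMPLE
    size = FRAME_SIZE * s
    layer = np.zeros((size, size), dtype=bool)
    layer[STEM_TOP * s : STEM_BOTTOM * s, STEM_COL * s : (STEM_COL + STEM_WIDTH) * s] = True

    rows = np.arange(size)[:, None] / s
    cols = np.arange(size)[None, :] / s
    anchor_col = STEM_COL + STEM_WIDTH / 2
    for (anchor_row, side), (tip_r, tip_c) in zip(
        LEAF_ANCHORS, leaf_tip_positions(displacement)
    ):
        cr, cc = (anchor_row + tip_r) / 2, (anchor_col + tip_c) / 2
        theta = math.atan2(tip_r - anchor_row, tip_c - anchor_col)
        dr, dc = rows - cr, cols - cc
        x = dc * math.cos(theta) + dr * math.sin(theta)
        y = -dc * math.sin(theta) + dr * math.cos(theta)
        layer |= (x / (LEAF_LENGTH / 2)) ** 2 + (y / LEAF_HALF_WIDTH) ** 2 <= 1.0
    cov = layer.reshape(FRAME_SIZE, s, FRAME_SIZE, s).mean(axis=(1, 3))
    return cov


def _background(minute_of_day: int, rng_clouds: np.random.Generator | None = None,
                cloud_offsets: np.ndarray | None = None) -> np.ndarray:
    bg = np.empty((FRAME_SIZE, FRAME_SIZE, 3), dtype=float)
    bg[:SOIL_TOP_ROW] = SKY_RGB
    bg[SOIL_TOP_ROW:] = SOIL_RGB
    if cloud_offsets is not None:
        rows = np.arange(FRAME_SIZE)[:, None]
        cols = np.arange(FRAME_SIZE)[None, :]
        for (row0, speed, r_rad, c_rad), off in zip(_CLOUDS, cloud_offsets):
            center_c = (off + speed * minute_of_day) % (FRAME_SIZE + 2 * c_rad) - c_rad
            inside = ((rows - row0) / r_rad) ** 2 + ((cols - center_c) / c_rad) ** 2 <= 1.0
            inside &= rows < SOIL_TOP_ROW
            bg[inside] = CLOUD_RGB
    return bg


#: (row, drift px/min, row radius, col radius) of the drifting clouds; kept in
#: the upper sky so no matching window centred on a plant pixel can see one
_CLOUDS = ((16, 0.9, 7, 22), (28, 0.6, 6, 16), (8, 1.3, 5, 12))


def render_frames(truth: pd.DataFrame, config: ScenarioConfig,
                  clouds: bool = True) -> ImageSequence:
    """Render the camera-window frames for the scenario.

    144x144 RGB scenes: a sky band with drifting achromatic cloud ellipses, a
    soil band, and a green plant (stem plus four leaf ellipses) whose leaves
    rotate downward by the latent ``wilt_displacement``.  The plant palette
    guarantees ExG > 0 for every pixel with plant coverage and ExG <= 0
    elsewhere (noise off), so the ground-truth plant set is exactly the
    ExG-positive set; it is returned in ``true_plant_masks``.
    """
    start, end = _time_minutes(config.image_start), _time_minutes(config.image_end)
    mod = _minutes_of_day(truth.index)
    window = (mod >= start) & (mod <= end)
    sub = truth.loc[window]
    if sub.empty:
        raise ValueError("truth does not cover the camera window")

    rng_noise = _rng(config, 4)
    cloud_offsets = _rng(config, 5).uniform(0, FRAME_SIZE, size=len(_CLOUDS))
    plant = np.array(PLANT_RGB, dtype=float)

    frames = np.empty((len(sub), FRAME_SIZE, FRAME_SIZE, 3), dtype=np.uint8)
    masks = np.empty((len(sub), FRAME_SIZE, FRAME_SIZE), dtype=bool)
    for k, (ts, disp) in enumerate(sub["wilt_displacement"].items()):
        minute = ts.hour * 60 + ts.minute
        bg = _background(minute, cloud_offsets=cloud_offsets if clouds else None)
        cov = _plant_coverage(float(disp))
        img = bg * (1.0 - cov[..., None]) + plant[None, None, :] * cov[..., None]
        if config.sensor_noise_sd > 0:
            img = img + rng_noise.normal(0.0, config.sensor_noise_sd, img.shape)
        frames[k] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        masks[k] = cov > 0
    return ImageSequence(
        frames=frames,
        timestamps=pd.DatetimeIndex(sub.index),
        plant_id="synthetic",
        true_plant_masks=masks,
    )


def synth_flow_fields(truth: pd.DataFrame, config: ScenarioConfig, w: int = 5) -> FlowSequence:
    """Precomputed (t-w, t) flow fields bypassing the flow estimator.

    Masked (plant) pixels carry vertical displacement equal to
    wilt_displacement(t) - wilt_displacement(t-w); off-mask pixels carry small
    random noise.  When ``config.flow_noise_sd > 0`` the same iid noise is
    added inside the mask, emulating flow-estimation error; at 0 the masked
    field is exact.
    """
    start, end = _time_minutes(config.image_start), _time_minutes(config.image_end)
    mod = _minutes_of_day(truth.index)
    window = (mod >= start) & (mod <= end)
    sub = truth.loc[window, "wilt_displacement"]
    if sub.empty:
        raise ValueError("truth does not cover the camera window")

    mask = _plant_coverage(0.0) > 0
    rng = _rng(config, 6)
    lag = pd.Timedelta(minutes=w)
    timestamps, flows, masks = [], [], []
    for ts, disp in sub.items():
        earlier = ts - lag
        if earlier not in sub.index:
            continue
        dv = float(disp - sub.loc[earlier])
        v = rng.normal(0.0, 0.05, mask.shape)
        u = rng.normal(0.0, 0.05, mask.shape)
        v[mask] = dv
        u[mask] = 0.0
        if config.flow_noise_sd > 0:
            v[mask] += rng.normal(0.0, config.flow_noise_sd, int(mask.sum()))
        timestamps.append(ts)
        flows.append(FlowField(u=u, v=v))
        masks.append(mask)
    return FlowSequence(
        timestamps=pd.DatetimeIndex(timestamps), flows=flows, masks=masks, window_w=w
    )


@dataclass
class SyntheticDataset:
    """Bundle of everything one scenario produces on a shared minute grid."""

    config: ScenarioConfig
    env: pd.DataFrame
    stem: pd.Series
    irrigation: pd.DataFrame
    truth: pd.DataFrame
    frames: ImageSequence | None = None
    flows: FlowSequence | None = None


def generate_dataset(
    config: ScenarioConfig,
    images: str = "none",  # none | frames | flows | both
    w: int = 5,
) -> SyntheticDataset:
    """Run environment + plant simulation and optionally render imagery."""
    env = generate_environment(config)
    stem, truth, irrigation = simulate_plant(config, env)
    frames = render_frames(truth, config) if images in ("frames", "both") else None
    flows = synth_flow_fields(truth, config, w=w) if images in ("flows", "both") else None
    return SyntheticDataset(
        config=config, env=env, stem=stem, irrigation=irrigation,
        truth=truth, frames=frames, flows=flows,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write the pipeline_io CSV schemas (stem/env/irrigation) and any frames."""
    from . import pipeline_io

    pipeline_io.write_stem_csv(dataset.stem, f"{outdir}/stem.csv")
    pipeline_io.write_env_csv(dataset.env, f"{outdir}/env.csv")
    pipeline_io.write_irrigation_csv(dataset.irrigation, f"{outdir}/irrigation.csv")
    if dataset.frames is not None:
        pipeline_io.write_image_dir(dataset.frames, f"{outdir}/frames")
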