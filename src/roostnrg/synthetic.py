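"""Synthetic roost-microclimate study generator.

Emulates the structure of a two-site field deployment of 40 rocket boxes
(2 sites x 4 landscape placements x 5 designs), each instrumented with 12
bi-hourly temperature loggers, over an April-September season: daily
weather (maximum air temperature and wind speed), daily bat counts per
box, and hourly roost temperatures quantized to the 0.5 °C logger
resolution.

Roost temperature for a box-day is built additively:

    T(hour, position) = T_a_mean
                        + damping * lagged(diel deviation + solar gain)
                        + vertical gradient(level) * solar shape(hour)
                        + bat heating(hours with bats present)
                        + sensor noise,   then quantized to 0.5 °C

Design modifiers act on the forcing curve, not on the noise: reflectance
and ventilation damp its amplitude; thermal mass is a moving-average lag
that both delays and buffers extremes (the physically coupled pair).
Placements scale and phase-shift the solar gain (easterly sun peaks in the
morning, westerly in the evening, forest shade nearly eliminates it).
Bat heating is saturating — linear in group size up to a configurable
colony size, flat above — and applies only to night/morning hours when
bats are in the roost.

Randomness flows through named substreams (weather, temperatures, bats,
parity) derived from one mandatory seed, so enlarging the box array does
not perturb the weather draws.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .microclimate import (
    LEVELS,
    FACES,
    POSITIONS,
    RoostTemperatureGrid,
    TemperatureRecord,
    LoggerPosition,
)

__all__ = [
    "DesignModifiers",
    "SimulationConfig",
    "SyntheticStudy",
    "simulate_weather",
    "simulate_box_day",
    "simulate_study",
]

DESIGN_NAMES = ("REF", "VR", "CH", "WTR", "EJW")
PLACEMENT_NAMES = ("open", "east", "west", "forest")

# substream labels -> integer keys mixed into the seed sequence
_STREAMS = {"weather": 1, "temps": 2, "bats": 3, "parity": 4}


def _rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, _STREAMS[stream], *extra)))


@dataclass(frozen=True)
class DesignModifiers:
    """How a box design reshapes the thermal forcing curve.

    thermal_mass_lag_hr
        Width (hours) of the moving-average applied to the forcing;
        delays the daily maximum and buffers extremes (external water
        jacket).
    ventilation_damping, reflectance_damping
        Fractions in [0, 1] by which ventilation (chimney) and surface
        reflectance (white roof) shrink the forcing amplitude.  A design
        with *less* ventilation than the reference (vent removal) simply
        carries less ventilation damping.
    """

    thermal_mass_lag_hr: float = 0.0
    ventilation_damping: float = 0.0
    reflectance_damping: float = 0.0

    def __post_init__(self) -> None:
        if self.thermal_mass_lag_hr < 0:
            raise ValueError("thermal_mass_lag_hr must be >= 0")
        for name in ("ventilation_damping", "reflectance_damping"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def amplitude_factor(self) -> float:
        return (1.0 - self.ventilation_damping) * (1.0 - self.reflectance_damping)


def _default_designs() -> dict[str, DesignModifiers]:
    return {
        "REF": DesignModifiers(ventilation_damping=0.06),
        "VR": DesignModifiers(ventilation_damping=0.0),
        "CH": DesignModifiers(ventilation_damping=0.22),
        "WTR": DesignModifiers(ventilation_damping=0.06, reflectance_damping=0.18),
        "EJW": DesignModifiers(thermal_mass_lag_hr=3.0, ventilation_damping=0.06,
                               reflectance_damping=0.12),
    }


def _default_placements() -> dict[str, float]:
    return {"open": 1.0, "east": 0.78, "west": 0.78, "forest": 0.08}


@dataclass
class SimulationConfig:
    """Study-design and microclimate parameters; ``seed`` is mandatory.

    Defaults describe the emulated field conditions: a temperate
    mid-continental season (daily maximum air temperature following a
    seasonal sinusoid within 1.3-36.4 °C), solar-exposed boxes exceeding
    air temperature by up to ~12 °C, a vertical top-to-bottom gradient of
    up to 10 °C on clear middays, and social thermoregulation worth up to
    ~7 °C for a large colony.
    """

    seed: int
    site_names: tuple[str, ...] = ("IN", "KY")
    start_date: dt.date = dt.date(2019, 4, 1)
    end_date: dt.date = dt.date(2019, 9, 15)
    placement_solar: Mapping[str, float] = field(default_factory=_default_placements)
    placement_solar_phase: Mapping[str, float] = field(
        default_factory=lambda: {"open": 0.0, "east": -2.0, "west": 2.0, "forest": 0.0}
    )
    designs: Mapping[str, DesignModifiers] = field(default_factory=_default_designs)
    diel_range: float = 11.0          # air daily max - min, °C
    solar_gain_max: float = 12.0      # peak box excess over air in full sun, °C
    vertical_gradient_max: float = 10.0  # top minus bottom at peak sun, °C
    bat_heating_per_bat: float = 0.1  # °C per bat below saturation
    bat_heating_saturation: int = 70  # colony size at which heating saturates
    bat_presence_hours: tuple[int, ...] = (21, 22, 23, 0, 1, 2, 3, 4, 5, 6, 7, 8, 9)
    weather_base_max: float = 19.0    # seasonal mean of daily max T_a, °C
    weather_seasonal_amp: float = 9.0
    weather_peak_doy: int = 201       # day-of-year of warmest expected maximum
    weather_noise_sd: float = 4.0
    t_a_bounds: tuple[float, float] = (1.3, 36.4)
    wind_shape: float = 2.0           # gamma shape of daily max wind
    wind_scale: float = 1.5           # gamma scale, m/s
    wind_max: float = 15.0
    wind_cooling: float = 0.02        # fractional solar-gain loss per m/s wind
    occupancy_prob: float = 0.5       # probability a box hosts a colony
    colony_size_mean: float = 15.0
    noise_sd: float = 0.5             # sensor noise sd, °C
    quantization: float = 0.5         # logger resolution, °C

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        self.start_date = _as_date(self.start_date)
        self.end_date = _as_date(self.end_date)
        if self.end_date < self.start_date:
            raise ValueError("end_date before start_date")
        for name, value in self.placement_solar.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"placement_solar[{name!r}] must lie in [0, 1]")
        if self.vertical_gradient_max < 0:
            raise ValueError("vertical_gradient_max must be >= 0")
        if not 0.0 <= self.occupancy_prob <= 1.0:
            raise ValueError("occupancy_prob must lie in [0, 1]")
        self.designs = {
            k: v if isinstance(v, DesignModifiers) else DesignModifiers(**v)
            for k, v in self.designs.items()
        }

    @property
    def dates(self) -> list[dt.date]:
        n = (self.end_date - self.start_date).days + 1
        return [self.start_date + dt.timedelta(days=d) for d in range(n)]

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if seed is not None:
            data["seed"] = seed
        if "designs" in data:
            data["designs"] = {k: DesignModifiers(**v) for k, v in data["designs"].items()}
        for key in ("start_date", "end_date"):
            if key in data and isinstance(data[key], str):
                data[key] = dt.date.fromisoformat(data[key])
        return cls(**data)


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


# ---------------------------------------------------------------------------
# weather


def simulate_weather(config: SimulationConfig, n_days: int | None = None) -> pd.DataFrame:
    """Daily weather per (site, placement) cluster.

    Daily maximum air temperature follows a seasonal sinusoid with
    Gaussian day-to-day noise, clipped to the configured plausible range;
    daily maximum wind speed is gamma-distributed.  Reproducible given
    the config seed; independent draws per cluster (each cluster has its
    own weather station).

    Returns a DataFrame with columns
    ``site, placement, date, max_temp, max_wind``.
    """
    dates = config.dates
    if n_days is not None:
        if n_days <= 0:
            raise ValueError("n_days must be positive")
        dates = dates[:n_days]
        if len(dates) < n_days:
            raise ValueError("n_days exceeds the configured date range")
    rng = _rng(config.seed, "weather")
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    seasonal = config.weather_base_max + config.weather_seasonal_amp * np.sin(
        2.0 * np.pi * (doy - (config.weather_peak_doy - 365.25 / 4)) / 365.25
    )
    frames = []
    for site in config.site_names:
        for placement in config.placement_solar:
            t_max = seasonal + rng.normal(0.0, config.weather_noise_sd, len(dates))
            t_max = np.clip(t_max, *config.t_a_bounds)
            wind = rng.gamma(config.wind_shape, config.wind_scale, len(dates))
            wind = np.clip(wind, 0.0, config.wind_max)
            frames.append(
                pd.DataFrame(
                    {
                        "site": site,
                        "placement": placement,
                        "date": dates,
                        "max_temp": np.round(t_max, 1),
                        "max_wind": np.round(wind, 1),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# roost temperature construction

_HOURS = np.arange(24, dtype=float)


def _solar_shape(phase: float) -> np.ndarray:
    """Normalized solar forcing over the 24 hours, peak 1 at 13:00 + phase."""
    h = _HOURS - phase
    s = np.sin(np.pi * (h - 7.0) / 12.0)
    s[(h < 7.0) | (h > 19.0)] = 0.0
    return np.clip(s, 0.0, None)


def _lagged(forcing: np.ndarray, lag_hr: float) -> np.ndarray:
    """Circular moving average of width ``lag_hr + 1`` (thermal mass)."""
    width = int(round(lag_hr)) + 1
    if width <= 1:
        return forcing
    kernel = np.ones(width) / width
    idx = (np.arange(24)[:, None] - np.arange(width)[None, :]) % 24
    return forcing[idx] @ kernel


def simulate_box_day(
    config: SimulationConfig,
    design: str,
    placement: str,
    weather_day: Mapping[str, float],
    n_bats: int,
    rng: np.random.Generator | None = None,
    box_id: str = "box",
    date: dt.date | None = None,
    parity_by_position: Sequence[str] | None = None,
) -> RoostTemperatureGrid:
    """One box-day of hourly roost temperatures at the 12 logger positions.

    ``weather_day`` supplies ``max_temp`` and ``max_wind``; ``n_bats`` the
    colony size that day.  ``parity_by_position`` fixes which loggers
    record on even vs odd hours (12 entries in position order, two per
    parity per level); the default alternates faces N, S even / E, W odd.
    Noise draws do not depend on ``n_bats`` or the design/placement, so
    effect sizes can be toggled without perturbing the noise realization.
    """
    if design not in config.designs:
        raise ValueError(f"unknown design {design!r}")
    if placement not in config.placement_solar:
        raise ValueError(f"unknown placement {placement!r}")
    if rng is None:
        rng = _rng(config.seed, "temps")
    mods: DesignModifiers = config.designs[design]
    t_max = float(weather_day["max_temp"])
    wind = float(weather_day["max_wind"])
    t_mean = t_max - config.diel_range / 2.0

    diel = (config.diel_range / 2.0) * np.cos(2.0 * np.pi * (_HOURS - 15.0) / 24.0)
    shape = _solar_shape(config.placement_solar_phase[placement])
    solar = (
        config.placement_solar[placement]
        * config.solar_gain_max
        * max(0.0, 1.0 - config.wind_cooling * wind)
        * shape
    )
    forcing = mods.amplitude_factor * _lagged(diel + solar, mods.thermal_mass_lag_hr)

    heating = config.bat_heating_per_bat * min(n_bats, config.bat_heating_saturation)
    bat_term = np.zeros(24)
    bat_term[list(config.bat_presence_hours)] = heating

    level_offset = {"top": 0.5, "middle": 0.0, "bottom": -0.5}
    temps = np.empty((24, len(POSITIONS)))
    gradient = config.vertical_gradient_max * shape
    for col, (level, _face) in enumerate(POSITIONS):
        temps[:, col] = t_mean + forcing + level_offset[level] * gradient + bat_term
    temps += rng.normal(0.0, config.noise_sd, temps.shape)
    q = config.quantization
    temps = np.round(temps / q) * q

    parity = parity_by_position or _canonical_parity()
    for col, (level, face) in enumerate(POSITIONS):
        off = 1 if parity[col] == "even" else 0  # mask hours the logger skips
        temps[off::2, col] = np.nan
    return RoostTemperatureGrid(
        box_id=box_id, date=date or config.start_date, temps=temps
    )


def _canonical_parity() -> list[str]:
    return ["even" if face in ("N", "S") else "odd" for _level, face in POSITIONS]


def _random_parity(rng: np.random.Generator) -> list[str]:
    """Per level, two random faces record even hours and two record odd."""
    parity = []
    for _level in LEVELS:
        even_faces = set(rng.choice(len(FACES), size=2, replace=False).tolist())
        parity.extend("even" if i in even_faces else "odd" for i in range(len(FACES)))
    return parity


# ---------------------------------------------------------------------------
# whole-study simulation


@dataclass
class SyntheticStudy:
    """Joined synthetic dataset ready for the pipeline.

    ``truth`` retains the generating configuration and derived per-design
    and per-placement forcing effects for parameter-recovery tests.
    """

    config: SimulationConfig
    metadata: pd.DataFrame       # box_id, site, design, placement
    weather: pd.DataFrame        # site, placement, date, max_temp, max_wind
    bat_counts: pd.DataFrame     # box_id, date, total_bats
    grids: list[RoostTemperatureGrid]
    truth: dict

    def to_records(self) -> list[TemperatureRecord]:
        from .microclimate import grid_to_records

        parities = self.truth["parity_by_box"]
        records = []
        for grid in self.grids:
            records.extend(grid_to_records(grid, parities[grid.box_id]))
        return records

    def write_csvs(self, directory: str | Path) -> None:
        """Emit native-dialect CSVs: records, weather, bat counts, metadata."""
        from .microclimate import write_logger_csv

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_logger_csv(directory / "temperatures.csv", self.to_records())
        self.weather.to_csv(directory / "weather.csv", index=False)
        self.bat_counts.to_csv(directory / "bat_counts.csv", index=False)
        self.metadata.to_csv(directory / "boxes.csv", index=False)


def _simulate_bat_counts(
    config: SimulationConfig, metadata: pd.DataFrame, dates: list[dt.date]
) -> pd.DataFrame:
    """Daily counts per box: colonies ramp up through the season."""
    rng = _rng(config.seed, "bats")
    n_days = len(dates)
    ramp = np.clip(np.linspace(0.1, 1.0, n_days), 0.0, 1.0)
    frames = []
    for _, box in metadata.iterrows():
        occupied = rng.random() < config.occupancy_prob
        if occupied and box["placement"] != "forest":
            size = rng.gamma(2.0, config.colony_size_mean / 2.0)
            lam = size * ramp
            counts = rng.poisson(lam)
        else:
            counts = np.zeros(n_days, dtype=int)
        frames.append(
            pd.DataFrame(
                {"box_id": box["box_id"], "date": dates, "total_bats": counts}
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate the full synthetic study: 2 sites x 4 placements x 5 designs.

    Every (site, placement, design) combination yields one box, matching
    the balanced field layout.  Returns joined tables plus per-box-day
    temperature grids and the ground-truth effect structure.
    """
    boxes = []
    for site in config.site_names:
        for placement in config.placement_solar:
            for design in config.designs:
                boxes.append(
                    {
                        "box_id": f"{site}-{placement}-{design}",
                        "site": site,
                        "design": design,
                        "placement": placement,
                    }
                )
    metadata = pd.DataFrame(boxes)
    dates = config.dates
    weather = simulate_weather(config)
    weather_idx = weather.set_index(["site", "placement", "date"])
    bat_counts = _simulate_bat_counts(config, metadata, dates)
    bats_idx = bat_counts.set_index(["box_id", "date"])["total_bats"]

    parity_by_box: dict[str, list[str]] = {}
    grids: list[RoostTemperatureGrid] = []
    for i, box in metadata.iterrows():
        parity = _random_parity(_rng(config.seed, "parity", i))
        parity_by_box[box["box_id"]] = parity
        box_rng = _rng(config.seed, "temps", i)
        for date in dates:
            wx = weather_idx.loc[(box["site"], box["placement"], date)]
            grids.append(
                simulate_box_day(
                    config,
                    design=box["design"],
                    placement=box["placement"],
                    weather_day=wx,
                    n_bats=int(bats_idx.loc[(box["box_id"], date)]),
                    rng=box_rng,
                    box_id=box["box_id"],
                    date=date,
                    parity_by_position=parity,
                )
            )
    truth = {
        "config": asdict(config),
        "design_amplitude_factor": {
            name: mods.amplitude_factor for name, mods in config.designs.items()
        },
        "design_lag_hr": {
            name: mods.thermal_mass_lag_hr for name, mods in config.designs.items()
        },
        "placement_solar": dict(config.placement_solar),
        "parity_by_box": parity_by_box,
    }
    return SyntheticStudy(
        config=config,
        metadata=metadata,
        weather=weather,
        bat_counts=bat_counts,
        grids=grids,
        truth=truth,
    )
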