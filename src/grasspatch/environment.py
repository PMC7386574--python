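"""Daily climate drivers and the simplified soil water / mineral-N buckets.

Climate can be read from CSV (columns ``date,tmean_C,par_mol_m2_d,precip_mm,
pet_mm``; day length is computed from latitude when absent) or synthesized.
The synthetic generator emulates a temperate seasonal driver: sinusoidal
mean temperature and photosynthetically active radiation peaking in
mid-summer with additive Gaussian noise, rainfall from a two-state Markov
occurrence chain with exponentially distributed wet-day amounts, potential
evapotranspiration as a noise-free seasonal sinusoid, and day length from
standard solar geometry.

The soil is a single-layer bucket standing in for a full soil-organic-matter
model: water is replenished by rain, depleted by bare-soil evaporation (a
fixed share of PET), plant supply and drainage beyond capacity; mineral
nitrogen is fed by first-order mineralization of the above/belowground
litter pools plus atmospheric deposition and depleted by plant uptake.  The
interface — one water supply and one N supply per day — is the same one a
full soil model would provide.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClimateConfig",
    "generate_synthetic_climate",
    "read_climate_csv",
    "write_climate_csv",
    "daylength_hours",
    "SoilState",
    "soil_water_step",
    "soil_nitrogen_step",
]


def daylength_hours(doy: np.ndarray | int, latitude_deg: float) -> np.ndarray:
    """Astronomical day length (h) from day-of-year and latitude."""
    if not -90.0 <= latitude_deg <= 90.0:
        raise ValueError(f"invalid latitude: {latitude_deg}")
    doy = np.asarray(doy, dtype=float)
    decl = np.deg2rad(23.44) * np.sin(2.0 * np.pi * (284.0 + doy) / 365.0)
    lat = np.deg2rad(latitude_deg)
    cos_omega = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(cos_omega)


@dataclass(frozen=True)
class ClimateConfig:
    """Settings of the synthetic temperate seasonal driver.

    Defaults approximate a Central German lowland site: mean annual
    temperature ~9 °C, ~600 mm annual precipitation, PAR between ~4 (winter)
    and ~40 (summer) mol photons m⁻² d⁻¹.
    """

    latitude_deg: float = 51.0
    tmean_C: float = 9.3            # annual mean temperature
    tamp_C: float = 9.0             # seasonal amplitude (peak minus mean)
    tnoise_sd_C: float = 3.0        # day-to-day Gaussian noise
    par_mean: float = 22.0          # mol photons m^-2 d^-1
    par_amp: float = 18.0
    par_noise_sd: float = 5.0
    peak_doy: int = 197             # mid-July seasonal peak
    p_wet_after_dry: float = 0.30   # Markov rainfall occurrence
    p_wet_after_wet: float = 0.60
    wet_day_mm: float = 4.0         # mean exponential wet-day amount
    pet_summer_mm: float = 3.5      # seasonal PET sinusoid extremes
    pet_winter_mm: float = 0.3


def generate_synthetic_climate(
    params: ClimateConfig | None = None,
    years: int = 1,
    seed: int | None = None,
    start_year: int = 2003,
) -> pd.DataFrame:
    """Synthesize ``years`` years of daily drivers (reproducible under seed).

    Returns a DataFrame with columns ``date, tmean, par, daylength, precip,
    pet`` (units °C, mol photons m⁻² d⁻¹, h, mm, mm).
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    cfg = params or ClimateConfig()
    rng = np.random.default_rng(seed)
    dates = pd.date_range(f"{start_year}-01-01",
                          f"{start_year + years - 1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    n = len(dates)
    phase = np.cos(2.0 * np.pi * (doy - cfg.peak_doy) / 365.25)
    tmean = cfg.tmean_C + cfg.tamp_C * phase + rng.normal(0.0, cfg.tnoise_sd_C, n)
    par = cfg.par_mean + cfg.par_amp * phase + rng.normal(0.0, cfg.par_noise_sd, n)
    par = np.maximum(par, 0.1)
    # Two-state Markov rain occurrence, exponential amounts.
    u = rng.random(n)
    amounts = rng.exponential(cfg.wet_day_mm, n)
    wet = np.empty(n, dtype=bool)
    prev = False
    for i in range(n):
        p = cfg.p_wet_after_wet if prev else cfg.p_wet_after_dry
        prev = wet[i] = u[i] < p
    precip = np.where(wet, amounts, 0.0)
    pet_mid = 0.5 * (cfg.pet_summer_mm + cfg.pet_winter_mm)
    pet_amp = 0.5 * (cfg.pet_summer_mm - cfg.pet_winter_mm)
    pet = pet_mid + pet_amp * phase
    return pd.DataFrame({
        "date": dates,
        "tmean": tmean,
        "par": par,
        "daylength": daylength_hours(doy, cfg.latitude_deg),
        "precip": precip,
        "pet": pet,
    })


_CSV_COLS = {"date": "date", "tmean_C": "tmean", "par_mol_m2_d": "par",
             "precip_mm": "precip", "pet_mm": "pet"}


def read_climate_csv(path: str | Path, latitude_deg: float = 51.0) -> pd.DataFrame:
    """Read a climate driver CSV (strict ISO dates); compute day length."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"climate CSV missing columns: {sorted(missing)}")
    df = df.rename(columns=_CSV_COLS)
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    if "daylength" not in df.columns:
        df["daylength"] = daylength_hours(
            df["date"].dt.dayofyear.to_numpy(), latitude_deg)
    return df[["date", "tmean", "par", "daylength", "precip", "pet"]]


def write_climate_csv(climate: pd.DataFrame, path: str | Path) -> None:
    out = climate.rename(columns={v: k for k, v in _CSV_COLS.items()})
    cols = [c for c in _CSV_COLS]
    out[cols].to_csv(path, index=False, date_format="%Y-%m-%d")


# ---------------------------------------------------------------------------
# Soil buckets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SoilState:
    """Single-layer soil water and mineral-nitrogen state (per m² patch)."""

    water: float = 60.0             # mm
    water_capacity: float = 120.0   # mm
    mineral_N: float = 5.0          # g m^-2
    litter_above: tuple[float, float] = (0.0, 0.0)  # (mass g, N g)
    litter_below: tuple[float, float] = (0.0, 0.0)
    mineralization_rate: float = 0.01   # d^-1, litter decay -> mineral N
    n_deposition: float = 0.005         # g m^-2 d^-1 atmospheric input
    pet_soil_share: float = 0.3         # share of PET evaporating from soil

    def __post_init__(self) -> None:
        if not 0.0 <= self.water <= self.water_capacity:
            raise ValueError("soil water outside [0, capacity]")
        if min(self.mineral_N, *self.litter_above, *self.litter_below) < 0:
            raise ValueError("negative soil pool")


def soil_water_step(
    soil: SoilState, precip: float, pet: float, transpiration_demand: float
) -> tuple[SoilState, float, dict[str, float]]:
    """One day of the water bucket.

    Order: bare-soil evaporation (a fixed share of PET, limited by storage),
    then rain input, then plant supply (limited by demand and storage), then
    drainage of any excess beyond capacity.  Returns the new state, the water
    supplied to plants (mm) and a flux breakdown for balance accounting.
    """
    if transpiration_demand < 0:
        raise ValueError("negative transpiration demand")
    evap = min(soil.pet_soil_share * pet, soil.water)
    water = soil.water - evap + precip
    supply = min(transpiration_demand, water)
    water -= supply
    drainage = max(0.0, water - soil.water_capacity)
    water -= drainage
    fluxes = {"precip": precip, "evaporation": evap,
              "supply": supply, "drainage": drainage}
    return replace(soil, water=water), supply, fluxes


def soil_nitrogen_step(
    soil: SoilState,
    litter_above_in: tuple[float, float] = (0.0, 0.0),
    litter_below_in: tuple[float, float] = (0.0, 0.0),
    n_demand: float = 0.0,
) -> tuple[SoilState, float, dict[str, float]]:
    """One day of the litter/mineral-N bucket.

    Fresh litter (mass, N) enters the above/belowground pools; both pools
    decay at the first-order mineralization rate, releasing their N to the
    mineral pool; deposition adds N; plant uptake removes up to the demand.
    """
    (am, an), (bm, bn) = litter_above_in, litter_below_in
    if min(am, an, bm, bn, n_demand) < 0:
        raise ValueError("negative litter flux or N demand")
    la_m, la_n = soil.litter_above[0] + am, soil.litter_above[1] + an
    lb_m, lb_n = soil.litter_below[0] + bm, soil.litter_below[1] + bn
    r = soil.mineralization_rate
    mineralized = r * (la_n + lb_n)
    la_m, la_n = la_m * (1 - r), la_n * (1 - r)
    lb_m, lb_n = lb_m * (1 - r), lb_n * (1 - r)
    mineral = soil.mineral_N + mineralized + soil.n_deposition
    supply = min(n_demand, mineral)
    mineral -= supply
    fluxes = {"mineralized": mineralized, "deposition": soil.n_deposition,
              "supply": supply}
    new = replace(soil, mineral_N=mineral,
                  litter_above=(la_m, la_n), litter_below=(lb_m, lb_n))
    return new, supply, fluxes
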