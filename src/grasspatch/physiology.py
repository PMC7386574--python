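"""Daily plant physiology: light capture, photosynthesis, limitation, growth.

Light competition follows the gap-model convention: the canopy is sliced
into 1-cm horizontal layers, every plant's leaf area is spread uniformly
over its own height, and irradiance declines downward by Beer–Lambert
extinction of the k-weighted leaf area overhead (each species' leaves
attenuate with their own extinction coefficient).  A plant's gross
photosynthesis is the closed-form vertical integral of the saturating leaf
light response

    p(I) = alpha * I * p_max / (alpha * I + p_max)

over its individual leaf area index, evaluated at the irradiance reaching
its top, with leaf-level irradiance inside the plant following
``I(l) = I_top * k/(1-m) * exp(-k l)`` (transmission ``m``).  Daytime mean
irradiance is daily PAR divided by day length; there is no diurnal cycle.

Growth is a carbon balance: gross uptake is reduced multiplicatively by
temperature, water and nitrogen limitation factors, maintenance and growth
respiration are paid, and the remaining net primary production is split
between shoot and root by the species' allocation fraction.  Green leaves
yellow into a senescent pool at 1/LLS, senescent shoot sheds to litter, and
roots turn over at 1/RLS.  Water demand follows from water use efficiency,
nitrogen demand from the green-tissue C:N ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _replace

import numpy as np

from . import _kernels
from .geometry import PlantState, update_dimensions
from .traits import SpeciesTraits

__all__ = [
    "LimitationFactors",
    "leaf_light_response",
    "canopy_light_profile",
    "plant_gross_photosynthesis",
    "limitation_factors",
    "daily_carbon_update",
    "ODM_PER_CO2",
]

#: g organic dry matter fixed per g CO2 assimilated (gap-model convention).
ODM_PER_CO2 = 0.63


@dataclass(frozen=True)
class LimitationFactors:
    """Multiplicative growth reduction factors, each in [0, 1] (1 = none)."""

    f_temp: float = 1.0
    f_water: float = 1.0
    f_nitrogen: float = 1.0

    def __post_init__(self) -> None:
        for v in (self.f_temp, self.f_water, self.f_nitrogen):
            if not 0.0 <= v <= 1.0:
                raise ValueError("limitation factors must lie in [0, 1]")

    @property
    def product(self) -> float:
        return self.f_temp * self.f_water * self.f_nitrogen


def leaf_light_response(
    i: float | np.ndarray, traits: SpeciesTraits
) -> np.ndarray:
    """Leaf-level gross photosynthesis (µmol CO₂ m⁻² s⁻¹) at irradiance ``i``.

    Saturating (Michaelis-type) response with initial slope ``alpha`` and
    asymptote ``p_max``.
    """
    i = np.asarray(i, dtype=float)
    if np.any(i < 0):
        raise ValueError("negative irradiance")
    return traits.alpha * i * traits.p_max / (traits.alpha * i + traits.p_max)


def canopy_light_profile(
    heights: np.ndarray,
    leaf_areas: np.ndarray,
    extinction: np.ndarray,
    par_top: float,
    patch_area_cm2: float = 10_000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Irradiance at each plant's top and per 1-cm layer.

    Parameters are per-plant arrays (heights cm, one-sided leaf areas cm²,
    species extinction coefficients).  Returns ``(i_top, i_layer)`` where
    ``i_layer[z]`` is the irradiance arriving at the bottom of layer ``z``
    (so ``i_layer[0]`` is the light on the ground).
    """
    heights = np.asarray(heights, dtype=float)
    n = heights.size
    # the kernel indexes per-species arrays; treat each plant as its own
    # pseudo-species so per-plant leaf areas/extinctions pass through
    sp = np.arange(n, dtype=np.int64)
    above = _kernels.canopy_attenuation(
        sp, heights, np.asarray(leaf_areas, float), n,
        np.ones(n), np.asarray(extinction, float) * np.ones(n),
        patch_area_cm2,
    )
    i_layer = par_top * np.exp(-above)
    tops = np.clip(np.ceil(heights).astype(np.int64), 0, _kernels.MAX_LAYERS)
    return i_layer[tops], i_layer[: _kernels.MAX_LAYERS + 1]


def plant_gross_photosynthesis(
    plant: PlantState,
    i_top: float,
    traits: SpeciesTraits,
    daylength: float,
    odm_per_co2: float = ODM_PER_CO2,
) -> float:
    """Daily gross photosynthesis of one plant in g ODM.

    Closed-form canopy integral per m² of covered ground, scaled by the
    plant's cover area, the day length and the CO₂ → dry-matter conversion.
    """
    cover = 0.25 * np.pi * plant.width**2
    leaf = traits.SLA * plant.shoot_green
    if cover <= 0.0 or leaf <= 0.0:
        return 0.0
    p_area = _kernels.gpp_area(
        float(i_top), leaf / cover, traits.p_max, traits.alpha,
        traits.k, traits.m)
    return p_area * cover * 1e-4 * daylength * 3600.0 * 44.0e-6 * odm_per_co2


def limitation_factors(
    tmean: float,
    water_supply_ratio: float,
    n_supply_ratio: float,
    t0: float = 0.0,
    t1: float = 10.0,
) -> LimitationFactors:
    """Temperature ramp between ``t0`` and ``t1`` °C; supply ratios pass through."""
    if not 0.0 <= water_supply_ratio <= 1.0 or not 0.0 <= n_supply_ratio <= 1.0:
        raise ValueError("supply ratios must lie in [0, 1]")
    f_temp = min(1.0, max(0.0, (tmean - t0) / (t1 - t0)))
    return LimitationFactors(f_temp, water_supply_ratio, n_supply_ratio)


def daily_carbon_update(
    plant: PlantState,
    gpp: float,
    lim: LimitationFactors,
    traits: SpeciesTraits,
    litter_fall_rate: float = 1.0 / 30.0,
) -> tuple[PlantState, dict[str, float], float, float]:
    """One day of carbon balance for a single plant.

    Returns the updated plant, a flux dict (``gpp_lim``, ``npp``,
    ``respiration``, ``litter_above``, ``litter_below`` in g ODM; litter N
    in g), the water demand (kg = mm per m²) and the nitrogen demand (g).
    """
    if gpp < 0:
        raise ValueError("negative gross photosynthesis")
    gpp_lim = gpp * lim.product
    sg, ss, rt, npp, resp, fall, rl = _kernels.carbon_scalar(
        plant.shoot_green, plant.shoot_senescent, plant.root, gpp_lim,
        traits.LLS, traits.RLS, traits.alloc_shoot, traits.r_m, traits.r_g,
        litter_fall_rate)
    height, width = update_dimensions(sg + ss, plant.width, traits)
    new = _replace(plant, age=plant.age + 1.0, height=height,
                   width=width, shoot_green=sg, shoot_senescent=ss,
                   root=rt)
    fluxes = {
        "gpp_lim": gpp_lim,
        "npp": npp,
        "respiration": resp,
        "litter_above": fall,
        "litter_below": rl,
        "litter_above_n": fall / traits.CN_sen,
        "litter_below_n": rl / traits.CN_sen,
    }
    water_demand = gpp_lim / traits.WUE
    n_demand = npp / traits.CN_green
    return new, fluxes, water_demand, n_demand
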