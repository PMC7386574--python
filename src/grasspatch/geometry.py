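"""Plant geometry: biomass <-> cylinder dimensions, areas, rooting depth.

Each plant is idealized as an encasing cylinder of height ``h`` and diameter
``w`` filled with shoot biomass at the effective density ``f_s``::

    B = f_s * (pi/4) * w**2 * h

Below the species' maximum height, plants keep a fixed height/width ratio
``hw`` (``h = hw * w``); once ``h_max`` is reached, additional biomass widens
the cylinder at constant height.  Mowing cuts the cylinder, leaving a plant
that is shorter than its geometric aspect ratio would dictate; such plants
regrow in height at constant width until the ratio is restored (see
:func:`update_dimensions`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traits import SpeciesTraits

__all__ = [
    "PlantState",
    "dimensions_from_shoot_biomass",
    "shoot_biomass_from_dimensions",
    "update_dimensions",
    "plant_areas",
    "rooting_depth",
    "make_seedling",
]

_QPI = 0.25 * np.pi


@dataclass
class PlantState:
    """One individual's size and biomass pools (g organic dry matter)."""

    species_id: str
    age: float = 0.0            # days
    height: float = 0.0         # cm
    width: float = 0.0          # cm, cylinder diameter
    shoot_green: float = 0.0    # g ODM
    shoot_senescent: float = 0.0
    root: float = 0.0
    alive: bool = True

    @property
    def shoot_total(self) -> float:
        return self.shoot_green + self.shoot_senescent


def dimensions_from_shoot_biomass(
    shoot_total: float | np.ndarray, traits: SpeciesTraits
) -> tuple[np.ndarray, np.ndarray]:
    """Cylinder (height, width) in cm holding ``shoot_total`` g of biomass.

    Solves ``B = f_s*(pi/4)*w^2*h`` with ``h = hw*w``; above the ``h_max``
    cap the extra biomass widens the plant at constant height.
    """
    b = np.asarray(shoot_total, dtype=float)
    if np.any(b < 0):
        raise ValueError("negative shoot biomass")
    c = _QPI * traits.f_s
    w = np.cbrt(b / (c * traits.hw))
    h = traits.hw * w
    over = h > traits.h_max
    if np.any(over):
        h = np.where(over, traits.h_max, h)
        w = np.where(over, np.sqrt(b / (c * traits.h_max)), w)
    return h, w


def shoot_biomass_from_dimensions(
    height: float | np.ndarray, width: float | np.ndarray, traits: SpeciesTraits
) -> np.ndarray:
    """Inverse of :func:`dimensions_from_shoot_biomass` (cylinder fill)."""
    return _QPI * traits.f_s * np.asarray(width, float) ** 2 * np.asarray(height, float)


def update_dimensions(
    shoot_total: float, width: float, traits: SpeciesTraits
) -> tuple[float, float]:
    """New (height, width) after the shoot pool changed to ``shoot_total``.

    Widths never shrink: a mown or senescing plant keeps its footprint and
    adjusts height so the cylinder stays mass-consistent; growing plants
    follow the aspect-ratio track of :func:`dimensions_from_shoot_biomass`.
    """
    if shoot_total <= 0.0:
        return 0.0, 0.0
    c = _QPI * traits.f_s
    iso_w = float(np.cbrt(shoot_total / (c * traits.hw)))
    if iso_w >= width:
        h = traits.hw * iso_w
        if h > traits.h_max:
            return traits.h_max, float(np.sqrt(shoot_total / (c * traits.h_max)))
        return h, iso_w
    h = shoot_total / (c * width * width)
    if h > traits.h_max:
        return traits.h_max, float(np.sqrt(shoot_total / (c * traits.h_max)))
    return h, width


def plant_areas(plant: PlantState, traits: SpeciesTraits) -> tuple[float, float, float]:
    """(cover_area, exclusive_area, leaf_area), all in cm².

    ``cover_area`` is the cylinder's ground shadow, ``exclusive_area`` the
    share of patch area the plant claims against crowding (reduced by the
    species' overlapping factor), ``leaf_area`` the green shoot scaled by SLA.
    """
    cover = _QPI * plant.width**2
    return cover, traits.f_O * cover, traits.SLA * plant.shoot_green


def rooting_depth(root: float | np.ndarray, traits: SpeciesTraits) -> np.ndarray:
    """Rooting depth (cm) from root mass via the power law ``r1 * root^r2``."""
    r = np.asarray(root, dtype=float)
    if np.any(r < 0):
        raise ValueError("negative root biomass")
    return traits.r1 * np.power(r, traits.r2, where=r > 0, out=np.zeros_like(r))


def make_seedling(traits: SpeciesTraits, day: int = 0) -> PlantState:
    """A newly emerged seedling at the species' initial height.

    The shoot fills the seedling cylinder; the root pool follows from the
    species' shoot:root ratio.
    """
    h = traits.h_min_cm
    w = h / traits.hw
    shoot = float(shoot_biomass_from_dimensions(h, w, traits))
    return PlantState(
        species_id=traits.species,
        age=0.0,
        height=h,
        width=w,
        shoot_green=shoot,
        shoot_senescent=0.0,
        root=shoot / traits.sr,
    )
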