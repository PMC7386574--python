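"""Per-species trait parameters: validation, (de)serialization, optimizer encoding.

Each species is described by 30 parameters (the rooting-depth power law counts
as one parameter with two coefficients): plant geometry (cylinder dimensions,
leaf and root morphology), recruitment and emergence, mortality, leaf
photosynthesis, resource competition (water use efficiency, tissue C:N) and
growth (allocation, respiration).  A subset of these — by convention the 16
traits that cannot be measured directly at the individual level — is exposed
to the inverse-parameterization optimizers as a bounded real vector.

Trait files are YAML, one document per species, with field names matching the
conventional symbols (``h_max``, ``hw``, ``f_s`` ...), so a trait file can be
read side by side with a published parameter table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SpeciesTraits",
    "TraitBounds",
    "CALIBRATABLE_TRAITS",
    "load_species_traits",
    "load_species_yaml",
    "save_species_yaml",
    "builtin_species",
    "builtin_species_names",
    "traits_to_frame",
    "encode_free_parameters",
    "decode_free_parameters",
    "default_bounds",
]


class TraitError(ValueError):
    """Invalid or incomplete species trait set."""


# Fields that must be strictly positive.
_POSITIVE = (
    "h_max", "hw", "f_s", "SLA", "SRL", "r1", "sr", "t_em",
    "h_min", "age_rep", "LLS", "RLS", "p_max", "alpha", "k", "WUE",
    "CN_green", "CN_sen", "alloc_shoot",
)
# Fields that must lie in [0, 1].
_UNIT_INTERVAL = ("germ_pct", "m", "r_g", "alloc_shoot")
# Fields that must be non-negative.
_NON_NEGATIVE = ("N_seed_meta", "m_seed", "m_basic", "r_m", "r2", "t_meta")


@dataclass(frozen=True)
class SpeciesTraits:
    """The full 30-parameter description of one species.

    Units follow field convention: lengths in cm except ``h_min`` (m, the
    convention for seedling height), masses in g organic dry matter (ODM),
    areas in cm², rates per day unless marked per year.
    """

    species: str
    h_max: float          # cm, maximum plant height
    hw: float             # -, height/width ratio of the encasing cylinder
    f_s: float            # g cm^-3, shoot correction factor
    f_O: float            # -, overlapping factor in (0, 1]
    SLA: float            # cm^2 g^-1, specific leaf area
    SRL: float            # cm g^-1, specific root length
    r1: float             # rooting-depth power law: depth = r1 * root^r2
    r2: float
    sr: float             # -, shoot:root ratio of biomass organs
    N_seed_meta: float    # m^-2 d^-1, external seed rain
    t_meta: int           # julian day at which seed rain starts
    t_em: int             # d, seed rain -> seedling emergence lag
    germ_pct: float       # -, germination probability
    h_min: float          # m, initial seedling height
    age_rep: float        # yr, age at which recruitment starts
    LLS: float            # d, leaf life span
    RLS: float            # d, root life span
    m_seed: float         # d^-1, seedling mortality rate
    m_basic: float        # yr^-1, mature-plant mortality rate
    life: str             # lifespan class ("perennial")
    p_max: float          # umol CO2 m^-2 s^-1, max gross leaf photosynthesis
    alpha: float          # umol CO2 / umol photons, light-response slope
    k: float              # -, light extinction coefficient
    m: float              # -, transmission coefficient
    WUE: float            # g ODM / kg H2O, water use efficiency
    CN_green: float       # -, C:N of green leaves
    CN_sen: float         # -, C:N of senescent leaves and roots
    N_fix: bool           # symbiotic N fixation flag (stored, inert)
    alloc_shoot: float    # -, NPP fraction allocated to shoot
    r_m: float            # d^-1, maintenance respiration rate
    r_g: float            # -, growth respiration factor
    N_seed_meta_mixture: float | None = None  # seed rain override in mixture

    def __post_init__(self) -> None:
        for name in _POSITIVE:
            if not getattr(self, name) > 0:
                raise TraitError(f"invalid trait value: {name}")
        for name in _UNIT_INTERVAL:
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise TraitError(f"invalid trait value: {name}")
        for name in _NON_NEGATIVE:
            if getattr(self, name) < 0:
                raise TraitError(f"invalid trait value: {name}")
        if not 0.0 < self.f_O <= 1.0:
            raise TraitError("invalid trait value: f_O")
        if self.CN_sen < self.CN_green:
            # Senescent tissue is N-depleted relative to green tissue.
            raise TraitError("invalid trait value: CN_sen")
        if self.h_min * 100.0 >= self.h_max:
            raise TraitError("invalid trait value: h_min")
        if self.N_seed_meta_mixture is not None and self.N_seed_meta_mixture < 0:
            raise TraitError("invalid trait value: N_seed_meta_mixture")

    @property
    def h_min_cm(self) -> float:
        return self.h_min * 100.0

    def seed_rain(self, mixture: bool = False) -> float:
        """Seed rain rate (m^-2 d^-1), using the mixture override if present."""
        if mixture and self.N_seed_meta_mixture is not None:
            return self.N_seed_meta_mixture
        return self.N_seed_meta

    def replace(self, **changes: object) -> "SpeciesTraits":
        return dataclasses.replace(self, **changes)


_REQUIRED_KEYS = frozenset(
    f.name for f in dataclasses.fields(SpeciesTraits)
    if f.name not in ("r1", "r2", "N_seed_meta_mixture")
) | {"rooting_depth_powerlaw"}


def load_species_traits(record: Mapping[str, object]) -> SpeciesTraits:
    """Build a validated :class:`SpeciesTraits` from a mapping.

    The rooting-depth coefficients come either as the ordered pair
    ``rooting_depth_powerlaw: [r1, r2]`` (the file convention) or as
    separate ``r1``/``r2`` keys.
    """
    rec = dict(record)
    if "rooting_depth_powerlaw" in rec:
        pair = rec.pop("rooting_depth_powerlaw")
        try:
            rec["r1"], rec["r2"] = (float(pair[0]), float(pair[1]))
        except (TypeError, IndexError) as exc:
            raise TraitError("invalid trait value: rooting_depth_powerlaw") from exc
    missing = _REQUIRED_KEYS - {"rooting_depth_powerlaw"} - set(rec)
    if missing:
        raise TraitError(f"incomplete trait set: missing {sorted(missing)}")
    field_names = {f.name for f in dataclasses.fields(SpeciesTraits)}
    unknown = set(rec) - field_names
    if unknown:
        raise TraitError(f"unknown trait fields: {sorted(unknown)}")
    kwargs: dict[str, object] = {}
    for f in dataclasses.fields(SpeciesTraits):
        if f.name not in rec:
            continue
        value = rec[f.name]
        if f.name in ("species", "life"):
            kwargs[f.name] = str(value)
        elif f.name == "N_fix":
            kwargs[f.name] = bool(value)
        elif f.name == "N_seed_meta_mixture":
            kwargs[f.name] = None if value is None else float(value)
        elif f.name in ("t_meta", "t_em"):
            kwargs[f.name] = int(value)
        else:
            try:
                kwargs[f.name] = float(value)  # type: ignore[arg-type]
            except (TypeError, ValueError) as exc:
                raise TraitError(f"invalid trait value: {f.name}") from exc
    return SpeciesTraits(**kwargs)  # type: ignore[arg-type]


def _traits_to_record(traits: SpeciesTraits) -> dict[str, object]:
    rec = dataclasses.asdict(traits)
    r1, r2 = rec.pop("r1"), rec.pop("r2")
    rec["rooting_depth_powerlaw"] = [r1, r2]
    return rec


def load_species_yaml(path: str | Path) -> SpeciesTraits:
    with open(path) as fh:
        return load_species_traits(yaml.safe_load(fh))


def save_species_yaml(traits: SpeciesTraits, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_traits_to_record(traits), fh, sort_keys=False)


_BUILTIN = {
    "Festuca pratensis": "festuca_pratensis.yaml",
    "Poa pratensis": "poa_pratensis.yaml",
    "Plantago lanceolata": "plantago_lanceolata.yaml",
}


def builtin_species_names() -> list[str]:
    return list(_BUILTIN)


def builtin_species(name: str) -> SpeciesTraits:
    """Load one of the three packaged species parameter sets."""
    try:
        fname = _BUILTIN[name]
    except KeyError:
        raise KeyError(f"unknown builtin species {name!r}; "
                       f"available: {sorted(_BUILTIN)}") from None
    ref = resources.files("grasspatch.data").joinpath(fname)
    return load_species_traits(yaml.safe_load(ref.read_text()))


def traits_to_frame(traits: Iterable[SpeciesTraits]) -> pd.DataFrame:
    """One row per species, one column per parameter (CSV export layout)."""
    rows = []
    for t in traits:
        rec = dataclasses.asdict(t)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("species")


# ---------------------------------------------------------------------------
# Bounded-vector encoding for the optimizers
# ---------------------------------------------------------------------------

#: The 16 traits handled by inverse parameterization.  The overlapping factor
#: f_O is predefined for grasses and only calibrated for forbs, so it is not
#: part of the default set; pass explicit bounds including "f_O" to free it.
CALIBRATABLE_TRAITS: tuple[str, ...] = (
    "hw", "f_s", "SLA", "SRL", "N_seed_meta", "age_rep", "LLS", "RLS",
    "m_seed", "p_max", "alpha", "k", "WUE", "CN_green", "CN_sen",
    "alloc_shoot",
)

_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "hw": (0.2, 3.0),
    "f_s": (1e-4, 3e-3),
    "f_O": (0.3, 1.0),
    "SLA": (50.0, 350.0),
    "SRL": (5e3, 2e5),
    "N_seed_meta": (100.0, 10_000.0),
    "age_rep": (0.01, 1.0),
    "LLS": (40.0, 400.0),
    "RLS": (60.0, 800.0),
    "m_seed": (0.005, 0.15),
    "p_max": (5.0, 45.0),
    "alpha": (0.02, 0.12),
    "k": (0.1, 1.2),
    "WUE": (1.0, 12.0),
    # non-overlapping so any draw keeps senescent tissue N-depleted
    "CN_green": (10.0, 30.0),
    "CN_sen": (30.0, 80.0),
    "alloc_shoot": (0.1, 0.9),
}


@dataclass(frozen=True)
class TraitBounds:
    """Ordered lower/upper bounds for the free (calibratable) traits.

    Traits not listed are fixed during calibration.
    """

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if not (len(self.names) == lower.size == upper.size):
            raise TraitError("bounds arrays must match the trait names")
        if not np.all(lower < upper):
            raise TraitError("each lower bound must be below its upper bound")
        valid = set(CALIBRATABLE_TRAITS) | {"f_O"}
        bad = [n for n in self.names if n not in valid]
        if bad:
            raise TraitError(f"traits not calibratable: {bad}")

    @classmethod
    def from_dict(cls, ranges: Mapping[str, tuple[float, float]]) -> "TraitBounds":
        names = tuple(ranges)
        lo = np.array([ranges[n][0] for n in names], dtype=float)
        hi = np.array([ranges[n][1] for n in names], dtype=float)
        return cls(names, lo, hi)

    def as_array(self) -> np.ndarray:
        """(D, 2) array of (lower, upper) rows."""
        return np.column_stack([self.lower, self.upper])

    def __len__(self) -> int:
        return len(self.names)


def default_bounds(names: Sequence[str] = CALIBRATABLE_TRAITS) -> TraitBounds:
    """Bounds spanning plausible temperate-grassland trait ranges."""
    return TraitBounds.from_dict({n: _DEFAULT_RANGES[n] for n in names})


def encode_free_parameters(traits: SpeciesTraits, bounds: TraitBounds) -> np.ndarray:
    """Map the calibratable subset of a trait set to a bounded real vector."""
    x = np.array([float(getattr(traits, n)) for n in bounds.names])
    _check_in_bounds(x, bounds)
    return x


def decode_free_parameters(
    x: np.ndarray, traits: SpeciesTraits, bounds: TraitBounds
) -> SpeciesTraits:
    """Inverse of :func:`encode_free_parameters`; fixed traits unchanged."""
    x = np.asarray(x, dtype=float)
    if x.shape != (len(bounds),):
        raise TraitError(
            f"parameter vector has length {x.size}, expected {len(bounds)}")
    _check_in_bounds(x, bounds)
    return traits.replace(**{n: float(v) for n, v in zip(bounds.names, x)})


def _check_in_bounds(x: np.ndarray, bounds: TraitBounds) -> None:
    if x.shape != (len(bounds),):
        raise TraitError(
            f"parameter vector has length {x.size}, expected {len(bounds)}")
    bad = np.flatnonzero((x < bounds.lower) | (x > bounds.upper))
    if bad.size:
        raise TraitError(
            f"out-of-bounds component: {bounds.names[bad[0]]}={x[bad[0]]}")
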