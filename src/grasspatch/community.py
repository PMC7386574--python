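"""The 1 m × 1 m patch community: daily loop, mowing, censuses, patterns.

The community holds all living plants in struct-of-arrays form (species
index, age, height, width, green/senescent shoot, root) plus the pending
seed cohorts and the soil bucket.  :func:`run_simulation` advances the
system one day at a time in a fixed process order:

    seed rain -> seedling emergence -> canopy light + photosynthesis with
    temperature/water/nitrogen limitation -> carbon balance and senescence
    -> intrinsic/starvation mortality -> crowding mortality -> soil water
    and nitrogen steps -> mowing (if scheduled) -> census (if scheduled)

Water and nitrogen limitation use the previous day's supply/demand ratios,
avoiding within-day iteration between plants and soil (one-day lag).

Censuses aggregate individuals into the vegetation attributes used for
calibration and evaluation: per-species aboveground biomass (summed shoot
pools per ground area), per-species cover (summed exclusive area), leaf
area index (summed leaf area over patch area) and vegetation height (the
tallest plant).  :func:`annual_aggregate` turns census series into annual
patterns (mean and intra-annual range per year).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .demography import (LitterFlux, crowding_step, emergence_step,
                         mortality_step)
from .environment import ClimateConfig, SoilState, generate_synthetic_climate
from .physiology import ODM_PER_CO2
from .traits import SpeciesTraits

__all__ = [
    "SimulationConfig",
    "Community",
    "CensusRecord",
    "PatternSeries",
    "MowingEvent",
    "SimulationResult",
    "run_simulation",
    "apply_mowing",
    "census",
    "annual_aggregate",
    "read_mowing_csv",
    "censuses_to_frame",
]

_QPI = 0.25 * np.pi


@dataclass(frozen=True)
class SimulationConfig:
    """Run settings for one patch simulation.

    ``mowing_days`` are (month, day) pairs applied every year;
    ``first_year_mowing`` optionally replaces them in the first simulated
    year (the establishment-year schedule of a freshly sown sward).
    Censuses default to the day before each mowing event;
    ``census_interval_days`` adds a regular vegetation census every that
    many days (e.g. 14 for the biweekly protocol common in grassland
    monitoring) on top of the pre-mowing censuses, restricted to the
    ``census_season_doy`` day-of-year window so every census falls inside
    the vegetated season (relative errors are undefined on a bare patch).
    ``census_skip_years`` drops all censuses from the first simulated
    years (the usual exclusion of the establishment phase from
    monitoring data).
    """

    years: int = 6
    start_year: int = 2003
    patch_area_cm2: float = 10_000.0
    mixture: bool = False
    mowing_days: tuple[tuple[int, int], ...] = ((6, 20), (9, 20))
    first_year_mowing: tuple[tuple[int, int], ...] | None = None
    cut_height_cm: float = 10.0
    census_lag_days: int = 1
    census_interval_days: int | None = None
    census_season_doy: tuple[int, int] = (160, 273)
    census_skip_years: int = 0
    seed_rain_duration: int = 120
    crowding_bias: str = "uniform"
    starvation_floor: float = 1e-4    # g green shoot below which a plant dies
    litter_fall_rate: float = 1.0 / 30.0
    odm_per_co2: float = ODM_PER_CO2
    t0_C: float = 0.0                 # temperature ramp of growth limitation
    t1_C: float = 10.0
    soil: SoilState = field(default_factory=SoilState)
    climate: ClimateConfig = field(default_factory=ClimateConfig)


class Community:
    """All living plants plus seed cohorts on one rectangular patch."""

    _GROW = 4096

    def __init__(
        self,
        traits_list: Sequence[SpeciesTraits],
        patch_area_cm2: float = 10_000.0,
        capacity: int = 4096,
    ) -> None:
        self.traits_list = list(traits_list)
        self.species_names = [t.species for t in self.traits_list]
        self.patch_area_cm2 = float(patch_area_cm2)
        ns = len(self.traits_list)
        if ns == 0:
            raise ValueError("at least one species required")

        def arr(f):
            return np.array([float(f(t)) for t in self.traits_list])

        # per-species parameter arrays indexed by the plants' species column
        self.p_sla = arr(lambda t: t.SLA)
        self.p_pmax = arr(lambda t: t.p_max)
        self.p_alpha = arr(lambda t: t.alpha)
        self.p_k = arr(lambda t: t.k)
        self.p_m = arr(lambda t: t.m)
        self.p_wue = arr(lambda t: t.WUE)
        self.p_cng = arr(lambda t: t.CN_green)
        self.p_cns = arr(lambda t: t.CN_sen)
        self.p_lls = arr(lambda t: t.LLS)
        self.p_rls = arr(lambda t: t.RLS)
        self.p_alloc = arr(lambda t: t.alloc_shoot)
        self.p_rm = arr(lambda t: t.r_m)
        self.p_rg = arr(lambda t: t.r_g)
        self.p_fs = arr(lambda t: t.f_s)
        self.p_hw = arr(lambda t: t.hw)
        self.p_hmax = arr(lambda t: t.h_max)
        self.p_fo = arr(lambda t: t.f_O)
        self.age_rep_days = arr(lambda t: t.age_rep * 365.0)
        self.m_seed_daily = arr(lambda t: t.m_seed)
        self.m_basic_daily = arr(lambda t: 1.0 - (1.0 - t.m_basic) ** (1 / 365))
        # seedling template per species
        h0 = arr(lambda t: t.h_min_cm)
        w0 = h0 / self.p_hw
        self.seedling_height = h0
        self.seedling_width = w0
        self.seedling_shoot = _QPI * self.p_fs * w0**2 * h0
        self.seedling_root = self.seedling_shoot / arr(lambda t: t.sr)
        self.seedling_excl = self.p_fo * _QPI * w0**2

        self.n = 0
        cap = max(capacity, 16)
        self.sp = np.zeros(cap, dtype=np.int64)
        self.age = np.zeros(cap)
        self.height = np.zeros(cap)
        self.width = np.zeros(cap)
        self.sg = np.zeros(cap)
        self.ss = np.zeros(cap)
        self.rt = np.zeros(cap)
        self.seed_cohorts: dict[int, np.ndarray] = defaultdict(
            lambda: np.zeros(ns, dtype=np.int64))

    # -- capacity ----------------------------------------------------------
    def _ensure(self, extra: int) -> None:
        need = self.n + extra
        cap = self.sp.size
        if need <= cap:
            return
        new = max(need, cap + self._GROW)
        for name in ("sp", "age", "height", "width", "sg", "ss", "rt"):
            old = getattr(self, name)
            grown = np.zeros(new, dtype=old.dtype)
            grown[: self.n] = old[: self.n]
            setattr(self, name, grown)

    # -- derived per-plant quantities -------------------------------------
    def cover_area(self) -> np.ndarray:
        return _QPI * self.width[: self.n] ** 2

    def exclusive_area(self) -> np.ndarray:
        return self.p_fo[self.sp[: self.n]] * self.cover_area()

    def leaf_area(self) -> np.ndarray:
        return self.p_sla[self.sp[: self.n]] * self.sg[: self.n]

    def occupied_area(self) -> float:
        return float(self.exclusive_area().sum())

    def total_plant_mass(self) -> float:
        n = self.n
        return float(self.sg[:n].sum() + self.ss[:n].sum() + self.rt[:n].sum())

    # -- membership --------------------------------------------------------
    def add_seedlings(self, species_index: int, count: int) -> float:
        """Append ``count`` identical seedlings; returns the mass added."""
        if count <= 0:
            return 0.0
        self._ensure(count)
        sl = slice(self.n, self.n + count)
        self.sp[sl] = species_index
        self.age[sl] = 0.0
        self.height[sl] = self.seedling_height[species_index]
        self.width[sl] = self.seedling_width[species_index]
        self.sg[sl] = self.seedling_shoot[species_index]
        self.ss[sl] = 0.0
        self.rt[sl] = self.seedling_root[species_index]
        self.n += count
        return count * (self.seedling_shoot[species_index]
                        + self.seedling_root[species_index])

    def remove(self, dead: np.ndarray) -> LitterFlux:
        """Drop plants where ``dead`` is True; their pools become litter."""
        n = self.n
        sp = self.sp[:n][dead]
        shoot = self.sg[:n][dead] + self.ss[:n][dead]
        root = self.rt[:n][dead]
        cns = self.p_cns[sp]
        flux = LitterFlux(
            above_mass=float(shoot.sum()),
            above_n=float((shoot / cns).sum()),
            below_mass=float(root.sum()),
            below_n=float((root / cns).sum()),
        )
        keep = ~dead
        m = int(keep.sum())
        for name in ("sp", "age", "height", "width", "sg", "ss", "rt"):
            a = getattr(self, name)
            a[:m] = a[:n][keep]
        self.n = m
        return flux


@dataclass
class CensusRecord:
    """One census of the patch, aggregated per species and community-wide."""

    date: pd.Timestamp
    species: tuple[str, ...]
    agb: np.ndarray          # g m^-2 per species (green + senescent shoot)
    cover: np.ndarray        # % of patch per species
    lai_species: np.ndarray  # per-species leaf area index
    lai: float               # community leaf area index
    height: float            # cm, tallest plant

    def __post_init__(self) -> None:
        if np.any(self.cover < 0) or np.any(self.cover > 100.0 + 1e-9):
            raise ValueError("cover must lie in [0, 100]")


def census(community: Community, date: pd.Timestamp | None = None) -> CensusRecord:
    """Aggregate the living plants into one census record."""
    n = community.n
    ns = len(community.species_names)
    patch = community.patch_area_cm2
    patch_m2 = patch / 1e4
    if n == 0:
        zero = np.zeros(ns)
        return CensusRecord(date, tuple(community.species_names),
                            zero, zero.copy(), zero.copy(), 0.0, 0.0)
    sp = community.sp[:n]
    shoot = community.sg[:n] + community.ss[:n]
    agb = np.bincount(sp, weights=shoot, minlength=ns) / patch_m2
    cover = 100.0 * np.bincount(sp, weights=community.exclusive_area(),
                                minlength=ns) / patch
    la = np.bincount(sp, weights=community.leaf_area(), minlength=ns)
    return CensusRecord(date, tuple(community.species_names), agb, cover,
                        la / patch, float(la.sum() / patch),
                        float(community.height[:n].max()))


def apply_mowing(community: Community, cut_height: float) -> float:
    """Cut every plant taller than ``cut_height`` cm down to it.

    Shoot pools scale with the retained height fraction (green and senescent
    equally); widths are unchanged.  Returns the harvested shoot mass (g).
    """
    if cut_height <= 0:
        raise ValueError("cut height must be positive")
    n = community.n
    if n == 0:
        return 0.0
    h = community.height[:n]
    tall = h > cut_height
    if not tall.any():
        return 0.0
    frac = cut_height / h[tall]
    removed = (community.sg[:n][tall] + community.ss[:n][tall]) * (1.0 - frac)
    community.sg[:n][tall] *= frac
    community.ss[:n][tall] *= frac
    community.height[:n][tall] = cut_height
    return float(removed.sum())


# ---------------------------------------------------------------------------
# Annual aggregation into vegetation patterns
# ---------------------------------------------------------------------------


@dataclass
class PatternSeries:
    """One vegetation attribute as an annual time series.

    ``mean`` is the mean of the within-year censuses; ``vmin``/``vmax`` the
    intra-annual range; ``census_values``/``census_dates`` keep the raw
    census-level series for calibration at sub-annual granularity.
    """

    pattern: str             # attribute id: "agb" | "lai" | "height" | "cover"
    subject: str             # species name or "community"
    years: np.ndarray
    mean: np.ndarray
    vmin: np.ndarray
    vmax: np.ndarray
    census_values: np.ndarray | None = None
    census_dates: tuple | None = None

    def values(self, granularity: str = "annual") -> np.ndarray:
        if granularity == "annual":
            return self.mean
        if granularity == "census":
            if self.census_values is None:
                raise ValueError("census-level values not available")
            return self.census_values
        raise ValueError(f"unknown granularity: {granularity}")


def annual_aggregate(
    censuses: Sequence[CensusRecord],
    species: Sequence[str] | None = None,
) -> dict[str, PatternSeries]:
    """Aggregate census records into annual pattern series.

    Returns a dict keyed ``"<attribute>:<subject>"`` with per-species AGB
    and cover, per-species and community LAI, and community height.  Every
    simulated year must contain at least one census.
    """
    if not censuses:
        raise ValueError("no census records to aggregate")
    species = list(species or censuses[0].species)
    years_all = np.array([c.date.year for c in censuses])
    years = np.unique(years_all)
    out: dict[str, PatternSeries] = {}

    def build(pattern: str, subject: str, vals: np.ndarray) -> None:
        mean = np.array([vals[years_all == y].mean() for y in years])
        vmin = np.array([vals[years_all == y].min() for y in years])
        vmax = np.array([vals[years_all == y].max() for y in years])
        out[f"{pattern}:{subject}"] = PatternSeries(
            pattern, subject, years, mean, vmin, vmax,
            census_values=vals,
            census_dates=tuple(c.date for c in censuses))

    for si, name in enumerate(species):
        build("agb", name, np.array([c.agb[si] for c in censuses]))
        build("cover", name, np.array([c.cover[si] for c in censuses]))
        build("lai", name, np.array([c.lai_species[si] for c in censuses]))
    build("agb", "community", np.array([c.agb.sum() for c in censuses]))
    build("cover", "community", np.array([c.cover.sum() for c in censuses]))
    build("lai", "community", np.array([c.lai for c in censuses]))
    build("height", "community", np.array([c.height for c in censuses]))
    return out


# ---------------------------------------------------------------------------
# The daily simulation loop
# ---------------------------------------------------------------------------


@dataclass
class MowingEvent:
    date: pd.Timestamp
    cut_height: float
    harvest: float           # g shoot removed from the patch
    pre_cut_shoot: float     # g shoot standing before the cut
    post_cut_shoot: float
    max_height_after: float


@dataclass
class SimulationResult:
    """Censuses plus full mass/water/N accounting of one run."""

    censuses: list[CensusRecord]
    mowing_events: list[MowingEvent]
    balance: dict[str, float]
    daily_occupied: np.ndarray       # cm² exclusive area after each day
    community: Community
    soil: SoilState
    discarded_seedlings: int

    def patterns(self) -> dict[str, PatternSeries]:
        return annual_aggregate(self.censuses)


def _schedule_flags(
    dates: pd.DatetimeIndex, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean mow/census flags per simulated day."""
    mow = np.zeros(len(dates), dtype=bool)
    first_year = dates[0].year
    for i, d in enumerate(dates):
        days = (config.first_year_mowing
                if (config.first_year_mowing is not None
                    and d.year == first_year)
                else config.mowing_days)
        if (d.month, d.day) in days:
            mow[i] = True
    cens = np.zeros_like(mow)
    idx = np.flatnonzero(mow)
    cidx = idx - config.census_lag_days
    cens[cidx[cidx >= 0]] = True
    cens |= _interval_census_flags(dates, config)
    _apply_census_skip(cens, dates, config)
    return mow, cens


def _interval_census_flags(
    dates: pd.DatetimeIndex, config: SimulationConfig
) -> np.ndarray:
    """Regular in-season censuses every ``census_interval_days`` days."""
    flags = np.zeros(len(dates), dtype=bool)
    if config.census_interval_days:
        step = int(config.census_interval_days)
        lo, hi = config.census_season_doy
        doy = dates.dayofyear.to_numpy()
        flags[(doy >= lo) & (doy <= hi) & ((doy - lo) % step == 0)] = True
    return flags


def _apply_census_skip(
    cens: np.ndarray, dates: pd.DatetimeIndex, config: SimulationConfig
) -> None:
    """Remove censuses in the first ``census_skip_years`` simulated years."""
    if config.census_skip_years:
        cutoff = dates[0].year + config.census_skip_years
        cens[dates.year.to_numpy() < cutoff] = False


def run_simulation(
    traits_list: Sequence[SpeciesTraits],
    config: SimulationConfig | None = None,
    climate: pd.DataFrame | None = None,
    mowing: pd.DataFrame | None = None,
    seed: int = 0,
    seed_rain_override: Mapping[str, float] | None = None,
) -> SimulationResult:
    """Simulate the patch over the climate span; reproducible under ``seed``.

    ``climate`` defaults to a synthetic driver generated from the config
    (seeded by ``seed``, so pass an explicit frame to share weather across
    replicates).  ``mowing`` may override the configured schedule with an
    explicit ``date,cut_height_cm`` frame.  ``seed_rain_override`` maps
    species names to seed-rain rates (m⁻² d⁻¹), e.g. for mixture designs.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    if climate is None:
        climate = generate_synthetic_climate(
            config.climate, config.years, seed=seed,
            start_year=config.start_year)
    dates = pd.DatetimeIndex(climate["date"])
    if dates.size == 0 or (dates[1:] - dates[:-1] != pd.Timedelta("1D")).any():
        raise ValueError("missing driver: climate must cover consecutive days")
    tmean = climate["tmean"].to_numpy(float)
    par = climate["par"].to_numpy(float)
    daylength = climate["daylength"].to_numpy(float)
    precip = climate["precip"].to_numpy(float)
    pet = climate["pet"].to_numpy(float)
    doy = dates.dayofyear.to_numpy()
    ndays = len(dates)

    if mowing is not None:
        mow = np.zeros(ndays, dtype=bool)
        cut_heights = np.full(ndays, config.cut_height_cm)
        pos = dates.get_indexer(pd.to_datetime(mowing["date"]))
        if (pos < 0).any():
            raise ValueError("mowing date outside the simulated span")
        mow[pos] = True
        cut_heights[pos] = mowing["cut_height_cm"].to_numpy(float)
        cens_flags = np.zeros(ndays, dtype=bool)
        cidx = pos - config.census_lag_days
        cens_flags[cidx[cidx >= 0]] = True
        cens_flags |= _interval_census_flags(dates, config)
        _apply_census_skip(cens_flags, dates, config)
    else:
        mow, cens_flags = _schedule_flags(dates, config)
        cut_heights = np.full(ndays, config.cut_height_cm)

    com = Community(traits_list, config.patch_area_cm2)
    ns = len(com.traits_list)
    soil0 = config.soil
    rates = np.array([
        (seed_rain_override or {}).get(
            t.species, t.seed_rain(config.mixture)) * t.germ_pct
        * (config.patch_area_cm2 / 1e4)
        for t in com.traits_list])
    t_meta = np.array([t.t_meta for t in com.traits_list])
    t_em = np.array([t.t_em for t in com.traits_list])

    # all seed-rain Poisson draws up front (per species, vectorized), and
    # emergence counts scheduled into a day-by-species table
    sched = np.zeros((ndays + int(t_em.max()) + 1, ns), dtype=np.int64)
    for s in range(ns):
        window = np.flatnonzero(
            (doy >= t_meta[s]) & (doy < t_meta[s] + config.seed_rain_duration))
        if window.size and rates[s] > 0:
            sched[window + t_em[s], s] = rng.poisson(rates[s], window.size)

    # precomputed daily limitation/irradiance drivers
    f_temp_arr = np.clip((tmean - config.t0_C) / (config.t1_C - config.t0_C),
                         0.0, 1.0)
    with np.errstate(divide="ignore"):
        par_umol_arr = np.where(daylength > 0,
                                par * 1e6 / (daylength * 3600.0), 0.0)

    # soil buckets as plain floats inside the loop (same math as the
    # environment-module step functions, which the tests pin)
    water = soil0.water
    capacity = soil0.water_capacity
    mineral_n = soil0.mineral_N
    la_m, la_n = soil0.litter_above
    lb_m, lb_n = soil0.litter_below
    minrate = soil0.mineralization_rate
    ndep = soil0.n_deposition
    pet_share = soil0.pet_soil_share

    f_water = 1.0
    f_n = 1.0
    c_gpp = c_resp = c_lit_a = c_lit_b = c_lit_an = c_lit_bn = 0.0
    c_harvest = c_seed_in = 0.0
    c_precip = c_evap = c_drain = c_wsup = 0.0
    c_ndep = c_nsup = c_nlit = 0.0
    daily_occupied = np.zeros(ndays)
    censuses: list[CensusRecord] = []
    mow_events: list[MowingEvent] = []
    discarded = 0
    single_species = ns == 1

    for i in range(ndays):
        # (a) recruitment: seedling emergence of scheduled cohorts
        due = sched[i]
        total_due = int(due.sum())
        if total_due:
            if single_species:
                free = com.patch_area_cm2 - com.occupied_area()
                est = min(total_due,
                          max(0, int(free / com.seedling_excl[0] + 1e-9)))
                com.add_seedlings(0, est)
                discarded += total_due - est
                c_seed_in += est * (com.seedling_shoot[0]
                                    + com.seedling_root[0])
            else:
                n0 = com.n
                est, disc = emergence_step(com, due, rng)
                discarded += disc
                if est:
                    counts = np.bincount(com.sp[n0:com.n], minlength=ns)
                    c_seed_in += float(
                        counts @ (com.seedling_shoot + com.seedling_root))

        # (c)-(d) growth: light competition, photosynthesis, carbon balance
        (gpp_lim, resp, lit_am, lit_an, lit_bm, lit_bn, wdem, ndem) = \
            _kernels.day_step(
                com.sp, com.age, com.height, com.width, com.sg, com.ss,
                com.rt, com.n,
                com.p_sla, com.p_pmax, com.p_alpha, com.p_k, com.p_m,
                com.p_wue, com.p_cng, com.p_cns, com.p_lls, com.p_rls,
                com.p_alloc, com.p_rm, com.p_rg, com.p_fs, com.p_hw,
                com.p_hmax,
                par_umol_arr[i], daylength[i], f_temp_arr[i], f_water, f_n,
                config.patch_area_cm2, config.odm_per_co2,
                config.litter_fall_rate)
        c_gpp += gpp_lim
        c_resp += resp

        # (b) senescence-driven mortality, starvation, crowding
        litter = mortality_step(com, rng, config.starvation_floor)
        litter += crowding_step(com, rng, config.crowding_bias)
        lit_am += litter.above_mass
        lit_an += litter.above_n
        lit_bm += litter.below_mass
        lit_bn += litter.below_n
        c_lit_a += lit_am
        c_lit_b += lit_bm
        c_lit_an += lit_an
        c_lit_bn += lit_bn

        # soil water bucket
        evap = min(pet_share * pet[i], water)
        water += precip[i] - evap
        wsup = wdem if wdem < water else water
        water -= wsup
        drain = water - capacity
        if drain > 0.0:
            water -= drain
        else:
            drain = 0.0
        c_precip += precip[i]
        c_evap += evap
        c_wsup += wsup
        c_drain += drain
        # soil nitrogen bucket
        la_m += lit_am
        la_n += lit_an
        lb_m += lit_bm
        lb_n += lit_bn
        mineralized = minrate * (la_n + lb_n)
        la_m *= 1.0 - minrate
        la_n *= 1.0 - minrate
        lb_m *= 1.0 - minrate
        lb_n *= 1.0 - minrate
        mineral_n += mineralized + ndep
        nsup = ndem if ndem < mineral_n else mineral_n
        mineral_n -= nsup
        c_ndep += ndep
        c_nsup += nsup
        c_nlit += lit_an + lit_bn
        f_water = min(1.0, wsup / wdem) if wdem > 1e-12 else 1.0
        f_n = min(1.0, nsup / ndem) if ndem > 1e-12 else 1.0

        # management and observation
        if mow[i]:
            pre = float(com.sg[:com.n].sum() + com.ss[:com.n].sum())
            harvest = apply_mowing(com, cut_heights[i])
            post = float(com.sg[:com.n].sum() + com.ss[:com.n].sum())
            c_harvest += harvest
            hmax = float(com.height[:com.n].max()) if com.n else 0.0
            mow_events.append(MowingEvent(dates[i], cut_heights[i], harvest,
                                          pre, post, hmax))
        if cens_flags[i]:
            censuses.append(census(com, dates[i]))
        daily_occupied[i] = com.occupied_area()

    soil = SoilState(water=water, water_capacity=capacity,
                     mineral_N=mineral_n, litter_above=(la_m, la_n),
                     litter_below=(lb_m, lb_n), mineralization_rate=minrate,
                     n_deposition=ndep, pet_soil_share=pet_share)
    bal = {
        "plant_mass_initial": 0.0,
        "plant_mass_final": com.total_plant_mass(),
        "gpp_lim": c_gpp, "respiration": c_resp,
        "litter_above": c_lit_a, "litter_below": c_lit_b,
        "litter_above_n": c_lit_an, "litter_below_n": c_lit_bn,
        "harvest": c_harvest, "seed_mass_in": c_seed_in,
        "soil_water_initial": soil0.water, "soil_water_final": water,
        "water_precip": c_precip, "water_evaporation": c_evap,
        "water_drainage": c_drain, "water_supply": c_wsup,
        "soil_n_initial": (soil0.mineral_N + soil0.litter_above[1]
                           + soil0.litter_below[1]),
        "soil_n_final": mineral_n + la_n + lb_n,
        "n_deposition": c_ndep, "n_supply": c_nsup, "n_litter_in": c_nlit,
    }
    return SimulationResult(censuses, mow_events, bal, daily_occupied,
                            com, soil, discarded)


def read_mowing_csv(path: str | Path) -> pd.DataFrame:
    """Mowing schedule CSV with columns ``date,cut_height_cm``."""
    df = pd.read_csv(path)
    missing = {"date", "cut_height_cm"} - set(df.columns)
    if missing:
        raise ValueError(f"mowing CSV missing columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    return df


def censuses_to_frame(censuses: Sequence[CensusRecord]) -> pd.DataFrame:
    """Long-format census table: one row per census and species."""
    rows = []
    for c in censuses:
        for si, name in enumerate(c.species):
            rows.append({
                "date": c.date, "species": name,
                "agb_g_m2": c.agb[si], "cover_pct": c.cover[si],
                "lai": c.lai_species[si], "height_cm": c.height,
            })
    return pd.DataFrame(rows)
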