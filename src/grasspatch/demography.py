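"""Recruitment, mortality and space-limited crowding (self-thinning).

Recruitment is driven by external seed rain from the surrounding landscape:
within a seasonal window starting at the species' julian day ``t_meta``, a
Poisson number of germinating seeds arrives each day and emerges as
seedlings after the species' emergence lag.  Seedlings establish only while
the summed exclusive ground area of the patch has room; surplus recruits
are discarded.

Mortality has three components, all stochastic or threshold-based:
intrinsic daily mortality (seedling rate below the recruitment age,
compounded annual rate above), starvation (green shoot below a floor), and
crowding — whenever the plants' summed exclusive area exceeds the patch
area, victims are removed one at a time (uniformly at random by default)
until the community fits again.  All biomass leaving the living pool goes
to the above/belowground litter fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .community import Community
    from .traits import SpeciesTraits

__all__ = [
    "SeedCohort",
    "LitterFlux",
    "seed_rain_step",
    "emergence_step",
    "mortality_step",
    "crowding_step",
    "daily_mortality_probability",
]


@dataclass
class SeedCohort:
    """Seeds of one species germinating together on a future day."""

    species_id: str
    count: int
    emergence_day: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("cohort count must be >= 0")


@dataclass
class LitterFlux:
    """Daily litter transfer (g ODM mass, g N) above and below ground."""

    above_mass: float = 0.0
    above_n: float = 0.0
    below_mass: float = 0.0
    below_n: float = 0.0

    def __iadd__(self, other: "LitterFlux") -> "LitterFlux":
        self.above_mass += other.above_mass
        self.above_n += other.above_n
        self.below_mass += other.below_mass
        self.below_n += other.below_n
        return self


def daily_mortality_probability(age_days: float, traits: "SpeciesTraits") -> float:
    """Daily death probability: seedling rate below the recruitment age,
    compounded annual mature rate above (``1-(1-m_basic)^(1/365)``)."""
    if age_days < traits.age_rep * 365.0:
        return traits.m_seed
    return 1.0 - (1.0 - traits.m_basic) ** (1.0 / 365.0)


def seed_rain_step(
    day: int,
    traits: "SpeciesTraits",
    rng: np.random.Generator,
    seed_rain_duration: int = 120,
    patch_area_m2: float = 1.0,
    mixture: bool = False,
    seed_rain_override: float | None = None,
) -> SeedCohort | None:
    """Poisson seed arrival for one species on julian day ``day``.

    The expected count is seed rain × germination probability × patch area;
    ``emergence_day`` is the julian day plus the species' emergence lag.
    Returns ``None`` outside the seed-rain window.
    """
    if not traits.t_meta <= day < traits.t_meta + seed_rain_duration:
        return None
    rate = seed_rain_override if seed_rain_override is not None \
        else traits.seed_rain(mixture)
    count = int(rng.poisson(rate * traits.germ_pct * patch_area_m2))
    return SeedCohort(traits.species, count, day + traits.t_em)


def emergence_step(
    community: "Community",
    due_counts: np.ndarray,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Establish due seedlings while exclusive area fits the patch.

    ``due_counts[s]`` is the number of seedlings of species ``s`` emerging
    today.  Candidates of all species are admitted in random order until
    the cumulative exclusive area (existing plants plus admitted seedlings)
    would exceed the patch; the rest are discarded.

    Returns (established, discarded).
    """
    total = int(due_counts.sum())
    if total == 0:
        return 0, 0
    free = community.patch_area_cm2 - community.occupied_area()
    seq = np.repeat(np.arange(due_counts.size), due_counts)
    rng.shuffle(seq)
    cum = np.cumsum(community.seedling_excl[seq])
    n_admit = int(np.searchsorted(cum, free, side="right"))
    if n_admit:
        admitted = np.bincount(seq[:n_admit], minlength=due_counts.size)
        for s, c in enumerate(admitted):
            if c:
                community.add_seedlings(s, int(c))
    return n_admit, total - n_admit


def mortality_step(
    community: "Community",
    rng: np.random.Generator,
    starvation_floor: float = 1e-4,
) -> LitterFlux:
    """Intrinsic and starvation mortality; dead plants become litter."""
    n = community.n
    if n == 0:
        return LitterFlux()
    sp = community.sp[:n]
    p = np.where(community.age[:n] < community.age_rep_days[sp],
                 community.m_seed_daily[sp], community.m_basic_daily[sp])
    dead = rng.random(n) < p
    dead |= community.sg[:n] < starvation_floor
    if not dead.any():
        return LitterFlux()
    return community.remove(dead)


def crowding_step(
    community: "Community",
    rng: np.random.Generator,
    bias: str = "uniform",
) -> LitterFlux:
    """Self-thinning: remove plants until exclusive area fits the patch.

    Victims fall one at a time, uniformly at random (``bias="uniform"``) or
    with probability inversely proportional to exclusive area
    (``bias="inverse_size"``, favouring small plants).  Sequential removal
    is realized by an exponential-race ordering, which is distributionally
    identical and vectorizes.
    """
    n = community.n
    if n == 0:
        return LitterFlux()
    excl = community.exclusive_area()
    total = float(excl.sum())
    if total <= community.patch_area_cm2:
        return LitterFlux()
    if bias == "uniform":
        order = rng.permutation(n)
    elif bias == "inverse_size":
        keys = rng.exponential(size=n) * excl  # rate 1/excl
        order = np.argsort(keys)
    else:
        raise ValueError(f"unknown crowding bias: {bias}")
    cum = np.cumsum(excl[order])
    j = int(np.searchsorted(cum, total - community.patch_area_cm2, "left")) + 1
    dead = np.zeros(n, dtype=bool)
    dead[order[:j]] = True
    return community.remove(dead)
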