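"""Replicate-averaged model evaluation and synthetic observations.

Because plant mortality is stochastic, model output is evaluated on the
mean of replicated simulations (the census values are averaged across
replicates first, then aggregated to annual series).  Simulated annual
values are compared with observations by ordinary least squares
(``sim = intercept + slope * obs``), the coefficient of determination, and
the normalized root mean square error; for cross-attribute overviews both
sides are divided by their joint per-pattern maximum.  Species mixtures
are compared against monocultures via relative yields (mixture value over
monoculture value; 0.5 is the equal-partition expectation in a two-species
mixture).

The synthetic-observation generator closes the loop for parameter-recovery
studies: it simulates with known "true" traits, aggregates to patterns and
multiplies annual values by lognormal noise of a stated coefficient of
variation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community import (CensusRecord, PatternSeries, SimulationConfig,
                        annual_aggregate, run_simulation)
from .traits import SpeciesTraits

__all__ = [
    "EvaluationResult",
    "run_replicates",
    "regression_eval",
    "normalize_by_max",
    "relative_yield",
    "generate_synthetic_observations",
    "summarize_patterns",
    "ten_patterns",
    "TEN_PATTERN_IDS",
]


@dataclass(frozen=True)
class EvaluationResult:
    """OLS regression of simulated on observed values plus nrmse."""

    slope: float
    intercept: float
    r2: float
    nrmse: float     # percent
    n: int

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r2 <= 1.0 + 1e-9:
            raise ValueError("R² must lie in [0, 1]")
        if self.n < 2:
            raise ValueError("regression needs at least two points")


def regression_eval(sim: np.ndarray, obs: np.ndarray) -> EvaluationResult:
    """OLS of sim on obs; R² is the squared Pearson correlation."""
    from .calibration import nrmse as _nrmse

    sim = np.asarray(sim, float)
    obs = np.asarray(obs, float)
    if sim.shape != obs.shape or sim.size < 2:
        raise ValueError("need two equally long series of length >= 2")
    if np.ptp(obs) == 0:
        raise ValueError("degenerate regression: observations are constant")
    fit = stats.linregress(obs, sim)
    return EvaluationResult(float(fit.slope), float(fit.intercept),
                            float(fit.rvalue**2), _nrmse(sim, obs), sim.size)


def run_replicates(
    traits_list: Sequence[SpeciesTraits],
    config: SimulationConfig,
    n: int = 100,
    seed: int = 0,
    climate: pd.DataFrame | None = None,
    **run_kwargs,
) -> tuple[dict[str, PatternSeries], dict[str, np.ndarray]]:
    """Mean patterns over ``n`` independent replicate simulations.

    All replicates share the climate driver (generated once from ``seed``
    when not provided) and differ only in the demographic random stream.
    Census values are averaged across replicates before annual aggregation.
    Returns (mean patterns, per-year standard deviation of the annual
    means across replicates).
    """
    if n < 1:
        raise ValueError("need at least one replicate")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n + 1)
    if climate is None:
        from .environment import generate_synthetic_climate
        climate = generate_synthetic_climate(
            config.climate, config.years,
            seed=int(children[0].generate_state(1)[0] % 2**31),
            start_year=config.start_year)
    mean_censuses: list[CensusRecord] | None = None
    annual_means: dict[str, list[np.ndarray]] = {}
    for r in range(n):
        rep_seed = int(children[r + 1].generate_state(1)[0] % 2**31)
        result = run_simulation(traits_list, config, climate=climate,
                                seed=rep_seed, **run_kwargs)
        cens = result.censuses
        if mean_censuses is None:
            mean_censuses = [
                CensusRecord(c.date, c.species, c.agb / n, c.cover / n,
                             c.lai_species / n, c.lai / n, c.height / n)
                for c in cens]
        else:
            for acc, c in zip(mean_censuses, cens):
                acc.agb += c.agb / n
                acc.cover += c.cover / n
                acc.lai_species += c.lai_species / n
                acc.lai += c.lai / n
                acc.height += c.height / n
        for key, series in annual_aggregate(cens).items():
            annual_means.setdefault(key, []).append(series.mean)
    assert mean_censuses is not None
    patterns = annual_aggregate(mean_censuses)
    spread = {key: np.std(np.stack(v), axis=0, ddof=0)
              for key, v in annual_means.items()}
    return patterns, spread


def normalize_by_max(
    sim_patterns: Mapping[str, np.ndarray],
    obs_patterns: Mapping[str, np.ndarray],
    groups: Mapping[str, Sequence[str]],
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Divide each pattern group by the joint max of sim and obs.

    ``groups`` maps a group label (e.g. an attribute) to the pattern keys
    normalized together; the joint maximum over observed and simulated
    values of all keys in a group maps to 1.
    """
    sim_out: dict[str, np.ndarray] = {}
    obs_out: dict[str, np.ndarray] = {}
    for label, keys in groups.items():
        mx = max(float(np.max(sim_patterns[k])) for k in keys)
        mx = max(mx, max(float(np.max(obs_patterns[k])) for k in keys))
        if mx <= 0:
            raise ValueError(f"all-zero pattern group: {label}")
        for k in keys:
            sim_out[k] = np.asarray(sim_patterns[k], float) / mx
            obs_out[k] = np.asarray(obs_patterns[k], float) / mx
    return sim_out, obs_out


def relative_yield(
    mixture: PatternSeries, monoculture: PatternSeries
) -> PatternSeries:
    """Per-year ratio of a species' attribute in mixture to its monoculture.

    A value of 1 means the species performs as in monoculture; 0.5 is the
    equal-partition expectation in a two-species mixture.
    """
    if not np.array_equal(mixture.years, monoculture.years):
        raise ValueError("mixture and monoculture years are not aligned")
    if np.any(monoculture.mean <= 0):
        raise ValueError("zero monoculture value: relative yield undefined")
    ratio = mixture.mean / monoculture.mean
    return PatternSeries(
        pattern=f"ry_{mixture.pattern}", subject=mixture.subject,
        years=mixture.years.copy(), mean=ratio,
        vmin=mixture.vmin / np.maximum(monoculture.vmin, 1e-300)
        if np.all(monoculture.vmin > 0) else ratio.copy(),
        vmax=mixture.vmax / np.maximum(monoculture.vmax, 1e-300)
        if np.all(monoculture.vmax > 0) else ratio.copy(),
    )


def _lognormal_factors(cv: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size))


def generate_synthetic_observations(
    traits_list: Sequence[SpeciesTraits],
    config: SimulationConfig,
    cv: float = 0.0,
    seed: int = 0,
    replicates: int = 8,
    climate: pd.DataFrame | None = None,
) -> tuple[dict[str, PatternSeries], dict[str, object]]:
    """Self-generated observations from known traits, with optional noise.

    Simulates ``replicates`` runs with the given ("true") traits, averages
    and aggregates to annual patterns, and multiplies every annual value by
    mean-one lognormal noise with coefficient of variation ``cv``.  Returns
    the noisy patterns and a record of the truth (traits, seed, cv).
    """
    if cv < 0:
        raise ValueError("noise CV must be >= 0")
    patterns, _ = run_replicates(traits_list, config, n=replicates,
                                 seed=seed, climate=climate)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
    noisy: dict[str, PatternSeries] = {}
    for key, series in patterns.items():
        if cv == 0:
            noisy[key] = series
            continue
        factors = _lognormal_factors(cv, series.mean.size, rng)
        census_values = None
        if series.census_values is not None:
            cfactors = _lognormal_factors(cv, series.census_values.size, rng)
            census_values = series.census_values * cfactors
        noisy[key] = PatternSeries(
            series.pattern, series.subject, series.years.copy(),
            series.mean * factors, series.vmin * factors,
            series.vmax * factors, census_values, series.census_dates)
    truth = {"traits": list(traits_list), "seed": seed, "cv": cv,
             "replicates": replicates}
    return noisy, truth


#: canonical ids of the ten vegetation patterns of the three-species setup:
#: monoculture AGB/LAI/height/cover (i-iv), mixture community LAI and height
#: (v-vi), per-species AGB and cover in the mixture (vii-viii), and relative
#: yields of AGB and cover (ix-x).
TEN_PATTERN_IDS = ("i", "ii", "iii", "iv", "v", "vi", "vii", "viii", "ix", "x")


def ten_patterns(
    mono_patterns: Mapping[str, Mapping[str, PatternSeries]],
    mixture_patterns: Mapping[str, PatternSeries],
    mixture_species: Sequence[str],
) -> dict[str, dict[str, PatternSeries]]:
    """Assemble the canonical ten vegetation patterns.

    ``mono_patterns`` maps each species name to its monoculture pattern set
    (from :func:`~grasspatch.community.annual_aggregate`);
    ``mixture_patterns`` is the aggregate of the mixture run and
    ``mixture_species`` names its two members.  Returns a dict keyed by the
    roman-numeral pattern id, each holding subject -> series.
    """
    mono_species = list(mono_patterns)
    out: dict[str, dict[str, PatternSeries]] = {
        "i": {s: mono_patterns[s][f"agb:{s}"] for s in mono_species},
        "ii": {s: mono_patterns[s][f"lai:{s}"] for s in mono_species},
        "iii": {s: mono_patterns[s]["height:community"] for s in mono_species},
        "iv": {s: mono_patterns[s][f"cover:{s}"] for s in mono_species},
        "v": {"community": mixture_patterns["lai:community"]},
        "vi": {"community": mixture_patterns["height:community"]},
        "vii": {s: mixture_patterns[f"agb:{s}"] for s in mixture_species},
        "viii": {s: mixture_patterns[f"cover:{s}"] for s in mixture_species},
    }
    out["ix"] = {s: relative_yield(mixture_patterns[f"agb:{s}"],
                                   mono_patterns[s][f"agb:{s}"])
                 for s in mixture_species}
    out["x"] = {s: relative_yield(mixture_patterns[f"cover:{s}"],
                                  mono_patterns[s][f"cover:{s}"])
                for s in mixture_species}
    return out


def summarize_patterns(
    patterns: Mapping[str, PatternSeries]
) -> pd.DataFrame:
    """Descriptive summary: per pattern, the mean of annual means and the
    average intra-annual minimum/maximum across years."""
    rows = []
    for key, s in patterns.items():
        rows.append({
            "pattern": s.pattern, "subject": s.subject,
            "mean_of_annual_means": float(s.mean.mean()),
            "avg_annual_min": float(s.vmin.mean()),
            "avg_annual_max": float(s.vmax.mean()),
            "n_years": int(s.years.size),
        })
    return pd.DataFrame(rows)
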