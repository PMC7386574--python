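"""Numba-compiled inner kernels of the daily simulation step.

The scalar kernels (`gpp_area`, `carbon_scalar`, `dims_update`) hold the
single authoritative formulation of leaf-level photosynthesis integration,
the plant carbon balance and the cylinder geometry update; both the
module-level scalar APIs and the fused per-day vector kernel call them, so
there is one source of truth for each formula.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: one more than the tallest supported plant (cm); canopy layers are 1 cm.
MAX_LAYERS = 201


@njit(cache=False)
def gpp_area(i_top: float, lai_ind: float, pmax: float, alpha: float,
             k: float, m: float) -> float:
    """Gross photosynthesis per m² covered ground (µmol CO₂ m⁻² s⁻¹).

    Closed-form vertical integral of the saturating leaf light response over
    the plant's own leaf area index under Beer–Lambert self-shading with
    extinction ``k`` and transmission ``m``.
    """
    if lai_ind <= 0.0 or i_top <= 0.0:
        return 0.0
    aki = alpha * k * i_top
    pm1 = pmax * (1.0 - m)
    return (pmax / k) * np.log((aki + pm1) / (aki * np.exp(-k * lai_ind) + pm1))


@njit(cache=False)
def dims_update(shoot_total: float, width: float, fs: float, hw: float,
                hmax: float) -> tuple[float, float]:
    """(height, width) after a shoot-pool change; widths never shrink."""
    if shoot_total <= 0.0:
        return 0.0, 0.0
    c = 0.25 * np.pi * fs
    iso_w = (shoot_total / (c * hw)) ** (1.0 / 3.0)
    if iso_w >= width:
        h = hw * iso_w
        if h > hmax:
            return hmax, np.sqrt(shoot_total / (c * hmax))
        return h, iso_w
    h = shoot_total / (c * width * width)
    if h > hmax:
        return hmax, np.sqrt(shoot_total / (c * hmax))
    return h, width


@njit(cache=False)
def carbon_scalar(sg: float, ss: float, rt: float, gpp_lim: float,
                  lls: float, rls: float, alloc: float, rm: float, rg: float,
                  litter_fall_rate: float
                  ) -> tuple[float, float, float, float, float, float, float]:
    """One day of a plant's carbon balance.

    Maintenance respiration on green shoot + root; growth respiration as a
    fraction of the surplus; NPP split between shoot and root; green shoot
    yellows at 1/LLS into the senescent pool, which sheds to aboveground
    litter at the litter fall rate; roots turn over at 1/RLS.  A negative
    balance shrinks green shoot and root proportionally instead of growing.

    Returns (sg, ss, rt, npp, respiration, litter_above, litter_below).
    """
    rm_total = rm * (sg + rt)
    if gpp_lim >= rm_total:
        npp = (1.0 - rg) * (gpp_lim - rm_total)
        resp = gpp_lim - npp
        sg += alloc * npp
        rt += (1.0 - alloc) * npp
    else:
        npp = 0.0
        deficit = rm_total - gpp_lim
        pool = sg + rt
        shrink = deficit if deficit < pool else pool
        if pool > 0.0:
            sg -= shrink * sg / pool
            rt -= shrink * rt / pool
        resp = gpp_lim + shrink
    sen = sg / lls
    sg -= sen
    ss += sen
    fall = ss * litter_fall_rate
    ss -= fall
    rl = rt / rls
    rt -= rl
    return sg, ss, rt, npp, resp, fall, rl


@njit(cache=False)
def canopy_attenuation(sp, height, sg, n, sla, kext, patch_area_cm2):
    """k-weighted leaf area above each 1-cm canopy layer.

    Each plant's leaf area is spread uniformly over its own height; the
    returned array ``above`` holds, at index z, the summed ``k * leaf_area``
    of all layers at height >= z cm, divided by patch area (i.e. the optical
    depth seen looking up from z).
    """
    diff = np.zeros(MAX_LAYERS + 1)
    for i in range(n):
        la = sla[sp[i]] * sg[i]
        h = height[i]
        if la > 0.0 and h > 0.0:
            t = int(np.ceil(h))
            if t < 1:
                t = 1
            if t > MAX_LAYERS:
                t = MAX_LAYERS
            d = kext[sp[i]] * la / t
            diff[0] += d
            diff[t] -= d
    above = np.zeros(MAX_LAYERS + 1)
    cum = np.zeros(MAX_LAYERS + 1)
    run = 0.0
    for z in range(MAX_LAYERS + 1):
        run += diff[z]
        cum[z] = run
    s = 0.0
    for z in range(MAX_LAYERS, -1, -1):
        s += cum[z]
        above[z] = s / patch_area_cm2
    return above


@njit(cache=False)
def day_step(sp, age, height, width, sg, ss, rt, n,
             sla, pmax, alpha, kext, mtrans, wue, cng, cns,
             lls, rls, alloc, rm, rg, fs, hw, hmax,
             par_umol, daylength_h, f_temp, f_water, f_n,
             patch_area_cm2, odm_per_co2, litter_fall_rate):
    """Fused daily physiology update for all plants (in place).

    Computes the canopy light profile, each plant's gross photosynthesis
    (closed form at the irradiance reaching its top), applies the
    multiplicative temperature/water/nitrogen limitation, runs the carbon
    balance and geometry update, and increments ages.

    Returns community totals:
    (gpp_lim, respiration, litter_above_mass, litter_above_N,
     litter_below_mass, litter_below_N, water_demand_mm, n_demand_g).
    """
    above = canopy_attenuation(sp, height, sg, n, sla, kext, patch_area_cm2)
    seconds = daylength_h * 3600.0
    # µmol CO2 -> g CO2 -> g ODM, per cm² of covered ground
    conv = seconds * 44.0e-6 * odm_per_co2 * 1e-4
    flim = f_temp * f_water * f_n
    gpp_sum = 0.0
    resp_sum = 0.0
    lit_am = 0.0
    lit_an = 0.0
    lit_bm = 0.0
    lit_bn = 0.0
    wdem = 0.0
    ndem = 0.0
    for i in range(n):
        s_ = sp[i]
        la = sla[s_] * sg[i]
        ca = 0.25 * np.pi * width[i] * width[i]
        gpp = 0.0
        if la > 0.0 and ca > 0.0 and par_umol > 0.0 and seconds > 0.0:
            t = int(np.ceil(height[i]))
            if t > MAX_LAYERS:
                t = MAX_LAYERS
            i_top = par_umol * np.exp(-above[t])
            p_area = gpp_area(i_top, la / ca, pmax[s_], alpha[s_],
                              kext[s_], mtrans[s_])
            gpp = p_area * ca * conv
        gpp_lim = gpp * flim
        sg2, ss2, rt2, npp, resp, fall, rl = carbon_scalar(
            sg[i], ss[i], rt[i], gpp_lim, lls[s_], rls[s_], alloc[s_],
            rm[s_], rg[s_], litter_fall_rate)
        sg[i] = sg2
        ss[i] = ss2
        rt[i] = rt2
        h2, w2 = dims_update(sg2 + ss2, width[i], fs[s_], hw[s_], hmax[s_])
        height[i] = h2
        width[i] = w2
        age[i] += 1.0
        gpp_sum += gpp_lim
        resp_sum += resp
        lit_am += fall
        lit_an += fall / cns[s_]
        lit_bm += rl
        lit_bn += rl / cns[s_]
        wdem += gpp_lim / wue[s_]
        ndem += npp / cng[s_]
    return (gpp_sum, resp_sum, lit_am, lit_an, lit_bm, lit_bn, wdem, ndem)
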