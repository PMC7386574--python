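# Festuca pratensis (meadow fescue, grass) — per-species parameters.
species: Festuca pratensis
h_max: 120.0              # cm, maximum plant height
hw: 1.5                   # height-width ratio of the encasing cylinder
f_s: 0.00072              # g cm^-3, shoot correction factor (cylinder fill density)
f_O: 1.0                  # overlapping factor (no overlap for grasses)
SLA: 117.48               # cm^2 g^-1, specific leaf area
SRL: 42462.8              # cm g^-1, specific root length
rooting_depth_powerlaw: [3.506, 0.301]   # r1, r2: depth = r1 * root_mass^r2
sr: 2.2                   # shoot-root ratio of biomass organs
N_seed_meta: 4013.0       # m^-2 d^-1, seed rain from surrounding landscape
N_seed_meta_mixture: null # no two-species-mixture override
t_meta: 136               # julian day at which seed rain starts
t_em: 14                  # d, time between seed rain and seedling emergence
germ_pct: 0.3             # seed germination rate
h_min: 0.03               # m, initial height of ingrowing seedlings
age_rep: 0.2              # yr, age at which recruitment starts
LLS: 219.0                # d, leaf life span (start of yellowing)
RLS: 166.0                # d, root life span
m_seed: 0.038             # d^-1, mortality rate of established seedlings
m_basic: 0.02             # yr^-1, mortality rate of mature plants
life: perennial
p_max: 17.0               # umol CO2 m^-2 s^-1, maximum gross leaf photosynthesis
alpha: 0.07               # umol CO2 / umol photons, initial slope of light response
k: 0.8                    # light extinction coefficient
m: 0.1                    # transmission coefficient
WUE: 2.7                  # g ODM / kg H2O, water use efficiency
CN_green: 18.0            # CN ratio of green leaves
CN_sen: 39.0              # CN ratio of senescent leaves and roots
N_fix: false              # symbiotic N fixation
alloc_shoot: 0.50         # allocation rate of NPP to shoot growth
r_m: 0.02                 # d^-1, maintenance respiration rate
r_g: 0.2                  # growth respiration factor
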