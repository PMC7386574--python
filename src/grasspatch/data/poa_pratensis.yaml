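# Poa pratensis (smooth meadow-grass) — per-species parameters.
species: Poa pratensis
h_max: 60.0
hw: 0.5
f_s: 0.00057
f_O: 1.0
SLA: 130.05
SRL: 17804.0
rooting_depth_powerlaw: [3.506, 0.301]
sr: 3.5
N_seed_meta: 1062.0
N_seed_meta_mixture: 1934.0   # seed rain when grown in the two-species mixture
t_meta: 136
t_em: 21
germ_pct: 0.75
h_min: 0.03
age_rep: 0.09
LLS: 80.0
RLS: 278.0
m_seed: 0.06
m_basic: 0.02
life: perennial
p_max: 29.0
alpha: 0.09
k: 0.3
m: 0.1
WUE: 6.1
CN_green: 27.0
CN_sen: 47.0
N_fix: false
alloc_shoot: 0.33
r_m: 0.02
r_g: 0.2
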