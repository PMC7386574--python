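# Plantago lanceolata (ribwort plantain, forb) — per-species parameters.
species: Plantago lanceolata
h_max: 70.0
hw: 0.6
f_s: 0.00041
f_O: 0.8        # forbs may overlap; calibrated rather than predefined
SLA: 197.25
SRL: 89051.1
rooting_depth_powerlaw: [5.777, 0.365]
sr: 10.4
N_seed_meta: 3038.0
N_seed_meta_mixture: 1100.0
t_meta: 136
t_em: 7
germ_pct: 0.9
h_min: 0.03
age_rep: 0.02
LLS: 77.0
RLS: 547.0
m_seed: 0.046
m_basic: 0.02
life: perennial
p_max: 37.0
alpha: 0.04
k: 0.27
m: 0.1
WUE: 7.5
CN_green: 23.0
CN_sen: 49.0
N_fix: false
alloc_shoot: 0.35
r_m: 0.02
r_g: 0.2
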