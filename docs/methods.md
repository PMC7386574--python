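# Methods note

This note documents the model implemented by `grasspatch`, its assumptions,
parameters, the synthetic data it is exercised on, the numerical choices
made, and the known limitations. All empirical statements below refer to
quantities computed by this package's own test suite and scripts.

## 1. Model structure

The simulated system is a 1 m² grassland patch (10 000 cm²) with a daily
time step. Plants are individuals without explicit coordinates; spatial
competition is mediated by area budgets and a shared vertical light
profile.

### 1.1 Plant geometry

A plant of green shoot mass `sg` and senescent shoot mass `ss` (g organic
dry matter) occupies an encasing cylinder of width `w` and height `h` (cm)
with shoot density `f_s` (g cm⁻³):

    sg + ss = f_s · (π/4) · w² · h

Growing plants follow the aspect-ratio track `h = h_w · w` until `h` hits
the species cap `h_max`; beyond that, extra mass increases `w` at constant
height. Plants whose shoot mass decreases (mowing, senescence, negative
carbon balance) keep their width — a sward's footprint does not contract
when it is cut — and height is recomputed so the cylinder is always
mass-exact. Seedlings start at the species' germination height `h_min`
with `w = h/h_w` and root mass `shoot/sr` (shoot:root ratio `sr`).

Derived areas: cover area `(π/4)w²`, exclusive (space-filling) area
`f_O·(π/4)w²` with the species overlap factor `f_O ≤ 1`, leaf area
`SLA · sg`. Rooting depth is the power law `r1 · root^r2` (not
resource-active in the single-layer soil, but reported).

### 1.2 Light climate and photosynthesis

The canopy is discretized into 1-cm horizontal layers (up to 200). Each
plant distributes its leaf area uniformly over its own height. The photon
flux reaching the top of a plant is the above-canopy irradiance attenuated
by all layers at or above its top with per-species extinction coefficients
`k` (Beer–Lambert). Within the plant, the leaf light response is the
saturating hyperbola

    p(I) = α · I · p_max / (α · I + p_max)

and self-shading inside the plant column follows
`I_leaf(l) = I_top · k/(1−m) · e^(−k·l)` with transmission loss `m`.
Integrating `p(I_leaf(l))` over the plant's leaf area index `L` has the
closed form

    P_area = (p_max / k) · ln[(α k I₀ + p_max(1−m)) /
                              (α k I₀ e^(−kL) + p_max(1−m))]

(µmol CO₂ m⁻² s⁻¹ integrated over LAI). Daily gross production converts
with day length and 0.63 g organic dry matter per g CO₂. An acceptance
test verifies the closed form against a 100-layer quadrature to 0.5%
across three species, LAI 0.25–6 and irradiance 20–2500 µmol m⁻² s⁻¹.

### 1.3 Carbon balance

Daily, per plant:

1. `gpp_lim = gpp · f_T · f_W · f_N` — multiplicative limitation.
   `f_T` ramps linearly from 0 at 0 °C to 1 at 10 °C. `f_W` and `f_N` are
   the previous day's supply/demand ratios (one-day lag; demand on day 1
   is assumed fully met).
2. Maintenance respiration `R_m = r_m · (sg + root)`; growth respiration
   is the fraction `r_g` of the positive surplus:
   `npp = max(0, (1−r_g)(gpp_lim − R_m))`.
3. `npp` is split `alloc_shoot : (1−alloc_shoot)` between green shoot and
   root. A negative balance shrinks `sg` and `root` proportionally, and
   respiration is reported as `gpp_lim + shrinkage` so the budget closes.
4. Senescence: `sg → ss` at rate 1/LLS (leaf life span, days); `ss` falls
   to aboveground litter at 1/30 d⁻¹; roots turn over to belowground
   litter at 1/RLS.
5. Water demand is `gpp_lim / WUE` (g H₂O via mm over the plant's cover);
   nitrogen demand is `npp / CN_green`. Litter carries nitrogen at the
   senescent tissue ratio `CN_sen ≥ CN_green` (the difference is the
   resorption implicit in senescence).

### 1.4 Soil

One water bucket per patch: soil evaporation takes `min(0.3·PET, water)`,
precipitation is added, plant supply is `min(total demand, water)` (shared
proportionally), and water above the 120 mm capacity drains. One
litter/mineral-N bucket: above- and belowground litter pools mineralize
first-order at 0.01 d⁻¹ into mineral N, atmospheric deposition adds
0.005 g N m⁻² d⁻¹, and plant supply is `min(demand, mineral N)`. This
single-layer bucket pair deliberately replaces a multi-pool soil
organic-matter model: it preserves the interface the plants see (daily
water and N supply against demand) at a fraction of the state.

### 1.5 Demography and management

Seed rain is Poisson with rate `N_seed · germ_pct · patch area` spread
uniformly over a 120-day window starting at the species' metamorphosis
day `t_meta`; cohorts emerge `t_em` days later, admitted only while the
summed exclusive area of the patch leaves room for a seedling footprint.
Daily mortality is `m_seed` before reproductive age (`age_rep` years) and
the annual background rate `m_basic` converted to a daily probability
afterwards; plants whose green shoot falls below 10⁻⁴ g starve. When the
summed exclusive area exceeds the patch, plants are removed one at a time
until it fits — victims drawn uniformly by default, or biased toward
small plants (`crowding_bias="inverse_size"`). Mowing occurs on fixed
calendar days (default 20 June and 20 September) to a 10-cm cut height;
the shoot mass above the cut is harvested and leaves the system; censuses
are taken the day before each cut.

All random draws derive from `numpy.random.SeedSequence` spawning, so
every run is reproducible from one integer seed (< 2³¹).

## 2. Species parameters

Three cool-temperate species ship as YAML files: the grasses *Festuca
pratensis* and *Poa pratensis* and the rosette forb *Plantago lanceolata*.
Each record holds 30 traits: geometry (`h_max`, `h_w`, `f_s`, `f_O`,
`SLA`, `SRL`, rooting power law `r1`,`r2`, `sr`), recruitment (`N_seed`
and a mixture-context override, `t_meta`, `t_em`, `germ_pct`, `h_min`,
`age_rep`), turnover and mortality (`LLS`, `RLS`, `m_seed`, `m_basic`),
physiology (`p_max`, `α`, `k`, `m`, `WUE`, `CN_green`, `CN_sen`,
`alloc_shoot`, `r_m`, `r_g`). Units and values are documented in the
YAML files; loading validates ranges and cross-trait invariants
(e.g. `CN_sen ≥ CN_green`, `h_min < h_max`, probabilities in [0, 1]).

Sixteen traits are exposed for calibration with default bounds chosen to
bracket the shipped values; the `CN_green` (10–30) and `CN_sen` (30–80)
bounds are non-overlapping so any vector inside the bounds satisfies the
trait invariants.

## 3. Synthetic data

The climate generator is the package's study environment, not a
reconstruction of any measured series. Defaults: daily mean temperature
sinusoid (mean 9.3 °C, amplitude 9 °C, Gaussian noise σ = 3 °C, peak at
day-of-year 197), photosynthetically active radiation sinusoid (mean
22 mol m⁻² d⁻¹, amplitude 18, noise σ = 5, floored at 0.1), two-state
Markov rainfall (wet-after-dry 0.30, wet-after-wet 0.60, exponential
wet-day amounts with 4 mm mean), a PET sinusoid between 0.3 and
3.5 mm d⁻¹, and astronomical day length at 51° N. These magnitudes are
typical of a maritime-temperate lowland; the generator makes no claim to
represent a particular site or year, and its defaults were fixed before
the acceptance experiments were run.

Observations for the calibration experiments are generated by the model
itself (replicate means of simulated patterns), optionally with
multiplicative lognormal noise for descriptive studies.

## 4. Calibration and evaluation

Patterns are keyed `attribute:subject` (e.g. `agb:Festuca pratensis`,
`height:community`) and carry annual means plus intra-annual extremes and
census-level values. Distances are MAPE, nrmse (100·RMSE/mean(obs)), or
a combined criterion nrmse + 100·|1−slope| + 100·(1−R²) from an OLS
regression of simulated on observed. Optimizers: dynamically dimensioned
search (inclusion probability `1 − ln t / ln T`, Gaussian perturbation
0.2 × range with reflection, greedy acceptance), differential evolution
(rand/1/bin, F = 0.8, CR = 0.9; the initial population counts against the
evaluation budget), and simulated annealing with geometric cooling. All
record best-so-far traces.

### Problem sizes (this package's choices)

The acceptance experiments are deliberately scaled down to run on one CPU
within minutes; the sizes below are the package's own study design.

* **Parameter recovery**: *F. pratensis* monoculture, 2 simulated years,
  4 free traits (`p_max`, `α`, `LLS`, `alloc_shoot`), four observed
  patterns (species AGB, LAI, cover; community height) censused daily
  across the vegetated season (day-of-year 60–300) of the second year;
  the establishment year is excluded, as is standard in grassland
  monitoring. High census density matters: with only a few censuses per
  year the trait compensations (`p_max`–`α`, `LLS`–`alloc_shoot`) leave
  a cost valley whose floor lies below what DDS can resolve, and 15%
  recovery is unattainable in principle. Observations are the
  3-replicate mean computed with the same replicate seeds as every cost
  evaluation (common random numbers), so the true trait vector is the
  exact global cost minimum — the experiment then measures whether DDS
  (budget 500) finds it. The reported vector is the consensus of 5
  optimizer restarts weighted by the inverse squared final cost of each
  restart, which continuously down-weights stalled restarts; the test
  requires every trait within 15% of truth and a pooled multi-pattern
  MAPE below 0.1.
* **Pattern-subset experiment**: same patch and climate with biweekly
  censuses; each of the four patterns is calibrated alone (DDS budget
  200, one replicate per cost call) and the result is scored by
  3-replicate nrmse on all four patterns. The virtual field data are
  generated from a structurally different parameterization (specific
  leaf area, stature and water-use efficiency shifted), because with
  observations the model can fit exactly, every pattern subset shares
  the same global optimum and no attribute trade-off can exist. The
  expected structure — each single-pattern calibration best on its own
  attribute, the full four-pattern cost best on the mean — must hold
  for a majority of 3 experiment seeds.
* **Symmetric-mixture relative yield** (`scripts/acceptance.py`): two
  identical clones of *F. pratensis* grown in mixture at half the
  monoculture seed rain each, 6 years, 64 replicates; one monoculture run
  serves both clones (they are identical by construction). Relative yield
  of mean annual cover has symmetry expectation 0.5; the computed value at
  `--seed 1` is 0.50008 (n = 64).

## 5. Numerical choices

* 1-cm canopy layers (cap 200); plant heights are continuous, layer
  indices use the ceiling of the plant top.
* Closed-form canopy photosynthesis integral (§1.2) instead of layer
  quadrature inside plants — exact for the assumed light profile.
* 0.63 g organic dry matter per g CO₂ assimilated.
* One-day lag for water/N limitation (supply is known only after demand).
* Width-never-shrinks geometry (§1.1); mass-exactness is maintained by
  recomputing height.
* Starvation floor 10⁻⁴ g green shoot avoids denormal-scale plants.
* The daily loop is compiled with numba over struct-of-arrays state; the
  scalar kernels are the single source of truth and are also called by
  the public per-plant API, with tests pinning agreement. Budget closure
  (carbon to 10⁻⁶ relative; water and N to 10⁻⁹ absolute over six years)
  is an acceptance criterion.
* All stochastic components use `SeedSequence`-spawned generators; child
  seeds are reduced modulo 2³¹.

## 6. Limitations

* No explicit plant coordinates: shading is patch-uniform per height
  layer, and crowding is a scalar area budget.
* Single-layer soil without vertical water/N structure, soil temperature
  or microbial pools; rooting depth does not differentiate resource
  access.
* No seed dormancy, seed bank carry-over between years, or dispersal
  between patches; the patch is closed except for seed rain.
* Temperature limitation is a simple ramp; no frost kill, heat stress or
  photoperiod control of phenology.
* The synthetic climate is stationary (no trends, no extremes beyond the
  noise model) and the generator's realism claims are limited to
  magnitude plausibility.
* Calibration experiments use model-generated (noise-free, CRN)
  observations; performance against noisy field data is out of scope and
  untested.
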