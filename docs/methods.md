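# Methods

## Model structure and assumptions

The simulator couples three time scales.  Between years, only eggs persist:
the final lunar cycle's egg pool is rescaled to `n0 = 10,000` overwintering
eggs with genotype proportions preserved, and the next season's start week is
drawn uniformly from {1, 2, 3, 4} because spring onset is set by water
temperature, not the moon.  Within a season (44 weeks), all weekly transitions
fire simultaneously from the previous week's state: eggs hatch into age-1
larvae, larvae age, mature larvae enter a sexed "pending" state, and pending
individuals emerge when their strain's cue arrives.  Within an emergence week,
mating runs in continuous time over five daily windows.

Timing genetics is one locus, three alleles (F, M1, M2), all variation
expressed through the emergence cue rule: full-moon weeks (`T mod 4 == 0`)
cue M1 and F phenotypes, new-moon weeks (`T mod 4 == 2`) cue M2 and F.  F is
recessive by default (`F_dominant` is available and changes no qualitative
outcome class we test).  Hybrid maladaptation is a pure viability cost: hybrid
eggs hatch at rate `gamma`; no intermediate timing phenotypes exist.  Because
the monthly strains' mating niches never overlap, M1M2 eggs can arise only
under F dominance (F-phenotype heterozygotes co-emerging with the opposite
monthly homozygote); the model assigns them viability zero and reports the
discarded mass, rather than invent a phenotype the biology excludes.

Within-week chaining follows the egg-arrow multiplier `C_D * gamma * S(T)`:
pending individuals whose cue falls on week T emerge in week T (multiplier
`S(T)`), mate the same week, and their eggs receive the laying week's
survival before appearing as age-1 larvae in week T+1.  Survival rates are
evaluated once per week from the pre-transition state and applied to every
arrow of that week; hatching eggs do not contribute to the density terms, and
adults never do (they die at the end of the mating window).

## Parameters

| symbol | meaning | default | notes |
|---|---|---|---|
| `s_max` | weekly survival cap | 0.85 | survival under unlimited resources |
| `alpha` | density strength (per larvae²) | 1e-8 | single-niche scenario |
| `alpha_n1`, `alpha_n2` | niche-specific density strengths | 1e-8, 2.6e-8 | Niche 2 must be stronger: fewer old larvae feed there |
| `w` | niche-shift age (weeks) | 2 | shift scenario only |
| `m_6..m_11` | weekly maturation probabilities | 0.1, 0.3, 0.5, 0.7, 0.9, 1 | see below |
| `gamma` | hybrid egg viability | 1.0 | presets use 0.3 for maladapted-hybrid panels |
| `C_D` | clutch size after D pending weeks | flat 100 | tradeoff presets: (60,90,120,150), (40,80,120,160) |
| `b` | mate-search efficiency | 5e-3 | presets: 5e-3 weak / 5e-4 strong Allee effect |
| `tau`, `t_end` | handling time, window length | 0.25, 1 | allow 4 completed matings per male |
| `daily_split` | emergence spread over days | 10/20/40/20/10 % | |
| `season_weeks`, `n0` | season length, overwinter eggs | 44, 10,000 | |

Maturation spreads development over ages 6–11 with `m_11 = 1`.  The exact
schedule is not identifiable from published material; the default above is a
smoothly increasing schedule on that support.  Basin boundaries shift with
this choice, and one qualitative outcome is genuinely sensitive to it (see
Limitations).  Strongly front-loaded schedules are avoided deliberately: they
lock generations onto an 8-week cycle whose laying weeks can miss the
final-lunar-cycle measurement window entirely, an artifact rather than
biology.

The Allee-panel search efficiencies were fixed once so that the mated fraction
spans ≈1 down to ≈0.3 at typical emergence-pool sizes (hundreds of adults per
day-pool): `b = 5e-3` (weak) and `5e-4` (strong).  Hybrid-viability panels use
`gamma = 1` (cost-free) and `0.3` (maladapted).

## Numerical choices

* Continuous (real-valued) masses; no rounding and no demographic noise in
  the main engine.  The within-season model is fully deterministic; the only
  randomness is the yearly season-start draw.
* The pair-formation ODE is solved with LSODA at rtol 1e-8 and scaled atol:
  the capacity checks run at `b = 1e6`, far too stiff for explicit
  Runge–Kutta steppers.  Searching + occupied males are conserved to solver
  tolerance; `p` is clipped to [0, 1] against solver dust.  Completed matings
  per male are female depletion minus males still occupied at the window end,
  which approaches `t_end/tau = 4` in the saturated limit.
* Mendelian proportions are exact rationals before conversion to floats;
  sires are weighted by male genotype frequencies among the day's emergers
  (handling time does not skew sire shares), and the mated fraction is
  independent of a female's pending duration D (D affects fecundity only).
* Season-level change (AFD, half the L1 distance between allele-frequency
  vectors) is measured on eggs of the last 4 weeks — one full-moon, one
  new-moon and two fortnightly cues — to avoid bias from the strains'
  staggered laying weeks.  The same final-cycle pool seeds the next year
  (whole-season egg production is also recorded for callers who prefer that
  reading).  An empty final pool marks the run extinct; the AFD is then
  reported missing rather than substituted from another pool.
* Winner classification in multi-year runs uses a fixed threshold: a genotype
  above frequency `1 - 1e-3` in the last year's pool wins, otherwise the run
  is classed as coexistence.  Ternary sweeps default to a 0.05 simplex grid
  (0.1 in the boundary sweeps, matching the reported grid resolution).
* Single-season runs fix the season start at week 1, which hands the
  full-moon strain the first emergence opportunity (week 8 vs week 10).

## The individual-based oracle

`scenarios.monte_carlo_oracle` reruns the identical weekly rules as an
individual-based stochastic model: binomial survival, maturation and sex
draws, multinomial day-splitting and sire assignment, binomial hybrid
viability thinning.  It exists to validate the deterministic engine and never
feeds results.  Two regimes matter for interpreting agreement:

* Without density dependence (`alpha = 0`) every weekly transition is a
  branching process, so the stochastic stage means equal the deterministic
  masses exactly; the test suite holds the engine to the 3-s.e. envelope of
  50 replicates over a full season there.
* With density dependence on, the deterministic engine is the mean-field
  limit, not the ensemble mean: survival is a nonlinear (concave, at the
  relevant densities) function of abundance, so the replicate mean acquires a
  Jensen-type offset of order 1–2 % that is visible from about week 6 and
  grows once replicate trajectories decohere in the boom-bust within-season
  cycling (hatch-week CV reaches ~13 % by week 20 at `n0 = 10,000`).  The
  suite therefore checks that the deterministic trajectory stays within 3
  replicate standard deviations (a typical realization) rather than within
  3 s.e. of the mean.

The oracle also exhibits demographic extinction at small `n0`, which the
continuous-mass engine cannot; this divergence regime is asserted, not hidden.

## What the scenario generator does and does not emulate

Presets cover the published panel grid: growth–survival tradeoffs (flat,
moderate, strong fecundity schedules), the Allee-effect × hybridization grid
(ecological vs random mixing, p = 1 vs weak vs strong mate limitation,
cost-free vs maladapted hybrids), the ontogenetic niche shift at age 2, and
100-year two-strain competitions.  All inputs are synthetic by construction —
the underlying study is a pure modelling exercise — so passing tests show
internal consistency of the model and reproduction of its published
behaviour, not agreement with field data on *Clunio* demography, which does
not exist at this resolution.

## Limitations

* The maturation schedule `m_i` is a modelling choice.  The sign of the
  one-season frequency change on the flat-fecundity monthly-strain edge at
  strongly lopsided starts depends on it: with maturation smeared over ages
  6–11, the late strain accumulates four pending classes by its first cue
  against the head-start strain's two, and this per-capita first-generation
  advantage outweighs the head start when the head-start strain is rare
  (boundary near 0.25–0.3 under the default schedule).  Under the default
  schedule the head-start strain does **not** gain everywhere on that edge;
  the basin boundaries under the moderate and strong tradeoffs (0.6 and 0.4)
  are insensitive to this and are reproduced.
* Mean-field vs individual-based agreement is s.e.-sharp only without
  density dependence (above).
* No mutation, no multi-locus architecture, no spatial structure, no female
  remating or protandry, no temperature-driven season-onset mechanics, and no
  evolution of the timing traits themselves — strains compete at fixed
  phenotypes.
* Problem sizes used by the packaged experiments: 44-week seasons at
  `n0 = 10,000`; 0.1-grid boundary sweeps (9 seasons per edge); 100-year
  multi-year runs at 9 initial frequencies × 5 seeds; 50-replicate oracle
  comparisons.
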