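"""Scenario presets, simplex grids and an individual-based testing oracle.

The model consumes no external data: every experiment is defined by a
parameter set plus an initial-condition grid.  ``preset`` resolves the named
figure-panel scenarios to full :class:`~cluniosim.demography.ModelParams`;
``simplex_grid`` enumerates the equidistant initial-frequency lattice on the
three-strain simplex; ``monte_carlo_oracle`` reruns the identical weekly rules
as an individual-based stochastic simulation (binomial survival/maturation,
multinomial sire assignment) and is used only to validate the deterministic
engine — it never feeds results.

Search-efficiency values for the Allee-effect panels and hybrid viabilities
for the random-mating panels are scenario choices (weak b = 5e-3 vs strong
b = 5e-4 Allee effect; cost-free gamma = 1 vs maladapted gamma = 0.3 hybrids),
spanning mated fractions from near 1 down to roughly 0.3 at typical emergence
densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .demography import (
    FEMALE,
    MALE,
    MATURE_AGE,
    MAX_PENDING,
    N_AGES,
    N_GENOTYPES,
    ModelParams,
    PopulationState,
    _cue_mask,
    survival_rates,
)
from .genetics import GENOTYPE_INDEX, GENOTYPES, mendelian_table
from .mating import solve_mating

_B_WEAK_ALLEE = 5e-3
_B_STRONG_ALLEE = 5e-4
_GAMMA_MALADAPTED = 0.3

_TRADEOFF_FLAT = (100.0, 100.0, 100.0, 100.0)
_TRADEOFF_CLEAR = (60.0, 90.0, 120.0, 150.0)
_TRADEOFF_STRONG = (40.0, 80.0, 120.0, 160.0)


@dataclass(frozen=True)
class Preset:
    """A named figure-panel scenario, fully resolved to model parameters."""

    name: str
    description: str
    params: ModelParams
    kind: str = "ternary"            # "ternary" (single-season sweep) or "multiyear"
    grid_step: float = 0.05
    years: int = 100
    strains: str = "all"             # "all" or "monthly" (E_F absent)


def _p(**overrides) -> ModelParams:
    return ModelParams(**overrides)


_PRESETS: dict[str, Preset] = {}


def _register(name: str, description: str, params: ModelParams, **kw) -> None:
    _PRESETS[name] = Preset(name=name, description=description, params=params, **kw)


# single niche, ecological competition, all females mate: growth-survival tradeoff
_register("fig2b", "no tradeoff: fortnightly strain sweeps, else head start wins",
          _p(fecundity=_TRADEOFF_FLAT))
_register("fig2c", "clear tradeoff: late monthly strain wins if common (>0.6)",
          _p(fecundity=_TRADEOFF_CLEAR))
_register("fig2d", "strong tradeoff: monthly strains exclude the fortnightly",
          _p(fecundity=_TRADEOFF_STRONG))

# single niche, flat fecundity: Allee effect x hybridisation grid
_register("fig3a", "ecological pools, all females mate", _p())
_register("fig3b", "ecological pools, weak mate-finding Allee effect",
          _p(mate_finding="ode", b=_B_WEAK_ALLEE))
_register("fig3c", "ecological pools, strong mate-finding Allee effect",
          _p(mate_finding="ode", b=_B_STRONG_ALLEE))
_register("fig3d", "random mating, cost-free hybrids, all females mate",
          _p(mixing="random", gamma=1.0))
_register("fig3e", "random mating, cost-free hybrids, weak Allee effect",
          _p(mixing="random", gamma=1.0, mate_finding="ode", b=_B_WEAK_ALLEE))
_register("fig3f", "random mating, cost-free hybrids, strong Allee effect",
          _p(mixing="random", gamma=1.0, mate_finding="ode", b=_B_STRONG_ALLEE))
_register("fig3g", "random mating, maladapted hybrids, all females mate",
          _p(mixing="random", gamma=_GAMMA_MALADAPTED))
_register("fig3h", "random mating, maladapted hybrids, weak Allee effect",
          _p(mixing="random", gamma=_GAMMA_MALADAPTED,
             mate_finding="ode", b=_B_WEAK_ALLEE))
_register("fig3i", "random mating, maladapted hybrids, strong Allee effect",
          _p(mixing="random", gamma=_GAMMA_MALADAPTED,
             mate_finding="ode", b=_B_STRONG_ALLEE))

# 100-year competitions of the two monthly strains
_register("fig4a", "100-year runs of the fig3a setting, monthly strains only",
          _p(), kind="multiyear", strains="monthly")
_register("fig4b", "100-year runs of the fig3b setting, monthly strains only",
          _p(mate_finding="ode", b=_B_WEAK_ALLEE),
          kind="multiyear", strains="monthly")
_register("fig4c", "100-year runs of the fig3c setting, monthly strains only",
          _p(mate_finding="ode", b=_B_STRONG_ALLEE),
          kind="multiyear", strains="monthly")
_register("fig4d", "100-year runs of the fig5a setting, monthly strains only",
          _p(niche="shift", w=2, alpha_n1=1e-8, alpha_n2=2.6e-8),
          kind="multiyear", strains="monthly")

# ontogenetic niche shift at 2 weeks
_register("fig5a", "niche shift at 2 weeks, no tradeoff",
          _p(niche="shift", w=2, alpha_n1=1e-8, alpha_n2=2.6e-8))
_register("fig5b", "niche shift at 2 weeks, clear tradeoff",
          _p(niche="shift", w=2, alpha_n1=1e-8, alpha_n2=2.6e-8,
             fecundity=_TRADEOFF_CLEAR))


def preset(name: str) -> Preset:
    """Look up a named scenario preset."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; known: {', '.join(sorted(_PRESETS))}"
        ) from None


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def simplex_grid(step: float) -> list[tuple[float, float, float]]:
    """All non-negative frequency triples on the step lattice summing to 1."""
    n = round(1.0 / step)
    if abs(n * step - 1.0) > 1e-9:
        raise ValueError("1/step must be an integer")
    points = []
    for i, j in product(range(n + 1), repeat=2):
        k = n - i - j
        if k >= 0:
            points.append((i / n, j / n, k / n))
    return points


# ---------------------------------------------------------------------------
# individual-based Monte-Carlo oracle (testing only)
# ---------------------------------------------------------------------------

_MENDEL = mendelian_table()


@dataclass
class OracleSummary:
    """Replicate summaries of weekly stage masses.

    ``mean``/``se`` are per-genotype (weeks, 5) arrays; ``total_mean``,
    ``total_se`` and ``total_sd`` summarise the genotype-summed stage totals
    (weeks,), with ``total_sd`` the across-replicate standard deviation (the
    envelope of individual realizations rather than of the mean).
    """

    replicates: int
    weeks: np.ndarray
    mean: dict[str, np.ndarray] = field(default_factory=dict)  # (weeks, 5)
    se: dict[str, np.ndarray] = field(default_factory=dict)
    total_mean: dict[str, np.ndarray] = field(default_factory=dict)
    total_se: dict[str, np.ndarray] = field(default_factory=dict)
    total_sd: dict[str, np.ndarray] = field(default_factory=dict)


def _mc_mating(females, males, params, rng):
    """Integer mated-female counts (5, 4) for one week's cohort."""
    mated = np.zeros_like(females)
    if males.sum() == 0 or females.sum() == 0:
        return mated
    if params.mate_finding == "p1":
        return females.copy()
    # multinomial split of every (genotype, D) cell over the five days
    split = np.asarray(params.daily_split)
    f_days = np.array([rng.multinomial(n, split) for n in females.ravel()])
    f_days = f_days.reshape(*females.shape, 5)
    m_days = np.array([rng.multinomial(n, split) for n in males.ravel()])
    m_days = m_days.reshape(*males.shape, 5)
    for day in range(5):
        f_d, m_d = f_days[..., day], m_days[..., day]
        if params.mixing == "ecological":
            for g in range(N_GENOTYPES):
                p_g = solve_mating(float(f_d[g].sum()), float(m_d[g].sum()),
                                   params.b, params.tau, params.t_end)
                mated[g] += rng.binomial(f_d[g], p_g)
        else:
            p_day = solve_mating(float(f_d.sum()), float(m_d.sum()),
                                 params.b, params.tau, params.t_end)
            mated += rng.binomial(f_d, p_day)
    return mated


def _mc_reproduce(mated, males, params, rng):
    """Integer viable egg counts (5,) from mated females."""
    fec = np.asarray(params.fecundity)
    clutch = (mated * fec).sum(axis=1)
    clutch = np.rint(clutch).astype(np.int64)
    if params.mixing == "ecological":
        return clutch
    total_males = males.sum()
    if total_males == 0:
        return np.zeros(N_GENOTYPES, dtype=np.int64)
    sire_freq = males.sum(axis=1) / total_males
    eggs = np.zeros(N_GENOTYPES, dtype=np.int64)
    for g in range(N_GENOTYPES):
        if clutch[g] == 0:
            continue
        by_sire = rng.multinomial(clutch[g], sire_freq)
        for s in range(N_GENOTYPES):
            if by_sire[s] == 0:
                continue
            by_off = rng.multinomial(by_sire[s], _MENDEL[g, s])
            eggs += by_off[:N_GENOTYPES]  # M1M2 slot is inviable, dropped
    # hybrid viability thinning
    for g, label in enumerate(GENOTYPES):
        if label in ("FM1", "FM2") and eggs[g] > 0:
            eggs[g] = rng.binomial(eggs[g], params.gamma)
    return eggs


def monte_carlo_season(freqs, params: ModelParams, week_start: int, rng):
    """One individual-based season; returns weekly per-genotype stage totals.

    Identical transition rules to the deterministic engine, with binomial
    survival/maturation/sex draws and multinomial day and sire assignment.
    """
    freq_vec = np.zeros(N_GENOTYPES)
    for g, f in freqs.items():
        freq_vec[GENOTYPE_INDEX[g]] = f
    larvae = np.zeros((N_GENOTYPES, N_AGES), dtype=np.int64)
    larvae[:, 0] = rng.multinomial(int(round(params.n0)), freq_vec)
    pending = np.zeros((2, N_GENOTYPES, MAX_PENDING), dtype=np.int64)

    n_weeks = params.season_weeks
    out = {
        "larvae": np.zeros((n_weeks, N_GENOTYPES)),
        "pending": np.zeros((n_weeks, N_GENOTYPES)),
        "eggs": np.zeros((n_weeks, N_GENOTYPES)),
    }

    for k in range(n_weeks):
        week = week_start + k
        out["larvae"][k] = larvae.sum(axis=1)
        out["pending"][k] = pending.sum(axis=(0, 2))

        # survival rates from the (float view of the) pre-transition state
        state = PopulationState(week, larvae.astype(float), pending.astype(float))
        s_age, s_hatch, s_pend = survival_rates(state, params)
        mask = _cue_mask(week, params)

        # emergence + mating + egg laying
        eggs = np.zeros(N_GENOTYPES, dtype=np.int64)
        adults = rng.binomial(pending[:, mask, :], s_pend)
        if adults.sum() > 0:
            full = np.zeros((2, N_GENOTYPES, MAX_PENDING), dtype=np.int64)
            full[:, mask, :] = adults
            mated = _mc_mating(full[FEMALE], full[MALE], params, rng)
            eggs = _mc_reproduce(mated, full[MALE], params, rng)
        out["eggs"][k] = eggs

        new_larvae = np.zeros_like(larvae)
        new_pending = np.zeros_like(pending)
        new_larvae[:, 0] = rng.binomial(eggs, s_hatch)
        for i in range(N_AGES):
            age = i + 1
            survivors = rng.binomial(larvae[:, i], s_age[i])
            if age >= MATURE_AGE:
                m_i = params.maturation[age - MATURE_AGE]
                to_pending = rng.binomial(survivors, m_i)
                females = rng.binomial(to_pending, 0.5)
                new_pending[FEMALE, :, 0] += females
                new_pending[MALE, :, 0] += to_pending - females
                survivors = survivors - to_pending
            if age < N_AGES:
                new_larvae[:, i + 1] += survivors
        waiting = rng.binomial(pending[:, ~mask, :], s_pend)
        new_pending[:, ~mask, 1:] += waiting[:, :, :-1]

        larvae, pending = new_larvae, new_pending

    return out


def monte_carlo_oracle(
    freqs,
    params: ModelParams,
    seed: int,
    replicates: int = 50,
    week_start: int = 1,
) -> OracleSummary:
    """Replicate the individual-based season and summarise stage trajectories."""
    rng = np.random.default_rng(seed)
    stacks: dict[str, list[np.ndarray]] = {"larvae": [], "pending": [], "eggs": []}
    for _ in range(replicates):
        rep = monte_carlo_season(freqs, params, week_start, rng)
        for key in stacks:
            stacks[key].append(rep[key])
    summary = OracleSummary(
        replicates=replicates,
        weeks=np.arange(week_start, week_start + params.season_weeks),
    )
    for key, reps in stacks.items():
        arr = np.stack(reps)
        summary.mean[key] = arr.mean(axis=0)
        summary.se[key] = arr.std(axis=0, ddof=1) / np.sqrt(replicates)
        totals = arr.sum(axis=2)
        summary.total_mean[key] = totals.mean(axis=0)
        summary.total_sd[key] = totals.std(axis=0, ddof=1)
        summary.total_se[key] = summary.total_sd[key] / np.sqrt(replicates)
    return summary
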