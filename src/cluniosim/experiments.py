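"""Season and multi-year experiments: sweeps, basins and winner analysis.

A season spans 44 weeks of absolute week numbers W_start..W_start+43 (W_start
in 1..4, so the modulo arithmetic of the lunar cues lines up differently from
year to year).  Within a season the weekly engine runs deterministically; on
cue weeks the emergence cohort mates and its eggs re-enter the larval
dynamics.  At season end all living larvae are discarded — only eggs persist.

Season-level change is summarised by the allele frequency difference

    AFD = 1/2 * (|df_F| + |df_M1| + |df_M2|),

half the L1 distance between the initial allele frequencies and those of the
egg pool produced during the final lunar cycle (the last 4 weeks, which cover
one full-moon cue, one new-moon cue and two fortnightly cues, avoiding bias
from the strains' staggered laying weeks).

Multi-year runs carry the final-cycle egg pool over the winter, rescaled to
n0 eggs with genotype proportions preserved, and redraw the season start week
uniformly from {1, 2, 3, 4} each year — the spring onset is set by water
temperature, not the moon, so which monthly strain gets the head start is a
coin flip.  Winner classification and a logistic summary of winning
probability against initial frequency mirror the multi-year analysis of
priority-effect regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .demography import (
    FEMALE,
    MALE,
    MAX_PENDING,
    N_AGES,
    N_GENOTYPES,
    ExtinctionError,
    ModelParams,
    PopulationState,
    emergence_cohort,
    init_population,
    weekly_update,
)
from .genetics import ALLELES, GENOTYPES, PHENOTYPES, allele_freq_vector
from .mating import mating_week, reproduce

FINAL_CYCLE_WEEKS = 4  # one lunar cycle

#: winner threshold: a genotype "wins" at the horizon above frequency 1 - EPS
WINNER_EPS = 1e-3


@dataclass
class SeasonResult:
    """Outcome of one 44-week season."""

    params: ModelParams
    week_start: int
    init_freqs: np.ndarray            # (3,) allele frequencies at initialisation
    weekly_eggs: np.ndarray           # (season_weeks, 5) viable eggs laid per week
    weekly_larvae: np.ndarray         # (season_weeks, 5) larval mass, pre-transition
    weekly_pending: np.ndarray        # (season_weeks, 5) pending mass, pre-transition
    final_pool: np.ndarray            # (5,) egg pool of the final lunar cycle
    max_pending_by_phenotype: np.ndarray  # (3,) max D with mass > 0, by phenotype
    discarded_hybrid_mass: float = 0.0
    extinct: bool = False
    final_freqs: np.ndarray | None = None   # (3,) allele freqs of final pool
    delta_f: np.ndarray | None = None       # (3,) final - initial
    afd: float = float("nan")
    trajectory: pd.DataFrame | None = None

    @property
    def season_eggs(self) -> np.ndarray:
        """(5,) whole-season viable egg production by genotype."""
        return self.weekly_eggs.sum(axis=0)


@dataclass
class MultiYearResult:
    """Outcome of a multi-year run with randomized season starts."""

    params: ModelParams
    seed: int
    years: int
    yearly_freqs: np.ndarray          # (years, 5) normalized genotype egg shares
    week_starts: np.ndarray           # (years,) drawn W_start values
    winner: str                       # genotype label or "coexistence"
    extinct_year: int | None = None


def compute_afd(init_freqs: np.ndarray, final_freqs: np.ndarray) -> float:
    """Half the L1 distance between two allele-frequency vectors."""
    f0 = np.asarray(init_freqs, dtype=float)
    f1 = np.asarray(final_freqs, dtype=float)
    if f0.shape != f1.shape:
        raise ValueError("frequency vectors must have the same shape")
    return 0.5 * float(np.abs(f1 - f0).sum())


def _trajectory_rows(year: int, state: PopulationState) -> list[dict]:
    rows = []
    for g, label in enumerate(GENOTYPES):
        for i in range(N_AGES):
            if state.larvae[g, i] > 0:
                rows.append(
                    dict(year=year, week=state.week, stage="larva",
                         genotype=label, sex="unsexed", age_or_D=i + 1,
                         mass=state.larvae[g, i])
                )
        for s, sex in ((FEMALE, "female"), (MALE, "male")):
            for d in range(MAX_PENDING):
                if state.pending[s, g, d] > 0:
                    rows.append(
                        dict(year=year, week=state.week, stage="pending",
                             genotype=label, sex=sex, age_or_D=d + 1,
                             mass=state.pending[s, g, d])
                    )
    return rows


def run_season(
    freqs: Mapping[str, float],
    params: ModelParams,
    week_start: int = 1,
    record_trajectory: bool = False,
    year: int = 0,
) -> SeasonResult:
    """Simulate one season from per-genotype initial frequencies.

    On every week the emergence cohort (if any) mates and reproduces; the
    resulting viable eggs enter the same week's transition with the laying
    week's survival.  Eggs of the last 4 weeks form the final pool used for
    the AFD and for overwintering.
    """
    if not 1 <= week_start <= 4:
        raise ValueError("week_start must lie in 1..4")
    state = init_population(freqs, params, week_start)
    init_f = allele_freq_vector(state.larvae[:, 0])
    phen = params.phenotypes

    n_weeks = params.season_weeks
    weekly_eggs = np.zeros((n_weeks, N_GENOTYPES))
    weekly_larvae = np.zeros((n_weeks, N_GENOTYPES))
    weekly_pending = np.zeros((n_weeks, N_GENOTYPES))
    max_pending = np.zeros(len(PHENOTYPES), dtype=int)
    discarded = 0.0
    rows: list[dict] = []

    for k in range(n_weeks):
        weekly_larvae[k] = state.larvae.sum(axis=1)
        weekly_pending[k] = state.pending.sum(axis=(0, 2))
        occupied = np.nonzero(state.pending.sum(axis=0) > 0)
        for g, d in zip(*occupied):
            ph = phen[g]
            max_pending[ph] = max(max_pending[ph], d + 1)
        if record_trajectory:
            rows.extend(_trajectory_rows(year, state))

        cohort = emergence_cohort(state, params)
        eggs = np.zeros(N_GENOTYPES)
        if cohort.total() > 0:
            outcome = mating_week(cohort, params)
            eggs, lost = reproduce(outcome, params)
            discarded += lost
        weekly_eggs[k] = eggs
        state, _ = weekly_update(state, params, eggs_in=eggs)

    final_pool = weekly_eggs[-FINAL_CYCLE_WEEKS:].sum(axis=0)
    result = SeasonResult(
        params=params,
        week_start=week_start,
        init_freqs=init_f,
        weekly_eggs=weekly_eggs,
        weekly_larvae=weekly_larvae,
        weekly_pending=weekly_pending,
        final_pool=final_pool,
        max_pending_by_phenotype=max_pending,
        discarded_hybrid_mass=discarded,
        trajectory=pd.DataFrame(rows) if record_trajectory else None,
    )
    if final_pool.sum() <= 0:
        result.extinct = True
        return result
    result.final_freqs = allele_freq_vector(final_pool)
    result.delta_f = result.final_freqs - init_f
    result.afd = compute_afd(init_f, result.final_freqs)
    return result


def overwinter(season_eggs: np.ndarray, n0: float) -> np.ndarray:
    """Rescale the season's egg pool so n0 eggs survive the winter.

    Genotype proportions are preserved; a zero pool means the population went
    extinct and raises :class:`ExtinctionError`.
    """
    eggs = np.asarray(season_eggs, dtype=float)
    total = eggs.sum()
    if total <= 0:
        raise ExtinctionError("no eggs produced: population extinct")
    return eggs * (n0 / total)


def run_multi_year(
    freqs: Mapping[str, float],
    params: ModelParams,
    years: int,
    seed: int,
) -> MultiYearResult:
    """Iterate seasons with overwintering and random season-start weeks.

    Each year W_start is drawn uniformly from {1, 2, 3, 4}; the final-cycle
    egg pool is normalized to n0 and seeds the next year's age-1 larvae.  The
    winner is the genotype exceeding frequency 1 - 1e-3 in the last year's
    pool, otherwise "coexistence".
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = np.random.default_rng(seed)
    yearly = np.zeros((years, N_GENOTYPES))
    starts = np.zeros(years, dtype=int)
    current = dict(freqs)
    extinct_year = None

    for y in range(years):
        w_start = int(rng.integers(1, 5))
        starts[y] = w_start
        season = run_season(current, params, week_start=w_start, year=y)
        if season.extinct:
            extinct_year = y
            break
        pool = overwinter(season.final_pool, params.n0)
        shares = pool / pool.sum()
        yearly[y] = shares
        current = {g: shares[i] for i, g in enumerate(GENOTYPES)}

    if extinct_year is not None:
        yearly = yearly[:extinct_year]
        starts = starts[:extinct_year]
        winner = "extinct"
    else:
        last = yearly[-1]
        top = int(np.argmax(last))
        winner = GENOTYPES[top] if last[top] > 1.0 - WINNER_EPS else "coexistence"

    return MultiYearResult(
        params=params,
        seed=seed,
        years=years,
        yearly_freqs=yearly,
        week_starts=starts,
        winner=winner,
        extinct_year=extinct_year,
    )


def ternary_sweep(
    params: ModelParams,
    grid_step: float = 0.05,
    week_start: int = 1,
) -> pd.DataFrame:
    """One season from every point of the homozygote-frequency simplex grid.

    Returns a tidy frame with the initial frequencies (f_F, f_M1, f_M2), the
    per-allele frequency changes over the season and the AFD magnitude —
    exactly the arrow-and-colour content of a ternary direction plot.
    """
    from .scenarios import simplex_grid

    records = []
    for f_f, f_m1, f_m2 in simplex_grid(grid_step):
        res = run_season(
            {"FF": f_f, "M1M1": f_m1, "M2M2": f_m2}, params, week_start
        )
        rec = dict(f_F=f_f, f_M1=f_m1, f_M2=f_m2, extinct=res.extinct)
        if res.extinct:
            rec.update(dF=np.nan, dM1=np.nan, dM2=np.nan, afd=np.nan)
        else:
            rec.update(
                dF=res.delta_f[0], dM1=res.delta_f[1], dM2=res.delta_f[2],
                afd=res.afd,
            )
        records.append(rec)
    return pd.DataFrame.from_records(records)


@dataclass
class BoundaryResult:
    """Basin-of-attraction boundary on a two-strain simplex edge."""

    focal: str
    other: str
    grid_step: float
    boundary: float | None            # smallest focal frequency gaining ground
    bracket: tuple[float, float] | None
    delta_by_freq: dict[float, float] = field(default_factory=dict)

    @property
    def no_interior_boundary(self) -> bool:
        signs = {np.sign(v) for v in self.delta_by_freq.values()}
        return len(signs - {0.0}) <= 1


_HOMOZYGOTE_OF = {"F": "FF", "M1": "M1M1", "M2": "M2M2"}


def basin_boundary(
    params: ModelParams,
    focal: str,
    other: str,
    grid_step: float = 0.1,
    week_start: int = 1,
) -> BoundaryResult:
    """Locate where the focal allele starts gaining on a two-strain edge.

    Sweeps the focal strain's initial frequency over the interior grid (the
    competitor at the complement) and reports the smallest frequency at which
    the focal allele's one-season change is positive, with its bracketing
    interval.  If the change never switches sign there is no interior
    boundary.
    """
    if focal not in _HOMOZYGOTE_OF or other not in _HOMOZYGOTE_OF:
        raise ValueError("focal/other must be allele labels F, M1 or M2")
    n = round(1.0 / grid_step)
    if abs(n * grid_step - 1.0) > 1e-9:
        raise ValueError("grid_step must divide 1")
    focal_idx = ALLELES.index(focal)
    deltas: dict[float, float] = {}
    for k in range(1, n):
        f = k / n
        res = run_season(
            {_HOMOZYGOTE_OF[focal]: f, _HOMOZYGOTE_OF[other]: 1.0 - f},
            params,
            week_start,
        )
        deltas[f] = float("nan") if res.extinct else float(res.delta_f[focal_idx])

    boundary = None
    bracket = None
    prev = 0.0
    for f in sorted(deltas):
        if deltas[f] > 0:
            boundary = f
            bracket = (prev, f)
            break
        prev = f
    return BoundaryResult(
        focal=focal, other=other, grid_step=grid_step,
        boundary=boundary, bracket=bracket, delta_by_freq=deltas,
    )


@dataclass
class LogisticFit:
    """Logistic regression of winning probability on initial frequency."""

    intercept: float
    slope: float
    separated: bool = False
    converged: bool = True

    def predict(self, x: np.ndarray) -> np.ndarray:
        z = self.intercept + self.slope * np.asarray(x, dtype=float)
        return 1.0 / (1.0 + np.exp(-z))


def winning_probability_fit(
    results: Sequence[tuple[float, bool]],
) -> LogisticFit:
    """Maximum-likelihood logistic fit of P(focal strain wins) vs initial freq.

    Perfect separation (including all-win / all-lose inputs) is flagged and
    the returned curve degenerates to a step at the midpoint between the
    outcome classes.
    """
    if len(results) < 2:
        raise ValueError("need at least two outcomes to fit")
    x = np.array([r[0] for r in results], dtype=float)
    y = np.array([1.0 if r[1] else 0.0 for r in results])

    wins, losses = x[y == 1], x[y == 0]
    if len(wins) == 0 or len(losses) == 0 or wins.min() > losses.max():
        # perfectly separated: represent as a (steep) step
        if len(wins) == 0:
            mid, sign = x.max() + 1.0, 1.0
        elif len(losses) == 0:
            mid, sign = x.min() - 1.0, 1.0
        else:
            mid, sign = 0.5 * (wins.min() + losses.max()), 1.0
        slope = sign * 1e3
        return LogisticFit(intercept=-slope * mid, slope=slope, separated=True)

    import statsmodels.api as sm

    X = sm.add_constant(x)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception:
        return LogisticFit(intercept=0.0, slope=0.0, separated=True,
                           converged=False)
    intercept, slope = fit.params
    return LogisticFit(
        intercept=float(intercept), slope=float(slope),
        separated=False, converged=bool(fit.mle_retvals.get("converged", True)),
    )


def trajectory_frame(result: SeasonResult) -> pd.DataFrame:
    """Tidy weekly aggregates (genotype-level) of a season, for CSV export."""
    n_weeks, _ = result.weekly_eggs.shape
    weeks = np.arange(result.week_start, result.week_start + n_weeks)
    frames = []
    for name, data in (
        ("larvae", result.weekly_larvae),
        ("pending", result.weekly_pending),
        ("eggs", result.weekly_eggs),
    ):
        df = pd.DataFrame(data, columns=list(GENOTYPES))
        df.insert(0, "week", weeks)
        df = df.melt(id_vars="week", var_name="genotype", value_name="mass")
        df.insert(1, "stage", name)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
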