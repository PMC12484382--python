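"""Within-tide mating kinetics and weekly egg production.

Adults live a few hours: each emergence week the cohort is split over five
days (10/20/40/20/10 % of adults), and within each day pairs form by mass
action at rate b*F*M_S, where M_S are searching males.  A mating occupies the
male for an average handling time tau before he resumes searching; females
mate once and leave the virgin pool:

    dF/dt   = -b F M_S
    dM_S/dt = -b F M_S + M_O / tau
    dM_O/dt =  b F M_S - M_O / tau,      M_O(0) = 0.

The window closes at t_end and the mated fraction is p = 1 - F(t_end)/F(0).
With tau = 0.25 and t_end = 1 a male can service at most four females; finite
search efficiency b wastes search time and yields fewer — the mate-finding
Allee effect.

Scenario structure: under *ecological* mixing each genotype forms its own
mating pool even when strains co-emerge (no hybridisation); under *random*
mixing all co-emerging adults share one pool per day with sires drawn in
proportion to male genotype frequencies.  Setting ``mate_finding="p1"``
bypasses the kinetics entirely (every female mates).

The system is integrated with LSODA (adaptive, stiffness-switching); the
saturated-search regimes used for capacity checks (b up to 1e6) are far too
stiff for explicit Runge-Kutta steppers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .demography import (
    FEMALE,
    MALE,
    MAX_PENDING,
    N_GENOTYPES,
    EmergenceCohort,
    ModelParams,
)
from .genetics import GENOTYPES, mendelian_table, viability_vector

_MENDEL = mendelian_table()  # (mother, sire, offspring-in-ALL_GENOTYPES)

_RTOL = 1e-8
_ATOL_SCALE = 1e-10


class MatingSolverError(RuntimeError):
    """The pair-formation ODE solver failed to converge."""


@dataclass
class MatingPool:
    """One day's mating arena: female and male masses by (genotype, D)."""

    females: np.ndarray
    males: np.ndarray
    scenario: str = "ecological"


@dataclass
class MatingOutcome:
    """Weekly mating result aggregated over the five emergence days.

    ``p`` is the overall probability that a female was mated;
    ``mated_females[g, d]`` the mated female mass by genotype and pending
    duration D = d+1; ``sire_dist`` the sire genotype distribution (pooled
    male genotype frequencies) under random mixing, or None under ecological
    mixing where sires always match the mother's genotype.
    """

    p: float
    mated_females: np.ndarray = field(
        default_factory=lambda: np.zeros((N_GENOTYPES, MAX_PENDING))
    )
    sire_dist: np.ndarray | None = None
    scenario: str = "ecological"


def _integrate(F0, M0, b, tau, t_end, t_eval=None):
    def rhs(_t, y):
        f, ms, mo = y
        pairing = b * f * ms
        release = mo / tau
        return (-pairing, -pairing + release, pairing - release)

    atol = [_ATOL_SCALE * max(F0, 1.0)] + [_ATOL_SCALE * max(M0, 1.0)] * 2
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        (F0, M0, 0.0),
        method="LSODA",
        rtol=_RTOL,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise MatingSolverError(
            f"mating kinetics failed (F0={F0}, M0={M0}, b={b}): {sol.message}"
        )
    return sol


def solve_mating(F0: float, M0: float, b: float, tau: float, t_end: float) -> float:
    """Mated-female probability p = 1 - F(t_end)/F(0) for one pool.

    Degenerate pools (no females, no males, or b = 0) return p = 0 without
    touching the solver.  Negative solver dust is clipped so p stays in [0, 1].
    """
    if F0 < 0 or M0 < 0:
        raise ValueError("pool masses must be non-negative")
    if b < 0:
        raise ValueError("search efficiency b must be non-negative")
    if F0 == 0 or M0 == 0 or b == 0:
        return 0.0
    sol = _integrate(F0, M0, b, tau, t_end)
    f_end = min(max(float(sol.y[0, -1]), 0.0), F0)
    return 1.0 - f_end / F0


def matings_per_male(
    F0: float, M0: float, b: float, tau: float, t_end: float
) -> float:
    """Completed matings per male over one mating window.

    A pairing removes the female immediately but counts as a mating for the
    male only once his handling time is over, so completed matings are female
    depletion minus the males still occupied when the window closes:
    (F(0) - F(t_end) - M_O(t_end)) / M0.  In the saturated-search limit every
    male is occupied throughout and the count approaches t_end / tau (4 with
    the default tau = 0.25, t_end = 1); finite b wastes search time and yields
    fewer.
    """
    if M0 <= 0:
        raise ValueError("need a positive male pool")
    if F0 == 0 or b == 0:
        return 0.0
    sol = _integrate(F0, M0, b, tau, t_end)
    f_end = min(max(float(sol.y[0, -1]), 0.0), F0)
    occupied = min(max(float(sol.y[2, -1]), 0.0), M0)
    return (F0 - f_end - occupied) / M0


def mating_trajectory(
    F0: float, M0: float, b: float, tau: float, t_end: float, n_points: int = 101
) -> np.ndarray:
    """(n, 4) array of (t, F, M_S, M_O) along the mating window (for probing)."""
    t_eval = np.linspace(0.0, t_end, n_points)
    if F0 == 0 or M0 == 0 or b == 0:
        return np.column_stack(
            [t_eval, np.full_like(t_eval, F0), np.full_like(t_eval, M0),
             np.zeros_like(t_eval)]
        )
    sol = _integrate(F0, M0, b, tau, t_end, t_eval=t_eval)
    return np.column_stack([sol.t, sol.y[0], sol.y[1], sol.y[2]])


def split_daily_pools(
    cohort: EmergenceCohort, daily_split: tuple[float, ...]
) -> list[MatingPool]:
    """Apportion a weekly emergence cohort over the five mating days."""
    if abs(sum(daily_split) - 1.0) > 1e-9:
        raise ValueError("daily_split must sum to 1")
    return [
        MatingPool(
            females=cohort.adults[FEMALE] * s,
            males=cohort.adults[MALE] * s,
        )
        for s in daily_split
    ]


def mating_week(cohort: EmergenceCohort, params: ModelParams) -> MatingOutcome:
    """Mate one week's emergence cohort, aggregating the five daily windows.

    Under ecological mixing each genotype's pool is solved separately per day,
    so a rare genotype suffers a smaller pool (the Allee effect is
    strain-specific); under random mixing one pooled solve per day applies a
    common p to every female genotype.  D never affects mating, only the
    female's later fecundity.
    """
    females = cohort.adults[FEMALE]
    males = cohort.adults[MALE]
    total_females = females.sum()
    outcome = MatingOutcome(p=0.0, scenario=params.mixing)

    total_males = males.sum()
    if params.mixing == "random" and total_males > 0:
        outcome.sire_dist = males.sum(axis=1) / total_males

    if total_females == 0:
        return outcome

    if params.mate_finding == "p1":
        if total_males > 0:
            outcome.mated_females = females.copy()
            outcome.p = 1.0
        return outcome

    mated = np.zeros_like(females)
    for pool in split_daily_pools(cohort, params.daily_split):
        if params.mixing == "ecological":
            for g in range(N_GENOTYPES):
                p_g = solve_mating(
                    pool.females[g].sum(), pool.males[g].sum(),
                    params.b, params.tau, params.t_end,
                )
                mated[g] += p_g * pool.females[g]
        else:
            p_day = solve_mating(
                pool.females.sum(), pool.males.sum(),
                params.b, params.tau, params.t_end,
            )
            mated += p_day * pool.females
    outcome.mated_females = mated
    outcome.p = float(mated.sum() / total_females)
    return outcome


def reproduce(
    outcome: MatingOutcome, params: ModelParams
) -> tuple[np.ndarray, float]:
    """Per-genotype egg production of a mating week.

    Each mated female lays C_D eggs; under random mixing the clutch is
    distributed over sires in proportion to their genotype frequencies and
    over offspring genotypes by exact Mendelian proportions, with hybrid eggs
    weighted by the viability gamma.  Ecological mixing has no hybrids, so
    offspring simply inherit the mother's genotype at full viability.

    Returns ``(eggs, discarded)`` where ``eggs`` is the (5,) viable egg mass
    entering the weekly cohort and ``discarded`` any inviable M1M2 mass
    (possible only under F dominance, where F-phenotype FM1/FM2 heterozygotes
    can co-emerge with the opposite monthly homozygote).
    """
    clutch = outcome.mated_females @ np.asarray(params.fecundity)  # (5,)
    if outcome.scenario == "ecological" or outcome.sire_dist is None:
        return clutch, 0.0
    # eggs6[o] = sum_{g,s} clutch[g] * sire_dist[s] * mendel[g, s, o]
    eggs6 = np.einsum("g,s,gso->o", clutch, outcome.sire_dist, _MENDEL)
    viable = eggs6 * viability_vector(params.gamma, params.dominance)
    return viable[:N_GENOTYPES], float(eggs6[-1])
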