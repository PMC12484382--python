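"""Weekly stage-structured larval demography with lunar-cue emergence gating.

The within-season engine tracks continuous (real-valued) masses of larvae by
genotype and age (1..11 weeks), and of "pending" individuals — developmentally
mature larvae waiting, sexed, for their strain's lunar cue — by sex, genotype
and weeks-spent-pending D (1..4).  All weekly transitions fire simultaneously
from last week's state:

* eggs laid this week enter next week's age-1 class after one application of
  the youngest class's survival;
* larvae of age 1-5 survive and age; from age 6 onwards a fraction m_i of the
  survivors becomes pending (split 1:1 by sex), the rest keep aging, and
  development always completes by age 11 (m_11 = 1);
* pending individuals whose cue arrives this week emerge as adults (and mate
  within the week); otherwise they survive with D incremented.

Weekly survival is density dependent, S = S_max * exp(-alpha * N^2), where N
counts all larvae including pending ones.  In the ontogenetic niche-shift
scenario larvae younger than ``w`` weeks compete in Niche 1 and older plus
pending larvae in Niche 2, each niche with its own alpha.  Survival rates are
evaluated once per week from the pre-transition state and applied to every
transition of that week, including the eggs -> age-1 arrow (hatching eggs do
not themselves contribute to the density terms).

Emergence cues: full-moon low tides fall on weeks divisible by 4, new-moon low
tides on weeks T with T mod 4 == 2.  The monthly phenotypes use one of the two,
the fortnightly phenotype uses both, so a fortnightly individual never waits
more than 2 weeks pending and a monthly one never more than 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .genetics import (
    DOMINANCE_MODES,
    GENOTYPE_INDEX,
    GENOTYPES,
    PHENOTYPES,
    phenotype_codes,
)

N_GENOTYPES = len(GENOTYPES)
N_AGES = 11            # larval ages 1..11 weeks
MAX_PENDING = 4        # pending durations D = 1..4 weeks
MATURE_AGE = 6         # youngest age at which larvae may become pending
SEXES = ("female", "male")
FEMALE, MALE = 0, 1

NICHE_MODES = ("single", "shift")
MIXING_MODES = ("ecological", "random")
MATE_FINDING_MODES = ("p1", "ode")

DEFAULT_MATURATION = (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
DEFAULT_DAILY_SPLIT = (0.10, 0.20, 0.40, 0.20, 0.10)


class PendingOverflowError(RuntimeError):
    """A pending class would exceed the structural maximum duration."""


class ExtinctionError(RuntimeError):
    """The population produced no eggs to carry over the winter."""


@dataclass(frozen=True)
class ModelParams:
    """All model parameters and scenario switches.

    Parameters
    ----------
    s_max
        Weekly survival under unlimited resources (0-1].
    alpha
        Density-dependence strength (per larvae^2), single-niche scenario.
    alpha_n1, alpha_n2
        Niche-specific density strengths (niche-shift scenario).
    w
        Age (weeks) of the ontogenetic niche shift; larvae of age < w feed in
        Niche 1, older and pending larvae in Niche 2.
    maturation
        m_6..m_11: weekly probabilities of entering the pending state at ages
        6..11; m_11 must be 1 (development completes by 11 weeks).
    gamma
        Hatching viability of hybrid (cross-strain) eggs relative to
        pure-strain eggs.
    fecundity
        C_D for D = 1..4: clutch size of a female that spent D weeks pending.
        A rising schedule implements the growth-survival tradeoff.
    b
        Mate-search efficiency (per female x male x time) of the within-tide
        pair-formation kinetics.  Only used when ``mate_finding == "ode"``.
    tau
        Mean mating (handling) duration, in mating-time units.
    t_end
        Length of the mating window, in mating-time units.
    daily_split
        Fractions of a weekly emergence cohort emerging on days 1-5.
    season_weeks
        Weeks per season during which mating can occur (default 44).
    n0
        Overwinter egg total: every season starts from n0 age-1 larvae.
    niche
        "single" (shared resource) or "shift" (ontogenetic niche shift).
    mixing
        "ecological": strains form separate mating pools even when
        co-emerging (no hybridisation); "random": co-emerging adults mate
        without assortment.
    mate_finding
        "p1": all females mate (mate limitation switched off); "ode": the
        mated fraction p comes from the pair-formation kinetics.
    dominance
        "F_recessive" (default) or "F_dominant".
    """

    s_max: float = 0.85
    alpha: float = 1e-8
    alpha_n1: float = 1e-8
    alpha_n2: float = 2.6e-8
    w: int = 2
    maturation: tuple[float, ...] = DEFAULT_MATURATION
    gamma: float = 1.0
    fecundity: tuple[float, float, float, float] = (100.0, 100.0, 100.0, 100.0)
    b: float = 5e-3
    tau: float = 0.25
    t_end: float = 1.0
    daily_split: tuple[float, ...] = DEFAULT_DAILY_SPLIT
    season_weeks: int = 44
    n0: float = 10_000.0
    niche: str = "single"
    mixing: str = "ecological"
    mate_finding: str = "p1"
    dominance: str = "F_recessive"

    def __post_init__(self) -> None:
        if not 0.0 < self.s_max <= 1.0:
            raise ValueError("s_max must lie in (0, 1]")
        for name in ("alpha", "alpha_n1", "alpha_n2", "b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if len(self.maturation) != N_AGES - MATURE_AGE + 1:
            raise ValueError("maturation must give m_6..m_11 (6 values)")
        if any(not 0.0 <= m <= 1.0 for m in self.maturation):
            raise ValueError("maturation probabilities must lie in [0, 1]")
        if self.maturation[-1] != 1.0:
            raise ValueError("m_11 must equal 1 (development completes by 11 weeks)")
        if len(self.fecundity) != MAX_PENDING or any(c <= 0 for c in self.fecundity):
            raise ValueError("fecundity must give positive C_D for D = 1..4")
        if self.tau <= 0 or self.t_end <= 0:
            raise ValueError("tau and t_end must be positive")
        if len(self.daily_split) != 5 or any(s < 0 for s in self.daily_split):
            raise ValueError("daily_split must be 5 non-negative fractions")
        if abs(sum(self.daily_split) - 1.0) > 1e-9:
            raise ValueError("daily_split must sum to 1")
        if self.niche not in NICHE_MODES:
            raise ValueError(f"niche must be one of {NICHE_MODES}")
        if self.niche == "shift" and not 2 <= self.w <= N_AGES:
            raise ValueError("niche-shift age w must lie in 2..11")
        if self.mixing not in MIXING_MODES:
            raise ValueError(f"mixing must be one of {MIXING_MODES}")
        if self.mate_finding not in MATE_FINDING_MODES:
            raise ValueError(f"mate_finding must be one of {MATE_FINDING_MODES}")
        if self.dominance not in DOMINANCE_MODES:
            raise ValueError(f"dominance must be one of {DOMINANCE_MODES}")
        if self.season_weeks < 1:
            raise ValueError("season_weeks must be positive")
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")

    def with_overrides(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    @property
    def phenotypes(self) -> np.ndarray:
        """(5,) genotype -> phenotype code under this dominance rule."""
        return phenotype_codes(self.dominance)


@dataclass
class PopulationState:
    """Larval population at the start of week ``week``.

    ``larvae[g, i]`` is the mass of unsexed, non-pending larvae of genotype g
    and age i+1 weeks; ``pending[s, g, d]`` the mass of pending individuals of
    sex s (0 female, 1 male), genotype g, that have spent d+1 weeks pending.
    """

    week: int
    larvae: np.ndarray = field(
        default_factory=lambda: np.zeros((N_GENOTYPES, N_AGES))
    )
    pending: np.ndarray = field(
        default_factory=lambda: np.zeros((2, N_GENOTYPES, MAX_PENDING))
    )

    def total_mass(self) -> float:
        return float(self.larvae.sum() + self.pending.sum())

    def copy(self) -> "PopulationState":
        return PopulationState(self.week, self.larvae.copy(), self.pending.copy())


@dataclass
class EmergenceCohort:
    """Adults emerging (and mating) in week ``week``.

    ``adults[s, g, d]`` by sex, genotype and weeks D spent pending; D feeds
    female fecundity C_D only, never male function.
    """

    week: int
    adults: np.ndarray = field(
        default_factory=lambda: np.zeros((2, N_GENOTYPES, MAX_PENDING))
    )

    @property
    def females(self) -> np.ndarray:
        return self.adults[FEMALE]

    @property
    def males(self) -> np.ndarray:
        return self.adults[MALE]

    def total(self) -> float:
        return float(self.adults.sum())


def emergence_cue(week: int, phenotype: str) -> bool:
    """Whether week ``week`` carries an emergence cue for ``phenotype``.

    Full-moon weeks (week mod 4 == 0) cue the M1 and F phenotypes; new-moon
    weeks (week mod 4 == 2) cue M2 and F.
    """
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    if week % 4 == 0:
        return phenotype in ("M1", "F")
    if week % 4 == 2:
        return phenotype in ("M2", "F")
    return False


def survival_single(n_larvae: float, params: ModelParams) -> float:
    """Single-niche weekly survival S = S_max * exp(-alpha * N^2)."""
    if n_larvae < 0:
        raise ValueError("larval mass must be non-negative")
    return params.s_max * float(np.exp(-params.alpha * n_larvae**2))


def niche_masses(state: PopulationState, params: ModelParams) -> tuple[float, float]:
    """Larval masses competing in Niche 1 (ages < w) and Niche 2 (rest + pending)."""
    w = params.w
    n1 = float(state.larvae[:, : w - 1].sum())
    n2 = float(state.larvae[:, w - 1 :].sum() + state.pending.sum())
    return n1, n2


def survival_rates(
    state: PopulationState, params: ModelParams
) -> tuple[np.ndarray, float, float]:
    """Per-age survival vector plus hatchling and pending survival for this week.

    Returns ``(s_age, s_hatch, s_pend)`` where ``s_age[i]`` applies to larvae
    currently aged i+1, ``s_hatch`` to the eggs -> age-1 arrow and ``s_pend``
    to pending individuals, all evaluated once from the pre-transition state.
    """
    if params.niche == "single":
        s = survival_single(state.total_mass(), params)
        return np.full(N_AGES, s), s, s
    n1, n2 = niche_masses(state, params)
    s1 = params.s_max * float(np.exp(-params.alpha_n1 * n1**2))
    s2 = params.s_max * float(np.exp(-params.alpha_n2 * n2**2))
    s_age = np.full(N_AGES, s2)
    s_age[: params.w - 1] = s1
    return s_age, s1, s2


def _cue_mask(week: int, params: ModelParams) -> np.ndarray:
    """(5,) boolean: genotypes whose phenotype receives a cue this week."""
    phen = params.phenotypes
    return np.array(
        [emergence_cue(week, PHENOTYPES[phen[g]]) for g in range(N_GENOTYPES)]
    )


def emergence_cohort(state: PopulationState, params: ModelParams) -> EmergenceCohort:
    """Adults that emerge in the state's current week (pending mass x survival)."""
    _, _, s_pend = survival_rates(state, params)
    cohort = EmergenceCohort(week=state.week)
    mask = _cue_mask(state.week, params)
    cohort.adults[:, mask, :] = state.pending[:, mask, :] * s_pend
    return cohort


def weekly_update(
    state: PopulationState,
    params: ModelParams,
    eggs_in: np.ndarray | None = None,
) -> tuple[PopulationState, EmergenceCohort]:
    """Apply one week of simultaneous transitions.

    ``eggs_in`` is this week's per-genotype egg output (clutch size and hybrid
    viability already applied by the mating step); those eggs receive the
    youngest class's survival of the laying week and appear as age-1 larvae in
    the returned state.  Returns the new state (week advanced by one) and the
    cohort of adults that emerged this week (already removed from the state).
    """
    s_age, s_hatch, s_pend = survival_rates(state, params)
    week = state.week

    new_larvae = np.zeros_like(state.larvae)
    new_pending = np.zeros_like(state.pending)

    if eggs_in is not None:
        eggs_in = np.asarray(eggs_in, dtype=float)
        if eggs_in.shape != (N_GENOTYPES,) or np.any(eggs_in < 0):
            raise ValueError("eggs_in must be a non-negative (5,) vector")
        new_larvae[:, 0] = eggs_in * s_hatch

    # larval aging and maturation into the (sexed) pending state
    for i in range(N_AGES):
        age = i + 1
        survivors = state.larvae[:, i] * s_age[i]
        if age >= MATURE_AGE:
            m_i = params.maturation[age - MATURE_AGE]
            to_pending = survivors * m_i
            new_pending[FEMALE, :, 0] += 0.5 * to_pending
            new_pending[MALE, :, 0] += 0.5 * to_pending
            survivors = survivors * (1.0 - m_i)
        if age < N_AGES:
            new_larvae[:, i + 1] += survivors
        elif np.any(survivors > 0):  # pragma: no cover - m_11 == 1 forbids this
            raise PendingOverflowError("age-11 larvae failed to mature (m_11 < 1)")

    # pending: emerge on a matching cue, otherwise survive with D + 1
    mask = _cue_mask(week, params)
    cohort = EmergenceCohort(week=week)
    cohort.adults[:, mask, :] = state.pending[:, mask, :] * s_pend
    waiting = state.pending[:, ~mask, :] * s_pend
    if np.any(waiting[:, :, -1] > 0):
        raise PendingOverflowError(
            f"pending mass would exceed {MAX_PENDING} weeks at week {week}"
        )
    new_pending[:, ~mask, 1:] += waiting[:, :, :-1]

    return PopulationState(week + 1, new_larvae, new_pending), cohort


def init_population(
    freqs: Mapping[str, float],
    params: ModelParams,
    week_start: int = 1,
) -> PopulationState:
    """Fresh season: ``n0`` age-1 larvae apportioned by genotype frequency."""
    vec = np.zeros(N_GENOTYPES)
    for g, f in freqs.items():
        if g not in GENOTYPE_INDEX:
            raise ValueError(f"unknown or disallowed genotype {g!r}")
        if f < 0:
            raise ValueError(f"negative frequency for {g!r}")
        vec[GENOTYPE_INDEX[g]] = f
    if abs(vec.sum() - 1.0) > 1e-9:
        raise ValueError("genotype frequencies must sum to 1")
    state = PopulationState(week=week_start)
    state.larvae[:, 0] = params.n0 * vec
    return state
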