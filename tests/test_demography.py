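"""Weekly transitions, density-dependent survival and cue gating."""

import numpy as np
import pytest

from cluniosim import (
    ModelParams,
    PopulationState,
    emergence_cue,
    init_population,
    niche_masses,
    run_season,
    survival_single,
    weekly_update,
)
from cluniosim.demography import (
    FEMALE,
    MALE,
    MAX_PENDING,
    N_AGES,
    N_GENOTYPES,
    PendingOverflowError,
    survival_rates,
)
from cluniosim.genetics import GENOTYPE_INDEX


def test_survival_under_unlimited_resources_is_smax(flat_params):
    assert survival_single(0.0, flat_params) == pytest.approx(0.85)


def test_survival_matches_gaussian_form(flat_params):
    # 10,000 larvae with alpha = 1e-8: exponent exactly -1
    s = survival_single(10_000.0, flat_params)
    assert s == pytest.approx(0.85 * np.exp(-1.0), rel=1e-12)


def test_survival_strictly_decreasing_in_density(flat_params):
    grid = np.linspace(0, 50_000, 11)
    vals = [survival_single(n, flat_params) for n in grid]
    assert all(a > b for a, b in zip(vals, vals[1:]))


@pytest.mark.parametrize(
    "week,phenotype,expected",
    [
        (8, "M1", True), (8, "F", True), (8, "M2", False),
        (10, "M2", True), (10, "F", True), (10, "M1", False),
        (9, "F", False), (9, "M1", False), (11, "M2", False),
        (4, "M1", True), (2, "M2", True),
    ],
)
def test_emergence_cue_follows_lunar_modulo(week, phenotype, expected):
    assert emergence_cue(week, phenotype) is expected


def test_niche_masses_split_by_shift_age():
    p = ModelParams(niche="shift", w=2)
    state = PopulationState(week=1)
    state.larvae[GENOTYPE_INDEX["M1M1"], 0] = 10_000.0  # age 1
    assert niche_masses(state, p) == (10_000.0, 0.0)

    state = PopulationState(week=1)
    state.larvae[GENOTYPE_INDEX["M1M1"], 2] = 500.0     # age 3
    state.pending[FEMALE, GENOTYPE_INDEX["M1M1"], 0] = 100.0
    assert niche_masses(state, p) == (0.0, 600.0)

    assert niche_masses(PopulationState(week=1), p) == (0.0, 0.0)


def test_pure_aging_conserves_mass(lossless_params):
    state = init_population({"M1M1": 1.0}, lossless_params)
    for _ in range(8):
        before = state.total_mass()
        state, _ = weekly_update(state, lossless_params)
        assert state.total_mass() == pytest.approx(before, rel=1e-12)


def test_first_transition_applies_density_dependent_survival(flat_params):
    state = init_population({"FF": 1.0}, flat_params)  # 10,000 age-1 larvae
    new, _ = weekly_update(state, flat_params)
    assert new.larvae[GENOTYPE_INDEX["FF"], 1] == pytest.approx(
        10_000 * 0.85 * np.exp(-1.0), rel=1e-9
    )
    assert new.week == 2


def test_pending_without_cue_advances_duration():
    p = ModelParams(s_max=1.0, alpha=0.0)
    state = PopulationState(week=7)
    g = GENOTYPE_INDEX["M1M1"]
    state.pending[FEMALE, g, 0] = 100.0  # D = 1 at week 7 (no cue)
    new, cohort = weekly_update(state, p)
    assert cohort.total() == 0.0
    assert new.pending[FEMALE, g, 1] == pytest.approx(100.0)
    assert new.week == 8


def test_pending_with_cue_emerges_and_leaves_state():
    p = ModelParams(s_max=1.0, alpha=0.0)
    state = PopulationState(week=8)  # full-moon week: M1 and F cues
    g = GENOTYPE_INDEX["M1M1"]
    state.pending[MALE, g, 1] = 40.0
    new, cohort = weekly_update(state, p)
    assert cohort.adults[MALE, g, 1] == pytest.approx(40.0)
    assert new.pending.sum() == 0.0


def test_pending_overflow_is_detected():
    p = ModelParams(s_max=1.0, alpha=0.0)
    state = PopulationState(week=9)  # no cue for anyone
    state.pending[FEMALE, GENOTYPE_INDEX["M1M1"], MAX_PENDING - 1] = 1.0
    with pytest.raises(PendingOverflowError):
        weekly_update(state, p)


def test_eggs_enter_with_youngest_class_survival(flat_params):
    state = PopulationState(week=3)  # empty: survival = s_max
    eggs = np.zeros(N_GENOTYPES)
    eggs[GENOTYPE_INDEX["FF"]] = 1000.0
    new, _ = weekly_update(state, flat_params, eggs_in=eggs)
    assert new.larvae[GENOTYPE_INDEX["FF"], 0] == pytest.approx(850.0)


def test_init_population_apportions_by_frequency(flat_params):
    state = init_population({"FF": 0.2, "M1M1": 0.8}, flat_params)
    assert state.larvae[GENOTYPE_INDEX["FF"], 0] == pytest.approx(2000.0)
    assert state.larvae[GENOTYPE_INDEX["M1M1"], 0] == pytest.approx(8000.0)
    assert state.larvae[:, 1:].sum() == 0.0
    with pytest.raises(ValueError):
        init_population({"FF": 0.5}, flat_params)
    with pytest.raises(ValueError):
        init_population({"FF": 1.5, "M1M1": -0.5}, flat_params)


def test_shift_mode_uses_niche_specific_survival():
    p = ModelParams(niche="shift", w=3, alpha_n1=1e-8, alpha_n2=2.6e-8)
    state = PopulationState(week=1)
    state.larvae[0, 0] = 10_000.0   # niche 1
    state.larvae[0, 5] = 10_000.0   # niche 2
    s_age, s_hatch, s_pend = survival_rates(state, p)
    assert s_age[0] == pytest.approx(0.85 * np.exp(-1e-8 * 1e8))
    assert s_age[5] == pytest.approx(0.85 * np.exp(-2.6e-8 * 1e8))
    assert s_hatch == s_age[0] and s_pend == s_age[-1]


def test_mass_non_negative_along_a_full_season(flat_params, equal_thirds):
    res = run_season(equal_thirds, flat_params)
    assert np.all(res.weekly_larvae >= 0)
    assert np.all(res.weekly_pending >= 0)
    assert np.all(res.weekly_eggs >= 0)


def test_maximum_pending_durations_by_phenotype(flat_params, equal_thirds):
    """Fortnightly individuals wait at most 2 weeks, monthly at most 4."""
    res = run_season(equal_thirds, flat_params)
    f_max, m1_max, m2_max = res.max_pending_by_phenotype
    assert f_max <= 2
    assert m1_max <= MAX_PENDING and m2_max <= MAX_PENDING
    # all three strains actually used the pending state
    assert f_max >= 1 and m1_max >= 1 and m2_max >= 1


def test_single_strain_reaches_bounded_seasonal_cycle():
    """Late-season larval mass cycles within bounds and falls with alpha."""
    equilibria = []
    for alpha in (5e-9, 1e-8, 2e-8):
        p = ModelParams(alpha=alpha)
        res = run_season({"M1M1": 1.0}, p)
        tail = res.weekly_larvae.sum(axis=1)[-16:]
        assert tail.max() < 1e6  # bounded
        equilibria.append(tail.mean())
    assert equilibria[0] > equilibria[1] > equilibria[2]


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ModelParams(s_max=0.0)
    with pytest.raises(ValueError):
        ModelParams(maturation=(0.1, 0.3, 0.5, 0.7, 0.9, 0.9))  # m_11 != 1
    with pytest.raises(ValueError):
        ModelParams(daily_split=(0.5, 0.5, 0.0, 0.0, 0.1))
    with pytest.raises(ValueError):
        ModelParams(niche="shift", w=1)
    with pytest.raises(ValueError):
        ModelParams(gamma=-0.1)
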