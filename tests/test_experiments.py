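"""Season/multi-year orchestration, AFD, sweeps and winner analysis."""

import numpy as np
import pytest

from cluniosim import (
    ExtinctionError,
    ModelParams,
    basin_boundary,
    compute_afd,
    overwinter,
    run_multi_year,
    run_season,
    ternary_sweep,
    winning_probability_fit,
)
from cluniosim.experiments import trajectory_frame
from cluniosim.genetics import GENOTYPE_INDEX


@pytest.mark.parametrize(
    "f0,f1,expected",
    [
        ((0.2, 0.3, 0.5), (0.2, 0.3, 0.5), 0.0),
        ((1, 0, 0), (0, 1, 0), 1.0),
        ((0.5, 0.5, 0.0), (0.6, 0.4, 0.0), 0.1),
    ],
)
def test_afd_is_half_l1_distance(f0, f1, expected):
    assert compute_afd(np.array(f0), np.array(f1)) == pytest.approx(expected)


def test_single_strain_season_has_zero_afd(flat_params):
    res = run_season({"M1M1": 1.0}, flat_params)
    assert not res.extinct
    assert res.afd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(res.delta_f, 0.0, atol=1e-12)


def test_delta_f_sums_to_zero_and_afd_in_unit_interval(flat_params, equal_thirds):
    res = run_season(equal_thirds, flat_params)
    assert res.delta_f.sum() == pytest.approx(0.0, abs=1e-9)
    assert 0.0 <= res.afd <= 1.0


def test_fortnightly_strain_gains_without_tradeoff(flat_params, equal_thirds):
    """Flat fecundity, shared niche, no Allee effect: the strain reproducing
    at every opportunity outcompetes both monthly strains."""
    res = run_season(equal_thirds, flat_params)
    assert res.delta_f[0] > 0  # F allele


def test_ecological_mode_conserves_allele_identity(flat_params):
    """No mutation, no hybrids: alleles absent at the start stay absent."""
    res = run_season({"M1M1": 0.5, "M2M2": 0.5}, flat_params)
    assert res.final_freqs[0] == 0.0  # F allele never appears
    assert res.weekly_eggs[:, GENOTYPE_INDEX["FM1"]].sum() == 0.0
    assert res.weekly_eggs[:, GENOTYPE_INDEX["FF"]].sum() == 0.0


def test_label_symmetry_under_m1_m2_exchange(flat_params):
    """Swapping the monthly strains and shifting the season start by two weeks
    relabels the dynamics exactly (cue weeks trade places)."""
    a = run_season({"M1M1": 0.7, "M2M2": 0.3}, flat_params, week_start=1)
    b = run_season({"M1M1": 0.3, "M2M2": 0.7}, flat_params, week_start=3)
    m1, m2 = GENOTYPE_INDEX["M1M1"], GENOTYPE_INDEX["M2M2"]
    np.testing.assert_allclose(
        a.weekly_eggs[:, m1], b.weekly_eggs[:, m2], rtol=1e-10, atol=1e-10
    )
    np.testing.assert_allclose(
        a.weekly_eggs[:, m2], b.weekly_eggs[:, m1], rtol=1e-10, atol=1e-10
    )
    assert a.delta_f[1] == pytest.approx(b.delta_f[2], abs=1e-10)


def test_overwinter_normalizes_preserving_proportions():
    pool = overwinter(np.array([3000.0, 0, 0, 1000.0, 0]), 10_000.0)
    np.testing.assert_allclose(pool, [7500.0, 0, 0, 2500.0, 0])
    pool = overwinter(np.array([0, 0, 0, 42.0, 0]), 10_000.0)
    assert pool[3] == pytest.approx(10_000.0)
    with pytest.raises(ExtinctionError):
        overwinter(np.zeros(5), 10_000.0)


def test_multi_year_single_strain_wins_trivially(flat_params):
    res = run_multi_year({"M1M1": 1.0}, flat_params, years=3, seed=7)
    assert res.winner == "M1M1"
    assert res.yearly_freqs.shape == (3, 5)
    np.testing.assert_allclose(res.yearly_freqs.sum(axis=1), 1.0, atol=1e-12)


def test_multi_year_is_reproducible_given_seed(flat_params):
    a = run_multi_year({"M1M1": 0.4, "M2M2": 0.6}, flat_params, years=5, seed=3)
    b = run_multi_year({"M1M1": 0.4, "M2M2": 0.6}, flat_params, years=5, seed=3)
    np.testing.assert_array_equal(a.yearly_freqs, b.yearly_freqs)
    np.testing.assert_array_equal(a.week_starts, b.week_starts)
    assert a.winner == b.winner


def test_ternary_sweep_covers_the_simplex(flat_params):
    df = ternary_sweep(flat_params, grid_step=0.5)
    assert len(df) == 6
    np.testing.assert_allclose(
        df[["f_F", "f_M1", "f_M2"]].sum(axis=1), 1.0, atol=1e-12
    )
    # edge points stay on their edge under ecological competition
    edge = df[(df.f_F == 0) & (df.f_M1 > 0) & (df.f_M2 > 0)]
    assert (edge.dF.abs() < 1e-12).all()


def test_basin_boundary_on_tradeoff_edge(tradeoff_params):
    """With the clear growth-survival tradeoff the late monthly strain gains
    only once sufficiently common."""
    br = basin_boundary(tradeoff_params, focal="M2", other="M1", grid_step=0.1)
    assert br.boundary is not None
    assert 0.4 <= br.boundary <= 0.8
    assert br.bracket[1] == br.boundary
    below = [f for f, d in br.delta_by_freq.items() if f < br.boundary]
    assert all(br.delta_by_freq[f] <= 0 for f in below)


def test_basin_boundary_brackets_the_sign_change(flat_params):
    """The reported boundary is the smallest grid frequency with a positive
    one-season gain, bracketed by the last losing grid point below it."""
    br = basin_boundary(flat_params, focal="M2", other="M1", grid_step=0.1)
    assert br.boundary is not None
    assert br.bracket[1] == br.boundary
    assert br.bracket[0] == pytest.approx(br.boundary - 0.1)
    assert br.delta_by_freq[br.boundary] > 0
    assert all(
        d <= 0 for f, d in br.delta_by_freq.items() if f < br.boundary
    )
    assert not br.no_interior_boundary


def test_logistic_fit_recovers_monotone_winning_probability():
    rng = np.random.default_rng(0)
    x = np.tile(np.linspace(0.1, 0.9, 9), 20)
    prob = 1 / (1 + np.exp(-(x - 0.5) * 8))
    y = rng.random(x.size) < prob
    fit = winning_probability_fit(list(zip(x, y)))
    assert not fit.separated
    assert fit.slope > 0
    curve = fit.predict(np.linspace(0, 1, 11))
    assert np.all(np.diff(curve) > 0)


def test_logistic_fit_flags_degenerate_outcomes():
    fit = winning_probability_fit([(0.1, True), (0.5, True), (0.9, True)])
    assert fit.separated
    fit = winning_probability_fit([(0.1, False), (0.9, True), (0.5, False)])
    assert fit.separated  # perfectly separated at 0.7
    assert fit.predict(np.array([0.9]))[0] > 0.99
    assert fit.predict(np.array([0.1]))[0] < 0.01
    # symmetric coin-flip outcomes: slope near zero
    pts = [(x, w) for x in (0.2, 0.5, 0.8) for w in (True, False)]
    fit = winning_probability_fit(pts)
    assert not fit.separated
    assert fit.slope == pytest.approx(0.0, abs=1e-6)


def test_trajectory_frame_is_tidy(flat_params):
    res = run_season({"M1M1": 1.0}, flat_params)
    df = trajectory_frame(res)
    assert set(df.columns) == {"week", "stage", "genotype", "mass"}
    assert set(df.stage) == {"larvae", "pending", "eggs"}
    assert (df.mass >= 0).all()
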