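"""Normalization, Fa/Fmc accounting and uptake rates."""

import copy

import numpy as np
import pytest

from lineagepump.fluorescence import (
    FluorescenceAccount,
    NormalizationError,
    build_accounts,
    compute_Fa,
    compute_Fmc,
    compute_rates,
    normalize_fluorescence,
)
from lineagepump.model import LineageForest

from conftest import make_cell, make_observation


def forest_with_reference_values(values):
    forest = LineageForest(experiment_id="x")
    for i, v in enumerate(values):
        forest.add(make_cell(
            f"C{i}", end=8.0,
            obs=[make_observation(0.0, fluorescence=v),
                 make_observation(4.0, fluorescence=v * 2.0)],
        ))
    return forest


def first_frame_values(forest):
    return sorted(
        c.fluorescence_observations()[0].fluorescence for c in forest
    )


class TestNormalization:
    def test_reference_median_already_100_leaves_values_unchanged(self):
        forest = forest_with_reference_values([50.0, 100.0, 150.0])
        out = normalize_fluorescence(forest)
        assert first_frame_values(out) == [50.0, 100.0, 150.0]
        assert out.normalization_factor == pytest.approx(1.0)

    def test_scale_factor_five(self):
        forest = forest_with_reference_values([10.0, 20.0, 30.0])
        out = normalize_fluorescence(forest)
        assert first_frame_values(out) == [50.0, 100.0, 150.0]

    def test_reference_median_is_exactly_100_after_scaling(self):
        forest = forest_with_reference_values([13.0, 17.0, 41.0, 7.0])
        out = normalize_fluorescence(forest)
        assert float(np.median(first_frame_values(out))) == pytest.approx(100.0)

    def test_scale_invariance(self):
        forest = forest_with_reference_values([13.0, 17.0, 41.0])
        scaled = copy.deepcopy(forest)
        for cell in scaled:
            for obs in cell.observations:
                if obs.fluorescence is not None:
                    obs.fluorescence *= 37.5
        a = normalize_fluorescence(forest)
        b = normalize_fluorescence(scaled)
        assert first_frame_values(a) == pytest.approx(first_frame_values(b))

    def test_idempotence(self):
        forest = forest_with_reference_values([13.0, 17.0, 41.0])
        once = normalize_fluorescence(forest)
        twice = normalize_fluorescence(once)
        assert first_frame_values(once) == pytest.approx(first_frame_values(twice))

    def test_input_forest_is_not_mutated(self):
        forest = forest_with_reference_values([10.0, 20.0, 30.0])
        normalize_fluorescence(forest)
        assert first_frame_values(forest) == [10.0, 20.0, 30.0]

    def test_empty_reference_set_raises(self):
        forest = LineageForest(experiment_id="x")
        forest.add(make_cell("A", obs=[make_observation(0.0)]))
        with pytest.raises(NormalizationError):
            normalize_fluorescence(forest)

    def test_zero_median_is_degenerate(self):
        forest = forest_with_reference_values([0.0, 0.0, 0.0])
        with pytest.raises(NormalizationError, match="degenerate"):
            normalize_fluorescence(forest)


class TestFa:
    def test_last_fluorescence_frame_rule(self):
        cell = make_cell("A", end=9.0, obs=[
            make_observation(0.0, fluorescence=100.0),
            make_observation(4.0, fluorescence=150.0),
            make_observation(8.0, fluorescence=210.0),
            make_observation(9.0, kind="phase"),
        ])
        assert compute_Fa(cell) == 210.0

    def test_single_frame(self):
        cell = make_cell("A", end=2.0, obs=[make_observation(0.0, fluorescence=80.0)])
        assert compute_Fa(cell) == 80.0

    def test_cell_born_between_frames_uses_first_grid_point_in_lifetime(self):
        # born 5 h, first fluorescence frame at 8 h, ends at 9 h
        cell = make_cell("A", generation=1, parent_id="M", birth=5.0, end=9.0,
                         obs=[make_observation(5.0, kind="phase"),
                              make_observation(8.0, fluorescence=42.0),
                              make_observation(9.0, kind="phase")])
        assert compute_Fa(cell) == 42.0

    def test_no_fluorescence_frame_yields_missing_marker(self):
        cell = make_cell("A", end=1.0, obs=[make_observation(0.5, kind="phase")])
        assert compute_Fa(cell) is None


class TestFmc:
    def test_daughter_gets_half_of_mother(self):
        cell = make_cell("D", generation=1, parent_id="M", birth=8.0, end=12.0,
                         obs=[make_observation(8.0, fluorescence=50.0)])
        assert compute_Fmc(cell, mother_Fa=200.0) == 150.0

    def test_starting_generation_equals_Fa(self):
        cell = make_cell("A", end=4.0, obs=[make_observation(0.0, fluorescence=80.0)])
        assert compute_Fmc(cell, mother_Fa=None) == 80.0

    def test_zero_mother_contribution(self):
        cell = make_cell("D", generation=1, parent_id="M", birth=8.0, end=12.0,
                         obs=[make_observation(8.0, fluorescence=12.0)])
        assert compute_Fmc(cell, mother_Fa=0.0) == 12.0

    def test_daughter_without_mother_value_raises(self):
        cell = make_cell("D", generation=1, parent_id="M", birth=8.0, end=12.0,
                         obs=[make_observation(8.0, fluorescence=12.0)])
        with pytest.raises(ValueError, match="mother"):
            compute_Fmc(cell, mother_Fa=None)


class TestRates:
    @pytest.mark.parametrize(
        "fa, days, expected",
        [(120.0, 2.0, 60.0), (0.0, 2.0, 0.0), (90.0, 1.5, 60.0)],
    )
    def test_rate_is_fa_per_day(self, fa, days, expected):
        account = compute_rates(FluorescenceAccount(cell_id="A", Fa=fa), days)
        assert account.Fa_rate == pytest.approx(expected)

    def test_non_positive_observation_time_rejected(self):
        with pytest.raises(ValueError):
            compute_rates(FluorescenceAccount(cell_id="A", Fa=1.0), 0.0)


class TestAccountsAcrossDivisions:
    def test_conservation_of_mother_share(self, two_generation_forest):
        accounts = build_accounts(two_generation_forest)
        mother_fa = accounts["M"].Fa
        gain1 = accounts["M.1"].Fmc - accounts["M.1"].Fa
        gain2 = accounts["M.2"].Fmc - accounts["M.2"].Fa
        assert gain1 + gain2 == pytest.approx(mother_fa, abs=1e-12)

    def test_generation_zero_has_Fmc_equal_Fa(self, two_generation_forest):
        accounts = build_accounts(two_generation_forest)
        assert accounts["M"].Fmc == accounts["M"].Fa
        assert accounts["B"].Fmc == accounts["B"].Fa

    def test_rates_use_observation_span(self, two_generation_forest):
        accounts = build_accounts(two_generation_forest)
        # M.1 observed 8 h -> 20 h = 0.5 days
        assert accounts["M.1"].observation_days == pytest.approx(0.5)
        assert accounts["M.1"].Fa_rate == pytest.approx(accounts["M.1"].Fa / 0.5)
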