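"""Kendall tau-b, generation-grouped correlations, mitosis comparison and
cross-experiment summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lineagepump.fluorescence import build_accounts
from lineagepump.model import LineageForest
from lineagepump.stats import (
    cell_feature_table,
    compare_dividing_vs_nondividing,
    correlate_by_generations,
    cross_experiment_summary,
    kendall_tau,
    sister_pair_differences,
)

from conftest import brute_force_tau_b, make_cell, make_observation


class TestKendallTau:
    def test_perfect_concordance(self):
        assert kendall_tau([1, 2, 3, 4], [2, 4, 6, 8]).tau == pytest.approx(1.0)

    def test_perfect_discordance(self):
        assert kendall_tau([1, 2, 3, 4], [8, 6, 4, 2]).tau == pytest.approx(-1.0)

    def test_tied_example_matches_pair_enumeration(self):
        x = [1, 2, 2, 3, 4]
        y = [1, 3, 2, 2, 4]
        assert kendall_tau(x, y).tau == pytest.approx(
            brute_force_tau_b(x, y), abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 2], [1, 2, 3])

    def test_constant_input_is_undefined_marker(self):
        res = kendall_tau([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(res.tau)

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        n=st.integers(2, 50),
        seed=st.integers(0, 10_000),
        levels=st.integers(2, 6),
    )
    def test_matches_brute_force_oracle_with_ties(self, n, seed, levels):
        rng = np.random.default_rng(seed)
        # coarse levels force heavy ties
        x = rng.integers(0, levels, n).astype(float)
        y = rng.integers(0, levels, n).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        assert kendall_tau(x, y).tau == pytest.approx(
            brute_force_tau_b(x, y), abs=1e-9
        )

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        base = kendall_tau(x, y).tau
        assert kendall_tau(np.exp(x), y).tau == pytest.approx(base)
        assert kendall_tau(x, np.cbrt(y)).tau == pytest.approx(base)

    def test_p_value_behaviour(self):
        rng = np.random.default_rng(5)
        x = np.arange(30.0)
        strong = kendall_tau(x, x + rng.normal(0, 1, 30))
        null = kendall_tau(x, rng.permutation(x))
        assert strong.p_value < 0.001
        assert null.p_value > 0.01
        assert 0.0 <= null.p_value <= 1.0


def _monotone_forest(n=12, slope=5.0):
    """Forest of starting-generation cells with area strictly monotone in Fa."""
    forest = LineageForest(experiment_id="x")
    for i in range(n):
        fa = 10.0 * (i + 1)
        forest.add(make_cell(
            f"C{i:02d}", end=8.0,
            obs=[
                make_observation(0.0, fluorescence=fa / 2),
                make_observation(
                    4.0, fluorescence=fa, area=200.0 + slope * fa,
                    kind="fluorescence",
                ),
            ],
        ))
    return forest


class TestCorrelateByGenerations:
    def test_noise_free_monotone_coupling_gives_tau_one_everywhere(self):
        forest = _monotone_forest()
        accounts = build_accounts(forest)
        feats = cell_feature_table(forest, accounts)
        for res in correlate_by_generations(feats, "area", "Fa", "x"):
            assert res.tau == pytest.approx(1.0)

    def test_permuted_labels_have_near_zero_tau(self):
        rng = np.random.default_rng(42)
        n = 500
        feats = pd.DataFrame({
            "generation": np.zeros(n, dtype=int),
            "area": rng.permutation(np.arange(n, dtype=float)),
            "Fa": np.arange(n, dtype=float),
        })
        results = correlate_by_generations(feats, "area", "Fa", "x")
        all_gen = [r for r in results if r.grouping_label == "all"][0]
        assert abs(all_gen.tau) < 0.1

    def test_all_generations_equals_concatenation(self):
        rng = np.random.default_rng(2)
        n = 60
        feats = pd.DataFrame({
            "generation": rng.integers(0, 3, n),
            "area": rng.normal(size=n),
            "Fa": rng.normal(size=n),
        })
        results = correlate_by_generations(feats, "area", "Fa", "x")
        all_gen = [r for r in results if r.grouping_label == "all"][0]
        assert all_gen.tau == pytest.approx(
            kendall_tau(feats["area"], feats["Fa"]).tau
        )
        assert all_gen.n == n

    def test_low_n_groupings_are_flagged_not_dropped(self):
        feats = pd.DataFrame({
            "generation": [0, 0, 0, 0, 0, 1, 1, 1],
            "area": [1.0, 2, 3, 4, 5, 1, 3, 2],
            "Fa": [1.0, 3, 2, 4, 5, 2, 3, 1],
        })
        results = correlate_by_generations(feats, "area", "Fa", "x")
        by_label = {r.grouping_label: r for r in results}
        assert by_label["generation-1"].low_n
        assert not by_label["generation-0"].low_n


def _paired_forest(deltas):
    """Forest of divided mothers whose daughters differ by given (dFa, dArea)."""
    forest = LineageForest(experiment_id="x")
    for k, (dfa, darea) in enumerate(deltas):
        mid = f"M{k:02d}"
        forest.add(make_cell(
            mid, end=8.0, fate="divided",
            obs=[make_observation(0.0, fluorescence=100.0),
                 make_observation(8.0, fluorescence=100.0, area=500.0,
                                  kind="fluorescence")],
        ))
        base_fa, base_area = 50.0, 400.0
        for j, sign in ((1, +0.5), (2, -0.5)):
            forest.add(make_cell(
                f"{mid}.{j}", generation=1, parent_id=mid, birth=8.0, end=16.0,
                obs=[make_observation(
                    12.0, fluorescence=base_fa + sign * dfa,
                    area=base_area + sign * darea, kind="fluorescence",
                )],
            ))
    return forest


class TestSisterPairDifferences:
    def test_consistent_ordering_gives_tau_one(self):
        deltas = [(10.0 * i, 5.0 * i) for i in range(1, 8)]
        forest = _paired_forest(deltas)
        feats = cell_feature_table(forest, build_accounts(forest))
        pairs, results = sister_pair_differences(forest, feats, "area")
        assert (pairs["d_Fa"] >= 0).all()
        all_gen = [r for r in results if r.grouping_label == "all"][0]
        assert all_gen.tau == pytest.approx(1.0)

    def test_exact_tie_retained_with_canonical_order(self):
        deltas = [(0.0, 5.0), (10.0, 8.0), (20.0, 12.0)]
        forest = _paired_forest(deltas)
        feats = cell_feature_table(forest, build_accounts(forest))
        pairs, _ = sister_pair_differences(forest, feats, "area")
        tied = pairs[pairs["d_Fa"] == 0.0]
        assert len(tied) == 1
        assert tied.iloc[0]["cell_id_high"] == "M00.1"  # lexicographic

    def test_too_few_pairs_yield_no_correlation(self):
        forest = _paired_forest([(10.0, 5.0)])
        feats = cell_feature_table(forest, build_accounts(forest))
        pairs, results = sister_pair_differences(forest, feats, "area")
        assert results == []

    def test_noisy_coupling_matches_monte_carlo_expectation(self):
        # dArea = 0.5 * dFa + noise; the expected tau under this coupling is
        # estimated by direct Monte-Carlo simulation, and one fixed-seed
        # realisation through the pipeline must land within 3 MC sd of it
        n_pairs, sd_noise = 80, 6.0

        def draw(rng):
            dfa = rng.uniform(1.0, 20.0, n_pairs)
            darea = 0.5 * dfa + rng.normal(0.0, sd_noise, n_pairs)
            return dfa, darea

        taus = []
        for rep in range(200):
            rng = np.random.default_rng(10_000 + rep)
            dfa, darea = draw(rng)
            taus.append(brute_force_tau_b(dfa, darea))
        expected, spread = np.mean(taus), np.std(taus)

        rng = np.random.default_rng(99)
        deltas = list(zip(*draw(rng)))
        forest = _paired_forest(deltas)
        feats = cell_feature_table(forest, build_accounts(forest))
        _, results = sister_pair_differences(forest, feats, "area")
        all_gen = [r for r in results if r.grouping_label == "all"][0]
        assert abs(all_gen.tau - expected) < 3.0 * spread


def _rates_forest(dividing_rates, nondividing_rates):
    """Cells observed exactly one day with prescribed Fa rates."""
    forest = LineageForest(experiment_id="x")
    for k, rate in enumerate(dividing_rates):
        mid = f"D{k:02d}"
        forest.add(make_cell(
            mid, end=24.0, fate="divided",
            obs=[make_observation(0.0, fluorescence=0.0),
                 make_observation(24.0, fluorescence=rate, kind="fluorescence")],
        ))
        for j in (1, 2):
            forest.add(make_cell(
                f"{mid}.{j}", generation=1, parent_id=mid, birth=24.0,
                end=24.25, obs=[make_observation(24.25, kind="phase")],
            ))
    for k, rate in enumerate(nondividing_rates):
        forest.add(make_cell(
            f"N{k:02d}", end=24.0, fate="incomplete",
            obs=[make_observation(0.0, fluorescence=0.0),
                 make_observation(24.0, fluorescence=rate, kind="fluorescence")],
        ))
    return forest


class TestMitosisComparison:
    def test_hand_computed_median_ratio(self):
        forest = _rates_forest([4.0, 6.0], [1.0, 2.0, 3.0])
        feats = cell_feature_table(forest, build_accounts(forest))
        comp = compare_dividing_vs_nondividing(forest, feats,
                                               min_observation_h=0.0)
        assert comp.pFa == pytest.approx(2.5)

    def test_published_style_rates_give_expected_ratio(self):
        # dividing median 66.7 and non-dividing 29.9 units/day -> pFa 2.23
        forest = _rates_forest([60.0, 66.7, 70.0], [25.0, 29.9, 35.0])
        feats = cell_feature_table(forest, build_accounts(forest))
        comp = compare_dividing_vs_nondividing(forest, feats,
                                               min_observation_h=0.0)
        assert comp.median_Fa_rate_dividing == pytest.approx(66.7)
        assert comp.median_Fa_rate_nondividing == pytest.approx(29.9)
        assert comp.pFa == pytest.approx(2.23, abs=0.005)

    def test_identical_distributions_give_ratio_one(self):
        forest = _rates_forest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        feats = cell_feature_table(forest, build_accounts(forest))
        comp = compare_dividing_vs_nondividing(forest, feats,
                                               min_observation_h=0.0)
        assert comp.pFa == pytest.approx(1.0)
        assert comp.p_value_Fa == pytest.approx(1.0)

    def test_ratio_is_scale_invariant(self):
        f1 = _rates_forest([4.0, 6.0], [1.0, 2.0, 3.0])
        f2 = _rates_forest([40.0, 60.0], [10.0, 20.0, 30.0])
        c1 = compare_dividing_vs_nondividing(
            f1, cell_feature_table(f1, build_accounts(f1)), min_observation_h=0.0
        )
        c2 = compare_dividing_vs_nondividing(
            f2, cell_feature_table(f2, build_accounts(f2)), min_observation_h=0.0
        )
        assert c1.pFa == pytest.approx(c2.pFa)

    def test_short_observation_nondividers_are_excluded(self):
        forest = _rates_forest([4.0, 6.0], [1.0, 2.0, 3.0])
        feats = cell_feature_table(forest, build_accounts(forest))
        with pytest.raises(ValueError, match="non-dividing"):
            # a 10-day minimum window disqualifies every non-divider
            compare_dividing_vs_nondividing(forest, feats,
                                            min_observation_h=240.0)


class TestCrossExperimentSummary:
    def test_median_of_reported_tau_values(self):
        taus = [0.55, 0.15, 0.76, 0.51, 0.13, 0.55, 0.54]
        median, p = cross_experiment_summary(taus)
        assert median == pytest.approx(0.54)
        assert p < 0.05

    def test_median_of_compensated_tau_values(self):
        taus = [0.53, 0.11, 0.68, 0.45, 0.08, 0.51, 0.41]
        median, _ = cross_experiment_summary(taus)
        assert median == pytest.approx(0.45)

    def test_symmetric_values_give_p_one(self):
        _, p = cross_experiment_summary([-1.0, 0.0, 1.0])
        assert p == pytest.approx(1.0)

    def test_paired_and_unpaired_variants(self):
        x = [0.5, 0.6, 0.7, 0.8]
        y = [0.1, 0.2, 0.3, 0.4]
        _, p_paired = cross_experiment_summary(
            x, "wilcoxon-signed-rank-paired", y
        )
        _, p_mw = cross_experiment_summary(x, "mann-whitney", y)
        assert p_paired < 0.2
        assert p_mw == pytest.approx(0.02857, abs=1e-4)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            cross_experiment_summary([0.1, 0.2])
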