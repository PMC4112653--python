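"""PSA engine: determinism, incremental analysis, acceptability, CE plane."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glueear.params import scenario_deck
from glueear.pathways import StrategyId
from glueear.psa import (
    PsaMatrix,
    ce_plane,
    ceaf,
    incremental_analysis,
    net_benefit,
    run_psa,
)


def _toy_matrix(costs, qalys, strategies=None):
    costs = np.asarray(costs, dtype=float)
    qalys = np.asarray(qalys, dtype=float)
    if strategies is None:
        strategies = tuple(StrategyId)[: costs.shape[1]]
    return PsaMatrix(costs=costs, qalys=qalys, strategies=tuple(strategies),
                     seed=None, deck_fingerprint="toy")


class TestNetBenefit:
    def test_worked_example(self):
        assert net_benefit(20_000, 2.0, 10_000) == 30_000

    def test_zero_lambda_is_negative_cost(self):
        assert net_benefit(0.0, 0.3, 1234.0) == -1234.0

    def test_table_level_magnitude(self):
        assert net_benefit(20_000, 0.218, 1_801) == pytest.approx(2_559, abs=1)

    @given(lam=st.floats(0, 50_000), q=st.floats(-1, 1), c=st.floats(0, 5_000),
           a=st.floats(0.1, 5), b=st.floats(-0.5, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_linearity_in_each_argument(self, lam, q, c, a, b):
        assert net_benefit(lam, a * q, a * c) == pytest.approx(
            a * net_benefit(lam, q, c), rel=1e-9, abs=1e-9)
        assert net_benefit(lam, q + b, c) == pytest.approx(
            net_benefit(lam, q, c) + lam * b, rel=1e-9, abs=1e-6)
        assert net_benefit(a * lam, q, a * c) == pytest.approx(
            a * lam * q - a * c, rel=1e-9, abs=1e-9)


class TestRunPsa:
    def test_same_seed_is_bit_reproducible(self, deck):
        a = run_psa(deck, n_sims=300, seed=99)
        b = run_psa(deck, n_sims=300, seed=99)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.qalys, b.qalys)
        assert a.deck_fingerprint == b.deck_fingerprint

    def test_different_seeds_differ(self, deck):
        a = run_psa(deck, n_sims=300, seed=1)
        b = run_psa(deck, n_sims=300, seed=2)
        assert not np.array_equal(a.costs, b.costs)

    def test_column_means_near_closed_form(self, psa10k):
        np.testing.assert_allclose(
            psa10k.costs.mean(axis=0), [1769.08, 1202.49, 2488.60], rtol=0.02)
        np.testing.assert_allclose(
            psa10k.qalys.mean(axis=0), [0.2175, 0.1066, 0.1387], atol=0.004)

    def test_invalid_n_sims_rejected(self, deck):
        with pytest.raises(ValueError):
            run_psa(deck, n_sims=0, seed=1)


class TestIncrementalAnalysis:
    def test_strong_dominance_detected_on_toy_means(self):
        # strategy 0 cheaper and more effective than strategy 2
        psa = _toy_matrix(
            costs=[[1800, 1200, 2500]] * 4,
            qalys=[[0.22, 0.11, 0.14]] * 4,
        )
        res = incremental_analysis(psa, lam=20_000)
        assert res.dominated() == [StrategyId.HAS_THEN_VTS.value]
        (key, icer), = res.icers.items()
        assert key == (StrategyId.VTS.value, StrategyId.HAS.value)
        assert icer == pytest.approx((1800 - 1200) / (0.22 - 0.11))

    def test_identical_strategies_no_dominance_icer_undefined(self):
        psa = _toy_matrix(costs=[[100, 100]] * 3, qalys=[[0.1, 0.1]] * 3,
                          strategies=(StrategyId.VTS, StrategyId.HAS))
        res = incremental_analysis(psa)
        assert res.dominated() == []
        (icer,) = res.icers.values()
        assert icer is None

    def test_dominated_strategy_never_tops_mean_net_benefit(self, psa10k):
        res = incremental_analysis(psa10k)
        dominated = set(res.dominated())
        assert dominated  # the combined arm is dominated on the default deck
        for lam in np.arange(0, 50_001, 1_000):
            mean_nb = psa10k.net_benefits(lam).mean(axis=0)
            best = psa10k.strategies[int(np.argmax(mean_nb))].value
            assert best not in dominated

    def test_icer_equals_mean_nb_crossing_point(self, psa10k):
        """For two strategies, mean net benefits cross exactly at the ICER."""
        res = incremental_analysis(psa10k)
        icer = res.icers[(StrategyId.VTS.value, StrategyId.HAS.value)]
        i, j = psa10k.index_of(StrategyId.VTS), psa10k.index_of(StrategyId.HAS)
        nb_i = psa10k.net_benefits(icer).mean(axis=0)[i]
        nb_j = psa10k.net_benefits(icer).mean(axis=0)[j]
        assert nb_i == pytest.approx(nb_j, abs=1e-6)

    def test_single_strategy_rejected(self):
        psa = _toy_matrix(costs=[[1.0]] * 2, qalys=[[0.1]] * 2,
                          strategies=(StrategyId.VTS,))
        with pytest.raises(ValueError):
            incremental_analysis(psa)


class TestCeaf:
    def test_probabilities_normalise_at_every_lambda(self, psa10k):
        curve = ceaf(psa10k)
        sums = curve.table.groupby("lam")["probability"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-12)

    def test_single_strategy_probability_one(self):
        psa = _toy_matrix(costs=[[5.0]] * 4, qalys=[[0.1]] * 4,
                          strategies=(StrategyId.VTS,))
        curve = ceaf(psa, lambda_grid=[0, 10_000, 20_000])
        assert (curve.table["probability"] == 1.0).all()
        assert curve.table["on_frontier"].all()

    def test_ties_split_equally(self):
        psa = _toy_matrix(costs=[[100, 100]] * 4, qalys=[[0.1, 0.1]] * 4,
                          strategies=(StrategyId.VTS, StrategyId.HAS))
        curve = ceaf(psa, lambda_grid=[20_000])
        assert set(curve.table["probability"]) == {0.5}

    def test_empty_grid_rejected(self, psa10k):
        with pytest.raises(ValueError):
            ceaf(psa10k, lambda_grid=[])

    def test_frontier_pipeline_reproducible_under_seed(self, deck):
        grid = [0, 5_000, 20_000]
        t1 = ceaf(run_psa(deck, 500, seed=5), grid).table
        t2 = ceaf(run_psa(deck, 500, seed=5), grid).table
        assert t1.equals(t2)


class TestCePlane:
    def test_strategy_against_itself_is_all_zero(self, psa10k):
        plane = ce_plane(psa10k, StrategyId.VTS, StrategyId.VTS)
        assert np.all(plane.delta_cost == 0)
        assert np.all(plane.delta_qaly == 0)

    def test_fraction_below_line_matches_two_strategy_ceac(self, psa10k):
        """Cross-module consistency: the CE-plane summary equals the
        acceptability of the comparator when the choice set is restricted
        to the two plotted strategies."""
        plane = ce_plane(psa10k, reference=StrategyId.HAS,
                         comparator=StrategyId.VTS)
        lam = 20_000.0
        restricted = _toy_matrix(
            costs=psa10k.costs[:, [psa10k.index_of(StrategyId.VTS),
                                   psa10k.index_of(StrategyId.HAS)]],
            qalys=psa10k.qalys[:, [psa10k.index_of(StrategyId.VTS),
                                   psa10k.index_of(StrategyId.HAS)]],
            strategies=(StrategyId.VTS, StrategyId.HAS),
        )
        ceac = ceaf(restricted, [lam]).probability(lam, StrategyId.VTS)
        assert plane.fraction_cost_effective(lam) == pytest.approx(ceac, abs=1e-12)


class TestDegenerateDeck:
    def test_collapsed_priors_give_constant_qalys(self, deck):
        """With gains and utility collapsed to their means, every draw
        produces the same QALY vector (cost variation remains through the
        probability and cost priors)."""
        overrides = {}
        d = scenario_deck(deck, overrides)
        # collapse normal priors by zeroing their spread
        from dataclasses import replace

        gains = {n: replace(g, sd_dBHL=0.0) for n, g in d.gains.items()}
        utility = replace(d.utility, ci_low=0.00874, ci_high=0.00874)
        d = type(d)(probabilities=d.probabilities, costs=d.costs,
                    gains=gains, utility=utility, constants=d.constants)
        psa = run_psa(d, n_sims=50, seed=3)
        assert np.allclose(psa.qalys, psa.qalys[0, :])
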