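"""DEC likelihood: oracle agreement, invariances, fitting, AIC ranking."""

import numpy as np
import pytest

import decranges as dr
from decranges.likelihood import DecModel
from decranges.rate_model import Epoch, EpochStratification

from oracles import brute_force_loglik


def single_area_tips(assignment):
    return {k: dr.RangeState((v,)) for k, v in assignment.items()}


def test_no_process_same_area_has_probability_one(cherry_tree, three_area_space):
    tips = single_area_tips({"a": 0, "b": 0})
    model = DecModel(space=three_area_space)
    ll = dr.compute_log_likelihood(cherry_tree, tips, model, dr.DecParams(0.0, 0.0))
    assert ll == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("d,e", [(0.05, 0.02), (0.3, 0.4), (1.0, 0.01)])
def test_pruning_equals_brute_force(five_tip_tree, three_area_space, rng, d, e):
    tips = single_area_tips(
        {l: int(rng.integers(3)) for l in "abcde"}
    )
    model = DecModel(space=three_area_space)
    params = dr.DecParams(d, e)
    ll = dr.compute_log_likelihood(five_tip_tree, tips, model, params)
    oracle = brute_force_loglik(five_tip_tree, tips, model, params)
    assert ll == pytest.approx(oracle, rel=1e-8)


def test_pruning_equals_brute_force_with_stratification(five_tip_tree, three_area_space):
    strat = EpochStratification(
        [Epoch(np.inf, 1.2, frozenset({0, 1})), Epoch(1.2, 0.0, frozenset({0, 1, 2}))]
    )
    tips = single_area_tips({"a": 0, "b": 1, "c": 0, "d": 2, "e": 1})
    model = DecModel(space=three_area_space, strat=strat)
    params = dr.DecParams(0.2, 0.1)
    ll = dr.compute_log_likelihood(five_tip_tree, tips, model, params)
    oracle = brute_force_loglik(five_tip_tree, tips, model, params)
    assert ll == pytest.approx(oracle, rel=1e-8)


def test_single_epoch_stratification_is_a_no_op(five_tip_tree, three_area_space):
    tips = single_area_tips({"a": 0, "b": 1, "c": 0, "d": 2, "e": 1})
    params = dr.DecParams(0.1, 0.05)
    plain = DecModel(space=three_area_space)
    strat = DecModel(
        space=three_area_space,
        strat=EpochStratification.single(3),
    )
    ll1 = dr.compute_log_likelihood(five_tip_tree, tips, plain, params)
    ll2 = dr.compute_log_likelihood(five_tip_tree, tips, strat, params)
    assert ll1 == pytest.approx(ll2, abs=1e-10)


def test_all_ones_multipliers_match_unconstrained(five_tip_tree, three_area_space):
    tips = single_area_tips({"a": 0, "b": 1, "c": 0, "d": 2, "e": 1})
    params = dr.DecParams(0.2, 0.1)
    plain = DecModel(space=three_area_space)
    ones = DecModel(space=three_area_space, mult=dr.DispersalMultipliers.ones(3))
    assert dr.compute_log_likelihood(five_tip_tree, tips, plain, params) == (
        dr.compute_log_likelihood(five_tip_tree, tips, ones, params)
    )


def test_likelihood_invariant_to_child_rotation(three_area_space):
    tips = single_area_tips({"a": 0, "b": 1, "c": 2, "d": 0, "e": 1})
    params = dr.DecParams(0.15, 0.08)
    model = DecModel(space=three_area_space)
    t1 = dr.read_tree("(((a:1,b:1):0.5,c:1.5):0.5,(d:1,e:1):1);")
    t2 = dr.read_tree("((e:1,d:1):1,((b:1,a:1):0.5,c:1.5):0.5);")
    ll1 = dr.compute_log_likelihood(t1, tips, model, params)
    ll2 = dr.compute_log_likelihood(t2, tips, model, params)
    assert ll1 == pytest.approx(ll2, rel=1e-12)


def test_loglik_finite_on_rate_grid(five_tip_tree, three_area_space):
    tips = single_area_tips({"a": 0, "b": 1, "c": 0, "d": 2, "e": 1})
    model = DecModel(space=three_area_space)
    for d in (1e-6, 1e-3, 1.0):
        for e in (1e-6, 1e-3, 1.0):
            ll = dr.compute_log_likelihood(
                five_tip_tree, tips, model, dr.DecParams(d, e)
            )
            assert np.isfinite(ll)


def test_observed_area_outside_model_rejected(cherry_tree, three_area_space):
    tips = {"a": dr.RangeState((0,)), "b": dr.RangeState((5,))}
    model = DecModel(space=three_area_space)
    with pytest.raises(ValueError, match="area"):
        dr.compute_log_likelihood(cherry_tree, tips, model, dr.DecParams(0.1, 0.1))


def test_fit_degenerate_data_drives_dispersal_to_bound(three_area_space):
    # identical single-area tips carry no dispersal signal
    tree = dr.read_tree("((a:1,b:1):1,(c:1,d:1):1);")
    tips = single_area_tips({l: 0 for l in "abcd"})
    fit = dr.fit_dec(tree, tips, DecModel(space=three_area_space))
    assert fit.d <= 1e-6
    assert fit.aic == pytest.approx(4 - 2 * fit.log_likelihood)


def test_fit_recovers_rates_on_simulated_data():
    # moderate-size simulation: estimates should land near the truth
    space = dr.enumerate_ranges(4, 2)
    model = DecModel(space=space, name="sim")
    true = dr.DecParams(0.08, 0.02)
    tree = dr.simulate_tree(100, seed=11, depth=20.0)
    hist = dr.simulate_dec_history(tree, model, true, dr.RangeState((0,)), seed=12)
    fit_tree, tips = hist.pruned()
    fit = dr.fit_dec(fit_tree, tips, model)
    assert fit.converged
    assert true.d / 2 < fit.d < true.d * 2


def test_compare_models_table(three_area_space):
    from decranges.likelihood import FitResult

    f1 = FitResult(d=0.1, e=0.1, log_likelihood=-498, model_name="m1", tree_id="t")
    f2 = FitResult(d=0.1, e=0.1, log_likelihood=-501, model_name="m2", tree_id="t")
    table = dr.compare_models([f2, f1])
    assert list(table.model) == ["m1", "m2"]
    assert list(table.dAIC) == [0.0, 6.0]
    assert list(table.neg2logL) == [996.0, 1002.0]
    with pytest.raises(ValueError):
        dr.compare_models([f1, FitResult(0.1, 0.1, -1, "m3", tree_id="other")])


def test_selection_frequency_single_and_ties(cherry_tree, three_area_space):
    tips = single_area_tips({"a": 0, "b": 0})
    m = DecModel(space=three_area_space, name="only")
    freq = dr.selection_frequency([cherry_tree], tips, [m])
    assert freq == {"only": 1.0}
    # two identical models tie and split the win
    m1 = DecModel(space=three_area_space, name="twin1")
    m2 = DecModel(space=three_area_space, name="twin2")
    freq = dr.selection_frequency([cherry_tree], tips, [m1, m2])
    assert freq["twin1"] == pytest.approx(0.5)
    assert freq["twin2"] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        dr.selection_frequency([], tips, [m1])
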