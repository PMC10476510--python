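"""Ancestral reconstruction, apportionment and transition counting."""

import numpy as np
import pytest

import decranges as dr
from decranges.ancestral import (
    DEFAULT_BINS,
    TransitionTable,
    count_transitions,
    summarize_transitions,
)
from decranges.likelihood import DecModel

from oracles import brute_force_marginals


def single_area_tips(assignment):
    return {k: dr.RangeState((v,)) for k, v in assignment.items()}


def test_trivial_reconstruction_is_certain(cherry_tree, three_area_space):
    tips = single_area_tips({"a": 0, "b": 0})
    model = DecModel(space=three_area_space)
    rec = dr.reconstruct_ancestral_ranges(
        cherry_tree, tips, model, dr.DecParams(0.0, 0.0)
    )
    root = rec.n_nodes - 1
    assert rec.range_probs[root, three_area_space.index((0,))] == pytest.approx(1.0)
    assert rec.majority_area[root] == 0


@pytest.mark.parametrize("d,e", [(0.1, 0.05), (0.4, 0.3)])
def test_marginals_match_brute_force_posterior(five_tip_tree, three_area_space, d, e):
    tips = single_area_tips({"a": 0, "b": 1, "c": 0, "d": 2, "e": 1})
    model = DecModel(space=three_area_space)
    params = dr.DecParams(d, e)
    rec = dr.reconstruct_ancestral_ranges(five_tip_tree, tips, model, params)
    oracle = brute_force_marginals(five_tip_tree, tips, model, params)
    for node, expected in oracle.items():
        np.testing.assert_allclose(rec.range_probs[node], expected, atol=1e-8)
    # every node's distribution normalises
    np.testing.assert_allclose(rec.range_probs.sum(axis=1), 1.0, atol=1e-8)
    np.testing.assert_allclose(rec.area_probs.sum(axis=1), 1.0, atol=1e-8)


def test_joint_mode_returns_valid_assignment(five_tip_tree, three_area_space):
    tips = single_area_tips({"a": 0, "b": 1, "c": 0, "d": 2, "e": 1})
    model = DecModel(space=three_area_space)
    rec = dr.reconstruct_ancestral_ranges(
        five_tip_tree, tips, model, dr.DecParams(0.1, 0.05), mode="joint"
    )
    # one-hot per node, never the null range
    assert np.all(rec.range_probs.sum(axis=1) == 1.0)
    assert np.all(rec.range_probs[:, 0] == 0.0)


def test_apportionment_rules(three_area_space):
    space = three_area_space
    # two-area mass splits evenly between member areas
    p = np.zeros(7)
    p[space.index((0, 1))] = 0.10
    p[space.index((0,))] = 0.90
    out = dr.apportion_to_areas(p, space)
    assert out[0] == pytest.approx(0.95)
    assert out[1] == pytest.approx(0.05)
    assert out.sum() == pytest.approx(1.0)
    # all single-area mass passes through unchanged
    p = np.zeros(7)
    p[1:4] = [0.2, 0.3, 0.5]
    np.testing.assert_allclose(dr.apportion_to_areas(p, space), [0.2, 0.3, 0.5])
    # null mass triggers a warning and renormalisation
    p = np.zeros(7)
    p[0] = 0.5
    p[1] = 0.5
    with pytest.warns(UserWarning, match="null"):
        out = dr.apportion_to_areas(p, space)
    assert out[0] == pytest.approx(1.0)


def make_table(entries, areas=None, bins=DEFAULT_BINS):
    if areas is None:
        areas = [
            dr.Area("E", category="mainland-terrane"),
            dr.Area("A", category="mainland-terrane"),
            dr.Area("W", category="island"),
        ]
    t = TransitionTable(areas, bins=bins)
    for src, dst, age in entries:
        t.record(src, dst, age)
    return t


def test_bin_edges_are_half_open():
    t = make_table([])
    assert t.bin_of(12.0) == 1  # 15-10 Ma
    assert t.bin_of(15.0) == 1  # boundary age joins the bin it opens
    assert t.bin_of(20.0) == 0  # oldest bin includes the root age
    assert t.bin_of(3.0) == 3
    assert t.bin_of(0.0) == 3  # youngest bin closed at the present
    assert t.bin_of(25.0) is None


def test_count_transitions_on_forced_history(three_area_space):
    # two-area root forced to split; with extreme rate asymmetry the
    # reconstruction must place an E -> A shift on the deep branch
    tree = dr.read_tree("((a:2,b:2):10,(c:2,d:2):10);")
    tips = single_area_tips({"a": 0, "b": 0, "c": 1, "d": 1})
    areas = [
        dr.Area("E", category="mainland-terrane"),
        dr.Area("A", category="mainland-terrane"),
        dr.Area("W", category="island"),
    ]
    model = DecModel(space=dr.RangeSpace(areas, max_size=2))
    rec = dr.reconstruct_ancestral_ranges(tree, tips, model, dr.DecParams(0.05, 0.01))
    table = count_transitions(rec)
    # the root is at 12 Ma; any shift on its child branches lands in 15-10 Ma
    assert table.total > 0
    assert table.counts[1].sum() == table.total


def test_no_shifts_yields_empty_table(cherry_tree, three_area_space):
    tips = single_area_tips({"a": 0, "b": 0})
    model = DecModel(space=three_area_space)
    rec = dr.reconstruct_ancestral_ranges(cherry_tree, tips, model, dr.DecParams(0.0, 0.0))
    table = count_transitions(rec)
    assert table.total == 0
    summary = summarize_transitions(table)
    assert summary["total"] == 0
    assert summary["mainland_to_mainland"] == 0


def test_summarize_single_transition_gives_full_share():
    t = make_table([(0, 1, 12.0)])
    s = summarize_transitions(t)
    assert s["total"] == 1
    assert s["mainland_to_mainland"] == 1
    assert s["mainland_source_pct_of_mainland_to_mainland"]["E"] == 100


def test_published_table_shares_and_totals():
    from decranges.study import published_dispersal_table

    table = published_dispersal_table()
    assert table.total == 71
    assert table.mainland_to_mainland == 29
    assert table.mainland_to_island == 42
    s = summarize_transitions(table)
    assert s["mainland_source_pct_of_mainland_to_mainland"]["E"] == 48
    assert s["mainland_source_pct_of_mainland_to_island"]["E"] == 98
    # conservation: every counted edge is mainland- or island-sourced
    island_src = sum(
        int(table.counts[:, i, :].sum())
        for i, a in enumerate(table.areas)
        if a.category == "island"
    )
    assert table.mainland_to_mainland + table.mainland_to_island + island_src == 71


def test_transition_overflow_bin_warns():
    t = make_table([])
    with pytest.warns(UserWarning, match="outside"):
        t.record(0, 1, 30.0)
    assert t.total == 1
    assert t.counts.sum() == 0
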