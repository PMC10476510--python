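"""Hypothesis builders: published matrices, distance weights, invariants."""

import numpy as np
import pytest

import decranges as dr
from decranges.hypotheses import (
    DEFAULT_FLOOR,
    DISPLAY_CODES,
    HypothesisSpec,
    builtin_hypotheses,
    display_multiplier_matrix,
    study_areas,
)

F = DEFAULT_FLOOR

# the published current-connectivity multiplier matrix on the 11-region
# display layout (V C F A E D W M S R B); printed zeros are the 0.001 floor
EXPECTED_D_A = np.array(
    [
        [1, 1, 1, 1, F, F, F, F, F, F, F],
        [1, 1, 1, F, F, F, F, F, F, F, F],
        [1, 1, 1, 1, 1, F, F, F, F, F, F],
        [1, F, 1, 1, 1, F, F, F, F, F, F],
        [F, F, 1, 1, 1, F, F, F, F, F, F],
        [F, F, F, F, F, 1, F, F, F, F, F],
        [F, F, F, F, F, F, 1, F, F, F, F],
        [F, F, F, F, F, F, F, 1, F, F, F],
        [F, F, F, F, F, F, F, F, 1, F, F],
        [F, F, F, F, F, F, F, F, F, 1, F],
        [F, F, F, F, F, F, F, F, F, F, 1],
    ]
)

# the published Owen Stanleys matrix: same mainland block, with the EPCT and
# every offshore island joined in one multiway connection
EXPECTED_D_G = np.array(
    [
        [1, 1, 1, 1, F, F, F, F, F, F, F],
        [1, 1, 1, F, F, F, F, F, F, F, F],
        [1, 1, 1, 1, 1, F, F, F, F, F, F],
        [1, F, 1, 1, 1, F, F, F, F, F, F],
        [F, F, 1, 1, 1, 1, 1, 1, 1, 1, 1],
        [F, F, F, F, 1, 1, 1, 1, 1, 1, 1],
        [F, F, F, F, 1, 1, 1, 1, 1, 1, 1],
        [F, F, F, F, 1, 1, 1, 1, 1, 1, 1],
        [F, F, F, F, 1, 1, 1, 1, 1, 1, 1],
        [F, F, F, F, 1, 1, 1, 1, 1, 1, 1],
        [F, F, F, F, 1, 1, 1, 1, 1, 1, 1],
    ]
)


def test_current_connectivity_reproduces_published_matrix():
    codes, m = display_multiplier_matrix("a")
    assert codes == DISPLAY_CODES
    np.testing.assert_array_equal(m, EXPECTED_D_A)


def test_owen_stanleys_reproduces_published_matrix():
    _, m = display_multiplier_matrix("g")
    np.testing.assert_array_equal(m, EXPECTED_D_G)


def test_unconstrained_is_all_ones():
    _, m = display_multiplier_matrix("unconstrained")
    assert np.all(m == 1.0)
    model = builtin_hypotheses()["unconstrained"]
    assert np.all(model.mult.m == 1.0)
    assert model.strat is None


def test_island_distance_weights():
    models = builtin_hypotheses()
    m = models["l"].mult.m
    codes = [a.code for a in models["l"].space.areas]
    ix = codes.index
    # near islands (D'Entrecasteaux, New Britain) at 0.1 to any mainland terrane
    for isl in ("Y", "G", "B"):
        for ml in ("V", "C", "F", "A", "E"):
            assert m[ix(isl), ix(ml)] == 0.1
    # far islands (Woodlark, Louisiades) at 0.001 to the mainland
    for isl in ("W", "M", "S", "R"):
        for ml in ("V", "C", "F", "A", "E"):
            assert m[ix(isl), ix(ml)] == 0.001
    # within-archipelago movement is unconstrained
    assert m[ix("Y"), ix("G")] == 1.0
    for i1 in ("W", "M", "S", "R"):
        for i2 in ("W", "M", "S", "R"):
            if i1 != i2:
                assert m[ix(i1), ix(i2)] == 1.0


def test_all_models_symmetric_unit_diagonal_and_deterministic():
    models = builtin_hypotheses()
    assert len(models) == 13
    again = builtin_hypotheses()
    for key, model in models.items():
        m = model.mult.m
        np.testing.assert_array_equal(m, m.T)
        np.testing.assert_array_equal(np.diag(m), np.ones(13))
        allowed = {DEFAULT_FLOOR, 0.1, 1.0}
        assert set(np.unique(m)) <= allowed
        assert m.tobytes() == again[key].mult.m.tobytes()


def test_time_stratified_hypotheses_masks():
    models = builtin_hypotheses()
    codes = [a.code for a in models["c"].space.areas]
    c, d = models["c"], models["d"]
    assert c.strat is not None and d.strat is not None
    # mobile belt: the Accreted Terranes unavailable until docking completes
    old = c.strat.epochs[0]
    assert codes.index("A") not in old.available
    assert codes.index("E") in old.available
    # recent emergence: only the Fold Belt among mainland terranes early on
    old_d = d.strat.epochs[0].available
    for terrane in ("V", "C", "A", "E"):
        assert codes.index(terrane) not in old_d
    assert codes.index("F") in old_d
    # every area is available in the youngest epoch of both models
    assert c.strat.epochs[-1].available == frozenset(range(13))
    assert d.strat.epochs[-1].available == frozenset(range(13))


def test_slow_and_steady_extends_current_connectivity():
    _, ma = display_multiplier_matrix("a")
    _, mb = display_multiplier_matrix("b")
    mainland = [DISPLAY_CODES.index(c) for c in ("V", "C", "F", "A", "E")]
    # b keeps every connection of a and joins all mainland terranes
    assert np.all(mb[ma == 1.0] == 1.0)
    for i in mainland:
        for j in mainland:
            assert mb[i, j] == 1.0
    # islands remain detached in both mainland-assembly hypotheses
    islands = [DISPLAY_CODES.index(c) for c in ("D", "W", "M", "S", "R", "B")]
    for i in islands:
        for j in range(11):
            if i != j:
                assert ma[i, j] == F and mb[i, j] == F


def test_unknown_area_code_rejected():
    spec = HypothesisSpec(name="bad", pairwise_connections=(("E", "ZZ"),))
    with pytest.raises(ValueError, match="ZZ"):
        dr.build_hypothesis(spec, study_areas())
    with pytest.raises(ValueError, match="georegions"):
        builtin_hypotheses(areas=study_areas()[:5])
    with pytest.raises(ValueError):
        HypothesisSpec(name="bad-floor", floor=0.0)
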