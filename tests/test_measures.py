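"""Explanatory-power measures: worked values, ranges, symmetry, dispatch."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from explanationism import (EvidenceModel, HypothesisSpace, MeasureSpec,
                            PowerInputs, power_from_conditionals,
                            power_from_model, power_ss, rescale_good,
                            study_measures)
from explanationism.errors import DegenerateMarginalError, UndefinedScoreError

probs = st.floats(0.01, 0.99)


@pytest.mark.parametrize("measure_id, peh, pe, expected", [
    # neutral point: independence scores zero under every likelihood measure
    ("simple", 0.4, 0.4, 0.0),
    ("popper", 0.4, 0.4, 0.0),
    ("good", 0.4, 0.4, 0.0),
    # hand-computed values
    ("popper", 0.75, 0.5625, 0.1875 / 1.3125),
    ("good", 0.4, 0.2, math.log(2)),
    ("popper", 0.0, 0.5, -1.0),
    ("simple", 0.75, 0.5625, 0.1875),
])
def test_likelihood_measures_worked_values(measure_id, peh, pe, expected):
    score = power_from_conditionals(MeasureSpec(measure_id),
                                    PowerInputs(p_e_given_h=peh, p_e=pe))
    assert score.value == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("x, alpha, expected", [
    (0.0, 1.0, 0.0),
    (1.0, 1.0, 1.0 - math.exp(-0.5)),
    (-1.0, 1.0, -(1.0 - math.exp(-0.5))),
    (1.0, 0.5, 1.0 - math.exp(-2.0)),           # the G1 = L_0.5 scaling
    (math.inf, 2.0, 1.0),
    (-math.inf, 2.0, -1.0),
])
def test_rescale_good_worked_values(x, alpha, expected):
    assert rescale_good(x, alpha).value == pytest.approx(expected, abs=1e-15)


@pytest.mark.parametrize("phe, phn, expected", [
    (0.3, 0.3, 0.0),
    (1.0, 0.0, 1.0),
    (2 / 3, 2 / 7, 0.4),  # one black draw from the default urns
])
def test_posterior_ratio_measure_worked_values(phe, phn, expected):
    score = power_ss(PowerInputs(p_h_given_e=phe, p_h_given_not_e=phn))
    assert score.value == pytest.approx(expected, abs=1e-12)


def test_measure_spec_validation_and_presets():
    with pytest.raises(ValueError):
        MeasureSpec("entropy")
    with pytest.raises(ValueError):
        MeasureSpec("good_rescaled")  # alpha required
    with pytest.raises(ValueError):
        MeasureSpec("good_rescaled", -1.0)
    with pytest.raises(ValueError):
        MeasureSpec("popper", alpha=1.0)
    assert MeasureSpec.from_config("G1") == MeasureSpec("good_rescaled", 0.5)
    assert MeasureSpec.from_config({"id": "G3"}) == MeasureSpec("good_rescaled", 2.0)
    spec = MeasureSpec.from_config({"id": "good_rescaled", "alpha": 3.0})
    assert spec.alpha == 3.0
    assert MeasureSpec.from_config(spec.to_config()) == spec


def test_degenerate_and_undefined_inputs():
    with pytest.raises(DegenerateMarginalError):
        power_from_conditionals(MeasureSpec("popper"),
                                PowerInputs(p_e_given_h=0.5, p_e=1.0))
    with pytest.raises(DegenerateMarginalError):
        power_from_conditionals(MeasureSpec("good"),
                                PowerInputs(p_e_given_h=0.5, p_e=0.0))
    with pytest.raises(UndefinedScoreError):
        power_ss(PowerInputs(p_h_given_e=0.0, p_h_given_not_e=0.0))
    # Good at Pr(E|H)=0: -inf sentinel by default, error in strict mode
    inputs = PowerInputs(p_e_given_h=0.0, p_e=0.5)
    assert power_from_conditionals(MeasureSpec("good"), inputs).value == -math.inf
    assert power_from_conditionals(
        MeasureSpec("good_rescaled", 1.0), inputs).value == -1.0
    with pytest.raises(UndefinedScoreError):
        power_from_conditionals(MeasureSpec("good"), inputs, zero_likelihood="error")


@given(peh=probs, pe=probs)
def test_bounded_measures_stay_in_range(peh, pe):
    inputs = PowerInputs(p_e_given_h=peh, p_e=pe)
    for mid in ("simple", "popper"):
        assert -1.0 <= power_from_conditionals(MeasureSpec(mid), inputs).value <= 1.0
    for alpha in (0.5, 1.0, 2.0):
        v = power_from_conditionals(MeasureSpec("good_rescaled", alpha), inputs).value
        assert -1.0 <= v <= 1.0


@given(phe=st.floats(0, 1), phn=st.floats(0, 1))
def test_posterior_ratio_stays_in_range(phe, phn):
    if phe + phn == 0:
        return
    assert -1.0 <= power_ss(PowerInputs(p_h_given_e=phe, p_h_given_not_e=phn)).value <= 1.0


@given(x=st.floats(-50, 50), y=st.floats(-50, 50), alpha=st.floats(0.1, 5))
def test_rescale_good_monotone_and_odd(x, y, alpha):
    lx, ly = rescale_good(x, alpha).value, rescale_good(y, alpha).value
    if x < y:
        assert lx <= ly
        # strict once the analytic increment is resolvable in doubles
        if y - x > 1e-6 and max(abs(x), abs(y)) < 6 * alpha:
            assert lx < ly
    assert rescale_good(-x, alpha).value == pytest.approx(-lx, abs=1e-15)


@given(pe=probs, lo=probs, hi=probs)
def test_measures_nondecreasing_in_likelihood(pe, lo, hi):
    """For fixed Pr(E), every measure ranks a higher likelihood at least as high."""
    lo, hi = min(lo, hi), max(lo, hi)
    for spec in (MeasureSpec("simple"), MeasureSpec("popper"), MeasureSpec("good"),
                 MeasureSpec("good_rescaled", 2.0)):
        v_lo = power_from_conditionals(spec, PowerInputs(p_e_given_h=lo, p_e=pe)).value
        v_hi = power_from_conditionals(spec, PowerInputs(p_e_given_h=hi, p_e=pe)).value
        assert v_hi >= v_lo - 1e-12


def test_model_dispatch_matches_hand_computed_conditionals(two_hyp):
    """power_from_model on the urn worked case reproduces the chained values."""
    space, ev = two_hyp
    assert power_from_model(MeasureSpec("schupbach_sprenger"), space, ev,
                            "H_A").value == pytest.approx(0.4, abs=1e-12)
    assert power_from_model(MeasureSpec("good"), space, ev, "H_A").value == \
        pytest.approx(math.log(4 / 3), abs=1e-12)
    # evidence independent of hypotheses: every measure is at its neutral point
    flat = EvidenceModel([0.6, 0.6])
    for m in study_measures().values():
        assert power_from_model(m, space, flat, "H_A").value == pytest.approx(0.0, abs=1e-12)


def test_model_oracle_equivalence_on_two_hypothesis_grid():
    """Exhaustive grid: model dispatch equals the formulas on independently
    assembled conditionals (Bayes's theorem done by hand in the test)."""
    grid = np.linspace(0.05, 0.95, 10)
    measures = list(study_measures().values()) + [MeasureSpec("simple"), MeasureSpec("good")]
    for pa in (0.2, 0.5, 0.8):
        space = HypothesisSpace(["H1", "H2"], [pa, 1 - pa])
        for l1 in grid:
            for l2 in grid:
                ev = EvidenceModel([l1, l2])
                pe = pa * l1 + (1 - pa) * l2
                hand = PowerInputs(
                    p_e_given_h=l1, p_e=pe,
                    p_h_given_e=pa * l1 / pe,
                    p_h_given_not_e=pa * (1 - l1) / (1 - pe),
                )
                for m in measures:
                    got = power_from_model(m, space, ev, "H1").value
                    if m.id == "schupbach_sprenger":
                        want = power_ss(hand).value
                    else:
                        want = power_from_conditionals(m, hand).value
                    assert got == pytest.approx(want, abs=1e-12)
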