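import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memfate import SourceDescriptor, eval_source, fit_source
from memfate.sources import SourceFitError


def test_sigmoid_anchors_at_smin_and_saturates_at_smax():
    desc = SourceDescriptor("sigmoid_growth", {"Smax": 1e7, "Smin": 1e5, "r": 0.1})
    assert eval_source(desc, 0.0) == pytest.approx(1e5, rel=1e-12)
    assert eval_source(desc, 1e4) == pytest.approx(1e7, rel=1e-9)


def test_sigmoid_monotone_nondecreasing():
    desc = SourceDescriptor("sigmoid_growth", {"Smax": 3.2e5, "Smin": 2e4, "r": 0.04})
    t = np.linspace(0, 600, 500)
    assert np.all(np.diff(eval_source(desc, t)) >= 0)


def test_exp_decay_half_life_identity():
    nu = math.log(2) / 228.0
    desc = SourceDescriptor("exp_decay", {"S0": 1e7, "nu": nu}, t_ref=0.0)
    assert eval_source(desc, 228.0) == pytest.approx(5e6, rel=1e-12)


@settings(derandomize=True, max_examples=30)
@given(st.floats(min_value=0.0, max_value=1000.0), st.floats(min_value=1e-4, max_value=0.1))
def test_exp_decay_halves_every_half_life(t, nu):
    desc = SourceDescriptor("exp_decay", {"S0": 2e7, "nu": nu}, t_ref=0.0)
    assert eval_source(desc, t + math.log(2) / nu) == pytest.approx(
        eval_source(desc, t) / 2.0, rel=1e-12
    )


def test_gen_logistic_confined_to_bounds():
    desc = SourceDescriptor(
        "gen_logistic",
        {"lower": 0.05, "upper": 0.9, "rate": 0.05, "midpoint": 60.0, "shape": 2.0},
    )
    v = eval_source(desc, np.linspace(0, 2000, 300))
    assert np.all(v >= 0.05 - 1e-12) and np.all(v <= 0.9 + 1e-12)
    assert np.all(np.diff(v) >= 0)


def test_negative_time_is_domain_error():
    desc = SourceDescriptor("exp_decay", {"S0": 1e6, "nu": 0.01})
    with pytest.raises(ValueError):
        eval_source(desc, -1.0)


def test_descriptor_validation():
    with pytest.raises(ValueError):
        SourceDescriptor("exp_decay", {"S0": -1.0, "nu": 0.01})
    with pytest.raises(ValueError):
        SourceDescriptor("sigmoid_growth", {"Smax": 1e4, "Smin": 1e5, "r": 0.1})
    with pytest.raises(ValueError):
        SourceDescriptor("gen_logistic", {"lower": 0.2, "upper": 1.4, "rate": 1, "midpoint": 0, "shape": 1})


@pytest.mark.parametrize(
    "kind,params,t_ref,times",
    [
        ("exp_decay", {"S0": 2e7, "nu": 0.003}, 66.0, np.linspace(66, 600, 15)),
        ("sigmoid_growth", {"Smax": 1e7, "Smin": 1e5, "r": 0.1}, 0.0, np.linspace(0, 120, 20)),
        (
            "gen_logistic",
            {"lower": 0.02, "upper": 0.9, "rate": 0.05, "midpoint": 60.0, "shape": 1.5},
            0.0,
            np.linspace(0, 300, 25),
        ),
    ],
)
def test_noiseless_fit_recovers_generating_curve(kind, params, t_ref, times):
    """fit_source . simulate is the identity (at curve level) on clean data."""
    truth = SourceDescriptor(kind, params, t_ref=t_ref)
    values = eval_source(truth, times)
    fitted = fit_source(times, values, kind, t_ref=t_ref)
    refit = eval_source(fitted, times)
    scale = np.maximum(np.abs(values), 1e-12)
    assert np.max(np.abs(refit - values) / scale) < 1e-5
    if kind == "exp_decay":
        assert fitted.params["S0"] == pytest.approx(params["S0"], rel=1e-6)
        assert fitted.params["nu"] == pytest.approx(params["nu"], rel=1e-6)


def test_noisy_exp_decay_recovers_decay_rate_within_15pct():
    rng = np.random.default_rng(42)
    truth = SourceDescriptor("exp_decay", {"S0": 2e7, "nu": 0.003}, t_ref=0.0)
    times = np.linspace(0, 600, 50)
    values = eval_source(truth, times) * np.exp(rng.normal(0, 0.2, size=50))
    fitted = fit_source(times, values, "exp_decay", t_ref=0.0)
    assert fitted.params["nu"] == pytest.approx(0.003, rel=0.15)


def test_fit_input_validation():
    with pytest.raises(ValueError):
        fit_source([1, 2], [10, 20], "exp_decay")  # too few points
    with pytest.raises(ValueError):
        fit_source([1, 2, 3, 4], [10, -5, 20, 30], "exp_decay")  # non-positive
    with pytest.raises(ValueError):
        fit_source([1, 2, 3, 4], [1, 2, 3, 4], "no_such_kind")
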