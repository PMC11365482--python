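"""Akaike weights, confidence sets, model averaging, inclusion, pooling."""

import math

import numpy as np
import pytest

from linecross import (
    akaike_weights,
    apply_inclusion_criteria,
    model_average,
    pool_and_scale,
)
from linecross.averaging import AveragedEffect, architecture_table
from linecross.models import ModelFit


def make_fit(effects, aicc, estimates=None, ses=None, n=5):
    """Hand-built ModelFit carrying only what the averaging stage reads."""
    effects = tuple(effects)
    estimates = {"intercept": 0.0, **(estimates or {})}
    ses = {"intercept": 0.0, **(ses or {})}
    return ModelFit(
        effects=effects,
        estimates=estimates,
        estimate_ses=ses,
        weighted_rss=0.0,
        k_params=len(effects) + 1,
        loglik=-aicc / 2,
        aicc=aicc,
        n_cohorts=n,
    )


def test_equal_aicc_pair_splits_weight():
    wset = akaike_weights([make_fit((), 10.0), make_fit(("Aa",), 10.0)])
    assert wset.weights == pytest.approx((0.5, 0.5))
    assert wset.delta == pytest.approx((0.0, 0.0))


def test_delta_two_weights():
    wset = akaike_weights([make_fit((), 0.0), make_fit(("Aa",), 2.0)])
    e = math.exp(-1.0)
    assert wset.weights == pytest.approx((1 / (1 + e), e / (1 + e)))
    assert wset.weights[0] == pytest.approx(0.7310585786)


def test_weights_sum_to_one_with_infinite_models(rng):
    aiccs = rng.uniform(0, 30, size=40).tolist() + [math.inf] * 5
    fits = [make_fit((), a) for a in aiccs]
    wset = akaike_weights(fits)
    assert sum(wset.weights) == pytest.approx(1.0)
    assert all(w == 0.0 for w, a in zip(wset.weights, aiccs) if math.isinf(a))
    assert min(d for d in wset.delta if math.isfinite(d)) == 0.0


def test_all_infinite_rejected():
    with pytest.raises(ValueError, match="finite"):
        akaike_weights([make_fit((), math.inf)])


def test_single_model_confidence_set():
    wset = akaike_weights([make_fit((), 3.0)])
    assert wset.weights == (1.0,)
    assert wset.confidence_set_size == 1


def test_confidence_set_minimality(rng):
    for trial in range(20):
        aiccs = rng.uniform(0, 12, size=30)
        wset = akaike_weights([make_fit((), a) for a in aiccs])
        inset = sorted(
            (w for w, f in zip(wset.weights, wset.confidence_flags) if f), reverse=True
        )
        assert sum(inset) >= 0.95
        assert sum(inset) - inset[-1] < 0.95  # dropping the weakest member breaks it


def test_model_average_zero_substitution():
    fits = [
        make_fit(("Aa",), 10.0, {"Aa": 4.0}, {"Aa": 1.0}),
        make_fit((), 10.0),
    ]
    avg = {e.effect: e for e in model_average(akaike_weights(fits))}
    aa = avg["Aa"]
    assert aa.estimate == pytest.approx(2.0)  # 0.5*4 + 0.5*0
    assert aa.variable_importance == pytest.approx(0.5)
    # unconditional SE: 0.5*sqrt(1 + (4-2)^2) + 0.5*sqrt(0 + (0-2)^2)
    assert aa.unconditional_se == pytest.approx(0.5 * math.sqrt(5) + 1.0)


def test_vi_bounds_and_extremes():
    fits = [
        make_fit(("Aa",), 0.0, {"Aa": 3.0}, {"Aa": 0.5}),
        make_fit(("Aa", "Ad"), 1.0, {"Aa": 3.2, "Ad": 0.1}, {"Aa": 0.5, "Ad": 0.2}),
    ]
    avg = {e.effect: e for e in model_average(akaike_weights(fits), ["Aa", "Ad", "Ca"])}
    assert avg["Aa"].variable_importance == pytest.approx(1.0)  # in every model
    assert avg["Ca"].variable_importance == 0.0                 # in none
    assert avg["Ca"].estimate == 0.0
    assert 0.0 < avg["Ad"].variable_importance < 1.0


def test_confidence_scope_renormalizes():
    # third model falls outside the 95% set; its estimate must not leak in
    fits = [
        make_fit(("Aa",), 0.0, {"Aa": 2.0}, {"Aa": 0.1}),
        make_fit((), 0.2),
        make_fit(("Ca",), 40.0, {"Ca": 99.0}, {"Ca": 0.1}),
    ]
    wset = akaike_weights(fits)
    assert wset.confidence_flags == (True, True, False)
    avg = {e.effect: e for e in model_average(wset, ["Aa", "Ca"])}
    assert avg["Ca"].estimate == 0.0
    w0 = 1 / (1 + math.exp(-0.1))
    assert avg["Aa"].estimate == pytest.approx(2.0 * w0)
    full = {e.effect: e for e in model_average(wset, ["Aa", "Ca"], scope="all")}
    assert full["Ca"].estimate != 0.0  # the switch really widens the pool


def test_inclusion_criteria_strict():
    effects = [
        AveragedEffect("AaAa", estimate=5.0, unconditional_se=1.0, variable_importance=0.26),
        AveragedEffect("Aa", estimate=2.0, unconditional_se=1.0, variable_importance=0.9),
        AveragedEffect("Ad", estimate=1.0, unconditional_se=1.5, variable_importance=0.9),
        AveragedEffect("Ca", estimate=1.0, unconditional_se=1.0, variable_importance=0.9),
        AveragedEffect("Mea", estimate=2.0, unconditional_se=1.0, variable_importance=0.5),
    ]
    out = {e.effect: e.included for e in apply_inclusion_criteria(effects)}
    assert out == {
        "AaAa": False,  # importance below threshold
        "Aa": True,
        "Ad": False,    # +-1 SE interval covers zero
        "Ca": False,    # boundary: |estimate| == se is not exclusion
        "Mea": False,   # boundary: importance == 0.5 is not enough
    }


def test_se_multiplier_knob():
    effects = [AveragedEffect("Aa", 2.0, 1.5, 0.9)]
    assert apply_inclusion_criteria(effects, se_multiplier=1.0)[0].included
    assert not apply_inclusion_criteria(effects, se_multiplier=1.96)[0].included


def test_pool_and_scale_categories():
    effects = apply_inclusion_criteria(
        [
            AveragedEffect("Ca", 3.0, 0.5, 0.9),
            AveragedEffect("AaAa", -4.0, 0.5, 0.9),
        ]
    )
    arch = pool_and_scale(effects, "leaf_area", confidence_set_size=1)
    assert arch.proportions["additive"] == pytest.approx(3 / 7)
    assert arch.proportions["epistatic"] == pytest.approx(4 / 7)
    assert arch.proportions["dominance"] == 0.0
    assert sum(arch.proportions.values()) == pytest.approx(1.0, abs=1e-12)


def test_pool_single_effect_gets_one():
    effects = apply_inclusion_criteria([AveragedEffect("Aa", 2.0, 0.1, 1.0)])
    arch = pool_and_scale(effects, "leaf_length", confidence_set_size=14)
    assert arch.proportions["additive"] == 1.0
    assert arch.confidence_set_size == 14


def test_pool_empty_inclusion_is_all_nan():
    effects = apply_inclusion_criteria([AveragedEffect("AaAa", 1.0, 2.0, 0.26)])
    arch = pool_and_scale(effects, "areal_ratio", confidence_set_size=13)
    assert all(math.isnan(v) for v in arch.proportions.values())
    table = architecture_table([arch])
    assert table["confidence_set_size"].iloc[0] == 13
    assert table[["additive", "dominance", "epistatic", "maternal"]].isna().all().all()


def test_vi_monotone_under_duplicated_support():
    """Adding another strong model containing an effect cannot lower its VI."""
    base = [
        make_fit(("Aa",), 0.0, {"Aa": 1.0}, {"Aa": 0.3}),
        make_fit((), 1.0),
    ]
    more = base + [make_fit(("Aa", "Ad"), 0.5, {"Aa": 1.1, "Ad": 0.2}, {"Aa": 0.3, "Ad": 0.1})]
    vi_base = {e.effect: e.variable_importance for e in model_average(akaike_weights(base), ["Aa"])}
    vi_more = {e.effect: e.variable_importance for e in model_average(akaike_weights(more), ["Aa"])}
    assert vi_more["Aa"] >= vi_base["Aa"] - 1e-12
    assert 0.0 <= vi_more["Aa"] <= 1.0
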