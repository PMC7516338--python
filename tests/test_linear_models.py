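"""Weighted-sum model fits: indexing, normalization, mixtures, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from retroeval.core import MomentSequence, RatedTrial
from retroeval.linear_models import (
    KNOT_LEVELS,
    FitError,
    PartitionWeights,
    PreferenceWeightFunction,
    absolute_preference_predict,
    combined_order_preference,
    fit_absolute_preference,
    fit_lambda,
    fit_linear_weights,
    fit_windowed_preference_weights,
    preference_weight,
    reindex_by_relative_preference,
)
from retroeval.core import DomainError

utilities = st.lists(
    st.floats(min_value=1.0, max_value=9.0, allow_nan=False), min_size=1, max_size=12
)


def test_reindex_example():
    xs, perm = reindex_by_relative_preference([9, 1, 8.99, 1.01])
    assert np.allclose(xs, [1, 1.01, 8.99, 9])
    assert list(perm) == [1, 3, 2, 0]


def test_reindex_sorted_input_unchanged():
    xs, perm = reindex_by_relative_preference([1.0, 2.0, 3.0])
    assert np.allclose(xs, [1, 2, 3])
    assert list(perm) == [0, 1, 2]


def test_reindex_stable_ties():
    _, perm = reindex_by_relative_preference([5.0, 5.0, 3.0])
    assert list(perm) == [2, 0, 1]  # earlier position gets the lower rank


@settings(max_examples=50, derandomize=True)
@given(utilities)
def test_reindex_matches_sort_oracle(x):
    xs, perm = reindex_by_relative_preference(x)
    assert list(xs) == sorted(x)
    assert sorted(perm) == list(range(len(x)))


def _fit_trials(target, rng, n=96, noise=0.0):
    trials = []
    for _ in range(n):
        x = rng.uniform(1, 9, 4)
        y = target(x) + (rng.normal(0, noise) if noise else 0.0)
        trials.append(RatedTrial(MomentSequence(x), float(np.clip(y, 1, 9)), "seq4"))
    return trials


@pytest.mark.parametrize(
    "target,indexing,expected",
    [
        (np.mean, "order", [0.25, 0.25, 0.25, 0.25]),
        (np.mean, "relative_preference", [0.25, 0.25, 0.25, 0.25]),
        (lambda x: x[-1], "order", [0, 0, 0, 1]),
        (np.max, "relative_preference", [0, 0, 0, 1]),
    ],
)
def test_linear_weight_fits_recover_generators(target, indexing, expected, rng):
    fit = fit_linear_weights(_fit_trials(target, rng), indexing)
    assert np.allclose(fit.weights.w, expected, atol=1e-8)
    assert fit.correlation == pytest.approx(1.0, abs=1e-9)
    # normalization invariants and the MSE-correlation identity
    assert fit.weights.w.sum() == pytest.approx(1.0, abs=1e-10)
    assert fit.weights.deviations.sum() == pytest.approx(0.0, abs=1e-10)
    assert fit.mse_identity_gap < 1e-10


def test_order_weight_recovery_under_noise(rng):
    """96 trials, noise SD 0.5: weights within 0.05 (L-inf), 20-seed mean."""
    truth = np.array([0.2325, 0.2224, 0.2665, 0.2786])
    errs = []
    for seed in range(20):
        r = np.random.default_rng(seed)
        trials = _fit_trials(lambda x: truth @ x, r, noise=0.5)
        fit = fit_linear_weights(trials, "order")
        errs.append(np.max(np.abs(fit.weights.w - truth)))
    assert np.mean(errs) < 0.05


def test_rank_deficient_design_raises(rng):
    trials = []
    for _ in range(20):
        x = rng.uniform(1, 9, 3)
        seq = np.array([5.0, *x])  # first position constant
        trials.append(RatedTrial(MomentSequence(seq), float(np.mean(seq)), "seq4"))
    with pytest.raises(FitError):
        fit_linear_weights(trials, "order")


def test_combined_model_endpoints(rng):
    x = rng.uniform(1, 9, 4)
    wo = np.array([0.05, -0.05, -0.1, 0.1])
    wp = np.array([-0.08, 0.02, 0.0, 0.06])
    xs = np.sort(x)
    assert combined_order_preference(x, wo, wp, 1.0) == pytest.approx(
        np.mean(x) + wo @ x
    )
    assert combined_order_preference(x, wo, wp, 0.0) == pytest.approx(
        np.mean(x) + wp @ xs
    )
    zero = np.zeros(4)
    for lam in (0.0, 0.37, 1.0):
        assert combined_order_preference(x, zero, zero, lam) == pytest.approx(
            np.mean(x)
        )


@pytest.mark.parametrize("lam_true,expected", [(1.0, 1.0), (0.0, 0.0)])
def test_lambda_recovery(lam_true, expected, rng):
    wo = np.array([0.05, -0.05, -0.1, 0.1])
    wp = np.array([-0.08, 0.02, 0.0, 0.06])

    def target(x):
        return combined_order_preference(x, wo, wp, lam_true)

    trials = _fit_trials(target, rng)
    fit = fit_lambda(trials, wo, wp)
    assert fit.extras["lambda"].lam == expected


def test_combined_at_least_as_good_as_components(rng):
    trials = _fit_trials(np.mean, rng, noise=0.8)
    fo = fit_linear_weights(trials, "order")
    fp = fit_linear_weights(trials, "relative_preference")
    fl = fit_lambda(trials, fo.weights.deviations, fp.weights.deviations)
    assert fl.correlation >= max(fo.correlation, fp.correlation) - 1e-12


def test_absolute_preference_reductions(rng):
    x = rng.uniform(1, 9, 4)
    assert absolute_preference_predict(x, PartitionWeights([0, 0, 0, 0])) == (
        pytest.approx(np.sum(x) / 4)
    )
    # permutation invariance
    pw = PartitionWeights([0.1, -0.05, 0.02, 0.2])
    assert absolute_preference_predict(x, pw) == pytest.approx(
        absolute_preference_predict(x[::-1], pw)
    )


def test_absolute_preference_single_bin_tracks_average(rng):
    pw = PartitionWeights([0.3, 0.0, 0.0, 0.0])
    preds, avgs = [], []
    for _ in range(30):
        x = rng.uniform(1, 2.99, 4)  # all utilities in the first bin
        preds.append(absolute_preference_predict(x, pw))
        avgs.append(np.mean(x))
    assert np.corrcoef(preds, avgs)[0, 1] == pytest.approx(1.0, abs=1e-12)


def test_absolute_preference_recovery_and_oracle(rng):
    truth = PartitionWeights([-0.06, -0.02, 0.02, 0.06])
    trials = _fit_trials(lambda x: absolute_preference_predict(x, truth), rng)
    fit = fit_absolute_preference(trials)
    assert np.allclose(fit.weights.w, truth.w, atol=1e-7)
    assert fit.mse_identity_gap < 1e-10

    # independent oracle: direct nonlinear search over the four weights must
    # not beat the closed-form OLS optimum
    y = np.array([tr.remembered_utility for tr in trials])

    def neg_corr(w):
        p = [absolute_preference_predict(tr.sequence, PartitionWeights(w))
             for tr in trials]
        return -np.corrcoef(p, y)[0, 1]

    res = optimize.minimize(neg_corr, x0=np.zeros(4), method="Nelder-Mead")
    assert fit.correlation >= -res.fun - 1e-6


def test_preference_weight_interpolation():
    pwf = PreferenceWeightFunction([0.1, 0.3, -0.2, 0.0, 0.4])
    for knot, val in zip(KNOT_LEVELS, pwf.knots):
        assert preference_weight(knot, pwf) == val
    assert preference_weight(2.0, pwf) == pytest.approx((0.1 + 0.3) / 2)
    with pytest.raises(DomainError):
        preference_weight(9.5, pwf)


@settings(max_examples=50, derandomize=True)
@given(
    st.floats(min_value=1.0, max_value=9.0, allow_nan=False),
    st.lists(st.floats(min_value=-1, max_value=1, allow_nan=False),
             min_size=5, max_size=5),
)
def test_preference_weight_matches_piecewise_oracle(x, knots):
    pwf = PreferenceWeightFunction(knots)
    # independent piecewise-linear evaluation
    j = min(int((x - 1.0) // 2.0), 3)
    x0, x1 = 1.0 + 2.0 * j, 3.0 + 2.0 * j
    frac = (x - x0) / (x1 - x0)
    expected = knots[j] * (1 - frac) + knots[j + 1] * frac
    assert preference_weight(x, pwf) == pytest.approx(expected, abs=1e-12)


def test_windowed_preference_fit_recovers_knots(rng):
    truth = PreferenceWeightFunction([-0.05, -0.02, 0.0, 0.03, 0.08])
    seqs, raw = [], []
    for _ in range(80):
        t = int(rng.integers(8, 60))
        x = rng.uniform(1, 9, t)
        win = x[-10:]
        w = 1 / win.size + np.interp(win, KNOT_LEVELS, truth.knots)
        seqs.append(x)
        raw.append(float(np.sum(w * win)))
    raw = np.array(raw)
    # affine-map onto the rating scale: the fit family is affine-invariant
    ys = 1.5 + 7.0 * (raw - raw.min()) / (raw.max() - raw.min())
    trials = [RatedTrial(MomentSequence(x), float(y), "continued")
              for x, y in zip(seqs, ys)]
    fit = fit_windowed_preference_weights(trials, L=10)
    assert fit.correlation > 0.999999
    assert np.allclose(fit.pwf.knots, truth.knots, atol=1e-6)
    # predict() agrees with the stored fitting-set predictions
    again = [fit.predict(tr.sequence) for tr in trials]
    assert np.allclose(again, fit.predictions, atol=1e-9)
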