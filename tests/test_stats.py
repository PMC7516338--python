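"""Correlation machinery, sign test, WM analyses, PCA regression."""

import math

import numpy as np
import pytest

from retroeval.core import DomainError, MomentSequence, RatedTrial, WMRecord
from retroeval.discounting import DiscountParams, fit_discounting, pd_total_utility
from retroeval.stats import (
    AnalysisError,
    affine_rescaled_mse,
    compare_models_ttest,
    correlation_test,
    pca_regression,
    sign_test,
    sse_group_analysis,
    wm_preference_vector,
)


def test_correlation_affine_invariance(rng):
    y = rng.uniform(1, 9, 40)
    ct = correlation_test(2 * y + 3, y)
    assert ct.pearson == pytest.approx(1.0)
    assert correlation_test(-y, y).pearson == pytest.approx(-1.0)


def test_correlation_spearman_monotone_invariance(rng):
    y = rng.uniform(1, 9, 40)
    pred = rng.uniform(0, 1, 40)
    a = correlation_test(pred, y)
    b = correlation_test(np.exp(5 * pred), y)  # strictly monotone transform
    assert a.spearman == pytest.approx(b.spearman, abs=1e-12)
    assert a.kendall == pytest.approx(b.kendall, abs=1e-12)


def test_correlation_errors():
    with pytest.raises(AnalysisError):
        correlation_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(DomainError):
        correlation_test([1.0, 2.0], [1.0, 2.0])


def test_mse_correlation_identity(rng):
    """MSE of the optimally rescaled prediction obeys MSE/s_y^2 = 1-corr^2."""
    for _ in range(10):
        y = rng.uniform(1, 9, 50)
        pred = 0.4 * y + rng.normal(0, 1.0, 50)
        mse = affine_rescaled_mse(pred, y)
        corr = np.corrcoef(pred, y)[0, 1]
        assert mse / np.var(y) == pytest.approx(1 - corr**2, abs=1e-10)


def test_sign_test_values():
    assert sign_test(5, 5, 0.25) == pytest.approx(0.25**5)
    assert f"{sign_test(5, 5, 0.25):.4g}" == "0.0009766"
    assert sign_test(0, 7, 0.3) == 1.0
    assert sign_test(2, 2, 0.5) == pytest.approx(0.25)


def test_sign_test_complement_exhaustive():
    """P(X >= k) + P(X <= k-1) = 1, checked by direct enumeration, n <= 10."""
    for n in range(1, 11):
        for k in range(0, n + 1):
            for p0 in (0.25, 0.5, 0.8):
                upper = sign_test(k, n, p0)
                lower = sum(
                    math.comb(n, j) * p0**j * (1 - p0) ** (n - j)
                    for j in range(0, k)
                )
                assert upper + lower == pytest.approx(1.0, abs=1e-12)


def test_sign_test_domain():
    with pytest.raises(DomainError):
        sign_test(6, 5, 0.5)
    with pytest.raises(DomainError):
        sign_test(1, 5, 1.0)


def test_ttest_identical_and_degenerate():
    assert compare_models_ttest([0.5, 0.6, 0.7], [0.5, 0.6, 0.7]) == (0.0, 1.0)
    with pytest.raises(AnalysisError):
        compare_models_ttest([0.5, 0.6, 0.7], [0.4, 0.5, 0.6])  # zero-variance diff
    with pytest.raises(DomainError):
        compare_models_ttest([0.5], [0.4, 0.3])


def test_ttest_matches_permutation_oracle(rng):
    """Rejection decision agrees with a 10,000-draw sign-flip test."""
    a = rng.uniform(0.5, 0.8, 20)
    b = a - rng.uniform(0.02, 0.12, 20)  # consistent but noisy advantage
    b += rng.normal(0, 0.03, 20)
    t, p = compare_models_ttest(a, b)
    d = a - b
    flips = rng.choice([-1.0, 1.0], size=(10000, 20))
    null_means = np.abs((flips * d).mean(axis=1))
    p_perm = float(np.mean(null_means >= abs(d.mean())))
    assert (p < 0.05) == (p_perm < 0.05)


def _records(profile, n_per_group=10, n_correct=None):
    out = []
    for g, acc in enumerate(profile, start=1):
        k = int(round(acc * n_per_group)) if n_correct is None else n_correct[g - 1]
        for i in range(n_per_group):
            correct = i < k
            out.append(WMRecord(5.0, g, 2, 2 if correct else 3))
    return out


def test_wm_vector_ceiling():
    vec = wm_preference_vector(_records([1, 1, 1, 1]))
    assert np.allclose(vec.accuracy, 1.0)
    assert vec.variance == 0.0


def test_wm_vector_flat_profile_zero_variance():
    vec = wm_preference_vector(_records([0.5, 0.5, 0.5, 0.5]))
    assert vec.variance == 0.0


def test_wm_vector_hand_variance():
    vec = wm_preference_vector(_records([0.9, 0.8, 0.6, 0.7]))
    assert np.allclose(vec.accuracy, [0.9, 0.8, 0.6, 0.7])
    assert vec.variance == pytest.approx(0.0125)


def test_wm_vector_empty_group():
    records = _records([0.9, 0.8, 0.6, 0.7])
    records = [r for r in records if r.preference_group != 3]
    with pytest.raises(AnalysisError, match="group 3"):
        wm_preference_vector(records)


def test_sse_group_analysis_basics():
    n = 12
    res = sse_group_analysis([10.0] * n, [10.0] * n, np.linspace(0, 0.01, n))
    assert np.allclose(res["change_ratios"], 0.0)
    res = sse_group_analysis([10.0], [8.0], [0.001], n_groups=1)
    assert res["change_ratios"][0] == pytest.approx(0.2)
    with pytest.raises(AnalysisError):
        sse_group_analysis([1, 2], [1, 2], [0.1, 0.2], n_groups=6)


def test_sse_group_analysis_recovers_preference_dependence():
    """Participants with preference-dependent forgetting show larger
    SD-to-PD improvement, producing a positive group-index correlation."""
    rng = np.random.default_rng(4)
    sse_sd, sse_pd, variances = [], [], []
    spreads = np.linspace(0.0, 0.4, 12)
    for spread in spreads:
        knots = np.clip([0.7 + spread, 0.7, 0.7 - spread, 0.7, 0.7 + spread], 0, 1)
        seqs = [np.round(rng.uniform(1, 9, int(rng.integers(8, 30))) * 2) / 2
                for _ in range(60)]
        raw = np.array([
            pd_total_utility(x, DiscountParams("PD", knots)) for x in seqs
        ])
        y = 1 + 8 * (raw - raw.min()) / (raw.max() - raw.min())
        y = np.clip(y + rng.normal(0, 0.3, 60), 1, 9)
        trials = [RatedTrial(MomentSequence(x), float(v), "continued")
                  for x, v in zip(seqs, y)]
        sd = fit_discounting(trials, "SD", max_iter=2000)
        pd = fit_discounting(trials, "PD", max_iter=2000)
        sse_sd.append(sd.sse)
        sse_pd.append(pd.sse)
        variances.append(spread**2)  # WM variance proxy scales with spread
    res = sse_group_analysis(sse_sd, sse_pd, variances)
    assert res["correlation"] > 0


def test_pca_regression_perfect_linear(rng):
    W = rng.uniform(0.55, 0.95, size=(30, 4))
    r = W @ np.array([0.5, -0.2, 0.3, 0.1]) + 0.2
    res = pca_regression(r, W)
    best = res["per_rate"][0]
    assert best["r_squared"] == pytest.approx(1.0, abs=1e-10)
    assert best["p_value"] < 1e-12


def test_pca_regression_null_calibration():
    """Independent rates: non-significant at alpha=0.05 in >= 90% of seeds."""
    rng = np.random.default_rng(0)
    rejections = 0
    for _ in range(100):
        W = rng.uniform(0.55, 0.95, size=(66, 4))
        r = rng.uniform(0, 1, size=66)
        res = pca_regression(r, W)
        rejections += res["per_rate"][0]["p_value"] < 0.05
    assert rejections <= 10


def test_pca_regression_one_component_structure(rng):
    """A single latent dimension: PC1 dominates and is the selected model."""
    latent = rng.uniform(-1, 1, size=(40, 1))
    W = 0.75 + latent @ np.array([[0.1, 0.08, 0.12, 0.09]])
    W += rng.normal(0, 0.002, W.shape)
    r = 0.5 + 0.4 * latent[:, 0]
    res = pca_regression(r, W)
    assert res["explained_variance_ratio"][0] > 0.95
    assert res["per_rate"][0]["n_components"] == 1
    # eigendecomposition oracle: PC1 direction matches the loading vector
    cov = np.cov(W.T)
    vals, vecs = np.linalg.eigh(cov)
    pc1 = vecs[:, -1]
    loading = np.array([0.1, 0.08, 0.12, 0.09])
    cos = abs(pc1 @ loading) / np.linalg.norm(loading)
    assert cos > 0.999


def test_pca_regression_preconditions(rng):
    with pytest.raises(AnalysisError):
        pca_regression(rng.uniform(0, 1, 4), rng.uniform(0, 1, (4, 4)))
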