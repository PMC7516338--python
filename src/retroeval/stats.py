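"""Correlation tests, model comparison, and working-memory analyses.

Model quality throughout the package is the Pearson correlation between a
model's total utilities and the participants' remembered utilities; because
every model is compared after optimal affine rescaling, minimizing the MSE of
the rescaled prediction and maximizing the squared correlation coincide
(MSE / s_y^2 = 1 - corr^2). This module provides that machinery plus the
cohort-level analyses: exact sign tests, paired t-tests on per-participant
correlations, preference-dependent working-memory accuracy vectors, the
six-group SSE-improvement analysis, and the PCA regression that relates
fitted discounting rates to working-memory accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from sklearn.decomposition import PCA

from .core import DomainError, WMRecord


class AnalysisError(ValueError):
    """An analysis precondition fails (constant input, empty group, ...)."""


def pearson(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise AnalysisError("correlation undefined for constant input")
    return float(np.corrcoef(a, b)[0, 1])


def optimal_affine(pred, y) -> tuple[float, float]:
    """Closed-form (a, b) minimizing MSE(y, a*pred + b) — simple regression."""
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    vp = np.var(pred)
    if vp == 0:
        return 0.0, float(np.mean(y))
    a = float(np.cov(pred, y, bias=True)[0, 1] / vp)
    b = float(np.mean(y) - a * np.mean(pred))
    return a, b


def affine_rescaled_mse(pred, y) -> float:
    """MSE of the optimally rescaled prediction, min_{a,b} MSE(y, a*pred+b)."""
    a, b = optimal_affine(pred, y)
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.mean((y - (a * pred + b)) ** 2))


@dataclass(frozen=True)
class CorrelationTest:
    """Pearson/Spearman/Kendall correlations of a model against the data."""

    pearson: float
    spearman: float
    kendall: float
    n: int
    p_value: float  # two-sided p of the Pearson correlation


def correlation_test(y_model, y) -> CorrelationTest:
    """All three correlation measures between model outputs and data.

    Pearson is the optimization criterion everywhere in the package (it is
    invariant under positive affine maps of either argument); Spearman and
    Kendall are reported as robustness checks only.
    """
    y_model = np.asarray(y_model, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_model.size != y.size or y.size < 3:
        raise DomainError("correlation_test requires equal lengths >= 3")
    if np.std(y_model) == 0 or np.std(y) == 0:
        raise AnalysisError("correlation undefined for constant input")
    r, p = sps.pearsonr(y_model, y)
    rho = sps.spearmanr(y_model, y).statistic
    tau = sps.kendalltau(y_model, y).statistic
    return CorrelationTest(float(r), float(rho), float(tau), int(y.size), float(p))


def sign_test(k: int, n: int, p0: float) -> float:
    """Exact upper-tail sign test: P(X >= k) for X ~ Binomial(n, p0)."""
    if not (0 <= k <= n):
        raise DomainError("need 0 <= k <= n")
    if not (0.0 < p0 < 1.0):
        raise DomainError("need 0 < p0 < 1")
    return float(sps.binom.sf(k - 1, n, p0))


def compare_models_ttest(corrs_A, corrs_B) -> tuple[float, float]:
    """Paired two-sided t-test on per-participant correlation values.

    Following the source analyses, correlations are compared directly (no
    Fisher z-transform); see ``fisher_z`` to transform first if desired.
    """
    a = np.asarray(corrs_A, dtype=float)
    b = np.asarray(corrs_B, dtype=float)
    if a.size != b.size:
        raise DomainError("paired samples must have equal length")
    if a.size < 2:
        raise DomainError("need at least 2 pairs")
    if np.allclose(a, b):
        return 0.0, 1.0
    d = a - b
    if np.std(d) == 0:
        raise AnalysisError("degenerate paired differences (zero variance)")
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def fisher_z(r) -> np.ndarray:
    return np.arctanh(np.asarray(r, dtype=float))


# ---------------------------------------------------------------------------
# Working-memory accuracy analyses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WMAccuracyVector:
    """Per-preference-group WM accuracy and its (population) variance."""

    accuracy: np.ndarray
    variance: float
    counts: np.ndarray


def wm_preference_vector(
    records: Sequence[WMRecord], n_groups: int = 4, ddof: int = 0
) -> WMAccuracyVector:
    """Fraction of correct position recalls per preference group.

    The variance of the vector indexes how strongly working memory depends
    on preference: it is exactly zero for a flat accuracy profile. The
    population convention (ddof=0) is the default.
    """
    correct = np.zeros(n_groups)
    total = np.zeros(n_groups)
    for r in records:
        g = r.preference_group
        if not (1 <= g <= n_groups):
            raise AnalysisError(f"preference group {g} outside 1..{n_groups}")
        total[g - 1] += 1
        correct[g - 1] += r.correct
    for g in range(n_groups):
        if total[g] == 0:
            raise AnalysisError(f"no probes for preference group {g + 1}")
    acc = correct / total
    return WMAccuracyVector(acc, float(np.var(acc, ddof=ddof)), total.astype(int))


def sse_group_analysis(
    sse_sd, sse_pd, wm_variances, n_groups: int = 6
) -> dict:
    """Six-group analysis of the SD-to-PD SSE improvement.

    Participants are split into ``n_groups`` equal-size groups by the
    variance of their WM accuracy vector (low to high; ties broken by input
    order). Each participant's improvement is the change ratio
    |(SSE_PD - SSE_SD) / SSE_SD|; reported per group as a mean, together with
    the Pearson correlation between group index and group mean.
    """
    sse_sd = np.asarray(sse_sd, dtype=float)
    sse_pd = np.asarray(sse_pd, dtype=float)
    v = np.asarray(wm_variances, dtype=float)
    n = v.size
    if not (sse_sd.size == sse_pd.size == n):
        raise DomainError("one SSE pair and one WM variance per participant")
    if n < n_groups:
        raise AnalysisError(f"need at least {n_groups} participants")
    ratio = np.abs((sse_pd - sse_sd) / sse_sd)
    order = np.argsort(v, kind="stable")
    groups = np.array_split(order, n_groups)
    means = np.array([ratio[g].mean() for g in groups])
    idx = np.arange(1, n_groups + 1, dtype=float)
    if np.std(means) == 0:
        corr, p = 0.0, 1.0
    else:
        corr, p = sps.pearsonr(idx, means)
    return {
        "group_means": means,
        "group_members": [g.tolist() for g in groups],
        "change_ratios": ratio,
        "correlation": float(corr),
        "p_value": float(p),
    }


# ---------------------------------------------------------------------------
# PCA regression of discounting rates on WM accuracy vectors
# ---------------------------------------------------------------------------


def pca_regression(r_values, wm_vectors, alpha: float = 0.05) -> dict:
    """Regress per-participant discount rates on PCA'd WM accuracy vectors.

    The accuracy vectors (participants x D) are decomposed by PCA; each
    discount rate (column of ``r_values``) is regressed on the leading q
    component scores, with q chosen to give the most significant regression
    (smallest F-statistic p-value). Also reported is the literal
    "simultaneous" criterion from the source analysis: whether the sum of
    the per-rate p-values falls below ``alpha`` (a non-standard aggregate,
    flagged as such).
    """
    R = np.atleast_2d(np.asarray(r_values, dtype=float))
    if R.shape[0] == 1 and R.shape[1] > 1 and np.asarray(r_values).ndim == 1:
        R = R.T
    W = np.asarray(wm_vectors, dtype=float)
    n, D = W.shape
    if n < D + 2:
        raise AnalysisError(f"need at least D+2={D + 2} participants")
    if R.shape[0] != n:
        raise DomainError("one rate row per participant required")
    pca = PCA()
    scores = pca.fit_transform(W)
    n_comp = int(np.sum(pca.explained_variance_ > 1e-12))
    if n_comp == 0:
        raise FitErrorLike("WM vectors have no variance")
    results = []
    for j in range(R.shape[1]):
        y = R[:, j]
        best = None
        for q in range(1, n_comp + 1):
            X = np.column_stack([np.ones(n), scores[:, :q]])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            fitted = X @ beta
            rss = float(np.sum((y - fitted) ** 2))
            tss = float(np.sum((y - y.mean()) ** 2))
            if tss == 0:
                raise AnalysisError("constant discount rates")
            dfn, dfd = q, n - q - 1
            if rss <= 1e-300:
                F, p = np.inf, 0.0
            else:
                F = ((tss - rss) / dfn) / (rss / dfd)
                p = float(sps.f.sf(F, dfn, dfd))
            cand = {
                "rate_index": j,
                "n_components": q,
                "r_squared": 1.0 - rss / tss,
                "F": float(F),
                "p_value": p,
                "coefficients": beta[1:].copy(),
                "intercept": float(beta[0]),
            }
            if best is None or p < best["p_value"]:
                best = cand
        results.append(best)
    p_sum = float(sum(r["p_value"] for r in results))
    return {
        "per_rate": results,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "p_value_sum": p_sum,
        "simultaneous_significant": p_sum < alpha,
    }


class FitErrorLike(RuntimeError):
    """Rank-deficient or degenerate decomposition in pca_regression."""
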