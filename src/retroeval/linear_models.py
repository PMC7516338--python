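"""Generalized weighted-sum evaluation models.

A sequence evaluation of the form y = sum_i w_i x_i subsumes the basic
estimators: uniform weights give Average, a unit weight on the last position
gives End, and a unit weight on the top preference rank gives Peak. This
module fits the two linear generalizations — order-dependent weights (indexed
by temporal position) and relative-preference-dependent weights (indexed by
within-sequence preference rank) — their lambda-mixture, and the non-linear
absolute-preference models whose weights depend on the moment utility itself
(four partition bins, or a 17-level weight function interpolated from 5 free
knots).

Fits maximize the Pearson correlation with the remembered utilities, which
for these models is equivalent to minimizing the MSE of the optimally
rescaled prediction (MSE / s_y^2 = 1 - corr^2); every fit records the gap in
that identity as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import RATING_LEVELS, DomainError, RatedTrial, _as_utilities
from .stats import affine_rescaled_mse, pearson

#: Knot placement for the 5 free preference-weight parameters: evenly spaced
#: over the 17 rating levels.
KNOT_LEVELS = np.array([1.0, 3.0, 5.0, 7.0, 9.0])

#: Absolute-preference partition bins: [1,3), [3,5), [5,7), [7,9].
PARTITION_EDGES = np.array([1.0, 3.0, 5.0, 7.0, 9.0])


class FitError(RuntimeError):
    """A model fit failed (rank deficiency, degenerate normalization, ...)."""


# ---------------------------------------------------------------------------
# Weight containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearWeights:
    """Normalized per-position (or per-rank) weights summing to one."""

    w: np.ndarray
    indexing: str  # "order" | "relative_preference"

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if self.indexing not in ("order", "relative_preference"):
            raise DomainError(f"unknown indexing {self.indexing!r}")
        if abs(w.sum() - 1.0) > 1e-8:
            raise DomainError("LinearWeights must sum to 1")
        object.__setattr__(self, "w", w)

    @property
    def n(self) -> int:
        return self.w.size

    @property
    def deviations(self) -> np.ndarray:
        """Zero-mean deviations from uniform averaging, w - 1/n."""
        return self.w - 1.0 / self.n


@dataclass(frozen=True)
class PartitionWeights:
    """Per-utility-bin weight deviations for the 4-partition model."""

    w: np.ndarray  # length 4, bins [1,3), [3,5), [5,7), [7,9]

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if w.shape != (4,):
            raise DomainError("PartitionWeights requires 4 bin weights")
        object.__setattr__(self, "w", w)

    def weight_of(self, x: float) -> float:
        if not (1.0 <= x <= 9.0):
            raise DomainError(f"utility {x} outside [1, 9]")
        b = min(int(np.searchsorted(PARTITION_EDGES, x, side="right")) - 1, 3)
        return float(self.w[b])


@dataclass(frozen=True)
class PreferenceWeightFunction:
    """Preference weights on the 17 rating levels from 5 free knot values.

    The free parameters sit at utilities {1, 3, 5, 7, 9}; the 17 level values
    (and any utility in between) follow by linear interpolation, so the
    function is exact at knots and piecewise linear elsewhere.
    """

    knots: np.ndarray  # length 5

    def __post_init__(self):
        k = np.asarray(self.knots, dtype=float)
        if k.shape != (5,):
            raise DomainError("PreferenceWeightFunction requires 5 knot values")
        object.__setattr__(self, "knots", k)

    @property
    def level_values(self) -> np.ndarray:
        return np.interp(RATING_LEVELS, KNOT_LEVELS, self.knots)

    def __call__(self, x: float) -> float:
        return preference_weight(x, self)


def preference_weight(x: float, pwf: PreferenceWeightFunction) -> float:
    """Evaluate the interpolated preference weight function at utility x."""
    x = float(x)
    if not (1.0 <= x <= 9.0):
        raise DomainError(f"utility {x} outside [1, 9]")
    return float(np.interp(x, KNOT_LEVELS, pwf.knots))


def knot_basis(x) -> np.ndarray:
    """Hat-function interpolation basis: column m is d f(x) / d knot_m."""
    x = np.asarray(x, dtype=float)
    cols = []
    for m in range(5):
        unit = np.zeros(5)
        unit[m] = 1.0
        cols.append(np.interp(x, KNOT_LEVELS, unit))
    return np.stack(cols, axis=-1)


@dataclass(frozen=True)
class LambdaMix:
    """Mixing ratio between the order and relative-preference components."""

    lam: float

    def __post_init__(self):
        if not (0.0 <= self.lam <= 1.0):
            raise DomainError("lambda must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Relative-preference reindexing
# ---------------------------------------------------------------------------


def reindex_by_relative_preference(seq) -> tuple[np.ndarray, np.ndarray]:
    """Sort utilities ascending by preference rank; rank 1 = least preferred.

    Returns (sorted utilities, permutation) with the permutation mapping rank
    index -> original 0-based position. Ties are stable: the earlier position
    receives the lower rank.
    """
    x = _as_utilities(seq)
    perm = np.argsort(x, kind="stable")
    return x[perm], perm


# ---------------------------------------------------------------------------
# Fit result container
# ---------------------------------------------------------------------------


@dataclass
class LinearFit:
    """A fitted weighted-sum model with its correlation-test diagnostics."""

    weights: LinearWeights | PartitionWeights | PreferenceWeightFunction | None
    correlation: float
    predictions: np.ndarray
    targets: np.ndarray
    model: str = "linear"
    extras: dict = field(default_factory=dict)

    @property
    def mse_identity_gap(self) -> float:
        """| MSE/s_y^2 - (1 - corr^2) | for the optimally rescaled prediction."""
        mse = affine_rescaled_mse(self.predictions, self.targets)
        sy2 = float(np.var(self.targets))
        return abs(mse / sy2 - (1.0 - self.correlation**2))


def _design_and_targets(
    trials: Sequence[RatedTrial], indexing: str
) -> tuple[np.ndarray, np.ndarray]:
    lengths = {tr.sequence.t for tr in trials}
    if len(lengths) != 1:
        raise FitError("linear weight fitting requires fixed-length trials")
    rows = []
    for tr in trials:
        x = tr.sequence.utilities
        if indexing == "relative_preference":
            x, _ = reindex_by_relative_preference(x)
        rows.append(x)
    X = np.array(rows)
    y = np.array([tr.remembered_utility for tr in trials])
    return X, y


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS with intercept; returns (intercept, coefficients)."""
    A = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise FitError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta


def fit_linear_weights(
    trials: Sequence[RatedTrial], indexing: str = "order"
) -> LinearFit:
    """Fit per-position (order) or per-rank (relative-preference) weights.

    Ordinary least squares on the (re)indexed utilities; the raw regression
    weights are then divided by their sum so they sum to one. Normalization
    is a positive rescaling whenever the weight sum is positive, so the
    reported Pearson correlation is computed before normalization and is
    unchanged by it. A near-zero weight sum (|sum| < 1e-6) is reported as a
    normalization error rather than silently producing huge weights.
    """
    if indexing not in ("order", "relative_preference"):
        raise DomainError(f"unknown indexing {indexing!r}")
    X, y = _design_and_targets(trials, indexing)
    n = X.shape[1]
    if len(X) < n + 2:
        raise FitError(f"need at least {n + 2} trials to fit {n} weights")
    beta = _ols(X, y)
    raw = beta[1:]
    pred = X @ raw  # intercept dropped: correlation is shift-invariant
    corr = pearson(pred, y)
    s = raw.sum()
    if abs(s) < 1e-6:
        raise FitError("weight sum is near zero; normalization undefined")
    w = LinearWeights(raw / s, indexing)
    return LinearFit(
        weights=w,
        correlation=corr,
        predictions=pred,
        targets=y,
        model=f"linear[{indexing}]",
        extras={"raw_weights": raw, "intercept": float(beta[0])},
    )


# ---------------------------------------------------------------------------
# Combined order + relative-preference model
# ---------------------------------------------------------------------------


def combined_order_preference(seq, wo: np.ndarray, wp: np.ndarray, lam: float) -> float:
    """Prediction with weights 1/n + lam*wo(position) + (1-lam)*wp(rank).

    ``wo`` and ``wp`` are zero-mean deviation vectors taken from the
    separately fitted order and relative-preference models (partial
    optimization; the two index systems are too collinear to refit jointly).
    """
    x = _as_utilities(seq)
    wo = np.asarray(wo, dtype=float)
    wp = np.asarray(wp, dtype=float)
    if wo.size != x.size or wp.size != x.size:
        raise DomainError("deviation vectors must match the sequence length")
    xs, _ = reindex_by_relative_preference(x)
    return float(np.mean(x) + lam * (wo @ x) + (1.0 - lam) * (wp @ xs))


def fit_lambda(
    trials: Sequence[RatedTrial],
    wo: np.ndarray,
    wp: np.ndarray,
    step: float = 0.01,
) -> LinearFit:
    """Grid-search the mixing ratio lambda in [0, 1] (ties -> smallest).

    lambda = 1 reproduces the order-dependent model, lambda = 0 the
    relative-preference model; because both endpoints are on the grid, the
    combined correlation is never below either component's.
    """
    X, y = _design_and_targets(trials, "order")
    Xs = np.sort(X, axis=1, kind="stable")
    base = X.mean(axis=1)
    po = X @ np.asarray(wo, dtype=float)
    pp = Xs @ np.asarray(wp, dtype=float)
    grid = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    best_lam, best_corr, best_pred = None, -np.inf, None
    for lam in grid:
        pred = base + lam * po + (1 - lam) * pp
        if np.std(pred) == 0:
            continue
        c = pearson(pred, y)
        if c > best_corr + 1e-15:
            best_lam, best_corr, best_pred = float(lam), c, pred
    if best_lam is None:
        raise FitError("all mixture predictions are constant")
    return LinearFit(
        weights=None,
        correlation=best_corr,
        predictions=best_pred,
        targets=y,
        model="combined_order_preference",
        extras={"lambda": LambdaMix(best_lam)},
    )


# ---------------------------------------------------------------------------
# Absolute-preference models
# ---------------------------------------------------------------------------


def absolute_preference_predict(seq, pw: PartitionWeights) -> float:
    """y = sum_i (1/n + w_bin(x_i)) x_i — weights depend on the utility value.

    Permutation-invariant by construction; unlike the linear models, the
    weight sum is not constrained to one (it varies with the sequence).
    """
    x = _as_utilities(seq)
    n = x.size
    w = np.array([pw.weight_of(u) for u in x])
    return float(np.sum((1.0 / n + w) * x))


def _partition_features(X_rows: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial [mean utility, per-bin utility sums] features."""
    base = np.array([np.mean(x) for x in X_rows])
    S = np.zeros((len(X_rows), 4))
    for i, x in enumerate(X_rows):
        b = np.minimum(np.searchsorted(PARTITION_EDGES, x, side="right") - 1, 3)
        for j in range(4):
            S[i, j] = x[b == j].sum()
    return base, S


def fit_absolute_preference(trials: Sequence[RatedTrial]) -> LinearFit:
    """Fit the 4-partition absolute-preference model.

    The model is linear in the four bin weights, so the correlation-maximal
    weights follow from OLS of y on the per-bin utility sums S_b. For
    fixed-length trials the sequence mean lies in the span of the S_b
    (mean = sum_b S_b / n), making the family over-parameterized: weights w
    and w' predict identically whenever 1/n + w is proportional to 1/n + w'.
    The reported weights are the canonical representative whose deviations
    sum to zero. For variable-length trials the mean is an independent
    regressor and the weights are identified directly.
    """
    rows = [tr.sequence.utilities for tr in trials]
    y = np.array([tr.remembered_utility for tr in trials])
    base, S = _partition_features(rows)
    used = np.flatnonzero(np.ptp(S, axis=0) > 0)  # drop empty bins
    lengths = {r.size for r in rows}
    w = np.zeros(4)
    if len(lengths) == 1:
        n = lengths.pop()
        beta = _ols(S[:, used], y)
        v = beta[1:]
        a = n * v.sum() / used.size  # scale making the deviations sum to 0
        if a <= 1e-12:
            raise FitError("bin-weight sum is non-positive; the "
                           "absolute-preference family cannot represent the fit")
        w[used] = v / a - 1.0 / n
    else:
        beta = _ols(np.column_stack([base, S[:, used]]), y)
        a = beta[1]
        if a <= 1e-12:
            raise FitError("mean-utility coefficient is non-positive; the "
                           "absolute-preference family cannot represent the fit")
        w[used] = beta[2:] / a
    pw = PartitionWeights(w)
    pred = np.array([
        absolute_preference_predict(tr.sequence, pw) for tr in trials
    ])
    return LinearFit(
        weights=pw,
        correlation=pearson(pred, y),
        predictions=pred,
        targets=y,
        model="absolute_preference",
    )


@dataclass
class WindowedPreferenceFit:
    """Fitted windowed preference-dependent (WP) model for one window L."""

    L: int
    pwf: PreferenceWeightFunction | None
    correlation: float
    predictions: np.ndarray
    targets: np.ndarray

    def predict(self, seq) -> float:
        x = _as_utilities(seq)
        m = min(self.L, x.size)
        win = x[-m:]
        f = self.pwf.level_values  # noqa: F841 — force knot validation
        w = 1.0 / m + np.interp(win, KNOT_LEVELS, self.pwf.knots)
        return float(np.sum(w * win))


def fit_windowed_preference_weights(
    trials: Sequence[RatedTrial], L: int
) -> WindowedPreferenceFit:
    """Fit the 5 preference-weight knots of the WP model at window length L.

    Within the window of effective length m the prediction is
    sum (1/m + f(x_i)) x_i with f linear in its 5 knots, so the fit is OLS of
    y on [window mean, per-knot aggregated features sum_i phi_k(x_i) x_i].
    """
    if L < 1:
        raise DomainError("window length L must be >= 1")
    wins = []
    for tr in trials:
        x = tr.sequence.utilities
        wins.append(x[-min(L, x.size):])
    y = np.array([tr.remembered_utility for tr in trials])
    base = np.array([np.mean(w) for w in wins])
    B = np.array([knot_basis(w).T @ w for w in wins])  # (n_trials, 5)
    A = np.column_stack([np.ones(len(wins)), base, B])
    # collinear knot columns (e.g., a level absent from every window) are
    # dropped rather than failing the whole fit
    keep = [0, 1]
    for j in range(2, A.shape[1]):
        if np.linalg.matrix_rank(A[:, keep + [j]]) == len(keep) + 1:
            keep.append(j)
    beta, *_ = np.linalg.lstsq(A[:, keep], y, rcond=None)
    fitted = A[:, keep] @ beta
    corr = pearson(fitted, y) if np.std(fitted) > 0 else 0.0

    a = beta[1]
    pwf = None
    if a > 1e-12:
        knots = np.zeros(5)
        for pos, j in enumerate(keep[2:], start=2):
            knots[j - 2] = beta[pos] / a
        pwf = PreferenceWeightFunction(knots)
        pred = base + B @ knots
    else:
        pred = fitted  # correlation-equivalent; knots not representable
    return WindowedPreferenceFit(
        L=L, pwf=pwf, correlation=corr, predictions=pred, targets=y
    )
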