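"""Temporal-discounting evaluation models and their combination.

The simple discounting (SD) model aggregates a sequence as
y_SD(t) = sum_k r^(t-k) x_k: a geometric down-weighting of past moments by a
single forgetting rate r in [0, 1], reducing to the End estimator at r = 0
(with the convention 0^0 = 1) and to (t times) the Average estimator at
r = 1. The preference-dependent discounting (PD) model lets the rate depend
on the moment's own utility, y_PD(t) = sum_k r(x_k)^(t-k) x_k, so a highly
preferred moment far in the past can retain weight that a recent mediocre
one loses — the "extreme peak" effect a fixed evaluation window cannot
express. r(x) is parameterized by 5 free knot values interpolated over the
17 rating levels.

Both models are fitted by minimizing the SSE between the remembered
utilities and an affinely rescaled prediction a*y + b (equivalent to
maximizing the Pearson correlation); a and b have closed forms by simple
linear regression, and the free rates follow by projected gradient descent.

The PD sum can equivalently be evaluated as a small recurrent network with
one leaky accumulator per distinct preference level
(h_{i,t} = r_i h_{i,t-1} + g_{i,t}, y_t = sum_i x_i h_{i,t}); that second
evaluation path exists purely as an equivalence check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import DomainError, RatedTrial, _as_utilities
from .linear_models import KNOT_LEVELS, WindowedPreferenceFit
from .stats import optimal_affine, pearson


class OptimizerError(RuntimeError):
    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = trace or []


@dataclass(frozen=True)
class DiscountParams:
    """Fitted discounting parameters: the rate(s) plus the affine rescale."""

    model: str  # "SD" | "PD"
    r: np.ndarray  # shape () for SD, (5,) knot values for PD
    a: float = 1.0
    b: float = 0.0

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        if self.model == "SD":
            r = r.reshape(())
        elif self.model == "PD":
            if r.shape != (5,):
                raise DomainError("PD requires 5 free knot rates")
        else:
            raise DomainError(f"unknown discounting model {self.model!r}")
        if np.any(r < 0.0) or np.any(r > 1.0):
            raise DomainError("discount rates must lie in [0, 1]")
        object.__setattr__(self, "r", r)

    def rate_of(self, x) -> np.ndarray:
        """r(x): constant for SD, interpolated over the knots for PD."""
        if self.model == "SD":
            return np.broadcast_to(self.r, np.shape(x)).astype(float)
        return np.interp(np.asarray(x, dtype=float), KNOT_LEVELS, self.r)


def sd_total_utility(seq, r: float) -> float:
    """Simple discounted total utility, sum_k r^(t-k) x_k (0^0 = 1)."""
    if not (0.0 <= r <= 1.0):
        raise DomainError("discount rate r must lie in [0, 1]")
    x = _as_utilities(seq)
    exps = np.arange(x.size - 1, -1, -1, dtype=float)
    return float(np.sum(np.power(r, exps) * x))


def pd_total_utility(seq, params: DiscountParams) -> float:
    """Preference-dependent discounted total utility, sum_k r(x_k)^(t-k) x_k."""
    x = _as_utilities(seq)
    rates = params.rate_of(x)
    if np.any(rates < 0.0) or np.any(rates > 1.0):
        raise DomainError("interpolated rates must lie in [0, 1]")
    exps = np.arange(x.size - 1, -1, -1, dtype=float)
    return float(np.sum(np.power(rates, exps) * x))


def pd_total_utility_recurrent(seq, params: DiscountParams) -> float:
    """Evaluate the PD sum through its recurrent hidden-state form.

    One accumulator per distinct utility value: h_i <- r(x_i) h_i + [x_t = x_i],
    read out as y = sum_i x_i h_i after the last step. Exists as an
    independent evaluation path for the equivalence test; it is not trained.
    """
    x = _as_utilities(seq)
    values = np.unique(x)
    rates = params.rate_of(values)
    h = np.zeros(values.size)
    for xt in x:
        h = rates * h + (values == xt)
    return float(np.sum(values * h))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class DiscountFit:
    """A fitted discounting model with its optimizer diagnostics."""

    params: DiscountParams
    correlation: float
    sse: float
    predictions: np.ndarray  # a * raw + b
    raw: np.ndarray
    targets: np.ndarray
    n_iter: int
    converged: bool
    trace: list = field(default_factory=list)
    a_negative_optimum: bool = False

    def predict_raw(self, seq) -> float:
        if self.params.model == "SD":
            return sd_total_utility(seq, float(self.params.r))
        return pd_total_utility(seq, self.params)

    def predict(self, seq) -> float:
        return self.params.a * self.predict_raw(seq) + self.params.b


def _pad_trials(trials: Sequence[RatedTrial]):
    n = len(trials)
    T = max(tr.sequence.t for tr in trials)
    X = np.zeros((n, T))
    mask = np.zeros((n, T))
    E = np.zeros((n, T))
    for i, tr in enumerate(trials):
        x = tr.sequence.utilities
        t = x.size
        X[i, :t] = x
        mask[i, :t] = 1.0
        E[i, :t] = np.arange(t - 1, -1, -1)
    y = np.array([tr.remembered_utility for tr in trials])
    return X, mask, E, y


def _raw_and_grad(X, mask, E, theta, model):
    """Raw model outputs and their gradient w.r.t. the free rates."""
    if model == "SD":
        r = float(theta)
        W = np.power(r, E) * mask
        u = np.sum(W * X, axis=1)
        dW = np.where(E > 0, E * np.power(r, np.maximum(E - 1, 0)), 0.0) * mask
        grad = np.sum(dW * X, axis=1)[:, None]  # (n, 1)
        return u, grad
    R = np.interp(X, KNOT_LEVELS, theta)
    W = np.power(R, E) * mask
    u = np.sum(W * X, axis=1)
    dR = np.where(E > 0, E * np.power(R, np.maximum(E - 1, 0)), 0.0) * mask
    # hat basis of each padded entry w.r.t. the 5 knots
    grad = np.empty((X.shape[0], 5))
    for m in range(5):
        unit = np.zeros(5)
        unit[m] = 1.0
        phi = np.interp(X, KNOT_LEVELS, unit)
        grad[:, m] = np.sum(dR * phi * X, axis=1)
    return u, grad


def _sse_at(u, y):
    a, b = optimal_affine(u, y)
    neg = a < 0
    resid = y - (a * u + b)
    return float(np.sum(resid**2)), a, b, resid, neg


def fit_discounting(
    trials: Sequence[RatedTrial],
    model: str = "SD",
    learning_rate: float = 1e-4,
    max_iter: int = 50_000,
    tol: float = 1e-8,
    init: np.ndarray | float | None = None,
    min_trials: int = 30,
    record_trace: bool = False,
) -> DiscountFit:
    """Fit the SD rate or the 5 PD knot rates by projected gradient descent.

    Each step holds the closed-form affine rescale (a, b) fixed, takes a
    gradient step on the rate(s), projects back into [0, 1], and re-derives
    (a, b); the step is accepted only if the SSE does not increase, with the
    step size adapted multiplicatively (x1.1 on acceptance, x0.5 on
    rejection) starting from ``learning_rate``. The accepted-step SSE trace
    is therefore non-increasing by construction. Convergence is declared
    when the relative SSE improvement of an accepted step falls below
    ``tol``; 200 consecutive rejected steps raise :class:`OptimizerError`
    with the trace.

    For PD, unless ``init`` is given, the knots start at the fitted SD rate,
    so the PD correlation can never end below the SD correlation (nesting).
    """
    trials = list(trials)
    if len(trials) < min_trials:
        raise DomainError(f"need at least {min_trials} trials")
    X, mask, E, y = _pad_trials(trials)

    if model == "SD":
        theta = np.atleast_1d(0.5 if init is None else float(init)).astype(float)
    elif model == "PD":
        if init is None:
            sd = fit_discounting(
                trials, "SD", learning_rate, max_iter, tol,
                min_trials=min_trials,
            )
            theta = np.full(5, float(sd.params.r))
        else:
            theta = np.asarray(init, dtype=float).copy()
            if theta.shape != (5,):
                raise DomainError("PD init requires 5 knot values")
    else:
        raise DomainError(f"unknown discounting model {model!r}")
    if np.any(theta < 0) or np.any(theta > 1):
        raise DomainError("initial rates must lie in [0, 1]")

    u, grad = _raw_and_grad(X, mask, E, theta if model == "PD" else theta[0], model)
    sse, a, b, resid, neg = _sse_at(u, y)
    any_neg_a = neg
    step = learning_rate
    trace = [(0, sse, theta.copy())] if record_trace else []
    n_iter = 0
    converged = False
    rejects = 0
    for n_iter in range(1, max_iter + 1):
        g = -2.0 * a * (grad.T @ resid)  # dSSE/dtheta at fixed (a, b)
        theta_new = np.clip(theta - step * g, 0.0, 1.0)
        u_new, grad_new = _raw_and_grad(
            X, mask, E, theta_new if model == "PD" else theta_new[0], model
        )
        sse_new, a_new, b_new, resid_new, neg = _sse_at(u_new, y)
        if sse_new <= sse:
            improvement = (sse - sse_new) / max(sse, 1e-300)
            theta, u, grad = theta_new, u_new, grad_new
            sse, a, b, resid = sse_new, a_new, b_new, resid_new
            any_neg_a = any_neg_a or neg
            step *= 1.1
            rejects = 0
            if record_trace:
                trace.append((n_iter, sse, theta.copy()))
            if improvement < tol:
                converged = True
                break
        else:
            step *= 0.5
            rejects += 1
            if rejects >= 200:
                raise OptimizerError(
                    "gradient descent failed to find a descent step "
                    "200 times in a row", trace=trace,
                )
            if step < 1e-16:
                converged = True
                break

    params = DiscountParams(
        model=model,
        r=theta[0] if model == "SD" else theta,
        a=float(a),
        b=float(b),
    )
    pred = a * u + b
    corr = pearson(u, y) if np.std(u) > 0 else 0.0
    return DiscountFit(
        params=params,
        correlation=corr,
        sse=sse,
        predictions=pred,
        raw=u,
        targets=y,
        n_iter=n_iter,
        converged=converged,
        trace=trace,
        a_negative_optimum=bool(any_neg_a),
    )


# ---------------------------------------------------------------------------
# Combined WP-PD model
# ---------------------------------------------------------------------------


@dataclass
class WPPDMix:
    """lambda-weighted mixture of the WP and PD models.

    Component predictions are z-scored with the fitting-set moments before
    mixing (both components are scale-free under the correlation criterion;
    mixing raw outputs of different scales would make lambda
    uninterpretable). lambda = 1 reproduces the WP prediction and lambda = 0
    the PD prediction, each up to that positive affine standardization.
    """

    lam: float
    wp: WindowedPreferenceFit
    pd: DiscountFit
    wp_moments: tuple[float, float] = (0.0, 1.0)
    pd_moments: tuple[float, float] = (0.0, 1.0)
    correlation: float = float("nan")

    def __post_init__(self):
        if not (0.0 <= self.lam <= 1.0):
            raise DomainError("lambda must lie in [0, 1]")

    def predict(self, seq) -> float:
        if self.wp is None or self.pd is None:
            raise RuntimeError("both component models must be fitted")
        zw = (self.wp.predict(seq) - self.wp_moments[0]) / self.wp_moments[1]
        zp = (self.pd.predict_raw(seq) - self.pd_moments[0]) / self.pd_moments[1]
        return float(self.lam * zw + (1.0 - self.lam) * zp)


def combined_wp_pd(seq, mix: WPPDMix) -> float:
    """Evaluate the combined WP-PD model on one sequence."""
    return mix.predict(seq)


def fit_wp_pd_mix(
    trials: Sequence[RatedTrial],
    wp_fit: WindowedPreferenceFit,
    pd_fit: DiscountFit,
    step: float = 0.01,
) -> WPPDMix:
    """Grid-search lambda in [0, 1] maximizing the mixture correlation.

    Both component fits must come from the same trial list (their stored
    prediction vectors are reused aligned). Ties prefer the larger lambda,
    matching the dominance of the windowed component in practice.
    """
    y = np.array([tr.remembered_utility for tr in trials])
    pw = np.asarray(wp_fit.predictions, dtype=float)
    pp = np.asarray(pd_fit.raw, dtype=float)
    if pw.size != y.size or pp.size != y.size:
        raise DomainError("component fits must align with the trial list")
    mw = (float(np.mean(pw)), float(np.std(pw)) or 1.0)
    mp = (float(np.mean(pp)), float(np.std(pp)) or 1.0)
    zw = (pw - mw[0]) / mw[1]
    zp = (pp - mp[0]) / mp[1]
    lams = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    corrs = []
    for lam in lams:
        pred = lam * zw + (1 - lam) * zp
        corrs.append(pearson(pred, y) if np.std(pred) > 0 else -np.inf)
    corrs = np.array(corrs)
    if not np.isfinite(corrs).any():
        raise OptimizerError("all mixture predictions are constant")
    # ties (within 1e-12) resolved toward the larger lambda
    best = np.flatnonzero(corrs >= corrs.max() - 1e-12)[-1]
    return WPPDMix(
        lam=float(lams[best]),
        wp=wp_fit,
        pd=pd_fit,
        wp_moments=mw,
        pd_moments=mp,
        correlation=float(corrs[best]),
    )


def split_lambda_groups(lambdas, cut: float = 0.9) -> tuple[list, list]:
    """Split participants by mixing ratio: group 1 has lambda > cut.

    Group 1 participants rely almost entirely on the windowed
    preference-dependent component; group 2 (lambda <= cut) genuinely mixes
    in the discounting component.
    """
    g1, g2 = [], []
    for i, lam in enumerate(lambdas):
        (g1 if lam > cut else g2).append(i)
    return g1, g2
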