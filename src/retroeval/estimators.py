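"""Parameter-free sequence estimators, windowed variants, and window selection.

The four basic estimators of a sequence's total utility are Peak (maximum
moment utility), End (last moment utility), Peak-End (their mean — the
classical peak-end rule), and Average (mean of the whole sequence). Windowed
variants apply a base estimator to only the last ``L`` moments, modelling a
finite evaluation window; ``L`` is selected per participant by maximizing the
leave-one-trial-out mean correlation with the remembered utilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from .core import DomainError, RatedTrial, _as_utilities

WINDOWED_ESTIMATORS = ("peak_end", "average", "preference_dependent")


def peak(seq) -> float:
    """Maximum moment utility; tie positions are irrelevant (value only)."""
    return float(np.max(_as_utilities(seq)))


def end(seq) -> float:
    """Last moment utility."""
    return float(_as_utilities(seq)[-1])


def peak_end(seq) -> float:
    """Mean of the peak and end utilities (the peak-end rule)."""
    x = _as_utilities(seq)
    return float((np.max(x) + x[-1]) / 2.0)


def average(seq) -> float:
    """Arithmetic mean of all moment utilities."""
    return float(np.mean(_as_utilities(seq)))


@dataclass
class WindowSpec:
    """A selected evaluation window and its selection diagnostics.

    ``diagnostics`` holds one dict per candidate k: the usable sample count,
    jackknife mean correlation, whether the candidate was skipped (too few
    samples) or discarded (not significant), and its final significance count.
    """

    L: int
    estimator: str = "average"
    diagnostics: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if self.L < 1:
            raise DomainError("window length L must be >= 1")
        if self.estimator not in WINDOWED_ESTIMATORS:
            raise DomainError(f"unknown windowed estimator {self.estimator!r}")


def windowed(seq, spec: WindowSpec, pref_weights: Callable[[float], float] | None = None) -> float:
    """Apply ``spec.estimator`` to the suffix of length min(L, t).

    The preference-dependent variant computes sum_i (1/m + f(x_i)) x_i over
    the window of effective length m, with ``pref_weights`` the preference
    weight function f.
    """
    x = _as_utilities(seq)
    m = min(spec.L, x.size)
    win = x[-m:]
    if spec.estimator == "average":
        return float(np.mean(win))
    if spec.estimator == "peak_end":
        return float((np.max(win) + win[-1]) / 2.0)
    if pref_weights is None:
        raise DomainError("preference_dependent window requires pref_weights")
    w = 1.0 / m + np.array([pref_weights(u) for u in win])
    return float(np.sum(w * win))


def _critical_r(n: int, alpha: float) -> float:
    """Two-sided critical Pearson r for p < alpha at sample size n."""
    if n < 3:
        return 1.0
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(np.sqrt(tcrit**2 / (tcrit**2 + n - 2)))


def _jackknife_correlations(pred: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-trial-out Pearson correlations (one per removed trial)."""
    n = y.size
    out = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        p, t = pred[keep], y[keep]
        if np.std(p) == 0 or np.std(t) == 0:
            out[i] = 0.0
        else:
            out[i] = np.corrcoef(p, t)[0, 1]
    return out


def _window_predictions(
    trials: Sequence[RatedTrial], k: int, estimator: str
) -> np.ndarray:
    """Predictions for all trials with a window of length k.

    For the preference-dependent estimator, the 5-knot preference weight
    function is refit (OLS) on the given trials for this candidate k.
    """
    if estimator in ("average", "peak_end"):
        spec = WindowSpec(L=k, estimator=estimator)
        return np.array([windowed(tr.sequence, spec) for tr in trials])
    from .linear_models import fit_windowed_preference_weights

    fit = fit_windowed_preference_weights(trials, L=k)
    return fit.predictions


class WindowSelectionError(RuntimeError):
    """No window size survives the sample-count and significance filters."""

    def __init__(self, msg, diagnostics=None):
        super().__init__(msg)
        self.diagnostics = diagnostics or []


def select_window_size(
    trials: Sequence[RatedTrial],
    estimator: str = "average",
    min_samples: int = 30,
    alpha: float = 0.05,
    max_k: int | None = None,
) -> WindowSpec:
    """Select the evaluation-window length for one participant's trials.

    For each candidate k the estimator is applied with window k to every
    trial of length >= k; trials shorter than the window are not usable (the
    preference-dependent variant needs them for its regression, and the other
    estimators skip the same cases for fair comparison). Candidates with
    fewer than ``min_samples`` usable trials are skipped. The correlation for
    a candidate is the mean of its leave-one-trial-out (jackknife) Pearson
    correlations with the remembered utilities; candidates whose mean falls
    below the two-sided critical r for p < ``alpha`` are discarded. Among the
    survivors, the winner is the candidate whose jackknife correlations are
    significantly (paired one-sided t-test, p < ``alpha``) greater than those
    of the largest number of other candidates; ties go to the smallest k.
    """
    if estimator not in WINDOWED_ESTIMATORS:
        raise DomainError(f"unknown windowed estimator {estimator!r}")
    trials = list(trials)
    y_all = np.array([tr.remembered_utility for tr in trials])
    lengths = np.array([tr.sequence.t for tr in trials])
    if max_k is None:
        max_k = int(lengths.max())

    diags = []
    jack: dict[int, np.ndarray] = {}
    usable_idx: dict[int, np.ndarray] = {}
    for k in range(1, max_k + 1):
        mask = lengths >= k
        n = int(mask.sum())
        d = {"k": k, "n": n, "mean_corr": np.nan, "skipped": False,
             "significant": False, "sig_count": 0}
        if n < min_samples:
            d["skipped"] = True
            diags.append(d)
            continue
        sub = [tr for tr, m in zip(trials, mask) if m]
        pred = _window_predictions(sub, k, estimator)
        jk = _jackknife_correlations(pred, y_all[mask])
        mean_corr = float(np.mean(jk))
        d["mean_corr"] = mean_corr
        d["significant"] = mean_corr >= _critical_r(n, alpha)
        if d["significant"]:
            jack[k] = jk
            usable_idx[k] = np.flatnonzero(mask)
        diags.append(d)

    if not jack:
        raise WindowSelectionError(
            "no window size passed the sample-count and significance filters",
            diagnostics=diags,
        )

    # significance counts: k beats j when the paired jackknife correlations
    # (over trials usable for both) are greater with p < alpha, one-sided
    counts = {}
    ks = sorted(jack)
    for k in ks:
        count = 0
        for j in ks:
            if j == k:
                continue
            common = np.intersect1d(usable_idx[k], usable_idx[j])
            if common.size < 3:
                continue
            ak = jack[k][np.searchsorted(usable_idx[k], common)]
            aj = jack[j][np.searchsorted(usable_idx[j], common)]
            diff = ak - aj
            if np.allclose(np.std(diff), 0.0):
                continue
            tstat, p_two = sps.ttest_rel(ak, aj)
            p_one = p_two / 2.0 if tstat > 0 else 1.0 - p_two / 2.0
            if p_one < alpha:
                count += 1
        counts[k] = count
        diags[k - 1]["sig_count"] = count

    best = max(counts.values())
    L = min(k for k, c in counts.items() if c == best)
    return WindowSpec(L=L, estimator=estimator, diagnostics=diags)
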