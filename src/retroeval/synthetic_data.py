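"""Synthetic participants for the picture-rating and sequence-rating tasks.

No public dataset exists for these tasks, so every fitting procedure in the
package is validated by parameter recovery on data generated here. A
synthetic participant consists of:

* a pool of pictures with two integer session ratings (1-9) whose
  across-pool correlation is calibrated to the observed test-retest
  reliability (~0.75), averaged onto the half-point grid and split into the
  seven preference partitions;
* 96 fixed-length (4-picture) rating trials spread over seven sequence
  types (increasing, decreasing, zigzag, peak position 1-4), and 36
  7-picture trials over the peak types;
* five "continued" 100-picture sessions with a running evaluation queried
  every 8-13 pictures (10 queries per session, the last always at 100);
* remembered utilities produced by a configurable ground-truth evaluator
  plus Gaussian rating noise, clipped to [1, 9] and (by default) rounded to
  the integer response grid;
* working-memory position probes whose per-preference-group accuracy
  follows a configurable profile within the empirically observed 0.55-0.95
  band.

Everything is a deterministic function of the configuration and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .core import (
    DomainError,
    MomentSequence,
    PictureRecord,
    RatedTrial,
    WMRecord,
    assign_partitions,
)
from .discounting import DiscountParams, pd_total_utility, sd_total_utility
from .linear_models import KNOT_LEVELS


class ConfigError(ValueError):
    """A generator configuration value is out of its legal range."""


#: Trial counts mirroring the task designs: 96 four-picture trials over the
#: seven sequence types, 36 seven-picture trials over the peak types, and
#: five continued sessions of 100 pictures with 10 queries each.
SEQ4_TYPES = ("increasing", "decreasing", "zigzag", "peak1", "peak2", "peak3", "peak4")
SEQ7_TYPES = ("peak1", "peak2", "peak3", "peak4")


@dataclass(frozen=True)
class TaskPlan:
    n_seq4: int = 96
    n_seq7: int = 36
    n_sessions: int = 5
    session_length: int = 100
    queries_per_session: int = 10
    interval_min: int = 8
    interval_max: int = 13

    def __post_init__(self):
        lo, hi = self.interval_min, self.interval_max
        q, L = self.queries_per_session, self.session_length
        if not (q * lo <= L <= q * hi):
            raise ConfigError(
                f"{q} intervals in [{lo}, {hi}] cannot sum to {L}"
            )


@dataclass(frozen=True)
class GroundTruth:
    """A ground-truth evaluator: model family plus its parameters.

    Every evaluator is used in *scaled* (weighted-mean) form, dividing the
    weighted sum by its weight sum, which maps any sequence into [1, 9]
    exactly and is the identity for the mean-type estimators. The scaling is
    a positive per-length affine map, so fits of the same family recover the
    generating parameters up to the affine rescale they optimize anyway.
    """

    model: str = "windowed_preference"
    L: int = 10
    knots: tuple = (-0.05, -0.02, 0.0, 0.03, 0.08)
    r: float = 0.7
    lam: float = 1.0
    order_weights: tuple | None = None

    def scaled(self, seq) -> float:
        x = np.asarray(
            seq.utilities if isinstance(seq, MomentSequence) else seq, dtype=float
        )
        m = self.model
        if m == "average":
            return float(np.mean(x))
        if m == "end":
            return float(x[-1])
        if m == "peak":
            return float(np.max(x))
        if m == "peak_end":
            return float((np.max(x) + x[-1]) / 2)
        if m == "windowed_average":
            return float(np.mean(x[-min(self.L, x.size):]))
        if m == "windowed_peak_end":
            w = x[-min(self.L, x.size):]
            return float((np.max(w) + w[-1]) / 2)
        if m == "windowed_preference":
            win = x[-min(self.L, x.size):]
            w = 1.0 / win.size + np.interp(win, KNOT_LEVELS, self.knots)
            if np.any(w <= 0):
                raise ConfigError("preference weights must stay positive")
            return float(np.sum(w * win) / np.sum(w))
        if m == "order_weights":
            w = np.asarray(self.order_weights, dtype=float)
            if w.size != x.size or np.any(w < 0):
                raise ConfigError("order_weights must be nonnegative, length t")
            return float(np.sum(w * x) / np.sum(w))
        if m == "sd":
            e = np.arange(x.size - 1, -1, -1, dtype=float)
            w = np.power(self.r, e)
            return float(np.sum(w * x) / np.sum(w))
        if m == "pd":
            rates = self._pd_params().rate_of(x)
            e = np.arange(x.size - 1, -1, -1, dtype=float)
            w = np.power(rates, e)
            return float(np.sum(w * x) / np.sum(w))
        if m == "wp_pd":
            wp = replace(self, model="windowed_preference",
                         knots=(-0.05, -0.02, 0.0, 0.03, 0.08))
            pd = replace(self, model="pd")
            return float(
                self.lam * wp.scaled(x) + (1 - self.lam) * pd.scaled(x)
            )
        raise ConfigError(f"unknown ground-truth model {m!r}")

    def _pd_params(self) -> DiscountParams:
        return DiscountParams("PD", np.asarray(self.knots, dtype=float))

    @property
    def batch_calibrated(self) -> bool:
        """Discounting ground truths are affine-mapped per trial batch.

        Their raw sums have no fixed per-sequence range, so the affine map
        onto [1, 9] is calibrated on the output range over a whole task's
        trials — which keeps the generated data affine-equivalent to the raw
        model that the fitting procedures optimize.
        """
        return self.model in ("sd", "pd")

    def raw(self, seq) -> float:
        """Unnormalized discounted sum (sd/pd models only)."""
        x = np.asarray(
            seq.utilities if isinstance(seq, MomentSequence) else seq, dtype=float
        )
        if self.model == "sd":
            return sd_total_utility(x, self.r)
        if self.model == "pd":
            return pd_total_utility(x, self._pd_params())
        raise ConfigError(f"{self.model!r} has no raw (unnormalized) form")


@dataclass(frozen=True)
class ParticipantConfig:
    seed: int = 0
    n_pictures: int = 500
    test_retest_corr: float = 0.75
    familiar_fraction: float = 0.05
    ground_truth: GroundTruth = field(default_factory=GroundTruth)
    rating_noise_sd: float = 0.5
    wm_accuracy_profile4: tuple = (0.9, 0.8, 0.6, 0.7)
    wm_accuracy_profile7: tuple = (0.9, 0.85, 0.8, 0.7, 0.65, 0.6, 0.7)
    discretize: bool = True
    plan: TaskPlan = field(default_factory=TaskPlan)

    def __post_init__(self):
        if not (0.0 < self.test_retest_corr <= 1.0):
            raise ConfigError("test_retest_corr must lie in (0, 1]")
        if self.rating_noise_sd < 0:
            raise ConfigError("rating_noise_sd must be nonnegative")
        if not (0.0 <= self.familiar_fraction < 1.0):
            raise ConfigError("familiar_fraction must lie in [0, 1)")


# ---------------------------------------------------------------------------
# Picture pool
# ---------------------------------------------------------------------------


def sample_picture_pool(config: ParticipantConfig, rng=None) -> list[PictureRecord]:
    """Draw the per-participant picture pool with calibrated reliability.

    A latent true preference per picture (uniform on [1, 9]) plus
    independent integer-rounded Gaussian session noise; the noise variance
    is solved from the target test-retest correlation with a 1/12 correction
    for the rounding noise. ``test_retest_corr = 1`` gives day1 = day2
    exactly.
    """
    if config.n_pictures < 50:
        raise ConfigError("need n_pictures >= 50")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    latent = rng.uniform(1.0, 9.0, size=config.n_pictures)
    rho = config.test_retest_corr
    if rho >= 1.0:
        sd = 0.0
    else:
        v = np.var(latent)
        sd = float(np.sqrt(max(v * (1.0 / rho - 1.0) - 1.0 / 12.0, 0.0)))
    day = []
    for _ in range(2):
        noisy = latent + rng.normal(0.0, sd, size=latent.size)
        day.append(np.clip(np.rint(noisy), 1, 9).astype(int))
    familiar = rng.random(config.n_pictures) < config.familiar_fraction
    pool = [
        PictureRecord(f"pic{i:04d}", int(day[0][i]), int(day[1][i]), bool(familiar[i]))
        for i in range(config.n_pictures)
    ]
    return assign_partitions(pool)


def _partition_ratings(pool: Sequence[PictureRecord]) -> dict[int, np.ndarray]:
    out: dict[int, list[float]] = {p: [] for p in range(1, 8)}
    for pic in pool:
        if not pic.familiar and pic.partition:
            out[pic.partition].append(pic.rating)
    return {p: np.array(v) for p, v in out.items() if len(v) > 0}


def partition_lookup(pool: Sequence[PictureRecord]) -> Callable[[float], int]:
    """Map a rating value to its partition (1-7) for this pool."""
    pairs = sorted(
        {(pic.rating, pic.partition) for pic in pool if not pic.familiar}
    )
    ratings = np.array([r for r, _ in pairs])
    parts = np.array([p for _, p in pairs])

    def lookup(x: float) -> int:
        i = int(np.clip(np.searchsorted(ratings, x), 0, ratings.size - 1))
        if i > 0 and abs(ratings[i - 1] - x) < abs(ratings[i] - x):
            i -= 1
        return int(parts[i])

    return lookup


# ---------------------------------------------------------------------------
# Sequence construction
# ---------------------------------------------------------------------------

#: Ascending preference tiers used for fixed-length sequences: the four
#: full-interval partitions for length 4, all seven for length 7.
_TIERS = {4: (1, 3, 5, 7), 7: (1, 2, 3, 4, 5, 6, 7)}


def make_sequence(
    seq_type: str,
    length: int,
    partitions: dict[int, np.ndarray],
    rng,
) -> MomentSequence:
    """Construct one fixed-length sequence of a given type.

    increasing/decreasing draw pictures across the whole pool and sort them
    (so utilities are monotone while the overall level still varies from
    trial to trial); zigzag alternates draws between a high (>= partition 5)
    and a low (<= partition 3) partition with random starting direction;
    peak-k places a top-partition picture at position k with the remaining
    pictures drawn from one single lower partition, so the non-peak
    utilities have similar preference values and the peak is the unique
    maximum.
    """
    if length not in _TIERS:
        raise DomainError("fixed-length sequences have length 4 or 7")
    tiers = [p for p in _TIERS[length] if p in partitions]
    if len(tiers) < len(_TIERS[length]):
        raise DomainError("partition map is missing populated partitions")

    def draw(part: int) -> float:
        return float(rng.choice(partitions[part]))

    if seq_type in ("increasing", "decreasing"):
        all_ratings = np.concatenate([partitions[p] for p in partitions])
        vals = np.sort(rng.choice(all_ratings, size=length, replace=False))
        return MomentSequence(vals if seq_type == "increasing" else vals[::-1])
    if seq_type == "zigzag":
        hi = int(rng.choice([p for p in (5, 6, 7) if p in partitions]))
        lo = int(rng.choice([p for p in (1, 2, 3) if p in partitions]))
        start_high = bool(rng.integers(0, 2))
        vals = []
        for i in range(length):
            high = (i % 2 == 0) == start_high
            vals.append(draw(hi if high else lo))
        return MomentSequence(vals)
    if seq_type.startswith("peak"):
        k = int(seq_type[4:])
        if not (1 <= k <= length):
            raise DomainError(f"peak position {k} outside 1..{length}")
        low_parts = [p for p in (1, 2, 3, 4, 5) if p in partitions]
        base = int(rng.choice(low_parts))
        vals = [draw(base) for _ in range(length)]
        vals[k - 1] = draw(7)
        return MomentSequence(vals)
    raise DomainError(f"unknown sequence type {seq_type!r}")


def make_continued_sessions(
    pool: Sequence[PictureRecord],
    rng,
    plan: TaskPlan = TaskPlan(),
) -> list[tuple[MomentSequence, list[int]]]:
    """Build the continued-version sessions: 100 pictures, 10 query points.

    Query intervals are drawn uniformly from {8..13}; the final interval is
    whatever makes the positions sum to exactly 100 and the draw is repeated
    until it also lands in [8, 13], so the last query is always at position
    100 and the first at position >= 8.
    """
    ratings = np.array(
        [pic.rating for pic in pool if not pic.familiar]
    )
    if ratings.size < plan.session_length:
        raise ConfigError("picture pool exhausted for a continued session")
    sessions = []
    q, lo, hi = plan.queries_per_session, plan.interval_min, plan.interval_max
    for _ in range(plan.n_sessions):
        while True:
            intervals = rng.integers(lo, hi + 1, size=q)
            intervals[-1] = plan.session_length - int(intervals[:-1].sum())
            if lo <= intervals[-1] <= hi:
                break
        positions = np.cumsum(intervals).tolist()
        seq = rng.choice(ratings, size=plan.session_length, replace=False)
        sessions.append((MomentSequence(seq), positions))
    return sessions


# ---------------------------------------------------------------------------
# Remembered utilities and WM responses
# ---------------------------------------------------------------------------


def simulate_remembered_utility(
    seq,
    ground_truth: GroundTruth,
    noise_sd: float,
    rng,
    discretize: bool = True,
) -> float:
    """One remembered utility: scaled evaluator output + Gaussian noise.

    The evaluator's weighted-mean scaling places its output in [1, 9]; noise
    is added on the rating scale, the result clipped to [1, 9] and, when
    ``discretize`` is set, rounded to the integer grid the participants
    responded on.
    """
    if noise_sd < 0:
        raise ConfigError("noise_sd must be nonnegative")
    val = ground_truth.scaled(seq)
    val = float(np.clip(val + rng.normal(0.0, noise_sd) if noise_sd > 0 else val,
                        1.0, 9.0))
    if discretize:
        val = float(np.clip(np.rint(val), 1, 9))
    return val


def simulate_remembered_utilities(
    seqs: Sequence,
    ground_truth: GroundTruth,
    noise_sd: float,
    rng,
    discretize: bool = True,
) -> list[float]:
    """Remembered utilities for a batch of sequences from one task.

    Mean-type evaluators are rated one sequence at a time (their scaled
    output is already on [1, 9]); discounting evaluators are first affine
    calibrated so the batch output range maps onto [1, 9], then noised,
    clipped and optionally discretized like the per-sequence path.
    """
    if not ground_truth.batch_calibrated:
        return [
            simulate_remembered_utility(s, ground_truth, noise_sd, rng, discretize)
            for s in seqs
        ]
    if noise_sd < 0:
        raise ConfigError("noise_sd must be nonnegative")
    raw = np.array([ground_truth.raw(s) for s in seqs])
    lo, hi = raw.min(), raw.max()
    vals = 1.0 + 8.0 * (raw - lo) / (hi - lo) if hi > lo else np.full_like(raw, 5.0)
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, size=vals.size)
    vals = np.clip(vals, 1.0, 9.0)
    if discretize:
        vals = np.clip(np.rint(vals), 1, 9)
    return [float(v) for v in vals]


def simulate_wm_responses(
    trials: Sequence[RatedTrial],
    profile: Sequence[float],
    partition_of: Callable[[float], int],
    rng,
) -> list[WMRecord]:
    """One position probe per trial with preference-dependent accuracy.

    The probed picture is chosen uniformly within the trial; with
    probability ``profile[g-1]`` (g = the picture's preference group) the
    answer is the true position, otherwise uniform over the other positions.
    A 4-entry profile addresses the four full-interval groups (half-interval
    partitions map to the nearest full group); a 7-entry profile addresses
    all seven partitions.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.size not in (4, 7):
        raise ConfigError("profile must have 4 or 7 accuracies")
    if np.any(profile < 0) or np.any(profile > 1):
        raise ConfigError("profile entries must lie in [0, 1]")
    records = []
    for tr in trials:
        x = tr.sequence.utilities
        t = x.size
        pos = int(rng.integers(1, t + 1))
        part = partition_of(float(x[pos - 1]))
        group = (part + 1) // 2 if profile.size == 4 else part
        if rng.random() < profile[group - 1]:
            answer = pos
        else:
            others = [p for p in range(1, t + 1) if p != pos]
            answer = int(rng.choice(others))
        records.append(
            WMRecord(
                queried_utility=float(x[pos - 1]),
                preference_group=group,
                true_position=pos,
                answered_position=answer,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Whole-participant generation
# ---------------------------------------------------------------------------


@dataclass
class ParticipantData:
    config: ParticipantConfig
    pool: list[PictureRecord]
    seq4: list[RatedTrial]
    seq7: list[RatedTrial]
    continued: list[RatedTrial]
    wm4: list[WMRecord]
    wm7: list[WMRecord]


def generate_participant(
    config: ParticipantConfig, participant_id: str = "p0"
) -> ParticipantData:
    """Generate one complete synthetic participant, deterministic in config."""
    rng = np.random.default_rng(config.seed)
    pool = sample_picture_pool(config, rng)
    parts = _partition_ratings(pool)
    lookup = partition_lookup(pool)
    gt, noise = config.ground_truth, config.rating_noise_sd

    def rate_batch(seqs) -> list[float]:
        return simulate_remembered_utilities(
            seqs, gt, noise, rng, discretize=config.discretize
        )

    seq4_types = [SEQ4_TYPES[i % len(SEQ4_TYPES)] for i in range(config.plan.n_seq4)]
    seq4_seqs = [make_sequence(st, 4, parts, rng) for st in seq4_types]
    seq4 = [
        RatedTrial(seq, y, "seq4", st, participant_id, f"s4-{i:03d}")
        for i, (seq, st, y) in enumerate(
            zip(seq4_seqs, seq4_types, rate_batch(seq4_seqs))
        )
    ]
    seq7_types = [SEQ7_TYPES[i % len(SEQ7_TYPES)] for i in range(config.plan.n_seq7)]
    seq7_seqs = [make_sequence(st, 7, parts, rng) for st in seq7_types]
    seq7 = [
        RatedTrial(seq, y, "seq7", st, participant_id, f"s7-{i:03d}")
        for i, (seq, st, y) in enumerate(
            zip(seq7_seqs, seq7_types, rate_batch(seq7_seqs))
        )
    ]
    cont_prefix, cont_ids = [], []
    for s, (seq, positions) in enumerate(
        make_continued_sessions(pool, rng, config.plan)
    ):
        for pos in positions:
            cont_prefix.append(MomentSequence(seq.utilities[:pos]))
            cont_ids.append(f"c{s}@{pos}")
    continued = [
        RatedTrial(seq, y, "continued", "none", participant_id, tid)
        for seq, tid, y in zip(cont_prefix, cont_ids, rate_batch(cont_prefix))
    ]
    wm4 = simulate_wm_responses(seq4, config.wm_accuracy_profile4, lookup, rng)
    wm7 = simulate_wm_responses(seq7, config.wm_accuracy_profile7, lookup, rng)
    return ParticipantData(config, pool, seq4, seq7, continued, wm4, wm7)


def cohort_seed(master_seed: int, index: int) -> int:
    """Per-participant seed derived from (master seed, participant index).

    Uses a SeedSequence spawn so adding participants never perturbs the
    data of existing ones; the result stays below 2**31.
    """
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
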