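"""Domain types, trial-table I/O, and validation shared by all modules.

The data model follows the behavioral tasks the package emulates and
analyzes: a *picture-rating* task producing per-picture preference ratings on
the 1–9 scale (two sessions, averaged onto a half-point grid), fixed-length
*sequence-rating* tasks (4 or 7 pictures per trial) with interleaved
working-memory position probes, and a *continued* sequence-rating task in
which a running evaluation of a 100-picture session is queried every 8–13
pictures.

Positions are 1-based throughout, matching the "1st"–"4th" probe labels shown
to participants.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RATING_MIN = 1.0
RATING_MAX = 9.0

#: The 17 rating levels reachable by averaging two integer ratings: 1, 1.5, ... 9.
RATING_LEVELS = np.arange(1.0, 9.01, 0.5)

TASKS = ("seq4", "seq7", "continued")
SEQUENCE_TYPES = (
    "increasing",
    "decreasing",
    "zigzag",
    "peak1",
    "peak2",
    "peak3",
    "peak4",
    "none",
)

_TASK_LENGTH = {"seq4": 4, "seq7": 7}


class DomainError(ValueError):
    """A value violates a domain constraint (range, grid, length)."""


class SchemaError(ValueError):
    """A trial table does not conform to the documented column schema."""


class PartitionError(ValueError):
    """The picture pool cannot be split into the requested partitions."""


def _as_utilities(seq) -> np.ndarray:
    """Coerce a MomentSequence or array-like to a float array of utilities."""
    if isinstance(seq, MomentSequence):
        return seq.utilities
    arr = np.asarray(seq, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise DomainError("a sequence must be a non-empty 1-D array of utilities")
    return arr


@dataclass(frozen=True, eq=False)
class MomentSequence:
    """An ordered list of moment utilities x_1 ... x_t for one trial."""

    utilities: np.ndarray

    def __eq__(self, other):
        return isinstance(other, MomentSequence) and np.array_equal(
            self.utilities, other.utilities
        )

    def __hash__(self):
        return hash(self.utilities.tobytes())

    def __post_init__(self):
        arr = np.asarray(self.utilities, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise DomainError("MomentSequence requires at least one utility")
        if np.any(arr < RATING_MIN) or np.any(arr > RATING_MAX):
            raise DomainError(
                f"utilities must lie in [{RATING_MIN:g}, {RATING_MAX:g}]"
            )
        object.__setattr__(self, "utilities", arr)

    @property
    def t(self) -> int:
        return int(self.utilities.size)

    def __len__(self) -> int:
        return self.t

    def __iter__(self):
        return iter(self.utilities)


@dataclass(frozen=True)
class RatedTrial:
    """A MomentSequence plus the participant's remembered utility of it."""

    sequence: MomentSequence
    remembered_utility: float
    task: str
    sequence_type: str = "none"
    participant_id: str = "p0"
    trial_id: str = "t0"

    def __post_init__(self):
        if self.task not in TASKS:
            raise DomainError(f"unknown task {self.task!r}")
        if self.sequence_type not in SEQUENCE_TYPES:
            raise DomainError(f"unknown sequence_type {self.sequence_type!r}")
        t = self.sequence.t
        want = _TASK_LENGTH.get(self.task)
        if want is not None and t != want:
            raise DomainError(f"task {self.task} requires t={want}, got t={t}")
        if self.task == "continued" and not (8 <= t <= 100):
            raise DomainError(f"continued task requires 8 <= t <= 100, got {t}")
        if not (RATING_MIN <= self.remembered_utility <= RATING_MAX):
            raise DomainError(
                f"remembered_utility {self.remembered_utility} outside [1, 9]"
            )


@dataclass(frozen=True)
class WMRecord:
    """One working-memory probe: which position held the queried picture?"""

    queried_utility: float
    preference_group: int
    true_position: int
    answered_position: int

    def __post_init__(self):
        if not (RATING_MIN <= self.queried_utility <= RATING_MAX):
            raise DomainError("queried_utility outside [1, 9]")
        if self.true_position < 1 or self.answered_position < 1:
            raise DomainError("positions are 1-based")

    @property
    def correct(self) -> bool:
        return self.true_position == self.answered_position


@dataclass(frozen=True)
class PictureRecord:
    """One picture with its two-session ratings, familiarity, and partition."""

    picture_id: str
    rating_day1: int
    rating_day2: int
    familiar: bool = False
    partition: int = 0  # 1..7 once assigned; 0 = unassigned

    def __post_init__(self):
        for r in (self.rating_day1, self.rating_day2):
            if int(r) != r or not (1 <= r <= 9):
                raise DomainError("day ratings must be integers in [1, 9]")

    @property
    def rating(self) -> float:
        """Two-session mean; lies on the 0.5 grid {1, 1.5, ..., 9}."""
        return (self.rating_day1 + self.rating_day2) / 2.0


def average_two_day_rating(day1: int, day2: int) -> float:
    """Average two integer session ratings onto the half-point grid."""
    for r in (day1, day2):
        if int(r) != r or not (1 <= r <= 9):
            raise DomainError(f"day rating {r!r} must be an integer in [1, 9]")
    return (day1 + day2) / 2.0


# ---------------------------------------------------------------------------
# Preference partitions
# ---------------------------------------------------------------------------

#: Partition labels: odd indices are the full-interval ("1"–"4 star") groups,
#: even indices the intermediate half-interval ("1.5"/"2.5"/"3.5 star") groups.
FULL_PARTITIONS = (1, 3, 5, 7)
HALF_PARTITIONS = (2, 4, 6)


def build_partitions(ratings: Sequence[float], tol: float = 0.2) -> np.ndarray:
    """Assign each rating to one of seven ordered preference partitions.

    Ratings are sorted and split into seven contiguous groups over the 17
    rating levels. Boundaries are chosen so that the three half-interval
    groups (partitions 2, 4, 6) are as small as possible while the four
    full-interval groups (1, 3, 5, 7) stay within ``tol`` (relative) of their
    mean size.  All C(16, 6) contiguous boundary placements are enumerated and
    scored lexicographically by (full-group spread beyond ``tol``, total
    half-group size, full-group spread), so the returned split is the global
    optimum of that criterion.

    Returns a partition index in 1..7 per input rating (same order as the
    input). Assignment is monotone: a higher rating never maps to a lower
    partition.
    """
    arr = np.asarray(ratings, dtype=float)
    if arr.size < 7:
        raise PartitionError("need at least 7 pictures to build 7 partitions")
    if np.unique(arr).size < 7:
        raise PartitionError("need at least 7 distinct rating values")
    # counts per rating level, in ascending level order
    levels = np.unique(arr)
    counts = np.array([(arr == lv).sum() for lv in levels])
    n_levels = levels.size

    best_key = None
    best_bounds = None
    # boundaries are cut points between levels: 6 cuts -> 7 contiguous groups
    for bounds in itertools.combinations(range(1, n_levels), 6):
        edges = (0, *bounds, n_levels)
        sizes = [counts[edges[i]:edges[i + 1]].sum() for i in range(7)]
        full = np.array([sizes[i - 1] for i in FULL_PARTITIONS])
        half = np.array([sizes[i - 1] for i in HALF_PARTITIONS])
        mean_full = full.mean()
        spread = (full.max() - full.min()) / mean_full if mean_full > 0 else np.inf
        violation = max(0.0, spread - 2 * tol)
        key = (round(violation, 12), int(half.sum()), round(spread, 12), bounds)
        if best_key is None or key < best_key:
            best_key = key
            best_bounds = bounds

    edges = (0, *best_bounds, n_levels)
    level_to_part = np.empty(n_levels, dtype=int)
    for g in range(7):
        level_to_part[edges[g]:edges[g + 1]] = g + 1
    idx = np.searchsorted(levels, arr)
    return level_to_part[idx]


def assign_partitions(pool: Iterable[PictureRecord]) -> list[PictureRecord]:
    """Partition the non-familiar pictures of a pool; familiar ones keep 0."""
    pool = list(pool)
    usable = [p for p in pool if not p.familiar]
    parts = build_partitions([p.rating for p in usable])
    out = []
    it = iter(parts)
    for p in pool:
        if p.familiar:
            out.append(p)
        else:
            out.append(
                PictureRecord(
                    p.picture_id, p.rating_day1, p.rating_day2, False, int(next(it))
                )
            )
    return out


# ---------------------------------------------------------------------------
# Trial-table I/O
#
# Fixed-length tasks (seq4/seq7): one row per trial,
#   participant_id,trial_id,task,sequence_type,utilities,remembered_utility
# with ``utilities`` a semicolon-joined list.
#
# Continued task: one row per picture keyed by (session, position),
#   participant_id,session,position,utility,remembered_utility
# where a non-empty ``remembered_utility`` marks a query made right after
# that position was shown.
# ---------------------------------------------------------------------------


def write_trials(trials: Sequence[RatedTrial], path: str | Path, schema: str) -> None:
    """Write trials as delimited text in the documented schema."""
    path = Path(path)
    if schema in ("seq4", "seq7"):
        rows = [
            {
                "participant_id": tr.participant_id,
                "trial_id": tr.trial_id,
                "task": tr.task,
                "sequence_type": tr.sequence_type,
                "utilities": ";".join(repr(float(u)) for u in tr.sequence),
                "remembered_utility": repr(float(tr.remembered_utility)),
            }
            for tr in trials
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    elif schema == "continued":
        rows = []
        # trials sharing (participant, session) are running queries of one
        # session; the longest prefix carries the full picture list.
        by_session: dict[tuple[str, str], list[RatedTrial]] = {}
        for tr in trials:
            sess = tr.trial_id.split("@")[0]
            by_session.setdefault((tr.participant_id, sess), []).append(tr)
        for (pid, sess), sess_trials in by_session.items():
            sess_trials = sorted(sess_trials, key=lambda tr: tr.sequence.t)
            longest = sess_trials[-1].sequence.utilities
            queries = {tr.sequence.t: tr.remembered_utility for tr in sess_trials}
            for pos, u in enumerate(longest, start=1):
                rows.append(
                    {
                        "participant_id": pid,
                        "session": sess,
                        "position": pos,
                        "utility": repr(float(u)),
                        "remembered_utility": repr(float(queries[pos]))
                        if pos in queries
                        else "",
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise SchemaError(f"unknown schema {schema!r}")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def load_trials(path: str | Path, schema: str) -> list[RatedTrial]:
    """Load a trial table written by :func:`write_trials`.

    Every returned trial satisfies its type invariants; row order (and, for
    the continued task, query order within a session) is preserved. Rows
    violating the schema raise :class:`SchemaError` naming the offender.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: no such file")
    if schema in ("seq4", "seq7"):
        df = pd.read_csv(path, dtype=str)
        _require_columns(
            df,
            ["participant_id", "trial_id", "task", "sequence_type",
             "utilities", "remembered_utility"],
            path,
        )
        trials = []
        for i, row in df.iterrows():
            try:
                utilities = [float(u) for u in str(row["utilities"]).split(";")]
                trials.append(
                    RatedTrial(
                        sequence=MomentSequence(np.array(utilities)),
                        remembered_utility=float(row["remembered_utility"]),
                        task=str(row["task"]),
                        sequence_type=str(row["sequence_type"]),
                        participant_id=str(row["participant_id"]),
                        trial_id=str(row["trial_id"]),
                    )
                )
            except (DomainError, ValueError) as exc:
                raise SchemaError(f"{path}: row {i}: {exc}") from exc
        return trials
    if schema == "continued":
        df = pd.read_csv(path, dtype=str)
        _require_columns(
            df,
            ["participant_id", "session", "position", "utility",
             "remembered_utility"],
            path,
        )
        trials = []
        for (pid, sess), grp in df.groupby(
            ["participant_id", "session"], sort=False
        ):
            grp = grp.sort_values("position", key=lambda s: s.astype(int))
            try:
                utilities = grp["utility"].astype(float).to_numpy()
            except ValueError as exc:
                raise SchemaError(f"{path}: session {sess}: {exc}") from exc
            for i, row in grp.iterrows():
                ru = row["remembered_utility"]
                if isinstance(ru, str) and ru.strip() != "":
                    pos = int(row["position"])
                    try:
                        trials.append(
                            RatedTrial(
                                sequence=MomentSequence(utilities[:pos]),
                                remembered_utility=float(ru),
                                task="continued",
                                participant_id=str(pid),
                                trial_id=f"{sess}@{pos}",
                            )
                        )
                    except (DomainError, ValueError) as exc:
                        raise SchemaError(f"{path}: row {i}: {exc}") from exc
        return trials
    raise SchemaError(f"unknown schema {schema!r}")


def write_wm_records(
    records: Sequence[WMRecord], path: str | Path
) -> None:
    rows = [
        {
            "queried_utility": repr(float(r.queried_utility)),
            "preference_group": r.preference_group,
            "true_position": r.true_position,
            "answered_position": r.answered_position,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_wm_records(path: str | Path) -> list[WMRecord]:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: no such file")
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["queried_utility", "preference_group", "true_position",
         "answered_position"],
        path,
    )
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                WMRecord(
                    queried_utility=float(row["queried_utility"]),
                    preference_group=int(row["preference_group"]),
                    true_position=int(row["true_position"]),
                    answered_position=int(row["answered_position"]),
                )
            )
        except (DomainError, ValueError) as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from exc
    return out
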