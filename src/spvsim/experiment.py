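"""Trial scheduling and scoring for SPV psychophysics experiments.

Builds per-subject trial plans (randomized stimulus order with the three
methods interleaved, 10 s per image, a 30 s pause every 15 images) and
scores response logs into the experiment's summary statistics: per-method
percentages of correct / incorrect / not-answered (NA) responses with 95%
confidence intervals, and the 6-room confusion matrices with recall
computed either over answered trials only or over all trials (NA counted
in the denominator).  NA is never a prediction, so precision is count-based
and common to both variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import ROOM_LABELS, SceneAnnotation

__all__ = [
    "OBJECT_SYNONYMS",
    "TrialPlan",
    "ResponseRecord",
    "ConfusionMatrix",
    "PlanningError",
    "make_plan",
    "score_objects",
    "score_rooms",
    "summarize",
    "read_log",
    "write_log",
    "paired_method_test",
]

NA = "NA"

#: Maps reported object names to canonical classes before matching.  The
#: experiment groups oven with microwave (their phosphene silhouettes are
#: indistinguishable rectangles); table synonyms cover detector vocabulary.
OBJECT_SYNONYMS: dict[str, str] = {
    "oven": "oven/microwave",
    "microwave": "oven/microwave",
    "dining table": "table",
    "desk": "table",
    "sofa": "couch",
    "fridge": "refrigerator",
    "bathtub": "bath",
    "tub": "bath",
}

_KNOWN_OBJECTS = {
    "chair",
    "table",
    "couch",
    "toilet",
    "bath",
    "sink",
    "bed",
    "oven",
    "microwave",
    "refrigerator",
    "laptop",
} | set(OBJECT_SYNONYMS)


class PlanningError(ValueError):
    """The requested plan cannot be built from the stimulus pool."""


@dataclass(frozen=True)
class TrialPlan:
    """One subject's stimulus sequence with pause markers."""

    subject_id: str
    stimuli: tuple[tuple[str, str], ...]  # (scene_id, method), presentation order
    display_seconds: float = 10.0
    pause_every: int = 15
    pause_seconds: float = 30.0
    seed: int = 0

    @property
    def pauses_after(self) -> tuple[int, ...]:
        """1-based stimulus indices after which a pause occurs."""
        n = len(self.stimuli)
        return tuple(range(self.pause_every, n, self.pause_every))


@dataclass
class ResponseRecord:
    """One trial's response: reported objects and room (or NA)."""

    subject_id: str
    scene_id: str
    method: str
    reported_objects: list[str] = field(default_factory=list)
    reported_room: str = NA
    answered: bool = True
    object_outcome: str | None = None  # filled by score_objects

    def __post_init__(self) -> None:
        if self.reported_room not in (*ROOM_LABELS, NA):
            raise ValueError(f"reported_room {self.reported_room!r} invalid")


def make_plan(
    scene_ids: Sequence[str],
    methods: Sequence[str],
    subject_id: str,
    images_per_subject: int,
    seed: int,
    display_seconds: float = 10.0,
    pause_every: int = 15,
    pause_seconds: float = 30.0,
) -> TrialPlan:
    """Build a randomized trial plan for one subject.

    Scenes are drawn without replacement (no subject ever sees the same
    scene twice, under any method) and methods are interleaved in a
    balanced, shuffled assignment.  The full stimulus pool exceeds what
    one subject can view, so different subjects overlap in the stimuli
    they are shown; that is how 54 images per subject are drawn from a
    pool of 300 scenes x 3 methods.
    """
    if images_per_subject > len(scene_ids):
        raise PlanningError(
            f"requested {images_per_subject} images but only "
            f"{len(scene_ids)} distinct scenes available"
        )
    rng = np.random.default_rng(seed)
    chosen = list(rng.permutation(np.asarray(scene_ids, dtype=object))[:images_per_subject])
    # balanced method assignment, then a joint shuffle of the pairing
    assigned = [methods[i % len(methods)] for i in range(images_per_subject)]
    rng.shuffle(assigned)
    stimuli = tuple(zip(chosen, assigned))
    return TrialPlan(
        subject_id=subject_id,
        stimuli=stimuli,
        display_seconds=display_seconds,
        pause_every=pause_every,
        pause_seconds=pause_seconds,
        seed=seed,
    )


def _canonical(name: str) -> str:
    key = name.strip().lower()
    if key not in _KNOWN_OBJECTS:
        raise ValueError(f"unknown object class {name!r}")
    return OBJECT_SYNONYMS.get(key, key)


def score_objects(record: ResponseRecord, truth: SceneAnnotation) -> str:
    """Grade one object-recognition response: correct / incorrect / NA.

    A trial is NA when it went unanswered; otherwise it is correct when at
    least one reported class matches a ground-truth instance class after
    synonym mapping (per-image grading), and incorrect otherwise.
    """
    if not record.answered and not record.reported_objects:
        record.object_outcome = NA
        return NA
    reported = {_canonical(r) for r in record.reported_objects}
    actual = {_canonical(inst.label) for inst in truth.instances}
    outcome = "correct" if reported & actual else "incorrect"
    record.object_outcome = outcome
    return outcome


def _pct(numer: int, denom: int) -> float | None:
    """Percentage to 2 decimals, half-up; None when the denominator is 0."""
    if denom == 0:
        return None
    q = Decimal(numer) / Decimal(denom) * 100
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """Actual-room x predicted-room counts with an extra NA column.

    ``recall(variant="answered")`` divides each row's diagonal count by the
    answered trials of that row; ``variant="total"`` divides by all trials
    including NA.  Precision divides by the predicted-column count; NA is
    never a prediction, so precision is identical in both variants.
    Undefined entries (zero denominators) are reported as None, never 0.
    """

    counts: np.ndarray  # shape (6, 7); columns = ROOM_LABELS + (NA,)
    rooms: tuple[str, ...] = ROOM_LABELS

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (len(self.rooms), len(self.rooms) + 1):
            raise ValueError("counts must be n_rooms x (n_rooms + 1)")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = c

    @property
    def n_trials(self) -> int:
        return int(self.counts.sum())

    def recall(self, variant: str = "answered") -> dict[str, float | None]:
        if variant not in {"answered", "total"}:
            raise ValueError("variant must be 'answered' or 'total'")
        out = {}
        for i, room in enumerate(self.rooms):
            row = self.counts[i]
            denom = int(row[:-1].sum()) if variant == "answered" else int(row.sum())
            out[room] = _pct(int(row[i]), denom)
        return out

    def precision(self) -> dict[str, float | None]:
        out = {}
        for j, room in enumerate(self.rooms):
            col = self.counts[:, j]
            out[room] = _pct(int(col[j]), int(col.sum()))
        return out

    def to_frame(self, variant: str = "answered") -> pd.DataFrame:
        """Tabulate as row-normalized proportions plus recall/precision."""
        denom = (
            self.counts[:, :-1].sum(axis=1, keepdims=True)
            if variant == "answered"
            else self.counts.sum(axis=1, keepdims=True)
        ).astype(float)
        denom[denom == 0] = np.nan
        cols = list(self.rooms) + ([NA] if variant == "total" else [])
        body = self.counts[:, : len(cols)] / denom
        df = pd.DataFrame(body.round(2), index=list(self.rooms), columns=cols)
        df["recall"] = [self.recall(variant)[r] for r in self.rooms]
        return df


def score_rooms(
    records: Iterable[ResponseRecord],
    truths: Mapping[str, str] | Mapping[str, SceneAnnotation],
) -> ConfusionMatrix:
    """Tally room-identification responses into a confusion matrix.

    ``truths`` maps scene_id to the actual room label (or to a full
    annotation).  Every record must have a truth.
    """
    counts = np.zeros((len(ROOM_LABELS), len(ROOM_LABELS) + 1), dtype=np.int64)
    room_idx = {room: i for i, room in enumerate(ROOM_LABELS)}
    for rec in records:
        truth = truths[rec.scene_id]
        actual = truth if isinstance(truth, str) else truth.room_label
        i = room_idx[actual]
        j = len(ROOM_LABELS) if rec.reported_room == NA else room_idx[rec.reported_room]
        counts[i, j] += 1
    return ConfusionMatrix(counts=counts)


def summarize(
    records: Sequence[ResponseRecord],
    truths: Mapping[str, SceneAnnotation] | None = None,
    by_room: bool = False,
) -> pd.DataFrame:
    """Per-method percentages of correct / incorrect / NA responses.

    Object outcomes are taken from ``record.object_outcome`` (call
    :func:`score_objects` first, or pass ``truths`` to score here).  The
    95% confidence half-width on the correct proportion uses the normal
    approximation ``1.96 * sqrt(p (1 - p) / n)``.  Groups with no records
    are omitted.
    """
    rows = []
    for rec in records:
        if rec.object_outcome is None:
            if truths is None:
                raise ValueError("records are unscored and no truths were given")
            score_objects(rec, truths[rec.scene_id])
        room = None
        if truths is not None:
            t = truths[rec.scene_id]
            room = t if isinstance(t, str) else t.room_label
        rows.append(
            {"method": rec.method, "room": room, "outcome": rec.object_outcome}
        )
    df = pd.DataFrame(rows)
    keys = ["method", "room"] if by_room else ["method"]
    out = []
    for key, grp in df.groupby(keys):
        n = len(grp)
        p = (grp["outcome"] == "correct").mean()
        rec_row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec_row.update(
            n=n,
            pct_correct=round(100 * p, 2),
            ci95_half_width=round(100 * 1.96 * math.sqrt(p * (1 - p) / n), 2),
            pct_incorrect=round(100 * (grp["outcome"] == "incorrect").mean(), 2),
            pct_na=round(100 * (grp["outcome"] == NA).mean(), 2),
        )
        out.append(rec_row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# response-log CSV I/O

_LOG_COLUMNS = [
    "subject_id",
    "scene_id",
    "method",
    "reported_objects",
    "reported_room",
    "answered",
]


def write_log(records: Sequence[ResponseRecord], path: str | Path) -> None:
    """Write records as CSV; reported objects are semicolon-joined."""
    df = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "scene_id": r.scene_id,
                "method": r.method,
                "reported_objects": ";".join(r.reported_objects),
                "reported_room": r.reported_room,
                "answered": r.answered,
            }
            for r in records
        ],
        columns=_LOG_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_log(path: str | Path) -> list[ResponseRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"log missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        objs = [s for s in str(row.reported_objects).split(";") if s]
        answered = str(row.answered).strip().lower() in {"true", "1", "yes"}
        records.append(
            ResponseRecord(
                subject_id=str(row.subject_id),
                scene_id=str(row.scene_id),
                method=str(row.method),
                reported_objects=objs,
                reported_room=str(row.reported_room),
                answered=answered,
            )
        )
    return records


def paired_method_test(
    records: Sequence[ResponseRecord], method_a: str, method_b: str
) -> tuple[float, float]:
    """Convenience paired t-test on per-subject correct fractions.

    Returns (t statistic, two-sided p value) comparing two methods across
    subjects; purely exploratory.
    """
    from scipy import stats

    df = pd.DataFrame(
        [
            {
                "subject": r.subject_id,
                "method": r.method,
                "correct": r.object_outcome == "correct",
            }
            for r in records
            if r.object_outcome is not None
        ]
    )
    per = df.pivot_table(index="subject", columns="method", values="correct", aggfunc="mean")
    res = stats.ttest_rel(per[method_a], per[method_b])
    return float(res.statistic), float(res.pvalue)
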