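"""Tap-test records: data model, CSV I/O, feature extraction and subject-level splits.

A tap-test record is one touch attempt: the screen shows ``n_objects``
circles (2, 3 or 5), the subject touches the highlighted one, and the app
logs the target centre ``(x, y)``, the touch point ``(xt, yt)``, the
reaction time ``rt`` in seconds and two identifiers (subject id, disease
flag).  The two derived features are the reaction time itself and ``delta``,
the Euclidean distance in pixels between target centre and touch point —
the tremor-sensitive accuracy feature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Additive floor inside the log transform so a perfect touch (delta = 0)
#: stays representable.  Negligible at the pixel/second scales of the data.
LOG_EPSILON = 1e-3

VALID_OBJECT_COUNTS = (2, 3, 5)

CSV_COLUMNS = ["x", "y", "xt", "yt", "nC", "rt", "delta", "User", "IsSick"]
TFC_COLUMN = "TFC"
SESSION_COLUMN = "session"


class InvalidRecordError(ValueError):
    """A record violates the tap-test schema (non-finite or out-of-domain field)."""


class SchemaError(ValueError):
    """A CSV file does not carry the expected header."""


class ConfigurationError(ValueError):
    """An operation was configured inconsistently (e.g. too few subjects to split)."""


@dataclass(frozen=True)
class TouchRecord:
    """One tap event.

    Attributes
    ----------
    x, y : float
        Pixel coordinates of the target circle's centre.
    xt, yt : float
        Pixel coordinates of the subject's touch.
    n_objects : int
        Number of circles on screen; one of 2, 3, 5.
    rt : float
        Reaction time in seconds, strictly positive.
    user_id : int
        Subject identifier.
    is_sick : int
        1 for a Huntington's disease patient, 0 for a healthy control.
    """

    x: float
    y: float
    xt: float
    yt: float
    n_objects: int
    rt: float
    user_id: int
    is_sick: int

    def __post_init__(self) -> None:
        for name in ("x", "y", "xt", "yt", "rt"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidRecordError(f"{name} must be finite, got {v!r}")
        if self.x < 0 or self.y < 0 or self.xt < 0 or self.yt < 0:
            raise InvalidRecordError("coordinates must be non-negative")
        if self.rt <= 0:
            raise InvalidRecordError(f"reaction time must be > 0, got {self.rt}")
        if self.n_objects not in VALID_OBJECT_COUNTS:
            raise InvalidRecordError(
                f"n_objects must be one of {VALID_OBJECT_COUNTS}, got {self.n_objects}"
            )
        if self.is_sick not in (0, 1):
            raise InvalidRecordError(f"is_sick must be 0 or 1, got {self.is_sick}")

    @property
    def delta(self) -> float:
        """Euclidean touch error in pixels (computed, never stored)."""
        return compute_delta((self.x, self.y), (self.xt, self.yt))


@dataclass(frozen=True)
class FeatureRow:
    """The regression unit: an (rt, delta) pair with log variants and optional label."""

    rt: float
    delta: float
    user_id: int
    is_sick: int
    n_objects: int
    tfc: float | None = None
    log_rt: float = field(init=False)
    log_delta: float = field(init=False)

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise InvalidRecordError(f"delta must be >= 0, got {self.delta}")
        if self.tfc is not None and not (0.0 <= self.tfc <= 10.0):
            raise InvalidRecordError(f"tfc label must lie in [0, 10], got {self.tfc}")
        object.__setattr__(self, "log_rt", log_transform(self.rt))
        object.__setattr__(self, "log_delta", log_transform(self.delta))


@dataclass(frozen=True)
class DatasetSplit:
    """Subject-disjoint train/validation/test partition of feature rows."""

    train: tuple[FeatureRow, ...]
    validation: tuple[FeatureRow, ...]
    test: tuple[FeatureRow, ...]
    seed: int

    def __post_init__(self) -> None:
        users = [
            {r.user_id for r in part} for part in (self.train, self.validation, self.test)
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                if users[i] & users[j]:
                    raise ConfigurationError(
                        f"subjects {sorted(users[i] & users[j])} appear in two partitions"
                    )


def compute_delta(target: tuple[float, float], touch: tuple[float, float]) -> float:
    """Euclidean distance in pixels between the target centre and the touch point.

    Full precision is kept internally; the conventional CSV rendering rounds
    to 3 decimals for display only.
    """
    x, y = target
    xt, yt = touch
    if not all(math.isfinite(v) for v in (x, y, xt, yt)):
        raise InvalidRecordError("compute_delta requires finite coordinates")
    return math.hypot(x - xt, y - yt)


def log_transform(value: float) -> float:
    """Natural log with a small additive floor: ``ln(value + 1e-3)``.

    Reaction times and touch errors are strongly right-skewed; working on the
    log scale brings them close to normal.  The floor keeps a perfect touch
    (delta exactly 0) in the domain.
    """
    if not math.isfinite(value) or value < 0:
        raise InvalidRecordError(f"log_transform requires a finite value >= 0, got {value!r}")
    return math.log(value + LOG_EPSILON)


#: Tolerance (px) for validating a stored delta column against the coordinates.
DELTA_MISMATCH_TOL = 0.01


def read_records(path, *, strict: bool = True) -> list[TouchRecord]:
    """Read tap-test records from CSV.

    The header must start with ``x,y,xt,yt,nC,rt,delta,User,IsSick``
    (optionally followed by ``TFC`` and/or ``session``).  A stored ``delta``
    column is validated against the coordinates; a mismatch beyond 0.01 px is
    logged as a warning (source tables occasionally carry typos) but the
    record is still loaded with the recomputed value authoritative.

    With ``strict=False`` unparseable rows are logged (with their line
    number) and skipped instead of raising.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns and c != "delta"]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    records: list[TouchRecord] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            rec = TouchRecord(
                x=float(row["x"]),
                y=float(row["y"]),
                xt=float(row["xt"]),
                yt=float(row["yt"]),
                n_objects=int(row["nC"]),
                rt=float(row["rt"]),
                user_id=int(row["User"]),
                is_sick=int(row["IsSick"]),
            )
        except (InvalidRecordError, ValueError, TypeError) as exc:
            if strict:
                raise InvalidRecordError(f"{path}, line {line_no}: {exc}") from exc
            logger.warning("%s, line %d: skipping unparseable row (%s)", path, line_no, exc)
            continue
        if "delta" in df.columns and pd.notna(row["delta"]):
            stored = float(row["delta"])
            if abs(stored - rec.delta) > DELTA_MISMATCH_TOL:
                logger.warning(
                    "%s, line %d: stored delta %.3f disagrees with recomputed %.3f",
                    path,
                    line_no,
                    stored,
                    rec.delta,
                )
        records.append(rec)
    return records


def write_records(
    path,
    records: Sequence[TouchRecord],
    tfc: Sequence[float] | None = None,
    session: Sequence[int] | None = None,
) -> None:
    """Write records in the canonical CSV dialect (delta rendered to 3 decimals)."""
    data = {
        "x": [r.x for r in records],
        "y": [r.y for r in records],
        "xt": [r.xt for r in records],
        "yt": [r.yt for r in records],
        "nC": [r.n_objects for r in records],
        "rt": [round(r.rt, 3) for r in records],
        "delta": [round(r.delta, 3) for r in records],
        "User": [r.user_id for r in records],
        "IsSick": [r.is_sick for r in records],
    }
    if tfc is not None:
        data[TFC_COLUMN] = [round(float(t), 4) for t in tfc]
    if session is not None:
        data[SESSION_COLUMN] = list(session)
    pd.DataFrame(data).to_csv(path, index=False)


def extract_features(
    records: Iterable[TouchRecord], tfc: Sequence[float] | None = None
) -> list[FeatureRow]:
    """Turn touch records into (rt, delta) feature rows, optionally attaching labels."""
    records = list(records)
    if tfc is not None and len(tfc) != len(records):
        raise ConfigurationError("tfc label sequence length must match the records")
    rows = []
    for i, rec in enumerate(records):
        rows.append(
            FeatureRow(
                rt=rec.rt,
                delta=rec.delta,
                user_id=rec.user_id,
                is_sick=rec.is_sick,
                n_objects=rec.n_objects,
                tfc=None if tfc is None else float(tfc[i]),
            )
        )
    return rows


def read_feature_rows(path) -> list[FeatureRow]:
    """Read a labeled dataset CSV (Table-style dialect with a TFC column) as feature rows."""
    df = pd.read_csv(path)
    records = read_records(path)
    if TFC_COLUMN in df.columns:
        return extract_features(records, tfc=df[TFC_COLUMN].to_numpy(dtype=float))
    return extract_features(records)


# Total-functional-capacity bands and their Shoulson–Fahn stages.
_STAGE_BANDS = (
    (11, 13, "Early", "I"),
    (7, 10, "Early", "II"),
    (4, 6, "Moderate or mid", "III"),
    (1, 3, "Advanced or late", "IV"),
    (0, 0, "Advanced or late", "V"),
)


def tfc_to_stage(tfc: float) -> tuple[str, str]:
    """Map a total-functional-capacity score in [0, 13] to (descriptor, stage).

    The clinical scale is integer-valued; continuous model outputs are
    rounded half-up before banding.
    """
    if not math.isfinite(tfc) or tfc < 0 or tfc > 13:
        raise InvalidRecordError(f"TFC score must lie in [0, 13], got {tfc!r}")
    score = math.floor(tfc + 0.5)  # round half-up
    for lo, hi, descriptor, stage in _STAGE_BANDS:
        if lo <= score <= hi:
            return descriptor, stage
    raise AssertionError("unreachable: bands cover 0..13")


def allocate_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of ``n`` items to ``fractions``."""
    quotas = [n * f for f in fractions]
    counts = [math.floor(q) for q in quotas]
    remainder = n - sum(counts)
    by_frac = sorted(range(len(fractions)), key=lambda i: (quotas[i] - counts[i]), reverse=True)
    for i in by_frac[:remainder]:
        counts[i] += 1
    return counts


def split_by_subject(
    rows: Sequence[FeatureRow],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> DatasetSplit:
    """Partition rows into train/validation/test with every subject in exactly one part.

    Subjects are shuffled with ``seed`` and apportioned by subject count with
    largest-remainder rounding; all of a subject's rows follow the subject,
    so no individual leaks across partitions.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ConfigurationError(f"fractions must sum to 1, got {fractions}")
    users = sorted({r.user_id for r in rows})
    if len(users) < 3:
        raise ConfigurationError(
            f"need at least 3 distinct subjects to form 3 partitions, got {len(users)}"
        )
    rng = np.random.default_rng(seed)
    order = [users[i] for i in rng.permutation(len(users))]
    counts = allocate_counts(len(users), fractions)
    cut1, cut2 = counts[0], counts[0] + counts[1]
    assignment = {u: 0 for u in order[:cut1]}
    assignment.update({u: 1 for u in order[cut1:cut2]})
    assignment.update({u: 2 for u in order[cut2:]})
    parts: tuple[list[FeatureRow], list[FeatureRow], list[FeatureRow]] = ([], [], [])
    for row in rows:
        parts[assignment[row.user_id]].append(row)
    return DatasetSplit(
        train=tuple(parts[0]), validation=tuple(parts[1]), test=tuple(parts[2]), seed=seed
    )
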