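"""End-to-end hybrid flow: per-mode prediction averages, fuzzy staging, and
the two-session impairment decision.

One test *session* is a batch of tap attempts across the three modes
(2, 3 and 5 on-screen objects).  The trained capacity regressor scores
every attempt; the per-mode means AVG1..AVG3 feed the fuzzy system, which
returns a crisp evaluation score and a reaction stage.  Repeating the
session at a later time and comparing stage labels yields the verdict:
a drop in stage flags an impaired reaction condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .fuzzy import STAGE_ORDER, FuzzySystem, rule_strengths, stage_label
from .network import TrainedNet
from .records import SESSION_COLUMN, TouchRecord, read_records

MODES = (2, 3, 5)


class IncompleteSessionError(ValueError):
    """A session is missing attempts for one of the three test modes."""


@dataclass(frozen=True)
class Session:
    """A batch of tap attempts from one sitting, grouped by test mode."""

    session_id: str
    records: tuple[TouchRecord, ...]
    timestamp: str | None = None

    def mode_group(self, n_objects: int) -> tuple[TouchRecord, ...]:
        return tuple(r for r in self.records if r.n_objects == n_objects)


@dataclass(frozen=True)
class SessionEvaluation:
    """AVG1..AVG3, the crisp fuzzy evaluation, and the reaction stage."""

    session_id: str
    avg1: float
    avg2: float
    avg3: float
    eval_score: float
    stage: str
    predictions: dict = field(default_factory=dict, compare=False)

    @property
    def stage_index(self) -> int:
        return STAGE_ORDER.index(self.stage)


Conclusion = Literal["improved", "stable", "impaired"]


@dataclass(frozen=True)
class ComparisonVerdict:
    first: SessionEvaluation
    second: SessionEvaluation
    conclusion: Conclusion

    @property
    def message(self) -> str:
        return {
            "impaired": "Impaired reaction condition.",
            "stable": "Stable reaction condition.",
            "improved": "Improved reaction condition.",
        }[self.conclusion]


def session_averages(net: TrainedNet, session: Session) -> tuple[float, float, float]:
    """Per-mode means of clipped capacity predictions: (AVG1, AVG2, AVG3).

    Each attempt's prediction is clipped to [0, 10] (the fuzzy input domain)
    before averaging.
    """
    avgs = []
    for mode in MODES:
        group = session.mode_group(mode)
        if not group:
            raise IncompleteSessionError(
                f"session {session.session_id!r} has no attempts in the "
                f"{mode}-object mode"
            )
        preds = net.predict([r.rt for r in group], [r.delta for r in group], clip=True)
        avgs.append(float(np.mean(preds)))
    return tuple(avgs)


def evaluate_session(net: TrainedNet, fls: FuzzySystem, session: Session) -> SessionEvaluation:
    """Score one session: predictions, per-mode averages, fuzzy stage.

    All intermediates (per-record features and predictions, rule firing
    strengths) are recorded on the evaluation for auditability.
    """
    avgs = session_averages(net, session)
    score, stage = stage_label(fls, avgs)
    intermediates = {"modes": {}}
    for mode in MODES:
        group = session.mode_group(mode)
        preds = net.predict([r.rt for r in group], [r.delta for r in group], clip=True)
        intermediates["modes"][mode] = {
            "rt": [r.rt for r in group],
            "delta": [round(r.delta, 3) for r in group],
            "predictions": [float(p) for p in preds],
        }
    strengths = rule_strengths(fls, avgs)
    intermediates["fired_rules"] = [
        {"if": list(rule.antecedent), "then": rule.consequent, "strength": float(s)}
        for rule, s in zip(fls.rules, strengths)
        if s > 0
    ]
    return SessionEvaluation(
        session_id=session.session_id,
        avg1=avgs[0], avg2=avgs[1], avg3=avgs[2],
        eval_score=score, stage=stage, predictions=intermediates,
    )


def compare_sessions(
    first: SessionEvaluation, second: SessionEvaluation, score_margin: float = 0.0
) -> ComparisonVerdict:
    """Verdict from two evaluations taken time apart.

    The comparison is ordinal on stage labels (ADVANCED < LATE < AVERAGE <
    EARLY < HEALTHY/PRECLINICAL), so defuzzification jitter cannot flip it:
    a lower second stage means impaired, equal means stable, higher means
    improved.  With ``score_margin > 0`` equal-stage pairs are additionally
    compared on crisp scores at that margin.
    """
    if second.stage_index < first.stage_index:
        conclusion = "impaired"
    elif second.stage_index > first.stage_index:
        conclusion = "improved"
    elif score_margin > 0 and first.eval_score - second.eval_score > score_margin:
        conclusion = "impaired"
    elif score_margin > 0 and second.eval_score - first.eval_score > score_margin:
        conclusion = "improved"
    else:
        conclusion = "stable"
    return ComparisonVerdict(first=first, second=second, conclusion=conclusion)


def read_sessions(path) -> dict[str, Session]:
    """Read sessions from a records CSV carrying a ``session`` column.

    Without the column the whole file forms a single session ``"1"``.
    Mode groups come from the nC column, never from row position.
    """
    df = pd.read_csv(path)
    records = read_records(path)
    if SESSION_COLUMN in df.columns:
        ids = [str(v) for v in df[SESSION_COLUMN]]
    else:
        ids = ["1"] * len(records)
    sessions: dict[str, list[TouchRecord]] = {}
    for sid, rec in zip(ids, records):
        sessions.setdefault(sid, []).append(rec)
    return {sid: Session(session_id=sid, records=tuple(recs))
            for sid, recs in sessions.items()}


def comparison_report(verdict: ComparisonVerdict) -> dict:
    """JSON-ready report: features, predictions, AVG values, scores, stages, verdict."""
    def block(ev: SessionEvaluation) -> dict:
        return {
            "session": ev.session_id,
            "avg": {"AVG1": round(ev.avg1, 4), "AVG2": round(ev.avg2, 4),
                    "AVG3": round(ev.avg3, 4)},
            "eval": round(ev.eval_score, 2),
            "stage": ev.stage,
            "detail": ev.predictions,
        }

    return {
        "first": block(verdict.first),
        "second": block(verdict.second),
        "conclusion": verdict.conclusion,
        "message": verdict.message,
    }


def write_report(verdict: ComparisonVerdict, path) -> None:
    with open(path, "w") as fh:
        json.dump(comparison_report(verdict), fh, indent=1)
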