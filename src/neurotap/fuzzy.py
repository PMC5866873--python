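"""Mamdani Type-1 fuzzy inference for reaction-stage evaluation.

Three inputs — the per-mode averages AVG1/AVG2/AVG3 of the capacity
regressor's predictions (2-, 3- and 5-object test modes), each on [0, 10] —
are fuzzified through triangular membership functions (LOW / AVERAGE /
HIGH), pushed through a complete 27-rule conjunctive rule base with
min-AND, min-implication and max-aggregation, and defuzzified by the
centroid method into a crisp score whose nearest output peak (1, 3, 5, 7, 9)
names the reaction stage:

    ADVANCED < LATE < AVERAGE < EARLY < HEALTHY/PRECLINICAL
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)


class NoRuleFiredError(ValueError):
    """Every rule fired at strength 0, so the centroid is undefined."""


def fuzzy_and(*degrees: float) -> float:
    """Minimum t-norm: conjunction of membership degrees."""
    return min(degrees)


def fuzzy_or(*degrees: float) -> float:
    """Maximum s-norm: disjunction of membership degrees.

    The built-in rule base is purely conjunctive, so inference never calls
    this; it is exposed for config-loaded rule bases that want disjunctive
    antecedents.
    """
    return max(degrees)


@dataclass(frozen=True)
class TriangularMF:
    """Triangular membership function with feet ``a``, ``c`` and peak ``b``."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c):
            raise ValueError(f"require a <= b <= c, got ({self.a}, {self.b}, {self.c})")

    def __call__(self, x) -> np.ndarray | float:
        return membership(self, x)


def membership(mf: TriangularMF, x) -> np.ndarray | float:
    """Degree of membership in [0, 1]: linear rise to the peak, linear fall after.

    Degenerate sides (``a == b`` or ``b == c``) give degree 1 at the shared
    point, so right-angled triangles at the domain edges behave sensibly.
    """
    xa = np.asarray(x, dtype=float)
    out = np.zeros_like(xa)
    if mf.b > mf.a:
        rise = (xa - mf.a) / (mf.b - mf.a)
        out = np.where((xa >= mf.a) & (xa <= mf.b), rise, out)
    else:
        out = np.where(xa == mf.b, 1.0, out)
    if mf.c > mf.b:
        fall = (mf.c - xa) / (mf.c - mf.b)
        out = np.where((xa > mf.b) & (xa <= mf.c), fall, out)
    out = np.where(xa == mf.b, 1.0, out)
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


@dataclass(frozen=True)
class LinguisticVariable:
    name: str
    domain: tuple[float, float]
    terms: tuple[tuple[str, TriangularMF], ...]

    def term(self, label: str) -> TriangularMF:
        for lab, mf in self.terms:
            if lab == label:
                return mf
        raise KeyError(f"{self.name} has no term {label!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.terms)


@dataclass(frozen=True)
class FuzzyRule:
    """Conjunctive rule: one antecedent term per input variable, one consequent term."""

    antecedent: tuple[str, ...]
    consequent: str


# Linguistic terms of the three AVG inputs on [0, 10].
INPUT_TERMS = (
    ("LOW", TriangularMF(0.0, 2.0, 4.0)),
    ("AVERAGE", TriangularMF(3.6, 5.5, 7.0)),
    ("HIGH", TriangularMF(6.6, 8.5, 10.0)),
)

# Output reaction-stage terms; peaks at 1, 3, 5, 7, 9.
OUTPUT_TERMS = (
    ("ADVANCED", TriangularMF(0.0, 1.0, 2.0)),
    ("LATE", TriangularMF(1.5, 3.0, 4.0)),
    ("AVERAGE", TriangularMF(3.5, 5.0, 6.0)),
    ("EARLY", TriangularMF(5.5, 7.0, 8.0)),
    ("HEALTHY/PRECLINICAL", TriangularMF(7.5, 9.0, 10.0)),
)

STAGE_ORDER = tuple(lab for lab, _ in OUTPUT_TERMS)

_INPUT_SCORE = {"LOW": 0, "AVERAGE": 1, "HIGH": 2}
# Ordinal-sum completion: the summed antecedent score (0..6) picks the stage.
_SUM_TO_STAGE = {0: "ADVANCED", 1: "LATE", 2: "LATE", 3: "AVERAGE",
                 4: "EARLY", 5: "EARLY", 6: "HEALTHY/PRECLINICAL"}


def complete_rule_base() -> list[FuzzyRule]:
    """All 27 antecedent combinations, consequents by the ordinal-sum policy.

    Inputs score LOW=0, AVERAGE=1, HIGH=2; the sum s of the three antecedent
    scores maps 0 -> ADVANCED, 1-2 -> LATE, 3 -> AVERAGE, 4-5 -> EARLY,
    6 -> HEALTHY/PRECLINICAL.  This is the monotone completion consistent
    with the published example rules.
    """
    rules = []
    for combo in itertools.product(("LOW", "AVERAGE", "HIGH"), repeat=3):
        s = sum(_INPUT_SCORE[t] for t in combo)
        rules.append(FuzzyRule(antecedent=combo, consequent=_SUM_TO_STAGE[s]))
    return rules


@dataclass(frozen=True)
class FuzzySystem:
    """A complete Mamdani system: variables, rule base and defuzzification grid."""

    inputs: tuple[LinguisticVariable, ...]
    output: LinguisticVariable
    rules: tuple[FuzzyRule, ...]
    grid_step: float = 0.005

    def __post_init__(self) -> None:
        for rule in self.rules:
            if len(rule.antecedent) != len(self.inputs):
                raise ValueError("rule arity must match the number of inputs")
            for var, lab in zip(self.inputs, rule.antecedent):
                var.term(lab)
            self.output.term(rule.consequent)

    @property
    def grid(self) -> np.ndarray:
        lo, hi = self.output.domain
        n = int(round((hi - lo) / self.grid_step)) + 1
        return np.linspace(lo, hi, n)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def var(v: LinguisticVariable) -> dict:
            return {"name": v.name, "domain": list(v.domain),
                    "terms": {lab: [mf.a, mf.b, mf.c] for lab, mf in v.terms}}

        return {
            "inputs": [var(v) for v in self.inputs],
            "output": var(self.output),
            "rules": [{"if": list(r.antecedent), "then": r.consequent} for r in self.rules],
            "grid_step": self.grid_step,
        }

    def save(self, path) -> None:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False) if str(path).endswith(
            (".yml", ".yaml")) else json.dumps(self.to_dict(), indent=1)
        with open(path, "w") as fh:
            fh.write(text)

    @classmethod
    def from_dict(cls, d: Mapping) -> "FuzzySystem":
        def var(v: Mapping) -> LinguisticVariable:
            return LinguisticVariable(
                name=v["name"], domain=tuple(v["domain"]),
                terms=tuple((lab, TriangularMF(*abc)) for lab, abc in v["terms"].items()),
            )

        return cls(
            inputs=tuple(var(v) for v in d["inputs"]),
            output=var(d["output"]),
            rules=tuple(FuzzyRule(tuple(r["if"]), r["then"]) for r in d["rules"]),
            grid_step=float(d.get("grid_step", 0.005)),
        )

    @classmethod
    def load(cls, path) -> "FuzzySystem":
        with open(path) as fh:
            text = fh.read()
        d = yaml.safe_load(text)
        return cls.from_dict(d)


def default_system(grid_step: float = 0.005) -> FuzzySystem:
    """The reaction-stage system: AVG1-3 inputs, five-stage output, 27 rules."""
    inputs = tuple(
        LinguisticVariable(name=f"AVG{i}", domain=(0.0, 10.0), terms=INPUT_TERMS)
        for i in (1, 2, 3)
    )
    output = LinguisticVariable(name="ReactionStage", domain=(0.0, 10.0), terms=OUTPUT_TERMS)
    return FuzzySystem(inputs=inputs, output=output,
                       rules=tuple(complete_rule_base()), grid_step=grid_step)


def _sanitize_inputs(system: FuzzySystem, values: Sequence[float]) -> list[float]:
    if len(values) != len(system.inputs):
        raise ValueError(f"expected {len(system.inputs)} inputs, got {len(values)}")
    out = []
    for var, v in zip(system.inputs, values):
        lo, hi = var.domain
        v = float(v)
        if v < lo or v > hi:
            logger.warning("%s=%.4g outside [%g, %g]; clipping", var.name, v, lo, hi)
            v = min(max(v, lo), hi)
        # Pure triangles have zero membership at the exact domain edges;
        # nudge edge inputs inward by one grid step rather than reshaping MFs.
        if v == lo or v == hi:
            logger.warning("%s at domain edge; nudging inward by one grid step", var.name)
            v = lo + system.grid_step if v == lo else hi - system.grid_step
        out.append(v)
    return out


def rule_strengths(system: FuzzySystem, values: Sequence[float]) -> np.ndarray:
    """Firing strength of every rule: min of its antecedent memberships."""
    vals = _sanitize_inputs(system, values)
    degrees = [
        {lab: membership(mf, v) for lab, mf in var.terms}
        for var, v in zip(system.inputs, vals)
    ]
    return np.array([
        min(degrees[i][lab] for i, lab in enumerate(rule.antecedent))
        for rule in system.rules
    ])


def infer(system: FuzzySystem, values: Sequence[float]) -> np.ndarray:
    """Aggregated output membership on the defuzzification grid.

    Min implication clips each rule's consequent at the rule's firing
    strength; max aggregation takes the pointwise maximum across rules.
    """
    strengths = rule_strengths(system, values)
    grid = system.grid
    aggregate = np.zeros_like(grid)
    for rule, s in zip(system.rules, strengths):
        if s <= 0:
            continue
        clipped = np.minimum(membership(system.output.term(rule.consequent), grid), s)
        aggregate = np.maximum(aggregate, clipped)
    return aggregate


def defuzzify_centroid(system: FuzzySystem, aggregate: np.ndarray) -> float:
    """Centre of mass of the aggregated membership over the output grid."""
    grid = system.grid
    total = float(aggregate.sum())
    if total == 0.0:
        raise NoRuleFiredError("aggregate membership is identically zero")
    return float((grid * aggregate).sum() / total)


def stage_label(system: FuzzySystem, values: Sequence[float]) -> tuple[float, str]:
    """(crisp score, stage label) for one input triple.

    The label is the output term with the largest clipped activation; a tie
    goes to the term whose peak lies nearest the crisp score.
    """
    strengths = rule_strengths(system, values)
    score = defuzzify_centroid(system, infer(system, values))
    activation: dict[str, float] = {lab: 0.0 for lab in system.output.labels}
    for rule, s in zip(system.rules, strengths):
        activation[rule.consequent] = max(activation[rule.consequent], float(s))
    best = max(
        activation.items(),
        key=lambda kv: (kv[1], -abs(system.output.term(kv[0]).b - score)),
    )
    return score, best[0]


# -- analytic reference ----------------------------------------------------

def clipped_triangle_centroid(mfs_and_heights: Sequence[tuple[TriangularMF, float]],
                              resolution: int = 200_000) -> float:
    """Exact-piecewise centroid of a max-aggregate of clipped triangles.

    Integrates x*mu(x) and mu(x) with the trapezoid rule on a dense grid
    over the union support, independently of the inference engine's grid
    machinery.  Used as a cross-check oracle, not in the inference path.
    """
    los = [mf.a for mf, _ in mfs_and_heights]
    his = [mf.c for mf, _ in mfs_and_heights]
    x = np.linspace(min(los), max(his), resolution)
    mu = np.zeros_like(x)
    for mf, h in mfs_and_heights:
        mu = np.maximum(mu, np.minimum(membership(mf, x), h))
    num = np.trapezoid(x * mu, x)
    den = np.trapezoid(mu, x)
    if den == 0:
        raise NoRuleFiredError("zero-area aggregate")
    return float(num / den)
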