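"""Mamdani inference and centroid defuzzification.

Inference family: min for conjunction (AND), clipping for implication, max for
aggregation across rules with the same consequent — the canonical type-1 fuzzy
controller.  Each disease owns a two-term output space on [0, 1] (ABSENT and
PRESENT triangles); the aggregated, clipped union of the two sets is collapsed
to a crisp score by its center of gravity.

With the default symmetric output sets the score range is [0.16, 0.84]: full
activation of PRESENT lands exactly on the 0.84 ceiling, a balanced 0.5/0.5
case defuzzifies to 0.50, and full ABSENT gives the 0.16 floor.  Scores are
possibilities, not probabilities — they carry no sum-to-one constraint across
diseases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping, Sequence

import numpy as np

from .config import ReferenceConfig, fuzzify_record
from .errors import InferenceError
from .labels import ALL_DISEASES, DiseaseLabel, LabParameter
from .membership import FuzzifiedValue, MembershipFunction
from .records import PatientRecord
from .rules import ABSENT, PRESENT, FuzzyRule, RuleBase

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OutputPartition:
    """Per-disease output space on [0, 1] with ABSENT and PRESENT fuzzy sets.

    Defaults: ABSENT triangle (0, 0.16, 0.32) and PRESENT triangle
    (0.68, 0.84, 1.0), whose centroids at full activation are 0.16 and 0.84.
    ``grid_points`` sets the fixed integration grid for the center-of-gravity
    computation; 8001 points keep the quadrature error well below the score's
    two-decimal reporting precision.
    """

    absent: MembershipFunction = MembershipFunction.triangle(0.0, 0.16, 0.32)
    present: MembershipFunction = MembershipFunction.triangle(0.68, 0.84, 1.0)
    grid_points: int = 8001

    def __post_init__(self) -> None:
        for mf in (self.absent, self.present):
            if mf.a < 0.0 or mf.d > 1.0:
                raise ValueError("output sets must lie within [0, 1]")
        if self.grid_points < 2001:
            raise ValueError("defuzzification grid needs at least 2001 points")

    @cached_property
    def _grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x = np.linspace(0.0, 1.0, self.grid_points)
        mu_absent = np.array([self.absent(v) for v in x])
        mu_present = np.array([self.present(v) for v in x])
        return x, mu_absent, mu_present


def rule_activation(
    rule: FuzzyRule, fuzzified: Mapping[LabParameter, FuzzifiedValue]
) -> float:
    """Firing strength: weight times the min over antecedent clause degrees."""
    degrees = []
    for param, category in rule.antecedent:
        if param not in fuzzified:
            raise InferenceError(
                f"rule for {rule.disease.value} references parameter "
                f"{param.value} which was not fuzzified"
            )
        degrees.append(fuzzified[param].degree(category))
    return rule.weight * min(degrees)


def aggregate_activation(
    rules: RuleBase,
    fuzzified: Mapping[LabParameter, FuzzifiedValue],
    disease: DiseaseLabel,
) -> tuple[float, float]:
    """Max-aggregated (present, absent) activations for one disease.

    Absent defaults to the complement ``1 - present``; explicit ABSENT rules
    can only raise it further.
    """
    present = max(
        (rule_activation(r, fuzzified) for r in rules.rules_for(disease, PRESENT)),
        default=0.0,
    )
    absent = max(
        (rule_activation(r, fuzzified) for r in rules.rules_for(disease, ABSENT)),
        default=0.0,
    )
    return present, max(absent, 1.0 - present)


def defuzzify_centroid(
    present: float, absent: float, out: OutputPartition | None = None
) -> float:
    """Center of gravity of the clipped union of the two output sets.

    The union takes, at every grid point, the larger of the two clipped
    memberships; the centroid is evaluated by trapezoidal quadrature on the
    partition's fixed grid.  Both activations zero is degenerate: the score
    falls back to 0.0 with a warning (the complement convention never
    produces this case from ``aggregate_activation``).
    """
    if out is None:
        out = _DEFAULT_OUTPUT
    if present == 0.0 and absent == 0.0:
        logger.warning("defuzzifying empty output set; returning 0.0")
        return 0.0
    x, mu_a, mu_p = out._grid
    mu = np.maximum(np.minimum(mu_a, absent), np.minimum(mu_p, present))
    area = np.trapezoid(mu, x)
    return float(np.trapezoid(mu * x, x) / area)


def defuzzify_mean_of_maxima(
    present: float, absent: float, out: OutputPartition | None = None
) -> float:
    """Mean-of-maxima alternative defuzzifier (config option, untuned)."""
    if out is None:
        out = _DEFAULT_OUTPUT
    if present == 0.0 and absent == 0.0:
        logger.warning("defuzzifying empty output set; returning 0.0")
        return 0.0
    x, mu_a, mu_p = out._grid
    mu = np.maximum(np.minimum(mu_a, absent), np.minimum(mu_p, present))
    peak = mu.max()
    return float(x[np.isclose(mu, peak)].mean())


_DEFAULT_OUTPUT = OutputPartition()

_DEFUZZIFIERS = {
    "centroid": defuzzify_centroid,
    "mom": defuzzify_mean_of_maxima,
}


@dataclass(frozen=True)
class DiseaseScoreVector:
    """Defuzzified score per disease, with artifact-version provenance."""

    scores: Mapping[DiseaseLabel, float]
    config_version: str = ""
    rulebase_version: str = ""

    def __getitem__(self, disease: DiseaseLabel) -> float:
        return self.scores[disease]

    def items(self):
        return self.scores.items()


@dataclass(frozen=True)
class RankedDiagnosis:
    """Top-N entries (descending score, index-ascending ties) above threshold."""

    entries: tuple[tuple[DiseaseLabel, float], ...]
    threshold: float
    cap: int

    def labels(self) -> tuple[DiseaseLabel, ...]:
        return tuple(d for d, _ in self.entries)

    def top(self, n: int) -> tuple[DiseaseLabel, ...]:
        return tuple(d for d, _ in self.entries[:n])

    def __str__(self) -> str:
        return "|".join(f"{d.value}:{s:.2f}" for d, s in self.entries)


def diagnose(
    record: PatientRecord,
    config: ReferenceConfig,
    rules: RuleBase,
    output: OutputPartition | None = None,
    defuzzifier: str = "centroid",
) -> DiseaseScoreVector:
    """Run the full pipeline on one record: fuzzify, infer, defuzzify."""
    try:
        defuzz = _DEFUZZIFIERS[defuzzifier]
    except KeyError:
        raise ValueError(f"unknown defuzzifier {defuzzifier!r}") from None
    fuzzified = fuzzify_record(record, config)
    scores = {}
    for disease in ALL_DISEASES:
        present, absent = aggregate_activation(rules, fuzzified, disease)
        scores[disease] = defuzz(present, absent, output)
    return DiseaseScoreVector(
        scores, config_version=config.version, rulebase_version=rules.version
    )


def rank_diagnoses(
    scores: DiseaseScoreVector, n: int = 8, threshold: float = 0.25
) -> RankedDiagnosis:
    """Order diseases by score (descending; ties by ascending disease index),
    keep those at or above ``threshold``, and cap the list at ``n``."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0].index))
    kept = [(d, s) for d, s in ordered if s >= threshold][:n]
    return RankedDiagnosis(tuple(kept), threshold=threshold, cap=n)
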