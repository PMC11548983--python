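"""Synthetic CBC cohort generation with the rule base's categorical structure.

Each disease has a *signature*: a target linguistic category per lab
parameter (or "any").  A record is generated by sampling each parameter
uniformly on its target category's plateau for the record's demographic
partition and perturbing it with centred Gaussian boundary noise whose scale
is ``sigma`` times the width of the nearer transition band; ``sigma = 0``
therefore yields records whose fuzzified degrees are exactly 1 in the target
categories.

Diseases sharing a crisp signature (e.g. the three microcytic-anisocytic
anemias) are inherently indistinguishable to the engine, so recovery
statements are made at the level of *signature groups*: the set of diseases
attaining the maximal score on a disease's pure (noise-free) signature
record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .config import ReferenceConfig
from .engine import RankedDiagnosis, diagnose, rank_diagnoses
from .errors import GenerationError
from .fixtures import table2_fixture
from .labels import (
    ALL_PARAMETERS,
    AgeGroup,
    DemographicGroup,
    DiseaseLabel,
    Gender,
    LabParameter,
)
from .records import LabeledRecord, PatientRecord
from .rules import RuleBase

ANY = "any"

Signature = Mapping[LabParameter, str]

_L, _N, _H = "LOW", "NORMAL", "HIGH"

#: Default disease signatures, consistent with the shipped rule base's
#: antecedents (anemias carry LOW Hb and LOW PCV; dehydration concentrates
#: the blood, raising PCV at normal Hb; polycythemia raises both).
DEFAULT_SIGNATURES: dict[DiseaseLabel, dict[LabParameter, str]] = {
    DiseaseLabel.D0: {LabParameter.MCV: _N, LabParameter.RDW: _N, LabParameter.HB: _N, LabParameter.PCV: _N},
    DiseaseLabel.D1: {LabParameter.MCV: _L, LabParameter.RDW: _N, LabParameter.HB: _L, LabParameter.PCV: _L},
    DiseaseLabel.D2: {LabParameter.MCV: _L, LabParameter.RDW: _N, LabParameter.HB: _L, LabParameter.PCV: _L},
    DiseaseLabel.D3: {LabParameter.MCV: _L, LabParameter.RDW: _H, LabParameter.HB: _L, LabParameter.PCV: _L},
    DiseaseLabel.D4: {LabParameter.MCV: _L, LabParameter.RDW: _H, LabParameter.HB: _L, LabParameter.PCV: _L},
    DiseaseLabel.D5: {LabParameter.MCV: _L, LabParameter.RDW: _H, LabParameter.HB: _L, LabParameter.PCV: _L},
    DiseaseLabel.D6: {LabParameter.MCV: _H, LabParameter.RDW: _N, LabParameter.HB: _L, LabParameter.PCV: _L},
    DiseaseLabel.D7: {LabParameter.MCV: _H, LabParameter.RDW: _N, LabParameter.HB: _L, LabParameter.PCV: _L},
    DiseaseLabel.D8: {LabParameter.MCV: _H, LabParameter.RDW: _H, LabParameter.HB: _L, LabParameter.PCV: _L},
    DiseaseLabel.D9: {LabParameter.MCV: _H, LabParameter.RDW: _H, LabParameter.HB: _L, LabParameter.PCV: _L},
    DiseaseLabel.D10: {LabParameter.MCV: _N, LabParameter.RDW: _N, LabParameter.HB: _L, LabParameter.PCV: _L},
    DiseaseLabel.D11: {LabParameter.MCV: _N, LabParameter.RDW: _N, LabParameter.HB: _L, LabParameter.PCV: _L},
    DiseaseLabel.D12: {LabParameter.MCV: _N, LabParameter.RDW: _H, LabParameter.HB: _L, LabParameter.PCV: _L},
    DiseaseLabel.D13: {LabParameter.MCV: _N, LabParameter.RDW: _H, LabParameter.HB: _L, LabParameter.PCV: _L},
    DiseaseLabel.D14: {LabParameter.MCV: _N, LabParameter.RDW: _H, LabParameter.HB: _L, LabParameter.PCV: _L},
    DiseaseLabel.D15: {LabParameter.MCV: _N, LabParameter.RDW: _N, LabParameter.HB: _H, LabParameter.PCV: _H},
    DiseaseLabel.D16: {LabParameter.MCV: _N, LabParameter.RDW: _N, LabParameter.HB: _N, LabParameter.PCV: _H},
    DiseaseLabel.D17: {LabParameter.MCV: _N, LabParameter.RDW: _N, LabParameter.HB: _L, LabParameter.PCV: _L},
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Per (disease, demographic) record counts plus noise level and seed.

    ``sigma`` is the boundary-noise scale as a fraction of the adjacent
    transition-band width; 0 produces categorically pure records.
    """

    counts: tuple[tuple[DiseaseLabel, DemographicGroup, int], ...]
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise GenerationError(f"sigma must be >= 0, got {self.sigma}")
        if any(n < 0 for _, _, n in self.counts):
            raise GenerationError("record counts must be >= 0")

    @property
    def total(self) -> int:
        return sum(n for _, _, n in self.counts)


def cohort_spec_from_table2(sigma: float = 0.0, seed: int = 0) -> SyntheticCohortSpec:
    """A cohort spec mirroring the printed 311-record test-set composition."""
    df = table2_fixture()
    counts: list[tuple[DiseaseLabel, DemographicGroup, int]] = []
    for code, row in df.iterrows():
        disease = DiseaseLabel(code)
        for gender, prefix in ((Gender.G1, "g1"), (Gender.G2, "g2")):
            for age in AgeGroup:
                n = int(row[f"{prefix}_{age.value.lower()}"])
                if n:
                    counts.append((disease, DemographicGroup(gender, age), n))
        n = int(row["g3"])
        if n:
            counts.append((disease, DemographicGroup(Gender.G3, AgeGroup.A5), n))
    return SyntheticCohortSpec(tuple(counts), sigma=sigma, seed=seed)


def _plateau(config: ReferenceConfig, param: LabParameter, demo: DemographicGroup,
             category: str) -> tuple[float, float, float]:
    """(plateau lo, plateau hi, adjacent band width) of a target category."""
    partition = config.partition_for(param, demo)
    if category == ANY:
        lo, hi = partition.universe
        return lo, hi, 0.0
    try:
        mf = partition.function(category)
    except KeyError:
        raise GenerationError(
            f"category {category!r} not in the {param.value} partition for {demo}"
        ) from None
    left_band = mf.b - mf.a
    right_band = mf.d - mf.c
    return mf.b, mf.c, max(left_band, right_band)


def generate_record(
    disease: DiseaseLabel,
    demo: DemographicGroup,
    config: ReferenceConfig,
    signatures: Mapping[DiseaseLabel, Signature] | None = None,
    sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    record_id: str = "synthetic",
) -> PatientRecord:
    """Sample one record from a disease signature's category plateaus."""
    signatures = DEFAULT_SIGNATURES if signatures is None else signatures
    if disease not in signatures:
        raise GenerationError(f"no signature defined for {disease.value}")
    rng = np.random.default_rng() if rng is None else rng
    sig = signatures[disease]
    values: dict[LabParameter, float] = {}
    for param in ALL_PARAMETERS:
        category = sig.get(param, ANY)
        lo, hi, band = _plateau(config, param, demo, category)
        x = float(rng.uniform(lo, hi))
        if sigma > 0 and band > 0:
            x += float(rng.normal(0.0, sigma * band))
        ulo, uhi = config.partition_for(param, demo).universe
        values[param] = min(max(x, ulo), uhi)
    return PatientRecord(
        record_id=record_id,
        gender=demo.gender,
        age_group=demo.age,
        mcv=values[LabParameter.MCV],
        rdw=values[LabParameter.RDW],
        hb=values[LabParameter.HB],
        pcv=values[LabParameter.PCV],
    )


def generate_cohort(
    spec: SyntheticCohortSpec,
    config: ReferenceConfig,
    signatures: Mapping[DiseaseLabel, Signature] | None = None,
) -> list[LabeledRecord]:
    """Generate the full cohort, truth-labeled by the generating disease and
    shuffled deterministically by the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    out: list[LabeledRecord] = []
    for disease, demo, n in spec.counts:
        for i in range(n):
            rec = generate_record(
                disease, demo, config, signatures, spec.sigma, rng,
                record_id=f"{disease.value}-{demo.gender.value}{demo.age.value}-{i}",
            )
            out.append(
                LabeledRecord(rec, professional=(disease,), further=disease, later=disease)
            )
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def signature_group(
    disease: DiseaseLabel,
    config: ReferenceConfig,
    rules: RuleBase,
    signatures: Mapping[DiseaseLabel, Signature] | None = None,
    demo: DemographicGroup | None = None,
) -> frozenset[DiseaseLabel]:
    """Diseases attaining the maximal score on this disease's pure signature.

    Computed by diagnosing the plateau-midpoint record of the signature for
    the given demographic (default: adult female).  Members of one group are
    indistinguishable from the engine's point of view.
    """
    signatures = DEFAULT_SIGNATURES if signatures is None else signatures
    if disease not in signatures:
        raise GenerationError(f"no signature defined for {disease.value}")
    demo = demo or DemographicGroup(Gender.G2, AgeGroup.A5)
    sig = signatures[disease]
    values: dict[LabParameter, float] = {}
    for param in ALL_PARAMETERS:
        category = sig.get(param, ANY)
        lo, hi, _ = _plateau(config, param, demo, category)
        values[param] = (lo + hi) / 2.0
    record = PatientRecord(
        record_id=f"signature-{disease.value}",
        gender=demo.gender,
        age_group=demo.age,
        mcv=values[LabParameter.MCV],
        rdw=values[LabParameter.RDW],
        hb=values[LabParameter.HB],
        pcv=values[LabParameter.PCV],
    )
    scores = diagnose(record, config, rules)
    peak = max(scores.scores.values())
    return frozenset(d for d, s in scores.items() if s == peak)


def topn_group_recall(
    cohort: list[LabeledRecord],
    predictions: list[RankedDiagnosis],
    config: ReferenceConfig,
    rules: RuleBase,
    n: int = 1,
    signatures: Mapping[DiseaseLabel, Signature] | None = None,
) -> float:
    """Fraction of records whose top-N predictions intersect the truth's
    signature group (per-demographic), the recovery statistic for synthetic
    cohorts."""
    groups: dict[tuple[DiseaseLabel, DemographicGroup], frozenset[DiseaseLabel]] = {}
    hit = 0
    for rec, pred in zip(cohort, predictions):
        truth = rec.professional[0]
        demo = rec.record.demographic
        key = (truth, demo)
        if key not in groups:
            groups[key] = signature_group(truth, config, rules, signatures, demo)
        if groups[key] & set(pred.top(n)):
            hit += 1
    return hit / len(cohort) if cohort else 0.0
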