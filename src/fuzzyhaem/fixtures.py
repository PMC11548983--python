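"""Machine-readable transcriptions of the publication's printed tables.

Two fixtures ship with the package so every stage is testable without any
external download:

- the per-disease, per-demographic sample counts of the 311-record test
  cohort (``table2_fixture``), and
- the 22 printed worked cases with their system score lists and the
  professional / further / later ground-truth columns (``table3_fixture``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import ValidationError
from .labels import AgeGroup, DiseaseLabel, Gender
from .records import LabeledRecord, PatientRecord

_RANGE_RE = re.compile(r"^D(\d+)-(\d+)$")


def _resource(name: str):
    return resources.files("fuzzyhaem.data").joinpath(name)


def table2_fixture() -> pd.DataFrame:
    """Cohort composition counts, indexed by disease code.

    Columns ``g1_a1`` ... ``g1_a5`` and ``g2_a1`` ... ``g2_a5`` are the male
    and female age strata, ``g3`` the pregnant-female stratum (not age
    stratified in the source), ``total`` the printed row total.
    """
    with _resource("table2_counts.csv").open() as fh:
        df = pd.read_csv(fh, index_col="disease")
    counts = df.drop(columns="total").sum(axis=1)
    mismatch = df.index[counts != df["total"]].tolist()
    if mismatch:  # pragma: no cover - fixture integrity
        raise ValidationError(f"fixture row totals do not add up for {mismatch}")
    return df


def expand_disease_labels(token: str) -> tuple[DiseaseLabel, ...]:
    """Expand a printed label token; ranges like 'D3-5' mean D3, D4, D5."""
    token = token.strip()
    m = _RANGE_RE.match(token)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        return tuple(DiseaseLabel(f"D{i}") for i in range(lo, hi + 1))
    return (DiseaseLabel(token),)


@dataclass(frozen=True)
class WorkedCase:
    """One printed worked case: the labeled record plus the system's printed
    (disease, score) list."""

    labeled: LabeledRecord
    printed_output: tuple[tuple[DiseaseLabel, float], ...]


def table3_fixture() -> list[WorkedCase]:
    """The 22 printed worked cases with their system outputs."""
    with _resource("table3_cases.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"id": str})
    cases = []
    for row in df.itertuples(index=False):
        record = PatientRecord(
            record_id=row.id,
            gender=Gender(row.gender),
            age_group=AgeGroup(row.age_group),
            mcv=float(row.mcv),
            rdw=float(row.rdw),
            hb=float(row.hb),
            pcv=float(row.pcv),
        )
        professional = expand_disease_labels(row.professional_1) + expand_disease_labels(
            row.professional_2
        )
        labeled = LabeledRecord(
            record=record,
            professional=professional,
            further=DiseaseLabel(row.further),
            later=DiseaseLabel(row.later),
        )
        printed = tuple(
            (DiseaseLabel(part.split(":")[0]), float(part.split(":")[1]))
            for part in str(row.system_output).split("|")
        )
        cases.append(WorkedCase(labeled, printed))
    return cases


def table3_records() -> list[LabeledRecord]:
    return [case.labeled for case in table3_fixture()]
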