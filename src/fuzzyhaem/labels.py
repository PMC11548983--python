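"""Domain enumerations: lab parameters, demographic groups, disease labels.

The system reads four red-cell indices from a complete blood count (CBC) —
MCV, RDW, Hb and PCV — and scores 18 diagnostic labels (D0 "normal" plus 17
diseases, mostly anemias) stratified by sex group (G1 male, G2 female,
G3 pregnant female) and age group (A1 infants through A5 adults).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class LabParameter(enum.Enum):
    """The four CBC indices the engine consumes.

    Units: MCV in fL, RDW in % (it is a coefficient of variation of red-cell
    volume; some sources mislabel it fL), Hb in g/dL, PCV (hematocrit) in %.
    """

    MCV = "MCV"
    RDW = "RDW"
    HB = "HB"
    PCV = "PCV"

    @property
    def units(self) -> str:
        return _UNITS[self]

    @property
    def universe(self) -> tuple[float, float]:
        """Default universe of discourse (plausible physical range)."""
        return _UNIVERSE[self]


_UNITS = {
    LabParameter.MCV: "fL",
    LabParameter.RDW: "%",
    LabParameter.HB: "g/dL",
    LabParameter.PCV: "%",
}

# Wide enough to cover extreme but real pathology values; inputs outside are
# clamped with a warning rather than rejected.
_UNIVERSE = {
    LabParameter.MCV: (40.0, 160.0),
    LabParameter.RDW: (5.0, 35.0),
    LabParameter.HB: (2.0, 25.0),
    LabParameter.PCV: (10.0, 75.0),
}


class Gender(enum.Enum):
    G1 = "G1"  # male
    G2 = "G2"  # female
    G3 = "G3"  # female (pregnant)


class AgeGroup(enum.Enum):
    A1 = "A1"  # 1 day to 2 months
    A2 = "A2"  # 2 months to 6 months
    A3 = "A3"  # 6 months to 6 years
    A4 = "A4"  # 6 years to 18 years
    A5 = "A5"  # over 18 years


@dataclass(frozen=True)
class DemographicGroup:
    """A (sex group, age group) stratum; 15 combinations are representable."""

    gender: Gender
    age: AgeGroup

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.gender.value}/{self.age.value}"


#: Age-group boundaries in years, half-open intervals [lower, upper).
AGE_BOUNDS_YEARS: list[tuple[float, float, AgeGroup]] = [
    (0.0, 2 / 12, AgeGroup.A1),
    (2 / 12, 6 / 12, AgeGroup.A2),
    (6 / 12, 6.0, AgeGroup.A3),
    (6.0, 18.0, AgeGroup.A4),
    (18.0, float("inf"), AgeGroup.A5),
]


def age_group_from_years(age_years: float) -> AgeGroup:
    """Map a raw age in years to its A1-A5 group (half-open [lower, upper))."""
    if age_years < 0:
        raise ValueError(f"age must be non-negative, got {age_years}")
    for lo, hi, group in AGE_BOUNDS_YEARS:
        if lo <= age_years < hi:
            return group
    raise AssertionError("unreachable")  # pragma: no cover


class DiseaseLabel(enum.Enum):
    """The 18 diagnostic labels D0 (normal) through D17."""

    D0 = "D0"
    D1 = "D1"
    D2 = "D2"
    D3 = "D3"
    D4 = "D4"
    D5 = "D5"
    D6 = "D6"
    D7 = "D7"
    D8 = "D8"
    D9 = "D9"
    D10 = "D10"
    D11 = "D11"
    D12 = "D12"
    D13 = "D13"
    D14 = "D14"
    D15 = "D15"
    D16 = "D16"
    D17 = "D17"

    @property
    def index(self) -> int:
        return int(self.value[1:])

    @property
    def condition(self) -> str:
        return _DISEASE_NAMES[self]


_DISEASE_NAMES = {
    DiseaseLabel.D0: "Normal",
    DiseaseLabel.D1: "Thalassemia carrier",
    DiseaseLabel.D2: "Anemia of chronic disease",
    DiseaseLabel.D3: "Iron deficiency anemia",
    DiseaseLabel.D4: "Hemoglobin H disease",
    DiseaseLabel.D5: "Sickle cell beta thalassemia",
    DiseaseLabel.D6: "Myelodysplastic syndrome",
    DiseaseLabel.D7: "Aplastic anemia",
    DiseaseLabel.D8: "Megaloblastic anemia",
    DiseaseLabel.D9: "Immune hemolytic anemia",
    DiseaseLabel.D10: "Sickle cell trait",
    DiseaseLabel.D11: "Hereditary spherocytosis",
    DiseaseLabel.D12: "Sideroblastic anemia",
    DiseaseLabel.D13: "Myelofibrosis",
    DiseaseLabel.D14: "Sickle cell anemia",
    DiseaseLabel.D15: "Polycythemia vera",
    DiseaseLabel.D16: "Dehydration",
    DiseaseLabel.D17: "Anemia",
}

ALL_DISEASES: tuple[DiseaseLabel, ...] = tuple(DiseaseLabel)
ALL_PARAMETERS: tuple[LabParameter, ...] = tuple(LabParameter)
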