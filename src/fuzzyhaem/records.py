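"""Patient record containers shared by IO, inference and evaluation."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError
from .labels import AgeGroup, DemographicGroup, DiseaseLabel, Gender, LabParameter


@dataclass(frozen=True)
class PatientRecord:
    """One CBC panel row: demographics plus the four red-cell indices."""

    record_id: str
    gender: Gender
    age_group: AgeGroup
    mcv: float  # fL
    rdw: float  # %
    hb: float   # g/dL
    pcv: float  # %

    def __post_init__(self) -> None:
        for name in ("mcv", "rdw", "hb", "pcv"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValidationError(
                    f"record {self.record_id!r}: field {name!r} must be a "
                    f"finite positive number, got {v!r}"
                )

    @property
    def demographic(self) -> DemographicGroup:
        return DemographicGroup(self.gender, self.age_group)

    def value(self, parameter: LabParameter) -> float:
        return {
            LabParameter.MCV: self.mcv,
            LabParameter.RDW: self.rdw,
            LabParameter.HB: self.hb,
            LabParameter.PCV: self.pcv,
        }[parameter]


@dataclass(frozen=True)
class LabeledRecord:
    """A patient record with its clinical ground-truth annotations.

    ``professional`` holds the professional's most-probable diagnoses (ranges
    like "D3-5" expand to the individual labels, so more than two entries may
    result); ``further`` is the outcome of further diagnostic work-up and
    ``later`` the disease that appeared later in the patient's history.
    """

    record: PatientRecord
    professional: tuple[DiseaseLabel, ...]
    further: DiseaseLabel | None = None
    later: DiseaseLabel | None = None

    def __post_init__(self) -> None:
        if not self.professional:
            raise ValidationError(
                f"record {self.record.record_id!r}: professional diagnosis "
                "list must be non-empty"
            )

    def truth(self, selector: str) -> DiseaseLabel:
        """Resolve one ground-truth label: 'first', 'further' or 'later'."""
        if selector == "first":
            return self.professional[0]
        if selector == "further":
            if self.further is None:
                raise ValidationError(
                    f"record {self.record.record_id!r} has no further-diagnosis label"
                )
            return self.further
        if selector == "later":
            if self.later is None:
                raise ValidationError(
                    f"record {self.record.record_id!r} has no later-disease label"
                )
            return self.later
        raise ValueError(f"unknown truth selector {selector!r}")
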