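"""Demographic-stratified reference configuration and record fuzzification.

A :class:`ReferenceConfig` maps every (lab parameter, demographic group) pair
to a :class:`~fuzzyhaem.membership.FuzzyPartition`.  The shipped default
encodes standard sex- and age-stratified hematology reference intervals as
LOW/NORMAL/HIGH partitions with complementary transition bands; the two adult
transition bands that published worked examples pin down (RDW LOW->NORMAL
[10.0, 12.5], MCV LOW->NORMAL [76.5, 81.5]) are calibrated to those anchors,
and the adult-female Hb lower band end (12.0113 g/dL) is solved so that a
textbook normal female panel with Hb 12.0 g/dL scores 0.83 for "normal".
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from .errors import ConfigurationError, ValidationError
from .labels import (
    ALL_PARAMETERS,
    AgeGroup,
    DemographicGroup,
    Gender,
    LabParameter,
)
from .membership import FuzzifiedValue, FuzzyPartition, MembershipFunction
from .records import PatientRecord

logger = logging.getLogger(__name__)

_Key = tuple[LabParameter, Gender, AgeGroup]


@dataclass
class ReferenceConfig:
    """Total map (parameter, demographic) -> partition, with JSON round-trip.

    Lookup falls back from an exact (gender, age) entry to the same gender's
    adult (A5) entry, so sparse configurations remain total; the shipped
    default populates all 15 strata explicitly.
    """

    partitions: dict[_Key, FuzzyPartition]
    version: str = "0"
    provenance: str = ""

    def partition_for(
        self, parameter: LabParameter, demo: DemographicGroup
    ) -> FuzzyPartition:
        key = (parameter, demo.gender, demo.age)
        if key in self.partitions:
            return self.partitions[key]
        fallback = (parameter, demo.gender, AgeGroup.A5)
        if fallback in self.partitions:
            logger.warning(
                "no %s partition for %s; falling back to %s/A5",
                parameter.value, demo, demo.gender.value,
            )
            return self.partitions[fallback]
        raise ConfigurationError(
            f"no partition for parameter {parameter.value} and demographic {demo}"
        )

    def vocabulary(self) -> tuple[str, ...]:
        """Union of category labels across all partitions, in first-seen order."""
        seen: dict[str, None] = {}
        for part in self.partitions.values():
            for lab in part.labels:
                seen.setdefault(lab)
        return tuple(seen)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        tree: dict = {}
        for (param, gender, age), part in self.partitions.items():
            tree.setdefault(param.value, {}).setdefault(gender.value, {})[
                age.value
            ] = [
                {
                    "label": lab,
                    "shape": mf.shape,
                    "breakpoints": list(mf.breakpoints()),
                }
                for lab, mf in part.terms
            ]
        return {
            "version": self.version,
            "provenance": self.provenance,
            "partitions": tree,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ReferenceConfig":
        if "partitions" not in doc:
            raise ConfigurationError("config document missing 'partitions'")
        partitions: dict[_Key, FuzzyPartition] = {}
        for pname, by_gender in doc["partitions"].items():
            try:
                param = LabParameter(pname)
            except ValueError:
                raise ConfigurationError(
                    f"partitions.{pname}: unknown lab parameter"
                ) from None
            for gname, by_age in by_gender.items():
                try:
                    gender = Gender(gname)
                except ValueError:
                    raise ConfigurationError(
                        f"partitions.{pname}.{gname}: unknown gender group"
                    ) from None
                for aname, terms in by_age.items():
                    try:
                        age = AgeGroup(aname)
                    except ValueError:
                        raise ConfigurationError(
                            f"partitions.{pname}.{gname}.{aname}: unknown age group"
                        ) from None
                    locus = f"partitions.{pname}.{gname}.{aname}"
                    partitions[(param, gender, age)] = _parse_partition(
                        param, terms, locus
                    )
        missing = [
            p.value for p in ALL_PARAMETERS
            if not any(k[0] == p for k in partitions)
        ]
        if missing:
            raise ConfigurationError(
                f"config defines no partitions for parameter(s): {', '.join(missing)}"
            )
        return cls(
            partitions,
            version=str(doc.get("version", "0")),
            provenance=str(doc.get("provenance", "")),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceConfig":
        try:
            doc = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigurationError(f"{path}: not valid JSON ({exc})") from exc
        config = cls.from_dict(doc)
        logger.info("loaded reference config version %s from %s", config.version, path)
        return config


def _parse_partition(param: LabParameter, terms, locus: str) -> FuzzyPartition:
    if not isinstance(terms, list) or not terms:
        raise ConfigurationError(f"{locus}: expected a non-empty list of terms")
    parsed = []
    for i, t in enumerate(terms):
        try:
            bp = t["breakpoints"]
            label = t["label"]
        except (TypeError, KeyError) as exc:
            raise ConfigurationError(
                f"{locus}[{i}]: term needs 'label' and 'breakpoints'"
            ) from exc
        if len(bp) != 4:
            raise ConfigurationError(
                f"{locus}[{i}]: breakpoints must be [a, b, c, d]"
            )
        try:
            mf = MembershipFunction(*map(float, bp))
        except ConfigurationError as exc:
            raise ConfigurationError(f"{locus}[{i}]: {exc}") from exc
        shape = t.get("shape")
        if shape is not None and shape != mf.shape:
            raise ConfigurationError(
                f"{locus}[{i}]: declared shape {shape!r} does not match "
                f"breakpoints ({mf.shape})"
            )
        parsed.append((str(label), mf))
    universe = (parsed[0][1].a, parsed[-1][1].d)
    try:
        return FuzzyPartition(param, tuple(parsed), universe)
    except ConfigurationError as exc:
        raise ConfigurationError(f"{locus}: {exc}") from exc


def default_config() -> ReferenceConfig:
    """The shipped reference configuration (packaged JSON resource)."""
    with resources.files("fuzzyhaem.data").joinpath("default_config.json").open() as fh:
        return ReferenceConfig.from_dict(json.load(fh))


def fuzzify_record(
    record: PatientRecord, config: ReferenceConfig
) -> dict[LabParameter, FuzzifiedValue]:
    """Fuzzify all four indices of a record with its demographic's partitions."""
    out: dict[LabParameter, FuzzifiedValue] = {}
    for param in ALL_PARAMETERS:
        value = record.value(param)
        if value is None:  # pragma: no cover - PatientRecord forbids this
            raise ValidationError(
                f"record {record.record_id!r}: missing value for {param.value}"
            )
        partition = config.partition_for(param, record.demographic)
        out[param] = partition.fuzzify(value)
    return out
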