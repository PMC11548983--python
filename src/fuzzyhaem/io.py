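"""CSV readers/writers and validated configuration loading.

Record CSV header: ``id, gender, age_group, mcv, rdw, hb, pcv`` plus
``professional_1, professional_2, further, later`` when labeled.  Decimal
points only; errors name the offending row and field.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config import ReferenceConfig
from .engine import DiseaseScoreVector, RankedDiagnosis
from .errors import ConfigurationError, ValidationError
from .fixtures import expand_disease_labels
from .labels import ALL_DISEASES, AgeGroup, DiseaseLabel, Gender
from .records import LabeledRecord, PatientRecord
from .rules import RuleBase, load_rulebase, validate_rulebase

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["id", "gender", "age_group", "mcv", "rdw", "hb", "pcv"]
LABEL_COLUMNS = ["professional_1", "professional_2", "further", "later"]


def _parse_enum(enum_cls, raw, row: int, column: str):
    try:
        return enum_cls(str(raw).strip().upper())
    except ValueError:
        raise ValidationError(
            f"row {row}: invalid {column} code {raw!r}"
        ) from None


def _parse_number(raw, row: int, column: str) -> float:
    try:
        v = float(raw)
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row}: non-numeric value {raw!r} in column {column!r}"
        ) from None
    if not math.isfinite(v):
        raise ValidationError(f"row {row}: non-finite value in column {column!r}")
    return v


def _parse_optional_label(raw, row: int, column: str) -> DiseaseLabel | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if not text or text == "--":
        return None
    try:
        return expand_disease_labels(text)[0]
    except ValueError:
        raise ValidationError(
            f"row {row}: invalid disease label {raw!r} in column {column!r}"
        ) from None


def read_records(
    path: str | Path, labeled: bool = False
) -> list[PatientRecord] | list[LabeledRecord]:
    """Read and validate a record CSV; row numbers refer to data rows (1-based)."""
    try:
        df = pd.read_csv(path, dtype=str)
    except FileNotFoundError:
        raise ValidationError(f"record file not found: {path}") from None
    required = RECORD_COLUMNS + (LABEL_COLUMNS if labeled else [])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing column(s): {', '.join(missing)}"
        )
    out: list = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        record = PatientRecord(
            record_id=str(row.id),
            gender=_parse_enum(Gender, row.gender, i, "gender"),
            age_group=_parse_enum(AgeGroup, row.age_group, i, "age_group"),
            mcv=_parse_number(row.mcv, i, "mcv"),
            rdw=_parse_number(row.rdw, i, "rdw"),
            hb=_parse_number(row.hb, i, "hb"),
            pcv=_parse_number(row.pcv, i, "pcv"),
        )
        if not labeled:
            out.append(record)
            continue
        professional: tuple[DiseaseLabel, ...] = ()
        for col in ("professional_1", "professional_2"):
            raw = getattr(row, col)
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                continue
            text = str(raw).strip()
            if not text or text == "--":
                continue
            try:
                professional += expand_disease_labels(text)
            except ValueError:
                raise ValidationError(
                    f"row {i}: invalid disease label {raw!r} in column {col!r}"
                ) from None
        if not professional:
            raise ValidationError(f"row {i}: no professional diagnosis given")
        out.append(
            LabeledRecord(
                record=record,
                professional=professional,
                further=_parse_optional_label(row.further, i, "further"),
                later=_parse_optional_label(row.later, i, "later"),
            )
        )
    logger.info("read %d record(s) from %s", len(out), path)
    return out


def write_records(path: str | Path, records: Sequence[LabeledRecord]) -> None:
    rows = []
    for lr in records:
        r = lr.record
        rows.append(
            {
                "id": r.record_id,
                "gender": r.gender.value,
                "age_group": r.age_group.value,
                "mcv": f"{r.mcv:.4f}",
                "rdw": f"{r.rdw:.4f}",
                "hb": f"{r.hb:.4f}",
                "pcv": f"{r.pcv:.4f}",
                "professional_1": lr.professional[0].value,
                "professional_2": lr.professional[1].value if len(lr.professional) > 1 else "",
                "further": lr.further.value if lr.further else "",
                "later": lr.later.value if lr.later else "",
            }
        )
    pd.DataFrame(rows, columns=RECORD_COLUMNS + LABEL_COLUMNS).to_csv(path, index=False)


def write_scores(
    path: str | Path,
    scores: Sequence[DiseaseScoreVector],
    rankings: Sequence[RankedDiagnosis],
    ids: Sequence[str] | None = None,
) -> None:
    """Score CSV: one row per record, 18 four-decimal score columns plus a
    ``top_n`` column formatted ``D3:0.84|D4:0.84``."""
    if len(scores) != len(rankings):
        raise ValidationError("scores and rankings must align")
    rows = []
    for i, (vec, rank) in enumerate(zip(scores, rankings)):
        row = {"id": ids[i] if ids is not None else str(i + 1)}
        row.update({d.value: f"{vec[d]:.4f}" for d in ALL_DISEASES})
        row["top_n"] = str(rank)
        rows.append(row)
    columns = ["id"] + [d.value for d in ALL_DISEASES] + ["top_n"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    logger.info("wrote %d score row(s) to %s", len(rows), path)


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read back a score CSV (scores as floats, ``top_n`` as text)."""
    df = pd.read_csv(path, dtype={"id": str, "top_n": str})
    for d in ALL_DISEASES:
        df[d.value] = df[d.value].astype(float)
    return df


def load_validated_bundle(
    config_path: str | Path, rules_path: str | Path
) -> tuple[ReferenceConfig, RuleBase]:
    """Load and cross-validate a configuration plus rule base."""
    config = ReferenceConfig.load(config_path)
    rules = load_rulebase(rules_path, vocab=config.vocabulary())
    report = validate_rulebase(rules, config)
    if not report.ok:
        raise ConfigurationError(
            "rule base fails validation: " + "; ".join(report.defects)
        )
    for warning in report.warnings:
        logger.warning("%s", warning)
    logger.info(
        "loaded bundle: config version %s, rule base version %s (%d rules)",
        config.version, rules.version, len(rules.rules),
    )
    return config, rules
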