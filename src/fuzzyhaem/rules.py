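"""Linguistic IF-THEN rule base: grammar, parser, validation, serialization.

Grammar (case-insensitive, one rule per line, ``#`` comments)::

    IF <param> IS <CATEGORY> [AND <param> IS <CATEGORY>]...
        THEN <Dk> IS <PRESENT|ABSENT> [WEIGHT w]

Antecedents are conjunctions only; disjunction is expressed as several rules
sharing a consequent (standard Mamdani practice).  ABSENT rules are optional:
for every disease the absent activation defaults to the complement
``1 - present`` unless an explicit ABSENT rule fires harder.

The shipped default rule base encodes the classical MCV/RDW anemia
classification matrix (microcytic/normocytic/macrocytic crossed with uniform
or heterogeneous cell size), plus Hb/PCV rules for polycythemia, dehydration,
generic anemia and the all-normal case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .errors import RuleParseError
from .labels import ALL_DISEASES, DiseaseLabel, LabParameter

logger = logging.getLogger(__name__)

PRESENT = "PRESENT"
ABSENT = "ABSENT"


@dataclass(frozen=True)
class FuzzyRule:
    """IF (conjunction of parameter-category clauses) THEN disease is present/absent."""

    antecedent: tuple[tuple[LabParameter, str], ...]
    disease: DiseaseLabel
    term: str  # PRESENT or ABSENT
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.antecedent:
            raise RuleParseError("rule antecedent must be non-empty")
        params = [p for p, _ in self.antecedent]
        if len(set(params)) != len(params):
            raise RuleParseError(
                f"duplicate parameter in antecedent of rule for {self.disease.value}"
            )
        if self.term not in (PRESENT, ABSENT):
            raise RuleParseError(f"output term must be PRESENT or ABSENT, got {self.term}")
        if not (0.0 < self.weight <= 1.0):
            raise RuleParseError(f"rule weight must be in (0, 1], got {self.weight}")


def parse_rule(
    text: str,
    vocab: Iterable[str] | None = None,
    diseases: Iterable[DiseaseLabel] = ALL_DISEASES,
) -> FuzzyRule:
    """Parse one rule line; errors carry the offending token position."""
    tokens = text.upper().split()
    disease_codes = {d.value for d in diseases}
    vocab_set = {v.upper() for v in vocab} if vocab is not None else None
    pos = 0

    def expect(word: str) -> None:
        nonlocal pos
        if pos >= len(tokens) or tokens[pos] != word:
            got = tokens[pos] if pos < len(tokens) else "<end of line>"
            raise RuleParseError(f"expected {word!r}, got {got!r}", pos)
        pos += 1

    def take() -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise RuleParseError("unexpected end of rule", pos)
        tok = tokens[pos]
        pos += 1
        return tok

    expect("IF")
    clauses: list[tuple[LabParameter, str]] = []
    while True:
        pname = take()
        try:
            param = LabParameter(pname)
        except ValueError:
            raise RuleParseError(f"unknown parameter {pname!r}", pos - 1) from None
        expect("IS")
        cat = take()
        if cat in ("THEN", "AND", "IS"):
            raise RuleParseError(f"expected a category, got {cat!r}", pos - 1)
        if vocab_set is not None and cat not in vocab_set:
            raise RuleParseError(f"unknown category {cat!r}", pos - 1)
        clauses.append((param, cat))
        nxt = take()
        if nxt == "THEN":
            break
        if nxt != "AND":
            raise RuleParseError(f"expected 'AND' or 'THEN', got {nxt!r}", pos - 1)
    dcode = take()
    if dcode not in disease_codes:
        raise RuleParseError(f"unknown disease {dcode!r}", pos - 1)
    expect("IS")
    term = take()
    if term not in (PRESENT, ABSENT):
        raise RuleParseError(
            f"expected 'PRESENT' or 'ABSENT', got {term!r}", pos - 1
        )
    weight = 1.0
    if pos < len(tokens):
        expect("WEIGHT")
        wtok = take()
        try:
            weight = float(wtok)
        except ValueError:
            raise RuleParseError(f"weight must be a number, got {wtok!r}", pos - 1) from None
    if pos != len(tokens):
        raise RuleParseError(f"trailing tokens after rule: {tokens[pos]!r}", pos)
    return FuzzyRule(tuple(clauses), DiseaseLabel(dcode), term, weight)


def serialize_rule(rule: FuzzyRule) -> str:
    clauses = " AND ".join(f"{p.value} IS {c}" for p, c in rule.antecedent)
    line = f"IF {clauses} THEN {rule.disease.value} IS {rule.term}"
    if rule.weight != 1.0:
        line += f" WEIGHT {rule.weight:g}"
    return line


@dataclass
class RuleBase:
    """Ordered rule list; order is semantically irrelevant (max-aggregation)."""

    rules: list[FuzzyRule]
    provenance: str = ""
    version: str = "0"

    def rules_for(self, disease: DiseaseLabel, term: str) -> list[FuzzyRule]:
        return [r for r in self.rules if r.disease is disease and r.term == term]

    def diseases_lacking_present(self) -> list[DiseaseLabel]:
        return [d for d in ALL_DISEASES if not self.rules_for(d, PRESENT)]


@dataclass
class RuleBaseReport:
    """validate_rulebase() output.  ``defects`` are structural faults that make
    the bundle unusable; ``warnings`` flag inert input combinations."""

    missing_present: list[DiseaseLabel] = field(default_factory=list)
    unknown_categories: list[str] = field(default_factory=list)
    dead_combinations: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def defects(self) -> list[str]:
        out = [f"{d.value} has no PRESENT rule" for d in self.missing_present]
        out += self.unknown_categories
        return out

    @property
    def warnings(self) -> list[str]:
        return [
            "no rule fires for input combination (" + ", ".join(combo) + ")"
            for combo in self.dead_combinations
        ]

    @property
    def ok(self) -> bool:
        return not self.defects


def validate_rulebase(rb: RuleBase, config) -> RuleBaseReport:
    """Cross-check a rule base against a reference configuration.

    Reports (as defects) diseases without a PRESENT rule and rule clauses whose
    category label exists in no partition of the referenced parameter, and (as
    warnings) crisp input-category combinations that activate no disease.
    """
    report = RuleBaseReport(missing_present=rb.diseases_lacking_present())

    vocab_by_param: dict[LabParameter, set[str]] = {}
    for (param, _, _), part in config.partitions.items():
        vocab_by_param.setdefault(param, set()).update(part.labels)
    for rule in rb.rules:
        for param, cat in rule.antecedent:
            if cat not in vocab_by_param.get(param, set()):
                report.unknown_categories.append(
                    f"rule for {rule.disease.value} references category "
                    f"{cat!r} absent from all {param.value} partitions"
                )

    # crisp combinations: one category per parameter, any partition vocabulary
    import itertools

    params = sorted(vocab_by_param, key=lambda p: p.value)
    axes = [sorted(vocab_by_param[p]) for p in params]
    for combo in itertools.product(*axes):
        assignment = dict(zip(params, combo))
        fired = any(
            all(assignment.get(p) == c for p, c in rule.antecedent)
            for rule in rb.rules
            if rule.term == PRESENT
        )
        if not fired:
            report.dead_combinations.append(
                tuple(f"{p.value}={c}" for p, c in assignment.items())
            )
    return report


# -- rule file IO ---------------------------------------------------------


def parse_rulebase(
    text: str,
    vocab: Iterable[str] | None = None,
    provenance: str = "",
    version: str = "0",
) -> RuleBase:
    rules = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            rules.append(parse_rule(line, vocab=vocab))
        except RuleParseError as exc:
            raise RuleParseError(f"line {lineno}: {exc}") from exc
    return RuleBase(rules, provenance=provenance, version=version)


def serialize_rulebase(rb: RuleBase) -> str:
    lines = [f"# fuzzyhaem rule base (version {rb.version})"]
    if rb.provenance:
        for chunk in rb.provenance.splitlines():
            lines.append(f"# {chunk}")
    lines.extend(serialize_rule(r) for r in rb.rules)
    return "\n".join(lines) + "\n"


def load_rulebase(path: str | Path, vocab: Iterable[str] | None = None) -> RuleBase:
    rb = parse_rulebase(Path(path).read_text(), vocab=vocab, provenance=str(path))
    logger.info("loaded %d rules from %s", len(rb.rules), path)
    return rb


def save_rulebase(rb: RuleBase, path: str | Path) -> None:
    Path(path).write_text(serialize_rulebase(rb))


def default_rulebase() -> RuleBase:
    """The shipped rule base (packaged text resource)."""
    text = (
        resources.files("fuzzyhaem.data").joinpath("default_rules.txt").read_text()
    )
    return parse_rulebase(
        text, provenance="shipped default rule base", version="1.0"
    )
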