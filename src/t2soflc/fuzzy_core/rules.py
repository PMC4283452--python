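"""Two-input/one-output fuzzy control rules and serializable rule-bases.

A rule reads ``IF x is F1 AND y is F2 THEN z is G`` with the two
antecedents drawn from the four controller inputs (error and integrated
error of muscle relaxation and of blood pressure) and the consequent a
drug-adjustment magnitude label.  A rule-base holds at most one rule per
(output, antecedent-signature): the self-organizing layer replaces
consequents in place rather than duplicating rules.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from .sets import INPUT_LABELS, OUTPUT_LABELS

__all__ = ["INPUT_VARIABLES", "Rule", "RuleBase", "read_rulebase", "write_rulebase"]

logger = logging.getLogger(__name__)

#: Canonical ordering of the controller input variables.
INPUT_VARIABLES = ("E_MR", "IE_MR", "E_BP", "IE_BP")

_CSV_HEADER = [
    "output_var",
    "in1_var",
    "in1_label",
    "in2_var",
    "in2_label",
    "consequent_label",
]


@dataclass(frozen=True)
class Rule:
    """One decomposed 2-input/1-output rule with linguistic labels."""

    in1: tuple[str, str]  # (variable, label)
    in2: tuple[str, str]
    consequent: str

    def __post_init__(self) -> None:
        v1, l1 = self.in1
        v2, l2 = self.in2
        if v1 == v2:
            raise ValueError("the two antecedent variables must be distinct")
        for v in (v1, v2):
            if v not in INPUT_VARIABLES:
                raise ValueError(f"unknown input variable {v!r}")
        for lab in (l1, l2):
            if lab not in INPUT_LABELS:
                raise ValueError(f"unknown input label {lab!r}")
        if self.consequent not in OUTPUT_LABELS:
            raise ValueError(f"unknown output label {self.consequent!r}")
        if INPUT_VARIABLES.index(v1) > INPUT_VARIABLES.index(v2):
            raise ValueError("antecedents must follow the canonical variable order")

    @staticmethod
    def make(in1: tuple[str, str], in2: tuple[str, str], consequent: str) -> "Rule":
        """Build a rule, normalizing the antecedent order."""
        if INPUT_VARIABLES.index(in1[0]) > INPUT_VARIABLES.index(in2[0]):
            in1, in2 = in2, in1
        return Rule(in1, in2, consequent)

    @property
    def signature(self) -> tuple[str, str, str, str]:
        return (*self.in1, *self.in2)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.in1[0], self.in2[0])


class RuleBase:
    """Rules for one output variable, indexed by antecedent signature."""

    def __init__(self, output_var: str, rules: list[Rule] | None = None):
        self.output_var = output_var
        self._rules: dict[tuple[str, str, str, str], Rule] = {}
        self._by_pair: dict[tuple[str, str], dict[tuple[str, str], str]] = {}
        for r in rules or []:
            self.put(r)

    def put(self, rule: Rule) -> None:
        """Insert or replace the rule with this antecedent signature."""
        self._rules[rule.signature] = rule
        pair_index = self._by_pair.setdefault(rule.pair, {})
        pair_index[(rule.in1[1], rule.in2[1])] = rule.consequent

    def get(self, signature: tuple[str, str, str, str]) -> Rule | None:
        return self._rules.get(signature)

    def remove(self, signature: tuple[str, str, str, str]) -> None:
        rule = self._rules.pop(signature)
        del self._by_pair[rule.pair][(rule.in1[1], rule.in2[1])]

    def pair_rules(self, pair: tuple[str, str]) -> dict[tuple[str, str], str]:
        """Label-pair -> consequent map of the rules over one input pair."""
        return self._by_pair.get(pair, {})

    def rules(self) -> list[Rule]:
        return list(self._rules.values())

    def __len__(self) -> int:
        return len(self._rules)

    def __contains__(self, signature: tuple[str, str, str, str]) -> bool:
        return signature in self._rules

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RuleBase):
            return NotImplemented
        return self.output_var == other.output_var and self._rules == other._rules

    def copy(self) -> "RuleBase":
        return RuleBase(self.output_var, self.rules())


class RuleParseError(ValueError):
    pass


def _rule_from_row(row: dict, where: str) -> tuple[str, Rule]:
    try:
        rule = Rule.make(
            (row["in1_var"], row["in1_label"]),
            (row["in2_var"], row["in2_label"]),
            row["consequent_label"],
        )
    except (KeyError, ValueError) as err:
        raise RuleParseError(f"{where}: {err}") from err
    return row["output_var"], rule


def read_rulebase(path: str | Path) -> RuleBase:
    """Load a rule-base from CSV or JSON (by file suffix).

    Duplicate antecedent signatures resolve last-wins with a logged
    warning; an unknown variable or label token raises
    :class:`RuleParseError` naming the offending line.
    """
    path = Path(path)
    rows: list[tuple[dict, str]] = []
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        for i, row in enumerate(payload["rules"]):
            rows.append(({**row, "output_var": payload["output_var"]}, f"rule {i}"))
    else:
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or set(_CSV_HEADER) - set(reader.fieldnames):
                raise RuleParseError(f"{path}: missing header {_CSV_HEADER}")
            for i, row in enumerate(reader, start=2):
                rows.append((row, f"{path.name} line {i}"))
    if not rows:
        raise RuleParseError(f"{path}: no rules found")
    output_var = rows[0][0]["output_var"]
    rb = RuleBase(output_var)
    for row, where in rows:
        out, rule = _rule_from_row(row, where)
        if out != output_var:
            raise RuleParseError(f"{where}: mixed output variables in one file")
        if rule.signature in rb:
            logger.warning("%s: duplicate antecedent %s, last wins", where, rule.signature)
        rb.put(rule)
    return rb


def write_rulebase(rulebase: RuleBase, path: str | Path) -> None:
    """Write a rule-base as CSV or JSON (by file suffix), losslessly."""
    path = Path(path)
    rules = sorted(rulebase.rules(), key=lambda r: (
        INPUT_VARIABLES.index(r.in1[0]),
        INPUT_VARIABLES.index(r.in2[0]),
        INPUT_LABELS.index(r.in1[1]),
        INPUT_LABELS.index(r.in2[1]),
    ))
    if path.suffix.lower() == ".json":
        payload = {
            "output_var": rulebase.output_var,
            "rules": [
                {
                    "in1_var": r.in1[0],
                    "in1_label": r.in1[1],
                    "in2_var": r.in2[0],
                    "in2_label": r.in2[1],
                    "consequent_label": r.consequent,
                }
                for r in rules
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for r in rules:
            writer.writerow(
                [rulebase.output_var, r.in1[0], r.in1[1], r.in2[0], r.in2[1], r.consequent]
            )
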