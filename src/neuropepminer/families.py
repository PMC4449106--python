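"""Consensus-motif classification of released peptides into families.

Neuropeptide families are recognisable from short, mostly C-terminal
consensus motifs on the processed (amidated) peptide — e.g. the sulfakinin
``…Y-G-H-M/L-R-F-NH2`` with acidic residues upstream of the sulfotyrosine,
the short neuropeptide F ``…R-L-R-F/Y-NH2``, or the allatostatin-A
``…Y/F-x-F-G-L-NH2``. Families defined by a cysteine skeleton rather than a
linear motif (the CHH/MIH superfamily with its six conserved cysteines,
neuroparsins with twelve, eclosion hormone) are gated on cysteine count plus
a length window instead.

The rule table is data, not code: ``data/family_rules.tsv`` ships the
defaults and can be replaced wholesale (``--rules`` on the command line).
Rules are tested in priority order and the first full match wins, which
makes classification deterministic; for peptides matching at most one rule
the outcome is independent of the order of equal-priority rules.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .processing import MaturePeptide

UNCLASSIFIED = "unclassified"

RULE_COLUMNS = ["family", "kind", "pattern", "requires_amidation",
                "min_len", "max_len", "cys_count", "priority"]


@dataclass(frozen=True)
class FamilyRule:
    family: str
    kind: str                      # "regex" | "cys"
    pattern: str                   # regex source ("" for cys rules)
    requires_amidation: bool
    min_len: int
    max_len: int
    cys_count: Optional[int]
    priority: int

    def matches(self, seq: str, amidated: bool) -> bool:
        if self.requires_amidation and not amidated:
            return False
        if not (self.min_len <= len(seq) <= self.max_len):
            return False
        if self.kind == "cys":
            return seq.count("C") == self.cys_count
        return re.search(self.pattern, seq) is not None


def load_rules(path: Optional[str | Path] = None) -> list[FamilyRule]:
    if path is None:
        path = Path(str(resources.files("neuropepminer")
                        .joinpath("data", "family_rules.tsv")))
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    if header != RULE_COLUMNS:
        raise ValueError(f"{path}: unexpected rule columns {header}")
    rules: list[FamilyRule] = []
    for line in lines[1:]:
        if not line.strip():
            continue
        d = dict(zip(RULE_COLUMNS, line.split("\t")))
        if d["kind"] not in ("regex", "cys"):
            raise ValueError(f"{path}: unknown rule kind {d['kind']!r}")
        if d["kind"] == "regex":
            re.compile(d["pattern"])  # fail fast on malformed patterns
        rules.append(FamilyRule(
            family=d["family"], kind=d["kind"], pattern=d["pattern"],
            requires_amidation=bool(int(d["requires_amidation"])),
            min_len=int(d["min_len"]), max_len=int(d["max_len"]),
            cys_count=int(d["cys_count"]) if d["cys_count"] else None,
            priority=int(d["priority"])))
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise ValueError(f"{path}: rule priorities must be unique")
    return sorted(rules, key=lambda r: r.priority)


_DEFAULT_RULES: Optional[list[FamilyRule]] = None


def default_rules() -> list[FamilyRule]:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_rules()
    return _DEFAULT_RULES


def classify(peptide: Union[MaturePeptide, str], amidated: bool = False,
             rules: Optional[Sequence[FamilyRule]] = None
             ) -> tuple[str, Optional[FamilyRule]]:
    """Return ``(family, matched_rule)`` or ``("unclassified", None)``."""
    if isinstance(peptide, MaturePeptide):
        seq, amid = peptide.sequence, peptide.amidated
    else:
        seq, amid = peptide, amidated
    for rule in rules if rules is not None else default_rules():
        if rule.matches(seq, amid):
            return rule.family, rule
    return UNCLASSIFIED, None


def assign_roles(peptides: Iterable[MaturePeptide],
                 rules: Optional[Sequence[FamilyRule]] = None
                 ) -> dict[str, int]:
    """Classify each peptide in place and set its role.

    A peptide matching a family rule is bioactive; anything else is a
    precursor-related peptide. Returns counts per role.
    """
    counts = {"bioactive": 0, "precursor-related": 0}
    for pep in peptides:
        family, _rule = classify(pep, rules=rules)
        pep.family = None if family == UNCLASSIFIED else family
        pep.role = "bioactive" if pep.family else "precursor-related"
        counts[pep.role] += 1
    return counts
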