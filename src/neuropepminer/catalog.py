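"""Packaged catalog of predicted preproneuropeptides and their peptides.

The fixture transcribes the published precursor summary (family, precursor
and signal-peptide lengths, per-tissue FPKM) and the predicted mature /
precursor-related peptide table into two plain-text files:

* ``data/catalog_precursors.json`` — one object per precursor, including the
  printed cleavage-site notation (e.g. ``K45R``) and, where every component
  of the architecture is printed, an ordered component list.
* ``data/catalog_peptides.tsv`` — one row per peptide with modification
  annotations (amidated, pyroglutamate, sulfotyrosine positions, copy count).

These files are the regression surface for the processing engine and the
family classifier.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

AA20 = set("ACDEFGHIKLMNPQRSTVWY")

PEPTIDE_COLUMNS = ["family_name", "peptide_seq", "role", "amidated", "pyroglu",
                   "sulfo_positions", "copies", "remark"]


@dataclass
class CatalogPeptide:
    family_name: str
    peptide_seq: str
    role: str                      # "mature" | "related"
    amidated: bool
    pyroglu: str                   # "" | "Q" | "E"
    sulfo_positions: list[int]     # 1-based Y positions within the peptide
    copies: int
    remark: str

    @property
    def partial(self) -> bool:
        return "[+partial]" in self.remark


@dataclass
class CatalogEntry:
    family_name: str
    precursor_length: int
    signal_length: int
    fpkm_by_tissue: dict[str, float]
    partial_flag: bool
    cleavage_positions: list[str]
    classifier_expected: Optional[str]
    architecture: Optional[list[str]]
    mature_peptides: list[CatalogPeptide] = field(default_factory=list)
    precursor_related_peptides: list[CatalogPeptide] = field(default_factory=list)

    @property
    def peptides(self) -> list[CatalogPeptide]:
        return self.mature_peptides + self.precursor_related_peptides


@dataclass
class ValidationCheck:
    name: str
    passed: bool
    message: str


def _data_path(name: str) -> Path:
    return Path(str(resources.files("neuropepminer").joinpath("data", name)))


def load_peptides(path: Optional[str | Path] = None) -> list[CatalogPeptide]:
    path = Path(path) if path else _data_path("catalog_peptides.tsv")
    rows: list[CatalogPeptide] = []
    lines = path.read_text().splitlines()
    if not lines:
        return rows
    header = lines[0].split("\t")
    if header != PEPTIDE_COLUMNS:
        raise ValueError(f"{path}: unexpected peptide columns {header}")
    for k, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        vals = line.split("\t")
        if len(vals) != len(PEPTIDE_COLUMNS):
            raise ValueError(f"{path}:{k}: expected {len(PEPTIDE_COLUMNS)} "
                             f"columns, found {len(vals)}")
        d = dict(zip(PEPTIDE_COLUMNS, vals))
        seq = d["peptide_seq"]
        if not seq or set(seq) - AA20:
            raise ValueError(f"{path}:{k}: bad peptide sequence {seq!r}")
        sulfo = [int(x) for x in d["sulfo_positions"].split(",") if x]
        for pos in sulfo:
            if not (1 <= pos <= len(seq)) or seq[pos - 1] != "Y":
                raise ValueError(f"{path}:{k}: sulfo position {pos} is not a Y")
        rows.append(CatalogPeptide(
            family_name=d["family_name"], peptide_seq=seq, role=d["role"],
            amidated=bool(int(d["amidated"])), pyroglu=d["pyroglu"],
            sulfo_positions=sulfo, copies=int(d["copies"]), remark=d["remark"]))
    return rows


def load_catalog(path: Optional[str | Path] = None,
                 peptides_path: Optional[str | Path] = None
                 ) -> list[CatalogEntry]:
    """Load the packaged catalog (or an alternative fixture at `path`)."""
    path = Path(path) if path else _data_path("catalog_precursors.json")
    text = path.read_text()
    if not text.strip():
        return []
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed catalog fixture: {exc}") from exc
    raw_entries = doc["entries"] if isinstance(doc, dict) else doc
    peptides = load_peptides(peptides_path)
    by_family: dict[str, list[CatalogPeptide]] = {}
    for pep in peptides:
        by_family.setdefault(pep.family_name, []).append(pep)
    entries: list[CatalogEntry] = []
    for rec in raw_entries:
        try:
            fam = rec["family_name"]
            peps = by_family.get(fam, [])
            entry = CatalogEntry(
                family_name=fam,
                precursor_length=int(rec["precursor_length"]),
                signal_length=int(rec["signal_length"]),
                fpkm_by_tissue=dict(rec["fpkm"]),
                partial_flag=bool(rec["partial"]),
                cleavage_positions=list(rec["cleavage_sites"]),
                classifier_expected=rec.get("classifier_expected"),
                architecture=rec.get("architecture"),
                mature_peptides=[p for p in peps if p.role == "mature"],
                precursor_related_peptides=[p for p in peps if p.role == "related"],
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}: malformed record {rec.get('family_name', rec)!r}: {exc}"
            ) from exc
        if any(v < 0 for v in entry.fpkm_by_tissue.values()):
            raise ValueError(f"{path}: negative FPKM in {fam!r}")
        entries.append(entry)
    return entries


def known_unclassifiable(path: Optional[str | Path] = None) -> list[str]:
    """Peptide remarks that the shipped rule table deliberately cannot place
    (no published consensus motif; cystine-skeleton/length gating only)."""
    path = Path(path) if path else _data_path("catalog_precursors.json")
    doc = json.loads(path.read_text())
    return list(doc.get("known_unclassifiable", [])) if isinstance(doc, dict) else []


def _component_length(token: str) -> int:
    if token == "G":
        return 1
    kind, _, value = token.partition(":")
    if kind == "signal":
        return int(value)
    if kind == "pep":
        return len(value)
    if kind == "site":
        return len(value)
    raise ValueError(f"unknown architecture token {token!r}")


def validate_entry(entry: CatalogEntry) -> list[ValidationCheck]:
    """Cross-check one catalog entry; failures are report items, not errors."""
    checks: list[ValidationCheck] = []

    if entry.architecture and not entry.partial_flag:
        total = sum(_component_length(t) for t in entry.architecture)
        checks.append(ValidationCheck(
            "architecture-length", total == entry.precursor_length,
            f"components sum to {total}, precursor length is "
            f"{entry.precursor_length}"))

    ok = entry.precursor_length > entry.signal_length >= 0
    checks.append(ValidationCheck(
        "signal-within-precursor", ok,
        f"signal {entry.signal_length} vs precursor {entry.precursor_length}"))

    for pep in entry.peptides:
        if pep.pyroglu and pep.peptide_seq[0] not in "QE":
            checks.append(ValidationCheck(
                "pyroglu-residue", False,
                f"{pep.remark}: pyroGlu on {pep.peptide_seq[0]!r}"))
        if pep.copies < 1:
            checks.append(ValidationCheck(
                "copy-count", False, f"{pep.remark}: copies {pep.copies}"))
    if not any(not c.passed and c.name in ("pyroglu-residue", "copy-count")
               for c in checks):
        checks.append(ValidationCheck(
            "peptide-annotations", True,
            f"{len(entry.peptides)} peptides annotated consistently"))
    return checks


def write_catalog(entries: list[CatalogEntry], json_path: str | Path,
                  tsv_path: str | Path) -> None:
    """Write a catalog back out in the packaged fixture format (round-trip)."""
    recs = []
    peps: list[CatalogPeptide] = []
    for e in entries:
        recs.append({
            "family_name": e.family_name,
            "precursor_length": e.precursor_length,
            "signal_length": e.signal_length,
            "fpkm": e.fpkm_by_tissue,
            "partial": e.partial_flag,
            "cleavage_sites": e.cleavage_positions,
            "classifier_expected": e.classifier_expected,
            "architecture": e.architecture,
        })
        peps.extend(e.peptides)
    Path(json_path).write_text(json.dumps({"entries": recs}, indent=1) + "\n")
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(PEPTIDE_COLUMNS) + "\n")
        for p in peps:
            fh.write("\t".join([
                p.family_name, p.peptide_seq, p.role, str(int(p.amidated)),
                p.pyroglu, ",".join(map(str, p.sulfo_positions)),
                str(p.copies), p.remark]) + "\n")
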