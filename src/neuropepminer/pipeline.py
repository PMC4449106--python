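"""End-to-end mining runs: translate -> search -> process -> classify -> report.

Two modes:

* ``run_mine`` — the full pipeline on transcript nucleotide FASTA plus a
  query library of known mature peptides. For each transcript with hits the
  best ORF becomes a candidate precursor; its full precursor call starts at
  the first Met of the ORF (entries without a Met are emitted as partial).
* ``process_only`` — skips the search stage and processes protein FASTA
  directly (used for regression against printed architectures).

Signal-peptide lengths are inputs (a two-column TSV), never predicted
silently. Every run writes a machine-readable manifest carrying the config,
the serialized rule set and the seed, so outputs are reproducible
byte-for-byte.
"""
from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO

from . import __version__
from .expression import fpkm_table
from .families import FamilyRule, assign_roles, load_rules
from .orfs import orfs_from_fasta
from .processing import (DEFAULT_RULES, CleavageSite, MaturePeptide,
                         PrecursorModel, RuleSet, find_cleavage_sites,
                         process_precursor)
from .search import (DEFAULT_MIN_SCORE, CandidatePrecursor, SearchHit,
                     collate_candidates, hits_to_rows, load_query_library,
                     search)

log = logging.getLogger("neuropepminer")

SUMMARY_COLUMNS = ["family", "transcript_id", "precursor_id",
                   "precursor_length", "signal_length", "n_mature",
                   "n_related", "fpkm"]


@dataclass
class RunConfig:
    transcripts: Optional[str] = None
    queries: Optional[str] = None
    proteins: Optional[str] = None          # processing-only mode
    signals: Optional[str] = None
    counts: Optional[str] = None
    rules_path: Optional[str] = None
    min_score: int = DEFAULT_MIN_SCORE
    min_orf_aa: int = 30
    fpkm_convention: str = "printed"
    seed: int = 0
    out_dir: Optional[str] = None

    def validate(self) -> None:
        mode_inputs = [self.transcripts, self.proteins]
        if not any(mode_inputs):
            raise ValueError("config error: need transcripts (mine mode) "
                             "or proteins (processing-only mode)")
        if self.transcripts and not self.queries:
            raise ValueError("config error: mine mode requires a query library")
        if self.min_score <= 0 or self.min_orf_aa <= 0:
            raise ValueError("config error: thresholds must be positive")
        for label, p in [("transcripts", self.transcripts),
                         ("queries", self.queries),
                         ("proteins", self.proteins),
                         ("signals", self.signals),
                         ("counts", self.counts),
                         ("rules", self.rules_path)]:
            if p is not None and not Path(p).exists():
                raise ValueError(f"config error: {label} file not found: {p}")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class PrecursorReport:
    precursor: PrecursorModel
    transcript_id: str
    family: str
    sites: list[CleavageSite]
    peptides: list[MaturePeptide]
    candidate: Optional[CandidatePrecursor] = None
    fpkm: Optional[float] = None


@dataclass
class RunResult:
    config: RunConfig
    rules: RuleSet
    reports: list[PrecursorReport]
    hits: list[SearchHit] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            rows.append({
                "family": r.family,
                "transcript_id": r.transcript_id,
                "precursor_id": r.precursor.id,
                "precursor_length": len(r.precursor.sequence),
                "signal_length": r.precursor.signal_length,
                "n_mature": sum(1 for p in r.peptides if p.role == "bioactive"),
                "n_related": sum(1 for p in r.peptides
                                 if p.role == "precursor-related"),
                "fpkm": "" if r.fpkm is None else f"{r.fpkm:.6g}",
            })
        frame = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
        return frame.sort_values(["family", "transcript_id"],
                                 kind="stable").reset_index(drop=True)

    def summary_tsv(self) -> str:
        return self.summary_frame().to_csv(sep="\t", index=False)

    def peptides_fasta(self) -> str:
        out = []
        for r in self.reports:
            for i, p in enumerate(r.peptides, start=1):
                flags = []
                if p.amidated:
                    flags.append("amidated")
                if p.pyroglu:
                    flags.append(f"pyroglu={p.pyroglu}")
                if p.sulfo_tyr:
                    flags.append("sulfoY=" + ",".join(map(str, p.sulfo_tyr)))
                desc = " ".join([f"role={p.role}",
                                 f"family={p.family or 'NA'}"] + flags)
                out.append(f">{r.precursor.id}|pep{i} {desc}\n{p.sequence}\n")
        return "".join(out)

    def architecture_gff(self) -> str:
        lines = ["##gff-version 3"]
        for r in self.reports:
            sid = r.precursor.id
            src = "neuropepminer"
            if r.precursor.signal_length:
                lines.append("\t".join([
                    sid, src, "signal_peptide", "1",
                    str(r.precursor.signal_length), ".", "+", ".",
                    "ID=signal"]))
            for k, s in enumerate(r.sites, start=1):
                lines.append("\t".join([
                    sid, src, "cleavage_site", str(s.position), str(s.end),
                    ".", "+", ".",
                    f"ID=site{k};motif_class={s.motif_class}"]))
            for k, p in enumerate(r.peptides, start=1):
                ftype = ("mature_peptide" if p.role == "bioactive"
                         else "related_peptide")
                lines.append("\t".join([
                    sid, src, ftype, str(p.start), str(p.end), ".", "+", ".",
                    f"ID=pep{k};family={p.family or 'NA'}"]))
        return "\n".join(lines) + "\n"

    def manifest(self) -> dict:
        return {
            "tool": "neuropepminer",
            "version": __version__,
            "seed": self.config.seed,
            "config": self.config.to_dict(),
            "rules": self.rules.to_dict(),
            "n_precursors": len(self.reports),
            "n_hits": len(self.hits),
            "warnings": self.warnings,
        }

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "summary": out / "summary.tsv",
            "peptides": out / "peptides.fasta",
            "architecture": out / "architecture.gff",
            "hits": out / "hits.tsv",
            "manifest": out / "manifest.json",
        }
        paths["summary"].write_text(self.summary_tsv())
        paths["peptides"].write_text(self.peptides_fasta())
        paths["architecture"].write_text(self.architecture_gff())
        pd.DataFrame(hits_to_rows(self.hits)).to_csv(
            paths["hits"], sep="\t", index=False)
        paths["manifest"].write_text(
            json.dumps(self.manifest(), indent=1, sort_keys=True) + "\n")
        return paths


def read_signals(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["transcript_id"].astype(str),
                    df["signal_length"].astype(int)))


def _resolve_rules(config: RunConfig) -> tuple[RuleSet, list[FamilyRule]]:
    family_rules = load_rules(config.rules_path) if config.rules_path \
        else load_rules()
    return DEFAULT_RULES, family_rules


def _fpkm_lookup(config: RunConfig) -> dict[str, float]:
    if not config.counts:
        return {}
    table = fpkm_table(config.counts, convention=config.fpkm_convention)
    return dict(zip(table["transcript_id"].astype(str), table["fpkm"]))


def run_mine(config: RunConfig, rules: RuleSet = DEFAULT_RULES) -> RunResult:
    """Full mining run on transcript nucleotide FASTA."""
    config.validate()
    _, family_rules = _resolve_rules(config)
    result = RunResult(config=config, rules=rules, reports=[])
    records = [(rec.id, str(rec.seq).upper())
               for rec in SeqIO.parse(config.transcripts, "fasta")]
    log.info("read %d transcripts", len(records))
    if not records:
        result.warnings.append("empty transcript file")
        return result
    orfs = orfs_from_fasta(records, config.min_orf_aa)
    log.info("extracted %d ORFs (min %d aa)", len(orfs), config.min_orf_aa)
    queries = load_query_library(config.queries)
    hits = search(queries, orfs, min_score=config.min_score)
    log.info("search: %d hits at raw score >= %d", len(hits), config.min_score)
    result.hits = hits
    candidates = collate_candidates(hits)
    log.info("collated %d candidate precursors", len(candidates))
    signals = read_signals(config.signals) if config.signals else {}
    fpkms = _fpkm_lookup(config)
    for cand in candidates:
        aa = cand.orf.aa_seq
        partial = "M" not in aa
        call = aa if partial else aa[aa.index("M"):]
        sig = signals.get(cand.transcript_id)
        precursor = PrecursorModel(
            id=f"{cand.transcript_id}|precursor", sequence=call,
            signal_length=sig, partial=partial)
        if sig is None:
            result.warnings.append(
                f"{cand.transcript_id}: no signal length provided; "
                "peptides not derived")
            peptides: list[MaturePeptide] = []
            sites: list[CleavageSite] = []
        else:
            sites = find_cleavage_sites(precursor, rules)
            peptides = process_precursor(precursor, rules)
            assign_roles(peptides, family_rules)
        result.reports.append(PrecursorReport(
            precursor=precursor, transcript_id=cand.transcript_id,
            family=cand.family, sites=sites, peptides=peptides,
            candidate=cand, fpkm=fpkms.get(cand.transcript_id)))
    return result


def process_only(config: RunConfig, rules: RuleSet = DEFAULT_RULES) -> RunResult:
    """Processing-only mode: protein FASTA + signal TSV, no search stage."""
    config.validate()
    _, family_rules = _resolve_rules(config)
    result = RunResult(config=config, rules=rules, reports=[])
    signals = read_signals(config.signals) if config.signals else {}
    fpkms = _fpkm_lookup(config)
    for rec in SeqIO.parse(config.proteins, "fasta"):
        seq = str(rec.seq).upper()
        sig = signals.get(rec.id)
        if sig is None:
            raise ValueError(f"{rec.id}: signal required (no entry in "
                             "the signal TSV and heuristic disabled)")
        precursor = PrecursorModel(id=rec.id, sequence=seq, signal_length=sig)
        sites = find_cleavage_sites(precursor, rules)
        peptides = process_precursor(precursor, rules)
        assign_roles(peptides, family_rules)
        fams = sorted({p.family for p in peptides if p.family})
        result.reports.append(PrecursorReport(
            precursor=precursor, transcript_id=rec.id,
            family=fams[0] if fams else "NA", sites=sites,
            peptides=peptides, fpkm=fpkms.get(rec.id)))
    return result


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
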