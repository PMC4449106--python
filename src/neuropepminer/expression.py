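"""Transcript expression (FPKM) and peptide-evidence matching.

The FPKM formula is implemented exactly as published for this data set:

    FPKM = (1000000 * C) / (N * L * 1000)

with C the fragments uniquely aligned to the transcript, N the total
fragments uniquely aligned to all transcripts, and L the transcript length
in bases. Note this differs from the conventional
``10^9 * C / (N * L)`` by a constant factor of 10^6; pass
``convention="standard"`` for the conventional scale. Because both are
linear rescalings, ratios and rankings are identical under either.

Evidence matching is the sequence-level counterpart of matching a
mass-spectrometry peptide back to precursors: plain substring search, with
optional isoleucine/leucine folding (isobaric residues that MS cannot
distinguish). A peptide found in two or more precursors is reported as one
ambiguous shared-match group, exactly as an identical precursor-related
peptide shared by two isoforms would be.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

CONVENTIONS = ("printed", "standard")


def fpkm(c: float, n: float, length: float, convention: str = "printed") -> float:
    """Fragments-per-kilobase-per-million for one transcript."""
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    if n < 1:
        raise ValueError("N (total fragments) must be >= 1")
    if length < 1:
        raise ValueError("L (transcript length) must be >= 1")
    if c < 0:
        raise ValueError("C (fragment count) must be >= 0")
    if c > n:
        raise ValueError("C cannot exceed N")
    if convention == "printed":
        return (1_000_000.0 * c) / (n * length * 1000.0)
    return (1_000_000_000.0 * c) / (n * length)


def fpkm_table(counts: Union[pd.DataFrame, str, Path],
               convention: str = "printed") -> pd.DataFrame:
    """Per-transcript FPKM from a counts table.

    Expects columns ``transcript_id``, ``fragment_count``, ``length_nt``;
    N is the column sum of fragment counts. Row order is preserved and does
    not affect the values.
    """
    if not isinstance(counts, pd.DataFrame):
        counts = pd.read_csv(counts, sep="\t")
    required = {"transcript_id", "fragment_count", "length_nt"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns {sorted(missing)}")
    if counts["transcript_id"].duplicated().any():
        dupes = counts.loc[counts["transcript_id"].duplicated(), "transcript_id"]
        raise ValueError(f"duplicate transcript ids: {sorted(set(dupes))}")
    out = counts.copy()
    if len(out) == 0:
        out["fpkm"] = pd.Series(dtype=float)
        return out
    n_total = float(out["fragment_count"].sum())
    out["fpkm"] = [
        fpkm(c, n_total, ln, convention=convention)
        for c, ln in zip(out["fragment_count"], out["length_nt"])]
    return out


@dataclass
class EvidenceMatch:
    observed: str
    precursor_ids: list[str]              # all precursors containing the peptide
    spans: dict[str, tuple[int, int]]     # precursor id -> 1-based inclusive span
    il_equivalent: bool

    @property
    def ambiguous(self) -> bool:
        return len(self.precursor_ids) >= 2


def _fold_il(seq: str) -> str:
    return seq.replace("I", "J").replace("L", "J")


def match_peptides(observed: Iterable[str],
                   catalog: Mapping[str, str],
                   il_equivalent: bool = False) -> list[EvidenceMatch]:
    """Match observed peptide strings against precursor sequences.

    Returns one :class:`EvidenceMatch` per observed peptide that occurs in
    at least one precursor (first occurrence per precursor is reported).
    """
    if not catalog:
        raise ValueError("catalog of precursor sequences is empty")
    folded_catalog = {k: (_fold_il(v) if il_equivalent else v)
                      for k, v in catalog.items()}
    matches: list[EvidenceMatch] = []
    for obs in observed:
        needle = _fold_il(obs) if il_equivalent else obs
        ids: list[str] = []
        spans: dict[str, tuple[int, int]] = {}
        for pid in sorted(folded_catalog):
            i = folded_catalog[pid].find(needle)
            if i >= 0:
                ids.append(pid)
                spans[pid] = (i + 1, i + len(needle))
        if ids:
            matches.append(EvidenceMatch(obs, ids, spans, il_equivalent))
    return matches
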