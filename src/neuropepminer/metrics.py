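"""Pairwise percent identity and similarity, Clustal-symbol style.

Identity and similarity follow the convention used when reading a Clustal
alignment by its annotation line: ``*`` marks an identical column, ``:`` a
column whose residue pair falls in a "strong" conservation group, ``.`` a
"weak" group. The percentages divide by the length of the LONGER of the two
unaligned sequences (not the alignment length), so a short peptide perfectly
nested in a longer one scores length_short / length_long, not 100%.

The alignment itself is an exact Needleman-Wunsch with affine gaps (see
:mod:`.align`); a progressive multiple aligner can produce slightly
different pairwise projections, so published cross-species percentages are
treated as ranges, not exact values, when compared against this module.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .align import global_align  # noqa: F401  (re-exported public surface)


@lru_cache(maxsize=1)
def conservation_groups() -> tuple[frozenset[frozenset[str]], frozenset[frozenset[str]]]:
    doc = json.loads(resources.files("neuropepminer")
                     .joinpath("data", "clustal_groups.json").read_text())
    strong = frozenset(frozenset(g) for g in doc["strong"])
    weak = frozenset(frozenset(g) for g in doc["weak"])
    return strong, weak


@dataclass
class AlignmentSummary:
    aligned_a: str
    aligned_b: str
    n_identical: int       # '*' columns
    n_strong: int          # ':' columns
    n_weak: int            # '.' columns
    len_longest: int       # length of the longer unaligned sequence
    symbols: str

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.n_identical / self.len_longest

    @property
    def percent_similarity(self) -> float:
        return 100.0 * (self.n_identical + self.n_strong + self.n_weak) \
            / self.len_longest


def column_symbol(x: str, y: str) -> str:
    if x == "-" or y == "-":
        return " "
    if x == y:
        return "*"
    strong, weak = conservation_groups()
    pair = {x, y}
    if any(pair <= g for g in strong):
        return ":"
    if any(pair <= g for g in weak):
        return "."
    return " "


def summarize(aligned_a: str, aligned_b: str) -> AlignmentSummary:
    """Score an aligned pair with the ``*``/``:``/``.`` symbol convention."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings must have equal length")
    symbols = "".join(column_symbol(x, y) for x, y in zip(aligned_a, aligned_b))
    return AlignmentSummary(
        aligned_a=aligned_a, aligned_b=aligned_b,
        n_identical=symbols.count("*"),
        n_strong=symbols.count(":"),
        n_weak=symbols.count("."),
        len_longest=max(len(aligned_a.replace("-", "")),
                        len(aligned_b.replace("-", ""))),
        symbols=symbols)


def identity_similarity(a: str, b: str, matrix: str = "BLOSUM62",
                        gap_open: int = 11, gap_extend: int = 1
                        ) -> AlignmentSummary:
    """Align two raw sequences globally and summarise in one call.

    The argument order is canonicalised before aligning: co-optimal global
    alignments can differ in their identical-column count depending on which
    sequence is treated as the reference, so without this the metric would
    not be exactly symmetric.
    """
    x, y = (a, b) if a <= b else (b, a)
    xx, yy, _score = global_align(x, y, matrix=matrix,
                                  gap_open=gap_open, gap_extend=gap_extend)
    if (x, y) != (a, b):
        xx, yy = yy, xx
    return summarize(xx, yy)
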