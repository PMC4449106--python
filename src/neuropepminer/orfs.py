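"""Six-frame translation and stop-to-stop ORF extraction.

ORFs are defined stop-to-stop rather than Met-to-stop: homology queries are
mature peptides that may sit mid-precursor, and 5' ends of assembled
transcripts are frequently truncated, so requiring an initiator Met at this
stage would lose genuine precursor fragments. The Met requirement is applied
later, only when a full precursor call is emitted.

Coordinates are 1-based inclusive on the forward strand for every frame,
including the three reverse frames. When an ORF segment is terminated by a
stop codon the span includes that codon, so ``aa_len * 3 == span - 3``;
open-ended segments satisfy ``aa_len * 3 == span``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio.Data import CodonTable
from Bio.Seq import reverse_complement

FRAMES = (1, 2, 3, -1, -2, -3)

_table = CodonTable.unambiguous_dna_by_id[1]
_CODON = dict(_table.forward_table)
for _stop in _table.stop_codons:
    _CODON[_stop] = "*"

_NT = set("ACGTN")


def translate(nt: str, frame: int = 1) -> str:
    """Translate one reading frame with the standard genetic code.

    Any codon containing N becomes 'X'; stop codons are kept as '*'.
    Reverse frames translate the reverse complement.
    """
    if frame not in FRAMES:
        raise ValueError(f"invalid frame {frame!r}")
    nt = nt.upper()
    bad = set(nt) - _NT
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    if frame < 0:
        nt = reverse_complement(nt)
    offset = abs(frame) - 1
    out = []
    for i in range(offset, len(nt) - 2, 3):
        codon = nt[i:i + 3]
        out.append("X" if "N" in codon else _CODON[codon])
    return "".join(out)


@dataclass
class OrfRecord:
    transcript_id: str
    frame: int
    start: int   # forward-strand nt coordinate, 1-based inclusive
    end: int     # includes the terminating stop codon when has_stop
    aa_seq: str
    has_initial_met: bool
    has_stop: bool

    @property
    def orf_id(self) -> str:
        sign = "+" if self.frame > 0 else ""
        return f"{self.transcript_id}|{sign}{self.frame}|{self.start}-{self.end}"


def _segments(aa: str) -> Iterator[tuple[int, int, bool]]:
    """Yield (codon_start, codon_stop, has_stop) for stop-delimited segments."""
    start = 0
    for i, c in enumerate(aa):
        if c == "*":
            if i > start:
                yield start, i, True
            start = i + 1
    if len(aa) > start:
        yield start, len(aa), False


def find_orfs(nt: str, min_aa: int, transcript_id: str = "seq") -> list[OrfRecord]:
    """All maximal stop-to-stop segments of length >= min_aa in all six frames."""
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    L = len(nt)
    orfs: list[OrfRecord] = []
    for frame in FRAMES:
        aa = translate(nt, frame)
        offset = abs(frame) - 1
        for c0, c1, has_stop in _segments(aa):
            if c1 - c0 < min_aa:
                continue
            seg = aa[c0:c1]
            # nt span in translation orientation (includes stop codon if any)
            s = offset + 3 * c0 + 1
            e = offset + 3 * (c1 + (1 if has_stop else 0))
            if frame < 0:  # map back to the forward strand
                s, e = L - e + 1, L - s + 1
            orfs.append(OrfRecord(transcript_id, frame, s, e, seg,
                                  "M" in seg, has_stop))
    order = {f: k for k, f in enumerate(FRAMES)}
    orfs.sort(key=lambda o: (order[o.frame], o.start))
    return orfs


def orfs_from_fasta(records: Iterable[tuple[str, str]], min_aa: int) -> list[OrfRecord]:
    out: list[OrfRecord] = []
    for rid, seq in records:
        out.extend(find_orfs(seq, min_aa, transcript_id=rid))
    return out
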