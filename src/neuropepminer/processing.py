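"""Prohormone processing: convertase cleavage sites, mature peptides, PTMs.

The engine models the canonical secretory-pathway maturation of a
preproneuropeptide: the signal peptide is removed, prohormone convertases cut
at basic cleavage motifs, carboxypeptidase-E-style trimming optionally
removes exposed C-terminal basics, a C-terminal glycine is converted to an
amide on the preceding residue, and N-terminal Gln/Glu may cyclise to
pyroglutamate while tyrosines in acidic context may be sulfated.

The default :class:`RuleSet` is calibrated on decapod precursor
architectures:

* KR and RR dibasics always cleave. KK and RK are recognised by convertases
  far less consistently — and genuine bioactive peptides (e.g. CRF-like
  diuretic hormone, CHH-family matures) carry internal KK/RK that are *not*
  processed — so they are opt-in.
* A lone terminal K or R (the "…Gly-Lys-stop" ending typical of amidated
  CHH-family matures) is a site. Internal monobasic cleavage (classically,
  a second basic at -4/-6/-8) is opt-in for the same reason as KK/RK:
  applied blindly it dissects real matures.
* Disulfide-loop protection: a candidate flanked by cysteines within
  ``cys_protection_window`` residues on both sides is skipped. Convertases
  cannot reach basics buried inside a disulfide-constrained loop; without
  this, the internal KR of the third CHH isoform's mature would be cut.

Cleavage positions follow the K(n)R field notation: the stored position is
the 1-based index of the FIRST basic residue of the site; the cut falls on
the C-terminal side of the last basic residue.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
BASIC = frozenset("KR")


@dataclass(frozen=True)
class RuleSet:
    """Cleavage and modification rules; serialisable into every report."""

    dibasic: tuple[str, ...] = ("KR", "RR")
    extended_dibasic: tuple[str, ...] = ()      # ("KK", "RK") to enable
    internal_monobasic: bool = False            # basic at -4/-6/-8 enables a lone K/R
    monobasic_offsets: tuple[int, ...] = (-4, -6, -8)
    terminal_basic: bool = True                 # final residue K/R is a site
    cys_protection_window: int = 10             # 0 disables
    trim_trailing_basics: bool = False          # carboxypeptidase-style trim
    sulfation_window: int = 5                   # acidic context for sulfo-Tyr

    def to_dict(self) -> dict:
        return {
            "dibasic": list(self.dibasic),
            "extended_dibasic": list(self.extended_dibasic),
            "internal_monobasic": self.internal_monobasic,
            "monobasic_offsets": list(self.monobasic_offsets),
            "terminal_basic": self.terminal_basic,
            "cys_protection_window": self.cys_protection_window,
            "trim_trailing_basics": self.trim_trailing_basics,
            "sulfation_window": self.sulfation_window,
        }


DEFAULT_RULES = RuleSet()


@dataclass
class PrecursorModel:
    id: str
    sequence: str
    signal_length: Optional[int] = None
    partial: bool = False

    def __post_init__(self) -> None:
        bad = set(self.sequence) - AA20 - {"X"}
        if bad:
            raise ValueError(f"{self.id}: non-canonical residues {sorted(bad)}")
        # == len(sequence) is the degenerate signal-only precursor
        if self.signal_length is not None and not (
                0 <= self.signal_length <= len(self.sequence)):
            raise ValueError(f"{self.id}: signal_length out of range")


@dataclass(frozen=True)
class CleavageSite:
    position: int          # 1-based index of the first basic residue
    motif_class: str       # KR | RR | KK | RK | monoK | monoR | terminal-basic
    residues: str

    @property
    def end(self) -> int:
        return self.position + len(self.residues) - 1


@dataclass
class Modifications:
    pyroglu: Optional[str] = None          # None | "Q" | "E"
    sulfo_tyr: list[int] = field(default_factory=list)  # 1-based peptide positions


@dataclass
class MaturePeptide:
    sequence: str
    start: int             # 1-based span of the untrimmed fragment on the precursor
    end: int
    amidated: bool = False
    pyroglu: Optional[str] = None
    sulfo_tyr: list[int] = field(default_factory=list)
    trimmed_basics: str = ""
    role: str = "unassigned"   # bioactive | precursor-related | unassigned
    family: Optional[str] = None
    copy_index: int = 1

    def __len__(self) -> int:
        return len(self.sequence)


def _cys_protected(seq: str, start0: int, end0: int, window: int) -> bool:
    """True if Cys occurs within `window` residues on both sides of [start0, end0)."""
    if window <= 0:
        return False
    left = seq[max(0, start0 - window):start0]
    right = seq[end0:end0 + window]
    return "C" in left and "C" in right


def find_cleavage_sites(p: PrecursorModel,
                        rules: RuleSet = DEFAULT_RULES) -> list[CleavageSite]:
    """Predict convertase sites on the pro-region (the signal is never scanned).

    Overlapping candidates are resolved left-to-right with longer motifs
    taking precedence at equal start positions.
    """
    seq = p.sequence
    sig = p.signal_length or 0
    L = len(seq)
    motifs = sorted(set(rules.dibasic) | set(rules.extended_dibasic),
                    key=lambda m: (-len(m), m))
    sites: list[CleavageSite] = []
    occupied_until = sig  # 1-based last occupied position
    for pos in range(sig + 1, L + 1):
        if pos <= occupied_until:
            continue
        placed = False
        for m in motifs:
            if seq[pos - 1:pos - 1 + len(m)] == m and pos + len(m) - 1 <= L:
                if _cys_protected(seq, pos - 1, pos - 1 + len(m),
                                  rules.cys_protection_window):
                    continue
                sites.append(CleavageSite(pos, m, m))
                occupied_until = pos + len(m) - 1
                placed = True
                break
        if placed:
            continue
        c = seq[pos - 1]
        if c not in BASIC:
            continue
        if pos == L and rules.terminal_basic:
            if not _cys_protected(seq, pos - 1, pos, rules.cys_protection_window):
                sites.append(CleavageSite(pos, "terminal-basic", c))
                occupied_until = pos
            continue
        if rules.internal_monobasic:
            helper = any(
                pos + off > sig and seq[pos + off - 1] in BASIC
                for off in rules.monobasic_offsets
            )
            if helper and not _cys_protected(seq, pos - 1, pos,
                                             rules.cys_protection_window):
                sites.append(CleavageSite(pos, f"mono{c}", c))
                occupied_until = pos
    return sites


def predict_ptms(peptide: str, context: str = "",
                 rules: RuleSet = DEFAULT_RULES) -> Modifications:
    """Annotate N-terminal pyroglutamate and acidic-context sulfotyrosine.

    A leading Gln cyclises readily (high confidence); a leading Glu is
    reported too but is the putative variant. Each Tyr with at least one
    Asp/Glu within ``sulfation_window`` peptide positions is flagged as a
    putative sulfotyrosine.
    """
    if not peptide:
        raise ValueError("empty peptide")
    mods = Modifications()
    if peptide[0] in "QE":
        mods.pyroglu = peptide[0]
    w = rules.sulfation_window
    for i, c in enumerate(peptide):
        if c != "Y":
            continue
        lo, hi = max(0, i - w), min(len(peptide), i + w + 1)
        if any(x in "DE" for x in peptide[lo:hi]):
            mods.sulfo_tyr.append(i + 1)
    return mods


def process_precursor(p: PrecursorModel,
                      rules: RuleSet = DEFAULT_RULES) -> list[MaturePeptide]:
    """Release peptides from a precursor: split at sites, trim, modify.

    Requires a known signal length (``signal_length`` may be 0 for an
    already-matured pro-region but not None unless the crude heuristic is
    invoked by the caller). Fragments are reported N-to-C; empty fragments
    (e.g. between back-to-back sites) are dropped.
    """
    if p.signal_length is None:
        raise ValueError(f"{p.id}: signal required "
                         "(provide signal_length or use crude_signal_length)")
    sites = find_cleavage_sites(p, rules)
    seq = p.sequence
    bounds: list[tuple[int, int]] = []  # 1-based inclusive fragment spans
    start = p.signal_length + 1
    for s in sites:
        bounds.append((start, s.position - 1))
        start = s.end + 1
    bounds.append((start, len(seq)))
    peptides: list[MaturePeptide] = []
    seen: dict[str, int] = {}
    for b0, b1 in bounds:
        if b1 < b0:
            continue
        frag = seq[b0 - 1:b1]
        trimmed = ""
        if rules.trim_trailing_basics:
            while frag and frag[-1] in BASIC:
                trimmed = frag[-1] + trimmed
                frag = frag[:-1]
        amidated = False
        if frag.endswith("G"):
            frag = frag[:-1]
            amidated = True
        if not frag:
            continue
        mods = predict_ptms(frag, rules=rules)
        seen[frag] = seen.get(frag, 0) + 1
        peptides.append(MaturePeptide(
            sequence=frag, start=b0, end=b1, amidated=amidated,
            pyroglu=mods.pyroglu, sulfo_tyr=mods.sulfo_tyr,
            trimmed_basics=trimmed, copy_index=seen[frag]))
    return peptides


def reassemble(p: PrecursorModel, peptides: Sequence[MaturePeptide],
               sites: Sequence[CleavageSite]) -> str:
    """Rebuild the precursor string from its processed parts.

    Signal + each peptide (+ its amidation Gly + trimmed basics) + the site
    residues, in coordinate order. Used as the residue-conservation check:
    the result must equal the input sequence exactly.
    """
    sig = p.sequence[:p.signal_length or 0]
    pieces: list[tuple[int, str]] = [(0, sig)] if sig else []
    for pep in peptides:
        text = pep.sequence + ("G" if pep.amidated else "") + pep.trimmed_basics
        pieces.append((pep.start, text))
    for s in sites:
        pieces.append((s.position, s.residues))
    pieces.sort()
    return "".join(t for _, t in pieces)


@dataclass
class CysteineProfile:
    count: int
    even_parity: bool
    max_pairs: int


def cysteine_profile(peptide: str) -> CysteineProfile:
    """Cys count, parity, and the upper bound on disulfide bridges."""
    n = peptide.count("C")
    return CysteineProfile(n, n % 2 == 0, n // 2)


# Kyte-Doolittle hydropathy, used only by the optional crude signal heuristic.
_KD = {"I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
       "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
       "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
       "R": -4.5, "X": 0.0}


def crude_signal_length(seq: str, search_to: int = 30, window: int = 8
                        ) -> Optional[int]:
    """Very crude signal-peptide guess; OFF by default and never a substitute
    for a measured signal length.

    Finds the most hydrophobic ``window``-residue stretch within the first
    ``search_to`` residues and cuts after the next small residue (A/G/S/C)
    following it. Returns None when no plausible signal is found.
    """
    head = seq[:search_to]
    if len(head) < window + 2:
        return None
    best_i, best_h = None, -1e9
    for i in range(len(head) - window + 1):
        h = sum(_KD.get(c, 0.0) for c in head[i:i + window])
        if h > best_h:
            best_i, best_h = i, h
    if best_h / window < 1.0:  # not hydrophobic enough to be a signal core
        return None
    for j in range(best_i + window, min(len(seq) - 1, search_to + 10)):
        if seq[j] in "AGSC":
            return j + 1
    return None


def check_no_internal_sites(peptide: str, rules: RuleSet = DEFAULT_RULES) -> bool:
    """True when re-processing `peptide` as a signal-less precursor returns it
    unchanged (no internal site, no terminal trimming side-effects)."""
    model = PrecursorModel("check", peptide, signal_length=0)
    out = process_precursor(model, rules)
    return len(out) == 1 and out[0].sequence == peptide and not out[0].amidated


_SITE_RE = re.compile(r"^([KR])(\d+)([KR]?)$")


def parse_site_notation(text: str) -> tuple[int, str]:
    """Parse field notation like 'K45R', 'R113' or 'K152' ->
    (position of first basic, motif text)."""
    m = _SITE_RE.match(text)
    if not m:
        raise ValueError(f"unparseable cleavage-site notation: {text!r}")
    return int(m.group(2)), m.group(1) + m.group(3)
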