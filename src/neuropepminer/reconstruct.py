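"""Reconstruction of published precursor architectures from the catalog.

Only the mature and precursor-related peptide strings are printed in the
source tables; signal peptides and some linker segments are not. The
reconstructions here therefore place the *printed* components at their
published cleavage positions and fill the unprinted stretches with inert
placeholder residues (Met start + poly-Ala), which contain no basic, Gly,
Cys or Tyr residues and hence cannot create or suppress cleavage sites,
amidation or modifications. Every quantity measured on a reconstruction
(peptide lengths, amidation, cysteine counts) is independent of the
placeholder content.
"""
from __future__ import annotations

from .catalog import CatalogEntry, load_catalog
from .processing import PrecursorModel

# the invariant arthropod cardioactive nonapeptide, used as the reference
# for the 100%-identity check of the local CCAP mature peptide
CANONICAL_CCAP = "PFCNAFTGC"

RECONSTRUCTABLE = ("CLDH", "DH45", "CHH-1", "CHH-2", "CHH-3")


def _placeholder(n: int, start_met: bool = False) -> str:
    if n <= 0:
        return ""
    return ("M" + "A" * (n - 1)) if start_met else "A" * n


def _entry(entries: list[CatalogEntry], family: str) -> CatalogEntry:
    for e in entries:
        if e.family_name == family:
            return e
    raise KeyError(family)


def _mature(entry: CatalogEntry) -> str:
    return entry.mature_peptides[0].peptide_seq


def _related(entry: CatalogEntry) -> str:
    return entry.precursor_related_peptides[0].peptide_seq


def reconstruct(family: str, entries: list[CatalogEntry] | None = None
                ) -> PrecursorModel:
    """Rebuild one of the reconstructable precursors as a PrecursorModel."""
    entries = entries if entries is not None else load_catalog()
    e = _entry(entries, family)
    sig = e.signal_length
    if family == "CLDH":
        # sites K30R, K63R, R97R; 31-aa amidated mature at 65-95, Gly 96
        mature = _mature(e)
        seq = (_placeholder(sig, True) + _placeholder(29 - sig) + "KR"
               + _placeholder(62 - 31) + "KR" + mature + "G" + "RR"
               + _placeholder(e.precursor_length - 98))
    elif family == "DH45":
        # sites K170R, R180R, K228R; 45-aa amidated mature at 182-226, Gly 227
        mature = _mature(e)
        seq = (_placeholder(sig, True) + _placeholder(169 - sig) + "KR"
               + _placeholder(179 - 171) + "RR" + mature + "G" + "KR"
               + _placeholder(e.precursor_length - 229))
    elif family in ("CHH-1", "CHH-3"):
        # signal + CPRP + KR + mature + amidation Gly + terminal monobasic K
        seq = (_placeholder(sig, True) + _related(e) + "KR"
               + _mature(e) + "G" + "K")
    elif family == "CHH-2":
        # signal + CPRP + KR + mature (no amidation signal)
        seq = _placeholder(sig, True) + _related(e) + "KR" + _mature(e)
    else:
        raise KeyError(f"no reconstruction for {family!r} "
                       f"(available: {RECONSTRUCTABLE})")
    if len(seq) != e.precursor_length:
        raise AssertionError(
            f"{family}: reconstruction length {len(seq)} != catalog "
            f"precursor length {e.precursor_length}")
    return PrecursorModel(id=f"Mro-{family}", sequence=seq, signal_length=sig)


def reconstruct_all(entries: list[CatalogEntry] | None = None
                    ) -> dict[str, PrecursorModel]:
    entries = entries if entries is not None else load_catalog()
    return {fam: reconstruct(fam, entries) for fam in RECONSTRUCTABLE}
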