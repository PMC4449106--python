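"""Synthetic transcriptomes with fully-known embedded preproneuropeptides.

Each synthetic precursor is assembled the way the real ones are organised: a
signal peptide, then peptide "cassettes" separated by convertase motifs,
with a glycine inserted before the motif when the cassette is amidated. The
generator and the processing engine share one rule definition — every
architecture is validated by actually running the engine on the built
precursor and demanding exact agreement with the constructed truth, so a
cassette that would be cut internally (or a boundary motif the rules would
not cut) raises ``ambiguous cassette`` instead of producing silent
disagreement.

Default architectures mirror published decapod precursor layouts (SIFamide,
CCAP, sulfakinin, FLRFamide, PDH, CHH-style cassettes and their
precursor-related spacers). Decoy transcripts are random nucleotide
sequences re-sampled until they are provably inert against the default
query library (no >= 8-residue shared substring, best local-alignment score
below the search threshold), so synthetic false positives are impossible by
construction and any reported decoy hit is an engine bug.

Fragment counts follow a negative binomial (default mean 200, dispersion
0.5), the usual over-dispersed model for RNA-seq counts.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import reverse_complement

from .align import sw_score
from .processing import (DEFAULT_RULES, MaturePeptide, PrecursorModel,
                         RuleSet, find_cleavage_sites, predict_ptms,
                         process_precursor)
from .search import DEFAULT_MIN_SCORE, Query

AA20 = "ACDEFGHIKLMNPQRSTVWY"
CASSETTE_MOTIFS = ("KR", "RR", "KK", "RK", "K", "R", "none")
# residues used for random signal peptides: no basics (would create spurious
# sites at the cassette boundary), no G (spurious amidation), no C (would
# trigger disulfide-loop protection near a boundary)
_SIGNAL_ALPHABET = "ADEFHILMNPQSTVWY"

_table = CodonTable.unambiguous_dna_by_id[1]
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(_table.forward_table.items()):
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
_STOPS = sorted(_table.stop_codons)


class AmbiguousCassetteError(ValueError):
    pass


@dataclass(frozen=True)
class Cassette:
    seq: str
    amidated: bool = False
    motif: str = "KR"    # one of CASSETTE_MOTIFS


@dataclass(frozen=True)
class ArchitectureSpec:
    name: str
    signal_length: int
    cassettes: tuple[Cassette, ...]

    def __post_init__(self) -> None:
        if self.signal_length < 1:
            raise ValueError(f"{self.name}: signal_length must be >= 1")
        for c in self.cassettes:
            if not c.seq or set(c.seq) - set(AA20):
                raise ValueError(f"{self.name}: bad cassette sequence {c.seq!r}")
            if c.motif not in CASSETTE_MOTIFS:
                raise ValueError(f"{self.name}: bad motif {c.motif!r}")


@dataclass
class BuiltPrecursor:
    spec_name: str
    sequence: str
    signal_length: int
    peptides: list[MaturePeptide]
    cleavage_positions: list[int]


def build_precursor(spec: ArchitectureSpec, rng: np.random.Generator,
                    rules: RuleSet = DEFAULT_RULES) -> BuiltPrecursor:
    """Assemble a precursor from a spec and enumerate its expected products.

    The result is checked against the processing engine; any disagreement —
    a cassette with an internal cleavable motif, a boundary the rules would
    not cut — raises :class:`AmbiguousCassetteError`.
    """
    signal = "M" + "".join(rng.choice(list(_SIGNAL_ALPHABET),
                                      size=spec.signal_length - 1))
    parts = [signal]
    expected: list[MaturePeptide] = []
    sites: list[int] = []
    pos = spec.signal_length
    seen: dict[str, int] = {}
    for c in spec.cassettes:
        start = pos + 1
        parts.append(c.seq)
        pos += len(c.seq)
        if c.amidated:
            parts.append("G")
            pos += 1
        end = pos
        if c.motif != "none":
            parts.append(c.motif)
            sites.append(pos + 1)
            pos += len(c.motif)
        mods = predict_ptms(c.seq, rules=rules)
        seen[c.seq] = seen.get(c.seq, 0) + 1
        expected.append(MaturePeptide(
            sequence=c.seq, start=start, end=end, amidated=c.amidated,
            pyroglu=mods.pyroglu, sulfo_tyr=mods.sulfo_tyr,
            copy_index=seen[c.seq]))
    sequence = "".join(parts)
    built = BuiltPrecursor(spec.name, sequence, spec.signal_length,
                           expected, sites)
    _check_engine_agreement(built, rules)
    return built


def _check_engine_agreement(built: BuiltPrecursor, rules: RuleSet) -> None:
    model = PrecursorModel(built.spec_name, built.sequence,
                           signal_length=built.signal_length)
    got = process_precursor(model, rules)
    want = built.peptides
    same = (len(got) == len(want) and all(
        g.sequence == w.sequence and g.start == w.start and g.end == w.end
        and g.amidated == w.amidated and g.pyroglu == w.pyroglu
        and g.sulfo_tyr == w.sulfo_tyr
        for g, w in zip(got, want)))
    got_sites = [s.position for s in find_cleavage_sites(model, rules)]
    if not same or got_sites != built.cleavage_positions:
        raise AmbiguousCassetteError(
            f"ambiguous cassette in {built.spec_name}: engine products "
            f"{[p.sequence for p in got]} (sites {got_sites}) do not match "
            f"the constructed truth {[p.sequence for p in want]} "
            f"(sites {built.cleavage_positions})")


def reverse_translate(protein: str, rng: np.random.Generator,
                      append_stop: bool = True) -> str:
    """Back-translate with codons drawn uniformly among synonyms."""
    bad = set(protein) - set(AA20)
    if bad:
        raise ValueError(f"cannot reverse-translate residues {sorted(bad)}")
    codons = []
    for aa in protein:
        options = _CODONS_BY_AA[aa]
        codons.append(options[int(rng.integers(len(options)))])
    if append_stop:
        codons.append(_STOPS[int(rng.integers(len(_STOPS)))])
    return "".join(codons)


# ---------------------------------------------------------------------------
# default architecture library (decapod-style layouts)
# ---------------------------------------------------------------------------

DEFAULT_ARCHITECTURES: tuple[ArchitectureSpec, ...] = (
    ArchitectureSpec("SIFamide-like", 27, (
        Cassette("GYRKPPFNGSIF", True, "KR"),
        Cassette("SGGDPAYESGKTLASICQVAVEACSAWFPGPE", False, "none"))),
    ArchitectureSpec("sNPF-like", 25, (
        Cassette("DRTPALRLRF", True, "KR"),
        Cassette("APALRLRF", True, "KR"),
        Cassette("VPTPPDYDAALSDMYDLLSHGVE", False, "none"))),
    ArchitectureSpec("tachykinin-like", 25, (
        Cassette("APSGFLGMR", True, "KR"),
        Cassette("APSGFLGMR", True, "KR"),
        Cassette("SDASVEALASGTELDDLAKHVLAEAKLWEQLQNKMDVMRSLAARMDEQRPLY",
                 False, "none"))),
    ArchitectureSpec("CCAP-like", 28, (
        Cassette("SPVA", False, "KR"),
        Cassette("PFCNAFTGC", True, "KR"),
        Cassette("DIGGLLEGKD", False, "none"))),
    ArchitectureSpec("FLRFamide-like", 18, (
        Cassette("GYGDRNFLRF", True, "KR"),
        Cassette("DGGRNFLRF", True, "KR"),
        Cassette("ADKNFLRF", True, "KR"))),
    ArchitectureSpec("allatostatin-B-like", 25, (
        Cassette("ADWSSMRGTW", True, "KR"),
        Cassette("AGWNKFQGSW", True, "KR"),
        Cassette("NSWSSLQGSW", True, "RR"))),
    ArchitectureSpec("CLDH-like", 20, (
        Cassette("AVVEIDDPDYVLELLTRLGHSIIRANELENA", False, "KR"),
        Cassette("GLDLGLGRGFSGSQAAKHLMGLAAANFAGGP", True, "RR"),
        Cassette("SSDDAANTTHDLHHLEDNYAQEPAAVDSAAAAS", False, "none"))),
    ArchitectureSpec("myosuppressin-like", 31, (
        Cassette("MPPPICTDQKLPLSPYAQKLCAALNNIAEFSRAMEEYLDAKAIKNSMPINEPEV",
                 False, "KR"),
        Cassette("QDLDHVFLRF", True, "none"))),
    ArchitectureSpec("NPF-like", 29, (
        Cassette("KPDPTQLAAMADALKYLQELDKYYSQVSRPRF", True, "KR"),
        Cassette("SEYAVPPGDVLMEASERLMETLA", False, "none"))),
    ArchitectureSpec("sulfakinin-like", 32, (
        Cassette("QFDEYGHMRF", True, "KR"),
        Cassette("GGGAEYDDYGHLRF", True, "KR"),
        Cassette("APSKPSLALA", False, "none"))),
    ArchitectureSpec("RPCH-like", 21, (
        Cassette("QLNFSPGW", True, "KR"),
        Cassette("AAAAGVGTGSEAQLHSASGLALPGSSVTRGDNCASMQISTVMHIYRLI",
                 False, "none"))),
    ArchitectureSpec("PDH-like", 22, (
        Cassette("QEELKYPERQVVAELAAQILRIA", False, "KR"),
        Cassette("NSELINSLLGLPKVMTDA", True, "RR"))),
)


def default_query_library(
        specs: Sequence[ArchitectureSpec] = DEFAULT_ARCHITECTURES
        ) -> list[Query]:
    """All distinct cassette peptides of the architecture library."""
    queries: list[Query] = []
    seen: set[str] = set()
    for spec in specs:
        for i, c in enumerate(spec.cassettes, start=1):
            if c.seq in seen:
                continue
            seen.add(c.seq)
            queries.append(Query(f"{spec.name}.{i}", spec.name, c.seq))
    return queries


# ---------------------------------------------------------------------------
# transcriptome generation
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    transcript_id: str
    spec_name: str
    strand: str              # "+" | "-"
    frame: int               # reading frame of the ORF on the forward strand
    cds_start: int           # 1-based forward-strand span incl. stop codon
    cds_end: int
    precursor: str
    signal_length: int
    peptides: list[MaturePeptide]
    cleavage_positions: list[int]


@dataclass
class SyntheticDataset:
    seed: int
    transcripts: list[tuple[str, str]]          # (id, nucleotide sequence)
    truth: dict[str, TruthRecord]
    counts: "object"                            # pandas DataFrame
    n_decoys: int
    nb_mean: float
    nb_dispersion: float
    rules: RuleSet = field(default_factory=lambda: DEFAULT_RULES)

    def fasta_text(self) -> str:
        return "".join(f">{tid}\n{seq}\n" for tid, seq in self.transcripts)

    def truth_json(self) -> str:
        doc = {
            "seed": self.seed, "n_decoys": self.n_decoys,
            "nb_mean": self.nb_mean, "nb_dispersion": self.nb_dispersion,
            "rules": self.rules.to_dict(),
            "transcripts": {
                tid: {
                    "spec": t.spec_name, "strand": t.strand, "frame": t.frame,
                    "cds_start": t.cds_start, "cds_end": t.cds_end,
                    "precursor": t.precursor,
                    "signal_length": t.signal_length,
                    "cleavage_positions": t.cleavage_positions,
                    "peptides": [{
                        "seq": p.sequence, "start": p.start, "end": p.end,
                        "amidated": p.amidated, "pyroglu": p.pyroglu,
                        "sulfo_tyr": p.sulfo_tyr} for p in t.peptides],
                } for tid, t in sorted(self.truth.items())},
        }
        return json.dumps(doc, indent=1) + "\n"

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "transcripts": out / "transcripts.fasta",
            "truth": out / "truth.json",
            "counts": out / "counts.tsv",
            "signals": out / "signals.tsv",
            "queries": out / "queries.fasta",
        }
        paths["transcripts"].write_text(self.fasta_text())
        paths["truth"].write_text(self.truth_json())
        self.counts.to_csv(paths["counts"], sep="\t", index=False)
        with open(paths["signals"], "w") as fh:
            fh.write("transcript_id\tsignal_length\n")
            for tid, t in sorted(self.truth.items()):
                fh.write(f"{tid}\t{t.signal_length}\n")
        with open(paths["queries"], "w") as fh:
            for q in default_query_library():
                fh.write(f">{q.id} family={q.family}\n{q.seq}\n")
        return paths


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _decoy_is_inert(nt: str, queries: Sequence[Query], min_score: int) -> bool:
    from .orfs import translate
    kmers = {q.seq[i:i + 8] for q in queries for i in range(len(q.seq) - 7)}
    for frame in (1, 2, 3, -1, -2, -3):
        aa = translate(nt, frame)
        if any(aa[i:i + 8] in kmers for i in range(len(aa) - 7)):
            return False
        for q in queries:
            if sw_score(q.seq, aa) >= min_score:
                return False
    return True


def generate_transcriptome(
        n_precursors: int, n_decoys: int, seed: int,
        length_range: tuple[int, int] = (300, 900),
        utr_range: tuple[int, int] = (30, 300),
        specs: Sequence[ArchitectureSpec] = DEFAULT_ARCHITECTURES,
        reuse_specs: bool = False,
        nb_mean: float = 200.0, nb_dispersion: float = 0.5,
        min_score: int = DEFAULT_MIN_SCORE,
        rules: RuleSet = DEFAULT_RULES) -> SyntheticDataset:
    """Generate a deterministic synthetic transcriptome.

    ``n_precursors`` transcripts embed known precursor ORFs (random UTRs,
    random strand); ``n_decoys`` transcripts are query-inert random
    sequence. All randomness flows from ``seed``.
    """
    if n_precursors < 0 or n_decoys < 0:
        raise ValueError("counts must be >= 0")
    if n_precursors > len(specs) and not reuse_specs:
        raise ValueError(
            f"{n_precursors} precursors requested but only {len(specs)} "
            "architecture specs available (pass reuse_specs=True to cycle)")
    rng = np.random.default_rng(seed)
    queries = default_query_library(specs)
    transcripts: list[tuple[str, str]] = []
    truth: dict[str, TruthRecord] = {}
    for i in range(n_precursors):
        spec = specs[i % len(specs)]
        built = build_precursor(spec, rng, rules)
        cds = reverse_translate(built.sequence, rng)
        # the last 5'UTR codon is an in-frame stop, so the stop-to-stop ORF
        # containing the precursor starts exactly at the initiator Met
        len5 = int(rng.integers(utr_range[0], utr_range[1] + 1))
        utr5 = _random_nt(rng, len5 - 3) + _STOPS[int(rng.integers(len(_STOPS)))]
        utr3 = _random_nt(rng, int(rng.integers(utr_range[0], utr_range[1] + 1)))
        plus = utr5 + cds + utr3
        minus_strand = bool(rng.integers(2))
        tid = f"prec_{i:03d}"
        if minus_strand:
            final = reverse_complement(plus)
            frame = -((len(utr5) % 3) + 1)
            cds_start = len(utr3) + 1
            cds_end = len(utr3) + len(cds)
            strand = "-"
        else:
            final = plus
            frame = (len(utr5) % 3) + 1
            cds_start = len(utr5) + 1
            cds_end = len(utr5) + len(cds)
            strand = "+"
        transcripts.append((tid, final))
        truth[tid] = TruthRecord(
            tid, spec.name, strand, frame, cds_start, cds_end,
            built.sequence, built.signal_length, built.peptides,
            built.cleavage_positions)
    for j in range(n_decoys):
        tid = f"decoy_{j:03d}"
        for _attempt in range(100):
            n = int(rng.integers(length_range[0], length_range[1] + 1))
            nt = _random_nt(rng, n)
            if _decoy_is_inert(nt, queries, min_score):
                break
        else:
            raise RuntimeError("could not sample an inert decoy in 100 tries")
        transcripts.append((tid, nt))

    import pandas as pd
    p = nb_dispersion / (nb_dispersion + nb_mean)
    counts = pd.DataFrame({
        "transcript_id": [tid for tid, _ in transcripts],
        "fragment_count": rng.negative_binomial(nb_dispersion, p,
                                                size=len(transcripts)),
        "length_nt": [len(seq) for _, seq in transcripts],
    })
    return SyntheticDataset(seed, transcripts, truth, counts, n_decoys,
                            nb_mean, nb_dispersion, rules)
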