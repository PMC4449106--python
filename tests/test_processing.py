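"""Cleavage-site prediction, peptide release, PTMs, cysteine profiling."""
import numpy as np
import pytest

from neuropepminer.processing import (DEFAULT_RULES, PrecursorModel, RuleSet,
                                      check_no_internal_sites,
                                      crude_signal_length, cysteine_profile,
                                      find_cleavage_sites, parse_site_notation,
                                      predict_ptms, process_precursor,
                                      reassemble)
from neuropepminer.reconstruct import reconstruct

BASIC = set("KR")


# ---------------------------------------------------------------------------
# cleavage sites
# ---------------------------------------------------------------------------

def test_cldh_reconstruction_reports_printed_sites(catalog):
    model = reconstruct("CLDH", catalog)
    sites = find_cleavage_sites(model)
    assert [(s.position, s.residues) for s in sites] == \
        [(30, "KR"), (63, "KR"), (97, "RR")]


def test_all_alanine_has_no_sites():
    p = PrecursorModel("x", "A" * 50, signal_length=10)
    assert find_cleavage_sites(p) == []


def test_signal_region_is_never_scanned():
    p = PrecursorModel("x", "MKRA" + "A" * 20, signal_length=4)
    assert find_cleavage_sites(p) == []


def test_terminal_basic_site():
    p = PrecursorModel("x", "M" + "A" * 10 + "K", signal_length=1)
    sites = find_cleavage_sites(p)
    assert [(s.position, s.motif_class) for s in sites] == \
        [(12, "terminal-basic")]


def test_disulfide_loop_protects_internal_dibasic():
    # KR flanked by Cys within the protection window is skipped...
    seq = "M" + "A" * 10 + "CAKRAC" + "A" * 10
    p = PrecursorModel("x", seq, signal_length=1)
    assert find_cleavage_sites(p) == []
    # ...but the same KR without nearby Cys cleaves
    seq2 = "M" + "A" * 10 + "AAKRAA" + "A" * 10
    sites = find_cleavage_sites(PrecursorModel("x", seq2, signal_length=1))
    assert [s.motif_class for s in sites] == ["KR"]


def test_internal_monobasic_rule_is_opt_in():
    seq = "M" + "AAKAAAR" + "A" * 10  # R has a K at offset -4
    p = PrecursorModel("x", seq, signal_length=1)
    assert find_cleavage_sites(p) == []
    rules = RuleSet(internal_monobasic=True)
    sites = find_cleavage_sites(p, rules)
    assert [(s.position, s.motif_class) for s in sites] == [(8, "monoR")]


def test_extended_dibasic_motifs_are_opt_in():
    seq = "M" + "AAAKKAAA" + "AAARKAAA"
    p = PrecursorModel("x", seq, signal_length=1)
    assert find_cleavage_sites(p) == []
    rules = RuleSet(extended_dibasic=("KK", "RK"))
    assert [s.residues for s in find_cleavage_sites(p, rules)] == ["KK", "RK"]


def _oracle_sites(seq, signal, rules):
    """Independent brute-force re-statement of the site rules."""
    window = rules.cys_protection_window

    def protected(lo, hi):  # 0-based [lo, hi)
        if window <= 0:
            return False
        return ("C" in seq[max(0, lo - window):lo]
                and "C" in seq[hi:hi + window])

    motifs = list(rules.dibasic) + list(rules.extended_dibasic)
    out = []
    taken_until = signal  # 1-based
    for pos in range(signal + 1, len(seq) + 1):
        if pos <= taken_until:
            continue
        two = seq[pos - 1:pos + 1]
        if two in motifs and not protected(pos - 1, pos + 1):
            out.append((pos, two))
            taken_until = pos + 1
            continue
        c = seq[pos - 1]
        if c not in BASIC:
            continue
        if pos == len(seq) and rules.terminal_basic and not protected(pos - 1, pos):
            out.append((pos, c))
        elif rules.internal_monobasic:
            helpers = [pos + o for o in rules.monobasic_offsets]
            if any(h > signal and seq[h - 1] in BASIC for h in helpers) \
                    and not protected(pos - 1, pos):
                out.append((pos, c))
    return out


@pytest.mark.parametrize("rules", [
    DEFAULT_RULES,
    RuleSet(extended_dibasic=("KK", "RK")),
    RuleSet(internal_monobasic=True),
    RuleSet(extended_dibasic=("KK", "RK"), internal_monobasic=True,
            cys_protection_window=0),
])
def test_site_finder_matches_brute_force_oracle(rules):
    rng = np.random.default_rng(77)
    alphabet = list("ACDEFGHIKLMNPQRSTVWYKRKRC")  # basic/Cys enriched
    for _ in range(500):
        n = int(rng.integers(5, 80))
        seq = "".join(rng.choice(alphabet, size=n))
        sig = int(rng.integers(0, min(6, n)))
        p = PrecursorModel("r", seq, signal_length=sig)
        got = [(s.position, s.residues) for s in find_cleavage_sites(p, rules)]
        assert got == _oracle_sites(seq, sig, rules), (seq, sig)


# ---------------------------------------------------------------------------
# peptide release
# ---------------------------------------------------------------------------

def test_chh2_releases_cprp_and_mature(catalog):
    peps = process_precursor(reconstruct("CHH-2", catalog))
    assert [(len(p), p.amidated) for p in peps] == [(33, False), (73, False)]
    assert peps[0].sequence.endswith("ALNLK")  # CPRP keeps its printed C-term


def test_chh3_releases_amidated_72mer_via_terminal_monobasic(catalog):
    model = reconstruct("CHH-3", catalog)
    sites = find_cleavage_sites(model)
    assert [s.motif_class for s in sites] == ["KR", "terminal-basic"]
    peps = process_precursor(model)
    assert [(len(p), p.amidated) for p in peps] == [(58, False), (72, True)]


def test_precursor_without_sites_returns_single_peptide():
    p = PrecursorModel("x", "M" * 5 + "AAAA", signal_length=5)
    peps = process_precursor(p)
    assert len(peps) == 1
    pep = peps[0]
    assert pep.sequence == "AAAA" and not pep.amidated
    assert pep.pyroglu is None and pep.sulfo_tyr == []


def test_signal_required():
    p = PrecursorModel("x", "MAAAA")
    with pytest.raises(ValueError, match="signal required"):
        process_precursor(p)


def test_amidation_requires_glycine_donor():
    with_g = process_precursor(
        PrecursorModel("x", "MMMAAAFG" + "KR" + "AAAA", signal_length=3))
    without = process_precursor(
        PrecursorModel("x", "MMMAAAF" + "KR" + "AAAA", signal_length=3))
    assert with_g[0].amidated and with_g[0].sequence == "AAAF"
    assert not without[0].amidated


def test_trailing_basic_trimming_is_opt_in():
    p = PrecursorModel("x", "MMM" + "AAAFGKK" + "RRAAAA", signal_length=3)
    rules = RuleSet(extended_dibasic=("KK", "RK"), trim_trailing_basics=True)
    peps = process_precursor(p, rules)
    assert peps[0].sequence == "AAAF" and peps[0].amidated


def test_inserting_dibasic_pair_adds_exactly_one_peptide():
    rng = np.random.default_rng(21)
    base = "M" + "".join(rng.choice(list("ADEFHILNPQSTVWY"), size=40))
    p0 = PrecursorModel("x", base, signal_length=1)
    n0 = len(process_precursor(p0))
    cut = base[:20] + "KR" + base[20:]
    n1 = len(process_precursor(PrecursorModel("x", cut, signal_length=1)))
    assert n1 == n0 + 1


def test_released_peptides_are_idempotent_under_reprocessing(catalog):
    # peptides ending in K/R (the CHH-type CPRP) are excluded: on
    # re-processing their last residue is, by definition, a terminal site
    for fam in ("CLDH", "DH45", "CHH-1", "CHH-2", "CHH-3"):
        for pep in process_precursor(reconstruct(fam, catalog)):
            if pep.sequence[-1] in BASIC or pep.sequence.endswith("G"):
                continue
            assert check_no_internal_sites(pep.sequence), (fam, pep.sequence)


def test_residue_conservation_reassembly(catalog):
    rng = np.random.default_rng(3)
    models = [reconstruct(f, catalog)
              for f in ("CLDH", "DH45", "CHH-1", "CHH-2", "CHH-3")]
    for _ in range(200):
        n = int(rng.integers(10, 90))
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
        models.append(PrecursorModel("r", seq,
                                     signal_length=int(rng.integers(0, 5))))
    for rules in (DEFAULT_RULES, RuleSet(extended_dibasic=("KK", "RK"),
                                         trim_trailing_basics=True)):
        for m in models:
            peps = process_precursor(m, rules)
            sites = find_cleavage_sites(m, rules)
            assert reassemble(m, peps, sites) == m.sequence, m.id


# ---------------------------------------------------------------------------
# PTMs and cysteine profile
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("pep,pyroglu,sulfo", [
    ("QFDEYGHMRF", "Q", [5]),          # sulfakinin I: pQ + one sulfo-Tyr
    ("GGGAEYDDYGHLRF", None, [6, 9]),  # sulfakinin II: two sulfo-Tyr
    ("AAAA", None, []),
    ("EASRLVQCQDEEYLA", "E", [13]),    # putative pyroGlu from Glu
    ("YAAAAAAD", None, []),            # acidic residue outside +-5 window
    ("YAAAAD", None, [1]),
])
def test_ptm_prediction(pep, pyroglu, sulfo):
    mods = predict_ptms(pep)
    assert mods.pyroglu == pyroglu
    assert mods.sulfo_tyr == sulfo


def test_ptm_empty_peptide_rejected():
    with pytest.raises(ValueError):
        predict_ptms("")


def test_cysteine_profiles_of_printed_peptides(catalog_by_family):
    eh = catalog_by_family["EH"].mature_peptides[0].peptide_seq
    np1 = catalog_by_family["NP-1"].mature_peptides[0].peptide_seq
    prof_eh, prof_np = cysteine_profile(eh), cysteine_profile(np1)
    assert (prof_eh.count, prof_eh.max_pairs) == (6, 3)
    assert (prof_np.count, prof_np.max_pairs) == (12, 6)
    small = cysteine_profile("ACA")
    assert (small.count, small.even_parity, small.max_pairs) == (1, False, 0)


# ---------------------------------------------------------------------------
# odds and ends
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("text,expected", [
    ("K45R", (45, "KR")), ("R97R", (97, "RR")), ("R113", (113, "R")),
    ("K152", (152, "K"))])
def test_site_notation_parsing(text, expected):
    assert parse_site_notation(text) == expected


def test_crude_signal_heuristic_is_sane():
    # hydrophobic head followed by a small-residue cleavage point
    seq = "MKTLLILAVLAAVSA" + "QDDFETPKRSAY" * 3
    guess = crude_signal_length(seq)
    assert guess is not None and 8 <= guess <= 30
    assert crude_signal_length("MDDEDDEDDEDDEDDEDDE") is None
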