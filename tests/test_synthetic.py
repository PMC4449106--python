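"""Synthetic transcriptome generator: construction, truth, determinism."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuropepminer.orfs import translate
from neuropepminer.processing import PrecursorModel, process_precursor
from neuropepminer.synthetic import (AmbiguousCassetteError, ArchitectureSpec,
                                     Cassette, DEFAULT_ARCHITECTURES,
                                     build_precursor, default_query_library,
                                     generate_transcriptome,
                                     reverse_translate)

AA = "ACDEFGHIKLMNPQRSTVWY"


def test_sifamide_style_cassette_layout():
    """27-residue signal + amidated 12-mer + KR places the amidation Gly at
    40 and the dibasic site at 41-42, total length 42."""
    spec = ArchitectureSpec("sif", 27, (Cassette("GYRKPPFNGSIF", True, "KR"),))
    built = build_precursor(spec, np.random.default_rng(0))
    assert len(built.sequence) == 27 + 12 + 1 + 2 == 42
    assert built.sequence[39] == "G"
    assert built.sequence[40:42] == "KR"
    assert built.cleavage_positions == [41]
    [pep] = built.peptides
    assert pep.sequence == "GYRKPPFNGSIF" and pep.amidated
    assert (pep.start, pep.end) == (28, 40)


def test_signal_only_spec_yields_no_peptides():
    built = build_precursor(ArchitectureSpec("sig", 20, ()),
                            np.random.default_rng(1))
    assert len(built.sequence) == 20
    assert built.peptides == [] and built.cleavage_positions == []


def test_two_cassettes_second_non_amidated_terminal_monobasic():
    spec = ArchitectureSpec("two", 10, (
        Cassette("AWDFNEWQPT", True, "KR"),
        Cassette("DFINEWPQST", False, "K")))
    built = build_precursor(spec, np.random.default_rng(2))
    assert [p.amidated for p in built.peptides] == [True, False]
    assert [p.sequence for p in built.peptides] == ["AWDFNEWQPT", "DFINEWPQST"]


def test_cassette_with_internal_cleavable_motif_is_rejected():
    spec = ArchitectureSpec("bad", 10, (Cassette("AAKRAA", False, "KR"),))
    with pytest.raises(AmbiguousCassetteError, match="ambiguous cassette"):
        build_precursor(spec, np.random.default_rng(3))


def test_mid_precursor_monobasic_motif_is_rejected_under_default_rules():
    spec = ArchitectureSpec("bad", 10, (
        Cassette("AWDFNEWQPT", False, "K"),
        Cassette("DFINEWPQST", False, "none")))
    with pytest.raises(AmbiguousCassetteError):
        build_precursor(spec, np.random.default_rng(4))


def test_default_architectures_all_build():
    rng = np.random.default_rng(5)
    for spec in DEFAULT_ARCHITECTURES:
        built = build_precursor(spec, rng)
        model = PrecursorModel(spec.name, built.sequence,
                               signal_length=spec.signal_length)
        got = [(p.sequence, p.amidated) for p in process_precursor(model)]
        want = [(p.sequence, p.amidated) for p in built.peptides]
        assert got == want


@given(st.text(alphabet=AA, min_size=1, max_size=40),
       st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_reverse_translate_round_trip(protein, seed):
    nt = reverse_translate(protein, np.random.default_rng(seed))
    assert translate(nt, 1) == protein + "*"
    again = reverse_translate(protein, np.random.default_rng(seed))
    assert nt == again


def test_reverse_translate_rejects_non_canonical():
    with pytest.raises(ValueError):
        reverse_translate("AXB", np.random.default_rng(0))


def test_zero_precursors_gives_only_decoys():
    ds = generate_transcriptome(0, 5, seed=1, length_range=(150, 300))
    assert len(ds.transcripts) == 5
    assert ds.truth == {}
    assert all(tid.startswith("decoy") for tid, _ in ds.transcripts)


def test_generation_is_byte_deterministic():
    a = generate_transcriptome(4, 3, seed=42, length_range=(150, 300))
    b = generate_transcriptome(4, 3, seed=42, length_range=(150, 300))
    assert a.fasta_text() == b.fasta_text()
    assert a.truth_json() == b.truth_json()
    assert a.counts.equals(b.counts)
    c = generate_transcriptome(4, 3, seed=43, length_range=(150, 300))
    assert a.fasta_text() != c.fasta_text()


def test_spec_exhaustion_requires_reuse_flag():
    with pytest.raises(ValueError, match="reuse_specs"):
        generate_transcriptome(len(DEFAULT_ARCHITECTURES) + 1, 0, seed=0)
    ds = generate_transcriptome(len(DEFAULT_ARCHITECTURES) + 1, 0, seed=0,
                                reuse_specs=True)
    assert len(ds.transcripts) == len(DEFAULT_ARCHITECTURES) + 1


def test_decoy_purity_no_shared_8mers(small_dataset):
    queries = default_query_library()
    kmers = {q.seq[i:i + 8] for q in queries for i in range(len(q.seq) - 7)}
    for tid, nt in small_dataset.transcripts:
        if not tid.startswith("decoy"):
            continue
        for frame in (1, 2, 3, -1, -2, -3):
            aa = translate(nt, frame)
            assert not any(aa[i:i + 8] in kmers for i in range(len(aa) - 7))


def test_truth_table_matches_engine_exactly(small_dataset):
    for tid, t in small_dataset.truth.items():
        model = PrecursorModel(tid, t.precursor, signal_length=t.signal_length)
        got = process_precursor(model)
        assert [(p.sequence, p.start, p.end, p.amidated, p.pyroglu,
                 tuple(p.sulfo_tyr)) for p in got] == \
               [(p.sequence, p.start, p.end, p.amidated, p.pyroglu,
                 tuple(p.sulfo_tyr)) for p in t.peptides]


def test_embedded_orf_frame_annotation(small_dataset):
    for tid, t in small_dataset.truth.items():
        nt = dict(small_dataset.transcripts)[tid]
        aa = translate(nt, t.frame)
        assert t.precursor in aa


def test_counts_table_is_complete_and_overdispersed():
    ds = generate_transcriptome(6, 40, seed=9, length_range=(150, 250))
    assert list(ds.counts["transcript_id"]) == [t for t, _ in ds.transcripts]
    counts = ds.counts["fragment_count"].to_numpy(dtype=float)
    assert (counts >= 0).all()
    # variance far above the mean is the negative-binomial signature
    assert counts.var() > 2 * counts.mean()


def test_written_outputs(tmp_path, small_dataset):
    paths = small_dataset.write(tmp_path)
    assert paths["transcripts"].read_text().startswith(">prec_000")
    assert "signal_length" in paths["signals"].read_text().splitlines()[0]
    assert paths["queries"].read_text().count(">") == \
        len(default_query_library())
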