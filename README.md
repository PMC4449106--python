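# neuropepminer

In-silico neuropeptidome mining for crustacean (and other invertebrate)
transcriptomes. Starting from assembled transcript nucleotide sequences,
`neuropepminer`:

1. translates all six reading frames and extracts stop-to-stop ORFs;
2. finds candidate neuropeptide precursors by exact Smith–Waterman search of
   a query library of known mature peptides against those ORFs (a
   desk-scale, fully reproducible replacement for a tBLASTn screen);
3. predicts prohormone-convertase cleavage sites on each precursor, releases
   the mature and precursor-related peptides, and annotates C-terminal
   amidation, N-terminal pyroglutamate and putative sulfotyrosines;
4. classifies released peptides into neuropeptide families from a
   data-driven consensus-motif table (SIFamide, sulfakinins, FLRFamides,
   sNPF/NPF, allatostatins, the CHH/MIH cysteine superfamily, …);
5. computes percent identity/similarity (Clustal `*`/`:`/`.` symbol
   convention, divided by the longer sequence) and per-transcript FPKM.

It is written for molecular physiologists who have a transcriptome and a
list of known peptides and want the precursor calls, peptide sets, and
expression summaries with every rule explicit and testable. The package
ships a machine-readable catalog of 37 decapod preproneuropeptide entries
(precursor/signal lengths, 132 peptide rows with modification annotations,
per-tissue FPKM) that serves as its regression surface, plus a synthetic
transcriptome generator with exact ground truth.

## The model in brief

A preproneuropeptide is `signal ∣ P₁ ∣ s₁ ∣ P₂ ∣ s₂ ∣ …` where the `Pᵢ` are
peptide cassettes and the `sᵢ` are basic convertase sites. The default rule
set cleaves C-terminal of KR and RR dibasics and of a terminal monobasic
K/R, skips candidates buried between cysteines (disulfide-constrained
loops), and leaves KK/RK and internal monobasic cleavage as opt-in flags —
the calibration that reproduces published decapod architectures, where
bioactive peptides themselves frequently contain unprocessed KK/RK. A
cassette ending in Gly before its site is amidated on the preceding
residue. Identity metrics follow

    %identity  = 100 · n(*) / len(longest)
    %similarity = 100 · (n(*) + n(:) + n(.)) / len(longest)

and expression follows the printed-formula FPKM
`(10⁶·C)/(N·L·10³)` (with `convention="standard"` for the usual
`10⁹·C/(N·L)` scale; the two differ only by a constant factor).

## Worked example

```python
from neuropepminer import (reconstruct, find_cleavage_sites,
                           process_precursor, classify)

model = reconstruct("CHH-3")   # catalog-derived precursor reconstruction
print(f"{model.id}: {len(model.sequence)} aa, signal {model.signal_length}")
for s in find_cleavage_sites(model):
    print(f"  site {s.residues} at {s.position} ({s.motif_class})")
for pep in process_precursor(model):
    fam, _ = classify(pep)
    print(f"  peptide {pep.start}-{pep.end}: {len(pep)} aa, "
          f"amidated={pep.amidated}, family={fam}")
```

prints

```
Mro-CHH-3: 152 aa, signal 18
  site KR at 77 (KR)
  site K at 152 (terminal-basic)
  peptide 19-76: 58 aa, amidated=False, family=unclassified
  peptide 79-151: 72 aa, amidated=True, family=CHH-superfamily
```

i.e. the third CHH isoform precursor is cut at the K⁷⁷R dibasic and at the
terminal monobasic K¹⁵², releasing its 58-residue precursor-related peptide
and a 72-residue amidated mature hormone that the classifier places in the
six-cysteine CHH superfamily.

The command line mirrors the library:

```bash
neuropepminer synth --n-precursors 10 --n-decoys 50 --seed 42 --out-dir demo/
neuropepminer mine --transcripts demo/transcripts.fasta \
    --queries demo/queries.fasta --signals demo/signals.tsv \
    --counts demo/counts.tsv --out demo/run/
```

which writes `summary.tsv` (one row per candidate precursor: family,
lengths, peptide counts, FPKM), `peptides.fasta`, an `architecture.gff`
annotation, `hits.tsv` and a `manifest.json` carrying the config, rule set
and seed.

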