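# Methods

## Scope and design

`neuropepminer` reimplements the desk half of a transcriptome-to-
neuropeptidome workflow: translated homology search, precursor processing,
modification prediction, family classification, and the bookkeeping metrics
(identity/similarity, FPKM). Everything upstream (read cleaning, de novo
assembly) and everything instrument-facing (spectrum searching) is out of
scope; signal-peptide lengths are *inputs*, not predictions, because neural
signal predictors are a separate, well-served problem.

## Six-frame translation and ORFs

ORFs are maximal stop-to-stop segments (not Met-to-stop) in all six frames,
because homology queries are mature peptides that can land mid-precursor
and transcript 5' ends are often truncated; the initiator-Met requirement
is applied only when a full precursor call is emitted (calls without any
Met are flagged partial). Codons containing N translate to `X`, and `X`
scores 0 against every residue so ambiguity neither creates nor destroys
hits. Coordinates are 1-based inclusive on the forward strand in every
frame, matching the K(n)R residue notation used throughout.

## Homology search

The mining stage is exact Smith–Waterman (Gotoh affine-gap DP) of each
query peptide against each ORF: BLOSUM62, gap open 11, gap extend 1 (a gap
of length L costs 11 + L), raw-score threshold 40. At desk scale
(≤10⁴ ORFs × ≤10² queries) the O(nm) cost is irrelevant and exactness buys
full reproducibility and freedom from seeding heuristics and E-value
machinery. The published screen reported no E-value cutoff for this stage,
so the raw threshold is a declared default; 40 raw ≈ 21 bits sits above
anything random 20-letter sequence reaches at these lengths (verified
empirically by the decoy-purity property) while every default query's
self-score but one exceeds it. An approximate bit score (ungapped
Karlin–Altschul constants λ = 0.3176, K = 0.134) is reported for
orientation only. The score-only kernel is vectorised over the query
dimension with the vertical gap state recovered as a running maximum
(extending a vertical gap from inside another vertical gap never beats
opening directly from its source cell, so the closed form is exact); the
traceback DP runs only on reported hits. Both kernels are cross-checked in
the tests against Biopython's `PairwiseAligner` and against an
independently written brute-force DP.

## Precursor processing rules

The default `RuleSet` was calibrated on published decapod precursor
architectures and is serialized into every run manifest:

| rule | default | why |
| --- | --- | --- |
| dibasic KR, RR | cleave | the canonical convertase sites; every printed dibasic site in the regression catalog is KR or RR |
| dibasic KK, RK | opt-in | real bioactive peptides (CRF-like diuretic hormone; CHH matures) contain internal KK/RK that are demonstrably not processed; a blanket rule would dissect them |
| internal monobasic (basic at −4/−6/−8) | opt-in | same failure mode: the CRF-like DH mature carries basics at those offsets from internal arginines yet is released intact |
| terminal monobasic K/R | cleave | the "…Gly-Lys-stop" ending of amidated CHH-type matures |
| disulfide-loop protection (Cys ≤ 10 residues on both sides) | on | convertases cannot access basics inside disulfide-constrained loops; the third CHH isoform's mature contains an internal KR between cysteines 2 residues away |
| carboxypeptidase trimming of trailing K/R | opt-in | with site residues removed at the cut, trimming is redundant for amidation and would shorten the CHH precursor-related peptide below its observed 33-mer form |

Overlapping candidates resolve left-to-right, longest motif first; the
stored site position is the first basic residue and the cut falls
C-terminal of the last. After splitting, a fragment ending in Gly loses the
Gly and gains the amidated flag (the Gly nitrogen becomes the amide).
Degenerate inputs: empty fragments between back-to-back sites are dropped;
`signal_length == len(sequence)` is a valid signal-only precursor with no
products; `X` is never basic, never Gly, never Tyr for rule purposes.

Residue conservation is an enforced invariant: signal + peptides + removed
site residues + removed amidation glycines + trimmed basics reassembles the
precursor exactly, string-equal.

PTMs: N-terminal Gln is flagged pyroglutamate (high confidence), N-terminal
Glu likewise but inherently putative; each Tyr with ≥ 1 Asp/Glu within ±5
peptide positions is a putative sulfotyrosine. The ±5 acidic window is a
declared default — it reproduces every sulfotyrosine annotation in the
shipped catalog (sulfakinins and acidic-context related peptides) but is
labelled putative because windowed context is a proxy, not a measurement.

## Family classification

The rule table is data (`data/family_rules.tsv`): anchored regular
expressions over the processed peptide plus amidation and length gates,
tested in priority order, first full match wins. Cysteine-skeleton families
carry no usable linear motif and are gated on exact Cys count plus a length
window instead (eclosion hormone: 6 Cys, 50–62 aa; CHH/MIH superfamily:
6 Cys, 66–80 aa; neuroparsin: 12 Cys, 70–80 aa). Myosuppressin is separated
from the generic FLRFamide rule by an exact-sequence rule at higher
priority; the CRF-like DH rule is a pure amidation + 40–50 aa length gate,
the weakest rule in the table, kept last among the regex rules. Bursicon
subunits, the female sex hormone and the neurophysin-like peptide have no
published motif and are deliberately unclassifiable (listed in the catalog
fixture); classified peptides are labelled bioactive, everything else
precursor-related. On the full shipped catalog every named mature peptide
classifies into its own family and no precursor-related peptide matches any
rule.

## Identity and similarity

Pairwise global Needleman–Wunsch (affine, same scoring as the search stage)
replaces a progressive multiple aligner for pairwise metrics. The `*`, `:`
and `.` symbols follow the classic Clustal conservation groups (shipped as
`data/clustal_groups.json`), and both percentages divide by the longer
unaligned sequence. Because co-optimal global alignments can differ in
identical-column count, `identity_similarity` canonicalises argument order
before aligning, making the metric exactly symmetric. Published
cross-species percentages obtained with a progressive aligner are therefore
comparable only as ranges, and are not regression-gated.

## FPKM

Implemented exactly as printed for this data set,
`FPKM = (10⁶·C)/(N·L·10³)`, which is a constant 10⁶ below the conventional
`10⁹·C/(N·L)`; `convention="standard"` switches. Fidelity to the printed
formula comes first because the catalog's FPKM columns are fixture data on
that scale; since the two conventions differ by a constant, all ratios,
rankings and linearity properties are convention-independent. Raw fragment
counts for the original tissues are not available, so catalog FPKM values
are never recomputation targets.

## Synthetic data

The generator emulates exactly the structure the pipeline exploits: a
transcript is 5'UTR + CDS + 3'UTR on a random strand (50/50), the CDS is a
uniform-synonymous-codon back-translation of a built precursor, and UTR
lengths are uniform in [30, 300] nt — small but realistic flanks that
exercise ORF finding in all six frames. The last 5'UTR codon is an in-frame
stop so the stop-to-stop ORF begins at the true initiator Met (real 5'UTRs
almost always terminate the upstream frame; without this the precursor
call can start at a spurious upstream Met). Twelve default architectures
mirror published decapod layouts (SIFamide, sNPF, tachykinin, CCAP,
FLRFamide, allatostatin-B, CLDH, myosuppressin, NPF, sulfakinin, RPCH, PDH
style cassettes with their related-peptide spacers). Every architecture is
validated by running the processing engine on the built precursor and
demanding exact agreement with the constructed truth — an internal
cleavable motif or an uncleavable boundary raises `ambiguous cassette`
instead of silently corrupting the truth table. Random signal-peptide
residues avoid K/R/G/C so they cannot create or suppress sites.

Decoys are uniform random nucleotide sequences re-sampled until inert
against the default query library: no ≥ 8-residue shared substring in any
frame and best local-alignment score below the search threshold. False
discoveries on synthetic data are therefore impossible by construction, so
the recall/FDR property tests validate the *pipeline machinery* (ORF
extraction, scoring, collation), not the statistical discrimination of the
threshold on real data. Fragment counts are negative binomial with mean
200 and dispersion 0.5 — the over-dispersed shape typical of RNA-seq gene
counts — and both parameters are recorded in the truth table.

What the generator does **not** emulate: sequencing error, assembly
artifacts and chimeras, alternative splicing, polymorphism, compositional
bias, and homologous-but-diverged precursors (decoys are random, not
near-miss). Passing the synthetic suite therefore demonstrates correctness
of the mechanics under the stated model, not expected sensitivity or
specificity on real transcriptomes.

## Reconstructions and placeholders

Only mature and precursor-related peptide strings are published for the
catalog entries; signal peptides and some linkers are not. Reconstructions
place the printed components at the published cleavage positions and fill
unprinted stretches with Met + poly-Ala placeholders, which contain no
basic, Gly, Cys or Tyr and hence cannot perturb site finding, amidation or
modification calls. Every reconstruction is length-checked against the
published precursor length at build time, and every quantity measured on a
reconstruction is independent of placeholder content.

## Problem sizes and numerical choices

The shipped tests run the synthetic pipeline at 3–6 precursors with 3–6
decoys per seed (20 seeds for the recall/FDR property), the cleavage-site
oracle at 10⁴ random sequences, and alignment-oracle equivalence at a few
hundred random pairs — sizes chosen so the whole suite completes in about
two minutes on one CPU while still exercising every code path; all scale
linearly if larger runs are wanted. All randomness flows through explicit
`numpy` generators seeded per call; fixed seeds give byte-identical FASTA,
truth JSON and count tables. Alignment DP uses 64-bit integer scores
(no floating-point ties); deterministic tie-breaks are documented on each
aligner (smallest target end then diagonal-first locally; match before
gap, gap-in-second-sequence before gap-in-first globally).

## Known limitations

* Cleavage rules are positional and local; they carry no learned scoring,
  so unusual sites (acidic-context monobasics, atypical convertases) need
  rule-set edits, and the disulfide-loop window (10 residues) is a
  structural proxy rather than a computed topology.
* The published sulfation and pyroglutamate calls were homology-based; the
  windowed rules here reproduce them but will over-call sulfotyrosine in
  acidic, Tyr-rich sequence.
* Family rules are only as sharp as their motifs: cysteine-count gates
  cannot separate CHH from MIH, and length windows were set from the
  shipped catalog.
* The crude hydropathy signal-length heuristic exists for exploratory use
  only; it is off by default and never used in any test or report.
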