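# Methods

## The problem and the data model

A transcribed enhancer produces a short noncoding RNA whose boundaries,
chromatin context and expression behavior together characterize the
element. This package implements the three measurement layers such a study
needs — RACE-seq transcript-boundary mapping, ChIP signal tracks with
chromatin-state classification, and qPCR/reporter quantitation — as a
reusable pipeline, together with a synthetic-data module that defines the
study conditions precisely enough for every stage to be tested end to end.

Coordinates are 1-based inclusive genomic throughout; BED/bedGraph exports
convert to 0-based half-open. TSS-relative coordinates use the
promoter-construct convention: the TSS base is +1, the base upstream of it
is −1, and position 0 does not exist.

## The synthetic locus

The packaged configuration models a 12-kb mini-genome with the pri-miR TSS
at position 10,000 on the + strand and an enhancer at −5771..−4607. The
eRNA transcribed from it has:

- a 5'-end distribution with a dominant mode at −5185 (probability 0.40)
  and nine near-modal minor starts between −5195 and −5170 — the
  heterogeneous-initiation pattern of a CpG-island promoter;
- a more homogeneous 3'-end distribution with mode −5000
  (probability 0.70) and four minor ends between −5005 and −4996;
- sense transcription ~5-fold over antisense (antisense fraction 1/6);
- a consensus interval −5185..−5000 (186 nt inclusive) whose realized GC
  is held within ±0.05 of 0.63, against a 0.50-GC background genome.

Reads are built as `barcode ⊕ library-adapter ⊕ insert ⊕ tail ⊕
RACE-adapter`. The insert's fixed inner boundary is the gene-specific
primer (GSP) site, as in real RACE chemistry: a 5' product runs from its
drawn start to the 5'-GSP site (−5071..−5052) and carries a poly(C)-derived
tail; a 3' product runs from the 3'-GSP site (−5062..−5043) to its drawn
end and carries a poly(A) tail from in-vitro polyadenylation (the
transcript itself is non-polyadenylated). The two GSP sites overlap by
10 bp so that neither primer is fully contained in the other product
class's insert. Tail lengths are uniform on 8–16 nt, substitution errors
i.i.d. per base across the whole read (default 1%), 2% of reads are
off-target uniform reference slices, and qualities are constant Phred 30
(no stage uses them). Barcodes are the four Ion Xpress 5–8 sequences
(pairwise Hamming distance ≥ 5, checked against the demultiplexer's
mismatch budget).

**End-base pinning.** The reference base at every modelled eRNA end
position is set to C in transcript orientation. Two reasons: CpG-island
initiators favor a C/G start (the modal start of the modelled transcript
is a C), and — decisively — a templated terminal A is indistinguishable
from the in-vitro poly(A) tail, so a 3' end falling on an A is not
identifiable by any 3'-RACE analysis; pinning keeps the generator's truth
recoverable in principle rather than by luck of the sequence draw. This is
the one place the generator constrains the reference to the measurement's
identifiability limit; everything else about the sequence is random.

**What the generator does not emulate:** indel sequencing errors and
flow-space (homopolymer-length) error modes of the real instrument, PCR
duplicates and amplification jackpots, chimeric reads, and per-cell-line
differences in end usage (all four pools share one end distribution).
Passing tests therefore demonstrate correct bookkeeping and statistical
behavior of the pipeline under substitution noise, barcode collisions,
off-target contamination and antisense admixture — not robustness to
indel-rich instruments, for which the aligner's affine gap model is
present but untested against a matched error model.

## Read processing

Demultiplexing is prefix-anchored Hamming matching at each barcode's own
length: assign to the unique barcode with minimal distance ≤ max_mismatch
(default 1); ties go to unassigned rather than to an arbitrary winner. N
counts as a mismatch everywhere. Adapter trimming considers every partial
overlap ≥ min_overlap (default 5) anchored at the stated end and removes
the longest overlap with mismatch fraction ≤ 0.1. Homopolymer-tail
trimming strips the maximal terminal run containing ≥ min_run (default 5)
matching bases and at most max_interruptions (default 0) others, ending on
a matching base.

Classification precedes tail trimming: the class is decided by which GSP
(either orientation) matches better within the read (qualifying overlap
≥ 12, error ≤ 0.1; exact score ties → unclassified), and only then is the
class-appropriate tail base trimmed. Ordering it this way means a poly(C)
trim can never eat genomic bases off a 3' product's measured end, at the
cost of classifying against reads that still carry their tails — harmless,
since the GSP lies inside the insert. Products shorter than 20 nt after
trimming are dropped (mirroring the bench gel selection, at a configurable
threshold).

## Mapping

The aligner is a desk-scale seed-and-extend design for kilobase
references: an exhaustive k-mer index (default k=11) of the forward
strand; seeds collected for the read and its reverse complement; seeds
clustered by alignment diagonal (drift tolerance 16 bp); and a local
affine-gap alignment (+2/−3/−5/−2, first gap base costs the open penalty)
over a reference window padded by `band` (default 32 bp) around the best
cluster. The windowed dynamic program is delegated to
`Bio.Align.PairwiseAligner`; the seeding, clustering, windowing, strand
resolution and tie-breaking (score, then identity, then leftmost start,
then + strand) are this package's own, and the whole path is checked
against an independent, hand-written exhaustive Gotoh DP in the test
suite (score and interval equality over 200 random mutated instances).
Only the single best hit per read is kept. Hits are filtered at identity
≥ 0.85 and aligned-read-fraction ≥ 0.5; an import path for externally
produced placements (BED6) bypasses the aligner for real data.

## End calling

Profiles count alignment termini of sense-strand hits only, and exclude
hits with aligned-read-fraction < 0.9: residual untrimmed bases shift a
terminus, and a heavily clipped alignment no longer pins the transcript
end. Percentages are 100·count/total per position (they sum to 100 by
construction). Modal ends break count ties toward the transcript-outermost
position — favoring the longest transcript — and flag the tie. The
consensus transcript spans the pooled modal 5' to pooled modal 3' end
inclusive; per-sample calls are emitted alongside. Lengths are inclusive
(−5185..−5000 is 186 nt under the +1 convention; note that inclusive
arithmetic under this convention makes an interval printed as "N bp"
ambiguous by ±1, which this package resolves by always reporting the
inclusive count). GC content is (G+C)/(A+C+G+T) with ambiguity codes
excluded from both numerator and denominator. The sense/antisense ratio is
(sense+p)/(antisense+p) with pseudocount p=0 by default and an explicit
infinity flag for a zero denominator.

## ChIP signal and state calls

Per-bp signal is coverage-per-million(ChIP) − coverage-per-million(input);
bin values are means over 50-bp bins, the trailing partial bin averaged
over its actual width, so the width-weighted bin mean equals the per-bp
mean exactly (mass conservation). Negative values are data (they mark
input excess) and are retained; the export variant clamps at zero and is
flagged as such. Thresholds for state calling default to each track's
locus-wide median + 3·MAD — a robust background estimate that needs no
peak calling — and can be overridden per mark with absolute cutoffs.
State rules: H3K4me1 is required; active = +H3K27ac −H3K27me3;
poised = +H3K27me3 −H3K27ac; intermediate = H3K4me1 alone; RNAPII and
methylation evidence are recorded but do not gate the call.

The fragment-coverage simulator places fragment midpoints with density
proportional to background (1) plus the configured fold enrichment,
Gaussian fragment lengths (default 500 ± 50 bp, the sonication target),
and returns exact overlap counts. The preset enrichment profiles
(enhancer: H3K4me1 8×, H3K27ac 6×, RNAPII 3×, H3K4me3 3×; promoter:
H3K4me3 8×, RNAPII 6×; H3K27me3 flat in the epithelial preset and
promoter-covering in the mesenchymal one) reproduce the qualitative
locus layout of an active enhancer next to a switchable promoter; the
absolute folds are design choices, not measured values.

## Quantitation conventions

Percent input is 100·DF·2^(Ct_input − Ct_chip) with DF = 10 for a 10%
input. The formula is also provided with the exponent written in the
opposite direction ("as-printed" mode) because that form circulates in
protocols; it yields values above 100% exactly when the ChIP is weaker
than the diluted input, so the conventional sign is the default and the
mode used is always recorded in output. β-values are M/(M+U+α) with
α = 100, the standard array stabilization offset (α = 0 gives the pure
ratio). Comparative quantitation combines replicates by arithmetic mean of
Ct before ΔCt, assumes perfect doubling (base 2; an efficiency-corrected
base can be supplied from a fitted curve), fixes the calibrator at exactly
1, and reports a dispersion range 2^−(ΔΔCt ± sd) with
sd = √(sd²_target + sd²_normalizer). Standard curves are least squares of
Ct on log₁₀(quantity) with efficiency 10^(−1/slope) − 1; absolute
quantities are 10^((Ct−b)/m) in curve units. Reporter readings are
firefly/renilla per replicate; rows with non-positive renilla are excluded
with a warning; folds are means over the control construct's mean, control
fixed at 1.

## Determinism and problem sizes

Every generator and the pipeline are pure functions of (inputs, config,
seed): reruns produce byte-identical TSVs, verified by checksum in the
tests. The run manifest records package version, parameters and input
checksums, and deliberately no timestamps. The test suite exercises the
full pipeline at 600–800 reads per run and the oracle comparison on
200–600-bp references; the acceptance script uses 10,000 reads per end
type — sizes chosen so a complete verification run stays in the
tens-of-seconds range on one CPU while keeping the modal-end estimates
far inside their sampling error (the modal 5' position carries ~40% of
10,000 reads; its nearest competitor ~12%).

## Known limitations

- The aligner is exhaustive-index based and quadratic in window size; it
  is built for kilobase loci, not genomes. Real hg19-scale mapping should
  come in through the BED import path.
- Barcode matching tolerates substitutions only; an indel inside a barcode
  shifts the frame and the read is lost to the unassigned bin.
- 3'-end positions on templated A runs are fundamentally unidentifiable
  after poly(A) tailing (see end-base pinning above); on real data such
  ends will be called at the upstream edge of the A run.
- Chromatin-state thresholds assume the classified interval is a minority
  of the track; an enrichment covering most of the locus would inflate the
  median+MAD background.
- The ΔΔCt dispersion range propagates Ct SDs in quadrature and ignores
  replicate pairing; it is a reporting convention, not a confidence
  interval.
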