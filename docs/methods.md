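# Methods

`ribostall` quantifies where a ribosome-targeting drug arrests translation,
starting from ribosome-profiling (Ribo-seq) footprint alignments for a
treated and an untreated condition with replicates.  This note documents the
model, the conventions that had to be fixed, the synthetic data used for
validation, and the known limits of both.

## Footprint processing and normalization

Footprints of 25–34 nt are retained; each is collapsed to its P-site
nucleotide by shifting a fixed 18 nt inward from the 3′-end of the aligned
read (soft-clipped bases excluded).  The offset is uniform across footprint
lengths — length-stratified offsets are deliberately not modelled — and is a
config knob (`psite_offset`).  A read contributes one count at that
nucleotide within every ORF containing the position on the matching strand;
it is counted once in the sample total even when overlapping ORFs each
receive it (`unique_orf=True` drops multi-ORF reads instead).  Counts are
normalized to reads per million assigned footprints (rpm), so all downstream
scores are invariant under sequencing-depth rescaling (tested).

Input is BAM (primary alignments only) or a paired-file bedGraph dialect:
one file per strand holding 3′-end counts, which exists so the pipeline is
exercisable without alignment machinery.

## Pause scores and drug-induced pause ratios

For a gene g with rpm vector r, the pause score of nucleotide i is
s_i = r_i / mean(r), so mean(s) = 1 exactly — a conservation law the tests
enforce at 1e-9.  The codon pause score is the mean of its three nucleotide
scores.  The gene mean uses *all* positions of the ORF, including zeros.
Gene scores are rpkm (rpm summed over the ORF per kb); genes below
`min_gene_rpkm` (default 5) in any sample are excluded as not actively
expressed.  The cutoff value is a calibration point, not a derived quantity.

Drug-induced pausing at a codon is the ratio of treated to control codon
pause scores, computed per replicate pair (treated rep *i* vs control rep
*i*).  A nucleotide enters ratio computation only if its rpm is at least
`inclusion_threshold` (default 0.5) in **both** samples of the pair; a codon
is included when at least one of its three nucleotides is included and the
control codon score is positive.  The threshold's units are switchable to
pause-score units (`inclusion_units="pause"`); rpm is the default because
the rule follows directly from the rpm definition.  Stop codons carry no
P-site amino acid and are excluded from the site universe.  A codon enters
the shared ratio table only when defined in every replicate pair, so site
selection and the enrichment background operate on a single universe.

## Arrest-site selection

Strong arrest sites require ratio ≥ `strong_fold` (default 2.5) in every
replicate pair; least-sensitive sites require ratio ≤ 1/`weak_fold`
(default 2) in every pair (switchable to any-pair).  Both bounds are
inclusive.  No multiple-testing control is applied — selection is a pure
fold-change rule, which means its false discovery proportion scales with the
number of null codons assayed (see the synthetic benchmark below).

## Nascent-chain context and enrichment logos

Each site's context is the ten residues at positions −8…−1 (C-terminal
region of the nascent chain), 0 (P site) and +1 (A site).  Windows at ORF
starts are padded with `-` rather than discarded — consequently the
initiator Met accumulates at −8 for early-ORF sites, a placement artifact
that is left uncorrected by default (`exclude_orf_start_windows` removes
sites with P-site codon < 9).  A stop codon in the A site renders as `*`.
Both symbols are excluded from all enrichment counts.

Enrichment uses the signed binomial tail log-odds: with k foreground
occurrences of a residue among n at a position and background frequency p,
score = −log10 P[X ≥ k] when k/n ≥ p (enrichment) and +log10 P[X ≤ k]
otherwise, X ~ Binomial(n, p), exact tails.  Background frequencies are
position-specific by default (pooled optional).  Significance is Bonferroni
corrected over 20 residues × 10 positions at `alpha` (default 0.05).
Fixed-residue conditioning (e.g. Arg/Lys at −1 and +1, or Pro at −1)
subsets foreground and background identically before re-scoring.

Motif grammar, applied with priority +X+ > PDX > PXX:

* **+X+** — Arg/Lys at −1 and +1, any P-site residue;
* **PDX** — Pro at −1, Asp at 0;
* **PXX** — Pro at −1 otherwise;
* **other** — everything else.

`scan_protein_motifs` applies the same grammar along a protein sequence and
reports all hits including overlapping (tandem) motifs.

## Metagene profiles

For anchor codons of one motif class, each anchor's 100 nt window (offsets
−50…+49 relative to the first nucleotide of the P-site codon) is normalized
to sum to 1 and the windows are averaged, so every site contributes equally
regardless of expression.  The window-center convention had to be fixed by
this package and is stated here because the alternative (centering on the
codon middle nucleotide) shifts profiles by 1 nt.  Anchors whose window does
not fit inside the ORF, or is empty in any sample, are filtered jointly
across samples so treated and control profiles share one anchor set.
Replicates are averaged at the profile level (per-replicate profiles, then
mean; pooling first is a config switch).

## Synthetic data

The generator emulates: ORFs of 120–400 codons built from random sense
codons; per-gene expression log-uniform over 0.6–600 expected footprints
per codon (~3 orders of magnitude, so lowly expressed genes genuinely fail
the rpkm and inclusion filters); codon counts drawn negative-binomial with
per-gene mean and shared dispersion φ = 10 (variance μ + μ²/φ; φ→∞ gives
the Poisson limit), independently per sample; counts split uniformly across
the codon's three nucleotides; planted arrest sites whose P-site codon mean
is multiplied (default 8×) in treated samples only, with the motif's
residues written into the coding sequence so translated contexts genuinely
carry the motif.  A fraction of genes sit on the minus strand (30%) or
carry one intron (20%) so the synthetic path exercises the same FASTA/GFF3/
bedGraph readers, strand handling and splicing as real data.  All
randomness derives from one seed via spawned sub-generators; outputs are
byte-reproducible.

It does **not** emulate: UTRs and initiation ramps, footprint-length
heterogeneity and length-dependent offsets, sequence-dependent
ligation/digestion bias, codon-usage-dependent baseline pausing, or
overlapping genes.  Passing the synthetic benchmarks therefore demonstrates
correctness of the computation and the selection logic under a realistic
noise magnitude — not robustness to every bias of real libraries.

### Benchmark design

The recovery benchmark plants 200 +X+ sites (8× multiplier) in 30 genes of
140–160 codons at NB mean 20 counts/codon, φ = 10, two replicates per
condition.  Under this noise the 2.5-fold both-replicate rule fires at
~0.3% of null codons, so the planted sites are placed at ~4% prevalence for
the false discovery proportion to be an informative readout; with a
genome-scale null universe the same null rate would dominate, which is the
expected behaviour of fold-change selection without FDR control, not a
defect.  Measured on this benchmark: sensitivity ≈ 0.93–0.95, FDP ≤ 0.05,
top logo enrichments at −1/+1 are Lys/Arg, and the treated/control metagene
ratio peaks inside the anchor codon.  Recovery counts a planted site as
found when a selected site lies within ±1 codon (nucleotide-level count
splitting can shift the peak codon by one); the exact-codon figure is
reported alongside and is typically identical.

## Numerical and degenerate-input choices

* Binomial tails via `scipy.stats.binom.logsf/logcdf` (exact, stable in log
  space); verified against full pmf enumeration to 1e-12 for n ≤ 12.
* Logo cells whose background frequency is 0 or 1 have no defined binomial
  score and carry NaN, never a pseudo-count.
* A gene with zero rpm in a sample has no pause profile (logged), and any
  (orf, codon) undefined in one replicate pair is absent from the table.
* `total_mapped = 0` is an error at normalization time, not a silent NaN.
* Ties in `top_residues` resolve by pandas stable sort order.
* CDS records whose length is not a multiple of 3 are skipped with a
  warning (strict mode raises); a CDS on an unknown chromosome always
  raises.  For genes with several annotated isoforms the lexicographically
  first transcript is used and the rest logged.

## Problem sizes

Default analyses run on synthetic experiments of 30–60 genes (~5,000–15,000
assayed codons, ~1–2 M simulated footprints per sample), which the full
pipeline processes in seconds; the pipeline itself streams per-ORF vectors
and scales linearly in assayed codons, and has no genome-size-specific
constants.
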