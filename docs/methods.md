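# Methods

`becall` analyses cytidine-base-editor (BE2/HF2-BE2-style) experiments in
which a deaminase–dCas9 fusion converts C·G pairs to T·A near a guide-RNA
target, embryos are genotyped by subcloning and Sanger-sequencing the target
amplicon, and whole-genome variant candidates are screened for association
with guide-like off-target sites. This note records the models, conventions
and numerical choices behind each stage, and what the synthetic generator
does and does not emulate.

## Coordinate model

All positions are expressed relative to the protospacer on the non-target
strand: position 1 is the 5'-most (PAM-distal) protospacer base, positions
L+1..L+3 are the NGG PAM for a guide of length L (21–23 for a 20-nt guide),
upstream positions are negative 1-based distances with no position 0, and
positions past the PAM are downstream. Truncated guides (16/17 nt) keep
position 1 at their own 5' end, so only the PAM-relative end of the axis
moves; the canonical deamination window stays [4, 8] unless overridden.
This convention is fixed, not configurable: the window definition and all
reported distances are stated under it. Loci may sit on either strand of
the amplicon; the relative axis always runs in guide orientation, and
file-facing coordinates are 0-based half-open everywhere except VCF I/O
(1-based, by format definition).

## Allele classification

Each subcloned allele is compared to the reference amplicon by global
pairwise alignment (match +1, mismatch −1, gap open −5, gap extend −1,
via Biopython's `PairwiseAligner`). Subclones are near-identical to the
reference, so the heavy gap-open suppresses spurious indels; equal-length
clones within Hamming distance 4 are called directly as substitutions,
which is provably optimal under this scoring (any gapped alternative for
equal lengths costs at least one insertion plus one deletion, −10, versus
at most −8 for four mismatches). Indels are left-normalized against the
reference (VCF convention). `N` bases are masked: aligned neutrally and
never called as events. Clones whose alignment identity falls below a
configurable floor (default 60%) are excluded with a warning rather than
failing the pool.

Events are categorized by a pure function of (kind, ref, alt, region):

- C>T is deamination on the non-target strand; G>A is deamination of the
  target-strand C read in protospacer sense (strand call `target`).
- C>G/A and G>T/C are the rarer non-canonical deamination outcomes, with
  the same strand logic.
- Any deamination-consistent change outside the protospacer — upstream,
  downstream, or in the PAM — is proximal-site deamination. No distance
  cutoff is applied (edits have been observed ≥ 42 bp out); the scan range
  is the full amplicon.
- Inside the window, canonical changes are window deamination regardless of
  strand; elsewhere in the protospacer they split into on-target
  (non-target strand) and target-strand deamination, and non-canonical
  outcomes are reported as noncanonical conversion.
- Everything else is an ordinary substitution; any insertion or deletion is
  an indel.

Each allele's sorted event list forms a canonical pattern key (sorted by
relative position, hence identical for a locus defined on either strand),
used to tally clones per distinct allele pattern.

## Genotyping and group statistics

Patterns supported by fewer than `min_support` clones (default 1; a
fraction is interpreted relative to pool size, rounded up) are dropped.
Genotype classes follow the subclone logic: all wild-type → wild type;
wild type plus one edited pattern → heterozygous; plus two or more →
mosaic; no wild type with one, two, or more edited patterns → homozygous,
biallelic, mosaic respectively. "Biallelic" in summaries includes
homozygous mutants. An embryo is mutant when it has at least one supported
non-wild-type pattern; a config switch controls whether an indel-only
pattern counts (default yes — in practice indel alleles also carry
substitutions, so the switch rarely matters).

Proximal-site-deaminated embryos are counted among mutants — a proximal
edit is an edit — which makes the two reported ratios
(proximal/mutant and proximal/total) consistent by construction.

All percentages round half-even to one decimal via exact `Decimal`
arithmetic; ratios over a zero denominator are reported blank, never 0.
Group comparisons use Pearson's χ² on 2×2 tables, df = 1, without Yates
continuity correction, p from the upper tail. The uncorrected variant
reproduces the expected significance pattern (non-significant
proximal-ratio comparisons, strongly significant mutant-rate contrasts);
degenerate margins raise rather than returning NaN.

Founder (pup) summaries reuse the embryo rules; coat-color mosaicism is
input metadata, never inferred from sequence. Litter percentages use the
denominators native to each column: survival over injected embryos, pups
over transferred, genotype columns over genotyped pups (pups lost before
genotyping count as born but not genotyped).

## Off-target variant triage

The triage starts from a called-variant VCF (alignment, deduplication and
variant calling are upstream and out of scope). Four independent,
per-candidate filters are applied — order cannot matter:

- quality: QUAL below `min_qual` (default 30; the threshold is deliberately
  explicit config) fails; a missing QUAL passes with a warning.
- known variant: exact chrom+pos+ref+alt membership in the known set
  (position-only matching available as config).
- low complexity: overlap of the REF-allele span with repeat-masked BED
  intervals (0-based half-open; touching intervals merge on read).
- flank homopolymer: any single-base run of `min_run` (default 8, i.e.
  runs longer than 7 bp) or more within ±`radius` (default 100 bp) of the
  variant position fails. The window is anchored on the POS base, clipped
  at contig ends, and runs are counted only within the window — bases
  outside it never extend a run.

Survivors' ±100 bp flanks are scanned exhaustively on both strands for
guide-like sites: every protospacer-length window immediately followed
(3', same strand) by an NGG PAM is accepted when its Hamming distance to
the spacer is ≤ `max_mm` (default 5) or its 3'-most `seed_len` bases
(default 10, the PAM-proximal seed; unchanged for truncated guides) match
exactly. The original heuristic short-read aligner used for this search is
replaced by the exhaustive scan — identical acceptance rules with no index
misses, feasible because the search space is only ±100 bp per candidate.
When both rules fire a site is reported once under the mismatch-budget
rule, with the mismatch count always recorded. A surviving variant with at
least one site hit is a potential off-target-associated variant; a run
with none reports the "no potential off-target site indel or SNV" outcome.

## Synthetic data

The cohort generator emulates subclone pools from edited embryos. Each
embryo carries 2 allele lineages (zygote-stage editing) or 4 (post-division
editing, the interpretation of coat-color mosaics); mosaicism can only
arise from lineages, never from clone sampling noise. Per lineage, each
non-target-strand C is deaminated independently: probability `p_window`
(default 0.12) inside the window, `p_protospacer_out` (0.01) elsewhere in
the protospacer, and `p_proximal_amp·exp(−d/20 bp)` (amplitude 0.012,
truncated at 100 bp) at distance d outside it. Target-strand Cs (Gs in
protospacer sense) use the same positional rate times
`p_target_strand_factor` (0.5). The deaminated base resolves to T/G/A with
probability 0.8/0.1/0.1. With probability `p_indel` (0.02) a lineage gains
a 1–3 bp indel near the window; substitutions within a few bases of a
planted indel are reverted, because an edit adjacent to a gap makes the
optimal alignment representation — and hence the ground truth — ambiguous.
Defaults were chosen once to give editing and proximal-site rates of the
magnitude seen in zygote base-editing cohorts (per-embryo mutant fractions
of roughly 40–50%); the exponential proximal decay is a modelling
invention for test realism and no analysis stage depends on its form.
Clones are drawn uniformly with replacement from lineages (default 15 per
embryo), and the recorded expected genotype is derived from the lineage
patterns actually represented among the drawn clones, by the same rules
the genotyper applies — so on noise-free data the pipeline must reproduce
the truth exactly, and the tests assert that it does. Clone-level
sequencing noise exists but is off by default.

The genome generator plants guide-like sites (chosen mismatch count, seed
integrity, PAM validity, strand), homopolymer runs, low-complexity
intervals and variant candidates into a random background whose own runs
are capped at 3 bp, so planted runs are the only ones the flank filter can
see; junction bases are adjusted so planted features never extend into
flanking runs. The per-variant truth table (expected verdict of every
filter, expected site association) is computed from the planting plan
alone, never by running the triage code.

What the generator does not emulate: chromatogram/read-level artifacts,
double-peak deconvolution, PCR chimeras, realistic genome composition or
genome-scale search. Passing the planted-truth tests therefore shows the
decision rules are implemented exactly as specified, not that the rules
themselves are robust to real-data artifacts upstream of the VCF.

## Deterministic table fixtures

`build_group_pools` and the founder-pool builders construct clone pools
realizing exact per-group counts (e.g. 67 embryos of which 26 mutant and
15 proximal-deaminated), choosing the 5'-most deamination-consistent
window edit for the locus at hand (C>T, or G>A for windows without a C, as
in the truncated-guide loci). They exist so the full classify → genotype →
summarize path, not hand-entered counts, produces the summary-table
percentages that the tests and the acceptance script assert.

## Problem sizes and checks

The test suite and acceptance script use: exhaustive coordinate round-trips
over the 143-bp demo amplicon; co-optimal-alignment enumeration (full
affine DP with complete backtracking) on ≤ 40-bp toy loci; exhaustive χ²
closed-form comparison over all 2×2 tables with cells ≤ 30; 5–6 kb planted
genomes with ~30 sites for scanner/oracle agreement; cohorts of 60–80
embryos for truth round-trips; and 20 replicates of 400 embryos for
parameter recovery, where the pooled observed mutant fraction is compared
with the analytic per-embryo probability 1−(1−q)² (q from the closed-form
per-allele edit probability) against its 99% binomial interval, allowing
at most one per-replicate 99%-interval excursion (about 0.2 expected among
20 replicates for a perfectly calibrated generator; requiring zero would
fail a correct implementation ~18% of the time).

## Known limitations

- The packaged demo locus is synthetic; it reproduces the geometry of a
  real amplicon (window Cs, target-strand G, proximal Cs at −2/−10/−38, a
  downstream C 42 bp past the PAM) but not any genomic sequence.
- Whether "downstream of the gRNA target site" should be measured from the
  protospacer or the PAM is ambiguous in common usage; both distances are
  representable on the relative axis and neither interpretation is
  hard-coded.
- The classifier assumes one clone = one allele sequence (subcloned Sanger
  reads); it does not deconvolve direct-sequencing double peaks or process
  FASTQ reads.
- Triage examines only variant flanks, as in the workflow it reproduces; it
  is not a genome-wide off-target enumerator.
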