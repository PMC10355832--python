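# Methods

This note documents the models, conventions and design choices behind
`cdspirna`, in the order data flow through the pipeline.

## Coordinates, alphabet, randomness

Internal coordinates are 0-based half-open; GFF3 I/O is 1-based closed,
BED/bedgraph 0-based half-open. Sequences live in the DNA alphabet (U→T on
input), so complementarity and the G·U wobble are defined on DNA (G·U ≡
G·T). Every stochastic step draws from a seeded numpy PCG64 stream; child
streams are keyed by the run seed plus a CRC32 of the library label, so
per-library simulation and classification are independent yet fully
reproducible, and identical config + seed yields byte-identical FASTQ,
assignment tables and screen output.

## Read classification

After adapter trimming (longest prefix before the leftmost adapter match;
adapterless reads kept and flagged; empty inserts dropped) and size
selection, reads pass a fixed tier order: **non-piRNA → cluster → TE →
genome**. The first matching tier claims the read.

* The internal matcher reports *all* end-to-end placements (no clipping,
  substitutions only) with identity ≥ a similarity threshold; the "80%
  similarity" mode means ≥ 0.8 · read length identical bases. Exact
  matching uses a 16-mer index (O(1) per read); the mismatch path is a
  vectorized sliding-window scan adequate for toy references (≤ tens of
  Mb), deliberately not a general aligner.
* Non-piRNA removal defaults to positional overlap of exact genome hits
  with annotated rRNA/tRNA/miRNA/sn/snoRNA loci; sequence-identity matching
  against the locus sequences is a config option, since either reading of
  the removal rule is defensible.
* Ambiguity within a tier ("mapped randomly") is a uniform seeded draw
  among maximal-identity hits. At the genome tier a read whose best hits
  touch two genes is discarded; multiple placements within one gene keep
  the read at a randomly drawn position (this is what preserves the
  repeat-bearing, muc14A-like host gene).
* An independent (non-sequential) cluster/TE mode supports between-library
  abundance comparisons.

Quantification: TPM normalizes exon-mapping reads per kilobase (gene TPMs
sum to 1e6 whenever any genic reads exist); RPM uses reads remaining after
non-piRNA removal. A read is attributed to the region (5′UTR/CDS/3′UTR)
containing its 5′-end base — the only unambiguous choice for reads that
straddle a region boundary. Coverage tracks scale by 1e6/N with the same
denominator and are written as run-length-merged bedgraph; a
unionbedg-style positionwise merge is provided.

## Host screen

Metrics per gene, aggregated across libraries as the arithmetic mean of
per-library normalized values (not pooled counts, matching how multiple
datasets are combined in the source experiments): TPM/TPM enrichment ratio
(strictly > 10 to retain), 18–29-nt size profile averaged over libraries
with a modal-length test for 24–26 nt, per-position nucleotide
probabilities over the first 23 bases (5′U fraction = P(T at position 1)),
IP enrichment = mean bound TPM / total TPM, strict Aub-RPM tiers (>100,
>10), per-nt region densities with a two-tailed paired t-test across genes
(CDS vs each UTR), sense fraction, and junction reads (exact transcript
match crossing a junction with ≥4-nt anchors and no contiguous genomic
placement).

Pseudocounts: ratios replace *zero* terms by 0.5 (so 100/10 stays exactly
10 while 0/10 floors at 0.05); fold changes in the differential module
instead add 0.5 to both terms when either is zero, which keeps
case = control at exactly 1. The two conventions are deliberate and
documented per function.

The composite call is a conjunction: ratio > 10 ∧ 24–26-nt peak ∧ u1 ≥ 0.5
∧ Aub enrichment ≥ 2. The u1 and enrichment thresholds are package
defaults (exposed in `ScreenCriteria`): the source analyses confirmed
these biases post hoc rather than publishing cutoffs, so conservative,
tunable values are used.

## Overlap pairing

Responders are indexed by their first 10 nt; for each trigger the set of
complementary 10-mers (2^k of them when k positions admit a wobble) is
enumerated and looked up, which is exactly equivalent to the all-pairs
comparison (tested against an O(n·m) oracle). ">10 reads" is strict
(≥ 11), summed over all responder groups paired with a trigger. In
cleavage mode each fragment is anchored on a transcript by exact
5′-anchored search, and the guide's 11th nucleotide must Watson-Crick pair
the transcript base immediately 5′ of the fragment start — the base t11
occupies under cleavage between target positions t10/t11. Which strand's
11th base the original deposited tool checked is not derivable from its
description; this geometric interpretation is used and switchable
(`require_g11`). The same machinery drives degradome pairing and
piRNA–piRNA self-pairing. The miRNA target-site rule defaults to a perfect
seed (nt 2–8) match — predicted sites need not be cleavage-competent — with
an optional 3′-supplementary variant.

## Phasing

The 3′ end is the last aligned base, so immediately adjacent reads give
d = 1. Distances are computed between distinct read species
(nearest downstream 5′ end by default; all-pairs within the window as an
option) and summarized as z1 against the d ∈ [2, 50] background. A
zero-variance background yields ±∞ ("saturated") when the d = 1 excess is
nonzero and 0 when the histogram is exactly flat. z1 is depth-dependent by
construction (documented, not "fixed"); the property that is stable is its
sign and magnitude class for phased vs shuffled data. The permutation
control reassigns distinct 5′ ends uniformly over the transcript and
averages z1 over 20 independent shuffles, because a single shuffle of a
sparse histogram has Poisson-level variance on the d = 1 bin.

## Differential comparisons

Replicates are paired by explicit order (case i vs control i); class fold
changes are ratios of class RPM, with the exon-mapper class optionally
restricted to a gene set such as an abundance tier. Correlations between
conditions are Pearson on log2 fold changes by default (fold changes are
ratio-scaled; a flag disables the log). Degradome enrichment is the
degradome/poly(A) TPM ratio, ranked.

## Proteomics

Counts + 0.5, normalized by per-run totals (per-condition totals by flag),
enrichment = mean(bait)/mean(control), two-tailed unpaired Student t-test
(Welch by flag). `significant` is p < 0.01; a volcano **hit** additionally
requires enrichment ≥ 2. The fold requirement is this package's criterion
for a bait-specific interactor: with hundreds of background proteins a
calibrated p < 0.01 alone would flag ~1% of true nulls, so a p-only flag
cannot isolate a single true interactor at any sample size.

## The synthetic-data generator

The generator's defaults define the standard study conditions; they were
chosen from the arithmetic of the design, and the same numbers are used by
the tests and the acceptance analyses.

* **Genome**: 2 × 400-kb chromosomes; 220 single-isoform genes (20 hosts,
  200 decoys) with 100–200-nt 5′UTRs, 900–1400-nt CDSs, 150–350-nt 3′UTRs
  and 1–3 introns of 60–200 nt; 3 piRNA clusters of 5 kb, each seeded with
  a 500-nt TE fragment so cluster/TE multimappers exist; 5 TE consensus
  sequences; 15 non-piRNA loci. One host gene carries a ~300-nt tandem
  repeat (3 copies) inside its CDS and is antisense-dominant
  (muc14A-like); four hosts are phased.
* **Libraries** (per library, before size selection): 6k host piRNAs, 37k
  decay fragments, 4k cluster, 3k TE, 3k non-piRNA reads. Host piRNA
  lengths follow {23: .05, 24: .25, 25: .30, 26: .25, 27: .10, 28: .04,
  29: .01} (reproducing the 24–26 mode; the exact shape is this package's
  choice), with P(5′U) = 0.8 enforced by drawing starts from U/non-U
  position classes, 95% sense reads, 5% junction-spanning reads with
  ≥4-nt anchors, and region weights 5/85/10% across 5′UTR/CDS/3′UTR (the
  planted CDS concentration). Decay fragments scale with mRNA level and
  draw lengths from a short-skewed geometric 18–29-nt ladder (ratio
  0.8/nt): a flat length profile would make the modal-length peak test a
  coin flip on decoys, whereas real degradation ladders skew short.
* **Expression**: lognormal (σ = 0.5) per gene; host mRNA scaled by 0.05,
  modeling piRNA production as uncoupled from (and here deliberately below)
  bulk mRNA abundance so the TPM/TPM axis separates hosts from decay at a
  220-gene scale. At genome scale the separation comes instead from the
  sheer number of genes sharing the denominators.
* **IP libraries** enrich piRNA classes (host/cluster/TE) 20-fold (Aub;
  Piwi 3-fold) over the decay/non-piRNA background before depth
  renormalization. Planted responders scale with the realized host-class
  factor, as Aub-bound species must.
* **Triggers**: 21-nt siRNAs antisense to host CDS sites; the responder 5′
  end sits at a uridine in a junction-free window, and the trigger's 11th
  nucleotide pairs the transcript base 5′ of the site (cleavage-competent
  by construction). Planted responder counts (200, 150, 100, 50, 25, 5)
  straddle the >10 reporting threshold; 4 decoy triggers have no planted
  responders. Degradome reads start exactly at these sites (50 each) over
  a uniform background.
* **Phased genes** emit one head-to-tail train tiling the transcript;
  lengths are drawn from the piRNA length prior with a 40× weight boost
  for a uridine at the next 5′ end, and 15% of steps skip 2–30 nt before
  resuming at the next uridine — reconciling the d = 1 geometry with the
  5′U bias, as Zucchini cleavage 5′ of uridines does in vivo.
* **Mutant comparisons** use an Aub-IP-like composition (4k host, 2k decay,
  55k cluster, 25k TE, 3k non-piRNA) so the exon-mapper class is a small
  share of the RPM denominator; depleting one class necessarily inflates
  the RPM of the others by its denominator share, so a composition where
  exon mappers are ~30% of the library would push cluster/TE fold changes
  outside any ±0.05 band around 1 regardless of implementation. The tier
  restricting the exon-mapper class is control RPM > 1000: at this depth
  and gene count decay-only genes already sit near ~200 RPM, so the cut
  plays the role a deep library's RPM > 10 tier plays against a ~14k-gene
  denominator.

What the simulator does **not** model: sequencing errors and quality
variation (constant Q40), PCR duplicates, isoform diversity, partial
adapters, genome-scale gene numbers, and realistic TE divergence. Passing
tests therefore demonstrate the correctness and discriminating power of
the analyses under the planted statistical structure, not performance on
real libraries.

## Problem sizes

The standard screen runs two total + two Aub-IP libraries of 53k raw reads
each (~2 × 10⁵ classified reads in total) over 220 genes; mutant
comparisons use 2 case + 2 control libraries of 89k reads, repeated over
10 seeds in the tests and 3 in the acceptance script; oracle comparisons
use 500 × 500 read groups. These sizes make every planted effect several
standard deviations wide while keeping a full run in minutes on one CPU.

## Known limitations

The matcher is substitution-only (no indels) and end-to-end; junction
reads are detected as a screen metric but remain "unassigned" in the
classification partition, so genic TPM slightly undercounts
junction-spanning species (~5% of host reads at the default junction
fraction); z1 is not comparable across sequencing depths; and the
g11/cleavage geometry is one (switchable) interpretation of an
underdocumented tool.
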