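# Methods

This note records the models, algorithms and numerical conventions behind
`avissr`, the choices made where the design was genuinely open, and what
the synthetic benchmarks do and do not demonstrate.

## Perfect-SSR detection

A perfect microsatellite is a maximal tandem array of a *primitive* motif
(one that is not itself a repetition of a shorter unit) of length 1–6 bp
with at least 12, 7, 5, 4, 4, 4 copies for mono- through hexanucleotide
units — the standard thresholds of genome-wide SSR surveys. The scanner
works per period p: a boolean match vector `seq[j] == seq[j-p]` is computed
with numpy, maximal True runs give candidate arrays, partial trailing
copies are truncated, and non-primitive units are skipped (such runs are
found at their shortest period, so an (ACAC)ₙ run is always the
dinucleotide (AC)₂ₙ). Candidates from different periods are merged
greedily: leftmost first, then longest, then shortest unit; a candidate
overlapping an accepted locus is re-evaluated on its remaining suffix,
exactly as a rescan from the accepted end would see it. Consequences:

* no base belongs to two reported perfect loci;
* `length_bp = repeats × motif_len` exactly, and the spanned sequence is
  the motif tiled;
* partial trailing copies are truncated on the right (left-anchored), so
  coordinates on the reverse complement may shift by up to `motif_len − 1`
  bases; canonical motifs and repeat counts are strand-invariant.

Runs containing N are broken at the N. Characters outside A/C/G/T/N raise
an error naming the offending position.

The test suite holds this scanner to *exact* agreement (coordinates,
motifs, copy numbers) with an independent regex oracle
(`(motif){k,}` with restart-rescan) over 1,000 random and repeat-spiked
10 kb sequences.

## Imperfect-SSR detection

No published parameterization exists for the interrupted-repeat search this
pipeline family uses, so the algorithm here is a conventional scored
seed-and-extend, fully configurable: seeds are pure runs with ≥ 3 copies
and ≥ 8 bases; extension outward scores +1 per matching base, −1 per
substitution and −2 per indel base; edits are classified by a 3-base
lookahead under the substitution/deletion/insertion hypotheses (ties prefer
substitution, then deletion); extension stops after more than 3 consecutive
edited positions and the locus is trimmed back to its maximal-score extent,
which always ends on a match. A locus is reported when the total score
reaches 10 *and* at least one edit occurred — edit-free runs belong to the
perfect detector. Overlapping extensions from multiple seeds are
deduplicated keeping the best score, then the longest, then the leftmost.
The RCN of an imperfect locus is estimated as `round(length / motif_len)`.

An imperfect call lying mostly (≥ half its span) inside a compound locus is
suppressed: a seed in one member otherwise extends across the spacer and
re-describes the same genomic locus. This keeps "one genomic locus, one
report" well-defined for the type-proportion statistic.

## Compound SSRs

Maximal chains of ≥ 2 perfect loci with adjacent gaps ≤ 10 bp (the
documented default of the standard mining tool; configurable) merge into
one compound locus; members are retained and flagged so proportions count
each genomic locus once. A flag restores member-level counting for
sensitivity analyses.

## Canonical motif classes

The class representative is the lexicographic minimum over all rotations of
the motif and of its reverse complement. The classes partition the
primitive k-mers into 2, 4, 10, 33, 102 and 350 classes for k = 1..6,
verified against an independent union-find over the rotation/
reverse-complement graph.

## Region assignment and positional profiles

Introns are always derived as gaps between consecutive exons of one
transcript; for multi-transcript genes the transcript with the largest
summed exon length is used. A locus is labelled by its **midpoint** with
precedence CDS > exon_noncoding > intron > intergenic — deterministic,
single-label, and matching a per-base majority oracle in ≥ 99% of random
loci (all disagreements straddle feature boundaries). The exon-level
statistic is CDS + exon_noncoding when a single "exon" compartment is
wanted. Exon/intron ranks are counted from both gene ends honouring
strand (introns mirror the exon convention), so rank r from 5′ plus rank
from 3′ equals n + 1; profiles are truncated at rank 30 by default.

## Statistics

* Type proportions are **locus counts** (not base counts), each genomic
  locus once; they sum to 100%.
* Abundance = count × 10⁶ / genome length; density = Σ length × 10⁶ /
  genome length. Genome length includes N bases by default.
* CV of RCN = 100 × sd/mean with the **sample (n−1)** standard deviation,
  reported in percent; cells with < 2 loci are missing, never zero.
* GC content is (G+C)/(A+C+G+T) over concatenated locus tracts.
* Motif-preference matrices are species × canonical motif, loci/Mb and
  bp/Mb; di-/trinucleotide classes keep all columns, longer classes keep
  the 25 columns with the highest **mean abundance across species**
  ("most common" needs a metric; mean loci/Mb is the natural one), ties
  broken lexicographically.

## Phylogenetic PCA

For a species × trait matrix X and tree VCV C (entry = shared root-to-MRCA
branch length):

    a = (1ᵀ C⁻¹ 1)⁻¹ 1ᵀ C⁻¹ X
    R = (X − 1a)ᵀ C⁻¹ (X − 1a) / (n − 1)

eigendecomposed in `cov` mode (default) or after correlation rescaling in
`corr` mode; scores are S = (X − 1a)V. Sign convention: the
largest-magnitude loading of each component is positive (PCA signs are
otherwise arbitrary). Near-singular C (zero-length branches in dated
trees) gets a logged ridge of 1e−8 × trace(C)/n. The implementation is
validated three ways: against ordinary PCA on a star tree (deviation
< 1e−8), against phytools' `phyl.pca` on identical inputs (agreement to
~1e−6), and by parameter recovery — the mean of R̂ over 500 Brownian-motion
simulations is within 5% of the generating trait covariance entrywise.
The comparative pipeline feeds **loci/Mb** matrices to the PCA; any matrix
can be supplied directly.

## Synthetic genomes

The generator emulates the study design of a multi-species SSR survey:
per-species genomes with a non-repetitive background of configurable GC
(default 0.42, the ballpark of an avian genome), planted perfect loci of
all six classes at or above threshold, imperfect loci built as 30-base
arrays whose interior edits split them into pure segments of 8–10 bases
(each a detectable seed, none a perfect locus by itself), compound plants
with spacers of 4–10 bp, multi-exon gene models with UTR-bearing terminal
exons, and Brownian-motion trait matrices on Yule trees of unit depth.

Truth-table exactness is engineered, not hoped for:

* background is drawn i.i.d. at the target GC and **rejection-resampled**:
  any window still producing a perfect or imperfect call is redrawn until
  a scan finds nothing unplanted (the truth table is exhaustive);
* four flanking bases around each plant exclude the characters that would
  continue the array under straight, one-inserted or one-deleted
  alignments, so the detector cannot extend a planted locus;
* plants are separated by ≥ 20 bp so compound merging never occurs unless
  requested (the minimum spacing the standard tool implies is not
  documented anywhere; 20 bp is this package's choice, exposed as
  `min_spacing`);
* compound spacers must be ≥ 4 bp — with shorter spacers the two members
  are a single interrupted array by any reasonable definition and the
  planted truth would be ambiguous;
* imperfect-plant edits must be ≥ 3 bases from the array ends and ≥ 4
  bases apart, so the scored extension provably crosses every edit and
  stops at the true boundaries.

Everything is deterministic for a fixed seed, down to output bytes.

**What passing these benchmarks does not show.** The background is i.i.d.;
real genomes have isochores, transposable elements and satellite arrays
that produce near-threshold repeat structure far more often than chance,
so real-data precision of the imperfect detector will be lower than the
synthetic 100%. Chromosome-size distributions, sequencing error and
assembly gaps are not modelled. Agreement of the imperfect-SSR calls with
any particular external mining tool is not claimed — the algorithm is
documented above and parameterized, not reverse-engineered.

## Problem sizes

Defaults keep the whole suite light: synthetic benchmark genomes are
2 × 60 kb with 50 planted loci; the oracle-equivalence sweeps use 10 kb
sequences (1,000 in the test suite, 300 in the acceptance script); the
simulated comparative study uses six 40 kb species; covariance recovery
uses 500 replicates on a 40-taxon tree. These sizes already give exact or
sub-percent results; all are parameters, and scale linearly.
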