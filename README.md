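# avissr

Genome-wide microsatellite (SSR) characterization for comparative genomics,
with a synthetic-genome simulator carrying planted ground truth.

Microsatellites — tandem repeats of 1–6 bp DNA motifs — are a major source
of genetic variation in compact vertebrate genomes such as birds.
Comparative SSR surveys ask how repeat classes, motif preferences, copy
numbers and genomic locations vary across a phylogeny. `avissr` implements
that survey pipeline end-to-end:

* **Detection** of three locus classes:
  * *perfect* (P-SSR): an uninterrupted array of a primitive 1–6 bp motif
    with at least **12 / 7 / 5 / 4 / 4 / 4** copies for mono- through
    hexanucleotide units;
  * *imperfect* (I-SSR): an array disrupted by substitutions or short
    indels, found by scored seed-and-extend;
  * *compound* (C-SSR): ≥ 2 perfect arrays separated by short (≤ 10 bp)
    spacers.
* **Canonical motif grouping**: motifs equivalent under circular
  permutation and/or reverse complementation are one class (the
  representative is the lexicographic minimum; the class counts are
  2/4/10/33/102/350 for k = 1..6).
* **Genomic-compartment assignment** (CDS / non-coding exon / intron /
  intergenic) from GFF3, by locus midpoint with precedence
  CDS > exon > intron, plus gene-end positional profiles (SSR counts in the
  top-30 exons/introns from each gene terminus).
* **Statistics**: P/I/C type proportions, abundance (loci/Mb) and density
  (bp/Mb), repeat-copy-number (RCN) histograms, the coefficient of
  variability CV = 100·sd/mean of RCN, GC content of repeat tracts, and
  species × canonical-motif preference matrices (full for di/tri, top-25
  columns for tetra/penta/hexa).
* **Phylogenetically-informed PCA** of motif-preference matrices: with tree
  variance–covariance matrix C (shared root-to-MRCA branch lengths), GLS
  ancestral mean a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X, evolutionary covariance
  R = (X−1a)ᵀC⁻¹(X−1a)/(n−1), eigendecomposition of R (or its correlation
  rescaling), scores S = (X−1a)V. On a star tree this reduces to ordinary
  PCA; results match phytools' `phyl.pca` to numerical precision.
* **Simulation**: synthetic genomes (FASTA + GFF3 + truth table) with
  planted perfect/imperfect/compound loci in every compartment, a
  rejection-sampled repeat-free background, Yule trees, and
  Brownian-motion trait matrices — so every stage is testable with known
  truth and no downloads.

## Worked example

Simulate a two-chromosome genome with 50 planted loci, then run the
per-species pipeline:

```bash
avissr simulate --seed 4 --out sim
avissr detect --fasta sim/genome.fa --gff sim/genome.gff3 --out sp1
```

`sp1/loci.tsv` (1-based inclusive coordinates) begins:

```
seq_id  start_1based  end   ssr_type   motif  canonical_motif  motif_len  repeats  length_bp  score  n_edits
seq1    3296          3321  perfect    CT     AG               2          13       26
seq1    3567          3596  imperfect  A      A                1          30       30         26.0   2.0
seq1    4903          4947  perfect    TTATT  AAAAT            5          9        45
```

The first row is a (CT)₁₃ array reported under its canonical class AG; the
second an interrupted poly-A tract (30 bp, 2 edits, alignment score 26).
`sp1/type_proportions.tsv` shows the planted class mixture recovered
exactly:

```
perfect  imperfect  compound
60.0     24.0       16.0
```

and `sp1/class_abundance.tsv` reports abundance/density per motif-length
class, e.g. mononucleotide arrays at 41.7 loci/Mb and 700 bp/Mb on this
80 kb genome. `sp1/cv_rcn.tsv` holds the CV of RCN per (class, region)
cell, with cells of fewer than two loci left blank.

For a comparative run, detect in each species directory and then:

```bash
avissr run-all --species-dir sp1 --species-dir sp2 ... --tree tree.nwk --out comp
```

which writes species × motif abundance/density matrices and per-class
phylo-PCA eigenvalues, loadings and scores.

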