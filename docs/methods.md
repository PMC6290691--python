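# Methods

`driftprof` quantifies genomic divergence between two clonally related cell
subpopulations ("SP a" and "SP b") that descend from one ancestor culture —
the situation that arises when a cell line is passaged in two laboratories
for years.  Four analyses are chained: genetic identity (IBD/PI_HAT),
read-depth CNV comparison, an SNV/indel reduction cascade, and pathway
over-representation of the surviving candidate genes.  A fully
ground-truthed synthetic paired-genome generator provides the test bed.

## Genetic identity (kinship)

At every biallelic site the pair shares 0, 1 or 2 alleles identical-by-state
(IBS = 2 − |dosage_a − dosage_b|).  Conditional on the latent
identity-by-descent state z and the population alt-allele frequency p
(q = 1 − p), the IBS class probabilities are

    P(IBS=0 | z=0) = 2 p²q²
    P(IBS=1 | z=0) = 4 p³q + 4 pq³      P(IBS=1 | z=1) = 2 pq
    P(IBS=2 | z=2) = 1                  P(IBS=2 | z=1) = p² + q²

Summing these over sites gives expected class counts linear in the unknown
P(IBD=z); the estimator solves sequentially for P(IBD=0) from the IBS=0
count, P(IBD=1) from IBS=1, and P(IBD=2) from the remainder, truncates
negative solutions to zero and renormalizes.  The scalar score is

    PI_HAT = P(IBD=2) + ½ P(IBD=1)

(1 ≈ monozygotic twins or duplicate samples, 0 ≈ unrelated).  Allele
frequencies come from the supplied panel VCF (AF INFO field); panel sites
that neither genome calls enter as double hom-ref, which is informative and
keeps the estimator unbiased.  Sites absent from the panel are dropped and
counted.  The estimator requires ≥ 1,000 usable polymorphic sites
(configurable); it is validated by simulation-based parameter recovery
(`simulate_dosage_pair` draws pairs under the generative IBD model) rather
than against an external binary.

Coordinate conventions: all interval types are 0-based half-open;
`VariantRecord.pos` alone is 1-based (the VCF convention), because
variants are anchored points rather than intervals and every consumer of
them (normalization, database keys, VCF I/O) speaks VCF coordinates.  The
single conversion happens inside the consequence annotator.

## CNV calling from binned coverage

1-kb bins carry mean per-base depth.  GC correction divides each bin by the
median depth of its 2 %-wide GC stratum (median, not mean, so CNV bins
cannot drag their stratum).  The sample is then divided by an identically
corrected reference coverage profile — a panel-style expectation track,
here simulated as the mean of 20 diploid draws — and rescaled so the
genome-wide median ratio is 1.  Per-bin ploidy is 2 × ratio.

Segmentation: bins are labelled loss/neutral/gain at ploidy ≤ 1.5 / ≥ 2.5
(half-integer midpoints; the single-copy change at ~30× is the observable
regime).  Labels are computed on a 5-bin moving average because raw 1-kb
bins at 30× are too noisy to threshold individually; maximal same-label
runs may bridge one neutral bin, same-type runs separated by ≤ 5 bins merge
when the merged raw mean still passes the threshold, and each boundary is
then re-located on the *raw* bins by a least-squares changepoint search
(±6 bins), which uses the full diploid-versus-segment contrast rather than
the half-contrast a threshold sees.  A segment is emitted when its mean
ploidy passes the calling threshold, its robust z-score
|mean − 2|·√n_bins / σ (σ = scaled MAD of per-bin ploidy) reaches 6.0, and
it is longer than 1 kb (strict).  The z floor of 6 sits above the
genome-wide maximum of the null scan statistic for ~10⁴ bins (~4.3–5 σ),
the usual genome-wide-significance argument; at 5.0 a no-CNV genome would
produce occasional false segments.

Common-CNV filtering removes a call when a database interval covers ≥ 50 %
of the *call's* length (one-way, inclusive: database records are
heterogeneous in size).  Cross-sample matching instead demands reciprocal
≥ 50 % overlap and equal direction, matched greedily by descending overlap,
one-to-one; for disjoint-per-sample call sets this greedy matching attains
the maximum matching (property-tested against exhaustive matching).

## SNV/indel reduction cascade

Stages, each a strict partition of its input: (1) read, split
multi-allelics, left-align and deduplicate; (2) concordance filter — depth
≥ 10, site quality ≥ 30, het allele balance in [0.2, 0.8] (conventional
30×-WGS values; the thresholds stand in for the published cross-platform
filtering strategy, whose exact parameters are not enumerated anywhere);
(3) subtraction of population-database alleles by exact
(chrom, pos, ref, alt) key — a new allele at a known site stays; the
surviving class is labelled `not_in_databases` ("somatic" in the cell-line
sense, kept as an alias); (4) allele-exact shared/private partition;
(5) consequence annotation, keeping missense, nonsense, splice, frameshift
and inframe_indel.

Annotation is codon-local: splice = any affected base within 2 bp of an
exon–intron boundary on the intron side; coding SNVs translate only the
affected codon (strand-aware, codons may span exon junctions); CDS indels
are frameshift/inframe by length mod 3; block substitutions are annotated
per constituent base.  Across transcripts the most severe class wins
(frameshift > nonsense > splice > missense > inframe_indel > synonymous >
noncoding).  The annotator is verified against an independent oracle that
rebuilds and translates the entire mutant CDS (`classify_by_cds_rebuild`),
1,000 random variants per strand, zero tolerance.

## Over-representation analysis

One-sided hypergeometric test per GMT gene set (the standard open
equivalent of proprietary over-representation scores): with universe N,
pathway K, query n, overlap k, p = P(X ≥ k), accumulated in log space.
Rows are sorted by raw p (the field's output convention);
Benjamini–Hochberg q-values are attached.  The universe defaults to all
genes in the pathway database unless a background list is supplied.  Note
the test is conservative at small set sizes because the hypergeometric is
discrete; its null calibration is checked in the tests with set sizes large
enough that attainable p-values are dense near 0.05.

## Synthetic paired-genome generator

The generator emulates the *statistical structure* of a real two-subculture
WGS comparison at desk scale — 2 × 5 Mb chromosomes, 10⁵ ancestor variants —
preserving class ratios rather than absolute counts (a real comparison has
millions of catalogued variants, tens of thousands of rare ones, and tens
of protein-changing private variants):

* Reference: random sequence whose per-kb GC follows a sinusoid
  (0.42 ± 0.15, period 700 kb) plus noise, so GC correction has a real,
  spatially structured signal to remove; ≥ 20 three-exon gene models on
  both strands whose CDS regions are overwritten with clean ORFs
  (ATG … sense codons … TAA), giving consequence classes exact meaning.
* Variants: one per 80-bp slot (collision-free by construction).  A
  `known_fraction` = 0.99 slice of ancestor variants populates the
  population database with allele frequencies ~ U(0.05, 0.95); 500 decoy
  database alleles absent from both descendants test subtraction
  specificity.  Both descendants inherit all ancestor variants; 40 rare
  variants are shared; 250 are private per side, of which exactly 3 are
  placed inside CDS so the rebuilt protein changes (verified against the
  whole-CDS oracle at generation time).  Private non-coding fillers avoid
  gene territory so those counts stay exact; ancestor and shared variants
  may fall anywhere and their true consequence is recorded.
* Platform noise: per variant and per platform, rate 1e-3 (a free
  parameter — cross-platform discordance before filtering is not published
  as a number), half dropout, half het↔hom corruption, applied last.
* CNVs: a default plant list of gains (ploidy 3) and losses (ploidy 1) of
  4–60 kb, bin-aligned, with shared / private / population-common
  ownership; common plants also populate the common-CNV database alongside
  two decoy intervals.
* Coverage: the number of reads per 1-kb bin is Poisson with mean
  depth_mean · (bin/read_length) · ploidy/2 · gcbias(gc), and raw_depth is
  the implied mean per-base coverage (E[raw_depth] = 30 · ploidy/2 ·
  gcbias).  Drawing at the read level (read_length 100) reproduces the
  per-bin noise of real binned WGS — ~300 reads per bin, CV ≈ 6 % — which
  is what makes ±1-bin CNV boundary recovery statistically possible at
  all; a single Poisson(30) draw per bin would overstate bin noise
  three-fold relative to real 30× data.  gcbias = 1 + 0.3·(gc − ḡ)/ḡ.  The
  reference profile is the mean of `ref_panel_size` = 20 diploid draws.

All randomness flows from one seed through named `SeedSequence` children;
every artifact (FASTA, VCFs, bedGraphs, truth table) is byte-deterministic.

What the generator does *not* emulate: linkage disequilibrium, mutation
signatures, read-level artifacts, mapping biases, mobile-element
insertions.  Passing recovery tests therefore demonstrates correctness of
the analysis logic under the stated noise model, not robustness to every
real-data pathology.

## Problem sizes and determinism

Default end-to-end runs (10 Mb, 10⁵ variants, 10⁴ coverage bins) complete
in well under a minute; the multi-seed recovery checks in the test suite
use 20 independent seeds at the default scale.  The IBD recovery grid uses
10,000 sites per grid point.  Reports are written as JSON/TSV with sorted
keys; reruns with the same seed are bit-identical except for the
provenance timestamp.

## Known limitations

* The concordance filter's thresholds are conventions, not fitted values.
* "Somatic" status is database membership, not tumor–normal evidence.
* The CNV caller reports bin-resolution boundaries and makes no attempt at
  sub-bin breakpoints, HMM/CBS segmentation or inversion calling.
* PI_HAT from two samples cannot separate recent drift from residual
  heterozygosity mismatch; it is a similarity summary, not a pedigree test.
* The pathway step cannot reproduce knowledge-base-specific hits of
  proprietary tools; only the over-representation statistic is comparable.
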