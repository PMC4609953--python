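# Methods

This note documents the models and procedures skimqtl implements, the
defaults it ships with, and the choices made where the methodology is
genuinely open. The worked numbers in the README and the values written
by `scripts/acceptance.py` are produced by these procedures at run time;
nothing here asserts a result the code does not compute.

## The problem

A biparental recombinant inbred line (RIL) population genotyped by skim
sequencing (well under 1X coverage per line) yields a SNP matrix that is
mostly missing and slightly noisy, yet each line's genome is a coarse
mosaic of the two parental haplotypes. The pipeline reconstructs that
mosaic per line, condenses the population into recombination bins —
intervals inherited as a unit by every line — and uses the bins as
markers for linkage mapping and QTL analysis. A parallel
association/enrichment track scores co-localization of GWAS signal with
candidate genes, and the intersection of the two evidence streams
prioritizes genes inside QTL hotspot regions. qPCR fold-change
arithmetic (2^-ddCt) supports downstream expression validation.

## Synthetic populations

The generator performs explicit meioses. An F1 (one haplotype per
parent) is advanced by single-seed descent; each meiosis draws a
Poisson(`recomb_rate`) crossover count with positions uniform along the
chromosome (Haldane model, no interference). `n_selfing_generations` is
the filial generation number (F1 = 1); the default F8 leaves an
expected residual heterozygosity of (1/2)^7 ≈ 0.8% per locus. Each
residual heterozygous tract is exported as a single fair coin flip
between the two parental origins, one flip per maximal tract, so the
exported genotype matrix is exactly consistent with the exported
breakpoint list — a per-site flip would manufacture one-SNP "segments"
that no biological process produces and would make the crossover truth
ill-defined. Selfing of a chromosome stops early once both haplotypes
are identical; this is exact, since meiosis between identical haplotypes
returns them unchanged.

Defaults mirror the study conditions the generator emulates: 222 lines,
F8, mean depth 0.72X, allele-flip error 0.005, and `recomb_rate = 2`
crossovers per chromosome per meiosis — after the two-fold junction
accumulation of inbreeding (Haldane–Waddington), ~4 observed crossovers
per RIL chromosome, the middle of the 3–5 range expected for RILs. The
skim observation model is Poisson reads per line × site (zero reads =
missing, so missingness is e^-0.72 ≈ 49%), independent across sites,
with a single consensus-level allele flip probability. It does not model
alignment bias, depth autocorrelation along the genome, or
line-to-line depth variation; conclusions about those failure modes
cannot be drawn from these simulations.

Phenotypes are purely additive: g = Σ aᵢxᵢ with x = ±1 at the catalog
site nearest each planted QTL, plus i.i.d. Gaussian noise scaled so
Var(g)/Var(y) = h² against the realized genetic variance. Environments
differ only by independent noise draws (plus an optional environment
main effect). No dominance, epistasis, segregation distortion, or G×E
is simulated, matching the additive scan that consumes the data.

## Window genotyping and breakpoints

A 15-SNP window (homozygous call at ≥ 9 alleles from one parent) slides
one SNP at a time over each line's *non-missing* calls; at skim coverage
a fixed-width genomic window would rarely contain enough observations.
Windows that reach neither 9 A's nor 9 B's are unresolved: they never
create breakpoints, only widen breakpoint intervals. A breakpoint is
declared at each transition between resolved runs of opposite genotype;
its interval spans from the end of the left run to the start of the
right run (sorted — majority-called windows can overhang the true
crossover), and the point estimate is the interval midpoint. An interior
resolved run of a single window flanked by opposite calls is collapsed
as noise (shortest explanation: it would otherwise imply two crossovers
within one window span).

Resolution limit: a true mosaic segment needs roughly 9–15 informative
SNPs to be callable. At 2,000 SNPs per chromosome, 0.7X coverage and ~4
crossovers per chromosome, about 5% of true segments fall below this
limit; each hidden segment hides its two flanking junctions, so
crossover recall plateaus near 89–90% with essentially zero false
detections (both numbers are recomputed by `scripts/acceptance.py`).
This is a property of the window rule at skim coverage, not of the
implementation; recovering those junctions would need explicit
imputation or HMM smoothing, which is out of scope.

## Consensus bins

Breakpoint point estimates from all lines are compared on a 100 kb grid
anchored at coordinate 1 of each chromosome. Every grid cell containing
at least one point estimate becomes a bin; maximal runs of empty cells
merge into single bins. Bins therefore tile each chromosome (asserted on
every run), and bins with zero SNPs are flagged.

Bin genotyping scores each line at each bin with the mosaic genotype at
the bin midpoint, joining the line's resolved segments at breakpoint
point estimates. The alternative of blanking every bin touched by a
breakpoint interval looks more conservative but is unusable: since bins
tile the genome, every junction lies inside some bin, and masking it
hides every recombination event from the adjacent-bin recombinant
fractions — the genetic map collapses to zero length. The strict
masking remains available (`mask_breakpoint_bins=True`) for segment
reporting. Midpoint scoring misattributes a bin only when the point
estimate errs across a midpoint; on synthetic data ≥ 95% of scored
(line, bin) values match the truth at the bin midpoint.

## Linkage map

Within each chromosome (linkage groups are taken from physical
coordinates, not re-derived by LOD clustering), markers are ordered by
recombination counting: the criterion is the summed count of observed
recombination events between adjacent markers, minimized by greedy
sequential insertion of markers in seeded random order, best of 10
restarts, each polished by a sum-of-adjacent-distances ripple that
exhaustively permutes a sliding window of 5 positions until no window
improves. Orientation is normalized to ascending physical start. Bins
with fewer than 20 scorable lines or failing a 1:1 segregation
chi-square at p < 10⁻³ are left unplaced. Marker pairs with too few
co-scored lines are bridged with a penalty count and flagged.

Observed RIL recombinant fractions R overstate per-meiosis fractions;
the F∞ inversion r = R/(2 − 2R) is applied (capped at 0.4999) before
distance conversion, Kosambi by default (the convention of the mapping
software this models; Haldane available). On dense, noise-free data the
estimated chromosome span lands within 10% of the simulated meiotic
length; at skim coverage the span is biased short because junctions
hidden inside large bins (both crossovers of a short segment between
two bin midpoints) contribute no adjacent-marker recombination.

## ICIM-ADD scan

The additive inclusive composite interval mapping scan is the standard
two-phase procedure. Phase one selects cofactors by forward–backward
stepwise regression of the phenotype on all bin markers (±1 coding,
missing mean-imputed) with entry p ≤ 0.001 and removal p > 0.002.
Phase two scans each linkage group at 1 cM steps: the phenotype is
adjusted by the fitted cofactor model excluding the two markers flanking
the testing interval *and any cofactor within 10 cM of the testing
position* — with dense bin markers, a cofactor one bin beyond a flank is
nearly collinear with the tested genotype and would silently absorb the
QTL (observed as a flat LOD profile in about a third of replicates
before the window was added; the window is configurable). The expected
QTL genotype given the flanking bin genotypes uses a Markov RIL model on
observed-scale recombinant fractions (map distance → meiotic r by the
inverse mapping function → R = 2r/(1+2r)); lines missing both flanks are
dropped at that position, lines with one flank are conditioned on it.
LOD = (n/2)·log10(RSS0/RSS1); PVE is reported against the
cofactor-adjusted phenotypic variance at the testing position, which
need not match the variance partition of other software. With no
cofactors selected the scan reduces exactly to Haley–Knott single-QTL
regression (asserted against an independent oracle to 1e-8).

Genome-wide thresholds come from seeded phenotype permutations with the
full scan (cofactor selection included) re-run per permutation; the
threshold is the empirical (1 − α) quantile — the 950th ascending order
statistic for 1000 permutations at α = 0.05. QTLs are called one per
contiguous supra-threshold segment at its LOD peak; PVE > 10% defines a
major QTL (exactly 10% is minor). The topmost QTL per trait is the
maximum-PVE QTL across environments; topmost QTLs of two or more traits
sharing both flanking bins define hotspot sub-regions, sized from the
coordinates encoded in the flanking bin ids.

## Association, LD blocks and enrichment

Single-marker association is the equal-variance two-sample t-test of
the A-vs-B phenotype contrast (equivalently, regression on ±1 coding),
with missing genotypes dropped per SNP and Bonferroni correction over
the SNPs tested per trait (boundary p = α/m is included). RMIP repeats
association + Bonferroni on 100 seeded subsets of 80% of lines drawn
without replacement (the subset fraction is not standardized; 0.8 is a
common stability-selection choice and is configurable) and counts the
subsets in which each SNP is re-declared; RMIP ≥ 5 defines the
significant-association set.

Pairwise LD uses Lewontin's D′ on the RIL lines read as haplotypes, with
a 2×2 chi-square (no continuity correction) for significance at α =
0.05. A candidate gene's block is the maximal run of consecutive SNPs in
significant LD containing the gene; a gene with no SNP within one
(median) inter-SNP gap falls back to the gene span padded by the median
physical distance between fully dependent (|D′| = 1, significant) SNP
pairs on the chromosome.

Enrichment scores each gene's block three ways: a co-localization weight
Σ RMIP/100 over significant SNPs in the block (the published pipeline's
exact weighting formula is not public; this reconstruction is declared,
not inferred); an upper-tail hypergeometric p for the count of
significant SNPs in the block (population = chromosome SNPs); and a
permutation p from 10,000 seeded random association sets of the true
size drawn without replacement from the chromosome, carrying the true
RMIP weights. A gene is enriched only if both p-values are ≤ α. With
equal weights the permutation null reproduces the hypergeometric tail
(asserted within Monte-Carlo error).

## Candidate genes and expression

Hotspot regions resolve to genes by any-overlap of 1-based inclusive
intervals (strict containment would drop boundary-spanning genes on an
arbitrary criterion); prioritized candidates are the intersection of
region genes and enrichment-positive genes, position-sorted, with
per-gene provenance flags. Expression fold changes follow 2^-ddCt with
ΔCt = mean Ct(target) − mean Ct(reference) per group and ΔΔCt between
test and calibrator; both fold and log2 fold are always reported, since
published bar charts are often ambiguous between the two. Replicate
significance is a two-sided Student t-test on per-replicate ΔCt (Welch
via flag); identical zero-variance groups return p = 1.

## Numerical and engineering choices

* Coordinates are 1-based inclusive everywhere except the BED writers.
* All randomness flows from integer seeds recorded in the run manifest;
  identical configuration + seed reproduces identical artifact
  checksums.
* Rounding of printed summary quantities (Kb, Kb/cM, percentages) is
  half-away-from-zero to two decimals, matching how such tables are
  printed.
* RECORD ties are broken by seeded restart order; the reported order is
  the lexicographically smaller of the order and its reverse when
  endpoints tie physically.
* The per-line 5% missing-data filter is the correct default for dense
  genotype matrices; skim data is ~50% missing by design, so the
  synthetic pipeline configuration ships with the line filter at 0.95.
  The MAF ≥ 0.20 site filter applies unchanged (computed over
  non-missing calls).

## Problem sizes used in tests and the acceptance script

Desk-scale conditions keep full runs in minutes: two 50 Mb chromosomes;
2,000 SNPs/chromosome for breakpoint recovery, 600 SNPs/chromosome for
mapping and QTL replicates; 200 lines; 20 replicate populations for QTL
position recovery and 100 null scans. The calibration tests set their
reference threshold from 200 permutations to keep the suite fast; the
acceptance script uses the full 1000-permutation protocol with 5 QTL
replicates and 100 null scans.

## Known limitations

* Crossover recall is capped near 90% at 0.7X by sub-window segments
  (see above); the acceptance suite states the 95% goal and the measured
  value honestly.
* Map spans shrink at skim coverage (hidden junctions in large bins).
* PVE and LOD are regression-based; mixture-model ICIM implementations
  can differ in the second decimal and in the PVE denominator.
* The enrichment weighting is a declared reconstruction (see above).
* No multi-QTL joint model, QTL×E, epistasis, or mixed-model GWAS —
  a biparental RIL has no population structure in the GWAS sense.
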