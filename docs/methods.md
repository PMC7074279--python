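# Methods

`invdiverge` re-implements, as a tested library, the statistical pipeline
used to characterise divergence between the cryptic malaria-vector species
*Anopheles messeae* and *An. daciae*: molecular species diagnosis from the
rDNA ITS2 marker, population genetics of polytene-chromosome inversion
karyotypes, and genome-wide divergence scans from SNV genotypes. Because
the underlying field and sequencing data are not redistributable, a
synthetic-data module generates inputs with the statistical structure each
stage assumes; what passing tests do and do not demonstrate is discussed at
the end.

## ITS2 species diagnosis

ITS2 is multicopy rDNA, so intragenomic variants appear in Sanger traces as
double peaks, base-called as IUPAC ambiguity letters (W = A/T, Y = C/T,
M = A/C, R = A/G, S = C/G). Throughout the package a base is the *set* of
nucleotides it can represent and two bases match when their sets intersect.

Six diagnostic positions (reference numbering of the *An. messeae* ITS2
record) carry the signal:

| position | 150 | 211 | 215 | 217 | 412 | 432 | reliability |
|---|---|---|---|---|---|---|---|
| *An. messeae* | M | T | T | C | G | G | 412/432 primary |
| *An. daciae*  | C | W | W | Y | A | C | others secondary |

The decision rule rests entirely on the two primary sites: (G,G) calls
*messeae*, (A,C) calls *daciae*, and double peaks at both — R (A+G) at 412
and S (C+G) at 432 — call an interspecific F1-like hybrid. A single-site
double peak is never sufficient. Secondary-site discordance (including the
documented *daciae* variants T at 217 and M at 150) is recorded in a
confidence note but cannot override the primary call; this ordering is a
deliberate design choice because only 412/432 are fixed between the
species.

Processing steps:

1. **In-silico PCR.** The published universal primer pair (22-mer forward,
   20-mer reverse) is located on the template with IUPAC-aware matching and
   a configurable per-primer mismatch budget (default 0). The amplicon
   spans both primer footprints (613 bp on the reference). A primer site
   truncated at a template end is accepted when at least 15 nt overlap
   remains, because deposited records often begin or end inside a primer.
2. **Anchoring.** Each query is aligned to the reference semiglobally
   (end overhangs free on both sequences) with match +1 (set-intersection),
   mismatch −1, gap open −2, gap extend −1 — for short near-identical
   amplicons any standard scheme suffices; this one is simply documented.
   Both orientations are tried (Sanger reads may be reverse-strand) and the
   higher-scoring one kept. Identity below 70% over aligned-plus-internal-gap
   columns rejects the query. Alignment is delegated to Biopython's
   `PairwiseAligner` with a custom IUPAC substitution matrix.
3. **Extraction and calling.** Diagnostic bases are read through the
   coordinate map (deletions/insertions elsewhere therefore cannot shift
   them); unreadable sites become N, and a specimen with both primary sites
   unreadable is untypeable.

Composition tables count all specimens of a population (sequence-diagnosed
plus externally identified congeners such as *An. beklemishevi* and
*An. maculipennis*, which enter as category counts) and report percentages
rounded to one decimal, half away from zero, matching how such survey
tables are conventionally printed.

## Inversion-karyotype statistics

Arrangements are scored per arm (X, 2R, 3R, 3L) with digit nomenclature: 0
standard, 1/2/4 inverted variants; diploid genotypes are unordered digit
pairs; males are hemizygous on the X (single digit). Allowed alleles per
arm: X ⊆ {0,1,2,4}, 2R ⊆ {0,1,4}, 3R and 3L ⊆ {0,1}. Multiallelic arms are
handled natively — nothing is collapsed to biallelic.

**Allele frequencies** count two copies per female and one per male on the
X, two per specimen on autosomes.

**Hardy–Weinberg test.** Fis = 1 − Ho/He with Ho the observed heterozygote
proportion and He = 1 − Σp² from the same diploid genotypes (plug-in
estimator; a small-sample correction is unnecessary because the permutation
null uses the identical statistic, so the bias cancels — the choice is
documented and switchable by supplying a different statistic). The null
re-pairs the pooled alleles into diploids (10,000 permutations by default);
p is the two-sided proportion of |Fis| at least the observed, with the
+1/(n+1) correction so p is never exactly zero. Only females enter the
X-linked test, since hemizygous males cannot be heterozygous; their alleles
still count toward frequencies. The pooled allele array is sorted before
permuting so p-values are bit-reproducible under a fixed seed and invariant
to input row order.

**Pairwise differentiation.** Weir–Cockerham (1984) θ with the multiallelic
extension: per-allele variance components (a, b, c) from per-population
(n, p, h) summaries, summed over alleles and loci, θ = Σa/Σ(a+b+c).
Interpopulation tests use autosomal arms only (mixed-ploidy X data are not
comparable across sexes). The permutation null shuffles whole specimens
between the two samples (genotypes intact), one-sided on θ ≥ observed,
+1/(n+1)-corrected; Bonferroni flags use p < α/m. Specimens are put in a
canonical order (genotype signature) before permuting, again for row-order
invariance.

**Frequency PCA.** Rows are population × species samples, columns the
frequencies of every non-standard arrangement on the autosomal arms.
Columns are centered but not scaled (covariance PCA) by default — the
frequencies share a scale, so unit-variance scaling would up-weight rare
variants; a correlation-PCA switch (`scale=True`) is provided because the
original analysis software's convention is not documented. Percent
variances always sum to 100.

## Genome-scale divergence

The pipeline starts at a VCF of SNV calls with site QUAL and per-genotype
GQ; alignment and variant calling are upstream and out of scope.

**Filtering** applies, in order: drop non-biallelic/non-SNV sites; drop
sites with QUAL < 400; mask genotypes with GQ < 10 to missing (masking
precedes the missingness rule, reproducing VCFtools' flag semantics);
drop sites with more than one missing genotype; thin greedily left-to-right
per contig, keeping a site only if ≥ 10 kb from the last kept site.
Thinning is order-dependent, so unsorted input is an error; the cascade is
idempotent. Filtering runs in scaffold space, before lifting, because the
thinning radius is defined on the coordinates the variants were called in.

**Coordinate lifting** converts scaffold to chromosome coordinates with an
offset map: `offset + pos` on forward placements,
`offset + (length − pos + 1)` on reverse ones; placements of distinct
contigs may not overlap, and unmapped contigs route to an `unplaced` bin
rather than raising.

**Windowed Fst.** Per biallelic site, two-group WC84 components for the
alternate allele (using both alleles would double numerator and denominator
alike, so single-allele components keep per-site weights consistent in
ratio sums). Windows tile each chromosome from coordinate 0 in
non-overlapping 5-kb steps (the anchor is a convention; the source analysis
does not state one); a window's fst is Σa/Σ(a+b+c) over its SNVs, empty
windows are omitted, and negative estimates are reported as computed, never
clamped. Two scope-level means are available: the unweighted
`mean_of_windows` (how per-window scans are usually summarised and plotted)
and the pooled `ratio_of_sums`. After 10-kb thinning a 5-kb window holds at
most one SNV, making the unweighted mean a mean of single-site ratios —
noisy and not a consistent estimator of the generating Fst — so parameter
recovery is always judged on `ratio_of_sums`, while both are reported.

**Admixture.** The standard admixture model: genotype
g<sub>ij</sub> ~ Binomial(2, Σ<sub>k</sub> q<sub>ik</sub> f<sub>kj</sub>)
with per-individual ancestry fractions q and per-cluster allele frequencies
f, K = 2, fitted by plain EM. EM shares its stationary points with the
faster block-relaxation solvers of dedicated ancestry tools and is easier
to verify; seeded restarts (default 4) guard against local optima and the
best likelihood is kept. q is initialised uniform and f at random, so the
fit is exactly equivariant under permuting individuals; cluster labels are
anchored to the majority ancestry of the first individual. The
log-likelihood is monotone non-decreasing up to floating-point round-off
(observed violations are below 10⁻⁹ relative; tests assert monotonicity at
that tolerance). Convergence: absolute log-likelihood change < 10⁻⁶
(default) within 2,000 iterations; non-convergence is flagged, not raised.

**Genotype PCA.** Missing genotypes are mean-imputed per locus; loci are
centered by 2p̂ and scaled by √(p̂(1−p̂)) (Patterson normalisation, which
equalises per-locus drift variance); monomorphic loci are dropped; scores
and percent variances come from the SVD.

## Synthetic data

The generators produce inputs with the declared statistical structure;
they are deterministic given (spec, seed).

- **ITS2**: a synthetic 613-bp reference amplicon (clearly labelled as a
  stand-in, not the deposited record) carries the primer footprints at its
  ends and plain reference bases at the six diagnostic positions, which
  keep their published numbering. Records plant a genotype class verbatim
  (the three observed *daciae* variants in their 115:2:2 proportions, the
  single *messeae* class, the all-double-peak hybrid) and sprinkle
  substitution errors elsewhere at the specified rate (≤ 5%). Diagnostic
  sites are protected from errors by construction — classifier tests are
  exact by design; realism is secondary to testability there.
- **Karyotypes**: per population × species group, genotypes are drawn from
  declared allele frequencies with an optional inbreeding coefficient
  (P(aa) = p² + f·p(1−p), P(ab) = 2p<sub>a</sub>p<sub>b</sub>(1−f);
  infeasible combinations are rejected with an error). Males draw a single
  X allele. The six bundled presets mirror the study system qualitatively:
  X1 effectively fixed in *messeae* with the rare X4 variant, X0/X1
  near-equal in *daciae*, autosomal inverted variants common in *messeae*
  and rare in *daciae*, 3L1 confined to *messeae*, and 2R4 a rare *daciae*
  variant in one population; group sizes are the survey's per-population
  species counts.
- **Genomes**: Balding–Nichols, the minimal standard divergence model
  consistent with a target Fst (the source study used real mosquitoes, so
  no generative model was specified): ancestral frequency per SNV
  ~ U(0.05, 0.95); each population's frequency ~ Beta with mean p and
  variance F·p(1−p); genotypes ~ Binomial(2, p_pop); admixed individuals
  draw from the q-weighted frequency. The divergence profile plants a
  0.027 baseline, 0.331 in the middle half of the X (the inversion-like
  region), and 0.15 in the terminal 5% of each autosome (centromere-like
  low-recombination regions). Chromosome lengths (X 150 Mb, chr2 330 Mb,
  chr3 270 Mb) are scaled so that ~50k SNVs survive 10-kb thinning at the
  default pre-thinning spacing of 5 kb; each chromosome is emitted as four
  scaffolds, alternating orientation, so lifting does real work. A small
  fraction of sites is written triallelic or with low QUAL, and of
  genotypes with low GQ, so the filter cascade has work to do.

## Problem sizes and numerical choices

- Window recovery runs at the full default panel (~150k raw, ~50k filtered
  SNVs, 5 + 5 individuals); the pooled estimator recovers both profile
  levels within ±0.01.
- Ancestry recovery uses 20 reference individuals per source and ~10k
  autosomal loci with one planted q = 0.75 individual. At the survey's own
  5 + 5 genome panel the cluster frequencies are weakly identified and
  estimated q attenuates toward 0.5 — a property of the model at that
  sample size, visible in the tests, and worth remembering when reading
  small-panel ancestry plots.
- The Hardy–Weinberg permutation test is calibrated over 1,000 null
  replicates (100 diploids, 999 permutations each); the observed type-I
  rate sits within the 3-SE binomial band of α = 0.05, slightly
  conservative as expected for a discrete statistic with the +1/(n+1)
  correction.
- Permutation p-values are reported with the +1/(n+1) correction and can
  never be exactly zero; all permutation machinery takes explicit seeds
  recorded in the results.
- Degenerate inputs: monomorphic loci short-circuit (HWE) or contribute
  zero components (θ); a θ over all-monomorphic loci is an error; PCA of
  identical rows warns and returns zero scores; empty populations are
  flagged, not dropped silently.

## What passing tests show — and what they do not

The synthetic generators validate the *statistics*: that the estimators
recover the parameters that generated the data, that the tests are
calibrated, and that every file format round-trips. They do not emulate
linkage disequilibrium along chromosomes, inversion genotypes' effect on
local SNV diversity, sequencing-error structure in QUAL/GQ, or
chromatogram-level artefacts in ITS2 reads; conclusions about real data of
those kinds need the real inputs. The per-specimen karyotype listing and
raw-read accessions behind the original survey are not machine-readable
from the publication text, so the karyotype and genomic results are
validated by estimator-against-oracle checks and parameter recovery rather
than by reproducing printed tables; the ITS2 composition arithmetic, by
contrast, is reproduced exactly from the printed counts.
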