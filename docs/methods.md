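# Methods

`methaxis` implements a reduced-representation bisulfite sequencing
(RRBS) methylome analysis for a multi-tissue, multi-replicate design:
per-cytosine methylation quantification, genomic feature annotation,
meta-profiles, differential methylation calling and feature
enrichment. This note records the statistical model, the conventions
and the design choices behind each stage.

## Data model and conventions

The atomic observation is one cytosine in one library: a methylated
read count m and an unmethylated count u, with coverage n = m + u.
Sites are strand-specific — the two cytosines of a CpG dyad are
separate sites and are never merged — and each site carries a context,
CpG or CpH (H = A, C or T; the CHG and CHH sub-contexts are collapsed
because the analysis never distinguishes them). Per-cytosine inputs
(Bismark-style coverage files and cytosine reports) are 1-based and
converted at the boundary to the internal 0-based half-open interval
convention shared with BED.

The methylation level of a site in a library is beta = m/n. A tissue's
level at a site is the *arithmetic mean of its replicates' betas*, not
the pooled-count ratio; the two differ when coverages differ, and the
replicate-mean convention keeps every tissue value a balanced
three-replicate average. A region's level is the unweighted mean of
the tissue-level betas of the sites it covers; a region with no
covered site is undefined (NaN), never zero.

Sites enter the analysis only if covered by at least `min_coverage`
(default 5) reads in **every** library. This is the stricter reading
of "co-present across all tissues": it guarantees full-replicate
tissue means everywhere downstream.

Bisulfite conversion QC treats CpH sites as unmethylated ground truth:
non-conversion = sum(m)/sum(n) over covered CpHs, efficiency its
complement in percent.

## Genomic annotation

Five genic features partition each chromosome: upstream (5 kb 5' of
the TSS), exon (union of exons), intron (gene body minus exons),
downstream (5 kb 3' of the TES) and intergenic (the complement). The
flanks are strand-aware. Where features of different genes overlap,
bases are resolved with the fixed priority exon > intron > upstream >
downstream; this makes the partition exact (every base has exactly one
label) and independent of gene input order. One TSS/TES per gene;
alternative transcripts are out of scope.

CGI shores are the 2-kb flanks outside islands, shelves the next 2 kb.
Flanks of nearby islands are merged and trimmed with priority
CGI > shore > shelf, so the three tracks are pairwise disjoint; a gap
of under 4 kb between two islands is therefore entirely shore.

A CGI is localized to the genic feature covering **strictly more than
half** of its length, with fractions computed against the
priority-resolved partition (so they sum to exactly 1); an exact
half-overlap stays unassigned. Genes owning the matched feature become
the CGI-Upstream/-Exon/-Intron/-Downstream gene sets; the sets are not
mutually exclusive.

The sequence-level island predicate follows the Gardiner-Garden &
Frommer thresholds: length > 200 bp, GC fraction > 0.5 and
observed/expected CpG > 0.6, with the expected count
((C+G)/2)^2 / length. The strict `>` form of all three thresholds is
used (the inclusive `>=` variant circulates as well; the difference
only matters on exact boundaries).

## Meta-profiles and window tracks

Gene profiles use 20 + 40 + 20 bins for the 5-kb upstream flank, the
length-scaled body and the 5-kb downstream flank (250-bp flank bins);
CGI profiles use 20 + 20 + 20 bins with 2-kb flanks (100-bp flank
bins). Gene bins run 5' to 3', so minus-strand genes are mirrored
before averaging; the profile is exactly invariant under mirroring the
whole genome. Bin assignment is half-open: a site exactly at the TSS
belongs to body bin 1. Bins with no assignments report NaN
methylation, not zero. Sites inside two overlapping elements' spans
contribute to both (element-centric averaging).

Per-bin methylation is the mean tissue beta over all (element, site)
assignments. Per-bin density is assigned sites per element per base
pair — flank bins use their fixed width, body bins the mean body-bin
width across elements — which makes flank and body bins comparable
despite unequal widths.

Methylation/density Pearson correlations are computed over selectable
bin ranges: all bins, the ten bins either side of the TSS or the TES
(ten flank + ten body bins), or all CGI bins, with undefined bins
excluded pairwise.

Window tracks tile each chromosome with non-overlapping windows
(1 Mb default; the final window may be partial). Window methylation is
the mean tissue beta of covered sites; windows without sites are
excluded pairwise from correlations. Gene density counts a gene in the
window containing its start (a TSS-based rule is available).

## Differential methylation

The two-group test is a beta-binomial Wald test on pooled group
proportions p_g = sum(m)/sum(n):

    Var(p_g) = sum_i n_i p_g (1-p_g) [1 + (n_i - 1) phi] / (sum_i n_i)^2
    Z = (p_1 - p_2) / sqrt(V_1 + V_2),  two-sided normal p-value.

The dispersion phi is estimated by method of moments from the
replicate scatter. Within one group, S = sum_i n_i (p_i - p_g)^2 has
expectation p q [(k-1) + phi (N - k - sum(n_i^2)/N + 1)] for k
replicates with total coverage N; the (k-1) term is the
degrees-of-freedom correction for estimating p_g from the same data,
and omitting it biases phi badly downward at k = 3. The estimator
pools numerator and denominator over both groups and — by default —
over all tested sites, yielding one shared ("common") dispersion.
Per-site moment estimates at 3v3 are so noisy that the resulting test
rejects far above its nominal level; the common estimate restores
calibration (measured type-I error ~0.012 at alpha = 0.01 on
beta-binomial null simulations with phi = 0.05 and negative-binomial
coverage). `dispersion="per-site"` retains the site-wise variant.

Degenerate sites with p_1 = p_2 in {0, 1} give Z = 0, p = 1.
All-or-nothing sites (zero estimated variance but unequal means) fall
back to 0.5 pseudo-counts on each group's pooled totals and are
flagged. phi is floored at 0 and capped at 1.

A DMC requires |p_1 - p_2| > 0.20 (strict) and p <= 0.01 (inclusive).
A DMR is a maximal run of *consecutive tested* CpGs that are all DMCs
of the same sign, with at least 3 members and a span (last - first + 1)
of at least 51 bp, i.e. strictly more than 50 bp. An untested cytosine
between DMCs does not break a run (it is absent from the tested
sequence); a tested non-DMC does. The same-direction requirement is
switchable (`same_direction=False`).

Constitutive classes across tissues use inclusive thresholds: HypoC if
every tissue level is <= 0.20, HyperC if every level is >= 0.80.

Feature enrichment builds, per feature, the 2x2 table of DMC
membership inside/outside the feature over all tested sites and
applies a two-tailed Fisher's exact test (the two-tail sums all table
probabilities not exceeding the observed one). Two odds-ratio
estimates are reported: the sample OR ad/bc — which satisfies the
exact complement identity OR' = 1/OR — and the conditional
maximum-likelihood estimate of the noncentral hypergeometric OR; the
two agree to two decimals for all but near-boundary tables. Features
may overlap each other (island and genic tracks are tested
independently); no multiple-testing correction is applied beyond the
fixed alpha.

## Synthetic data generator

The generator emulates the structure of a 3-tissue x 3-replicate RRBS
experiment so every stage can be validated with known truth:

- **Site placement.** CpGs come in clusters: dense runs (6-25 bp
  spacing) inside islands, and MspI-fragment-like background clusters
  (3-10 CpGs, ~3-kb mean gaps). CpHs are sprinkled sparsely through
  background clusters. Clustering approximates RRBS site spacing; no
  genome sequence is cut.
- **Methylation means.** Feature-dependent: islands and upstream
  regions 0.10, exons 0.65, introns/downstream/intergenic 0.75, shores
  0.45, shelves 0.65, CpH 0.006 everywhere. Tissue offsets
  (+0.02 / 0 / -0.002 for hypothalamus / pituitary / ovary) mirror the
  ~2-percentage-point global-mean spread reported between these
  tissues.
- **Counts.** Coverage is negative-binomial (mean 30, size 5 —
  overdispersed, as RRBS coverage is); methylated counts are
  beta-binomial with dispersion phi = 0.01 (a typical within-group
  biological dispersion; binomial at phi = 0). Beta-binomial rather
  than binomial generation is used precisely so the Wald test's
  dispersion estimation is genuinely exercised.
- **Planted differential regions.** 60 regions by default, each a run
  of >= 5 consecutive background CpGs spanning > 50 bp, shifted by
  +-0.4 in one tissue (sign chosen to stay inside [0.02, 0.98]).
  Islands are left untouched, mirroring their observed protection from
  methylation dynamics. With three tissues this yields ~3% truly
  differential CpGs per pairwise comparison, bracketing the 1-2.4%
  DMC fractions reported in real multi-tissue comparisons. The truth
  table records every site's true means, its planted-region id and the
  true DMC flag per tissue pair.

The default genome is 3.5 Mb over two chromosomes (~105 genes, ~100
islands, ~15,000 sites), sized so the full pipeline and the validation
suite run in seconds while leaving >= 10^4 CpGs for calibration
checks. The seed fully determines every output, byte-for-byte.

What the generator does **not** model: read-level errors and bisulfite
chemistry, genuine MspI digestion of a reference sequence, correlated
methylation between neighbouring sites outside planted regions,
CNV/mappability artefacts, or chromosome-scale covariates. Passing
tests therefore demonstrate the pipeline's arithmetic and its
statistical calibration under the stated model, not performance on
real libraries.

## Numerical choices and degenerate inputs

- Interval arithmetic is integer-exact; partition and overlap checks
  are asserted exactly, not within tolerance.
- Histogram bands are left-closed with the last band closed:
  [0, 20), [20, 60), [60, 90), [90, 100].
- Group-level comparisons of region levels use the Welch t-test for
  significance flags (the classical equal-variance statistic is
  reported alongside); regions, not sites, are the replication unit.
- Empty strata, empty regions and windows without sites are reported
  as undefined and excluded pairwise, never imputed.
- Genes shorter than the body-bin count leave empty body bins rather
  than erroring; flank bins of genes near chromosome ends are clipped.

## Known limitations

- DMC p-values rely on a normal approximation to the Wald statistic;
  at very low coverage (near the 5x floor) the test leans on the
  |delta| > 0.2 filter for specificity, and site-level precision on
  planted fixtures sits near 0.8 when coverage is strongly
  overdispersed.
- The common-dispersion default trades per-site adaptivity for
  calibration; datasets with strongly site-dependent dispersion would
  warrant an empirical-Bayes shrinkage between the two extremes, which
  is not implemented.
- One TSS/TES per gene; alternative promoters are not represented.
- GO-term analysis of DMR genes is out of scope (external ontology
  resources).
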