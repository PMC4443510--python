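# Methods

This note documents the models, the simulator's assumptions, the numerical
choices and the known limitations of `nilseq`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The experimental design being modelled

The package analyses (and simulates) a multi-NIL pooled RNA-seq contrast
for a single targeted QTL. Four founder cultivars, one of which (the
*donor*, index 0) carries the trait-increasing allele, are crossed in a
(A×B)×(C×D) funnel and selfed to produce recombinant inbred lines. Lines
still heterozygous donor-vs-other across the QTL interval but homozygous
nearly everywhere else found heterogeneous inbred families; selfing each
founder yields 1:2:1-segregating progeny from which a near-isogenic pair is
fixed: `nil_plus` (donor-homozygous across the interval) and `nil_minus`
(non-donor-homozygous), identical wherever the founder was already
homozygous. Pooling all QTL-positive samples (pool A) against all
QTL-negative samples (pool B) across families and timepoints makes the
shared interval signal coherent while family-specific background
differences decorrelate.

## Germination index

`GI = Σ (n−d+1)·N_d / (n·total)` over an n-day test (default 7), where
`N_d` counts grains *newly* germinated on day d. The weights generalize the
classic 7-day screen to any n ≥ 1; grains never germinating contribute
weight 0 implicitly. Inputs are per-day new germinations; cumulative curves
must be differenced (the CLI's `--cumulative` flag does this). Properties
enforced by tests: GI ∈ [0,1] with the bounds attained exactly at the
all-day-1 and never-germinated extremes; moving a germination event earlier
never decreases GI; jointly scaling counts and total leaves GI unchanged.
Class summaries report mean, sample-SD-based standard error (undefined for
singleton groups) and count per (genotype class, treatment); light and dark
screens are never merged into one phenotype.

## Trait-linked SNP filter

Allele calling: depths are summed per biological entity (founder, or
family×pool) across timepoints; zero total depth → *absent* (a
configurable `absent_max_depth`, default 0, tolerates stray error reads);
a maximum-nucleotide fraction ≥ `min_frac` (default 0.95, inclusive at the
boundary) → *homozygous*; otherwise *ambiguous*. Founder rows are
identified by `pool == '.'` in the depth table, and the donor founder by
name (`FilterParams.donor_founder`, default "Yitpi"), since the depth TSV
carries no donor column.

The four criteria, with the conventions adopted where the procedure is
under-specified:

1. **Donor-distinct.** The candidate donor allele is the donor founder's
   homozygous call; if the donor is absent (e.g. its allele is not
   expressed), the pool-A family consensus substitutes. Non-donor founders
   conflict only when *called homozygous* for that allele — absent or
   ambiguous non-donor founders cannot exhibit it and are non-conflicting.
2. **Donor state.** The donor founder must be homozygous or absent;
   ambiguity fails this criterion for the donor only.
3. **Family concordance.** Joint reading (default): a family is concordant
   when its pool-A entity is homozygous for the donor allele *and* its
   pool-B entity homozygous for a different allele; ≥
   `min_family_concordance` (default 4) of `n_families` (default 5) must be
   concordant. The alternative per-pool independent count is available via
   `concordance_mode="per_pool"`.
4. **Coverage.** Reads supporting the candidate allele, summed over the
   entities called homozygous for it, must reach `min_allele_depth`
   (default 2). The per-sample alternative is not implemented; summing
   matches the aggregation used everywhere else in the filter.

A `per_timepoint` mode calls each timepoint separately and unions the
decisions (a site passes if any timepoint passes). Decisions are emitted as
a per-criterion TSV report and passing sites as minimal VCF 4.2 (1-based
POS; REF = non-donor allele, ALT = donor allele, INFO flags C1–C4 and
NFAM). There is no manual-inspection stage; the report is the machine
replacement.

## Differential expression

Model: per gene, counts ~ NB(μ, φ) with
`log μ = offset + unit + timepoint + β_qtl·status`; unit (family or parent)
and timepoint are treatment-coded, status is 0/1, and the offset is the log
effective library size (raw total × TMM factor; a library-size-only mode
exists). Offsets, not weights, carry normalization. Genes with zero counts
in every sample are dropped before fitting and reported.

*TMM*: reference sample = the one whose upper-quartile/total ratio is
closest to the mean ratio; per pair, genes zero in either sample are
excluded, M and A values trimmed 30 % and 5 % from each tail respectively,
and the trimmed M values averaged with delta-method precision weights;
factors are rescaled to geometric mean 1.

*Fitting*: IRLS at fixed φ, batched across genes (all genes share the
design, so the weighted least-squares solves are stacked). Convergence is a
relative deviance change < 1e−8 (cap 100 iterations); non-convergence is
flagged on the result, never raised. Linear predictors are clipped at ±30
and a 1e−10 ridge keeps near-degenerate weighted systems solvable. φ = 0
reduces exactly to the Poisson GLM (verified against statsmodels).

*Dispersion*: the common estimate maximizes the Cox–Reid adjusted profile
likelihood (ll − ½·log det XᵀWX per gene) over log φ, alternating scalar
maximization with GLM refits of the gene-wise means until φ stabilizes
(tolerance 1e−3 relative, ≤ 5 outer rounds). The Cox–Reid term removes the
O(p/n) downward bias of plain profile ML, which matters here (8
coefficients on 30 samples). Tagwise mode maximizes each gene's likelihood
at the common fitted means and shrinks linearly toward the common value
with `prior_weight` (default 10): φ_g = (w·φ_c + φ̂_g)/(w+1).

*Testing*: LRT statistic 2(ll_full − ll_reduced), floored at 0, referred to
χ²(1). The reported effect is the QTL coefficient / ln 2 (log2 fold
change). Adjustment: Benjamini–Hochberg step-up by default; the named
"Hochberg" step-up (FWER) is available since the two are often conflated —
the package treats the FDR-controlling BH as the intended default. Both
delegate to `statsmodels.stats.multitest`. The DE call is *strict*:
adjusted p < alpha (default 0.01), so adjusted p = 0.01 is not called.

A caveat the tests encode: step-up adjusted p-values are *not* idempotent
under re-adjustment in general (re-adjusting collapses toward the maximum);
they are idempotent on tied inputs, and thresholding them always reproduces
the step-up procedure's rejection set. The tests assert the true
properties.

## Candidate ranking

Coordinates are 0-based half-open internally; VCF output converts to
1-based and BED stays 0-based (round-trip tested at position 0 and at
interval ends). A contig is in-region when it overlaps the QTL interval by
≥ 1 base (a containment mode exists). Candidates are in-region contigs with
a DE call or ≥ 1 passing SNP, sorted by adjusted p ascending (contigs
without a DE test after all tested ones), then by worst coding consequence
(nonsense > nonsynonymous > synonymous > noncoding), then by contig id for
determinism. DE significance leads because expression evidence, not SNP
severity, defines the primary ranking; the severity tie-break is a declared
convention. Out-of-region evidence is reported in a separate table — such
genes may be downstream responses to the QTL rather than causes.

SNP consequences translate the affected codon on the coding strand with the
standard nuclear code; stop-gain → nonsense, amino-acid change →
nonsynonymous (stop-loss is reported as nonsynonymous), else synonymous;
positions outside the ORF → noncoding. A reference-allele mismatch raises —
it signals a coordinate or strand bug, not data noise.

In-silico PCR is exact-match only (no mismatches, no degenerate bases):
the forward primer must occur once on the plus strand, the reverse primer
once as its reverse complement downstream; the product includes both
primers. Deleting d bases strictly between the primer sites shortens the
product by exactly d — the property that makes an INDEL-spanning primer
pair a genotyping marker.

## Simulator

The generator's defaults are the study conditions, not tuning knobs:

| parameter | default | rationale |
|---|---|---|
| founders | 4, donor first | four-parent funnel design |
| RILs per batch | 1579 | source mapping-population size |
| selfing generations | 6 | F1 → F7 inbreeding |
| families | 5 | five HIF-derived NIL pairs |
| background homozygosity | ≥ 0.95 | selection threshold slightly below the ~97 % marker-based figure, attainable on a small simulated genome |
| genome | 3 chromosomes × 200 markers, 150 cM each | desk-scale stand-in for a full genome |
| QTL interval | 8 markers ≈ 6 cM | small enough that a 1579-RIL batch typically contains ≥ 5 qualifying HIF founders |
| timepoints | 15/25/35 DPA | grain-maturation sampling |
| causal effect | log2FC 1/2/3 at 15/25/35 DPA | donor-allele expression rising with maturation |
| NB dispersion φ | 0.2 | typical bulk RNA-seq overdispersion |
| mean site depth | 30× | moderate expressed-SNP coverage |
| sequencing error | 0.005/read | Illumina-scale miscall rate |
| dormancy effect | 2.0 per donor allele (daily-hazard logit) | produces clearly semi-dominant GI separation |
| decoy sites | 50 | negative controls for the filter |

Meiosis draws Poisson(L/100) crossovers per chromosome with uniform
positions and no interference (Haldane); genetic positions are marker
indices on a uniform map, with a fixed 10 kb/marker physical scale — no
separate physical/genetic map is modelled. The funnel order is fixed at
(A×B)×(C×D); by symmetry the order is immaterial to pipeline behaviour.
HIF-founder selection requires the donor haplotype *intact on one homolog*
across the interval (not merely per-marker heterozygosity): a
phase-switching heterozygote could not yield interval-homozygous progeny
and would never have been usable as a NIL source. When a batch yields fewer
qualifying founders than requested, further seeded batches are drawn
(capped at 8) — mirroring selection from a population in which such lines
exist. NIL fixation resolves each residual heterozygous block to one
homolog with a fair coin per block, the fixation outcome of one further
selfing round.

Expression: gene baselines are log-normal (log-mean ~ N(log 100, 1)), with
N(0, 0.1) unit effects and N(0, 0.2) timepoint effects per gene; the causal
gene adds ln 2 × log2FC(t) for QTL-positive samples. Counts are
gamma-Poisson draws. Parents are included once per timepoint with status
set by their QTL allele, as in the pooled design. Allele-depth coverage is
Poisson(mean_depth × relative expression of the carrying gene in the
matching sample) — so a silenced allele yields zero reads and an *absent*
call, the phenomenon that motivates criterion 2's "or absent" clause; a
flag decouples coverage from expression. Each read reports a uniformly
chosen homolog, miscalled to a uniform other nucleotide with the error
rate. Germination is a per-day logistic hazard
`expit(−1 + 0.5·d − 2·dosage)`, giving mean GI ordered donor-hom < het <
other-hom (semi-dominance).

Decoy sites cycle three constructions: donor allele shared with another
founder (violates criterion 1), fully random founder alleles (segregates
with each family's background, defeating concordance), and monomorphic.
Linked sites in the causal gene are one nonsynonymous (GCT→GAT, Ala→Asp),
one synonymous (GCT→GCC) and one 3′ noncoding, so the consequence
annotator is exercised end to end. The marker assay plants an 18-bp
promoter insertion on the donor haplotype between a unique primer pair,
amplifying at 117 bp vs 99 bp.

What the simulator does **not** emulate: raw reads, alignment artefacts,
mapping bias, batch effects, library-preparation variation, genotyping
error in marker data, or any temperature-by-genotype interaction beyond
the per-timepoint effect hook. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative
model, not robustness to real-data pathologies upstream of the count and
depth tables.

## Problem sizes used in validation

The pytest suite runs the statistical checks at the sizes its assertions
state: type-I calibration and dispersion recovery on 2000 genes × 30
samples; filter-oracle equivalence on 200 randomized sites; Mendelian
segregation on ≥ 400 progeny; heterozygosity decay on 1000 RILs;
end-to-end recovery on ten full-size (2000-gene, 50-decoy) replicates; the
power property across 20 replicates uses 500 background genes. Shared
fixtures use a 300-gene experiment. These sizes were chosen so the whole
suite completes in a couple of minutes while keeping every interval test at
its stated confidence level.

## Known limitations

* The NB machinery targets this design (shared design matrix across genes,
  one tested coefficient); it is not a general DE framework — no
  empirical-Bayes moderation of per-gene dispersions beyond the linear
  shrinkage, no quasi-likelihood F-tests.
* `estimate_dispersion` assumes more samples than coefficients; saturated
  or near-saturated designs are rejected rather than regularized.
* The SNP filter starts from depth tables; no pileup generation,
  base-quality modelling or alignment-error handling.
* In-silico PCR is exact-match; primer thermodynamics and mismatch
  tolerance are out of scope.
* Whether criterion 3 should count concordance jointly or per pool, and
  whether criterion 4's threshold is per sample or summed, are genuinely
  ambiguous in the source procedure; both defaults are documented above and
  the alternatives are switches, not silent behaviour.
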