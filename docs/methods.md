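# Methods

This note documents the models, estimators and design choices behind
`clonotracer`, the assumptions they rest on, and what the simulation-based
validation does and does not demonstrate.

## Data model

A sample is a `GenotypeMatrix`: cells × variants diploid genotype calls
(WT/HET/HOM/MISSING, stored as ALT-allele counts 0/1/2 with −1 for
MISSING) with parallel read-depth and genotype-quality integer layers and
an amplicon panel annotation. Panel variants carry a category:

- `common` — well-annotated germline SNVs; the substrate for
  donor/recipient discrimination and (with `pathogenic`) for clustering;
- `pathogenic` — disease-related somatic variants defining clones;
- `ado_control` — control amplicons at sites heterozygous in every cell by
  design, used exclusively to measure allele dropout. They are excluded
  from clustering distances (being HET everywhere, they contribute only
  dropout noise) and from VAF tables.

MISSING never enters a distance, a VAF denominator, or an ADO denominator.
Genotype calls are taken as given (the package consumes caller output; it
does not re-call or impute genotypes).

## Quality control

Order: **mask calls → filter variants → filter cells.** The cell rule is
defined over the retained ("called") variant set, which fixes this order.

- Call mask: depth < `min_depth` (default 10) or quality <
  `min_variant_quality` (default 30) ⇒ MISSING. Thresholds are
  inclusive-pass (depth 10 and quality 30 survive). Raw depth/quality are
  retained for diagnostics after masking.
- Variant filter: missing fraction > `max_variant_missing_fraction`
  removes the variant. The default is 1.0 (off): the filter exists and is
  configurable, but no defensible universal threshold presents itself, so
  none is imposed.
- Cell filter: missing fraction **strictly greater than**
  `max_cell_missing_fraction` (default 7.5%) removes the cell; a cell at
  exactly the threshold is kept.

Filtering is monotone in its thresholds and idempotent; both properties
are asserted in the test suite.

## Allele dropout

ADO converts a true heterozygote into an apparent homozygote by failing to
amplify one allele. It is *measured*, never corrected for: at each control
locus, `rate = #(WT or HOM calls) / #(non-MISSING calls)`, averaged
unweighted over ≥ 3 informative control loci (loci with zero called cells
are dropped with a warning; fewer than 3 remaining is an error). MISSING
calls are excluded from the denominator because a no-call is amplicon
failure, not allele dropout; counting them would conflate the two.

The simulator's ADO model is symmetric at the call level: each HET call is
corrupted with probability `ado_rate`, going to WT or HOM with equal
probability. Symmetry has a useful consequence exploited by the zygosity
diagnostic and verified by simulation: the expected pseudo-bulk VAF of a
truly heterozygous variant is invariant under ADO (HET→WT and HET→HOM
transfers cancel).

The estimator is unbiased under this model; recovery tests check a true
rate of 0.10 to ±0.02 per replicate and ±0.005 in the mean over 200
replicates of 2,000 cells × 4 loci.

## Genotype distance and clone calling

Pairwise cell distance is Euclidean on the 0/1/2 encoding over loci where
both cells are called, rescaled by `sqrt(total loci / shared loci)` so that
sparsely shared pairs are not spuriously close; a pair sharing zero called
loci is assigned the maximum observed distance + 1. The 0/1/2 metric
treats WT→HOM (distance 2 per locus) as farther than WT→HET (distance 1),
which is what makes homozygous-mutant clones well separated.

Clone calling is agglomerative clustering with complete linkage on this
distance (the default of the standard R heatmap-clustering stack this
field uses; linkage is configurable). The clone count `k` may be given —
the practical choice when the analyst has inspected the heatmap, and the
one used in the validation scenarios — or chosen automatically in
2..min(10, n−1) by maximal mean silhouette, falling back to a single clone
below a silhouette of 0.25. Clone signatures are per-locus majority
genotypes over member cells (ties break toward the lower code,
deterministically); clone frequencies are computed over **all** QC-passing
cells, donor- and recipient-derived alike, matching whole-population
percentages.

With no noise, the clustering partition at the correct `k` equals the
partition by distinct genotype signatures exactly (asserted as an oracle
test). With ADO 0.1 and 2% missing data, clones differing at ≥ 2
homozygous loci (squared separation ≥ 8) or ≥ 5 heterozygous loci are
recovered with ARI ≥ 0.95 at 2,000 cells.

## Donor/recipient chimerism

Assumption from the study design: the pre-BMT sample is 100%
recipient-derived. Its per-locus majority genotype over common SNVs is the
recipient germline profile. The post-BMT sample is clustered 2-way on the
same loci; the cluster consensus nearer the recipient profile (Hamming
over non-MISSING loci) keeps the recipient label and the other becomes the
donor profile. Inference refuses (`NoChimerismError`) when:

- the post-BMT sample does not support two clusters (silhouette below
  floor),
- the two cluster consensuses diverge at < `min_profile_divergence`
  (default 0.1) of common SNVs — two unrelated germlines differ at many
  common SNVs, so a near-identical split is an ADO-outlier artifact, not a
  donor population, or
- the profiles end up with zero discriminative loci.

Discriminative loci are those where both profiles are called and differ
(HET vs HOM counts). Each cell is assigned by exact-genotype majority vote
over the discriminative loci where it has calls; equal votes (including
zero usable loci) yield `ambiguous`, which is reported as its own fraction
and never redistributed — the three fractions always sum to 1.

A hard majority vote (rather than ADO-aware likelihood weighting) is the
default because the downstream report is a hard partition; with ≥ 10
discriminative loci and ADO ≤ 0.12 per-cell accuracy exceeds 99% and the
donor-fraction error stays within 2 percentage points at ≥ 2,000 cells
(recovery-tested). With a single discriminative locus the vote degrades
gracefully: the error plus ambiguous rate is bounded by the per-locus
corruption rate.

## Longitudinal clone matching and expansion flagging

Consecutive timepoints are matched greedily by ascending normalized
Hamming distance between clone consensus signatures, accepting pairs below
0.2. The threshold is permissive enough to absorb ADO perturbation of a
signature (a few percent of loci) and strict enough never to bridge donor
and recipient germlines (~13/19 loci ≈ 0.68 apart). Unmatched clones open
new lineages (frequency 0 before first appearance) or let lineages end.

A lineage is flagged as an **expanding oncogenic clone** when its
signature carries ≥ 1 pathogenic variant in non-WT state and its frequency
increases at *every* transition by more than `min_increase` (default 0.02,
i.e. 2 percentage points). The margin exists because clone frequencies are
multinomial estimates: at a few thousand cells a genuinely flat clone
drifts by ±1 point per timepoint and would otherwise be "strictly
increasing" by chance in roughly a quarter of realizations. 2 points is
several standard errors of a clone-frequency difference at the cell counts
this pipeline targets, while real expansions in this setting move tens of
points per transition.

## Pseudo-bulk VAF, clonal fraction, zygosity

Pseudo-bulk VAF aggregates allele counts implied by calls:
`(n_het + 2·n_hom) / (2·n_called)`; a variant with zero called cells is
flagged undefined rather than erroring. This is genotype-derived, not
read-derived: discrepancies with bulk assays due to different input
material or callers are out of scope, and the concordance table simply
reports side-by-side values with |Δ| ≤ 0.10 as the default concordance
call, labelling assay-unique detections.

The clonal-fraction rule inverts a bulk VAF to a clone-frequency estimate:
`min(2·VAF, 1)` under the heterozygosity assumption, `VAF` under
homozygosity. The returned object carries a note naming the assumption,
because the rule's failure is exactly the interesting case: a homozygous
clone's true frequency is half what the het rule claims.

The zygosity diagnostic quantifies whether apparent mutant homozygosity is
explainable by dropout: under symmetric ADO at measured rate *r*,
`P(HOM | mutant call) = (r/2)/(1 − r/2)`; the binomial upper tail of the
observed HOM count among mutant calls is reported, with a flag below α.
The accompanying depth comparison (two-sided Wilcoxon rank-sum between
mutant-call and WT-call cell depths, α = 0.05, with a `hom_only` mode)
checks that genotype structure is not a coverage artifact. The report
always lists the three candidate explanations — true homozygosity, loss of
heterozygosity, unbalanced dropout — and deliberately never adjudicates,
because genotype data alone cannot. The rank-sum test was chosen because
per-cell depth distributions are skewed and overdispersed; its type-I
error on null negative-binomial depths is 5.0% (verified by simulation at
n = 500 per group). No multiple-testing correction is applied by default
(one variant is tested); Benjamini–Hochberg is available when scanning
panels.

## Synthetic experiments

The generator emulates the longitudinal transplant study design: 2–3
timepoints, 1,500–4,700 cells per sample, a panel of 19 common SNVs
(13 discriminative by default), 2 pathogenic variants, 4 ADO-control loci,
donor fractions 0 / 48.3% / 27.3%, an oncogenic clone at 9% → 42% → 70%
of the whole population, ADO 8%, 2% missing calls, negative-binomial depth
(mean 80, dispersion 5) and constant quality 60. Germline genotypes at
common SNVs are drawn WT/HET/HOM with probabilities 0.5/0.35/0.15 (no
population model is imposed by the data; these give realistic
heterozygosity). The default oncogenic clone carries its pathogenic
variants homozygously — matching the observed mutant-allele-only relapse
clones and making pseudo-bulk VAF ≈ clone frequency.

Noise order per cell: germline+clone genotype → ADO → missing mask →
depth/quality sampling. Depth is independent of genotype by default
(cluster formation must not depend on read depth); a genotype-biased depth
mode and an optional doublet rate exist for robustness studies. All
randomness flows from one integer seed through `numpy.random.SeedSequence`,
so identical configs are byte-identical on disk.

What the simulator does **not** model — and hence what passing recovery
tests do not establish about real data: doublets (off by default),
copy-number change, allele-specific (unbalanced) dropout, per-amplicon
efficiency differences, index hopping/barcode collisions, caller-specific
genotype error beyond the symmetric ADO + uniform missingness model, and
clone genotypes evolving by an explicit mutational process (trajectories
are specified per timepoint, not evolved).

## Numerical and reproducibility choices

- Deterministic tie-breaks throughout: consensus ties go to the lower
  genotype code; clusters are relabelled by decreasing size; lineages are
  named by first appearance then peak frequency.
- Pipeline reports are JSON with sorted keys and TSVs with fixed row
  order; wall-clock timings live only in the run manifest, so reports are
  byte-identical across reruns of the same config+seed.
- t-SNE embedding (visualization only) imputes MISSING to the per-locus
  mode; imputed values never flow back into analysis. Coordinates are
  seed-stable but only topology (e.g. clone separability) is meaningful.
- Validation scenarios run at reduced but study-representative sizes
  (2,000–3,000 cells per sample, 100–10,000 statistical replicates),
  chosen so recovery targets are several standard errors wide.

## Known limitations

- Chimerism inference needs a recipient-pure anchor sample; without a
  pre-BMT sample the donor/recipient orientation is undefined.
- The ADO estimator assumes control amplicons are truly heterozygous in
  every cell; germline homozygosity at a control locus in a given
  individual would inflate the estimate.
- Clone matching is greedy 1:1 between consecutive timepoints; clone
  splits/merges are represented as lineage ends plus new lineages, not as
  branching events.
- Automatic clone-count selection by silhouette is conservative for very
  small clones (< ~5% of cells); pass `k` explicitly when the heatmap
  shows more structure than silhouette admits.
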