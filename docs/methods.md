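# Methods

`bdvp` implements a pipeline for prioritizing germline variants associated
with malignant tumors in birth-defect (BD) cohorts, and a synthetic-cohort
generator that reproduces the statistical structure the pipeline assumes so
that every stage can be exercised and tested without access-restricted
patient data.

## Cohort model and variant identity

The analysis assumes three groups of whole-genome-sequenced individuals:
affected probands with at least one malignant tumor (cases), affected
probands without cancer (disease controls), and healthy parents/siblings of
probands (family controls). Two calls are the *same variant* iff they share
contig, normalized position, reference and alternative allele. Keys are
parsimony-trimmed — shared trailing bases removed first, then shared
leading bases with the position advanced, always retaining at least one
base per allele — and multi-allelic records are split into one key per
alternative allele before trimming. Carrier status is dominant: a sample
carries a variant iff its genotype contains ≥ 1 copy of the alternative
allele. Missing genotypes count as non-carrier, so the exclusivity filter
always sees a definite 0/1; users with low-quality sites should pre-filter
(a `--pass-only` flag restricts to FILTER=PASS).

## The exclusive-recurrence filter

A variant is a *variant of interest* iff

1. it is carried by ≥ `min_cases` (default 3) case probands, counted at
   most once per family (`require_unrelated`, default on; a toggle counts
   samples instead), and
2. it has **zero** carriers among disease-control probands and among family
   controls.

The filter is set-theoretic; no per-variant statistic is computed. Family
collapsing implements the "unrelated cases" requirement; counting modes are
both available because recurrence could defensibly be counted either way.
Only case-group probands are eligible as cases; control-group relatives
never are, whatever their genotype.

## Region strata and gene mapping

Each selected variant is classified against a user-supplied gene model
(GFF3: gene/exon/CDS/UTR features with `gene_id` and `biotype` attributes)
into CODING, UTR, NCRNA, INTRONIC or INTERGENIC, which collapse into the
three analysis strata: coding, non-coding (introns + UTRs + ncRNA exons)
and intergenic. When features overlap, precedence is
CODING > UTR > NCRNA > INTRONIC: the strata must partition the selection,
and the most specific functional context wins. This is a documented choice;
annotators differ here and no single convention is canonical. Positions
inside a gene span but outside every exon are intronic; positions in no
span are intergenic and carry the nearest gene(s) by distance to the span
boundary, with both genes reported on an exact tie (mirroring common
annotator behavior). Strand is stored but ignored — containment is
strand-symmetric. Internal coordinates are 0-based half-open; VCF and GFF3
are converted at I/O boundaries. Transcript-level consequences (missense,
splice sites, isoform resolution) are out of scope.

## Gene-load features and two-layer reduction

Per stratum, selected variants collapse to a samples × genes matrix of
integer *mutation loads*: the entry for (sample, gene) counts the selected
variants mapped to that gene that the sample carries. A variant mapped to
k genes contributes to all k columns (a `--first-gene-only` alternative
avoids the double count; `--binarize` gives presence/absence for
sensitivity analysis). Counts are over probands only; on discovery data the
disease-control rows are all zero by construction of the filter — the
feature signal is therefore trivially separable *in discovery*, and all
interesting evaluation happens on independent cohorts.

Reduction has two layers:

1. **Importance filter.** A random forest (default 500 trees,
   class-balanced, seeded) is fit to (loads, labels); impurity importances
   are normalized to sum to 1 and genes below a threshold (default 1e-5)
   are dropped.
2. **Forward selection.** Greedy wrapper maximizing cross-validated
   balanced accuracy (default 5 folds, stratified, seeded). Each round adds
   the best-scoring candidate; the search stops after `patience` (default
   1) consecutive rounds without improvement and returns the best-scoring
   prefix in pick order. The default scoring model is a smaller random
   forest — wrapper selection with the deployment network would multiply
   cost for little gain; the final MLP can be substituted. With more than
   `max_candidates` (default 64) surviving genes, the candidate pool is
   pre-screened by class-mean load difference to keep the quadratic wrapper
   affordable.

Balanced accuracy, fold count and patience are package defaults, stated
here because no standard convention exists. A variant-level summary reports
how many selected variants still map to a kept gene and the percent
reduction.

## Classification and majority vote

One multi-layer perceptron is trained per stratum on the reduced discovery
features. Hyperparameters — max iterations, L2 alpha (log scale),
activation, solver, learning-rate schedule, hidden-layer count and units
per layer — are chosen by sequential model-based minimization of 3-fold
cross-validated log-loss: random initial configurations, then a
Gaussian-process surrogate (Matérn 5/2 on unit-scaled coordinates, integer
and categorical dimensions by rounding) with expected-improvement
acquisition over a random candidate pool. Failed trials (non-finite loss)
are penalized with the worst finite loss and the search continues; the best
configuration is refit on all discovery data. The whole search is
deterministic given one seed. Class imbalance is handled by seeded
oversampling of the minority class before each fit, since sklearn's MLP has
no class-weighted loss.

An independent cohort is featurized with the *discovery* gene order
(missing genes become zero columns — re-running selection on validation
data would leak), each stratum model casts one vote per sample, and the
majority of the three votes is the combined label. With three votes the
majority is never tied; if a stratum model is missing (its stratum was
empty) that vote abstains and a two-vote tie breaks toward the non-cancer
label, the conservative direction for a screening tool. Accuracies are
reported as fractions alongside rounded integer percents.

## Mutation-load comparison

Per-individual counts of selected variants are compared between groups with
a two-sided Wilcoxon rank-sum (Mann–Whitney U) test: an exact permutation
null when C(n1+n2, n1) ≤ 20,000 (valid under the heavy ties integer loads
produce), otherwise the normal approximation with tie correction. All-equal
pooled counts short-circuit to p = 1. Groups smaller than 2 skip the test
with a warning but still report five-number summaries (boxplot-ready).
Calibration under a null of i.i.d. Poisson loads at the validation-cohort
shape (25 vs 15) is verified in the acceptance suite: type-I error 0.046 at
nominal 0.05 over 2,000 simulations.

## Enrichment and catalogue overlap

Gene-set enrichment is a one-sided hypergeometric upper tail per set with
Benjamini–Hochberg adjustment across sets, over any GMT collection and a
configurable universe (default: all genes in the gene model; the universe
choice is the user's). This replaces web-based enrichment services so the
pipeline runs offline; reproducing any particular database's tables is a
non-goal. Somatic-catalogue screening is exact key intersection (same
locus, same alternative allele) against a user-supplied VCF/TSV catalogue,
normalized with the same parsimony rule as cohort variants.

## Synthetic cohorts

The generator emulates:

* **Shape** — default 60/80/40 discovery probands/controls and 25/15
  validation, a scaled-down version of the 541/767/345 and 25/15 reference
  shape (`full_scale_config()` restores the full sizes). One family per
  proband; controls attach round-robin to proband families as
  parents/siblings.
* **Gene model** — non-overlapping genes (default 120 on a 1 Mb contig)
  with 2–4 exons, UTRs carved from terminal exons, CDS elsewhere, and a
  20 % ncRNA fraction, leaving intergenic gaps, so all five region classes
  occur.
* **Background variation** — default 2,000 variants with carrier
  frequencies log-uniform on [0.005, 0.2] (both rare and common background
  exists), i.i.d. across probands. A family control copies its proband's
  carrier status with probability 0.5 and is an independent carrier
  otherwise — a one-parameter transmission approximation that is enough to
  stress the family-exclusivity logic without pedigree simulation.
* **Planted signal** — default 10 variants per stratum concentrated in 5
  signal genes per stratum, each carried by 3–6 distinct-family cases and
  nobody else, so every planted variant passes the filter by construction
  (an adversarial flag plants one disease-control carrier to verify the
  filter removes it).
* **Validation** — cancer probands carry a per-sample random half
  (`replant_rate = 0.5`) of the signal variants; non-cancer probands carry
  background only; all draw background at the discovery frequencies.

All outputs (VCF, sample sheet, GFF3, truth JSON) are byte-identical for a
fixed seed.

The number of *spurious* filter passes among background variants has a
closed form under this generative model. With transmission rate t,
P(control clean | its proband carries) = (1−t)(1−f) and
P(control clean | its proband is clean) = 1−(1−t)f. A case proband i with
c_i attached controls therefore contributes a carry-and-clean weight
a_i = f·((1−t)(1−f))^{c_i} and a clean weight
b_i = (1−f)·(1−(1−t)f)^{c_i}; convolving the per-proband
polynomials (b_i + a_i z) gives the joint probability of k carrying cases
with all case-side controls clean, and multiplying by the disease-control
clean probability and summing k ≥ min_cases gives the per-variant pass
probability. The expectation and Poisson-binomial variance over variants
follow by summation. The implementation is validated against an
independent Monte-Carlo simulation of the generative process in the test
suite, and observed spurious counts match the expectation within 3 SE in
the acceptance suite.

### What passing tests do and do not show

The simulator plants *clean* signal: case-exclusive, recurrent,
concentrated in a few genes, with validation cases re-carrying half of it.
Passing end-to-end tests therefore demonstrates that the machinery —
filter, annotation, collapsing, reduction, training, voting — is correct
and recovers signal that satisfies the method's own assumptions, at the
scaled problem sizes (chosen so the suite runs in minutes: 2,030 variants,
180 discovery samples, 10–20 seeds per property). It does **not** show
that such signal exists in real cohorts, nor how the method degrades under
incomplete penetrance, population stratification, relatedness mis-
specification, sequencing artifacts or genes absent from the model — none
of which the generator emulates. The near-perfect synthetic validation
accuracy (median 100 %) mirrors, but does not reproduce, the ~75–80 %
reported on real data.

A consequence of the clean-signal design worth knowing: in the
label-permuted null experiment, discovery loads remain bimodal (original
cases carry signal, disease controls are zero), so a trained classifier
maps "high load" to an essentially arbitrary side per stratum and per-seed
null validation accuracy is strongly over-dispersed relative to 40
independent coin flips — it spans [0, 1] across seeds with a median near
chance. The acceptance suite asserts the median against the central 95 %
interval of Binomial(40, ½); by the above, that interval is narrower than
this statistic's true seed-to-seed spread, and the check can fail for seed
sets on which the planted check still passes.

## Numerical and degenerate-input choices

* Deterministic ordering everywhere: selections sort by (contig, pos, ref,
  alt); gene columns sort by gene id; ties in forward selection keep the
  earlier candidate.
* An empty stratum yields an empty feature matrix (sentinel), not an
  error; its model is absent and its vote abstains.
* Degenerate variants (ref = alt after trimming) are errors; duplicate
  keys from separate VCF records merge by logical OR with a warning.
* A single global seed fans out per stage via a stage-name CRC, so stages
  are individually reproducible; `--threads` never affects results.

## Known limitations

Zygosity is discarded (dominance coding), VAF/mosaicism is not modeled, sex
chromosomes are treated as autosomes, the annotator is transcript-unaware,
and the simulator has no linkage disequilibrium, mutation-rate variation or
sequencing error. The feature reduction's gene counts depend on forest and
fold seeds in ways the underlying studies typically do not report, so gene
counts are not comparable across tools — only the pipeline's behavior on
its own outputs is.
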