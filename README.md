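# bdvp — birth-defect variant prioritization

Children with non-chromosomal birth defects (BD) carry a several-fold
increased risk of malignant tumors. `bdvp` implements, as a tested and
reusable pipeline, a strategy for finding germline variants associated with
that risk from multi-sample whole-genome genotypes, and for evaluating them
as predictive biomarkers:

1. **Exclusive recurrence filter.** A variant (identified by contig,
   normalized position, REF and ALT) is a *variant of interest* iff it is
   carried by ≥ 3 unrelated BD probands **with** cancer and by zero BD-only
   probands and zero healthy family controls.
2. **Region-stratified gene loads.** Selected variants are classified
   against a gene model into coding, non-coding (intronic/UTR/ncRNA) and
   intergenic strata and collapsed per stratum into gene-level *mutation
   loads*: load(s, g) = number of selected variants in gene g carried by
   sample s.
3. **Two-layer feature reduction.** A random-forest importance filter
   (normalized importances summing to 1; genes < 1e-5 dropped) followed by
   greedy forward feature selection on cross-validated balanced accuracy.
4. **Per-stratum MLP classifiers + majority vote.** One multi-layer
   perceptron per stratum, hyperparameters chosen by Bayesian (sequential
   model-based) minimization of CV log-loss; an independent cohort is
   labeled by each stratum and combined by majority over the three votes.
5. **Supporting analyses.** Per-individual mutation-load comparison between
   groups (Wilcoxon rank-sum), hypergeometric gene-set enrichment with BH
   adjustment over any GMT collection, and exact-key overlap against a
   somatic-variant catalogue.

Because the cohorts such a study needs are access-restricted, the package
ships a first-class synthetic-cohort generator (three groups with family
structure, shared background variation, planted case-exclusive recurrent
signal per stratum, and an independent validation cohort) plus ground-truth
tables, so the whole pipeline is testable end to end. See
`docs/methods.md` for the model, its assumptions and its limits.

Audience: statistical-genetics and rare-disease researchers who want to
apply or stress-test case-exclusive recurrence filtering and mutation-load
classification on their own VCF cohorts.

## Worked example

Run the full analysis on one synthetic cohort (60/80/40 discovery probands
and controls, 2,000 background variants, 30 planted signal variants, 25/15
validation):

```python
from bdvp.classify import TuningSpace
from bdvp.pipeline import run_synthetic_experiment
from bdvp.synthetic import SimConfig

res = run_synthetic_experiment(SimConfig(seed=7), tuning=TuningSpace(budget=8))
```

which prints, formatted:

```
variants selected:       35
planted-signal recall:   1.0
spurious selections:     5 (expected 3.19 +/- 1.78)
accuracy coding     :  40/40 (100%)
accuracy noncoding  :  40/40 (100%)
accuracy intergenic :  38/40 (95%)
majority vote:           40/40 (100%)
validation load medians: {'BD_CANCER': 15.0, 'BD_ONLY': 0.0}  rank-sum p = 3.01e-09
```

Reading: all 30 planted variants pass the filter (recall 1.0); 5 background
variants slip through by chance, consistent with the analytic expectation
3.19 ± 1.78 for this cohort; per-stratum MLPs label 38–40 of the 40
validation patients correctly and the majority vote labels all 40; the
median validation mutation load is 15 in cancer patients versus 0 in
BD-only patients (rank-sum p ≈ 3e-9). On this clean synthetic signal the
classifier is near-perfect — real cohorts are far noisier.

The same stages are available as a CLI:

```sh
bdvp simulate --seed 7 --out sim/
bdvp discover --vcf sim/discovery.vcf --sheet sim/discovery.samples.tsv \
              --gff sim/genes.gff3 --min-cases 3 --out selection.tsv
bdvp run-all --seed 7 --out results/        # all stages + manifest.json
```

Other subcommands: `annotate`, `features`, `train`, `predict`,
`compare-load`, `enrich`, `overlap`.

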