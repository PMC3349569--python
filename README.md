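# coremod

Cross-cohort **core-module biomarker discovery** from gene-expression
cohorts: pathway-activity inference, cross-cohort reproducibility scoring,
consensus feature elimination with linear classifiers, pairwise
inference/validation core-module assembly, gene-set enrichment, and
network-based driver-gene extraction — with a synthetic multi-cohort
generator so every stage can be exercised offline against a known ground
truth.

## The problem

Expression signatures of disease outcome (e.g. breast-cancer metastasis)
rarely replicate between independent patient cohorts: single-gene markers
are dominated by cohort-specific "passenger" differential expression.
Summarizing expression at the level of pathway activity and demanding that a
marker discriminate in *every* cohort yields a compact, reproducible "core
module" of disease, whose highly connected member genes are candidate
drivers. `coremod` is aimed at computational biologists with two or more
case/control cohorts (genes × samples matrices with binary outcome labels),
a gene-set collection (GMT), and optionally a protein-interaction edge list.

## The method

**Core-module inference (CMI).** For a pathway with differentially expressed
genes (two-tailed two-sample t-test, p ≤ 0.05) ranked g₁, g₂, … by
descending |t|, prefix activities are built from per-cohort z-scores:

    P_j(s) = (1/j) · Σ_{i≤j} z_{g_i}(s) · sign(t(g_i)),   j = 1 … min(#DEGs, 20)

and the member count K = argmax_j t(P_j) is chosen, where t(·) is the
activity's own case/control t statistic. Up- and down-regulated genes enter
together with aligned signs. Comparators: the CORG single-direction search,
per-sample mean/median of member z-scores, first principal-component score,
per-gene Gaussian log-likelihood ratio, and raw individual genes.

**Reproducibility (Cscore).** Models fitted on an inference cohort are
projected onto a validation cohort; for the top-N ranked activities

    Cscore(N) = (1/N) · Σ_{i≤N} t(P_I_i) · t(P_V_i),

averaged over all ordered cohort pairs (six pairs for three cohorts).

**Consensus feature elimination (CFE).** On the projected activity matrix,
100 stratified 5-fold splits yield 500 linear classifiers (shrinkage LDA or
linear SVM) per elimination step; features are ranked by mean squared weight
w̄ = Σ_j w_j²/500, the lowest is removed, and the feature set at the
maximum mean held-out AUC is selected. The run is repeated 100 times and the
most frequent set wins.

**Core module and drivers.** A pathway inferred from cohort D is a core
marker iff CFE selects it against every other cohort; core markers pooled
over all inference cohorts form the core module. Member genes are annotated
up/down/contradictory from per-cohort t-scores, enriched against reference
gene lists with the hypergeometric tail P(X > K), and the hubs of their
induced interaction subnetwork that are also marker genes are called
drivers.

## Worked example

```python
import coremod as cm

cfg = cm.SimulationConfig(n_cohorts=3, n_genes=500, samples_per_cohort=80,
                          n_pathways=20, n_driver_pathways=4, seed=7)
study = cm.simulate_study(cfg)

pairs, overall = cm.overall_reproducibility(study.cohorts, study.pathways,
                                            "cmi", n_grid=[5, 10])
print(overall.to_string(index=False))

results, core = cm.run_all_pairs(study.cohorts, study.pathways,
                                 n_repeats=10, n_splits=10, seed=7)
print("core pathways:", sorted(core.pathway_ids))
sens, spec = cm.core_module_recovery(core.pathway_ids, study)
print(f"sensitivity={sens:.2f} specificity={spec:.2f}")

hubs = cm.hub_genes(study.network, n_hubs=len(study.driver_genes))
print("driver genes:", len(cm.driver_genes(hubs, core.gene_set)))
```

prints

```
method  N  overall_cscore
   cmi  5       26.974812
   cmi 10       18.118924
core pathways: ['PW001', 'PW002', 'PW003', 'PW004', 'PW005', 'PW006', 'PW020']
sensitivity=1.00 specificity=0.81
driver genes: 20
```

The overall Cscore is the six-pair average reproducibility of the top-N
activities (large positive values mean the same activities discriminate, in
the same direction, in independent cohorts). All four planted driver
pathways (`PW001`–`PW004`) are recovered in the core module (sensitivity
1.00) while 81% of the cohort-private passenger pathways are excluded; the
20 planted network hubs are all recalled as driver genes.

The same workflow is available from the shell:

```sh
coremod simulate --out sim/ --seed 3
coremod run --cohort sim/cohort1.tsv --cohort sim/cohort2.tsv \
    --cohort sim/cohort3.tsv --gmt sim/pathways.gmt --edges sim/network.tsv \
    --n-repeats 10 --n-splits 10 --seed 3 --out run/
```

`run/` then holds per-stage TSV reports (`core_markers.tsv`,
`core_genes.tsv`, `drivers.tsv`, …) and a `manifest.json` recording all
parameters and the master seed; reruns with the same seed are bit-identical.

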