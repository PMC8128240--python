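# sepsismeta

Machine-learning diagnosis of sepsis from merged microarray gene expression
data, rebuilt as a tested analysis pipeline on synthetic multi-study data
with known ground truth.

## The problem

Whole-blood transcriptomes separate sepsis patients from healthy controls
easily — the hard differential diagnosis is against SIRS and trauma, whose
transcriptional response overlaps heavily with sepsis.  Meta-analyses merge
dozens of public microarray series into one gene-by-sample matrix
(restricted to the genes all platforms share), pool healthy/SIRS/trauma
into a composite *non-septic* entity, and ask two questions:

1. How well do classifiers — a decision tree (DT), a random forest (RF),
   an RBF support-vector machine (SVM), and a dropout/L2-regularized
   multi-layer perceptron (DNN) — discriminate sepsis from non-sepsis
   under repeated stratified shuffle-split evaluation (AUC and probability
   of correct classification, PCC)?
2. How *resilient* is each classifier when the test data are corrupted by
   three cumulative degradation levels — uniform noise on every value
   (R `jitter`, factor 10,000), zero-replacement of 75% of the genes, and
   substitution of 50% of all genes by N(gene median, 20²) draws — and
   when all genes flagged by differential expression
   (|log₂FC| ≥ 1, BH-adjusted p < 0.05) are removed before training?

Real repository downloads are out of scope.  Instead, `sepsismeta` ships a
multi-study generator that emulates the collection — per-study batch
effects γ_gb + δ_gb·ε (the ComBat model), platform gene panels intersecting
in a common core, co-expression modules, the ~56/44 class split, planted
strong (log₂FC = 2) and weak (log₂FC = 0.5) differential tiers, and an
attenuated-responder sepsis subgroup — so every stage can be tested against
known ground truth.  See `docs/methods.md` for the full model.

## Worked example

```bash
python analysis/01_simulate_meta.py
python analysis/02_preprocess_diffexp.py
python analysis/03_classify_full.py
python analysis/04_resilience.py
python analysis/05_ablation.py
```

`01` simulates 6 studies (~1,000 samples, 2,000 common genes, 55.9%
sepsis).  `02` merges them, applies empirical-Bayes batch adjustment, and
flags **800 of 2,000 genes** as differential; Ward clustering of samples
on those genes finds the familiar three subgroups (one almost pure sepsis
cluster, one pure non-septic cluster, one mixed):

```
         sepsis  non-sepsis
cluster
1           423           0
2             9         174
3            83         232
```

`03` runs the classification experiment (25 stratified shuffle-split
iterations, 85/15 splits, 80/5/15 for the DNN) on native and cumulatively
degraded test data:

```
Mean AUC over 25 iterations (full gene set):
level   native  level1  level2  level3
DNN      1.000   0.781   0.642   0.520
DT       0.953   0.526   0.510   0.495
RF       1.000   0.702   0.578   0.519
SVM      1.000   0.500   0.500   0.500
```

Native discrimination is near-ceiling for RF/SVM/DNN with the single tree
lowest, and performance decays monotonically with degradation.  `04`
extracts the resilience headline — the neural network loses the least when
noise hits the test data:

```
Native-to-level-1 AUC drop per method (smallest = most resilient):
DNN    0.2187
RF     0.2980
DT     0.4270
SVM    0.5000
```

`05` removes all 800 flagged DE genes and repeats the experiment on the
1,200 residual genes: the DNN's native AUC is unchanged (shift 0.0000)
while the decision tree loses visibly (0.953 → 0.944) — the regularized
network spreads its evidence over the weak sub-threshold genes rather than
leaning on the top univariate markers.

Summaries land in `results/` (per-iteration records and bulk data in
`scratch/`).

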