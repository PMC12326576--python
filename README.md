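# crcstrat

Explainable microbiome risk stratification along the adenoma–carcinoma
sequence.

Benign colorectal adenomas progress to invasive colorectal cancer (CRC), and
the gut microbiome shifts along the way: genera such as *Fusobacterium* and
*Peptostreptococcus* enrich in CRC while butyrate producers like the
*Eubacterium eligens* group deplete. This package implements, as a tested and
reusable pipeline, the analysis pattern used in recent explainable-AI
microbiome studies of that transition: genus-level 16S abundance tables plus
clinical covariates are classified adenoma-vs-CRC with tree ensembles, every
subject's prediction is decomposed into Shapley values, the Shapley matrix is
embedded and clustered to find adenoma subgroups whose microbial profile
converges toward CRC, and pairwise SHAP interaction values are thresholded
into weighted "hub" networks. A calibrated synthetic cohort generator with
known ground truth stands in for patient data, so every stage is testable
end to end.

It is aimed at computational microbiome researchers who want the statistical
machinery of such studies — not the biology of one cohort — as a library.

## The model

**Features.** Counts are filtered to genera detected in ≥ 10% of samples and
mapped per sample to centered log-ratios,
`clr_j(x) = ln x_j − (1/D) Σ_k ln x_k` (pseudocount 1), then joined with age,
BMI, gender and country.

**Classifier.** Pluggable tree ensembles (XGBoost, random forest, LightGBM)
under stratified 5-fold cross-validation repeated 20 times; the 100 fitted
models are retained. CRC is the positive class; performance is accuracy,
AU-ROC (Mann–Whitney concordance) and AU-PRC (average precision). External
cohorts are predicted by majority vote and mean probability over all 100
models.

**Explanations.** The Shapley value of feature *j* for subject *x* is

φ_j(x) = Σ_{F ⊆ S∖{j}} |F|! (|S|−|F|−1)! / |S|! · [v(F ∪ {j}) − v(F)]

Each training subject is explained out-of-fold (by the model that never saw
it) and averaged over the 20 repeats. Three attribution routes are
implemented and cross-checked: a brute-force subset-enumeration oracle, an
exact interventional TreeSHAP for scikit-learn forests (closed-form per-leaf
conjunction games), and a double-precision path-dependent TreeSHAP for
XGBoost boosters whose local accuracy Σφ + E[f] = f(x) holds to ~1e−12.

**Stratification.** t-SNE embeds the subject × feature φ matrix in 2-D;
adenoma subjects are clustered on the two components (K-means, agglomerative,
BIRCH over k = 2..10, silhouette-selected); external adenoma subjects are
projected in by a KNN fitted on training φ vectors; clusters are profiled by
out-of-fold CRC probability and taxon distributions.

**Interaction networks.** Per CV fold, the SHAP interaction tensor Φ_ij of
the held-out subjects is computed (its signed rows sum to φ_i), absolute
values averaged over subjects and then over all 100 folds. Features with
≥ 10 interactions above the 95th percentile form a weighted network; hubs are
ranked by interaction count, weighted degree and betweenness (edge distance
1/weight). The analysis repeats within high-risk clusters. Networks export to
GEXF/GraphML for Gephi.

## Worked example

The numbered drivers under `analysis/` run the whole study on the synthetic
cohorts (a 453-subject training cohort with 189:264 CRC:adenoma design, 462
genera, five planted discriminative genera and one planted pairwise label
interaction; a 43-subject shifted external cohort):

```bash
python analysis/01_simulate.py --seed 0
python analysis/02_preprocess.py
python analysis/03_train_eval.py --seed 0
python analysis/04_explain.py
python analysis/05_stratify.py --seed 0
python analysis/06_interactions.py
```

With seed 0 this prints, among other things:

```
prevalence filter (10%): 462 -> 157 genera
feature matrix: 453 x 161 (157 CLR taxa + 4 covariates)

xgboost: 100 models (5-fold x 20 repeats)
           mean    std
accuracy  0.677  0.043
auroc     0.740  0.043
auprc     0.696  0.054

top-20 features carry 64.86% of cumulative SHAP importance
planted discriminative genera in top 10: 5/5 ['g005', 'g009', 'g014', 'g021', 'g030']
external top-20 share: 65.04%; rank overlap with training top-20: 19

best clustering: kmeans with k=4, silhouette 0.528
per-cluster CRC probability (ordered by median risk):
          n  median     q1     q3
cluster
4        46   0.452  0.280  0.754
...
```

Reading this: the 10% prevalence filter reduces 462 simulated genera to 157;
the cross-validated classifier separates adenoma from CRC at AU-ROC 0.74
under the planted effect sizes; all five planted genera surface in the top-10
SHAP ranking and the ranking transfers to the external cohort (19/20
overlap); K-means on the SHAP embedding isolates an adenoma subgroup
(cluster 4) whose median predicted CRC probability (0.45) is seven times that
of the lowest-risk cluster — the "transitional" subgroup the method is
designed to expose.

The same pipeline is scriptable as one seeded run:

```bash
crcstrat run-all --out results/run --seed 0
```

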