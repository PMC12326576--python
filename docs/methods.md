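# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `crcstrat`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic cohort generator

The generator emulates a pooled multi-country genus-level 16S case-control
study of adenoma vs CRC. It is the package's ground-truth source; every
downstream property test is phrased against quantities it plants.

**Counts.** Each sample draws a composition from a Dirichlet with per-class
concentration vectors, a sequencing depth from a lognormal, counts from a
multinomial at that depth, and an independent per-cell Bernoulli
zero-inflation mask. The Dirichlet-multinomial captures the two dominant
features of real 16S tables — overdispersion relative to multinomial
sampling and compositionality — without modelling phylogenetic correlation.

**Base composition.** Concentrations follow a power law
`α_j ∝ j^−1.2` scaled to total 40. This was calibrated once so that a
462-taxon cohort at the default depth (lognormal, ln-mean 9.2 ≈ 10⁴ reads,
ln-sd 0.4) with 10% zero-inflation retains roughly 160 genera under the 10%
prevalence filter — the pre/post-filter scale of the study population the
generator emulates (462 → 164). A steeper tail (exponent 1.5) was tried
first and retained only ~70 genera; the calibration is part of the fixed
study conditions, not a tunable.

**Class signal, two routes.**

* *Conditional route* (no interaction planted): labels are fixed by design
  (`n_cases`/`n_controls`, default 189/264) and cases draw from
  concentrations with each planted effect taxon multiplied by `2^log2FC`
  (defaults: five taxa at |log2FC| = 2, mixed signs — CRC-enriched and
  CRC-depleted genera).
* *Logistic route* (interaction planted): all samples draw from the base
  composition; labels are Bernoulli with logit
  `Σ_e fc_e·ln2·z_e + γ·z_i·z_j + c`, where `z` are the cohort-standardised
  latent log proportions (floored at 1e−290 before the log so tiny-α taxa
  stay finite), `γ` is the interaction coefficient, and the intercept `c` is
  solved (Brent) so the expected case fraction matches the design ratio.
  Because the interaction acts on the noise-free latent scale, the planted
  pair is an unambiguous ground truth for interaction-recovery experiments;
  label counts are then binomial around the design ratio rather than exact.

**Metadata.** Age and BMI are Gaussian per class, gender Bernoulli, country
multinomial, with defaults matching the pooled training population
(age ≈ 62.6/62.5 ± 12.6/10.7, BMI 28.2 ± 6.2 vs 26.5 ± 4.6, ~40% female,
CA/FRA/USA mix) and an external variant (older CRC arm, all-Italian). BMI
therefore genuinely associates with the label — a realistic competing signal
that explanation tests must tolerate.

**External cohorts** reuse the training truth with base concentrations
multiplied by `exp(shift)` per taxon (a geography/batch effect; default ln 2
on 50 non-effect taxa) and the design sizes 34 CRC / 9 adenoma.

**What the generator does not emulate:** phylogenetic or co-occurrence
correlation between taxa, taxonomy noise, depth-abundance confounding, and
real effect sizes (the study it emulates reports none). Passing recovery
tests therefore shows the pipeline detects planted signals of stated
strength under realistic sparsity/overdispersion — not that it would reach
any particular AU-ROC on real cohorts.

## Preprocessing

Prevalence filtering keeps taxa detected (count > 0) in at least 10% of
samples, boundary inclusive, before normalisation (the filter-then-transform
order matches the 462→164 bookkeeping). The centered log-ratio transform
uses pseudocount 1 by default (counts are integers; zero replacement is a
config choice, with ALR behind a flag). Gender is coded F=0/M=1 and country
as integer codes over the sorted category list by default — tree models
split integer-coded categories adequately — with one-hot available; the
external cohort is encoded against the union of category lists so feature
matrices align.

Cohort comparison tables use the exact two-sided Fisher test for categorical
covariates — 2×2 via the hypergeometric, r×c via full Freeman–Halton
enumeration over fixed-margin tables — under the probability-mass convention
(sum of probabilities of tables no more probable than the observed one);
other two-sided conventions can shift the second decimal. Continuous
covariates use the two-sided Mann–Whitney U test, exact when both groups
have ≤ 12 untied observations, tie-corrected normal approximation otherwise.
Enumeration refuses tables beyond ~5×10⁶ candidates.

## Classification protocol

Stratified 5-fold cross-validation, re-randomised each of 20 repeats, all
100 models retained. One master seed spawns fold and model seeds through
`numpy.random.SeedSequence`, so runs are bit-reproducible. Backends (XGBoost,
random forest, LightGBM) run their library's stock hyperparameters with one
thread; nothing is tuned, matching the protocol the package emulates.
AU-PRC is average precision (precision-weighted recall increments), not
trapezoidal interpolation, which is optimistic on sparse curves. Accuracy
thresholds probability at 0.5 with ≥ mapping to CRC. External ensembling:
majority vote over the registry, exact ties resolved toward CRC when the
mean probability is ≥ 0.5.

## Shapley machinery

Three independent routes, deliberately kept separate so each can check the
others:

1. **Exact oracle** — subset enumeration with the factorial weights, value
   function v(F) = mean over a background set of the prediction with
   features outside F replaced by the background row (interventional
   expectation). Capped at 15 features (2^|S| values); background 50 seeded
   training rows in pipeline use.
2. **Interventional TreeSHAP (scikit-learn forests)** — for each leaf and
   background row, the coalition game is a conjunction `U ⊆ S, S ∩ V = ∅`
   whose Shapley value is closed-form (`+c(k−1)!m!/(k+m)!` on U,
   `−c·k!(m−1)!/(k+m)!` on V); exact to machine precision and verified
   against route 1.
3. **Path-dependent TreeSHAP (XGBoost)** — the booster's cover-weighted
   descent value function factorises per leaf as a multilinear game
   `v_L(S) = c·Π_f (a_f if f∈S else b_f)`; φ is assembled from the
   elementary-symmetric-polynomial coefficients of `Π(b_f + a_f z)`.
   Computed in float64 from the full-precision JSON model (the text dump
   rounds thresholds), with path conditions evaluated in float32 because the
   booster compares features at that precision. It reproduces the booster's
   own `pred_contribs` to float32 rounding (~2e−6) while local accuracy
   holds to ~1e−12, which is what lets the pipeline assert the efficiency
   axiom at 1e−6 on every emitted explanation. LightGBM's `pred_contrib` is
   already float64 and is used as-is.

Training-set explanations are out-of-fold (each subject explained only by
the model that held it out, averaged over the 20 repeats; refit-on-all is a
flag); external explanations are the mean over all 100 models, mirroring
mean-probability ensembling. Global importance is mean |φ| with ties broken
by feature name; cumulative top-k shares are reported on [0, 1].

## Stratification

t-SNE (perplexity 30, 1000 iterations, PCA initialisation, fixed seed; exact
method below 50 subjects, Barnes-Hut above) embeds all subjects' φ vectors.
Clustering runs on the two embedding coordinates, restricted to adenoma
subjects: K-means (10 restarts), agglomerative (Ward) and BIRCH over
k = 2..10, scored by Euclidean silhouette; the full method × k grid is
returned so the argmax can be audited, invalid cells (empty clusters)
recorded as missing. Ties resolve to the first method in the list, then the
smaller k. Labels are renumbered 1..k in order of first appearance for
determinism.

External adenoma subjects get coordinates as the unweighted mean of their 5
nearest training subjects in full φ-space (not embedding space — the KNN
learns the φ → t-SNE map) and a cluster from the nearest selected-cluster
centroid in embedding space. Box statistics use the 1.5×IQR whisker rule
with quartiles from linear-interpolation percentiles.

## Interaction networks

Per fold, the signed feature×feature interaction tensor of the held-out
subjects is computed (XGBoost `pred_interactions`; the row-sum identity
Σ_j Φ_ij = φ_i is asserted at 1e−5 against the booster's native
contributions, which share its float32 arithmetic). Absolute values are
taken per subject *before* averaging — a signed mean lets opposite-sign
interactions cancel; the signed-then-absolute variant sits behind a flag.
Fold matrices are averaged element-wise over all 100 folds. Diagonals (main
effects) are excluded from both the percentile distribution and the counts:
they dominate the magnitude scale and the analysis targets pairs.

The significance threshold is the 95th percentile (linear-interpolation
definition) of the upper-triangle off-diagonal distribution, strict
inequality; features keep ≥ 10 significant partners. The retained-count grid
over the 90/95/99 percentiles is always computed for auditing. Betweenness
uses edge distance 1/weight (stronger interactions are "closer") with
standard (n−1)(n−2)/2 normalisation; "interaction count" is the unweighted
degree and "degree" in exported colourings the weighted degree. Subgroup
networks restrict each fold's averaging to the cluster members it held out,
skipping folds that held out none; subgroups under 5 subjects compute with a
warning.

## Problem sizes in the test suite

CI runs scale the protocol down, as the package's own choice of test size:
most model-based tests use 200-subject cohorts with 30–40 taxa and 1–2 CV
repeats; parameter-recovery acceptance tests use n = 450 with 30–100 taxa
and 10 fixed seeds. The interaction-recovery test is the one place the full
20-repeat aggregation protocol is kept, because averaging interaction
matrices over all 100 folds is integral to that method's power. The
acceptance script runs the full study scale (453 × 462, 100 models).

## Known limitations

* Interaction tensors require a backend exposing them; only the XGBoost
  backend does. Random-forest explanations go through the interventional
  TreeSHAP and are exact but slower (they scale with background size and
  leaf count), so the boosting backend is the pipeline default.
* Recovery of a planted interaction is power-limited: a latent product term
  on taxa whose counts are mostly zero cannot be expressed in CLR features,
  and strong main-effect/covariate hubs compete for top edge ranks. The
  acceptance experiment plants the pair on high-prevalence taxa for that
  reason.
* Freeman–Halton enumeration is exponential in table size; large sparse
  tables need a Monte-Carlo variant that is out of scope.
* t-SNE coordinates are seed-dependent; all claims about embeddings are made
  through statistics (silhouette, ARI, cluster risk ordering), never through
  coordinates themselves.
* BIOM input and CatBoost-style ordered boosting are not provided; the
  abundance interface is TSV/CSV and the third backend is LightGBM.
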