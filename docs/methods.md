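# Methods

`neodx` implements the statistical workflow used to mine a 57-analyte
dried-blood-spot (DBS) newborn-screening panel for diagnostic markers of
hypoxic–ischemic encephalopathy (HIE): univariate screening, differential
correlation networks, pathway over-representation, OPLS-DA
classification, and a stepwise logistic diagnostic model, together with a
synthetic cohort generator that supplies data with the structure these
stages assume.

## The panel

The measured variables are the 57 channels of a non-derivatized MSMS
newborn-screening assay: 14 amino acids, 36 acylcarnitines, 2
nucleosides, succinylacetone and 4 lysophosphatidylcholines, in µmol/L.
Several channels are isobaric composites ("Gln/Lys", "C3DC/C4OH",
"Leu/Ile/Hyp"); each such code carries a list of identification
variants. Composite codes are treated as single measured variables by
every statistical stage; the variants matter only for pathway analysis.
The default panel hard-codes every analyte with a published identity;
slots without one are filled with conventional screening codes (C0, C10,
C12, the C16/C18 hydroxy series, Pro, adenosine, ...) flagged
`placeholder=True`, and the whole catalogue can be replaced from a file.

## Synthetic cohorts

The generator draws `x = exp(log median + log fold + L z ∘ sd)` with `z`
standard normal and `L` the Cholesky factor of a block correlation
matrix, i.e. log-normal marginals with multiplicative group effects.
Rationale: concentrations are positive and right-skewed, and the
screening stages are rank-based, so only the monotone structure is
identified anyway. Defaults:

* baseline medians — typical DBS screening levels (amino acids
  tens–hundreds µmol/L, long-chain acylcarnitines ≪ 1 µmol/L);
* log-scale SD 0.3 for every analyte;
* within-class correlation blocks (amino acids, acylcarnitines, LPCs) at
  ρ = 0.4, giving the network stage non-trivial structure;
* effect sizes: the source designs report directions and significance
  but not magnitudes, so fold-changes are stand-ins chosen once —
  glycine 1.5× at 3 h and 2.0× at 6 h, methionine 0.7× at 6 h,
  listed acylcarnitines 1.4–1.5×, and analogous values for the
  inflammation and hypothermia designs.

Shipped scenarios mirror the three animal designs (group sizes 10/13/12,
11/11/27, 13/16/14), a pooled 23-vs-26 validation design, and a null
scenario. The inflammation scenario additionally rewires two
correlation blocks between its arms (an amino-acid block tight under
inflammation alone, a short-chain acylcarnitine block tight when
hypoxia–ischemia is superimposed) so differential-network recovery can
be exercised end to end.

What the generator does **not** emulate: instrument noise, batch and
plate effects, censoring at the limit of detection, heavy-tailed
outliers, and any mechanistic kinetics. Passing tests therefore show
that the pipeline recovers planted monotone effects and correlation
rewiring at the study's sample sizes — not that it is robust to assay
artefacts.

## Univariate screening

Two-sided Mann–Whitney per analyte (exact null distribution when
min(n, m) ≤ 8 without ties, tie-corrected normal approximation with
continuity correction otherwise), Benjamini–Hochberg adjustment across
the 57 analytes *within* each pairwise comparison. Two marker lists are
reported: the FDR-surviving set (q < 0.05) and the raw p < 0.05 set used
for PCA variable selection. Time association is Spearman's rho against
hours post-insult with average-rank ties. PCA standardizes columns
(unit variance) and uses the SVD; zero-variance analytes are dropped
with a warning rather than an error.

## Network rewiring

Per arm, adjacency `a_ij = |Spearman rho_ij|`; change matrix
`c_ij = |a_ij(1) − a_ij(2)|`; dissimilarity `d_ij = 1 − c_ij/max(C)` so
that strongly co-rewired pairs cluster together (the inverse convention,
`d = c`, is available behind a flag). Ward linkage on the condensed
dissimilarity (the Lance–Williams Ward.D2 update, via scipy); the
dendrogram is cut at each candidate k and the mean silhouette width,
with D as a precomputed distance, selects k. Identical correlation
structure in both arms (max C = 0) is reported as "no rewiring" instead
of an arbitrary clustering. With arms of only ~11 samples the rank
correlations are noisy; planted two-block structure is recovered
essentially always at n = 60/arm, while at the smallest study arms the
k = 2 cut still tracks the planted blocks (adjusted Rand ≈ 0.7) even
when the silhouette picks a finer k.

## Pathway over-representation

Marker lists containing composite codes are expanded by Cartesian
product over identification variants — one marker set per combination.
Each set is scored against each pathway by the hypergeometric upper tail
P(X ≥ hits) with population = universe, successes = pathway, draws =
markers ∩ universe; the enrichment ratio is hits/expected. A pathway is
consensus-significant when p < 0.1 for *every* expanded set; p and
enrichment are averaged and the hit count summarised by its median. No
multiplicity correction is applied across pathways, mirroring the
procedure the pipeline reproduces. The universe defaults to the panel's
variant names intersected with the library (overridable to the full
library universe). A consequence worth knowing: enlarging the universe
with non-members makes a fixed overlap *more* surprising (p decreases).
Pathway content is consumed as GMT files; the packaged
`pathways_synthetic.gmt` is a small synthetic stand-in library built
from the panel's own compound names for tests, examples and pipeline
smoke runs — it is not SMPDB or KEGG content.

## OPLS-DA

Authored from scratch (NIPALS-style O-PLS): X autoscaled to unit
variance (sd with ddof = 1), y centred; each orthogonal component
removes from the loading the part collinear with the predictive weight
(`w_o ∝ p − (w'p)w`), deflating X; one predictive PLS component is then
fitted on the filtered X. With n_ortho = 0 the model reproduces
single-component PLS1 exactly (tested against scikit-learn to 1e-8).
Statistics: R2X = explained fraction of autoscaled-X sum of squares over
predictive + orthogonal components; R2Y = described fraction of centred
y; Q2 = 1 − PRESS/SS under leave-one-out refits (rescaling inside every
fold). "Described" and "predicted" Y map to R2Y and Q2 respectively.

VIP uses normalised component weights, so mean(VIP²) = 1 holds exactly
for any weighting. The default (`vip`) credits orthogonal components
through their explained X-variance (averaged X/Y-variance weighting, in
the spirit of the "total" VIP variants for O-PLS); `vip_pred` is the
classical y-variance-weighted VIP, which for a single predictive
component ignores the orthogonal space. Both are reported.

Classification: LOO cv-scores feed the ROC (threshold sweep over unique
scores, trapezoidal AUC — identical to the Mann–Whitney U identity) and
the cutoff is the Youden-J maximiser over observed scores, taking the
lowest score among ties (favouring sensitivity, the usual screening
preference). The component counts default to 2 (3 h-style models) and
4 (6 h-style models) and are constructor parameters.

## Stepwise logistic diagnostic model

Feature expansion: bases ∪ squares ∪ pairwise products — 1710 features
for 57 analytes, in deterministic order. All model fitting runs on
column-standardized features; the scaler travels with the model.

Builder stages:

1. **VIP prefilter** — OPLS-DA (default 2 orthogonal components) on the
   expanded matrix; keep VIP > 1. Because mean(VIP²) = 1, this always
   removes a substantial fraction of candidates.
2. **Forward AIC** — from the intercept-only model, add the
   AIC-minimising feature while AIC decreases. Candidate scans are run
   as a batched IRLS over all candidates (a tiny ridge keeps the batched
   normal equations solvable); the accepted feature is refit exactly.
   A cap of n/5 selected features guards against runaway paths on
   near-separable cohorts.
3. **Backward Wald elimination** — drop the largest-p coefficient and
   refit until every retained coefficient has p < 0.05 (intercept
   exempt). If everything is eliminated an intercept-only model is
   returned with a warning.

Logistic fits use iteratively reweighted least squares (iteration cap
50, tolerance 1e-8). Quasi-separation policy: a fit is flagged when any
fitted probability sits within 1e-4 of 0/1 (the classical glm
"fitted probabilities numerically 0 or 1" diagnostic) or any
standardized slope exceeds 10; flagged fits are re-estimated with a unit
L2 penalty on the slopes (roughly a unit-information prior on the
standardized scale) and the flag is recorded. Without this, the
Hauck–Donner collapse of Wald statistics near separation makes the
elimination stage discard exactly the strongest markers. Wald tests are
the default "zero coefficient" criterion, as in the workflow being
reproduced; note that forward AIC over hundreds of candidates retains
noise terms under the null (maximal selection) — it is the elimination
stage that keeps the final null-model size at a median of ≤ 1 feature.

Model quality: leave-one-out CV with the *entire* builder re-run inside
each fold (prefilter, selection, elimination — no information from the
held-out sample), pooled out-of-fold probabilities for ROC, Youden
cutoff and sensitivity/specificity.

## Split validation

100 stratified 70/30 train/test splits of the pooled 6 h design (23
controls vs 26 cases); per split both model families are rebuilt on the
training part. Cutoffs are placed by Youden's J on training
leave-one-out scores — full refits for OPLS, fixed-feature coefficient
refits for the logistic model (re-running the whole builder inside every
split-LOO fold would cost ~10⁴ builder fits for no change in the
leakage guarantee; the test split is never touched either way).
Degenerate splits are redrawn and counted. A single seeded generator
drives all splits; identical seed ⇒ identical report.

## Determinism and problem sizes

Every stochastic step (cohort generation, splits) consumes an explicit
seed; the pipeline writes byte-identical outputs for identical
config + seed. Default problem sizes follow the study designs
(n = 10–27 per arm); the test suite exercises the stochastic recovery
claims at 20–100 seeds and the full pipeline run completes in well under
a minute on one CPU.

## Known limitations

* The default panel's placeholder identities and the packaged pathway
  library are synthetic stand-ins; analyses of real screening exports
  should supply the actual panel catalogue and SMPDB/KEGG-derived GMT
  files.
* The cutoff-selection rule (Youden's J on CV scores) is the package's
  choice; reported cutoffs shift with it.
* OPLS-DA is binary-class only, with unit-variance scaling (Pareto not
  implemented); no permutation-based choice of component counts.
* The logistic builder's ridge fallback biases coefficients of flagged
  fits toward zero by construction; flagged models should be read as
  "direction and ranking reliable, effect size shrunken".
* No handling of missing values or values below the limit of detection;
  tables must be complete and nonnegative.
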