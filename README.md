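# neodx

Statistical pipeline for mining dried-blood-spot (DBS) newborn-screening
metabolite panels for disease markers — built around the use case of
diagnosing hypoxic–ischemic encephalopathy (HIE) from the 57 analytes
(amino acids, acylcarnitines, nucleosides, succinylacetone,
lysophosphatidylcholines) quantified by routine MSMS screening kits.
It is aimed at metabolomics analysts who have a samples × analytes
concentration table with group labels and want the full screening
workflow as reproducible, tested Python.

The pipeline chains five analyses:

1. **Univariate screen** — two-sided Mann–Whitney per analyte,
   Benjamini–Hochberg FDR across the panel, Spearman ρ against time
   post-insult, PCA on the significant analytes.
2. **Correlation-network rewiring** — per-group adjacencies
   `a_ij = |ρ_ij|`, change matrix `c_ij = |a_ij^{(1)} − a_ij^{(2)}|`,
   Ward clustering of `d_ij = 1 − c_ij/max(C)` with the cluster count
   chosen by maximum mean silhouette.
3. **Pathway over-representation** — hypergeometric upper tail
   `P(X ≥ hits)` against GMT compound sets, with ambiguous assay codes
   ("Gln/Lys") expanded into one marker set per identification variant
   and a consensus rule (`p < 0.1` in *every* set).
4. **OPLS-DA** — one predictive + `n_ortho` orthogonal components,
   R²X / R²Y / Q² (leave-one-out), VIP with `mean(VIP²) = 1`, ROC and
   Youden-J cutoff on cross-validated scores.
5. **Stepwise logistic diagnostic model** — features
   `{x_i} ∪ {x_i²} ∪ {x_i·x_j}`, OPLS-VIP > 1 prefilter, forward
   selection by AIC, backward Wald-p elimination (`p < 0.05`), all
   re-run inside every leave-one-out fold; plus 100× stratified 70/30
   split validation.

A synthetic cohort generator (log-normal marginals, multiplicative
group effects, block correlations, scenario library mirroring
three-arm HIE/inflammation/hypothermia designs) makes every stage
runnable and testable without any measured data.

## Worked example

```python
import neodx

table = neodx.scenario_library()["hie_timecourse"].generate(seed=1)

res3 = neodx.compare_groups(table, "control", "hie_3h")
print(res3.significant)          # ['Gly']
print(round(res3.q("Gly"), 4))   # 0.0261

sub = table.select_groups("control", "hie_3h")
y = table.binary_labels("control", "hie_3h")
model = neodx.fit_opls(sub.X, y, n_ortho=2)
q2, cv, _ = neodx.loo_cv_opls(sub.X, y, n_ortho=2)
print(f"R2X={model.R2X:.2f} R2Y={model.R2Y:.2f} Q2={q2:.2f}")
# R2X=0.47 R2Y=0.94 Q2=0.67
```

Only glycine survives FDR correction three hours after the insult
(q = 0.026 here), and the OPLS-DA model describes 47 % of the metabolite
variation (R²X), 94 % of the class variation (R²Y) and predicts 67 % of
it under leave-one-out CV (Q²). Building the stepwise logistic model on
the same cohort at 6 h,

```python
feats = neodx.expand_features(table.select_groups("control", "hie_6h"))
m = neodx.loo_cv_logit(feats, table.binary_labels("control", "hie_6h"))
print(m.features, round(m.roc_curve.auc, 2))   # ['Gly*C4'] 0.91
```

the builder reduces 1710 candidate features to a single glycine-derived
term with cross-validated AUC 0.91 — the glycine-carries-the-signal
pattern the pipeline is designed to surface.

The `examples/` directory holds one short script per capability
(cohort simulation, univariate screen, network rewiring, enrichment,
OPLS-DA, logistic builder, split validation, full pipeline); each
prints the numbers it computes with a note on what they mean. A thin
CLI covers the same ground from a shell:

```bash
neodx simulate --scenario hie_timecourse --seed 1 -o table.csv
neodx opls --table table.csv --comparison control:hie_3h --n-ortho 2
neodx run --config cfg.yaml --seed 1 --out-dir results/
```

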