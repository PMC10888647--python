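"""OPLS-DA classification of hypoxia–ischemia vs control.

One predictive component plus n_ortho orthogonal (class-unrelated)
components; R2X/R2Y describe the fit, Q2 the leave-one-out predictive
power, VIP the per-analyte importance (mean VIP² = 1).
"""

import numpy as np

import neodx

table = neodx.scenario_library()["hie_timecourse"].generate(seed=1)
sub = table.select_groups("control", "hie_3h")
y = table.binary_labels("control", "hie_3h")

model = neodx.fit_opls(sub.X, y, n_ortho=2,
                       feature_names=table.panel.codes)
print(f"R2X = {model.R2X:.2f}  R2Y = {model.R2Y:.2f}")

q2, cv_scores, _ = neodx.loo_cv_opls(sub.X, y, n_ortho=2)
print(f"Q2 (LOO) = {q2:.2f}")

cutoff = neodx.youden_cutoff(cv_scores, y)
sens, spec = neodx.classify_at_cutoff(cv_scores, y, cutoff)
curve = neodx.roc(cv_scores, y)
print(f"cutoff = {cutoff:.2f}  sensitivity = {sens:.0%}  "
      f"specificity = {spec:.0%}  AUC = {curve.auc:.2f}")

top = np.argsort(model.vip)[::-1][:5]
print("top VIP analytes:",
      [(table.panel.codes[i], round(float(model.vip[i]), 2))
       for i in top])
# VIP > 1 flags the analytes that drive the class separation; glycine
# should lead on this scenario.
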