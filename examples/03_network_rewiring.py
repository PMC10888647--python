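"""Differential correlation-network clustering between two arms.

The change matrix |a_ij(arm1) − a_ij(arm2)| of absolute Spearman
adjacencies captures which analyte pairs are rewired; Ward clustering
on 1 − C/max(C) groups co-rewired compounds, with the cluster count
picked by the maximum mean silhouette.
"""

import neodx

table = neodx.scenario_library()["lps_vs_lps_hie"].generate(seed=1)

change = neodx.adjacency_change(table, "lps", "lps_hie")
print("analytes clustered:", len(change.analytes),
      "(excluded:", change.excluded, ")")
print("max adjacency change:", round(change.C.max(), 2))

clusters = neodx.ward_silhouette(change, range(2, 8))
print("chosen k:", clusters.k,
      " mean silhouette:", round(clusters.mean_silhouette, 3))
for label in sorted(set(clusters.labels))[:3]:
    members = clusters.members(label)
    print(f"  cluster {label}: {len(members)} compounds, e.g.",
          members[:5])
# The scenario plants an amino-acid block that is tightly coupled under
# inflammation alone and a short-chain acylcarnitine block coupled only
# when hypoxia–ischemia is superimposed; those pairs carry the largest
# change entries.
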