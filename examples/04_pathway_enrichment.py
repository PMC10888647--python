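"""Ambiguity-aware pathway over-representation.

Combined assay codes ("Gln/Lys") are expanded into one marker set per
identification variant; a pathway is consensus-significant only if the
hypergeometric p stays below alpha for every expanded set.
"""

import neodx

table = neodx.scenario_library()["hie_timecourse"].generate(seed=1)
res6 = neodx.compare_groups(table, "control", "hie_6h")
print("6 h marker list:", res6.significant)

family = neodx.expand_markers(res6.significant, table.panel)
print("identification-variant sets:", len(family))
# each ambiguous code multiplies the number of sets (2 per two-variant
# code, 3 per three-variant code, ...)

gmt = neodx.read_gmt(neodx.default_gmt_path(), library="synthetic")
universe = table.panel.all_variants() & gmt.universe
enr = neodx.consensus_enrich(family, gmt, alpha=0.1, universe=universe)
cols = ["pathway", "mean_p", "mean_enrichment", "median_hits",
        "consensus_significant"]
print(enr.table[cols].round(3).to_string(index=False))
# mean_p / mean_enrichment are averaged over the variant sets;
# median_hits is the median marker count falling in the pathway.
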