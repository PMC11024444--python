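"""Compare the 19 metrics across phenotypes at baseline and over recovery.

Simulates a cohort, runs Kruskal–Wallis tests (Holm-adjusted across the 19
metrics) on the baseline panels and on the within-patient follow-up-minus-
baseline changes, and prints the resulting test tables.
"""

from tlbkit import (delta_metrics, kruskal_wallis_panel, results_to_frame,
                    simulate_cohort)

ds = simulate_cohort(seed=1)
ds.compute_panels()
m = ds.manifest

t0 = m.loc[m["timepoint"] == "T0"]
table_t0 = results_to_frame(
    kruskal_wallis_panel(ds.panels.loc[t0["sample_id"]], t0["phenotype"]))
print("baseline (T0) group comparison, Holm-adjusted:")
print(table_t0.round(4).to_string())

tfu = m.loc[m["timepoint"] == "Tfu"]
delta = delta_metrics(ds.panels.loc[t0["sample_id"]],
                      ds.panels.loc[tfu["sample_id"]],
                      t0["patient_id"], tfu["patient_id"])
pheno = t0.set_index("patient_id")["phenotype"].loc[delta.index]
table_d = results_to_frame(kruskal_wallis_panel(delta, pheno))
print("\nwithin-patient change (Tfu - T0):")
print(table_d.round(4).to_string())
print("\nmedian TMI recovery: dPeak1 = "
      f"{delta.loc[pheno == 'TMI', 'Peak1'].median():+.4f}, dPeak3 = "
      f"{delta.loc[pheno == 'TMI', 'Peak3'].median():+.4f}")
# Small adjusted p-values at T0 mean the metric's distribution differs
# between at least two phenotypes at presentation; the positive dPeak1 /
# negative dPeak3 medians are the recovery of the dominant-Peak-1 signature.
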