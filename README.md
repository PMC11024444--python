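# tlbkit

Analysis toolkit for **thermal liquid biopsy (TLB)** — plasma thermograms
measured by differential scanning calorimetry (DSC) — aimed at
characterizing acute myocardial-injury phenotypes: acute thrombotic
myocardial infarction (TMI), acute non-thrombotic myocardial injury (nTMi)
and chronic coronary atherosclerotic disease (cCAD), sampled along an acute
time course (T0, T2, T4, T24, T48) and a stable follow-up (Tfu).

A plasma thermogram is the excess specific heat capacity
Cp<sup>ex</sup>(T) in cal/(°C·g) of a patient's plasma proteome as it
denatures between 45 and 90 °C. The package provides:

* **Preprocessing** (`tlbkit.io`): buffer-reference subtraction,
  concentration normalization (signal / (scan rate × concentration × cell
  volume)), linear sample-baseline removal anchored on the 45–50 / 85–90 °C
  flanks, interpolation onto the standard 45.0–90.0 °C, 0.1 °C grid
  (451 points), and replicate averaging.
* **The 19-metric panel** (`tlbkit.metrics`): peak amplitudes and
  temperatures in the three canonical transition windows — Peak 1
  (60–66 °C), Peak 2 (67–73 °C), Peak 3 (73–81 °C) — the inter-peak valley
  V1.2, six amplitude ratios, the global maximum, the first-moment
  temperature T_FM = Σ T·Cp(T) / Σ Cp(T), the width at half height and the
  integrated area.
* **Statistics** (`tlbkit.stats`): Kruskal–Wallis tests per metric across
  phenotype groups with Holm (or Bonferroni/BH) adjustment across the
  19-metric family; pairwise Wilcoxon rank-sum (exact where feasible) and
  signed-rank tests; within-patient ΔTfu − T0 change panels; pointwise
  median / 95 % quantile-interval profile bands and per-phenotype mean
  difference curves.
* **Clustering** (`tlbkit.clustering`): k-means on whole 451-point profiles
  (Euclidean, no standardization), WSS/silhouette model selection, and
  phenotype-purity contingency tables.
* **Synthetic cohorts** (`tlbkit.synthetic`): a generator of
  phenotype-structured longitudinal cohorts (Gaussian-mixture transitions,
  monotone recovery toward the shared quiescent signature, per-patient
  random effects), since the original patient data are not publicly
  available.
* **Pipeline + CLI** (`tlbkit.pipeline`, `tlbkit` command): one-config
  end-to-end runs with a troponin-based censoring rule, cohort summary
  tables, and deterministic CSV/JSON outputs.

## Worked example

```python
from tlbkit import kmeans_profiles, purity_table, simulate_cohort

ds = simulate_cohort(seed=0)                    # 35 cCAD / 60 TMI / 20 nTMi, 6 timepoints
t0 = ds.manifest.loc[ds.manifest["timepoint"] == "T0"]
result = kmeans_profiles(ds.curves(t0["sample_id"]), k=3, seed=0, restarts=50,
                         sample_ids=list(t0["sample_id"]))
print(purity_table(result, dict(zip(t0["sample_id"], t0["phenotype"]))).formatted())
```

prints

```
                     1           2           3
phenotype
cCAD          0 (0.0%)  35 (63.6%)    0 (0.0%)
TMI        57 (100.0%)    0 (0.0%)  3 (100.0%)
nTMi          0 (0.0%)  20 (36.4%)    0 (0.0%)
```

Each column is one cluster of baseline profiles; cells are sample counts
with the share of the cluster they represent. The small third cluster
collects exactly the TMI patients carrying the distinctive 80 °C-peak
subtype and contains no cCAD samples — an acute-thrombotic signature that
unsupervised clustering finds without seeing any clinical labels. (For this
seed the binomial subtype draw assigned 3 of the 60 TMI patients the
subtype.)

The `examples/` directory contains one short script per capability
(preprocessing, metric extraction, group statistics, simulation +
clustering); each builds its own input and prints annotated output.

The `tlbkit` command exposes the same stages from a shell:

```sh
tlbkit simulate --seed 0 -o cohort/
tlbkit metrics cohort/thermograms/*.csv -o panels.csv
tlbkit stats panels.csv cohort/manifest.csv --family T0 -o stats_t0.csv
tlbkit cluster cohort/thermograms cohort/manifest.csv --k 3 -o clusters/
tlbkit run --config run.yaml        # full pipeline under one config
```

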