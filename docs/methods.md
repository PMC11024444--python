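# Methods

This note documents the models, conventions and numerical choices behind
tlbkit, and what the synthetic-data tests do and do not demonstrate.

## Thermogram preprocessing

A raw DSC scan is a power-like heat signal sampled over a strictly
increasing temperature sweep (nominally 20–110 °C at 1 °C/min). The
correction chain is:

1. **Buffer subtraction.** The buffer reference scan is linearly
   interpolated onto the sample's temperatures and subtracted pointwise.
   The buffer must cover the sample's portion of the 45–90 °C analysis
   range; the output is restricted to the covered temperatures. No
   automatic buffer-quality screening is performed — judging whether a
   buffer scan is "suitable" remains the operator's call.
2. **Concentration normalization.** The signal is divided by
   `scan_rate × protein_conc × cell_volume` (defaults 1 °C/min, assay
   value, 0.3 ml), converting it to heat capacity per gram of protein.
   Whether to normalize by concentration alone or by total protein mass in
   the sensing volume is exposed through `cell_volume` (set it to 1.0 for
   concentration-only normalization); the default includes the cell volume,
   the standard excess-heat-capacity conversion.
3. **Linear baseline removal.** A straight line through the
   (mean T, mean signal) points of two anchor windows is subtracted. The
   default anchors, 45–50 °C and 85–90 °C, are the flat flanks outside all
   three transition windows; both are configurable. By construction the
   post-correction mean within each anchor window is exactly zero (the mean
   of a line over a window equals the line at the window's mean
   temperature). Windows with fewer than three points are rejected.
4. **Regridding.** Linear interpolation onto the fixed 451-point grid
   45.0, 45.1, …, 90.0 °C. Linear interpolation is used everywhere: at
   0.1 °C sampling the difference from higher-order schemes is immaterial
   against instrument noise. The grid values are rounded to one decimal so
   comparisons against window edges are exact.
5. **Replicate averaging.** Duplicates are combined by pointwise mean; the
   maximum pointwise spread between replicates is recorded in provenance
   but not thresholded — duplicates establish reproducibility, they are not
   screened out.

Negative Cp<sup>ex</sup> values that survive baseline correction are
retained, not clipped.

## The 19-metric panel

Peak windows are **half-open** — [60, 66), [67, 73), [73, 81) — so the
73 °C edge shared by the Peak 2 and Peak 3 ranges belongs to exactly one
window (Peak 3's). The 66–67 °C gap belongs to no window. A window "peak"
is simply the maximum gridded amplitude in the window and its temperature;
extrema ties break toward the lowest temperature so plateaus are handled
deterministically. The valley V1.2 is the minimum strictly between the
detected Peak 1 and Peak 2 temperatures. Consequences worth knowing:

* a profile monotone across a window reports the window's edge supremum,
  not a true local maximum;
* T_Peak values are grid-quantized to 0.1 °C.

Global metrics: Max/T_Max over the full grid; T_FM is the discrete first
moment Σ T·Cp / Σ Cp over the grid (flagged NaN with a warning if the total
signal is non-positive); Area is the trapezoidal integral over 45–90 °C;
Width is the span between the outermost half-of-global-maximum crossings
(first upward before T_Max, last downward after), each located by linear
interpolation between bracketing grid points, truncated at a grid boundary
with a warning if the profile never drops below half height on that side.
Ratios with a zero denominator are NaN (flagged), never ±inf. Whether Max
is constrained to the peak-window union or taken globally is configurable
in spirit — the implementation takes the global maximum, which matches the
panel's graphical definition.

Oracle tests compare every metric against a brute-force evaluation of the
analytic Gaussian mixture on a 0.001 °C grid; temperatures agree to
±0.06 °C (grid quantization plus interpolation), amplitudes to 1 %, area to
0.5 %.

## Synthetic cohorts

Each phenotype template is a pair of three-component Gaussian mixtures
(acute, quiescent) plus a monotone recovery fraction λ(t) with λ(T0) = 0
and λ(Tfu) = 1; the mean curve at a timepoint is
(1 − λ)·acute + λ·quiescent. Gaussian components were chosen over two-state
van't Hoff transitions because the analysis consumes only curve shape and
Gaussians give closed-form oracles for every metric. Default amplitudes
(cal/(°C·g)) and centers:

| template | component 1 | component 2 | component 3 |
|---|---|---|---|
| quiescent (shared) | 63.0 °C, σ1.8, 0.150 | 70.0 °C, σ2.0, 0.095 | 77.0 °C, σ2.2, 0.040 |
| cCAD acute | 63.0, 1.8, 0.135 | 70.0, 2.0, 0.097 | 77.0, 2.2, 0.042 |
| TMI acute | 63.0, 1.8, 0.085 | 70.0, 2.0, 0.090 | 77.0, 2.2, 0.075 |
| nTMi acute | 63.0, 1.8, 0.095 | 70.5, 2.0, 0.105 | 76.0, 1.1, 0.055 |
| TMI 80 °C subtype | 63.0, 1.8, 0.045 | 70.0, 2.0, 0.040 | 80.0, 1.4, 0.165 |

These constants are implementation defaults tuned to reproduce the
qualitative phenotype orderings (dominant Peak 1 in the quiescent state,
diminished Peak 1 in both acute groups, highest Peak 3 in TMI, an elevated
68–75 °C region in nTMi, a dominant well-defined 80 °C peak in the
subtype) — they are **not** estimates from patient data, and no claim is
made that effect sizes match the study's biology. Recovery schedules are
monotone with nTMi faster than TMI (e.g. λ(T24) = 0.50 vs 0.35) and cCAD
nearly stable; the TMI 80 °C subtype is assigned per TMI patient with
probability 7/60.

Noise: per patient, one multiplicative amplitude factor
exp(N(0, cv²)) with cv = 0.08 and one temperature jitter N(0, 0.25 °C),
both shared across that patient's timepoints (patients are their own
controls); per scan, i.i.d. pointwise noise N(0, 0.003 cal/(°C·g)). The
amplitude cv emulates residual concentration error, the jitter small
calibration drift, the pointwise term instrument noise at a plausible
signal-to-noise for ~0.15-amplitude profiles.

**What passing tests show — and don't.** The generator produces smooth
three-transition curves with clean group structure; real plasma thermograms
carry correlated baseline wander, asymmetric transitions, overlapping
subpopulations and far more biological overlap between groups. Synthetic
group separations are therefore much cleaner than the published ones (the
default cohort clusters TMI apart from cCAD/nTMi almost perfectly, where
the study reports substantially mixed clusters, and the silhouette-maximal
k on the default cohort can exceed 3). Passing the recovery tests shows the
machinery is correct, not that real cohorts would separate this well.

## Statistics

* Kruskal–Wallis per metric (scipy, tie-corrected H, χ² reference with
  groups − 1 df); a metric constant across all samples gets p = 1 with a
  warning.
* Family-wise adjustment across the 19 metrics, one family per contrast
  (T0, Tfu, ΔTfu − T0). Holm step-down is the default: it is consistent
  with a published adjusted-p pattern whose per-metric inflation factors
  vary, which a constant Bonferroni multiplier cannot produce. Bonferroni
  and Benjamini–Hochberg are selectable.
* Pairwise two-group comparisons between independent phenotype groups use
  the Wilcoxon **rank-sum** form (exact null distribution when both sizes
  ≤ 25 without ties, otherwise normal approximation with tie and
  continuity correction). The signed-rank form is applied only to genuinely
  paired (within-patient) data, where all-zero differences return p = 1
  with a warning. Both forms are exposed because the field's terminology
  frequently conflates them.
* ΔTfu − T0 panels are computed per patient on the intersection of patients
  present at both timepoints; unpaired patients are dropped and logged.
* Profile bands use pointwise median and 2.5/97.5 % quantiles with the
  linear-interpolation quantile convention; significance statements use
  α = 0.05 throughout.

## Clustering

Raw Cp<sup>ex</sup> vectors at the 451 grid points, Euclidean distance, no
per-feature standardization (the features share one physical unit, and
standardizing would erase peak-amplitude information). Lloyd's algorithm
with k-means++ initialization, best of 50 restarts by WSS, fixed seed;
scikit-learn's implementation relocates clusters that empty during
iteration. Output clusters are relabeled in decreasing-size order so
reports are deterministic. Model selection reports WSS and mean silhouette
per k over a configurable range (default 2–8) and flags the
silhouette-maximizing k. Purity percentages are column shares rounded
half-away-from-zero to one decimal, matching the published table's
formatting convention.

## Pipeline

The censoring rule marks the post-baseline acute samples (T2–T48) of
flagged cCAD patients as censored — baseline and follow-up are retained —
and censored samples are excluded from every downstream stage. The flag
column is configurable; the rule is generic over manifest columns.
Summary tables compute categorical percentages over non-missing
denominators (with missing counts reported separately) and continuous
variables as mean ± SD or median (Q1, Q3) when flagged as skewed.

Determinism: every random stage consumes a seed from the single run
configuration, CSVs are written with a fixed float format (`%.10g`), and
the run log records seed, a configuration hash and per-stage sizes, so
repeated runs are byte-identical.

## Problem sizes

Test and acceptance workloads are sized to the study's own design: the
default synthetic cohort is 115 patients (35/60/20) × 6 timepoints = 690
thermograms; the metric-oracle suite checks 100 random three-transition
profiles at 0.001 °C oversampling; the type-I-error Monte Carlo uses 1,000
replicates of three n = 20 groups; equivariance properties use 200 random
profiles.

## Known limitations

* No instrument calibration, buffer-quality screening or scan-rejection
  logic; preprocessing assumes scans already pass operator QC.
* The first-moment temperature uses the discrete grid sum, not a continuous
  integral; for profiles with substantial negative excursions its value is
  sensitive to the near-zero denominator (flagged when non-positive).
* The synthetic generator does not model dialysis/buffer chemistry,
  troponin kinetics or covariate structure, and its effect sizes are
  deliberately testable rather than biologically calibrated.
* p-values from the published patient cohort cannot be reproduced (data
  unavailable); statistical machinery is validated by calibration and
  enumeration oracles instead.
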