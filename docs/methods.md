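# Methods

This note documents the models, conventions and numerical choices behind
`tilquant`, and what the synthetic-data tests do and do not establish.

## Data model and units

A section is a rectangular analyzable window with continuous cell
coordinates in micrometres, origin at the lower-left corner. Areas are
reported in mm² (1 mm² = 10⁶ μm²) because infiltrate densities are
conventionally quoted per mm²; keeping a single unit convention avoids
10⁶-scale errors. Marker positivity is binary; raw intensities are optional
and consumed only by the thresholding step, whose cutoff is closed
(intensity ≥ cutoff ⇒ positive) so boundary behavior is deterministic.
Every cell carries exactly one region label — `tumor`, `stroma` or
`excluded` — and excluded cells (necrosis, normal epithelium) are invisible
to all phenotypes and metrics. Cells exactly on a polygon boundary count as
inside (closed polygons).

## Phenotype rules

A phenotype is a conjunction of required-positive and required-negative
markers, optionally with an at-least-one set: the default rule set is

| name | definition |
|---|---|
| `TUMOR` | PANCK+ |
| `CD4_T` | CD4+ CD8− PANCK− |
| `CD8_T` | CD8+ CD4− PANCK− |
| `LAG3_T` | LAG3+ (CD4+ or CD8+) PANCK− |
| `<M>_CD4_T`, `<M>_CD8_T` | base rule plus marker M ∈ {LAG3, KI67, IFNG} |
| `KI67_TUMOR` | PANCK+ KI67+ |

CD4+CD8+ double positives are excluded from both subset rules by default
(the subsets are treated as disjoint) but still count as `LAG3_T` when
LAG3+; how staining platforms handle such cells is not standardized, so
`default_rules(double_positive="include")` switches the convention rather
than hard-coding a guess.

## Region segmentation

Manual tumor–stroma annotation is not reproducible, so the pipeline
recovers cancer nests algorithmically from the PANCK+ point pattern:
single-linkage clustering at `nest_link_distance` (connected components of
the proximity graph), clusters of at least `min_nest_cells` cells become
nest polygons (convex hull dilated by `boundary_buffer`), overlapping
polygons are unioned before area computation, and every cell is relabeled
by point-in-polygon with exclusion masks taking precedence. The partition
identity `tumor + stroma + exclusion = window` holds to 10⁻⁶ relative.

Defaults — link distance 30 μm, minimum nest 10 cells, buffer 10 μm — are
**calibration defaults tuned only against the synthetic generator** (they
recover ≥ 95% of ground-truth labels there, ~98.6% pooled). They are not
derived from any annotation protocol and are exposed in the configuration.
Convex hulls were preferred over alpha shapes because nests are compact and
hulls are deterministic and dependency-light; strongly concave nests would
need an alpha-shape variant. When masks are supplied,
`assign_regions_from_masks` overrides the algorithm entirely.

## Spatial metrics

Densities, positivity percentages, per-tumor-cell nearest-neighbor (NN)
distances and fixed-radius neighbor counts (default radius 50 μm, the
pairing radius used when relating tumor cells to surrounding immune cells).
Conventions that matter:

* **Exact k-d tree queries.** `cKDTree` accelerates the search; results are
  bit-identical to the O(n²) all-pairs computation (enforced by test).
* **Distances cross region boundaries** — a stromal immune cell can be the
  nearest neighbor of a tumor cell.
* **No edge correction.** Raw per-cell values are reported, which is what
  per-cell image-analysis exports contain; the analytic validation
  (mean count = λπr², NN CDF = 1 − exp(−λπd²)) therefore restricts itself
  to centers ≥ r from the window edge.
* **A cell is never its own neighbor**, even when it matches both the
  center and neighbor phenotype; if its own point is the only candidate,
  the distance is missing, not zero.
* **Missing ≠ zero.** A section with no CD8+ T cells has *missing* CD8
  positivity and NN summaries (plus a diagnostic), never zeros; downstream
  correlations drop missing rows listwise. Neighbor *counts* over an
  existing center set with no neighbor cells are genuinely observed zeros.
* Paired change = on-treatment / baseline per metric; missing whenever the
  baseline is missing or zero. Both the mean and the median of the
  per-center NN minima are exported; downstream analyses use the mean.

## Cohort statistics

* **Wilcoxon signed-rank** (two-sided): zero differences dropped by default
  (Pratt optional); exact null by convolution over sign assignments for
  ≤ 25 non-zero pairs (mid-ranks handled on a half-integer lattice),
  otherwise a normal approximation with continuity correction and the
  tie-corrected variance Σrᵢ²/4. Exact p equals the 2ⁿ enumeration.
* **Spearman**: Pearson correlation of mid-ranks; p from the t
  approximation with n − 2 df; < 4 complete pairs is an error.
* **Kaplan–Meier**: product-limit estimator, deaths before censorings at
  tied times; the median is the smallest observed time with S(t) ≤ 0.5
  (tolerance 10⁻⁹ for float dust), otherwise "not reached" (NR). Whether
  published NR medians reflect this convention or software interpolation is
  generally unstated; this convention is fixed here.
* **Log-rank**: k-group statistic from the summed hypergeometric
  observed-minus-expected vector and covariance; χ² on k − 1 components.
* **ROC cutpoint**: every midpoint between adjacent sorted unique values is
  scored; the cutoff maximizing |Youden J| wins, ties broken toward the
  more balanced split, then the smaller cutoff. *Both orientations are
  scored* because the main features here are protective (high TIL density →
  longer survival): with a fixed "high predicts death" orientation the
  optimum would be noise. The chosen orientation is reported. The ROC
  outcome is vital status at end of follow-up by default; a fixed-horizon
  outcome (`horizon=` months) is available since the outcome definition
  underlying published ROC cutoffs is usually not stated.
* **Cutpoint optimism.** Optimizing the cutpoint inflates the log-rank
  type-I error, so `dichotomized_survival` can rerun the whole cutpoint +
  log-rank pipeline on permuted feature labels (pipeline default 1000
  permutations) and report a calibrated p alongside the raw one.
* No multiple-testing correction by default; Benjamini–Hochberg available
  (`bh_adjust`). Survival is in months (days / 30.44 when converting).

## Synthetic generator

The generator emulates the statistical structure of paired mIHC biopsies
from a chemoradiotherapy-treated esophageal squamous carcinoma cohort; no
cell-level dataset of this kind is publicly deposited, so it is the ground
truth for every recovery test.

* **Geometry**: nests are hard discs (Neyman–Scott: uniform parent centers,
  radius ~ Normal(200, 40) μm truncated, cells uniform in the disc),
  window 2 × 2 mm. Stroma is the window minus the nest union.
* **Intensities** (cells/mm², Poisson): tumor cells 2000 in nests; stromal
  CD4/CD8 T cells 183.95 / 61.80, intratumoral 40.03 / 29.57 — the reported
  magnitudes for this tissue type, giving the stroma > tumor ordering.
* **Marker rates**: LAG3 2%/1% (CD4/CD8 T), Ki67 1.5%, IFN-γ 3.4%/5.9%;
  tumor Ki67 25%.
* **LAG3 coupling**: a cell's LAG3 log-odds are
  logit(rate) + b_s + β·(k − μ₀)/√μ₀, where k is its T-cell neighbor count
  within 50 μm, μ₀ = λ_T·πr² is the count expected under the *configured*
  stromal T-cell intensity (a fixed reference — standardizing within the
  sample would cancel the sample's own density signal and no across-sample
  correlation could arise), β = `lag3_coupling` (default 0.8) and
  b_s ~ Normal(0, 0.8) is a per-section intercept modeling section-level
  variability in LAG3 expression. The intercept also keeps the coupling-0
  null honest: without it, binomial thinning alone ties LAG3+ density to
  T-cell density (ρ ≈ √(p·λ_CD4/λ_T) ≈ 0.2).
* **Cohorts**: per patient a shared lognormal density factor (log-sd 0.4)
  plus a small per-phenotype jitter (log-sd 0.15) — this between-patient
  heterogeneity is what makes density–density correlations observable.
  On-treatment sections multiply immune intensities by 0.67 (CD4) / 0.69
  (CD8) and shift IFN-γ rates by +9.45 / +17.01 percentage points — the
  reported on-treatment dynamics. Survival is exponential with hazard
  h₀·exp(β·z) on the standardized true stromal CD4 intensity
  (h₀ = 0.03/month, β = −0.55 per SD by default; a `median_split` link
  makes exp(β) the exact hazard ratio between halves), censored
  administratively at 76.3 months (the follow-up horizon). Closed-form
  exponential medians (ln 2 / h) give analytic expectations.
* **Reproducibility**: each sample draws from a generator seeded by
  (seed, patient index, timepoint code), so cohorts are bit-reproducible
  and parallelizable.

**What the generator does not emulate**: cell morphology and segmentation
errors, staining artefacts and intensity drift across slides, anisotropic
or serpentine tumor architecture, immune phenotypes beyond CD4/CD8 T cells,
non-exponential survival, informative censoring. Passing recovery tests
shows the pipeline is correct and well calibrated *under these mechanisms*,
not that real tissue obeys them.

## Simulation sizes in the test suite

Simulation-heavy tests use sizes chosen to balance statistical resolution
against runtime on one CPU: the log-rank type-I calibration uses 1000
replicates (50/arm); the Wilcoxon-uniformity check 120 null cohorts of 12
patients on 0.36 mm² sections; treatment-ratio recovery one 100-patient
cohort (0.64 mm² sections); hazard-ratio recovery 20 replicates of 200
patients; the coupling-0 null 100 cohorts of 30 full-size (4 mm²) sections
— the false-positive rate is evaluated with patient heterogeneity off,
because with heterogeneity on the thinning-induced correlation is real, not
a false positive, and small windows inflate small-count effects; the
segmentation recovery pools 100 default sections. Acceptance bands are the
spec'd tolerances or ±3σ binomial bands around the analytic expectation.

## Known limitations

* Convex-hull nests overestimate concave nest area; two nests closer than
  the link distance merge into one hull that can swallow the stroma strip
  between them.
* The across-sample LAG3–CD4 density correlation under coupling mixes the
  coupling mechanism with patient-level density heterogeneity; the
  generator cannot make the coupling the *only* source of correlation while
  heterogeneity is on.
* Optimal-cutpoint survival p-values are anti-conservative by construction;
  use the permutation-calibrated p for inference.
* No edge correction means spatial summaries near section borders are
  biased low (counts) or high (distances); comparisons between sections of
  similar geometry are unaffected, absolute values should be interpreted
  with care.
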