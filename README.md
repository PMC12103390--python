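# tilquant

Spatial quantification of tumor-infiltrating lymphocytes (TILs) from
multiplexed immunohistochemistry (mIHC) cell tables, with paired-treatment
dynamics and survival stratification.

## The problem

Multiplexed IHC of a tumor biopsy yields one row per segmented cell: 2-D
coordinates in micrometres and positive/negative calls for a marker panel —
here PANCK (pan-cytokeratin, the epithelial tumor marker), CD4, CD8, LAG3
(an inhibitory immune checkpoint on activated/exhausted T cells), Ki67
(proliferation) and IFN-γ (effector cytokine). Questions a translational
immuno-oncology group asks of such data:

* How dense are CD4+/CD8+ T-cell infiltrates in the **cancer nests** versus
  the surrounding **stroma** (cells/mm²)?
* What fraction of each T-cell subset expresses LAG3 / Ki67 / IFN-γ, and how
  do densities and rates shift between a **baseline** biopsy and an
  **on-treatment** biopsy from the same patient?
* How close do TILs get to tumor cells (nearest-neighbor distances, mean
  neighbor counts within a 50 μm pairing radius), and do any of these
  readouts stratify **overall survival**?

`tilquant` implements this pipeline end to end:

1. **Data model + I/O** (`tilquant.model`) — validated cell tables (CSV),
   region masks (GeoJSON, μm coordinates), clinical tables (CSV).
2. **Phenotyping** (`tilquant.phenotype`) — named marker-logic rules
   (e.g. `CD4_T = CD4+ CD8− PANCK−`, `LAG3_T = LAG3+ (CD4+ or CD8+) PANCK−`),
   intensity thresholding with a closed (≥) cutoff.
3. **Region segmentation** (`tilquant.regions`) — tumor nests recovered
   from the PANCK+ point pattern by single-linkage clustering + buffered
   convex hulls; manual GeoJSON masks override when provided; exclusion
   masks (necrosis) take precedence everywhere.
4. **Spatial metrics** (`tilquant.spatial`) — densities per region,
   positivity percentages, per-tumor-cell nearest distances and
   fixed-radius neighbor counts (k-d tree, exactly equal to the all-pairs
   computation), paired on/baseline ratios. Missing is never silently zero.
5. **Cohort statistics** (`tilquant.stats`) — exact/approximate Wilcoxon
   signed-rank, Spearman rank correlation, ROC-optimal (Youden) cutpoints,
   Kaplan–Meier estimation with the S(t) ≤ 0.5 median convention, k-group
   log-rank, and optimal-cutpoint survival stratification with an optional
   permutation-calibrated p-value.
6. **Synthetic tissue generator** (`tilquant.synth`) — Neyman–Scott tumor
   nests in a Poisson immune field with configurable treatment effects,
   LAG3–density coupling and an exponential proportional-hazards survival
   link; it provides ground truth for every stage.

## The core quantities

For a section with region areas |T| and |S| (mm²) and phenotype counts
n(p, r):

* density: ρ(p, r) = n(p, r) / |r|  (cells/mm²)
* positivity: %(m in p, r) = 100 · n(p ∧ m+, r) / n(p, r)
* nearest distance: d_i = min over neighbor cells j of ‖x_i − x_j‖ for each
  tumor cell i (summarized by mean/median of the d_i)
* neighbor count: k_i = #{j : ‖x_i − x_j‖ ≤ r}, r = 50 μm by default
* paired change: ratio = on-treatment / baseline per patient and metric

Survival features are dichotomized at the cutoff maximizing Youden's
J = sensitivity + specificity − 1 over all midpoints between observed
values (both orientations scored), then compared by Kaplan–Meier medians
and the log-rank test.

## Worked example

```python
import tilquant as tq

# one synthetic 4 mm^2 section with ground-truth regions
sample = tq.generate_tissue(tq.TissueConfig(seed=1))
seg = tq.segment_regions(sample)                  # recover nests from PANCK+
print(round(tq.label_accuracy(sample, seg), 3))   # 0.99
summary = tq.summarize_sample(seg)
print(round(summary.metrics["density_CD4_T_stroma"], 1))  # 179.3
print(round(summary.metrics["density_CD4_T_tumor"], 1))   # 55.2
print(round(summary.metrics["pct_LAG3_in_CD8_T_all"], 1)) # 8.8
print(round(summary.metrics["ncount_mean_CD4_T"], 2))     # 0.47
```

`0.99` — 99% of cells got their ground-truth tumor/stroma label back from
the segmenter alone. `179.3` vs `55.2` cells/mm² — the stroma carries about
3× the CD4+ T-cell density of the cancer nests, the hallmark of an
immune-excluded architecture. `8.8` — percent of CD8+ T cells expressing
LAG3 in this section. `0.47` — mean number of CD4+ T cells within 50 μm of
each tumor cell.

The same flow from the shell:

```sh
tilquant simulate --outdir cohort/ --seed 1
tilquant segment --input cohort/cells/P001_baseline.csv --output seg.csv
tilquant summarize cohort/cells/*.csv --out metrics.csv
tilquant survival --metrics metrics.csv --clinical cohort/clinical.csv \
    --feature density_CD4_T_stroma --out survival.csv
tilquant run-all --outdir full/ --seed 1     # everything above at once
```

`run-all` is deterministic: the same config and seed reproduce every output
file byte for byte.

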