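"""End-to-end orchestration: cohort -> segmentation -> spatial metrics ->
cohort statistics -> survival stratification, with deterministic CSV/JSON
outputs.

``run_all`` is the single entry point behind the ``run-all`` CLI
subcommand: given a cohort configuration and a seed it writes

* ``cells/<patient>_<timepoint>.csv`` — generated cell tables
* ``clinical.csv`` — per-patient survival records
* ``metrics.csv`` — one row per sample, one column per spatial metric
* ``paired_ratios.csv`` — on-treatment / baseline density ratios
* ``results.csv`` — one row per statistical analysis
* ``km_curves.csv`` — Kaplan-Meier curve coordinates per stratified group
* ``report.json`` — seed, configuration echo and configuration hash

All randomness flows from the single seed, so rerunning with the same
configuration reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import write_cell_table, write_clinical
from .regions import SegmentationParams, label_accuracy, segment_regions
from .spatial import paired_change, summaries_to_frame, summarize_sample
from .stats import dichotomized_survival, log_rank, spearman, wilcoxon_signed_rank
from .synth import CohortConfig, generate_cohort

#: metrics compared baseline vs on-treatment with a paired Wilcoxon test
DEFAULT_PAIRED_METRICS = (
    "density_CD4_T_stroma",
    "density_CD8_T_stroma",
    "density_LAG3_T_stroma",
    "density_IFNG_CD4_T_all",
    "pct_IFNG_in_CD4_T_all",
    "pct_IFNG_in_CD8_T_all",
    "pct_KI67_in_CD4_T_all",
    "pct_KI67_in_CD8_T_all",
    "nndist_mean_CD4_T",
    "nndist_mean_CD8_T",
    "ncount_mean_CD4_T",
    "ncount_mean_CD8_T",
)

#: (x, y) metric pairs rank-correlated within each timepoint
DEFAULT_CORRELATIONS = (
    ("density_LAG3_T_stroma", "density_CD4_T_stroma"),
    ("density_LAG3_T_stroma", "density_CD8_T_stroma"),
    ("density_LAG3_T_all", "nndist_mean_CD4_T"),
    ("density_LAG3_T_all", "nndist_mean_CD8_T"),
    ("density_LAG3_T_all", "ncount_mean_CD4_T"),
    ("density_LAG3_T_all", "ncount_mean_CD8_T"),
)

#: features dichotomized for survival: "timepoint:metric" with timepoint in
#: {baseline, on_treatment, ratio}
DEFAULT_SURVIVAL_FEATURES = (
    "baseline:density_CD4_T_stroma",
    "baseline:density_LAG3_T_all",
    "baseline:pct_LAG3_in_CD8_T_all",
    "on_treatment:density_CD4_T_stroma",
    "on_treatment:density_LAG3_T_all",
    "on_treatment:nndist_mean_CD8_T",
    "on_treatment:ncount_mean_CD8_T",
    "ratio:density_CD4_T_stroma",
    "ratio:density_CD8_T_stroma",
    "ratio:density_LAG3_T_stroma",
)


def _feature_column(metrics: pd.DataFrame, ratios: pd.DataFrame, spec: str) -> dict:
    """Per-patient values of a 'timepoint:metric' feature specification."""
    timepoint, metric = spec.split(":", 1)
    if timepoint == "ratio":
        if metric not in ratios.columns:
            return {}
        sub = ratios
    else:
        sub = metrics[metrics["timepoint"] == timepoint]
        if metric not in sub.columns:
            return {}
    return {
        str(r["patient_id"]): float(r[metric])
        for _, r in sub.iterrows()
        if np.isfinite(r[metric])
    }


def run_all(
    config: CohortConfig,
    outdir: str | Path,
    *,
    seed: int | None = None,
    segmentation: SegmentationParams = SegmentationParams(),
    paired_metrics=DEFAULT_PAIRED_METRICS,
    correlations=DEFAULT_CORRELATIONS,
    survival_features=DEFAULT_SURVIVAL_FEATURES,
    permutation_reps: int = 1000,
    write_cells: bool = True,
) -> dict:
    """Run the full pipeline; returns a summary dict of what was written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    cohort = generate_cohort(config)

    # segmentation (algorithmic tumor/stroma recovery) + spatial summaries
    summaries = []
    seg_acc = []
    cells_dir = outdir / "cells"
    if write_cells:
        cells_dir.mkdir(exist_ok=True)
    for bl, tx in cohort.pairs:
        for sample in (bl, tx):
            if sample is None:
                continue
            seg = segment_regions(sample, segmentation)
            seg_acc.append(label_accuracy(sample, seg))
            summaries.append(summarize_sample(seg))
            if write_cells:
                write_cell_table(seg, cells_dir / f"{sample.patient_id}_{sample.timepoint}.csv")
    metrics = summaries_to_frame(summaries)
    metrics.to_csv(outdir / "metrics.csv", index=False)
    write_clinical(cohort.records, outdir / "clinical.csv")
    cohort.truth.to_csv(outdir / "truth.csv", index=False)

    # paired on/baseline density ratios
    by_key = {(s.patient_id, s.timepoint): s for s in summaries}
    ratio_rows = []
    for bl, tx in cohort.pairs:
        if tx is None:
            continue
        pc = paired_change(
            by_key[(bl.patient_id, "baseline")], by_key[(tx.patient_id, "on_treatment")]
        )
        ratio_rows.append({"patient_id": pc.patient_id, **pc.ratios})
    ratios = pd.DataFrame(ratio_rows)
    ratios.to_csv(outdir / "paired_ratios.csv", index=False)

    # cohort statistics
    results = []
    bl_df = metrics[metrics["timepoint"] == "baseline"].set_index("patient_id")
    tx_df = metrics[metrics["timepoint"] == "on_treatment"].set_index("patient_id")
    common = bl_df.index.intersection(tx_df.index)
    for metric in paired_metrics:
        if metric not in metrics.columns or len(common) == 0:
            continue
        a = bl_df.loc[common, metric].to_numpy(dtype=float)
        b = tx_df.loc[common, metric].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() == 0:
            continue
        res = wilcoxon_signed_rank(b[ok], a[ok])
        results.append(
            {
                "analysis": "paired_wilcoxon",
                "metric": metric,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n": res.n,
                "estimate": float(np.nanmedian(b[ok] - a[ok])),
            }
        )
    for timepoint, df in (("baseline", bl_df), ("on_treatment", tx_df)):
        for mx, my in correlations:
            if mx not in df.columns or my not in df.columns or len(df) < 4:
                continue
            try:
                res = spearman(df[mx].to_numpy(float), df[my].to_numpy(float))
            except Exception:
                continue
            results.append(
                {
                    "analysis": f"spearman_{timepoint}",
                    "metric": f"{mx}~{my}",
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n": res.n,
                    "estimate": res.estimate,
                }
            )

    # survival stratification
    km_rows = []
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0xD1C0])
    for spec in survival_features:
        feat = _feature_column(metrics, ratios, spec)
        if len(feat) < 4:
            continue
        res = dichotomized_survival(
            feat,
            cohort.records,
            feature_name=spec,
            n_permutations=permutation_reps,
            rng=rng,
        )
        row = {"analysis": "dichotomized_survival", "metric": spec}
        if res.degenerate:
            row.update({"statistic": math.nan, "p_value": math.nan, "n": 0,
                        "estimate": math.nan, "note": res.reason})
        else:
            row.update(
                {
                    "statistic": res.logrank.statistic,
                    "p_value": res.logrank.p_value,
                    "n": res.logrank.n,
                    "estimate": res.cutpoint.cutoff,
                    "permutation_p": res.permutation_p,
                    "median_high": res.km_high.median,
                    "median_low": res.km_low.median,
                    "n_high": res.km_high.n,
                    "n_low": res.km_low.n,
                }
            )
            for km in (res.km_high, res.km_low):
                for t, s in zip(km.times, km.survival):
                    km_rows.append(
                        {"feature": spec, "group": km.label, "time_months": t,
                         "survival": s}
                    )
        results.append(row)

    results_df = pd.DataFrame(results)
    results_df.to_csv(outdir / "results.csv", index=False)
    pd.DataFrame(km_rows).to_csv(outdir / "km_curves.csv", index=False)

    from .synth import cohort_config_to_dict

    cfg_dict = cohort_config_to_dict(config)
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    report = {
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_samples": len(summaries),
        "segmentation_mean_accuracy": float(np.nanmean(seg_acc)) if seg_acc else None,
        "permutation_reps": permutation_reps,
    }
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
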