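"""Per-sample spatial readouts: densities, positivity rates, tumor-centered
nearest-neighbor distances and fixed-radius neighbor counts, and paired
timepoint ratios.

Conventions
-----------
* Densities are cells/mm^2 within a region (tumor, stroma, or their union).
* Positivity rates are percentages of a base phenotype expressing a marker.
* Distances are Euclidean in um and computed across region boundaries: a
  stromal immune cell may be the nearest neighbor of a tumor cell.
* No edge correction is applied to neighbor counts or NN distances; raw
  values are reported, which is what per-cell image-analysis exports
  contain.  Analytic validation therefore restricts itself to centers far
  from the window edge.
* Missing is never zero: a section with no CD8+ T cells has *missing* CD8
  positivity and NN metrics (with a diagnostic), so that empty sections do
  not deflate downstream correlations with artificial zeros.

Nearest-neighbor and radius queries use a k-d tree; results are exactly
equal to the brute-force all-pairs computation (the tree only accelerates
the search).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import ConfigError, TissueSample, ValidationError
from .phenotype import PhenotypeRule, default_rules, match_mask, rules_by_name

#: Default pairing radius (um) for tumor-cell-centered neighbor counts.
DEFAULT_RADIUS_UM = 50.0

#: Phenotypes whose tumor-centered spatial relationships are summarized.
DEFAULT_NEIGHBOR_PHENOTYPES = ("CD4_T", "CD8_T", "LAG3_T", "LAG3_CD4_T", "LAG3_CD8_T")


def density(
    sample: TissueSample,
    phenotype: str,
    region: str = "all",
    rules: Sequence[PhenotypeRule] | None = None,
) -> float:
    """Cell density of a phenotype in a region, cells/mm^2.

    Returns NaN (missing) when the region has zero area.
    """
    rules = default_rules() if rules is None else rules
    rule = rules_by_name(rules).get(phenotype)
    if rule is None:
        raise ConfigError(f"unknown phenotype {phenotype!r}")
    area = sample.geometry.area_mm2(region)
    if area <= 0:
        return float("nan")
    mask = match_mask(sample, rule)
    reg = sample.cells["region"].to_numpy() if len(sample.cells) else np.array([])
    if region == "tumor":
        mask = mask & (reg == "tumor")
    elif region == "stroma":
        mask = mask & (reg == "stroma")
    elif region == "all":
        mask = mask & (reg != "excluded")
    else:
        raise ValueError(f"unknown region {region!r}")
    return float(mask.sum()) / area


def positivity_rate(
    sample: TissueSample,
    base: str,
    marker: str,
    region: str = "all",
    rules: Sequence[PhenotypeRule] | None = None,
) -> float:
    """Percentage of base-phenotype cells positive for a marker in a region.

    Missing (NaN) when the base phenotype has zero cells there — a section
    without CD8+ T cells has no LAG3-in-CD8 rate, not a rate of zero.
    """
    rules = default_rules() if rules is None else rules
    rule = rules_by_name(rules).get(base)
    if rule is None:
        raise ConfigError(f"unknown base phenotype {base!r}")
    if marker not in sample.panel:
        raise ConfigError(f"unknown marker {marker!r}")
    mask = match_mask(sample, rule)
    reg = sample.cells["region"].to_numpy() if len(sample.cells) else np.array([])
    if region == "tumor":
        mask = mask & (reg == "tumor")
    elif region == "stroma":
        mask = mask & (reg == "stroma")
    elif region == "all":
        mask = mask & (reg != "excluded")
    else:
        raise ValueError(f"unknown region {region!r}")
    n_base = int(mask.sum())
    if n_base == 0:
        return float("nan")
    n_pos = int((mask & (sample.cells[marker].to_numpy() == 1)).sum())
    return 100.0 * n_pos / n_base


@dataclass
class NearestDistanceResult:
    """Per-center minima (um) from each center cell to the nearest neighbor-
    phenotype cell, with sample-level mean and median."""

    per_center: np.ndarray
    mean: float
    median: float
    n_centers: int
    n_neighbors: int

    @property
    def is_missing(self) -> bool:
        return self.n_centers == 0 or self.n_neighbors == 0


def nearest_distances(
    sample: TissueSample,
    centers: str = "TUMOR",
    neighbors: str = "CD4_T",
    rules: Sequence[PhenotypeRule] | None = None,
) -> NearestDistanceResult:
    """Distance from each center cell to its closest neighbor-phenotype cell.

    Distances cross region boundaries.  A cell matching both rules is never
    its own neighbor.  Missing (NaN summaries, empty per-center array) when
    either set is empty.
    """
    rules = default_rules() if rules is None else rules
    by_name = rules_by_name(rules)
    for name in (centers, neighbors):
        if name not in by_name:
            raise ConfigError(f"unknown phenotype {name!r}")
    c_mask = match_mask(sample, by_name[centers])
    n_mask = match_mask(sample, by_name[neighbors])
    df = sample.cells
    c_xy = df.loc[c_mask, ["x_um", "y_um"]].to_numpy(dtype=float)
    n_xy = df.loc[n_mask, ["x_um", "y_um"]].to_numpy(dtype=float)
    if len(c_xy) == 0 or len(n_xy) == 0:
        return NearestDistanceResult(
            per_center=np.array([]),
            mean=float("nan"),
            median=float("nan"),
            n_centers=len(c_xy),
            n_neighbors=len(n_xy),
        )
    both = c_mask & n_mask
    tree = cKDTree(n_xy)
    # map each center to its own row index inside the neighbor array so it
    # can be skipped when the same cell matches both rules
    n_row = np.full(len(df), -1, dtype=int)
    n_row[np.flatnonzero(n_mask)] = np.arange(len(n_xy))
    dists = np.empty(len(c_xy))
    c_idx = np.flatnonzero(c_mask)
    plain = ~both[c_idx]
    if plain.any():
        dists[plain] = tree.query(c_xy[plain], k=1)[0]
    dual = ~plain
    if dual.any():
        dd, ii = tree.query(c_xy[dual], k=2)
        own = n_row[c_idx[dual]]
        pick_second = ii[:, 0] == own
        dists[dual] = np.where(pick_second, dd[:, 1], dd[:, 0])
        # a center whose only candidate neighbor is itself has no distance
        dists[np.isinf(dists)] = np.nan
    finite = np.isfinite(dists)
    return NearestDistanceResult(
        per_center=dists,
        mean=float(np.mean(dists[finite])) if finite.any() else float("nan"),
        median=float(np.median(dists[finite])) if finite.any() else float("nan"),
        n_centers=len(c_xy),
        n_neighbors=len(n_xy),
    )


@dataclass
class NeighborCountResult:
    """Per-center counts of neighbor-phenotype cells within ``radius`` um."""

    per_center: np.ndarray
    mean: float
    radius: float
    n_centers: int
    n_neighbors: int

    @property
    def is_missing(self) -> bool:
        return self.n_centers == 0


def neighbor_counts(
    sample: TissueSample,
    centers: str = "TUMOR",
    neighbors: str = "CD4_T",
    radius: float = DEFAULT_RADIUS_UM,
    rules: Sequence[PhenotypeRule] | None = None,
) -> NeighborCountResult:
    """Count neighbor-phenotype cells within ``radius`` of each center cell.

    The center cell itself is never counted even if it matches both rules.
    With no neighbor cells in the sample the mean over centers is 0 (an
    observed absence, unlike the undefined nearest distance).
    """
    if radius <= 0:
        raise ConfigError(f"radius must be > 0, got {radius}")
    rules = default_rules() if rules is None else rules
    by_name = rules_by_name(rules)
    for name in (centers, neighbors):
        if name not in by_name:
            raise ConfigError(f"unknown phenotype {name!r}")
    c_mask = match_mask(sample, by_name[centers])
    n_mask = match_mask(sample, by_name[neighbors])
    df = sample.cells
    c_xy = df.loc[c_mask, ["x_um", "y_um"]].to_numpy(dtype=float)
    n_xy = df.loc[n_mask, ["x_um", "y_um"]].to_numpy(dtype=float)
    if len(c_xy) == 0:
        return NeighborCountResult(
            per_center=np.array([], dtype=int),
            mean=float("nan"),
            radius=radius,
            n_centers=0,
            n_neighbors=len(n_xy),
        )
    if len(n_xy) == 0:
        counts = np.zeros(len(c_xy), dtype=int)
    else:
        tree = cKDTree(n_xy)
        counts = tree.query_ball_point(c_xy, r=radius, return_length=True)
        both = (c_mask & n_mask)[c_mask]
        counts = counts - both.astype(int)  # a cell is not its own neighbor
    return NeighborCountResult(
        per_center=counts,
        mean=float(np.mean(counts)),
        radius=radius,
        n_centers=len(c_xy),
        n_neighbors=len(n_xy),
    )


@dataclass
class SpatialSummary:
    """All per-sample metrics as a flat name -> value mapping.

    Metric names:

    * ``density_<phenotype>_<region>`` — cells/mm^2
    * ``pct_<marker>_in_<base>_<region>`` — positivity %
    * ``nndist_mean_<neighbors>`` / ``nndist_median_<neighbors>`` — um,
      centers are tumor cells
    * ``ncount_mean_<neighbors>`` — mean neighbor count within ``radius``
    """

    patient_id: str
    timepoint: str
    metrics: dict
    radius: float
    diagnostics: list = field(default_factory=list)

    def to_row(self) -> pd.Series:
        row = pd.Series(self.metrics, dtype=float)
        row["radius_um"] = self.radius
        return row


#: metric-name prefixes that represent densities (used for paired ratios)
_DENSITY_PREFIX = "density_"


def summarize_sample(
    sample: TissueSample,
    rules: Sequence[PhenotypeRule] | None = None,
    radius: float = DEFAULT_RADIUS_UM,
    neighbor_phenotypes: Sequence[str] = DEFAULT_NEIGHBOR_PHENOTYPES,
) -> SpatialSummary:
    """Compute the full spatial summary of a segmented, phenotyped sample.

    Deterministic for fixed input; component errors (zero areas, empty
    phenotypes) propagate as missing values plus an entry in
    ``diagnostics``.
    """
    rules = default_rules() if rules is None else rules
    diagnostics: list[str] = []
    metrics: dict[str, float] = {}
    for rule in rules:
        for region in ("tumor", "stroma", "all"):
            val = density(sample, rule.name, region, rules=rules)
            metrics[f"density_{rule.name}_{region}"] = val
            if math.isnan(val):
                diagnostics.append(f"density_{rule.name}_{region}: zero region area")
    from .phenotype import BASE_T_PHENOTYPES, REFINING_MARKERS

    for base in (*BASE_T_PHENOTYPES, "TUMOR"):
        markers = REFINING_MARKERS if base != "TUMOR" else ("KI67",)
        for marker in markers:
            for region in ("tumor", "stroma", "all"):
                val = positivity_rate(sample, base, marker, region, rules=rules)
                metrics[f"pct_{marker}_in_{base}_{region}"] = val
                if math.isnan(val):
                    diagnostics.append(
                        f"pct_{marker}_in_{base}_{region}: no {base} cells in {region}"
                    )
    for neigh in neighbor_phenotypes:
        nd = nearest_distances(sample, "TUMOR", neigh, rules=rules)
        metrics[f"nndist_mean_{neigh}"] = nd.mean
        metrics[f"nndist_median_{neigh}"] = nd.median
        if nd.is_missing:
            diagnostics.append(f"nndist_{neigh}: no centers or no neighbor cells")
        nc = neighbor_counts(sample, "TUMOR", neigh, radius=radius, rules=rules)
        metrics[f"ncount_mean_{neigh}"] = nc.mean
        if nc.is_missing:
            diagnostics.append(f"ncount_{neigh}: no center cells")
    return SpatialSummary(
        patient_id=sample.patient_id,
        timepoint=sample.timepoint,
        metrics=metrics,
        radius=radius,
        diagnostics=diagnostics,
    )


@dataclass
class PairedChange:
    """On-treatment / baseline ratios of density metrics for one patient.

    ``ratios[name]`` is on/baseline; missing (NaN) whenever the baseline
    value is missing or zero, or the on-treatment value is missing.
    """

    patient_id: str
    baseline: dict
    on_treatment: dict
    ratios: dict


def paired_change(baseline: SpatialSummary, on_treatment: SpatialSummary) -> PairedChange:
    """Element-wise on/baseline ratio of the density metrics of one patient."""
    if baseline.patient_id != on_treatment.patient_id:
        raise ValidationError(
            f"patient mismatch: {baseline.patient_id!r} vs {on_treatment.patient_id!r}"
        )
    ratios: dict[str, float] = {}
    bl: dict[str, float] = {}
    tx: dict[str, float] = {}
    for name, b in baseline.metrics.items():
        if not name.startswith(_DENSITY_PREFIX):
            continue
        t = on_treatment.metrics.get(name, float("nan"))
        bl[name] = b
        tx[name] = t
        if not math.isfinite(b) or b <= 0 or not math.isfinite(t):
            ratios[name] = float("nan")
        else:
            ratios[name] = t / b
    return PairedChange(
        patient_id=baseline.patient_id, baseline=bl, on_treatment=tx, ratios=ratios
    )


def summaries_to_frame(summaries: Sequence[SpatialSummary]) -> pd.DataFrame:
    """One row per sample, one column per metric, indexed by (patient, timepoint)."""
    rows = []
    for s in summaries:
        row = s.to_row()
        row["patient_id"] = s.patient_id
        row["timepoint"] = s.timepoint
        rows.append(row)
    df = pd.DataFrame(rows)
    front = ["patient_id", "timepoint"]
    return df[front + [c for c in df.columns if c not in front]]
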