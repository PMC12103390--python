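"""Synthetic tissue and cohort generator.

No public cell-level mIHC dataset accompanies the analyses this pipeline
reproduces, so ground truth comes from a generator that emulates their
statistical structure:

* PANCK+ tumor nests drawn as a Neyman-Scott cluster process: nest centers
  uniform in the window, tumor cells uniform within discs around them.
* CD4+ and CD8+ T cells as independent homogeneous Poisson processes with
  region-specific intensities, higher in stroma than inside nests.
* Bernoulli marker positivity (LAG3 / Ki67 / IFN-gamma) per phenotype, with
  an optional positive coupling between local T-cell crowding and the
  log-odds of LAG3 positivity, so that LAG3+ T-cell density co-varies with
  CD4/CD8 T-cell density across samples.
* Paired on-treatment sections whose immune intensities are multiplied by
  per-phenotype treatment factors and whose IFN-gamma rates are shifted up.
* Overall survival from an exponential proportional-hazards model on a
  designated (standardized) spatial feature, censored administratively.

Default intensities and rates are set to the magnitudes reported for
chemoradiotherapy-treated esophageal squamous carcinoma biopsies: stromal
CD4/CD8 densities of about 184 and 62 cells/mm^2 at baseline (40 and 30
inside nests), on-treatment density multipliers of about 0.67/0.69, and
IFN-gamma positivity rising from a few percent to 13-23% during treatment.

Reproducibility: every sample draws from its own generator seeded by
``(seed, patient index, timepoint code)``, so cohorts are reproducible even
under parallel generation, and the same seed yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import expit, logit
from shapely.geometry import Point, Polygon

from .model import (
    ConfigError,
    RegionGeometry,
    SurvivalRecord,
    TissueSample,
    PANEL,
    UM2_PER_MM2,
)

IMMUNE_PHENOTYPES = ("CD4_T", "CD8_T")
_MARKER_OF = {"CD4_T": "CD4", "CD8_T": "CD8"}
_TP_CODE = {"patient": 0, "baseline": 1, "on_treatment": 2, "survival": 3}


def _default_marker_rates() -> dict:
    return {
        "CD4_T": {"LAG3": 0.02, "KI67": 0.015, "IFNG": 0.034},
        "CD8_T": {"LAG3": 0.01, "KI67": 0.015, "IFNG": 0.059},
        "TUMOR": {"KI67": 0.25},
    }


@dataclass
class TissueConfig:
    """Parameters of one synthetic section (distances um, densities /mm^2)."""

    window: tuple[float, float] = (2000.0, 2000.0)
    n_nests: int = 4
    nest_radius_mean: float = 200.0
    nest_radius_sd: float = 40.0
    tumor_density_in_nest: float = 2000.0
    immune_density_stroma: dict = field(
        default_factory=lambda: {"CD4_T": 183.95, "CD8_T": 61.80}
    )
    immune_density_tumor: dict = field(
        default_factory=lambda: {"CD4_T": 40.03, "CD8_T": 29.57}
    )
    marker_rates: dict = field(default_factory=_default_marker_rates)
    lag3_coupling: float = 0.8
    lag3_rate_logit_sd: float = 0.8
    coupling_radius: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        w, h = self.window
        if w <= 0 or h <= 0:
            raise ConfigError("window dimensions must be positive")
        if self.n_nests < 0 or self.nest_radius_mean < 0 or self.nest_radius_sd < 0:
            raise ConfigError("nest parameters must be >= 0")
        if self.n_nests > 0 and 2 * self.nest_radius_mean > min(w, h):
            raise ConfigError("nests do not fit within the window")
        if self.tumor_density_in_nest < 0:
            raise ConfigError("tumor density must be >= 0")
        for dens in (self.immune_density_stroma, self.immune_density_tumor):
            for phen, lam in dens.items():
                if phen not in IMMUNE_PHENOTYPES:
                    raise ConfigError(f"unknown immune phenotype {phen!r}")
                if lam < 0:
                    raise ConfigError(f"density for {phen} must be >= 0")
        for phen, rates in self.marker_rates.items():
            for marker, rate in rates.items():
                if not 0.0 <= rate <= 1.0:
                    raise ConfigError(f"rate ({phen},{marker}) must be in [0,1]")
        if self.lag3_coupling < 0:
            raise ConfigError("lag3_coupling must be >= 0")

    def replace(self, **kw) -> "TissueConfig":
        d = asdict(self)
        d.update(kw)
        return TissueConfig(**d)


def _sample_in_region(
    rng: np.random.Generator,
    n: int,
    window: tuple[float, float],
    region,  # shapely geometry or None for the whole window
    inside: bool,
) -> np.ndarray:
    """Uniform points in (window ∩ region) or (window \\ region) by rejection."""
    import shapely

    w, h = window
    if n == 0:
        return np.empty((0, 2))
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(4 * (n - len(out)), 64)
        pts = rng.uniform((0, 0), (w, h), size=(m, 2))
        if region is None or region.is_empty:
            ok = np.ones(m, dtype=bool) if not inside else np.zeros(m, dtype=bool)
        else:
            hit = shapely.intersects_xy(region, pts[:, 0], pts[:, 1])
            ok = hit if inside else ~hit
        out = np.vstack([out, pts[ok]])
    return out[:n]


def generate_tissue(
    config: TissueConfig,
    rng: np.random.Generator | None = None,
    patient_id: str = "sample",
    timepoint: str = "baseline",
) -> TissueSample:
    """Draw one synthetic section; same config + seed -> identical sample.

    The generating discs become the ground-truth tumor polygons of the
    sample's geometry, and cells carry their ground-truth region labels.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    w, h = config.window
    # --- tumor nests (Neyman-Scott: uniform parents, uniform cells in discs)
    discs: list[Polygon] = []
    for _ in range(config.n_nests):
        lo = 0.25 * config.nest_radius_mean
        hi = 0.49 * min(w, h)
        r = float(
            np.clip(rng.normal(config.nest_radius_mean, config.nest_radius_sd), lo, hi)
        )
        cx = rng.uniform(r, w - r)
        cy = rng.uniform(r, h - r)
        discs.append(Point(cx, cy).buffer(r, quad_segs=64))
    geometry = RegionGeometry(window=(0.0, 0.0, w, h), tumor_polygons=discs)
    tumor_union = geometry._tumor_union
    tumor_area = geometry.tumor_area_mm2
    stroma_area = geometry.stroma_area_mm2

    xs: list[np.ndarray] = []
    phen_labels: list[str] = []
    regions: list[str] = []

    n_tumor = rng.poisson(config.tumor_density_in_nest * tumor_area)
    pts = _sample_in_region(rng, n_tumor, config.window, tumor_union, inside=True)
    xs.append(pts)
    phen_labels += ["TUMOR"] * n_tumor
    regions += ["tumor"] * n_tumor

    for phen in IMMUNE_PHENOTYPES:
        lam_s = config.immune_density_stroma.get(phen, 0.0)
        lam_t = config.immune_density_tumor.get(phen, 0.0)
        n_s = rng.poisson(lam_s * stroma_area)
        pts = _sample_in_region(rng, n_s, config.window, tumor_union, inside=False)
        xs.append(pts)
        phen_labels += [phen] * n_s
        regions += ["stroma"] * n_s
        n_t = rng.poisson(lam_t * tumor_area) if tumor_area > 0 else 0
        pts = _sample_in_region(rng, n_t, config.window, tumor_union, inside=True)
        xs.append(pts)
        phen_labels += [phen] * n_t
        regions += ["tumor"] * n_t

    xy = np.vstack(xs) if xs else np.empty((0, 2))
    phen = np.array(phen_labels, dtype=object)
    n = len(phen)

    markers = {m: np.zeros(n, dtype=np.int8) for m in PANEL}
    markers["PANCK"][phen == "TUMOR"] = 1
    for p in IMMUNE_PHENOTYPES:
        markers[_MARKER_OF[p]][phen == p] = 1

    # KI67 / IFNG: independent Bernoulli per (phenotype, marker) rate
    for p, rates in config.marker_rates.items():
        sel = phen == p
        for marker in ("KI67", "IFNG"):
            rate = rates.get(marker, 0.0)
            if rate > 0 and sel.any():
                markers[marker][sel] = rng.random(int(sel.sum())) < rate

    # LAG3: logistic model on the local T-cell neighbor count.  The count is
    # standardized against the *configured* stromal T-cell intensity (a fixed
    # reference), so sample-to-sample density variation propagates into the
    # realized LAG3 rate and LAG3+ T density co-varies with T density across
    # samples; a per-sample logit-normal intercept models section-level
    # variability in LAG3 expression.
    t_sel = (phen == "CD4_T") | (phen == "CD8_T")
    b_sample = rng.normal(0.0, config.lag3_rate_logit_sd)
    if t_sel.any():
        z = np.zeros(int(t_sel.sum()))
        if config.lag3_coupling > 0:
            lam_t_total = sum(config.immune_density_stroma.values())  # /mm^2
            mu0 = lam_t_total * math.pi * config.coupling_radius**2 / UM2_PER_MM2
            if mu0 > 0:
                t_xy = xy[t_sel]
                tree = cKDTree(t_xy)
                k = tree.query_ball_point(
                    t_xy, r=config.coupling_radius, return_length=True
                ) - 1  # exclude self
                z = (k - mu0) / math.sqrt(mu0)
        for p in IMMUNE_PHENOTYPES:
            rate = config.marker_rates.get(p, {}).get("LAG3", 0.0)
            sel_p = (phen == p)[t_sel]
            if not sel_p.any():
                continue
            if rate <= 0.0:
                prob = np.zeros(int(sel_p.sum()))
            elif rate >= 1.0:
                prob = np.ones(int(sel_p.sum()))
            else:
                eta = logit(rate) + b_sample + config.lag3_coupling * z[sel_p]
                prob = expit(eta)
            draws = rng.random(int(sel_p.sum())) < prob
            idx = np.flatnonzero(t_sel)[sel_p]
            markers["LAG3"][idx] = draws
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i:06d}" for i in range(n)],
            "x_um": xy[:, 0] if n else np.array([], dtype=float),
            "y_um": xy[:, 1] if n else np.array([], dtype=float),
            **{m: markers[m] for m in PANEL},
            "region": pd.Series(regions, dtype=object)
            if n
            else pd.Series([], dtype=object),
        }
    )
    sample = TissueSample(
        patient_id=patient_id, timepoint=timepoint, cells=cells, geometry=geometry
    )
    sample.validate()
    return sample


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class TreatmentEffect:
    """On-treatment change: multiplicative density factors + IFN-gamma shift."""

    density_multipliers: dict = field(
        default_factory=lambda: {"CD4_T": 0.67, "CD8_T": 0.69}
    )
    ifng_rate_shift: dict = field(
        default_factory=lambda: {"CD4_T": 0.0945, "CD8_T": 0.1701}
    )

    def validate(self) -> None:
        for phen, mult in self.density_multipliers.items():
            if mult <= 0:
                raise ConfigError(f"density multiplier for {phen} must be > 0")


@dataclass
class HazardModel:
    """Exponential proportional-hazards link from a spatial feature to OS.

    ``link="linear"`` uses the cohort-standardized feature directly;
    ``"median_split"`` assigns z = +0.5 / -0.5 above/below the cohort
    median, so ``exp(log_hr)`` is the hazard ratio between the halves.
    """

    baseline_hazard: float = 0.03  # events per month
    feature: str = "density_CD4_T_stroma"
    log_hr: float = -0.55
    link: str = "linear"

    def validate(self) -> None:
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline hazard must be > 0")
        if self.link not in ("linear", "median_split"):
            raise ConfigError(f"unknown hazard link {self.link!r}")


@dataclass
class CohortConfig:
    """A paired-biopsy cohort with survival follow-up."""

    n_patients: int = 84
    tissue: TissueConfig = field(default_factory=TissueConfig)
    treatment: TreatmentEffect = field(default_factory=TreatmentEffect)
    hazard: HazardModel = field(default_factory=HazardModel)
    patient_density_logsd: float = 0.4
    phenotype_density_logsd: float = 0.15
    censor_time: float = 76.3  # months (about 2323 days of follow-up)
    include_on_treatment: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.censor_time <= 0:
            raise ConfigError("censor_time must be > 0")
        self.tissue.validate()
        self.treatment.validate()
        self.hazard.validate()


@dataclass
class CohortResult:
    """Generated cohort plus the ground truth needed for recovery tests."""

    pairs: list  # (baseline TissueSample, on-treatment TissueSample | None)
    records: list  # SurvivalRecord per patient
    truth: pd.DataFrame  # per-patient intensities, feature, hazard, raw time

    @property
    def baseline_samples(self) -> list:
        return [p[0] for p in self.pairs]

    @property
    def on_treatment_samples(self) -> list:
        return [p[1] for p in self.pairs if p[1] is not None]


_TRUTH_FEATURES = {
    "density_CD4_T_stroma": "true_stroma_CD4_T",
    "density_CD8_T_stroma": "true_stroma_CD8_T",
}


def _patient_rng(seed: int, i: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, i, _TP_CODE[stream]])


def generate_cohort(config: CohortConfig) -> CohortResult:
    """Generate paired samples, survival records and the ground-truth table.

    Per patient, baseline immune intensities are the configured means times
    a shared lognormal patient factor (and a small per-phenotype lognormal
    jitter); on-treatment intensities apply the treatment multipliers and
    IFN-gamma rate shifts.  Survival is exponential with hazard
    ``h0 * exp(log_hr * z)`` on the standardized true feature, censored at
    ``censor_time``.
    """
    config.validate()
    seed = config.seed
    pairs = []
    truth_rows = []
    sig = config.patient_density_logsd
    sigp = config.phenotype_density_logsd
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        rng_p = _patient_rng(seed, i, "patient")
        shared = math.exp(rng_p.normal(-0.5 * sig**2, sig)) if sig > 0 else 1.0
        factors = {}
        for phen in IMMUNE_PHENOTYPES:
            jit = math.exp(rng_p.normal(-0.5 * sigp**2, sigp)) if sigp > 0 else 1.0
            factors[phen] = shared * jit
        bl_stroma = {
            p: config.tissue.immune_density_stroma.get(p, 0.0) * factors[p]
            for p in IMMUNE_PHENOTYPES
        }
        bl_tumor = {
            p: config.tissue.immune_density_tumor.get(p, 0.0) * factors[p]
            for p in IMMUNE_PHENOTYPES
        }
        bl_cfg = config.tissue.replace(
            immune_density_stroma=bl_stroma, immune_density_tumor=bl_tumor
        )
        bl = generate_tissue(
            bl_cfg, rng=_patient_rng(seed, i, "baseline"),
            patient_id=pid, timepoint="baseline",
        )
        tx = None
        tx_stroma = {
            p: bl_stroma[p] * config.treatment.density_multipliers.get(p, 1.0)
            for p in IMMUNE_PHENOTYPES
        }
        if config.include_on_treatment:
            tx_tumor = {
                p: bl_tumor[p] * config.treatment.density_multipliers.get(p, 1.0)
                for p in IMMUNE_PHENOTYPES
            }
            rates = {k: dict(v) for k, v in config.tissue.marker_rates.items()}
            for phen, shift in config.treatment.ifng_rate_shift.items():
                base = rates.setdefault(phen, {}).get("IFNG", 0.0)
                rates[phen]["IFNG"] = float(np.clip(base + shift, 0.0, 1.0))
            tx_cfg = config.tissue.replace(
                immune_density_stroma=tx_stroma,
                immune_density_tumor=tx_tumor,
                marker_rates=rates,
            )
            tx = generate_tissue(
                tx_cfg, rng=_patient_rng(seed, i, "on_treatment"),
                patient_id=pid, timepoint="on_treatment",
            )
        pairs.append((bl, tx))
        truth_rows.append(
            {
                "patient_id": pid,
                "patient_factor": shared,
                "true_stroma_CD4_T": bl_stroma["CD4_T"],
                "true_stroma_CD8_T": bl_stroma["CD8_T"],
                "true_tumor_CD4_T": bl_tumor["CD4_T"],
                "true_tumor_CD8_T": bl_tumor["CD8_T"],
                "true_tx_stroma_CD4_T": tx_stroma["CD4_T"],
                "true_tx_stroma_CD8_T": tx_stroma["CD8_T"],
            }
        )
    truth = pd.DataFrame(truth_rows)

    # survival from the designated ground-truth feature
    col = _TRUTH_FEATURES.get(config.hazard.feature)
    if col is None:
        raise ConfigError(
            f"hazard feature {config.hazard.feature!r} not available as ground truth; "
            f"choose one of {sorted(_TRUTH_FEATURES)}"
        )
    f = truth[col].to_numpy(dtype=float)
    if config.hazard.link == "median_split":
        z = np.where(f >= np.median(f), 0.5, -0.5)
    else:
        sd = f.std()
        z = (f - f.mean()) / sd if sd > 0 else np.zeros_like(f)
    hazards = config.hazard.baseline_hazard * np.exp(config.hazard.log_hr * z)
    records = []
    raw_times = np.empty(config.n_patients)
    for i in range(config.n_patients):
        rng_s = _patient_rng(seed, i, "survival")
        t_raw = rng_s.exponential(1.0 / hazards[i])
        raw_times[i] = t_raw
        event = int(t_raw <= config.censor_time)
        records.append(
            SurvivalRecord(
                patient_id=truth.loc[i, "patient_id"],
                os_months=float(min(t_raw, config.censor_time)),
                event=event,
            )
        )
    truth["feature_value"] = f
    truth["feature_z"] = z
    truth["hazard_per_month"] = hazards
    truth["uncensored_months"] = raw_times
    return CohortResult(pairs=pairs, records=records, truth=truth)


# ---------------------------------------------------------------------------
# Config (de)serialization for the CLI
# ---------------------------------------------------------------------------

def tissue_config_from_dict(d: Mapping) -> TissueConfig:
    d = dict(d)
    if "window" in d:
        d["window"] = tuple(float(v) for v in d["window"])
    return TissueConfig(**d)


def cohort_config_from_dict(d: Mapping) -> CohortConfig:
    d = dict(d)
    if "tissue" in d:
        d["tissue"] = tissue_config_from_dict(d["tissue"])
    if "treatment" in d:
        d["treatment"] = TreatmentEffect(**d["treatment"])
    if "hazard" in d:
        d["hazard"] = HazardModel(**d["hazard"])
    return CohortConfig(**d)


def cohort_config_to_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["tissue"]["window"] = list(d["tissue"]["window"])
    return d
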