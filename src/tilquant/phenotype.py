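"""Marker logic: intensity thresholding and named cell phenotypes.

A phenotype is a predicate over the binary marker calls of a cell: a set of
markers that must be positive, a set that must be negative, and optionally a
set of which at least one must be positive (needed for the pan-T-cell
phenotypes such as LAG3+ T = LAG3+ and (CD4+ or CD8+) and PANCK-).  Cells in
excluded regions (necrosis, normal epithelium) never match any phenotype.

Default rule set
----------------
``TUMOR`` = PANCK+; ``CD4_T`` = CD4+ CD8- PANCK-; ``CD8_T`` = CD8+ CD4-
PANCK-; ``LAG3_T`` = LAG3+ (CD4+ or CD8+) PANCK-; marker-refined phenotypes
(``LAG3_CD8_T``, ``KI67_CD4_T``, ...) add one required-positive marker to a
base rule.  CD4+CD8+ double positives are excluded from both subset rules by
default but still counted in ``LAG3_T``; set ``double_positive="include"``
to drop the mutual exclusion.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Cell, ConfigError, TissueSample

#: Immune phenotypes whose positivity rates for these markers are reported.
BASE_T_PHENOTYPES: tuple[str, ...] = ("CD4_T", "CD8_T")
REFINING_MARKERS: tuple[str, ...] = ("LAG3", "KI67", "IFNG")


@dataclass(frozen=True)
class PhenotypeRule:
    """Named marker-logic predicate.

    ``require_positive`` markers must all be positive, ``require_negative``
    all negative, and at least one of ``require_any_positive`` (when
    non-empty) must be positive.
    """

    name: str
    require_positive: frozenset = frozenset()
    require_negative: frozenset = frozenset()
    require_any_positive: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "require_positive", frozenset(self.require_positive))
        object.__setattr__(self, "require_negative", frozenset(self.require_negative))
        object.__setattr__(
            self, "require_any_positive", frozenset(self.require_any_positive)
        )
        if self.require_positive & self.require_negative:
            overlap = sorted(self.require_positive & self.require_negative)
            raise ConfigError(
                f"rule {self.name!r}: markers {overlap} both required positive and negative"
            )

    @property
    def markers(self) -> frozenset:
        return self.require_positive | self.require_negative | self.require_any_positive


def default_rules(double_positive: str = "exclude") -> list[PhenotypeRule]:
    """The standard rule set used throughout the pipeline.

    Parameters
    ----------
    double_positive:
        ``"exclude"`` (default) keeps CD4+CD8+ cells out of both the CD4_T
        and CD8_T subsets (they still count as LAG3_T when LAG3+);
        ``"include"`` counts them in both subsets.
    """
    if double_positive not in ("exclude", "include"):
        raise ConfigError(f"double_positive must be 'exclude' or 'include', got {double_positive!r}")
    cd4_neg = frozenset({"CD8", "PANCK"}) if double_positive == "exclude" else frozenset({"PANCK"})
    cd8_neg = frozenset({"CD4", "PANCK"}) if double_positive == "exclude" else frozenset({"PANCK"})
    rules = [
        PhenotypeRule("TUMOR", require_positive=frozenset({"PANCK"})),
        PhenotypeRule("CD4_T", require_positive=frozenset({"CD4"}), require_negative=cd4_neg),
        PhenotypeRule("CD8_T", require_positive=frozenset({"CD8"}), require_negative=cd8_neg),
        PhenotypeRule(
            "LAG3_T",
            require_positive=frozenset({"LAG3"}),
            require_negative=frozenset({"PANCK"}),
            require_any_positive=frozenset({"CD4", "CD8"}),
        ),
        PhenotypeRule("KI67_TUMOR", require_positive=frozenset({"PANCK", "KI67"})),
    ]
    for marker in REFINING_MARKERS:
        rules.append(
            PhenotypeRule(
                f"{marker}_CD4_T",
                require_positive=frozenset({"CD4", marker}),
                require_negative=cd4_neg,
            )
        )
        rules.append(
            PhenotypeRule(
                f"{marker}_CD8_T",
                require_positive=frozenset({"CD8", marker}),
                require_negative=cd8_neg,
            )
        )
    return rules


def rules_by_name(rules: Iterable[PhenotypeRule]) -> dict[str, PhenotypeRule]:
    out: dict[str, PhenotypeRule] = {}
    for r in rules:
        if r.name in out:
            raise ConfigError(f"duplicate rule name {r.name!r}")
        out[r.name] = r
    return out


@dataclass(frozen=True)
class ThresholdSpec:
    """Per-marker intensity cutoffs; positivity is intensity >= cutoff."""

    cutoffs: dict

    def __post_init__(self):
        for m, c in self.cutoffs.items():
            if not np.isfinite(c) or c < 0:
                raise ConfigError(f"cutoff for {m} must be finite and >= 0, got {c}")


def apply_thresholds(sample: TissueSample, spec: ThresholdSpec) -> TissueSample:
    """Recompute marker positivity from raw intensities.

    The threshold is closed: intensity exactly equal to the cutoff is
    positive.  Markers without a cutoff keep their existing calls.
    """
    out = sample.copy()
    for marker, cutoff in spec.cutoffs.items():
        col = f"{marker}_intensity"
        if col not in out.cells.columns:
            raise ConfigError(f"threshold for {marker} but no column {col!r} in sample")
        out.cells[marker] = (out.cells[col].to_numpy(dtype=float) >= cutoff).astype(np.int8)
    return out


def match_rule(cell: Cell, rule: PhenotypeRule) -> bool:
    """True iff the cell satisfies the rule.  Excluded cells never match."""
    if cell.region == "excluded":
        return False
    for m in rule.markers:
        if m not in cell.markers:
            raise ConfigError(f"rule {rule.name!r} references unknown marker {m!r}")
    if any(not cell.markers[m] for m in rule.require_positive):
        return False
    if any(cell.markers[m] for m in rule.require_negative):
        return False
    if rule.require_any_positive and not any(
        cell.markers[m] for m in rule.require_any_positive
    ):
        return False
    return True


def match_mask(sample: TissueSample, rule: PhenotypeRule) -> np.ndarray:
    """Vectorized :func:`match_rule` over a whole sample (boolean array)."""
    df = sample.cells
    for m in rule.markers:
        if m not in df.columns:
            raise ConfigError(f"rule {rule.name!r} references unknown marker {m!r}")
    mask = (df["region"] != "excluded").to_numpy()
    for m in rule.require_positive:
        mask &= df[m].to_numpy() == 1
    for m in rule.require_negative:
        mask &= df[m].to_numpy() == 0
    if rule.require_any_positive:
        any_pos = np.zeros(len(df), dtype=bool)
        for m in rule.require_any_positive:
            any_pos |= df[m].to_numpy() == 1
        mask &= any_pos
    return mask


def phenotype_counts(
    sample: TissueSample, rules: Sequence[PhenotypeRule]
) -> pd.DataFrame:
    """Count matching cells per phenotype per region (tumor, stroma).

    A cell may contribute to several phenotypes (e.g. both ``CD8_T`` and
    ``LAG3_CD8_T``); excluded cells contribute to none.
    """
    region = sample.cells["region"].to_numpy() if len(sample.cells) else np.array([])
    data = {}
    for rule in rules:
        mask = match_mask(sample, rule)
        data[rule.name] = {
            "tumor": int((mask & (region == "tumor")).sum()),
            "stroma": int((mask & (region == "stroma")).sum()),
        }
    out = pd.DataFrame.from_dict(data, orient="index", columns=["tumor", "stroma"])
    out.index.name = "phenotype"
    return out


def annotate_phenotypes(
    sample: TissueSample, rules: Sequence[PhenotypeRule]
) -> pd.DataFrame:
    """Cell table with one extra 0/1 column per phenotype rule."""
    df = sample.cells.copy()
    for rule in rules:
        df[rule.name] = match_mask(sample, rule).astype(np.int8)
    return df
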