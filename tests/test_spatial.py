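"""Spatial metrics: densities, positivity, NN distances, neighbor counts."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from tilquant.model import ValidationError
from tilquant.spatial import (
    density,
    nearest_distances,
    neighbor_counts,
    paired_change,
    positivity_rate,
    summarize_sample,
)
from tilquant.phenotype import default_rules, match_mask, rules_by_name

from conftest import make_sample, random_sample


class TestDensity:
    def test_hundred_cells_two_mm2(self):
        # 2 mm^2 window = 2e6 um^2
        n = 100
        sample = make_sample(
            np.linspace(10, 1990, n), np.full(n, 500.0),
            CD4=np.ones(n, dtype=int), window=(0, 0, 2000, 1000),
        )
        assert density(sample, "CD4_T", "all") == pytest.approx(50.0)

    def test_zero_cells_zero_density(self):
        sample = make_sample([], [], window=(0, 0, 1000, 1000))
        assert density(sample, "CD8_T", "all") == 0.0

    def test_zero_area_is_missing(self):
        sample = make_sample([5.0], [5.0], window=(0, 0, 1000, 1000))
        assert math.isnan(density(sample, "TUMOR", "tumor"))


class TestPositivity:
    def test_four_of_eight(self):
        sample = make_sample(
            np.arange(8), np.arange(8),
            CD8=[1] * 8, LAG3=[1, 1, 1, 1, 0, 0, 0, 0],
        )
        assert positivity_rate(sample, "CD8_T", "LAG3") == pytest.approx(50.0)

    def test_empty_base_is_missing_not_zero(self):
        sample = make_sample([1.0], [1.0], CD4=[1])
        assert math.isnan(positivity_rate(sample, "CD8_T", "LAG3"))


class TestNearestDistances:
    def test_three_four_five_triangle(self):
        sample = make_sample(
            [0.0, 3.0, 6.0], [0.0, 4.0, 8.0],
            PANCK=[1, 0, 0], CD4=[0, 1, 1],
        )
        res = nearest_distances(sample, "TUMOR", "CD4_T")
        assert res.per_center[0] == pytest.approx(5.0)

    def test_no_neighbors_is_missing(self):
        sample = make_sample([1.0], [1.0], PANCK=[1])
        res = nearest_distances(sample, "TUMOR", "CD4_T")
        assert res.is_missing and math.isnan(res.mean)

    def test_cell_is_never_its_own_neighbor(self):
        # the only LAG3+CD4 T cell is also the only center candidate
        sample = make_sample(
            [0.0, 10.0], [0.0, 0.0], CD4=[1, 1], LAG3=[1, 0]
        )
        res = nearest_distances(sample, "CD4_T", "LAG3_CD4_T")
        assert res.per_center[1] == pytest.approx(10.0)
        # the sole LAG3+ cell has no *other* LAG3+ neighbor: undefined
        assert math.isnan(res.per_center[0])
        assert res.mean == pytest.approx(10.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            sample = random_sample(rng, int(rng.integers(5, 500)))
            res = nearest_distances(sample, "TUMOR", "CD8_T")
            c = match_mask(sample, rules_by_name(default_rules())["TUMOR"])
            n = match_mask(sample, rules_by_name(default_rules())["CD8_T"])
            if c.sum() == 0 or n.sum() == 0:
                assert res.is_missing
                continue
            xy = sample.cells[["x_um", "y_um"]].to_numpy(float)
            d = cdist(xy[c], xy[n])
            same = np.equal.outer(np.flatnonzero(c), np.flatnonzero(n))
            d[same] = np.inf
            expected = d.min(axis=1)
            expected[np.isinf(expected)] = np.nan  # self-only neighbor set
            assert np.allclose(
                res.per_center, expected, rtol=0, atol=0, equal_nan=True
            )


class TestNeighborCounts:
    def test_radius_cutoff(self):
        sample = make_sample(
            [0.0, 10.0, 60.0], [0.0, 0.0, 0.0],
            PANCK=[1, 0, 0], CD4=[0, 1, 1],
        )
        res = neighbor_counts(sample, "TUMOR", "CD4_T", radius=50.0)
        assert res.per_center[0] == 1

    def test_no_neighbor_cells_mean_zero(self):
        sample = make_sample([1.0, 2.0], [1.0, 2.0], PANCK=[1, 1])
        res = neighbor_counts(sample, "TUMOR", "CD4_T")
        assert res.mean == 0.0 and not res.is_missing

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            sample = random_sample(rng, int(rng.integers(5, 400)), size=300.0)
            radius = float(rng.uniform(20, 120))
            res = neighbor_counts(sample, "TUMOR", "CD4_T", radius=radius)
            c = match_mask(sample, rules_by_name(default_rules())["TUMOR"])
            n = match_mask(sample, rules_by_name(default_rules())["CD4_T"])
            if c.sum() == 0:
                assert res.is_missing
                continue
            xy = sample.cells[["x_um", "y_um"]].to_numpy(float)
            d = cdist(xy[c], xy[n]) if n.sum() else np.empty((c.sum(), 0))
            same = np.equal.outer(np.flatnonzero(c), np.flatnonzero(n))
            counts = ((d <= radius) & ~same).sum(axis=1)
            assert (res.per_center == counts).all()

    def test_counts_nondecreasing_in_radius(self, rng):
        sample = random_sample(rng, 200, size=400.0)
        means = [
            neighbor_counts(sample, "TUMOR", "CD8_T", radius=r).mean
            for r in (10, 25, 50, 100, 200)
        ]
        assert all(b >= a for a, b in zip(means, means[1:]))


class TestRigidInvariance:
    def test_translation_rotation_leave_metrics_unchanged(self, rng):
        sample = random_sample(rng, 150, size=500.0)
        base_nd = nearest_distances(sample, "TUMOR", "CD4_T")
        base_nc = neighbor_counts(sample, "TUMOR", "CD4_T")
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        xy = sample.cells[["x_um", "y_um"]].to_numpy(float) @ rot.T + [800.0, 300.0]
        moved = sample.copy()
        moved.cells["x_um"] = xy[:, 0]
        moved.cells["y_um"] = xy[:, 1]
        nd = nearest_distances(moved, "TUMOR", "CD4_T")
        nc = neighbor_counts(moved, "TUMOR", "CD4_T")
        assert np.allclose(nd.per_center, base_nd.per_center, rtol=1e-9)
        assert (nc.per_center == base_nc.per_center).all()


class TestSummary:
    def test_empty_sample_counts_zero_rates_missing(self):
        summary = summarize_sample(make_sample([], [], window=(0, 0, 1000, 1000)))
        assert summary.metrics["density_CD4_T_all"] == 0.0
        assert math.isnan(summary.metrics["pct_LAG3_in_CD8_T_all"])
        assert summary.diagnostics  # missingness is reported

    def test_summary_equals_single_metric_calls(self, rng):
        sample = random_sample(rng, 300)
        summary = summarize_sample(sample)
        assert summary.metrics["density_CD4_T_stroma"] == density(
            sample, "CD4_T", "stroma"
        )
        assert summary.metrics["pct_LAG3_in_CD8_T_tumor"] == positivity_rate(
            sample, "CD8_T", "LAG3", "tumor"
        )
        nd = nearest_distances(sample, "TUMOR", "CD8_T")
        assert summary.metrics["nndist_mean_CD8_T"] == nd.mean
        nc = neighbor_counts(sample, "TUMOR", "LAG3_T")
        assert summary.metrics["ncount_mean_LAG3_T"] == nc.mean


class TestPairedChange:
    def _summary(self, pid, dens):
        from tilquant.spatial import SpatialSummary

        return SpatialSummary(
            patient_id=pid, timepoint="baseline",
            metrics={"density_CD4_T_stroma": dens}, radius=50.0,
        )

    def test_simple_ratio(self):
        pc = paired_change(self._summary("P1", 100.0), self._summary("P1", 50.0))
        assert pc.ratios["density_CD4_T_stroma"] == pytest.approx(0.5)

    def test_zero_baseline_is_missing(self):
        pc = paired_change(self._summary("P1", 0.0), self._summary("P1", 50.0))
        assert math.isnan(pc.ratios["density_CD4_T_stroma"])

    def test_patient_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            paired_change(self._summary("P1", 1.0), self._summary("P2", 1.0))
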