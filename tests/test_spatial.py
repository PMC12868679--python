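import numpy as np
import pandas as pd
import pytest
from scipy.spatial import ConvexHull

from metatme.core import ValidationError
from metatme.spatial import (
    edge_cells,
    gcross_auc,
    interaction_zscore,
    jsd,
    kde_pmf,
)


def brute_force_gcross_auc(ref, tgt, r_max=150.0, exclude_self=False):
    """All-pairs nearest-neighbor oracle for the G-Cross AUC."""
    d = np.sqrt(((ref[:, None, :] - tgt[None, :, :]) ** 2).sum(axis=2))
    if exclude_self:
        np.fill_diagonal(d, np.inf)
    nnd = d.min(axis=1)
    return float(np.mean(r_max - np.minimum(nnd, r_max)) / r_max)


class TestGCross:
    def test_single_pair_analytic(self):
        res = gcross_auc(np.array([[0.0, 0.0]]), np.array([[50.0, 0.0]]))
        assert res.auc == pytest.approx((150 - 50) / 150, abs=1e-15)

    def test_coincident_sets_auc_one(self, rng):
        pts = rng.uniform(0, 500, (40, 2))
        assert gcross_auc(pts, pts.copy()).auc == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            a = rng.uniform(0, 600, (200, 2))
            b = rng.uniform(0, 600, (200, 2))
            res = gcross_auc(a, b)
            assert abs(res.auc - brute_force_gcross_auc(a, b)) < 1e-12

    def test_cdf_monotone_and_bounded(self, rng):
        res = gcross_auc(rng.uniform(0, 600, (100, 2)), rng.uniform(0, 600, (80, 2)))
        assert (np.diff(res.cdf) >= 0).all()
        assert res.cdf.min() >= 0 and res.cdf.max() <= 1
        assert 0 <= res.auc <= 1

    def test_empty_sets_give_null(self):
        res = gcross_auc(np.empty((0, 2)), np.array([[1.0, 1.0]]))
        assert res.auc is None
        res = gcross_auc(np.array([[1.0, 1.0]]), np.empty((0, 2)))
        assert res.auc is None

    def test_self_pairs_excluded_same_phenotype(self, rng):
        pts = rng.uniform(0, 300, (50, 2))
        res = gcross_auc(pts, pts, exclude_self=True)
        oracle = brute_force_gcross_auc(pts, pts, exclude_self=True)
        assert res.auc == pytest.approx(oracle, abs=1e-12)
        assert res.auc < 1.0

    def test_rigid_motion_invariance(self, rng):
        a = rng.uniform(0, 300, (60, 2))
        b = rng.uniform(0, 300, (60, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        shift = np.array([123.0, -45.0])
        res0 = gcross_auc(a, b)
        res1 = gcross_auc(a @ rot.T + shift, b @ rot.T + shift)
        assert res0.auc == pytest.approx(res1.auc, abs=1e-9)


class TestEdgeCells:
    def _frame(self, pts, region="r"):
        return pd.DataFrame({
            "core_id": "c0",
            "x_um": pts[:, 0], "y_um": pts[:, 1],
            "cn2_label": region,
        })

    def test_square_grid_perimeter(self):
        xs, ys = np.meshgrid(np.arange(5.0), np.arange(5.0))
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        cells = self._frame(pts)
        flags = edge_cells(cells, view="cn2_label")
        on_perimeter = (
            (pts[:, 0] == 0) | (pts[:, 0] == 4) | (pts[:, 1] == 0) | (pts[:, 1] == 4)
        )
        assert flags.sum() == 16
        assert (flags.to_numpy() == on_perimeter).all()

    def test_large_alpha_matches_convex_hull(self, rng):
        pts = rng.uniform(0, 100, (120, 2))
        cells = self._frame(pts)
        flags = edge_cells(cells, view="cn2_label", alpha=1e6)
        hull = set(ConvexHull(pts).vertices)
        assert set(np.where(flags.to_numpy())[0]) == hull

    def test_concave_region_beats_convex_hull(self, rng):
        # C-shape: ring segment; inner-arc points are boundary for the alpha
        # shape but interior to the convex hull
        theta = rng.uniform(0.25 * np.pi, 1.75 * np.pi, 800)
        r = rng.uniform(60, 100, 800)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        cells = self._frame(pts)
        flags = edge_cells(cells, view="cn2_label", alpha=25.0)
        hull = set(ConvexHull(pts).vertices)
        inner = np.where((np.hypot(pts[:, 0], pts[:, 1]) < 65) & flags.to_numpy())[0]
        assert len(set(inner) - hull) > 10

    def test_collinear_region_all_boundary(self):
        pts = np.column_stack([np.arange(6.0), np.zeros(6)])
        flags = edge_cells(self._frame(pts), view="cn2_label")
        assert flags.all()

    def test_tiny_region_skipped(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        flags = edge_cells(self._frame(pts), view="cn2_label")
        assert not flags.any()


class TestJsd:
    def test_identical_sets_zero(self, rng):
        pts = rng.uniform(0, 500, (80, 2))
        assert jsd(pts, pts.copy()).distance <= 1e-9

    def test_symmetry(self, rng):
        a = rng.uniform(0, 500, (60, 2))
        b = rng.uniform(0, 500, (60, 2))
        assert jsd(a, b).distance == pytest.approx(jsd(b, a).distance, abs=1e-12)

    def test_separated_clusters_near_one(self, rng):
        a = rng.normal(0, 10, (100, 2))
        b = rng.normal(0, 10, (100, 2)) + np.array([500.0, 0.0])
        assert jsd(a, b, bandwidth=20.0).distance >= 0.99

    def test_monotone_under_separation_sweep(self, rng):
        a = rng.normal(0, 15, (80, 2))
        base = rng.normal(0, 15, (80, 2))
        prev = -1.0
        for shift in (0.0, 50.0, 100.0, 200.0, 400.0):
            d = jsd(a, base + np.array([shift, 0.0]), bandwidth=20.0).distance
            assert d >= prev - 1e-9
            prev = d

    def test_too_few_points_null(self, rng):
        assert jsd(rng.uniform(0, 10, (1, 2)), rng.uniform(0, 10, (5, 2))).distance is None

    def test_bounds(self, rng):
        for _ in range(5):
            a = rng.uniform(0, 200, (30, 2))
            b = rng.uniform(0, 200, (30, 2))
            d = jsd(a, b).distance
            assert 0.0 <= d <= 1.0

    def test_translation_invariance(self, rng):
        a = rng.uniform(0, 200, (50, 2))
        b = rng.uniform(0, 200, (50, 2))
        shift = np.array([1000.0, -400.0])
        d0 = jsd(a, b, bandwidth=15.0).distance
        d1 = jsd(a + shift, b + shift, bandwidth=15.0).distance
        assert d0 == pytest.approx(d1, abs=1e-9)


class TestInteractionZscore:
    def test_random_labels_null_calibrated(self):
        flagged = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            xy = r.uniform(0, 600, (300, 2))
            labels = r.choice(["a", "b"], size=300)
            z = interaction_zscore(xy, labels, ("a", "b"), n_perm=100, seed=seed)
            flagged += abs(z) >= 3
        assert flagged <= 1

    def test_constructed_enrichment_large_z(self, rng):
        a = rng.uniform(100, 500, (40, 2))
        b = a + rng.normal(scale=10.0, size=(40, 2))  # B hugs A within ~50 um
        far = rng.uniform(2000, 3000, (200, 2))
        xy = np.vstack([a, b, far])
        labels = np.array(["a"] * 40 + ["b"] * 40 + ["c"] * 200)
        z = interaction_zscore(xy, labels, ("a", "b"), n_perm=200, seed=0)
        assert z > 5

    def test_zero_permutations_rejected(self, rng):
        xy = rng.uniform(0, 100, (10, 2))
        labels = np.array(["a", "b"] * 5)
        with pytest.raises(ValidationError):
            interaction_zscore(xy, labels, ("a", "b"), n_perm=0)

    def test_absent_phenotype_null(self, rng):
        xy = rng.uniform(0, 100, (10, 2))
        labels = np.array(["a"] * 10)
        assert interaction_zscore(xy, labels, ("a", "b"), n_perm=10) is None


def test_kde_pmf_normalized(rng):
    pts = rng.uniform(0, 100, (50, 2))
    pmf = kde_pmf(pts, np.linspace(-30, 130, 64), np.linspace(-30, 130, 64), 10.0)
    assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
    assert (pmf >= 0).all()
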