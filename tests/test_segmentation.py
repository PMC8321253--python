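import numpy as np
import pytest
from scipy import stats

from mwiseg import (PermittivityImage, RegionMask, SegmentationParams, Tissue,
                    cluster_once, component_images, ecdf, iterate_segmentation,
                    ks_two_sample, map_clusters, prepare_field,
                    segment_components)
from mwiseg.segmentation import ClusterLabeling


def make_field(values_2d, roi_grid=None, sentinel=-100.0):
    arr = np.asarray(values_2d, dtype=float)
    grid = (np.ones_like(arr, dtype=np.uint8) if roi_grid is None
            else np.asarray(roi_grid, dtype=np.uint8))
    return prepare_field(arr, RegionMask(grid, 1.0), sentinel=sentinel)


def plateau_field():
    """ROI with three well-separated constant plateaus over a sentinel
    background: the tumor plateau is far from the two lower ones."""
    yy, xx = np.mgrid[:40, :40]
    rr = np.hypot(xx - 19.5, yy - 19.5)
    img = np.full((40, 40), 10.0)
    img[rr < 12] = 15.0
    img[rr < 5] = 60.0
    return make_field(img, (rr < 16).astype(np.uint8))


class TestEcdf:
    def test_midpoint_fraction(self):
        assert ecdf([1, 2, 3, 4])(2.5) == 0.5

    def test_constant_sample_single_step(self):
        e = ecdf([7, 7, 7])
        assert e(6.999) == 0.0 and e(7.0) == 1.0

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(4)
        sample = rng.uniform(size=50)
        e = ecdf(sample)
        for q in rng.uniform(-0.1, 1.1, size=100):
            assert e(q) == np.sum(sample <= q) / 50

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            ecdf([])


class TestKsTwoSample:
    def test_identical_samples_not_rejected(self):
        r = ks_two_sample([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert r.statistic == 0.0 and not r.rejected and r.p_value == 1.0

    def test_disjoint_supports_statistic_one(self):
        assert ks_two_sample([0, 0, 0], [1, 1, 1]).statistic == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_statistic_equals_brute_force_sup(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=int(rng.integers(3, 51)))
        b = rng.normal(rng.uniform(-1, 1), size=int(rng.integers(3, 51)))
        r = ks_two_sample(a, b)
        pooled = np.concatenate([a, b])
        ea, eb = ecdf(a), ecdf(b)
        brute = max(abs(ea(x) - eb(x)) for x in pooled)
        assert r.statistic == brute

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_scipy_statistic_and_decision(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.normal(size=400)
        b = rng.normal(0.5 * (seed % 2), size=350)
        r = ks_two_sample(a, b, alpha=0.01)
        s = stats.ks_2samp(a, b, method="asymp")
        assert np.isclose(r.statistic, s.statistic, rtol=0, atol=1e-12)
        # both formulations must agree on clear-cut decisions
        if min(r.p_value, s.pvalue) > 0.05 or max(r.p_value, s.pvalue) < 0.005:
            assert r.rejected == (s.pvalue < 0.01)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            ks_two_sample([], [1.0])


class TestClusterOnce:
    def test_separated_triplet_centroids(self):
        field = make_field([[-100.0, -100.0, 0.0, 0.0, 10.0, 10.0]],
                           [[0, 0, 1, 1, 1, 1]])
        lab = cluster_once(field, k=3, restarts=5, seed=0)
        np.testing.assert_allclose(lab.centroids, [-100.0, 0.0, 10.0])
        # ascending labels: background is cluster 1
        assert set(lab.labels[0, :2]) == {1}

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        field = make_field(rng.uniform(size=(10, 10)))
        a = cluster_once(field, 4, restarts=6, seed=9)
        b = cluster_once(field, 4, restarts=6, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.objective == b.objective

    def test_selected_objective_is_best_restart(self):
        rng = np.random.default_rng(6)
        field = make_field(rng.uniform(size=(8, 8)))
        lab = cluster_once(field, 5, restarts=12, seed=2)
        assert lab.objective <= lab.restart_objectives.min() + 1e-12
        assert lab.restart_objectives.size == 12

    def test_every_label_occupied_and_centroids_sorted(self):
        rng = np.random.default_rng(7)
        field = make_field(rng.normal(size=(12, 12)))
        lab = cluster_once(field, 6, restarts=4, seed=1)
        assert set(np.unique(lab.labels)) == set(range(1, 7))
        assert np.all(np.diff(lab.centroids) >= 0)

    def test_unclusterable_when_k_exceeds_distinct_values(self):
        field = make_field([[1.0, 1.0, 2.0, 2.0]])
        with pytest.raises(ValueError, match="unclusterable"):
            cluster_once(field, k=3, restarts=2, seed=0)


class TestIterateSegmentation:
    def test_three_plateaus_terminate_at_k4(self):
        lab, history = iterate_segmentation(plateau_field(), seed=3)
        assert history.final_k == 4 and lab.k == 4
        assert history.terminated_cleanly()
        # first refinement record carries both KS results
        assert history.records[0].ks_tumor is None
        assert history.records[1].ks_tumor is not None

    def test_final_cluster_count_equals_final_k(self, default_truth, default_roi):
        comp = component_images(default_truth.image)["real"]
        lab, history = iterate_segmentation(
            prepare_field(comp, default_roi), seed=0)
        assert len(np.unique(lab.labels)) == history.final_k
        ks = [rec.k for rec in history.records]
        assert ks == list(range(3, history.final_k + 1))

    def test_uniform_noise_roi_terminates_with_predicate(self):
        rng = np.random.default_rng(8)
        yy, xx = np.mgrid[:50, :50]
        roi = (np.hypot(xx - 24.5, yy - 24.5) <= 20).astype(np.uint8)
        img = rng.uniform(0, 1, size=(50, 50))
        lab, history = iterate_segmentation(make_field(img, roi), seed=1)
        last = history.records[-1]
        assert last.ks_tumor.p_value >= 0.01
        assert last.ks_complement.p_value >= 0.01

    def test_background_conservation_each_iteration(self, default_truth,
                                                    default_roi):
        comp = component_images(default_truth.image)["real"]
        field = prepare_field(comp, default_roi)
        _, history = iterate_segmentation(field, seed=0)
        background = ~default_roi.as_bool()
        for rec in history.records:
            np.testing.assert_array_equal(rec.labeling.labels == 1, background)


class TestMapClusters:
    @staticmethod
    def labeling_with_k(kmax):
        labels = np.tile(np.arange(1, kmax + 1), (2, 1))
        return ClusterLabeling(labels=labels,
                               centroids=np.arange(kmax, dtype=float),
                               k=kmax, objective=0.0,
                               restart_objectives=np.zeros(1))

    def test_mid_cluster_maps_to_fibroglandular(self):
        seg = map_clusters(self.labeling_with_k(10))
        assert seg.labels[0, 6] == Tissue.FIBROGLANDULAR  # cluster 7 of 10

    def test_full_mapping_at_k10(self):
        seg = map_clusters(self.labeling_with_k(10))
        expected = ([Tissue.BACKGROUND, Tissue.FATTY, Tissue.TRANSITION,
                     Tissue.TRANSITION] + [Tissue.FIBROGLANDULAR] * 5
                    + [Tissue.MALIGNANT])
        assert [Tissue(v) for v in seg.labels[0]] == expected

    def test_single_iteration_special_case(self):
        seg = map_clusters(self.labeling_with_k(4))
        assert [Tissue(v) for v in seg.labels[0]] == [
            Tissue.BACKGROUND, Tissue.FATTY, Tissue.FIBROGLANDULAR,
            Tissue.MALIGNANT]

    def test_k5_empty_fibroglandular_warns(self):
        with pytest.warns(UserWarning, match="fibroglandular"):
            seg = map_clusters(self.labeling_with_k(5))
        present = {Tissue(v) for v in seg.labels.ravel()}
        assert present == {Tissue.BACKGROUND, Tissue.FATTY,
                           Tissue.TRANSITION, Tissue.MALIGNANT}

    def test_k3_rejected(self):
        with pytest.raises(ValueError, match="max\\(k\\) >= 4"):
            map_clusters(self.labeling_with_k(3))


class TestSegmentComponents:
    def test_purely_real_image_real_equals_magnitude(self, default_truth,
                                                     default_roi):
        img = PermittivityImage(default_truth.image.real_part,
                                np.zeros(default_truth.image.shape),
                                default_truth.image.pixel_spacing_mm)
        # the all-zero loss component is constant, hence unclusterable
        out = segment_components(
            img, default_roi,
            SegmentationParams(seed=2, components=("real", "magnitude")))
        np.testing.assert_array_equal(out["real"][0].labels,
                                      out["magnitude"][0].labels)

    def test_three_components_with_histories(self, default_truth, default_roi):
        out = segment_components(default_truth.image, default_roi,
                                 SegmentationParams(seed=2))
        assert set(out) == {"real", "imaginary", "magnitude"}
        for seg, history in out.values():
            assert history.final_k >= 4
            assert seg.labels.shape == default_truth.image.shape

    def test_components_agree_on_tumor(self, default_truth, default_roi):
        out = segment_components(default_truth.image, default_roi,
                                 SegmentationParams(seed=2))
        masks = [seg.mask(Tissue.MALIGNANT) for seg, _ in out.values()]
        for other in masks[1:]:
            inter = (masks[0] & other).sum()
            dice = 2 * inter / (masks[0].sum() + other.sum())
            assert dice >= 0.9
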