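import numpy as np
import pytest

import selfloc as sl
from selfloc.datatypes import AcquisitionParams, ROIMask, TrialResponseMatrix
from selfloc.searchlight import (
    ClassifierSpec,
    SearchlightDecoder,
    aggregate_voxelwise,
    build_clusters,
    loro_decode,
)
from _oracle import naive_clusters, naive_searchlight_map

ACQ = AcquisitionParams()


def _random_resp(seed, n_vox=12, trials_per_run=20, n_runs=5, coords=None):
    rng = np.random.default_rng(seed)
    n = trials_per_run * n_runs
    labels = np.concatenate([
        rng.permutation(np.array(["A", "B"]).repeat(trials_per_run // 2))
        for _ in range(n_runs)
    ])
    if coords is None:
        coords = np.argwhere(np.ones((n_vox, 1, 1), bool))
    return TrialResponseMatrix(
        values=rng.normal(size=(n, len(coords))),
        labels=labels,
        runs=np.repeat(np.arange(n_runs), trials_per_run),
        condition=np.array(["SYNCHRONOUS"] * n),
        voxel_index_map=coords,
    )


class TestClusters:
    def test_k1_is_own_center(self):
        mask = ROIMask(np.ones((3, 3, 2), bool), np.eye(4))
        cs = build_clusters(mask, ACQ, 1)
        assert np.array_equal(cs.members[:, 0], np.arange(18))

    def test_matches_bruteforce_at_k33(self):
        rng = np.random.default_rng(0)
        mask = ROIMask(rng.random((7, 6, 5)) > 0.35, np.eye(4))
        cs = build_clusters(mask, ACQ, 33)
        oracle = naive_clusters(mask.voxel_coords(), ACQ.voxel_size_mm, 33)
        for v in range(cs.n_clusters):
            assert list(cs.members[v]) == oracle[v]

    def test_anisotropic_metric(self):
        # 2 steps along x (3.0 mm) closer than 2 steps along z (3.6 mm)
        data = np.zeros((5, 1, 5), bool)
        data[2, 0, 2] = data[4, 0, 2] = data[2, 0, 4] = True
        cs = build_clusters(ROIMask(data, np.eye(4)), ACQ, 2)
        coords = cs.voxel_index_map
        center = int(np.flatnonzero((coords == [2, 0, 2]).all(1))[0])
        x_neighbor = int(np.flatnonzero((coords == [4, 0, 2]).all(1))[0])
        assert list(cs.members[center]) == [center, x_neighbor]

    def test_small_roi_uses_whole_roi(self):
        mask = ROIMask(np.ones((2, 2, 2), bool), np.eye(4))
        cs = build_clusters(mask, ACQ, 33)
        assert cs.k == 8
        for v in range(8):
            assert set(cs.members[v]) == set(range(8))

    def test_every_cluster_contains_center(self, null_responses):
        _, cs = null_responses
        for v in range(cs.n_clusters):
            assert cs.members[v, 0] == v  # nearest neighbor is itself


class TestLoroDecode:
    def test_separable_patterns_decode_perfectly(self):
        resp = _random_resp(0)
        y = resp.y_signed()
        resp.values[:, :4] += np.outer(y, [3, -3, 3, -3])
        assert loro_decode(resp) == 100.0

    def test_chance_under_null(self):
        accs = [loro_decode(_random_resp(s)) for s in range(50)]
        assert abs(np.mean(accs) - 50.0) <= 3.0

    def test_fold_mean_is_unweighted(self):
        # decoding is perfect in every fold regardless of fold size, so
        # corrupting one run's labels moves the mean by exactly 1/R of
        # that fold's drop
        resp = _random_resp(1)
        y = resp.y_signed()
        resp.values[:] = np.outer(y, np.ones(resp.n_voxels)) * 3
        assert loro_decode(resp) == 100.0
        flipped = resp.labels.copy()
        mask = resp.runs == 0
        flipped[mask] = np.where(flipped[mask] == "A", "B", "A")
        resp2 = TrialResponseMatrix(resp.values, flipped, resp.runs,
                                    resp.condition, resp.voxel_index_map)
        # fold 0 scores 0 against its flipped labels, the other four 100;
        # the unweighted fold mean is exactly 80
        assert loro_decode(resp2) == pytest.approx(80.0)

    def test_needs_two_runs_and_both_classes(self):
        resp = _random_resp(2)
        one_run = TrialResponseMatrix(resp.values[:20], resp.labels[:20],
                                      np.zeros(20, int), resp.condition[:20],
                                      resp.voxel_index_map)
        with pytest.raises(ValueError, match="2 runs"):
            loro_decode(one_run)
        single = resp.labels.copy()
        single[resp.runs != 0] = "A"
        bad = TrialResponseMatrix(resp.values, single, resp.runs,
                                  resp.condition, resp.voxel_index_map)
        with pytest.raises(ValueError, match="class"):
            loro_decode(bad)


class TestMap:
    def test_voxelwise_is_mean_of_covering_clusters(self, null_responses):
        resp, clusters = null_responses
        amap = sl.map_locally_multivariate(resp.restrict("SYNCHRONOUS"), clusters)
        v = 7
        cov = clusters.cover[v]
        assert amap.voxelwise_accuracy[v] == pytest.approx(
            amap.cluster_accuracies[cov].mean()
        )
        # bounded by covering cluster accuracies
        lo = np.array([amap.cluster_accuracies[c].min() for c in clusters.cover])
        hi = np.array([amap.cluster_accuracies[c].max() for c in clusters.cover])
        assert (amap.voxelwise_accuracy >= lo - 1e-12).all()
        assert (amap.voxelwise_accuracy <= hi + 1e-12).all()
        assert amap.peak_accuracy == amap.voxelwise_accuracy.max()

    def test_k1_map_equals_cluster_map(self):
        resp = _random_resp(3)
        mask = ROIMask(np.ones((12, 1, 1), bool), np.eye(4))
        clusters = build_clusters(mask, ACQ, 1)
        amap = sl.map_locally_multivariate(resp, clusters)
        assert np.array_equal(amap.voxelwise_accuracy, amap.cluster_accuracies)

    def test_map_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(4)
        mask_data = rng.random((5, 4, 3)) > 0.4
        mask_data[0, 0, 0] = True
        mask = ROIMask(mask_data, np.eye(4))
        coords = mask.voxel_coords()
        resp = _random_resp(4, coords=coords)
        clusters = build_clusters(mask, ACQ, 7)
        amap = sl.map_locally_multivariate(resp, clusters)
        vox, cl = naive_searchlight_map(resp.values, resp.y_signed(), resp.runs,
                                        coords, ACQ.voxel_size_mm, 7)
        assert np.array_equal(amap.cluster_accuracies, cl)
        assert np.array_equal(amap.voxelwise_accuracy, vox)

    def test_trial_order_invariance(self, null_responses):
        # exchangeability sanity: reordering trials (labels move with
        # them) leaves every accuracy unchanged; asserted at a tight
        # optimization tolerance where the SMO path dependence vanishes
        resp, clusters = null_responses
        sy = resp.restrict("SYNCHRONOUS")
        spec = ClassifierSpec(tol=1e-6)
        amap = sl.map_locally_multivariate(sy, clusters, spec)
        rng = np.random.default_rng(0)
        perm = rng.permutation(sy.n_trials)
        shuffled = TrialResponseMatrix(sy.values[perm], sy.labels[perm],
                                       sy.runs[perm], sy.condition[perm],
                                       sy.voxel_index_map)
        amap2 = sl.map_locally_multivariate(shuffled, clusters, spec)
        assert np.array_equal(amap.voxelwise_accuracy, amap2.voxelwise_accuracy)


class TestEstimatorProtocol:
    def test_fit_attributes_and_params(self, null_responses):
        resp, clusters = null_responses
        sy = resp.restrict("SYNCHRONOUS")
        dec = SearchlightDecoder(clusters=clusters, C=1.0)
        assert dec.get_params()["C"] == 1.0
        dec.set_params(C=1.0)
        dec.fit(sy.values, sy.labels, groups=sy.runs)
        assert dec.voxelwise_accuracy_.shape == (sy.n_voxels,)
        assert 0 <= dec.peak_accuracy_ <= 100
        assert list(dec.classes_) == ["A", "B"]

    def test_fit_requires_groups_and_clusters(self, null_responses):
        resp, clusters = null_responses
        sy = resp.restrict("SYNCHRONOUS")
        with pytest.raises(ValueError, match="groups"):
            SearchlightDecoder(clusters=clusters).fit(sy.values, sy.labels)
        with pytest.raises(ValueError, match="clusters"):
            SearchlightDecoder().fit(sy.values, sy.labels, groups=sy.runs)


class TestCrossCondition:
    def _subject_maps(self, seed, **kw):
        spec = sl.SimulationSpec(seed=seed, **kw)
        subj = sl.generate_subject(spec)
        from selfloc.preprocess import preprocess_subject
        resp = preprocess_subject(subj.volume, subj.roi, subj.trials,
                                  spec.acquisition, sl.PreprocConfig())
        clusters = sl.build_clusters(subj.roi, spec.acquisition, 15)
        within = sl.map_locally_multivariate(resp.restrict("SYNCHRONOUS"), clusters)
        cross = sl.cross_condition_decode(resp.restrict("SYNCHRONOUS"),
                                          resp.restrict("ASYNCHRONOUS"), clusters)
        return within, cross

    def test_shared_patterns_generalize(self):
        d = []
        for s in range(10):
            w, c = self._subject_maps(s, async_has_location_signal=True)
            d.append(c.cluster_accuracies.mean() - w.cluster_accuracies.mean())
        assert abs(np.mean(d)) <= 5.0

    def test_no_async_signal_gives_chance_transfer(self):
        means = []
        for s in range(20):
            _, c = self._subject_maps(s)
            means.append(c.cluster_accuracies.mean())
        assert abs(np.mean(means) - 50.0) <= 3.0

    def test_swapped_patterns_anti_learn(self):
        d = []
        for s in range(10):
            w, c = self._subject_maps(s, async_has_location_signal=True,
                                      async_swap_locations=True)
            d.append(c.cluster_accuracies.mean() - (100 - w.cluster_accuracies.mean()))
        assert abs(np.mean(d)) <= 5.0

    def test_run_mismatch_rejected(self, null_responses):
        resp, clusters = null_responses
        sy = resp.restrict("SYNCHRONOUS")
        asy = resp.restrict("ASYNCHRONOUS")
        bad = TrialResponseMatrix(asy.values, asy.labels, asy.runs + 10,
                                  asy.condition, asy.voxel_index_map)
        with pytest.raises(ValueError, match="runs"):
            sl.cross_condition_decode(sy, bad, clusters)
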