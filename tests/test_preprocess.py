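import numpy as np
import pytest

import selfloc as sl
from selfloc.datatypes import AcquisitionParams, ROIMask, Volume4D
from selfloc.preprocess import (
    PreprocConfig,
    detrend_linear,
    discard_initial_volumes,
    form_trial_responses,
    normalize_runwise,
    preprocess_subject,
    shift_labels,
    smooth_gaussian,
)

ACQ = AcquisitionParams()


def _vol(data, runs=None):
    data = np.asarray(data, float)
    return Volume4D(data, np.diag([1.5, 1.5, 1.8, 1.0]),
                    runs or [data.shape[3]])


class TestSmoothing:
    def test_fwhm_zero_is_identity(self):
        rng = np.random.default_rng(0)
        vol = _vol(rng.normal(size=(6, 6, 6, 3)))
        out = smooth_gaussian(vol, 0.0, ACQ)
        assert np.array_equal(out.data, vol.data)

    def test_constant_volume_unchanged(self):
        vol = _vol(np.full((8, 8, 8, 2), 7.0))
        out = smooth_gaussian(vol, 3.0, ACQ)
        assert np.allclose(out.data, 7.0)

    def test_impulse_mass_conserved(self):
        data = np.zeros((21, 21, 21, 1))
        data[10, 10, 10, 0] = 1.0
        out = smooth_gaussian(_vol(data), 3.0, ACQ)
        assert abs(out.data.sum() - 1.0) < 1e-6

    def test_anisotropic_sigma(self):
        # equal mm FWHM spreads over more voxels along the finer axis
        data = np.zeros((21, 21, 21, 1))
        data[10, 10, 10, 0] = 1.0
        out = smooth_gaussian(_vol(data), 6.0, ACQ).data[..., 0]
        assert out[14, 10, 10] > out[10, 10, 14]  # 1.5 mm x vs 1.8 mm z

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_gaussian(_vol(np.zeros((2, 2, 2, 1))), -1.0, ACQ)


class TestNormalize:
    def test_mean_100_fixed_point(self):
        mat = np.array([[90.0], [100.0], [110.0]])
        assert np.allclose(normalize_runwise(mat, [3]), mat)

    def test_arithmetic(self):
        mat = np.array([[1.0], [2.0], [3.0]])
        assert np.allclose(normalize_runwise(mat, [3]), [[50], [100], [150]])

    def test_constant_series(self):
        mat = np.full((4, 2), 3.7)
        assert np.allclose(normalize_runwise(mat, [4]), 100.0)

    def test_zero_mean_error_names_voxel_and_run(self):
        mat = np.ones((6, 2))
        mat[3:, 1] = [-1, 0, 1]  # run 1, voxel column 1 has zero mean
        with pytest.raises(ValueError, match="column 1.*run 1"):
            normalize_runwise(mat, [3, 3])


class TestShiftLabels:
    def test_zero_shift_identity(self):
        labels = np.array(["A", "B", "A", "B"], dtype=object)
        assert np.array_equal(shift_labels(labels, [4], 0), labels)

    def test_shift_moves_labels_later_and_drops(self):
        labels = np.array(["A", "A", "B", "B"], dtype=object)
        out = shift_labels(labels, [4], 2)
        assert list(out) == [None, None, "A", "A"]

    def test_shift_is_per_run(self):
        labels = np.array(["A", "B", "C", "D"], dtype=object)
        out = shift_labels(labels, [2, 2], 1)
        assert list(out) == [None, "A", None, "C"]

    def test_shift_too_large(self):
        with pytest.raises(ValueError):
            shift_labels(np.array(["A", "B"], dtype=object), [2], 2)


class TestDetrend:
    def test_exact_line_removed(self):
        t = np.arange(10.0)
        mat = np.outer(t, [2.0, -1.0]) + 5.0
        assert np.max(np.abs(detrend_linear(mat, [10]))) < 1e-10

    def test_runwise_zero_mean_and_idempotent(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(20, 3)) + 50
        out = detrend_linear(mat, [12, 8])
        assert abs(out[:12].mean(axis=0)).max() < 1e-10
        assert abs(out[12:].mean(axis=0)).max() < 1e-10
        assert np.allclose(detrend_linear(out, [12, 8]), out, atol=1e-10)

    def test_short_run_rejected(self):
        with pytest.raises(ValueError):
            detrend_linear(np.zeros((4, 1)), [2, 2])


class TestTrialResponses:
    def _trials(self, n_runs=1, blocks=2):
        spec = sl.SimulationSpec(seed=0, n_runs=max(n_runs, 1),
                                 blocks_per_condition_per_run=max(blocks // 4, 1))
        return sl.generate_design(spec)

    def test_worked_example_two_volumes_averaged(self):
        """A block at onset 0 with the 13.5-21.5 s Curtain window selects
        the volumes acquired at 16 s and 20 s; their mean is the trial."""
        import pandas as pd
        from selfloc.datatypes import TrialTable
        frame = pd.DataFrame([dict(run=0, block_index=0, sync="SYNCHRONOUS",
                                   location="A", block_onset_s=0.0,
                                   room_s=13.5, curtain_s=8.0, eyesclosed_s=2.5)])
        trials = TrialTable(frame)
        mat = np.zeros((6, 1))  # volumes at 0,4,8,12,16,20 s
        mat[4, 0] = 1.0
        mat[5, 0] = 3.0
        cfg = PreprocConfig(label_shift_volumes=0)
        resp = form_trial_responses(mat, np.zeros((1, 3), int), trials, [6], ACQ, cfg)
        assert resp.values.shape == (1, 1)
        assert resp.values[0, 0] == 2.0

    def test_default_design_yields_200_trials_of_2_volumes(self):
        spec = sl.SimulationSpec(seed=5)
        trials = sl.generate_design(spec)
        n_task = spec.volumes_per_run - ACQ.n_discard_initial
        rng = np.random.default_rng(0)
        mat = rng.normal(size=(n_task * 5, 150))
        resp = form_trial_responses(mat, np.zeros((150, 3), int), trials,
                                    [n_task] * 5, ACQ, PreprocConfig())
        assert resp.n_trials == 200
        # the shifted Curtain window [21.5, 29.5)s selects exactly volumes
        # at +24 s and +28 s from each block onset
        row = trials.frame.iloc[0]
        start = int(row.block_onset_s / 4)
        expected = mat[[start + 6, start + 7]].mean(axis=0)
        assert np.allclose(resp.values[0], expected)

    def test_degenerate_window_errors(self):
        import pandas as pd
        from selfloc.datatypes import TrialTable
        frame = pd.DataFrame([dict(run=0, block_index=0, sync="SYNCHRONOUS",
                                   location="A", block_onset_s=0.0,
                                   room_s=13.8, curtain_s=2.0, eyesclosed_s=8.2)])
        trials = TrialTable(frame)  # Curtain 13.8-15.8 s contains no onset
        with pytest.raises(ValueError, match="selects no volumes"):
            form_trial_responses(np.zeros((6, 1)), np.zeros((1, 3), int),
                                 trials, [6], ACQ, PreprocConfig(label_shift_volumes=0))


class TestPipeline:
    def test_discard_initial(self):
        rng = np.random.default_rng(2)
        vol = _vol(rng.normal(size=(3, 3, 3, 10)), [5, 5])
        out = discard_initial_volumes(vol, ACQ)
        assert out.run_lengths == [2, 2]
        assert np.array_equal(out.data[..., 0], vol.data[..., 3])
        assert np.array_equal(out.data[..., 2], vol.data[..., 8])

    def test_preprocess_deterministic(self, signal_subject):
        spec, subj = signal_subject
        a = preprocess_subject(subj.volume, subj.roi, subj.trials,
                               spec.acquisition, PreprocConfig())
        b = preprocess_subject(subj.volume, subj.roi, subj.trials,
                               spec.acquisition, PreprocConfig())
        assert np.array_equal(a.values, b.values)
        assert a.n_trials == 200

    def test_trial_counts_balanced_after_preprocessing(self, signal_responses):
        resp, _ = signal_responses
        import collections
        counts = collections.Counter(zip(resp.condition, resp.labels))
        assert set(counts.values()) == {50}

    def test_normalization_variant_is_decoding_equivalent(self, signal_subject):
        """Percent-of-run-mean vs run-mean subtraction: the two differ only
        by a per-voxel-per-run rescaling by mean/100 (within a point of
        1.0 on baseline-100 data), which the linear SVM almost entirely
        absorbs -- searchlight maps agree to a fraction of a percentage
        point."""
        spec, subj = signal_subject
        maps = {}
        for how in ("PERCENT_OF_RUN_MEAN", "SUBTRACT_RUN_MEAN"):
            resp = preprocess_subject(subj.volume, subj.roi, subj.trials,
                                      spec.acquisition,
                                      PreprocConfig(normalization=how))
            clusters = sl.build_clusters(subj.roi, spec.acquisition, 15)
            maps[how] = sl.map_locally_multivariate(
                resp.restrict("SYNCHRONOUS"), clusters
            ).voxelwise_accuracy
        diff = np.abs(maps["PERCENT_OF_RUN_MEAN"] - maps["SUBTRACT_RUN_MEAN"])
        assert diff.max() <= 1.0
        assert diff.mean() <= 0.1
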