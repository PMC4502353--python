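"""Locally multivariate (searchlight) decoding with leave-one-run-out CV.

The ROI is covered by overlapping, approximately spherical clusters: for
every ROI voxel, the k nearest ROI voxels (k = 33 by default) by Euclidean
distance in physical mm, anisotropic voxel size respected. Each cluster is
decoded with a linear C-SVC (C = 1) under leave-one-run-out
cross-validation; a voxel's representative accuracy is the mean of the
accuracies of all clusters that contain it, and the map peak is the
maximum voxelwise value.

:class:`SearchlightDecoder` follows the scikit-learn estimator protocol
(``fit`` computes the map; fitted results live in trailing-underscore
attributes), in the mold of nilearn's ``SearchLight``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import _kernels
from .datatypes import AcquisitionParams, ROIMask, TrialResponseMatrix


@dataclass(frozen=True)
class ClassifierSpec:
    """Linear soft-margin SVM configuration (fixed C, no tuning).

    Zero decision values classify as the positive class ("A"): a
    deterministic tie-break on a measure-zero event.
    """

    C: float = 1.0
    tol: float = _kernels.SVM_TOL
    max_iter: int = _kernels.SVM_MAX_ITER

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass
class ClusterSet:
    """Overlapping searchlight clusters, one per ROI voxel.

    ``members[v]`` lists the ROI column indices of the cluster centered at
    voxel v (the center itself included), nearest-first. ``cover[v]`` lists
    the clusters whose member set contains v, ascending.
    """

    members: np.ndarray  # (n_voxels, k) int
    k: int
    voxel_index_map: np.ndarray  # (n_voxels, 3)
    cover: list[np.ndarray] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        if not self.cover:
            n = self.members.shape[0]
            lists: list[list[int]] = [[] for _ in range(n)]
            for c in range(n):
                for v in self.members[c]:
                    lists[v].append(c)
            self.cover = [np.array(l, dtype=np.int64) for l in lists]

    @property
    def n_clusters(self) -> int:
        return self.members.shape[0]


def build_clusters(
    roi: ROIMask, acq: AcquisitionParams, k: int = 33
) -> ClusterSet:
    """k-nearest-neighbor searchlights in physical mm over the ROI.

    Distances use the anisotropic voxel size (a voxel two steps along a
    1.5-mm axis is nearer than two steps along a 1.8-mm axis); ties break
    by lexicographic voxel index. If the ROI holds fewer than k voxels,
    every cluster is the whole ROI.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    coords = roi.voxel_coords()
    n = len(coords)
    if n == 0:
        raise ValueError("empty ROI")
    mm = coords * np.asarray(acq.voxel_size_mm)
    kk = min(k, n)
    members = np.empty((n, kk), dtype=np.int64)
    idx = np.arange(n)
    for v in range(n):
        d2 = ((mm - mm[v]) ** 2).sum(axis=1)
        order = np.lexsort((idx, d2))  # distance, then lexicographic index
        members[v] = order[:kk]
    return ClusterSet(members=members, k=kk, voxel_index_map=coords)


@dataclass
class AccuracyMap:
    """Voxelwise representative decoding accuracies (percent)."""

    voxelwise_accuracy: np.ndarray  # (n_voxels,)
    cluster_accuracies: np.ndarray  # (n_clusters,)
    voxel_index_map: np.ndarray  # (n_voxels, 3)

    @property
    def peak_accuracy(self) -> float:
        return float(self.voxelwise_accuracy.max())

    @property
    def peak_index(self) -> int:
        """Index of the peak voxel (first in lexicographic order on ties)."""
        return int(np.argmax(self.voxelwise_accuracy))

    def peak_coordinate(self, affine: np.ndarray) -> np.ndarray:
        ijk = self.voxel_index_map[self.peak_index]
        return ijk @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]

    def to_volume(self, roi: ROIMask) -> np.ndarray:
        """Dense 3D array: voxelwise accuracy inside the ROI, 0 elsewhere."""
        out = np.zeros(roi.data.shape)
        ijk = self.voxel_index_map
        out[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = self.voxelwise_accuracy
        return out


def aggregate_voxelwise(cluster_acc: np.ndarray, clusters: ClusterSet) -> np.ndarray:
    """Mean cluster accuracy over the clusters covering each voxel."""
    return np.array([cluster_acc[cov].mean() for cov in clusters.cover])


def _signed_labels(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(np.asarray(y))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    signed = np.where(np.asarray(y) == classes[0], 1.0, -1.0)
    return signed, classes


def _validate_folds(y_signed: np.ndarray, groups: np.ndarray) -> np.ndarray:
    runs = np.unique(groups)
    if len(runs) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    for r in runs:
        train = y_signed[groups != r]
        if not ((train > 0).any() and (train < 0).any()):
            raise ValueError(f"training fold leaving out run {r} misses a class")
    return runs


_EMPTY_X = np.zeros((0, 0))
_EMPTY_Y = np.zeros(0)
_EMPTY_R = np.zeros(0, dtype=np.int64)


def batch_cluster_accuracies(
    X: np.ndarray,
    Y_signed: np.ndarray,
    groups: np.ndarray,
    clusters: ClusterSet,
    spec: ClassifierSpec,
    transfer: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-cluster LORO accuracies for a stack of labelings.

    ``Y_signed`` is (L, n_trials) in {+1,-1}. When ``transfer`` is given
    as ``(X_t, y_t_signed, groups_t)``, the classifiers trained on each
    fold also score the transfer trials of the corresponding left-out run
    against the fixed ``y_t_signed``. Returns (L, n_clusters) arrays.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    Y_signed = np.ascontiguousarray(np.atleast_2d(Y_signed), dtype=np.float64)
    groups = np.asarray(groups, dtype=np.int64)
    runs = np.unique(groups)
    if transfer is not None:
        Xt, yt, gt = transfer
        Xt = np.ascontiguousarray(Xt, dtype=np.float64)
        yt = np.ascontiguousarray(yt, dtype=np.float64)
        gt = np.asarray(gt, dtype=np.int64)
        extra = set(np.unique(gt)) - set(runs)
        if extra:
            raise ValueError(f"transfer trials reference unknown runs {sorted(extra)}")
    else:
        Xt, yt, gt = _EMPTY_X, _EMPTY_Y, _EMPTY_R
    acc_w, acc_t = _kernels.cluster_accuracies_batch(
        X,
        Y_signed,
        groups,
        runs.astype(np.int64),
        clusters.members,
        float(spec.C),
        float(spec.tol),
        int(spec.max_iter),
        Xt,
        yt,
        gt,
        transfer is not None,
    )
    return acc_w, (acc_t if transfer is not None else None)


class SearchlightDecoder(BaseEstimator):
    """Searchlight mapper: overlapping-cluster linear-SVM decoding under
    leave-one-run-out cross-validation.

    Parameters
    ----------
    clusters : ClusterSet
        Precomputed searchlights over the ROI (see :func:`build_clusters`).
    C : float
        SVM regularization (fixed at 1.0 in the protocol emulated here).

    Attributes (after ``fit``)
    --------------------------
    cluster_accuracies_ : (n_clusters,) percent correct per searchlight.
    voxelwise_accuracy_ : (n_voxels,) representative accuracy per voxel.
    peak_accuracy_ : float, maximum of the voxelwise map.
    accuracy_map_ : the full :class:`AccuracyMap`.
    """

    def __init__(
        self,
        clusters: ClusterSet | None = None,
        C: float = 1.0,
        tol: float = _kernels.SVM_TOL,
        max_iter: int = _kernels.SVM_MAX_ITER,
    ):
        self.clusters = clusters
        self.C = C
        self.tol = tol
        self.max_iter = max_iter

    def _spec(self) -> ClassifierSpec:
        return ClassifierSpec(C=self.C, tol=self.tol, max_iter=self.max_iter)

    def fit(self, X, y, groups=None):
        if self.clusters is None:
            raise ValueError("clusters must be provided (see build_clusters)")
        X = np.asarray(X, dtype=float)
        if groups is None:
            raise ValueError("groups (run index per trial) is required")
        groups = np.asarray(groups)
        if X.ndim != 2 or X.shape[1] != self.clusters.voxel_index_map.shape[0]:
            raise ValueError("X columns must match the cluster voxel universe")
        y_signed, self.classes_ = _signed_labels(y)
        _validate_folds(y_signed, groups)
        self._X = X
        self._y_signed = y_signed
        self._groups = groups
        acc, _ = batch_cluster_accuracies(
            X, y_signed[None, :], groups, self.clusters, self._spec()
        )
        self.cluster_accuracies_ = acc[0]
        self.voxelwise_accuracy_ = aggregate_voxelwise(acc[0], self.clusters)
        self.accuracy_map_ = AccuracyMap(
            voxelwise_accuracy=self.voxelwise_accuracy_,
            cluster_accuracies=self.cluster_accuracies_,
            voxel_index_map=self.clusters.voxel_index_map,
        )
        self.peak_accuracy_ = self.accuracy_map_.peak_accuracy
        return self

    def transfer_map(self, X_t, y_t, groups_t) -> AccuracyMap:
        """Cross-condition generalization map.

        The fold classifiers trained during :meth:`fit` (e.g. on
        SYNCHRONOUS trials of all runs but one) predict the transfer
        trials (e.g. ASYNCHRONOUS) of the corresponding left-out run.
        """
        if not hasattr(self, "cluster_accuracies_"):
            raise ValueError("fit the decoder before requesting a transfer map")
        X_t = np.asarray(X_t, dtype=float)
        yt_signed = np.where(np.asarray(y_t) == self.classes_[0], 1.0, -1.0)
        _, acc_t = batch_cluster_accuracies(
            self._X,
            self._y_signed[None, :],
            self._groups,
            self.clusters,
            self._spec(),
            transfer=(X_t, yt_signed, np.asarray(groups_t)),
        )
        return AccuracyMap(
            voxelwise_accuracy=aggregate_voxelwise(acc_t[0], self.clusters),
            cluster_accuracies=acc_t[0],
            voxel_index_map=self.clusters.voxel_index_map,
        )


def loro_decode(
    resp: TrialResponseMatrix,
    member_columns: Sequence[int] | None = None,
    spec: ClassifierSpec = ClassifierSpec(),
) -> float:
    """LORO decoding accuracy (percent) of one voxel cluster.

    ``member_columns`` restricts the response matrix to one cluster's
    voxels; all columns are used when omitted.
    """
    X = resp.values if member_columns is None else resp.values[:, list(member_columns)]
    y_signed = resp.y_signed()
    groups = resp.runs
    _validate_folds(y_signed, groups)
    members = np.arange(X.shape[1], dtype=np.int64)[None, :]
    acc, _ = _kernels.cluster_accuracies_batch(
        np.ascontiguousarray(X, dtype=np.float64),
        np.ascontiguousarray(y_signed[None, :]),
        np.asarray(groups, dtype=np.int64),
        np.unique(groups).astype(np.int64),
        members,
        float(spec.C),
        float(spec.tol),
        int(spec.max_iter),
        _EMPTY_X,
        _EMPTY_Y,
        _EMPTY_R,
        False,
    )
    return float(acc[0, 0])


def map_locally_multivariate(
    resp: TrialResponseMatrix,
    clusters: ClusterSet,
    spec: ClassifierSpec = ClassifierSpec(),
) -> AccuracyMap:
    """Voxelwise accuracy map of one condition's trial responses."""
    dec = SearchlightDecoder(clusters=clusters, C=spec.C, tol=spec.tol,
                             max_iter=spec.max_iter)
    dec.fit(resp.values, resp.labels, groups=resp.runs)
    return dec.accuracy_map_


def cross_condition_decode(
    train_resp: TrialResponseMatrix,
    test_resp: TrialResponseMatrix,
    clusters: ClusterSet,
    spec: ClassifierSpec = ClassifierSpec(),
) -> AccuracyMap:
    """Train on one condition, test on the other, fold by fold."""
    if set(np.unique(test_resp.runs)) - set(np.unique(train_resp.runs)):
        raise ValueError("test condition references runs absent from training")
    dec = SearchlightDecoder(clusters=clusters, C=spec.C, tol=spec.tol,
                             max_iter=spec.max_iter)
    dec.fit(train_resp.values, train_resp.labels, groups=train_resp.runs)
    return dec.transfer_map(test_resp.values, test_resp.labels, test_resp.runs)
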