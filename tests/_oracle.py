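"""Naive brute-force searchlight reimplementation used as a test oracle.

Deliberately structured as plain Python loops over clusters, folds, and
voxels, independent of the batched mapping pipeline. The SVM primitive
itself (`svm_train_weights`) is shared with the pipeline so that the
comparison exercises the searchlight logic (cluster construction, fold
bookkeeping, aggregation) rather than solver round-off.
"""

from __future__ import annotations

import numpy as np

from selfloc._kernels import SVM_MAX_ITER, SVM_TOL, svm_train_weights


def naive_clusters(coords: np.ndarray, voxel_size, k: int) -> list[list[int]]:
    """k nearest ROI voxels per center, mm metric, lexicographic ties."""
    mm = coords * np.asarray(voxel_size, dtype=float)
    n = len(coords)
    out = []
    for v in range(n):
        d = [(float(((mm[u] - mm[v]) ** 2).sum()), u) for u in range(n)]
        d.sort()
        out.append([u for _, u in d[: min(k, n)]])
    return out


def naive_loro_accuracy(X, y_signed, runs, member, C=1.0) -> float:
    """Leave-one-run-out percent accuracy of one cluster, fold mean."""
    member = list(member)
    acc_sum = 0.0
    uruns = np.unique(runs)
    for r in uruns:
        tr = runs != r
        Xtr = np.ascontiguousarray(X[tr][:, member])
        ytr = y_signed[tr]
        w = np.empty(len(member))
        rho = svm_train_weights(Xtr, ytr, C, SVM_TOL, SVM_MAX_ITER, w)
        correct = 0
        ntest = 0
        for i in np.flatnonzero(runs == r):
            s = -rho
            for j, col in enumerate(member):
                s += w[j] * X[i, col]
            pred = 1.0 if s >= 0.0 else -1.0
            if pred == y_signed[i]:
                correct += 1
            ntest += 1
        acc_sum += 100.0 * correct / ntest
    return acc_sum / len(uruns)


def naive_searchlight_map(X, y_signed, runs, coords, voxel_size, k, C=1.0):
    """Full brute-force map: (voxelwise, cluster_accuracies)."""
    clusters = naive_clusters(coords, voxel_size, k)
    cluster_acc = np.array(
        [naive_loro_accuracy(X, y_signed, runs, m, C) for m in clusters]
    )
    n = len(coords)
    voxelwise = np.empty(n)
    for v in range(n):
        covering = [c for c in range(n) if v in clusters[c]]
        voxelwise[v] = np.array([cluster_acc[c] for c in covering]).mean()
    return voxelwise, cluster_acc
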