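"""Max-statistic permutation inference for searchlight accuracy maps.

The null distribution is built by rerunning the identical mapping
procedure with trial labels permuted independently within each run
(preserving per-run class counts, the exchangeability the leave-one-run-out
design assumes). Familywise error over the map is controlled by the
distribution of the map maximum; the P-value formula is

    P = (1 + #{permuted values > true value}) / (1 + n_iterations)

with a strict ">". Voxelwise (uncorrected) P-values use the same formula
per voxel, thresholded at P < 0.001 for the descriptive informative-voxel
maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import TrialResponseMatrix
from .searchlight import (
    AccuracyMap,
    ClassifierSpec,
    ClusterSet,
    aggregate_voxelwise,
    batch_cluster_accuracies,
    _signed_labels,
    _validate_folds,
)


@dataclass(frozen=True)
class PermutationConfig:
    """n_iterations: null-sample count (10,000 in the emulated protocol;
    tests and desk-scale runs use fewer). ``scheme`` fixes the
    exchangeability: labels permute within run. ``store_voxel_values``
    keeps the full (n_iterations x n_voxels) null matrix; when off, only
    streaming per-voxel exceedance counts are kept — the voxelwise
    P-values are identical, the per-iteration maps just cannot be
    inspected afterwards."""

    n_iterations: int = 10_000
    scheme: str = "WITHIN_RUN"
    seed: int = 0
    store_voxel_values: bool = True

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.scheme != "WITHIN_RUN":
            raise ValueError(f"unknown permutation scheme {self.scheme!r}")


@dataclass
class NullDistribution:
    """Permutation null: peak value per iteration, optionally per voxel."""

    peak_values: np.ndarray  # (n_iterations,)
    voxel_values: np.ndarray | None = None  # (n_iterations, n_voxels)

    def __post_init__(self) -> None:
        self.peak_values = np.asarray(self.peak_values, dtype=float)
        if self.voxel_values is not None:
            self.voxel_values = np.asarray(self.voxel_values, dtype=float)
            if self.voxel_values.shape[0] != len(self.peak_values):
                raise ValueError("voxel_values rows must match n_iterations")

    @property
    def n_iterations(self) -> int:
        return len(self.peak_values)


def _permuted_signed(
    y_signed: np.ndarray, groups: np.ndarray, seed: int, iteration: int
) -> np.ndarray:
    """One within-run permutation, deterministic in (seed, iteration)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, iteration]))
    out = y_signed.copy()
    for r in np.unique(groups):
        m = groups == r
        out[m] = rng.permutation(out[m])
    return out


def permute_labels(
    resp: TrialResponseMatrix, cfg: PermutationConfig, iteration: int
) -> TrialResponseMatrix:
    """Relabeled copy of a response matrix (labels shuffled within run)."""
    if iteration < 1 or iteration > cfg.n_iterations:
        raise ValueError("iteration must be in 1..n_iterations")
    for r in np.unique(resp.runs):
        if len(np.unique(resp.labels[resp.runs == r])) < 2:
            raise ValueError(f"run {r} has a single class; labels not exchangeable")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, iteration]))
    labels = resp.labels.copy()
    for r in np.unique(resp.runs):
        m = resp.runs == r
        labels[m] = rng.permutation(labels[m])
    return TrialResponseMatrix(
        values=resp.values,
        labels=labels,
        runs=resp.runs,
        condition=resp.condition,
        voxel_index_map=resp.voxel_index_map,
    )


def fwe_peak_pvalue(true_peak: float, null: NullDistribution) -> float:
    """Familywise-error-corrected P of the map peak (strict ">")."""
    n = null.n_iterations
    return (1 + int((null.peak_values > true_peak).sum())) / (1 + n)


def voxelwise_pvalues(true_map: AccuracyMap, null: NullDistribution) -> np.ndarray:
    """Uncorrected per-voxel permutation P-values (strict ">")."""
    if null.voxel_values is None:
        raise ValueError("null distribution was built without voxel_values")
    true = true_map.voxelwise_accuracy
    if null.voxel_values.shape[1] != len(true):
        raise ValueError("null voxel universe does not match the map")
    n = null.n_iterations
    exceed = (null.voxel_values > true[None, :]).sum(axis=0)
    return (1 + exceed) / (1 + n)


def informative_voxels(
    pvals: np.ndarray, alpha: float = 0.001
) -> tuple[np.ndarray, int]:
    """Voxels with P strictly below alpha; returns (indices, count)."""
    idx = np.flatnonzero(np.asarray(pvals) < alpha)
    return idx, int(idx.size)


@dataclass(frozen=True)
class SubregionScheme:
    """Anterior/posterior x hemisphere partition of the ROI.

    Hemisphere comes from the world-x sign (RAS+: x < 0 is left). The
    anterior/posterior boundary is ``boundary_y_mm`` when given (e.g.
    y = -21 mm for MNI-space hippocampi); otherwise each hemisphere splits
    at the midpoint of its voxels' projections on their longest principal
    axis, anterior being the +y end.
    """

    boundary_y_mm: float | None = None
    labels: tuple[str, str, str, str] = ("LA", "LP", "RA", "RP")


def assign_subregions(
    world_coords: np.ndarray, scheme: SubregionScheme = SubregionScheme()
) -> dict[str, int]:
    """Count voxels per subregion {LA, LP, RA, RP}; counts sum to input size."""
    coords = np.atleast_2d(np.asarray(world_coords, dtype=float))
    counts = {lab: 0 for lab in scheme.labels}
    if coords.shape[0] == 0 or coords.size == 0:
        return counts
    la, lp, ra, rp = scheme.labels
    left = coords[:, 0] < 0
    for hemi_mask, ant_lab, post_lab in ((left, la, lp), (~left, ra, rp)):
        pts = coords[hemi_mask]
        if len(pts) == 0:
            continue
        if scheme.boundary_y_mm is not None:
            anterior = pts[:, 1] > scheme.boundary_y_mm
        else:
            centered = pts - pts.mean(axis=0)
            if len(pts) == 1:
                anterior = np.array([True])
            else:
                w, v = np.linalg.eigh(np.cov(centered.T))
                axis = v[:, -1]
                if axis[1] < 0:  # orient toward +y = anterior
                    axis = -axis
                proj = centered @ axis
                mid = (proj.min() + proj.max()) / 2.0
                anterior = proj > mid
        counts[ant_lab] += int(anterior.sum())
        counts[post_lab] += int((~anterior).sum())
    return counts


@dataclass
class PermutationResult:
    """Everything one permutation test produces for one condition."""

    true_map: AccuracyMap
    null: NullDistribution
    fwe_p: float
    voxel_p: np.ndarray
    config: PermutationConfig


def run_permutation_test(
    resp: TrialResponseMatrix,
    clusters: ClusterSet,
    spec: ClassifierSpec = ClassifierSpec(),
    cfg: PermutationConfig = PermutationConfig(),
    transfer: TrialResponseMatrix | None = None,
    batch_size: int = 64,
    n_jobs: int = 1,
) -> tuple[PermutationResult, PermutationResult | None]:
    """True map + permutation null + P-values, within- and cross-condition.

    Each iteration permutes the training labels within run and reruns the
    identical mapping; when ``transfer`` trials are given, the
    permuted-trained fold classifiers also rescore them (test labels
    untouched), building the cross-decoding null with the same seed. The
    true labels are iteration 0 only and never enter the null.

    ``n_jobs`` parallelizes over permutation batches (joblib). Every
    labeling is a pure function of (seed, iteration), and batches are
    reassembled in iteration order, so results are bit-identical for any
    job count.
    """
    y_signed, classes = _signed_labels(resp.labels)
    groups = np.asarray(resp.runs)
    _validate_folds(y_signed, groups)
    has_transfer = transfer is not None
    if has_transfer:
        yt_signed = np.where(np.asarray(transfer.labels) == classes[0], 1.0, -1.0)
        transfer_tuple = (transfer.values, yt_signed, np.asarray(transfer.runs))
    else:
        transfer_tuple = None

    n_iter = cfg.n_iterations
    n_vox = resp.n_voxels
    peaks_w = np.empty(n_iter)
    peaks_t = np.empty(n_iter) if has_transfer else None
    vox_w = np.empty((n_iter, n_vox)) if cfg.store_voxel_values else None
    vox_t = np.empty((n_iter, n_vox)) if (cfg.store_voxel_values and has_transfer) else None
    exceed_w = np.zeros(n_vox, dtype=np.int64)
    exceed_t = np.zeros(n_vox, dtype=np.int64)

    def labeling(i: int) -> np.ndarray:
        if i == 0:
            return y_signed
        return _permuted_signed(y_signed, groups, cfg.seed, i)

    true_map_w: AccuracyMap | None = None
    true_map_t: AccuracyMap | None = None
    bounds = []
    start = 0
    while start <= n_iter:
        stop = min(start + batch_size, n_iter + 1)
        bounds.append((start, stop))
        start = stop

    def one_batch(lo: int, hi: int):
        Y = np.stack([labeling(i) for i in range(lo, hi)])
        return batch_cluster_accuracies(
            resp.values, Y, groups, clusters, spec, transfer=transfer_tuple
        )

    if n_jobs == 1:
        batch_results = (one_batch(lo, hi) for lo, hi in bounds)
    else:
        from joblib import Parallel, delayed

        batch_results = Parallel(n_jobs=n_jobs)(
            delayed(one_batch)(lo, hi) for lo, hi in bounds
        )

    for (start, stop), (acc_w, acc_t) in zip(bounds, batch_results):
        for row, i in enumerate(range(start, stop)):
            vmap_w = aggregate_voxelwise(acc_w[row], clusters)
            vmap_t = aggregate_voxelwise(acc_t[row], clusters) if has_transfer else None
            if i == 0:
                true_map_w = AccuracyMap(vmap_w, acc_w[row], resp.voxel_index_map)
                if has_transfer:
                    true_map_t = AccuracyMap(vmap_t, acc_t[row], resp.voxel_index_map)
            else:
                peaks_w[i - 1] = vmap_w.max()
                exceed_w += vmap_w > true_map_w.voxelwise_accuracy
                if vox_w is not None:
                    vox_w[i - 1] = vmap_w
                if has_transfer:
                    peaks_t[i - 1] = vmap_t.max()
                    exceed_t += vmap_t > true_map_t.voxelwise_accuracy
                    if vox_t is not None:
                        vox_t[i - 1] = vmap_t

    null_w = NullDistribution(peaks_w, vox_w)
    res_w = PermutationResult(
        true_map=true_map_w,
        null=null_w,
        fwe_p=fwe_peak_pvalue(true_map_w.peak_accuracy, null_w),
        voxel_p=(1 + exceed_w) / (1 + n_iter),
        config=cfg,
    )
    res_t = None
    if has_transfer:
        null_t = NullDistribution(peaks_t, vox_t)
        res_t = PermutationResult(
            true_map=true_map_t,
            null=null_t,
            fwe_p=fwe_peak_pvalue(true_map_t.peak_accuracy, null_t),
            voxel_p=(1 + exceed_t) / (1 + n_iter),
            config=cfg,
        )
    return res_w, res_t
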