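"""MVPA preprocessing: smoothing, run-wise normalization, label shift,
linear detrending, and trial-response formation.

The pipeline order is fixed: discard initial volumes -> smooth -> extract
ROI -> normalize to percent of run mean -> shift labels by the hemodynamic
delay -> remove linear trends -> average the Curtain-phase volumes into
single-trial responses. Everything is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .datatypes import (
    AcquisitionParams,
    ROIMask,
    TrialResponseMatrix,
    TrialTable,
    Volume4D,
)
from .io import extract_roi_matrix

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class PreprocConfig:
    """Tunable preprocessing parameters.

    smoothing_fwhm_mm : isotropic Gaussian kernel width in mm (3.0).
    label_shift_volumes : hemodynamic delay in whole volumes (2); labels
        move *later* in time — the stimulus at t explains the BOLD signal
        at t + shift volumes.
    phase_for_response : block phase averaged into the trial response
        (the 8-s CURTAIN phase, whose visual input is identical across
        conditions).
    """

    smoothing_fwhm_mm: float = 3.0
    label_shift_volumes: int = 2
    phase_for_response: str = "CURTAIN"
    normalization: str = "PERCENT_OF_RUN_MEAN"

    def __post_init__(self) -> None:
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing_fwhm_mm must be >= 0")
        if self.label_shift_volumes < 0:
            raise ValueError("label_shift_volumes must be >= 0")
        if self.phase_for_response not in ("ROOM", "CURTAIN", "EYES_CLOSED"):
            raise ValueError(f"unknown phase {self.phase_for_response!r}")
        if self.normalization not in ("PERCENT_OF_RUN_MEAN", "SUBTRACT_RUN_MEAN"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def discard_initial_volumes(vol: Volume4D, acq: AcquisitionParams) -> Volume4D:
    """Drop the first ``n_discard_initial`` frames of every run."""
    k = acq.n_discard_initial
    if k == 0:
        return vol
    keep = []
    for sl, n in zip(vol.run_slices(), vol.run_lengths):
        if k >= n:
            raise ValueError(f"cannot discard {k} of a {n}-volume run")
        keep.append(vol.data[..., sl][..., k:])
    return Volume4D(
        data=np.concatenate(keep, axis=3),
        affine=vol.affine,
        run_lengths=[n - k for n in vol.run_lengths],
    )


def smooth_gaussian(vol: Volume4D, fwhm_mm: float, acq: AcquisitionParams) -> Volume4D:
    """Smooth each 3D frame with an isotropic-in-mm Gaussian kernel.

    The mm FWHM is converted per axis to voxel sigmas with the (possibly
    anisotropic) voxel size. The kernel is renormalized at the volume
    boundary by dividing by the smoothed all-ones volume, so a constant
    image stays exactly constant.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return vol
    sigmas = [fwhm_mm / _FWHM_TO_SIGMA / v for v in acq.voxel_size_mm]
    ones = np.ones(vol.shape3d)
    norm = gaussian_filter(ones, sigmas, mode="constant", cval=0.0)
    out = np.empty_like(vol.data, dtype=float)
    for t in range(vol.data.shape[3]):
        frame = gaussian_filter(
            vol.data[..., t].astype(float), sigmas, mode="constant", cval=0.0
        )
        out[..., t] = frame / norm
    return Volume4D(data=out, affine=vol.affine, run_lengths=vol.run_lengths)


def _run_slices(run_lengths: list[int]) -> list[slice]:
    out, start = [], 0
    for n in run_lengths:
        out.append(slice(start, start + n))
        start += n
    return out


def normalize_runwise(
    mat: np.ndarray, run_lengths: list[int], how: str = "PERCENT_OF_RUN_MEAN"
) -> np.ndarray:
    """Normalize each voxel's series relative to its within-run average.

    Default: percent of run mean (divide by the run mean, times 100).
    ``SUBTRACT_RUN_MEAN`` subtracts it instead; the two are equivalent for
    linear decoding after detrending, and a test asserts that equivalence.
    """
    mat = np.asarray(mat, dtype=float)
    if sum(run_lengths) != mat.shape[0]:
        raise ValueError("run lengths do not sum to the number of time points")
    out = np.empty_like(mat)
    for run, sl in enumerate(_run_slices(run_lengths)):
        means = mat[sl].mean(axis=0)
        if how == "PERCENT_OF_RUN_MEAN":
            zero = np.flatnonzero(means == 0)
            if zero.size:
                raise ValueError(
                    f"voxel column {zero[0]} has zero mean in run {run}; "
                    "cannot express values as percent of run mean"
                )
            out[sl] = 100.0 * mat[sl] / means
        else:
            out[sl] = mat[sl] - means
    return out


def shift_labels(volume_labels: np.ndarray, run_lengths: list[int], k: int) -> np.ndarray:
    """Shift per-volume labels ``k`` volumes later within each run.

    The label of volume t is reassigned to volume t+k of the same run; the
    first k volumes of each run become unlabeled (None) and labels shifted
    past the run end are dropped.
    """
    labels = np.asarray(volume_labels, dtype=object)
    if sum(run_lengths) != len(labels):
        raise ValueError("run lengths do not sum to the number of labels")
    if k < 0:
        raise ValueError("shift must be >= 0")
    out = np.full(len(labels), None, dtype=object)
    for n, sl in zip(run_lengths, _run_slices(run_lengths)):
        if k >= n:
            raise ValueError(f"shift {k} >= run length {n}")
        if k == 0:
            out[sl] = labels[sl]
        else:
            run = labels[sl]
            out[sl.start + k : sl.stop] = run[: n - k]
    return out


def detrend_linear(mat: np.ndarray, run_lengths: list[int]) -> np.ndarray:
    """Remove the per-run, per-voxel OLS linear trend (mean included)."""
    mat = np.asarray(mat, dtype=float)
    if sum(run_lengths) != mat.shape[0]:
        raise ValueError("run lengths do not sum to the number of time points")
    out = np.empty_like(mat)
    for n, sl in zip(run_lengths, _run_slices(run_lengths)):
        if n < 3:
            raise ValueError(f"run of length {n} too short to detrend")
        t = np.arange(n, dtype=float)
        t -= t.mean()
        block = mat[sl]
        slope = (t @ block) / (t @ t)
        out[sl] = block - block.mean(axis=0) - np.outer(t, slope)
    return out


def form_trial_responses(
    mat: np.ndarray,
    voxel_index_map: np.ndarray,
    trials: TrialTable,
    run_lengths: list[int],
    acq: AcquisitionParams,
    cfg: PreprocConfig,
) -> TrialResponseMatrix:
    """Average the phase-of-interest volumes of each block into one trial.

    A volume belongs to a block's phase if its acquisition onset falls in
    the half-open window [phase_start, phase_end), displaced later by
    ``label_shift_volumes * TR`` (the hemodynamic label shift). With
    TR = 4 s and the 13.5/21.5 s Curtain bounds this selects exactly two
    volumes per block. Block onsets are seconds from the first retained
    volume of the block's run.
    """
    mat = np.asarray(mat, dtype=float)
    if sum(run_lengths) != mat.shape[0]:
        raise ValueError("run lengths do not sum to the number of time points")
    tr = acq.tr_seconds
    shift_s = cfg.label_shift_volumes * tr
    run_start = {}
    start = 0
    runs_sorted = trials.runs
    if len(runs_sorted) != len(run_lengths):
        raise ValueError(
            f"trial table has {len(runs_sorted)} runs, data has {len(run_lengths)}"
        )
    for run, n in zip(runs_sorted, run_lengths):
        run_start[run] = (start, n)
        start += n

    values, labels, runs, condition = [], [], [], []
    for _, row in trials.frame.iterrows():
        lo, hi = trials.phase_window(row, cfg.phase_for_response)
        lo += shift_s
        hi += shift_s
        start, n = run_start[int(row["run"])]
        onsets = np.arange(n) * tr
        sel = np.flatnonzero((onsets >= lo) & (onsets < hi))
        if sel.size == 0:
            raise ValueError(
                f"block {int(row['block_index'])} of run {int(row['run'])} "
                f"selects no volumes (window [{lo:.1f}, {hi:.1f}) s)"
            )
        values.append(mat[start + sel].mean(axis=0))
        labels.append(row["location"])
        runs.append(int(row["run"]))
        condition.append(row["sync"])
    return TrialResponseMatrix(
        values=np.array(values),
        labels=np.array(labels),
        runs=np.array(runs),
        condition=np.array(condition),
        voxel_index_map=voxel_index_map,
    )


def preprocess_subject(
    vol: Volume4D,
    roi: ROIMask,
    trials: TrialTable,
    acq: AcquisitionParams,
    cfg: PreprocConfig,
) -> TrialResponseMatrix:
    """The full fixed-order preprocessing chain for one subject."""
    vol = discard_initial_volumes(vol, acq)
    vol = smooth_gaussian(vol, cfg.smoothing_fwhm_mm, acq)
    mat, coords = extract_roi_matrix(vol, roi)
    mat = normalize_runwise(mat, vol.run_lengths, cfg.normalization)
    mat = detrend_linear(mat, vol.run_lengths)
    return form_trial_responses(mat, coords, trials, vol.run_lengths, acq, cfg)
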