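"""Core data model: acquisition parameters, volumes, masks, designs, trials.

Conventions
-----------
* Voxel indices are 0-based ``(x, y, z)``; world coordinates in mm come from
  the NIfTI affine (RAS+ assumed).
* Run structure is not stored in the NIfTI itself; ``Volume4D`` carries an
  explicit list of run lengths summing to the number of frames.
* Condition factors use the canonical upper-case levels
  ``SYNCHRONOUS``/``ASYNCHRONOUS`` (visuo-tactile stimulation mode) and
  ``A``/``B`` (perceived location).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

SYNC = "SYNCHRONOUS"
ASYNC = "ASYNCHRONOUS"
LOC_A = "A"
LOC_B = "B"

#: default block phase structure, seconds from block onset:
#: Room 0-13.5, Curtain 13.5-21.5, Eyes-closed 21.5-24.
PHASE_BOUNDS_S = (0.0, 13.5, 21.5, 24.0)
BLOCK_DURATION_S = 24.0

TRIAL_COLUMNS = [
    "run",
    "block_index",
    "sync",
    "location",
    "block_onset_s",
    "room_s",
    "curtain_s",
    "eyesclosed_s",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Scanner timing and geometry of the acquisition.

    tr_seconds : volume repetition time (4.0 s in the experiment emulated).
    voxel_size_mm : anisotropic voxel dimensions (1.5, 1.5, 1.8 mm).
    n_discard_initial : leading volumes per run dropped before analysis
        (non-steady-state magnetization; 3 in the emulated protocol).
    """

    tr_seconds: float = 4.0
    voxel_size_mm: tuple[float, float, float] = (1.5, 1.5, 1.8)
    n_discard_initial: int = 3

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be three positive values")
        if self.n_discard_initial < 0:
            raise ValueError("n_discard_initial must be non-negative")


@dataclass
class Volume4D:
    """A 4D BOLD image: ``data[x, y, z, t]`` plus affine and run boundaries."""

    data: np.ndarray
    affine: np.ndarray
    run_lengths: list[int]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        self.run_lengths = [int(r) for r in self.run_lengths]
        if any(r <= 0 for r in self.run_lengths):
            raise ValueError("run lengths must be positive")
        if sum(self.run_lengths) != self.data.shape[3]:
            raise ValueError(
                f"run lengths sum to {sum(self.run_lengths)} "
                f"but volume has {self.data.shape[3]} frames"
            )

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_runs(self) -> int:
        return len(self.run_lengths)

    def run_slices(self) -> list[slice]:
        """Frame index ranges of each run, in acquisition order."""
        out, start = [], 0
        for r in self.run_lengths:
            out.append(slice(start, start + r))
            start += r
        return out


@dataclass
class ROIMask:
    """Binary mask on the same grid as its companion volume."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not self.data.any():
            raise ValueError("mask contains no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def voxel_coords(self) -> np.ndarray:
        """(n, 3) voxel indices of true voxels in lexicographic (x, y, z) order."""
        return np.argwhere(self.data)  # argwhere of C-ordered array is lexicographic

    def world_coords(self) -> np.ndarray:
        """(n, 3) world-mm coordinates of the mask voxels (same order)."""
        ijk = self.voxel_coords()
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


class TrialTable:
    """The experiment design: one row per 24-s block.

    Wraps a validated :class:`pandas.DataFrame` with columns ``run``,
    ``block_index``, ``sync``, ``location``, ``block_onset_s`` and the
    three phase durations ``room_s``, ``curtain_s``, ``eyesclosed_s``.
    Onsets are seconds from the first *retained* volume of the block's run.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        if len(frame) == 0:
            raise ValueError("trial table is empty")
        frame = frame.loc[:, TRIAL_COLUMNS].copy()
        frame["run"] = frame["run"].astype(int)
        frame["block_index"] = frame["block_index"].astype(int)
        frame["sync"] = frame["sync"].astype(str).str.upper()
        frame["location"] = frame["location"].astype(str).str.upper()
        bad_sync = set(frame["sync"]) - {SYNC, ASYNC}
        if bad_sync:
            raise ValueError(f"unknown sync levels: {sorted(bad_sync)}")
        bad_loc = set(frame["location"]) - {LOC_A, LOC_B}
        if bad_loc:
            raise ValueError(f"unknown location levels: {sorted(bad_loc)}")
        for col in ("room_s", "curtain_s", "eyesclosed_s"):
            if (frame[col] <= 0).any():
                raise ValueError(f"non-positive phase duration in {col}")
        if (frame[["run", "block_index"]].duplicated()).any():
            raise ValueError("duplicate (run, block_index)")
        for run, grp in frame.groupby("run"):
            grp = grp.sort_values("block_onset_s")
            onsets = grp["block_onset_s"].to_numpy(float)
            durations = (
                grp[["room_s", "curtain_s", "eyesclosed_s"]].sum(axis=1).to_numpy(float)
            )
            if len(onsets) > 1:
                if not (np.diff(onsets) > 0).all():
                    raise ValueError(f"run {run}: block onsets not strictly increasing")
                if (onsets[:-1] + durations[:-1] > onsets[1:] + 1e-9).any():
                    raise ValueError(f"run {run}: overlapping blocks")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def runs(self) -> list[int]:
        return sorted(self.frame["run"].unique())

    def phase_window(self, row: pd.Series, phase: str) -> tuple[float, float]:
        """Absolute [start, end) of a phase of one block, seconds in-run."""
        t0 = float(row["block_onset_s"])
        room, curtain = float(row["room_s"]), float(row["curtain_s"])
        eyes = float(row["eyesclosed_s"])
        if phase == "ROOM":
            return t0, t0 + room
        if phase == "CURTAIN":
            return t0 + room, t0 + room + curtain
        if phase == "EYES_CLOSED":
            return t0 + room + curtain, t0 + room + curtain + eyes
        raise ValueError(f"unknown phase {phase!r}")

    def select(self, sync: str | None = None) -> "TrialTable":
        frame = self.frame
        if sync is not None:
            frame = frame[frame["sync"] == sync.upper()]
            if len(frame) == 0:
                raise ValueError(f"no trials with sync={sync}")
        return TrialTable(frame)


@dataclass
class TrialResponseMatrix:
    """Trials x ROI-voxels matrix of averaged Curtain-phase responses.

    Rows carry the location label, run index, and stimulation condition;
    columns follow ``voxel_index_map`` (lexicographic mask order), the
    shared voxel universe of all downstream maps.
    """

    values: np.ndarray
    labels: np.ndarray  # location factor per trial, "A"/"B"
    runs: np.ndarray  # run index per trial
    condition: np.ndarray  # sync factor per trial
    voxel_index_map: np.ndarray  # (n_voxels, 3) int voxel coords

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.runs = np.asarray(self.runs, dtype=int)
        self.condition = np.asarray(self.condition)
        self.voxel_index_map = np.asarray(self.voxel_index_map, dtype=int)
        n = self.values.shape[0]
        if not (len(self.labels) == len(self.runs) == len(self.condition) == n):
            raise ValueError("per-trial metadata length mismatch")
        if self.voxel_index_map.shape != (self.values.shape[1], 3):
            raise ValueError("voxel_index_map must be (n_voxels, 3)")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def y_signed(self) -> np.ndarray:
        """Labels as +1 (A) / -1 (B) floats, the classifier convention."""
        return np.where(self.labels == LOC_A, 1.0, -1.0)

    def restrict(self, condition: str) -> "TrialResponseMatrix":
        """Trials of one stimulation condition, order preserved."""
        m = self.condition == condition.upper()
        if not m.any():
            raise ValueError(f"no trials with condition {condition!r}")
        return TrialResponseMatrix(
            self.values[m], self.labels[m], self.runs[m], self.condition[m],
            self.voxel_index_map,
        )
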