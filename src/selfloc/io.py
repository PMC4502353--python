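"""Readers and writers for volumes, masks, trial tables, and ROI matrices.

NIfTI-1 handling goes through nibabel; trial tables are TSV with a header
row; run lengths travel in a JSON sidecar (NIfTI itself has no run
structure). Images in non-RAS+ orientation are reoriented to closest
canonical axes on load so one voxel-index convention holds everywhere.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import ROIMask, TrialTable, TrialResponseMatrix, Volume4D, TRIAL_COLUMNS


def _load_canonical(path: str | Path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    return nib.as_closest_canonical(img)


def read_volume(path: str | Path, run_lengths: list[int] | None = None) -> Volume4D:
    """Read a 4D NIfTI volume.

    ``run_lengths`` may be given directly or via a ``<stem>.runs.json``
    sidecar (``{"run_lengths": [...]}``) next to the image; a single run
    covering all frames is assumed when neither exists.
    """
    img = _load_canonical(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got {data.ndim}D")
    if run_lengths is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            run_lengths = json.loads(sidecar.read_text())["run_lengths"]
        else:
            run_lengths = [data.shape[3]]
    return Volume4D(data=np.asarray(data, dtype=np.float64), affine=img.affine,
                    run_lengths=list(run_lengths))


def _sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".runs.json")
    return path.with_suffix(".runs.json")


def write_volume(vol: Volume4D, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data, vol.affine)
    nib.save(img, str(path))
    _sidecar_path(path).write_text(json.dumps({"run_lengths": vol.run_lengths}))


def read_mask(path: str | Path) -> ROIMask:
    img = _load_canonical(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got {data.ndim}D")
    return ROIMask(data=data > 0, affine=img.affine)


def write_mask(mask: ROIMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def read_trial_table(path: str | Path) -> TrialTable:
    """Read and validate a TSV trial table (tab-separated, header row)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty trial table") from None
    return TrialTable(frame)


def write_trial_table(trials: TrialTable, path: str | Path) -> None:
    trials.frame.to_csv(path, sep="\t", index=False)


def extract_roi_matrix(vol: Volume4D, mask: ROIMask) -> tuple[np.ndarray, np.ndarray]:
    """Time x voxels matrix of the masked time series.

    Column ``j`` is the series of the j-th true mask voxel in lexicographic
    (x, y, z) index order — the fixed voxel universe for all downstream
    maps. Returns ``(matrix, voxel_index_map)``.
    """
    if vol.shape3d != mask.data.shape:
        raise ValueError(
            f"grid mismatch: volume {vol.shape3d} vs mask {mask.data.shape}"
        )
    if not np.allclose(vol.affine, mask.affine, atol=1e-4):
        raise ValueError("volume and mask affines differ")
    coords = mask.voxel_coords()
    mat = vol.data[mask.data, :].T  # boolean indexing follows C order = lexicographic
    return np.ascontiguousarray(mat, dtype=np.float64), coords


def write_response_matrix(resp: TrialResponseMatrix, path: str | Path) -> None:
    """Serialize a TrialResponseMatrix to TSV (metadata + voxel columns)."""
    cols = {"run": resp.runs, "sync": resp.condition, "location": resp.labels}
    frame = pd.DataFrame(cols)
    voxel_names = ["v_%d_%d_%d" % tuple(c) for c in resp.voxel_index_map]
    frame = pd.concat([frame, pd.DataFrame(resp.values, columns=voxel_names)], axis=1)
    frame.to_csv(path, sep="\t", index=False)


def read_response_matrix(path: str | Path) -> TrialResponseMatrix:
    frame = pd.read_csv(path, sep="\t")
    voxel_names = [c for c in frame.columns if c.startswith("v_")]
    coords = np.array([[int(p) for p in name[2:].split("_")] for name in voxel_names])
    return TrialResponseMatrix(
        values=frame[voxel_names].to_numpy(float),
        labels=frame["location"].to_numpy(),
        runs=frame["run"].to_numpy(int),
        condition=frame["sync"].to_numpy(),
        voxel_index_map=coords,
    )
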