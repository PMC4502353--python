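"""Synthetic subject generator for the 2x2 out-of-body-illusion experiment.

Emulates a block-design acquisition: five runs, 40 blocks per run (10 per
cell of the SYNCHRONOUS/ASYNCHRONOUS x Location A/B factorial), 24-s blocks
split into Room (13.5 s) / Curtain (8 s) / Eyes-closed (2.5 s) phases,
TR = 4 s, anisotropic 1.5 x 1.5 x 1.8 mm voxels, three non-steady-state
volumes per run. The ROI is a pair of ellipsoidal "hippocampi".

The signal model matches the assumption the decoding analysis itself makes:
location-specific *multivoxel patterns*. Two fixed zero-mean, orthogonal
pattern vectors over the informative voxels are added during each block's
Room+Curtain span, delayed by a whole number of volumes (the analysis
models hemodynamic delay as a two-volume label shift, so the simulator
does the same; canonical-HRF convolution is available behind a flag).
SYNCHRONOUS blocks carry pattern A or B; ASYNCHRONOUS blocks carry a
location-independent common activation of equal energy, so overall
stimulation responses match but no location information is present —
unless ``async_has_location_signal`` puts it there deliberately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .datatypes import (
    AcquisitionParams,
    ASYNC,
    BLOCK_DURATION_S,
    LOC_A,
    LOC_B,
    PHASE_BOUNDS_S,
    ROIMask,
    SYNC,
    TrialTable,
    Volume4D,
)
from .io import write_mask, write_trial_table, write_volume

import pandas as pd


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic subject.

    Amplitudes are in raw signal units on a baseline of 100 (so with
    ``noise_sd=1`` the thermal noise is ~1% of baseline, ordinary for a
    3T block design). ``pattern_amplitude`` is the RMS of the multivoxel
    pattern across informative voxels, i.e. amplitude 3 with noise_sd 1
    is a 3:1 voxelwise contrast-to-noise ratio.
    """

    grid_shape: tuple[int, int, int] = (18, 14, 10)
    n_roi_voxels: int = 150
    n_runs: int = 5
    blocks_per_condition_per_run: int = 10
    n_informative_voxels: int = 20
    pattern_amplitude: float = 3.0
    noise_sd: float = 1.0
    baseline: float = 100.0
    drift_slope_sd: float = 0.5  # signal units over a full run
    temporal_autocorr: float = 0.0  # AR(1) coefficient of the noise
    hemodynamic_delay_volumes: int = 2
    hrf_convolve: bool = False
    async_has_location_signal: bool = False
    async_swap_locations: bool = False  # label-swapped patterns in async
    n_rest_volumes_end: int = 7  # trailing rest so shifted windows stay in-run
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_roi_voxels < 2 or self.n_roi_voxels % 2:
            raise ValueError("n_roi_voxels must be an even count >= 2")
        if not (0 <= self.n_informative_voxels <= self.n_roi_voxels):
            raise ValueError("n_informative_voxels must be within the ROI size")
        if self.pattern_amplitude < 0:
            raise ValueError("pattern_amplitude must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 <= self.temporal_autocorr < 1):
            raise ValueError("temporal_autocorr must be in [0, 1)")
        if self.n_runs < 1 or self.blocks_per_condition_per_run < 1:
            raise ValueError("need at least one run and one block per cell")

    @property
    def blocks_per_run(self) -> int:
        return 4 * self.blocks_per_condition_per_run

    @property
    def task_seconds_per_run(self) -> float:
        return self.blocks_per_run * BLOCK_DURATION_S

    @property
    def volumes_per_run(self) -> int:
        tr = self.acquisition.tr_seconds
        task = int(np.ceil(self.task_seconds_per_run / tr))
        return self.acquisition.n_discard_initial + task + self.n_rest_volumes_end


@dataclass
class SyntheticSubject:
    """A generated dataset plus the ground truth that produced it."""

    volume: Volume4D
    roi: ROIMask
    trials: TrialTable
    informative_coords: np.ndarray  # (n_informative, 3) voxel indices
    pattern_a: np.ndarray  # (n_informative,) zero-mean
    pattern_b: np.ndarray
    spec: SimulationSpec


def _roi_mask(spec: SimulationSpec) -> ROIMask:
    """Two ellipsoids ("left/right hippocampus") of exactly n_roi_voxels."""
    nx, ny, nz = spec.grid_shape
    vx, vy, vz = spec.acquisition.voxel_size_mm
    affine = np.diag([vx, vy, vz, 1.0])
    affine[:3, 3] = -np.array([vx * (nx - 1), vy * (ny - 1), vz * (nz - 1)]) / 2.0
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    mask = np.zeros(spec.grid_shape, dtype=bool)
    half = spec.n_roi_voxels // 2
    # hemisphere centers at +-1/4 of the grid along x; elongated along y
    semi = np.array([nx / 5.0, ny / 2.5, nz / 3.0])
    for cx in (nx / 4.0, 3.0 * nx / 4.0):
        center = np.array([cx, (ny - 1) / 2.0, (nz - 1) / 2.0])
        d = (
            ((ii - center[0]) / semi[0]) ** 2
            + ((jj - center[1]) / semi[1]) ** 2
            + ((kk - center[2]) / semi[2]) ** 2
        )
        flat = np.argsort(d, axis=None, kind="stable")[:half]  # lexicographic ties
        chosen = np.unravel_index(flat, spec.grid_shape)
        mask[chosen] = True
    if int(mask.sum()) != spec.n_roi_voxels:
        raise ValueError("hemisphere ellipsoids overlap; enlarge grid_shape")
    return ROIMask(data=mask, affine=affine)


def generate_design(spec: SimulationSpec) -> TrialTable:
    """Balanced pseudo-randomized design: contiguous 24-s blocks per run."""
    rng = np.random.default_rng(spec.seed)
    cells = [(s, l) for s in (SYNC, ASYNC) for l in (LOC_A, LOC_B)]
    rows = []
    room = PHASE_BOUNDS_S[1] - PHASE_BOUNDS_S[0]
    curtain = PHASE_BOUNDS_S[2] - PHASE_BOUNDS_S[1]
    eyes = PHASE_BOUNDS_S[3] - PHASE_BOUNDS_S[2]
    for run in range(spec.n_runs):
        order = np.repeat(np.arange(4), spec.blocks_per_condition_per_run)
        rng.shuffle(order)
        for b, cell in enumerate(order):
            sync, loc = cells[cell]
            rows.append(
                dict(
                    run=run,
                    block_index=b,
                    sync=sync,
                    location=loc,
                    block_onset_s=b * BLOCK_DURATION_S,
                    room_s=room,
                    curtain_s=curtain,
                    eyesclosed_s=eyes,
                )
            )
    return TrialTable(pd.DataFrame(rows))


def _glover_hrf(tr: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the TR, peak normalized to 1."""
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0, duration_s, tr)
    peak = gamma_dist.pdf(t, 6)  # shape 6, scale 1 (seconds)
    undershoot = gamma_dist.pdf(t, 16)
    h = peak - undershoot / 6.0
    return h / h.max()


def _pattern_vectors(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Two zero-mean, mutually orthogonal, unit-RMS pattern vectors."""
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    a -= a.mean()
    b -= b.mean()
    b -= (b @ a) / (a @ a) * a
    a /= np.sqrt((a**2).mean())
    b /= np.sqrt((b**2).mean())
    return a, b


def signal_component(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray, dict]:
    """Noise-free condition signal for the ROI voxels.

    Returns ``(signal, roi_linear_index, info)`` where ``signal`` is
    (T, n_roi) for the full concatenated (dummies included) time axis.
    Separated from :func:`generate_subject` so tests can assert signal
    properties (e.g. zero location contrast in asynchronous data) exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    trials = generate_design(spec)
    roi = _roi_mask(spec)
    n_roi = roi.n_voxels
    acq = spec.acquisition
    tr = acq.tr_seconds

    n_inf = spec.n_informative_voxels
    inf_local = np.sort(rng.choice(n_roi, size=n_inf, replace=False)) if n_inf else np.array([], int)
    if n_inf >= 2:
        pat_a, pat_b = _pattern_vectors(rng, n_inf)
    else:
        pat_a = np.zeros(n_inf)
        pat_b = np.zeros(n_inf)
    common = rng.normal(size=n_inf)
    if n_inf >= 2:
        common -= common.mean()
        for p in (pat_a, pat_b):
            den = p @ p
            if den > 0:
                common -= (common @ p) / den * p
        rms = np.sqrt((common**2).mean())
        if rms > 0:
            common /= rms

    vols_per_run = spec.volumes_per_run
    n_task = vols_per_run - acq.n_discard_initial
    T = vols_per_run * spec.n_runs
    signal = np.zeros((T, n_roi))
    hrf = _glover_hrf(tr) if spec.hrf_convolve else None

    for run in range(spec.n_runs):
        run0 = run * vols_per_run
        # onset (s) of each retained volume, relative to first retained one
        onsets = np.arange(n_task) * tr
        grp = trials.frame[trials.frame["run"] == run]
        boxcars: dict[tuple[str, str], np.ndarray] = {}
        for _, row in grp.iterrows():
            t0 = float(row["block_onset_s"])
            t1 = t0 + float(row["room_s"]) + float(row["curtain_s"])  # Room+Curtain
            key = (row["sync"], row["location"])
            box = boxcars.setdefault(key, np.zeros(n_task))
            box[(onsets >= t0) & (onsets < t1)] = 1.0
        for (sync, loc), box in boxcars.items():
            if hrf is not None:
                resp = np.convolve(box, hrf)[:n_task]
            else:
                resp = np.zeros(n_task)
                d = spec.hemodynamic_delay_volumes
                if d < n_task:
                    resp[d:] = box[: n_task - d]
            if sync == SYNC:
                pat = pat_a if loc == LOC_A else pat_b
            elif spec.async_has_location_signal:
                if spec.async_swap_locations:
                    pat = pat_b if loc == LOC_A else pat_a
                else:
                    pat = pat_a if loc == LOC_A else pat_b
            else:
                pat = common
            amp = spec.pattern_amplitude
            if n_inf:
                rows = slice(run0 + acq.n_discard_initial, run0 + vols_per_run)
                signal[rows, inf_local] += np.outer(resp, amp * pat)
    info = dict(
        trials=trials,
        roi=roi,
        inf_local=inf_local,
        pattern_a=pat_a,
        pattern_b=pat_b,
    )
    return signal, inf_local, info


def generate_subject(spec: SimulationSpec) -> SyntheticSubject:
    """Full synthetic subject: baseline + drift + condition signal + noise."""
    signal_roi, inf_local, info = signal_component(spec)
    roi: ROIMask = info["roi"]
    trials: TrialTable = info["trials"]
    acq = spec.acquisition
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))

    nx, ny, nz = spec.grid_shape
    vols_per_run = spec.volumes_per_run
    T = vols_per_run * spec.n_runs
    nvox = nx * ny * nz

    # noise over the whole grid: iid or AR(1) with marginal sd noise_sd
    noise = rng.normal(scale=spec.noise_sd, size=(T, nvox))
    rho = spec.temporal_autocorr
    if rho > 0:
        innov_scale = np.sqrt(1.0 - rho**2)
        for run in range(spec.n_runs):
            r0 = run * vols_per_run
            for t in range(1, vols_per_run):
                noise[r0 + t] = rho * noise[r0 + t - 1] + innov_scale * noise[r0 + t]

    data = np.full((T, nvox), float(spec.baseline))
    data += noise
    for run in range(spec.n_runs):
        r0 = run * vols_per_run
        slope = rng.normal(scale=spec.drift_slope_sd, size=nvox)
        ramp = np.linspace(-0.5, 0.5, vols_per_run)
        data[r0 : r0 + vols_per_run] += np.outer(ramp, slope)
        # decaying non-steady-state excess on the dummy volumes
        for d in range(acq.n_discard_initial):
            data[r0 + d] += spec.baseline * 0.05 * 0.5**d

    roi_flat = np.flatnonzero(roi.data.reshape(-1))
    data[:, roi_flat] += signal_roi

    vol = Volume4D(
        data=np.ascontiguousarray(data.T.reshape(nx, ny, nz, T)),
        affine=roi.affine,
        run_lengths=[vols_per_run] * spec.n_runs,
    )
    coords = roi.voxel_coords()[inf_local] if len(inf_local) else np.zeros((0, 3), int)
    return SyntheticSubject(
        volume=vol,
        roi=roi,
        trials=trials,
        informative_coords=coords,
        pattern_a=info["pattern_a"],
        pattern_b=info["pattern_b"],
        spec=spec,
    )


def generate_null_subject(spec: SimulationSpec) -> SyntheticSubject:
    """A subject with no location information anywhere (amplitude 0)."""
    null_spec = replace(spec, pattern_amplitude=0.0, n_informative_voxels=0)
    subj = generate_subject(null_spec)
    subj.informative_coords = np.zeros((0, 3), int)
    return subj


def write_subject(subj: SyntheticSubject, out_dir: str | Path) -> dict[str, Path]:
    """Write NIfTI volume + mask, TSV trial table, and JSON ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "bold": out / "bold.nii.gz",
        "mask": out / "roi_mask.nii.gz",
        "trials": out / "trials.tsv",
        "truth": out / "ground_truth.json",
    }
    write_volume(subj.volume, paths["bold"])
    write_mask(subj.roi, paths["mask"])
    write_trial_table(subj.trials, paths["trials"])
    paths["truth"].write_text(
        json.dumps(
            {
                "informative_voxels": subj.informative_coords.tolist(),
                "pattern_a": subj.pattern_a.tolist(),
                "pattern_b": subj.pattern_b.tolist(),
                "seed": subj.spec.seed,
                "rng": "numpy PCG64 via SeedSequence([seed, stage])",
            },
            indent=2,
        )
    )
    return paths
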