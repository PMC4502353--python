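"""Subject- and group-level orchestration with deterministic seeding.

``run_subject`` takes one subject's data (real files or a synthetic
subject), runs preprocess -> searchlight -> permutation inference for the
within-SYNCHRONOUS analysis and the sync->async cross-decoding, optionally
repeats everything in control ROIs, and returns a JSON-serializable result
bundle with a provenance block. ``run_group`` applies the cross-subject
statistics battery to a list of bundles.

Seeding: every randomized stage derives its own seed from the global seed
with a fixed counter scheme (``SeedSequence([seed, stage])``), so stages
can be rerun independently and results are byte-identical across reruns.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .datatypes import (
    AcquisitionParams,
    ASYNC,
    ROIMask,
    SYNC,
    TrialResponseMatrix,
    TrialTable,
    Volume4D,
)
from .permutation import (
    PermutationConfig,
    SubregionScheme,
    assign_subregions,
    informative_voxels,
    run_permutation_test,
)
from .preprocess import PreprocConfig, preprocess_subject
from .searchlight import ClassifierSpec, build_clusters
from . import stats as group_stats

VOXEL_ALPHA = 0.001  # uncorrected threshold for descriptive voxel maps
FWE_ALPHA = 0.05


@dataclass(frozen=True)
class PipelineConfig:
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    cluster_k: int = 33
    n_permutations: int = 10_000
    subregions: SubregionScheme = field(default_factory=SubregionScheme)
    seed: int = 0
    n_jobs: int = 1  # parallelism over permutation batches; result-invariant

    def permutation_config(self) -> PermutationConfig:
        perm_seed = int(np.random.SeedSequence([self.seed, 3]).generate_state(1)[0] % (2**31))
        return PermutationConfig(n_iterations=self.n_permutations, seed=perm_seed)


def _condition_analysis(
    resp_all: TrialResponseMatrix,
    roi: ROIMask,
    cfg: PipelineConfig,
) -> dict:
    """Within-sync + sync->async cross-decoding inference for one ROI."""
    clusters = build_clusters(roi, cfg.acquisition, cfg.cluster_k)
    sync_resp = resp_all.restrict(SYNC)
    async_resp = resp_all.restrict(ASYNC)
    res_sync, res_cross = run_permutation_test(
        sync_resp,
        clusters,
        cfg.classifier,
        cfg.permutation_config(),
        transfer=async_resp,
        n_jobs=cfg.n_jobs,
    )
    world = roi.world_coords()
    out = {}
    for name, res in (("sync", res_sync), ("async_cross", res_cross)):
        idx, count = informative_voxels(res.voxel_p, VOXEL_ALPHA)
        out[name] = {
            "peak_accuracy": res.true_map.peak_accuracy,
            "peak_coordinate_mm": res.true_map.peak_coordinate(roi.affine).tolist(),
            "fwe_p": res.fwe_p,
            "significant_fwe": bool(res.fwe_p <= FWE_ALPHA),
            "n_informative": count,
            "subregion_counts": assign_subregions(world[idx], cfg.subregions),
            "null_peak_mean": float(res.null.peak_values.mean()),
        }
    return out


def run_subject(
    vol: Volume4D,
    roi: ROIMask,
    trials: TrialTable,
    cfg: PipelineConfig,
    control_rois: dict[str, ROIMask] | None = None,
    subject_id: str = "subject",
) -> dict:
    """Full single-subject pipeline; returns a JSON-serializable bundle."""
    t0 = time.time()
    resp = preprocess_subject(vol, roi, trials, cfg.acquisition, cfg.preproc)
    bundle = {
        "subject_id": subject_id,
        "hippocampus": _condition_analysis(resp, roi, cfg),
        "controls": {},
    }
    for name, mask in (control_rois or {}).items():
        resp_c = preprocess_subject(vol, roi=mask, trials=trials,
                                    acq=cfg.acquisition, cfg=cfg.preproc)
        bundle["controls"][name] = _condition_analysis(resp_c, mask, cfg)
    bundle["provenance"] = {
        "seed": cfg.seed,
        "n_permutations": cfg.n_permutations,
        "cluster_k": cfg.cluster_k,
        "config_hash": config_hash(cfg),
        "n_trials": resp.n_trials,
        "n_roi_voxels": resp.n_voxels,
        "wall_seconds": round(time.time() - t0, 3),
    }
    return bundle


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_group(bundles: list[dict]) -> dict:
    """Cross-subject statistics over subject result bundles.

    Peak accuracies sync vs async compare by paired t (or Wilcoxon when
    the differences fail the Shapiro-Wilk gate); informative-voxel counts
    by Wilcoxon signed-rank; subregion counts by the Friedman test.
    """
    if len(bundles) < 2:
        raise ValueError("group statistics need at least 2 subjects")
    peaks_sync = [b["hippocampus"]["sync"]["peak_accuracy"] for b in bundles]
    peaks_async = [b["hippocampus"]["async_cross"]["peak_accuracy"] for b in bundles]
    n_inf_sync = [b["hippocampus"]["sync"]["n_informative"] for b in bundles]
    n_inf_async = [b["hippocampus"]["async_cross"]["n_informative"] for b in bundles]
    sub_labels = ("LA", "LP", "RA", "RP")
    sub_matrix = np.array(
        [[b["hippocampus"]["sync"]["subregion_counts"][s] for s in sub_labels]
         for b in bundles],
        dtype=float,
    )
    report = {
        "n_subjects": len(bundles),
        "peak_accuracy": {
            "sync_mean": float(np.mean(peaks_sync)),
            "async_mean": float(np.mean(peaks_async)),
            "comparison": group_stats.paired_location_test(
                peaks_sync, peaks_async
            ).as_dict(),
        },
        "informative_voxels": {
            "sync_mean": float(np.mean(n_inf_sync)),
            "sync_sd": float(np.std(n_inf_sync, ddof=1)),
            "async_mean": float(np.mean(n_inf_async)),
            "async_sd": float(np.std(n_inf_async, ddof=1)),
        },
        "n_significant_sync": int(
            sum(b["hippocampus"]["sync"]["significant_fwe"] for b in bundles)
        ),
        "n_significant_async": int(
            sum(b["hippocampus"]["async_cross"]["significant_fwe"] for b in bundles)
        ),
    }
    try:
        report["informative_voxels"]["comparison"] = group_stats.wilcoxon_signed_rank(
            n_inf_sync, n_inf_async
        ).as_dict()
    except ValueError as err:  # e.g. all counts zero in a pure-null group
        report["informative_voxels"]["comparison"] = {"error": str(err)}
    try:
        report["subregions"] = {
            "labels": list(sub_labels),
            "mean_counts": sub_matrix.mean(axis=0).tolist(),
            "friedman": group_stats.friedman(sub_matrix).as_dict(),
        }
    except ValueError as err:
        report["subregions"] = {"error": str(err)}
    return report


def format_group_report(report: dict) -> str:
    """Human-readable rendering of a run_group result."""
    lines = [f"Group report ({report['n_subjects']} subjects)"]
    pk = report["peak_accuracy"]
    cmp_ = pk["comparison"]
    lines.append(
        f"  peak accuracy: sync {pk['sync_mean']:.1f}% vs async {pk['async_mean']:.1f}% "
        f"({cmp_['method']}: stat={cmp_['statistic']:.3f}, P={cmp_['pvalue']:.4g})"
    )
    iv = report["informative_voxels"]
    lines.append(
        f"  informative voxels (P<{VOXEL_ALPHA}): sync {iv['sync_mean']:.1f}+-{iv['sync_sd']:.1f}"
        f" vs async {iv['async_mean']:.1f}+-{iv['async_sd']:.1f}"
    )
    if "friedman" in report.get("subregions", {}):
        fr = report["subregions"]["friedman"]
        lines.append(
            f"  subregions {report['subregions']['labels']}: "
            f"chi2({fr['df']})={fr['statistic']:.3f}, P={fr['pvalue']:.3f}"
        )
    lines.append(
        f"  significant FWE decoding: sync {report['n_significant_sync']}"
        f"/{report['n_subjects']}, async {report['n_significant_async']}"
        f"/{report['n_subjects']}"
    )
    return "\n".join(lines)
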