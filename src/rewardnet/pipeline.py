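"""End-to-end orchestration: phantom -> tensors -> tracts -> connectome ->
metrics, plus the simulated-cohort statistics, from a single config.

Every source of randomness flows from the seeds recorded in the config,
and the config is serialized next to the outputs, so a run is fully
reproducible from config + inputs.  Stages write their outputs under the
run directory and can be skipped when their outputs already exist
(``resume=True``).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic import (PhantomSpec, CohortSpec, make_phantom, make_cohort,
                        save_phantom, load_phantom)
from .tensor import fit_tensors
from .tracking import TrackingConfig, track, save_streamlines_text
from .connectome import build_connectome, phantom_node_table, save_connectome
from .metrics import compute_subject_metrics
from .qc import log_transform_covariates
from .stats import run_model_hierarchy

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("rewardnet")


@dataclass
class RunConfig:
    """Parameters of one reproducible pipeline run."""

    out_dir: str = "rewardnet_run"
    seed: int = 0
    resume: bool = False
    # phantom stage
    phantom: dict = field(default_factory=dict)       # PhantomSpec overrides
    tensor_method: str = "ols"
    # tracking stage
    fa_threshold: float = 0.1
    angle_threshold: float = 45.0
    min_length: int = 3
    # cohort + stats stage
    cohort: dict = field(default_factory=dict)        # CohortSpec overrides
    alpha: float = 0.05
    qc_k: float = 2.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))


def _stage_done(resume: bool, *paths: Path) -> bool:
    return resume and all(p.exists() for p in paths)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in order; returns the run summary (also written as
    ``run_summary.json`` in the output directory).

    A failure in any stage raises with the stage name in the message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    stage = "phantom"
    try:
        spec = PhantomSpec(**{"seed": config.seed, **config.phantom})
        acq, parc, truth = make_phantom(spec)
        save_phantom(acq, parc, truth, out / "phantom", spec)
        summary["stages"][stage] = {
            "geometry": spec.geometry,
            "n_bundle_voxels": len(truth.bundle_voxels),
            "expected_bundle_fa": truth.expected_bundle_fa,
        }

        stage = "tensor"
        field_ = fit_tensors(acq, method=config.tensor_method,
                             fit_mask=acq.wm_mask | (parc > 0))
        _save_scalar_maps(field_, acq.voxel_size, out / "tensor")
        summary["stages"][stage] = {
            "method": config.tensor_method,
            "n_defined": int(field_.defined.sum()),
            "n_flagged": len(field_.flagged_voxels),
        }

        stage = "tracking"
        cfg = TrackingConfig(fa_threshold=config.fa_threshold,
                             angle_threshold=config.angle_threshold,
                             min_length=config.min_length)
        mask = acq.wm_mask | (parc > 0)
        streams = track(field_, mask, cfg, seed_mask=acq.wm_mask)
        save_streamlines_text(streams, out / "streamlines.txt")
        summary["stages"][stage] = {"n_seeds": streams.n_seeds,
                                    "n_streamlines": len(streams)}

        stage = "connectome"
        nodes = phantom_node_table(truth.end_region_labels)
        conn = build_connectome(streams, parc, field_.fa, nodes)
        save_connectome(conn, out / "connectome")
        n_edges = int((np.triu(conn.nos, k=1) > 0).sum())
        summary["stages"][stage] = {"n_nodes": len(nodes), "n_edges": n_edges}

        stage = "metrics"
        if n_edges == 0:
            summary["stages"][stage] = {
                "usable": False,
                "note": "empty connectome (no streamlines connect any node "
                        "pair); network metrics undefined",
            }
            log.warning("metrics stage: empty connectome, metrics skipped")
        else:
            row = compute_subject_metrics(conn)
            row.to_frame().T.to_csv(out / "phantom_metrics.csv", index=False)
            summary["stages"][stage] = {"usable": True,
                                        "n_metrics": int(row.notna().sum())}

        stage = "cohort"
        cspec = CohortSpec(**{"seed": config.seed + 1, **config.cohort})
        cohort = log_transform_covariates(make_cohort(cspec))
        cohort.to_csv(out / "cohort.csv", index=False)
        summary["stages"][stage] = {"n": len(cohort)}

        stage = "stats"
        hier = run_model_hierarchy(cohort, alpha=config.alpha)
        hier.results.to_csv(out / "stats.csv", index=False)
        summary["stages"][stage] = {
            "n_results": len(hier.results),
            "alpha_network": hier.alpha_network,
            "alpha_node": hier.alpha_node,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    log.info("pipeline complete: %s", out)
    return summary


def _save_scalar_maps(field_, voxel_size: float, out_dir: Path) -> None:
    import nibabel as nib

    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(field_.fa.astype(np.float32), affine),
             out_dir / "fa.nii")
    nib.save(nib.Nifti1Image(field_.v1.astype(np.float32), affine),
             out_dir / "v1.nii")
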