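"""End-to-end orchestration: preprocess -> [external SfM] -> clean -> mesh -> localize.

The external incremental-SfM tool is invoked by the *user*, never by this
package; the pipeline consumes its sparse-model output directory (or a
synthetic reconstruction) and persists every intermediate stage — the P',
P-hat and P-tilde clouds, cleaning/dedup reports, the mesh — together with
the fully serialised configuration and seed, so a run is reproducible from
its output directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io_formats, meshing, outlier_removal
from .frame_preprocess import DedupConfig, DedupReport, remove_duplicates
from .outlier_removal import CleaningConfig, CleaningReport, PointCloudStage
from .synthetic_data import PointLabel, SyntheticScene

__all__ = ["PipelineConfig", "EvalReport", "run_pipeline", "evaluate"]

log = logging.getLogger("gastro3d")


@dataclass
class PipelineConfig:
    """All stage parameters plus paths and the run seed.

    Defaults are the published operating point: phi = 0.6 for dedup,
    A = 0.05, M = 80, B = 5 for cleaning, retrieval N = 100.
    """

    dedup: DedupConfig = field(default_factory=DedupConfig)
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    mesh_depth: int = 7
    retrieval_n: int = 100
    retrieval_method: str = "downsample"
    sparse_dir: str | None = None
    frames_dir: str | None = None
    out_dir: str = "gastro3d_out"
    seed: int = 0
    run_dedup: bool = False
    transfer_colors: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("dedup"), dict):
            d["dedup"] = DedupConfig(**d["dedup"])
        if isinstance(d.get("cleaning"), dict):
            d["cleaning"] = CleaningConfig(**d["cleaning"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class EvalReport:
    """Cleaning quality against synthetic ground-truth labels.

    With removal as the positive decision: ``outlier_precision`` =
    TP/(TP+FP) and ``outlier_recall`` = TP/(TP+FN) over planted outliers.
    ``inlier_precision`` is the purity of the kept cloud — the fraction of
    kept points that are true inliers — which is what "the final cloud is
    free from outliers" means operationally.  ``surface_rmse`` is the RMS
    analytic-surface distance of the kept points (scene units).
    """

    outlier_precision: float
    outlier_recall: float
    inlier_precision: float
    surface_rmse: float
    dedup_exact_match: bool | None = None

    def to_dict(self) -> dict:
        return {
            "outlier_precision": self.outlier_precision,
            "outlier_recall": self.outlier_recall,
            "inlier_precision": self.inlier_precision,
            "surface_rmse": self.surface_rmse,
            "dedup_exact_match": self.dedup_exact_match,
        }


def _stage_log(fh, stage: str, **info) -> None:
    rec = {"stage": stage, **info}
    fh.write(json.dumps(rec) + "\n")
    log.info("%s: %s", stage, info)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages in order, persisting every intermediate.

    Requires a sparse-model directory (``config.sparse_dir``).  Returns the
    artifact directory.  A stage failure raises after partial state has been
    persisted.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    logf = open(out / "stages.jsonl", "w")

    try:
        if config.sparse_dir is None:
            raise ValueError("pipeline requires sparse_dir (external SfM output)")
        sparse_dir = Path(config.sparse_dir)
        if not sparse_dir.is_dir():
            raise FileNotFoundError(f"sparse model directory does not exist: {sparse_dir}")

        dedup_report = None
        if config.run_dedup:
            if config.frames_dir is None:
                raise ValueError("run_dedup requires frames_dir")
            seq = io_formats.read_frame_dir(config.frames_dir, channel="R")
            kept, dedup_report = remove_duplicates(seq, config.dedup)
            with open(out / "dedup_report.json", "w") as fh:
                json.dump(dedup_report.to_dict(), fh, indent=1)
            _stage_log(logf, "dedup", n_in=len(seq) + 0, n_kept=len(kept))

        recon = io_formats.read_colmap_sparse(sparse_dir)
        _stage_log(
            logf, "read_sparse", n_frames=len(recon.frames), n_points=len(recon.points)
        )

        cleaned, report = outlier_removal.run_outlier_removal(recon, config.cleaning)
        xyz, ids = recon.point_array()
        io_formats.write_ply_points(out / "P.ply", xyz)
        removed = report.removed_per_stage
        kept_ids = set(cleaned.ids.tolist())
        # persist each intermediate stage cloud
        pp_ids = [i for i in ids if i not in set(removed.get("P_prime", []))]
        ph_ids = [i for i in pp_ids if i not in set(removed.get("P_hat", []))]
        id_to_xyz = {int(i): x for i, x in zip(ids, xyz)}
        io_formats.write_ply_points(out / "P_prime.ply", np.array([id_to_xyz[int(i)] for i in pp_ids]))
        io_formats.write_ply_points(out / "P_hat.ply", np.array([id_to_xyz[int(i)] for i in ph_ids]))
        io_formats.write_ply_points(out / "P_tilde.ply", cleaned.points)
        with open(out / "cleaning_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
        _stage_log(
            logf,
            "clean",
            n_in=len(ids),
            n_P_prime=len(pp_ids),
            n_P_hat=len(ph_ids),
            n_P_tilde=len(cleaned),
            avg_D=report.avg_D,
            sigma=report.sigma,
        )

        normals = meshing.estimate_normals(cleaned.points, k=min(100, max(3, len(cleaned) - 1)))
        oriented = meshing.orient_normals(cleaned, normals, recon)
        smoothed = meshing.smooth_normals(cleaned.points, oriented)
        mesh = meshing.reconstruct_surface(cleaned.points, smoothed, depth=config.mesh_depth)
        mesh.vertex_normals = mesh.compute_vertex_normals()
        if config.transfer_colors and config.frames_dir is not None:
            frames = io_formats.read_frame_dir(config.frames_dir, channel="RGB")
            fid_sorted = sorted(recon.frames)
            if len(frames) == len(fid_sorted):
                frames.indices = list(fid_sorted)
            mesh = meshing.transfer_vertex_colors(mesh, recon, frames)
        io_formats.write_ply_mesh(out / "model.ply", mesh)
        _stage_log(logf, "mesh", n_vertices=len(mesh.vertices), n_faces=len(mesh.faces))
    finally:
        logf.close()
    return out


def evaluate(
    scene: SyntheticScene,
    cleaned: PointCloudStage,
    dedup: DedupReport | None = None,
    dedup_truth: list[int] | None = None,
) -> EvalReport:
    """Score a cleaning result against the scene's planted labels."""
    n = len(scene.points)
    kept = np.zeros(n, dtype=bool)
    kept[cleaned.ids] = True
    if len(cleaned.ids) and (cleaned.ids.max() >= n or cleaned.ids.min() < 0):
        raise ValueError("cleaned ids do not align with scene points")

    is_out = scene.outlier_mask
    tp = int((~kept & is_out).sum())  # outlier removed
    fp = int((~kept & ~is_out).sum())  # inlier removed
    fn = int((kept & is_out).sum())  # outlier kept
    outlier_precision = tp / (tp + fp) if tp + fp else float("nan")
    outlier_recall = tp / (tp + fn) if tp + fn else float("nan")
    kept_true = int((kept & ~is_out).sum())
    inlier_precision = kept_true / kept.sum() if kept.sum() else float("nan")

    kept_pts = scene.points[kept]
    if len(kept_pts):
        surface_rmse = float(np.sqrt(np.mean(scene.surface.signed_distance(kept_pts) ** 2)))
    else:
        surface_rmse = float("nan")

    dedup_match = None
    if dedup is not None and dedup_truth is not None:
        dedup_match = list(dedup.kept_indices) == list(dedup_truth)

    return EvalReport(
        outlier_precision=outlier_precision,
        outlier_recall=outlier_recall,
        inlier_precision=inlier_precision,
        surface_rmse=surface_rmse,
        dedup_exact_match=dedup_match,
    )
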