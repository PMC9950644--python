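"""End-to-end orchestration: scenes -> masks -> features -> screening -> models.

One configuration drives the whole chain.  A single global seed is fanned
out to each stage by hashing the stage name, so any stage can be re-run in
isolation and reproduces bit-identically.  Every artifact is written under
the output directory and checksummed into a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from canopysc import features as feat
from canopysc import regression as reg
from canopysc import segmentation as seg
from canopysc import subset_selection as subsel
from canopysc import synthetic

logger = logging.getLogger("canopysc.pipeline")


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one full run on synthetic scenes."""

    outdir: str = "runs/default"
    seed: int = 0
    n_scenes: int = 30
    scene: synthetic.SceneConfig = field(default_factory=synthetic.SceneConfig)
    segmentation_method: str = "hsv"          # hsv | otsu_vi
    segmentation_vi: str = "EXG"              # for otsu_vi
    compare_all_methods: bool = True          # also score HSV + all 7 VI-Otsu variants
    glcm: feat.GlcmConfig = field(default_factory=feat.GlcmConfig)
    train_fraction: float = 0.7
    stratify: bool = True
    screen_max_size: int | None = 6
    sc_table_path: str | None = None          # override: load Sc from CSV instead

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scene_raw = raw.pop("scene", {})
        glcm_raw = raw.pop("glcm", {})
        scene_kwargs = dict(scene_raw)
        if "image_size" in scene_kwargs:
            scene_kwargs["image_size"] = tuple(scene_kwargs["image_size"])
        if "stress_assignment" in scene_kwargs:
            scene_kwargs["stress_assignment"] = tuple(scene_kwargs["stress_assignment"])
        cfg = cls(**raw)
        cfg.scene = dataclasses.replace(synthetic.SceneConfig(), **scene_kwargs)
        cfg.glcm = dataclasses.replace(feat.GlcmConfig(), **glcm_raw)
        return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(cfg: RunConfig) -> dict:
    """Execute all stages and return the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "artifacts": {}}
    artifacts: dict[str, Path] = {}

    def _stage(name: str):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                if exc is not None:
                    logger.error("stage %s failed after %.2fs: %s", name, dt, exc)
                    raise PipelineError(name, exc) from exc
                manifest["stages"][name] = {"seconds": round(dt, 3)}
                logger.info("stage %s finished in %.2fs", name, dt)
                return False

        return _Ctx()

    # --- scenes -----------------------------------------------------------
    with _stage("generate_scenes"):
        scenes = synthetic.generate_scene_batch(
            cfg.n_scenes, seed=stage_seed(cfg.seed, "scenes"), cfg=cfg.scene
        )

    # --- stomatal conductance table ---------------------------------------
    with _stage("sc_table"):
        if cfg.sc_table_path is not None:
            sc_table = pd.read_csv(cfg.sc_table_path)
            need = {"tree_id", "stress", "sc"}
            if not need.issubset(sc_table.columns):
                raise ValueError(f"Sc table must have columns {sorted(need)}")
        else:
            sc_table = pd.concat([s.sc_table() for s in scenes], ignore_index=True)
        all_ids = sorted(
            int(t) for s in scenes for t in np.unique(s.labels) if t > 0
        )
        known = set(sc_table["tree_id"].astype(int))
        missing = [t for t in all_ids if t not in known]
        if missing:
            raise ValueError(
                f"build_feature_table would fail: missing Sc for trees {missing}"
            )
        p = outdir / "sc_table.csv"
        sc_table.to_csv(p, index=False)
        artifacts["sc_table"] = p

    # --- segmentation ------------------------------------------------------
    with _stage("segmentation"):
        masks = []
        score_rows = []
        methods: list[tuple[str, str | None]] = [("hsv", None)]
        if cfg.compare_all_methods:
            methods += [("otsu_vi", vi) for vi in seg.VISIBLE_VI_NAMES]
        for i, scene in enumerate(scenes):
            per_scene = {}
            for method, vi in methods:
                if method == "hsv":
                    m = seg.hsv_segment(scene.rgb)
                else:
                    m = seg.otsu_vi_segment(scene.rgb, vi)
                per_scene[(method, vi)] = m
                if scene.truth_mask is not None:
                    s = seg.score_mask(m, scene.truth_mask)
                    score_rows.append(
                        {"scene": i, "method": method, "vi": vi or "",
                         "iou": s.iou, "acc": s.acc / 100.0, "mcc": s.mcc}
                    )
            chosen = (
                ("hsv", None)
                if cfg.segmentation_method == "hsv"
                else ("otsu_vi", cfg.segmentation_vi)
            )
            masks.append(per_scene[chosen].mask)
        if score_rows:
            df = pd.DataFrame(score_rows)
            summary = (
                df.groupby(["method", "vi"], as_index=False)[["iou", "acc", "mcc"]]
                .mean()
                .sort_values("mcc", ascending=False)
            )
            p = outdir / "segmentation_scores.csv"
            summary.to_csv(p, index=False)
            artifacts["segmentation_scores"] = p

    # --- features -----------------------------------------------------------
    with _stage("features"):
        table = feat.build_feature_table(scenes, masks, sc_table, cfg.glcm)
        p = outdir / "features.csv"
        table.to_csv(p, index=False)
        artifacts["features"] = p

    # --- correlations --------------------------------------------------------
    with _stage("correlations"):
        corr = feat.correlation_table(table)
        p = outdir / "correlations.csv"
        corr.to_csv(p, index=False)
        artifacts["correlations"] = p

    # --- subset screening ------------------------------------------------------
    with _stage("screening"):
        from canopysc.features import COMBINED_POOL, TEXTURE_POOL, VI_POOL

        pools = {"vis": VI_POOL, "texture": TEXTURE_POOL, "combined": COMBINED_POOL}
        reports = {
            name: subsel.full_subset_screen(
                table, pool, max_size=(
                    None if cfg.screen_max_size is None
                    else min(cfg.screen_max_size, len(pool))
                ),
                relative_to_null=True,
            )
            for name, pool in pools.items()
        }
        summary = subsel.screening_summary(reports)
        p = outdir / "screening.csv"
        summary.to_csv(p, index=False)
        artifacts["screening"] = p
        screened_sets = {
            name: list(rep.overall_best.subset) for name, rep in reports.items()
        }

    # --- model grid --------------------------------------------------------------
    with _stage("models"):
        split_spec = reg.SplitSpec(
            train_fraction=cfg.train_fraction,
            seed=stage_seed(cfg.seed, "split"),
            stratify_by="stress" if cfg.stratify else None,
        )
        feature_sets = {
            "vi": screened_sets["vis"],
            "texture": screened_sets["texture"],
            "combined": screened_sets["combined"],
        }
        grid = reg.run_model_grid(table, split_spec, feature_sets)
        summary = reg.grid_summary(grid)
        p = outdir / "model_grid.csv"
        summary.to_csv(p, index=False)
        artifacts["model_grid"] = p
        preds = []
        for r in grid:
            for part, y, yhat in (
                ("train", r.train_y, r.train_pred),
                ("validation", r.val_y, r.val_pred),
            ):
                for yy, pp_ in zip(y, yhat):
                    preds.append(
                        {"model": r.model.family, "feature_set": r.feature_set,
                         "partition": part, "measured": yy, "predicted": pp_}
                    )
        p = outdir / "predictions.csv"
        pd.DataFrame(preds).to_csv(p, index=False)
        artifacts["predictions"] = p

    manifest["artifacts"] = {k: {"path": str(v), "sha256": _sha256(v)} for k, v in artifacts.items()}
    manifest["stage_seeds"] = {
        s: stage_seed(cfg.seed, s) for s in ("scenes", "split")
    }
    import canopysc

    manifest["version"] = canopysc.__version__
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
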