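"""Reading and writing scenes and tables.

A scene on disk is: a multi-band TIFF (band order 560, 650, 725, 808 nm),
an RGB PNG composite, an optional mask PNG ({0, 255}), a stomatal
conductance CSV (tree_id, stress, sc) and a YAML sidecar recording the
generating configuration, panel geometry and seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from canopysc.synthetic import BANDS, SceneConfig, SpectralScene


def write_scene(scene: SpectralScene, outdir: str | Path, stem: str = "scene",
                cfg: SceneConfig | None = None) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    stack = np.stack([scene.bands[b] for b in BANDS])
    tif = outdir / f"{stem}.tif"
    kw = dict(photometric="minisblack", planarconfig="separate")
    if scene.units == "dn":
        tifffile.imwrite(tif, stack.astype(np.uint16), **kw)
    else:
        tifffile.imwrite(tif, stack.astype(np.float32), **kw)
    paths["bands"] = tif

    rgb8 = np.clip(np.rint(scene.rgb * 255), 0, 255).astype(np.uint8)
    paths["rgb"] = outdir / f"{stem}_rgb.png"
    iio.imwrite(paths["rgb"], rgb8)

    if scene.truth_mask is not None:
        paths["mask"] = outdir / f"{stem}_mask.png"
        iio.imwrite(paths["mask"], (scene.truth_mask * 255).astype(np.uint8))
    if scene.labels is not None:
        paths["labels"] = outdir / f"{stem}_labels.tif"
        tifffile.imwrite(paths["labels"], scene.labels.astype(np.int32))
    if scene.truth_sc is not None:
        paths["sc"] = outdir / f"{stem}_sc.csv"
        scene.sc_table().to_csv(paths["sc"], index=False)

    sidecar: dict = {
        "bands_nm": list(BANDS),
        "units": scene.units,
        "panel_region": list(scene.panel_region),
        "panel_reflectance": {int(k): float(v) for k, v in (scene.panel_reflectance or {}).items()},
    }
    if cfg is not None:
        d = dataclasses.asdict(cfg)
        d["image_size"] = list(cfg.image_size)
        d["stress_assignment"] = list(cfg.stress_assignment)
        d["band_means"] = {k: {int(b): float(x) for b, x in v.items()} for k, v in cfg.band_means.items()}
        d["soil_means"] = {int(b): float(x) for b, x in cfg.soil_means.items()}
        if isinstance(cfg.panel_reflectance, Mapping):
            d["panel_reflectance"] = {int(b): float(x) for b, x in cfg.panel_reflectance.items()}
        sidecar["config"] = d
    paths["sidecar"] = outdir / f"{stem}.yaml"
    with open(paths["sidecar"], "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    return paths


def read_scene(outdir: str | Path, stem: str = "scene") -> SpectralScene:
    outdir = Path(outdir)
    with open(outdir / f"{stem}.yaml") as fh:
        sidecar = yaml.safe_load(fh)
    stack = tifffile.imread(outdir / f"{stem}.tif")
    bands = {b: stack[i].astype(float) for i, b in enumerate(sidecar["bands_nm"])}
    units = sidecar["units"]
    if units == "dn":
        bands = {b: a.astype(np.uint16) for b, a in bands.items()}
    rgb = iio.imread(outdir / f"{stem}_rgb.png").astype(float) / 255.0

    mask_path = outdir / f"{stem}_mask.png"
    truth_mask = None
    if mask_path.exists():
        truth_mask = (iio.imread(mask_path) > 127).astype(np.uint8)
    labels_path = outdir / f"{stem}_labels.tif"
    labels = tifffile.imread(labels_path) if labels_path.exists() else None

    truth_sc = stress_of_tree = None
    sc_path = outdir / f"{stem}_sc.csv"
    if sc_path.exists():
        df = pd.read_csv(sc_path)
        truth_sc = dict(zip(df["tree_id"].astype(int), df["sc"].astype(float)))
        stress_of_tree = dict(zip(df["tree_id"].astype(int), df["stress"]))

    panel_refl = sidecar.get("panel_reflectance") or None
    if panel_refl:
        panel_refl = {int(k): float(v) for k, v in panel_refl.items()}
    return SpectralScene(
        bands=bands,
        rgb=rgb,
        panel_region=tuple(sidecar["panel_region"]),
        units=units,
        truth_mask=truth_mask,
        labels=labels,
        truth_sc=truth_sc,
        stress_of_tree=stress_of_tree,
        panel_reflectance=panel_refl,
    )
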